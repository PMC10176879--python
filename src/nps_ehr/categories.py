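"""The 13 neuropsychiatric-symptom categories used throughout the package.

Twelve categories correspond one-to-one to NPI domains; ``NPS_GENERAL``
collects nonspecific descriptions of behavioural change and has no NPI
counterpart.
"""

from __future__ import annotations

import enum


class NpsCategory(str, enum.Enum):
    DELUSIONS = "delusions"
    HALLUCINATIONS = "hallucinations"
    AGITATION = "agitation"
    DEPRESSION = "depression"
    ANXIETY = "anxiety"
    EUPHORIA = "euphoria"
    APATHY = "apathy"
    DISINHIBITION = "disinhibition"
    IRRITABILITY = "irritability"
    ABERRANT_MOTOR_BEHAVIOR = "aberrant_motor_behavior"
    SLEEPING_BEHAVIOR = "sleeping_behavior"
    EATING_BEHAVIOR = "eating_behavior"
    NPS_GENERAL = "nps_general"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Categories in canonical column order.
ALL_CATEGORIES: tuple[NpsCategory, ...] = tuple(NpsCategory)

#: The 12 categories that map onto NPI domains (everything but nps_general).
NPI_DOMAINS: tuple[NpsCategory, ...] = tuple(
    c for c in NpsCategory if c is not NpsCategory.NPS_GENERAL
)

#: Common alternative spellings seen in annotation guidelines.
DEFAULT_CATEGORY_SYNONYMS: dict[str, NpsCategory] = {
    "amb": NpsCategory.ABERRANT_MOTOR_BEHAVIOR,
    "aberrant motor behavior": NpsCategory.ABERRANT_MOTOR_BEHAVIOR,
    "aberrant_motor_behaviour": NpsCategory.ABERRANT_MOTOR_BEHAVIOR,
    "motor": NpsCategory.ABERRANT_MOTOR_BEHAVIOR,
    "nps general": NpsCategory.NPS_GENERAL,
    "nps": NpsCategory.NPS_GENERAL,
    "general": NpsCategory.NPS_GENERAL,
    "sleep": NpsCategory.SLEEPING_BEHAVIOR,
    "sleeping": NpsCategory.SLEEPING_BEHAVIOR,
    "sleeping behavior": NpsCategory.SLEEPING_BEHAVIOR,
    "eating": NpsCategory.EATING_BEHAVIOR,
    "eating behavior": NpsCategory.EATING_BEHAVIOR,
    "elation": NpsCategory.EUPHORIA,
}


def resolve_category(
    name: str, synonyms: dict[str, NpsCategory] | None = None
) -> NpsCategory:
    """Map a label string onto a :class:`NpsCategory`, case-insensitively.

    Parameters
    ----------
    name:
        Raw label as it appears in an annotation file.
    synonyms:
        Optional extra mapping applied after the canonical names fail;
        defaults to :data:`DEFAULT_CATEGORY_SYNONYMS`.

    Raises
    ------
    KeyError
        If the name matches neither a canonical category nor a synonym.
        The message lists the valid names.
    """
    key = name.strip().lower().replace("-", "_")
    try:
        return NpsCategory(key)
    except ValueError:
        pass
    table = DEFAULT_CATEGORY_SYNONYMS if synonyms is None else synonyms
    lowered = {k.lower(): v for k, v in table.items()}
    if key in lowered:
        return lowered[key]
    if key.replace("_", " ") in lowered:
        return lowered[key.replace("_", " ")]
    valid = ", ".join(c.value for c in NpsCategory)
    raise KeyError(
        f"unknown NPS category {name!r}; valid names are: {valid}"
    )
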