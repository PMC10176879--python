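"""Synthetic clinical-note corpus with known ground truth.

Generates patient-level note clusters containing lexical cue phrases for 13
NPS categories, optionally inside negations, together with gold labels,
paired imperfect annotator views, and NPI-style proxy assessments. All
generators are deterministic given the config seed, so every downstream
stage (preprocessing, classification, prevalence, agreement) can be tested
against known parameters.
"""

from __future__ import annotations

import dataclasses
import datetime
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .categories import ALL_CATEGORIES, NPI_DOMAINS, NpsCategory

#: Cue phrases per category. Each phrase is at most three tokens so the
#: default negation window removes it entirely; vocabulary is disjoint from
#: the background word stock and across categories.
DEFAULT_CUE_LEXICON: dict[NpsCategory, list[str]] = {
    NpsCategory.DELUSIONS: ["paranoid delusions", "delusional beliefs"],
    NpsCategory.HALLUCINATIONS: ["visual hallucinations", "hearing voices"],
    NpsCategory.AGITATION: ["agitated behavior", "verbally aggressive"],
    NpsCategory.DEPRESSION: ["depressive symptoms", "low mood"],
    NpsCategory.ANXIETY: ["anxious feelings", "panic episodes"],
    NpsCategory.EUPHORIA: ["euphoric mood", "inappropriate elation"],
    NpsCategory.APATHY: ["loss of initiative", "apathetic presentation"],
    NpsCategory.DISINHIBITION: ["disinhibited remarks", "socially inappropriate"],
    NpsCategory.IRRITABILITY: ["irritable outbursts", "short tempered"],
    NpsCategory.ABERRANT_MOTOR_BEHAVIOR: ["constant pacing", "repetitive rummaging"],
    NpsCategory.SLEEPING_BEHAVIOR: ["disturbed sleep", "nocturnal wandering"],
    NpsCategory.EATING_BEHAVIOR: ["increased appetite", "eating excessively"],
    NpsCategory.NPS_GENERAL: ["behavioral changes", "challenging behavior"],
}

DEFAULT_NEGATION_CUES: tuple[str, ...] = ("no", "denies", "without")

# Neutral boilerplate; deliberately free of cue words and negation cues.
_BOILERPLATE = (
    "patient seen at the memory clinic",
    "history obtained from partner",
    "neurological examination performed",
    "mmse score recorded",
    "medication reviewed",
    "follow up planned",
)


@dataclass
class SyntheticConfig:
    """Parameters governing corpus, annotator, and NPI generation."""

    n_patients: int = 100
    true_prevalence: dict[NpsCategory, float] = field(
        default_factory=lambda: {c: 0.3 for c in ALL_CATEGORIES}
    )
    cue_lexicon: dict[NpsCategory, list[str]] = field(
        default_factory=lambda: {k: list(v) for k, v in DEFAULT_CUE_LEXICON.items()}
    )
    negation_rate: float = 0.1
    negation_cues: tuple[str, ...] = DEFAULT_NEGATION_CUES
    background_vocab_size: int = 200
    notes_per_patient: int = 2
    note_span_days: int = 90
    tokens_per_note: int = 30
    center: str = "A"
    annotator_sensitivity: dict[str, float] = field(
        default_factory=lambda: {"rater_a": 0.9, "rater_b": 0.85}
    )
    annotator_specificity: dict[str, float] = field(
        default_factory=lambda: {"rater_a": 0.95, "rater_b": 0.9}
    )
    npi_report_prob_given_present: float = 0.6
    npi_report_prob_given_absent: float = 0.05
    npi_availability: float = 1.0
    #: when False, gold labels are drawn but no positive cue sentences are
    #: written into the text — a pure-noise corpus for null calibration
    insert_cues: bool = True
    seed: int = 13

    def __post_init__(self) -> None:
        self.true_prevalence = {NpsCategory(k): float(v) for k, v in self.true_prevalence.items()}
        self.cue_lexicon = {NpsCategory(k): list(v) for k, v in self.cue_lexicon.items()}
        self.validate()

    def validate(self) -> None:
        if self.n_patients <= 0:
            raise ValueError("n_patients must be positive")
        if self.notes_per_patient < 1:
            raise ValueError("notes_per_patient must be >= 1")
        if self.background_vocab_size <= 0:
            raise ValueError("background_vocab_size must be positive")
        probs = {
            "negation_rate": self.negation_rate,
            "npi_report_prob_given_present": self.npi_report_prob_given_present,
            "npi_report_prob_given_absent": self.npi_report_prob_given_absent,
            "npi_availability": self.npi_availability,
        }
        for cat, p in self.true_prevalence.items():
            probs[f"true_prevalence[{cat}]"] = p
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {p}")
        for table, label in (
            (self.annotator_sensitivity, "annotator_sensitivity"),
            (self.annotator_specificity, "annotator_specificity"),
        ):
            for rater, p in table.items():
                if not 0.0 < p <= 1.0:
                    raise ValueError(f"{label}[{rater}] must lie in (0, 1], got {p}")
        if set(self.annotator_sensitivity) != set(self.annotator_specificity):
            raise ValueError("sensitivity and specificity must name the same raters")
        for cat, p in self.true_prevalence.items():
            if p > 0 and not self.cue_lexicon.get(cat):
                raise ValueError(
                    f"category {cat} has prevalence {p} > 0 but no cue phrases"
                )


@dataclass
class Document:
    """One patient-level cluster of free-text note sections."""

    doc_id: str
    patient_id: str
    center: str
    text: str
    note_dates: list[datetime.date]
    #: (category, start, end) offsets of non-negated cue phrases, tracked at
    #: generation time so brat exports need no re-search of the text.
    cue_spans: list[tuple[NpsCategory, int, int]] = field(
        default_factory=list, repr=False
    )

    def __post_init__(self) -> None:
        if self.note_dates:
            span = (max(self.note_dates) - min(self.note_dates)).days
            if span > 366:
                raise ValueError(f"note dates of {self.doc_id} span {span} days")


def _rng(config: SyntheticConfig, stream: int) -> np.random.Generator:
    # Independent streams per stage so regenerating one stage does not
    # perturb the others.
    return np.random.default_rng([config.seed, stream])


def generate_corpus(
    config: SyntheticConfig,
) -> tuple[list[Document], pd.DataFrame]:
    """Generate documents and their gold label matrix.

    Gold labels are drawn independently per category as
    Bernoulli(true_prevalence). Gold-positive documents contain at least one
    non-negated cue phrase for the category; gold-negative documents contain
    none, though either may contain a negated cue at ``negation_rate``.
    Identical config and seed yield byte-identical output.
    """
    config.validate()
    rng = _rng(config, 0)
    vocab = [f"bg{w:04d}" for w in range(config.background_vocab_size)]
    categories = list(ALL_CATEGORIES)
    prev = np.array([config.true_prevalence.get(c, 0.0) for c in categories])

    gold = (rng.random((config.n_patients, len(categories))) < prev).astype(np.int8)

    documents: list[Document] = []
    base_date = datetime.date(2016, 1, 1)
    for i in range(config.n_patients):
        patient_id = f"P{i:05d}"
        doc_id = f"{config.center}-{patient_id}"
        sentences: list[tuple[str, NpsCategory | None, str | None]] = []
        for _ in range(config.notes_per_patient):
            sentences.append((rng.choice(len(_BOILERPLATE)), None, None))
            n_bg = max(1, config.tokens_per_note // 6)
            for _ in range(n_bg):
                words = rng.choice(config.background_vocab_size, size=6)
                sentences.append((" ".join(vocab[w] for w in words), None, None))
        # replace boilerplate indices drawn above by their strings
        sentences = [
            (_BOILERPLATE[s] if isinstance(s, (int, np.integer)) else s, c, p)
            for s, c, p in sentences
        ]
        for j, cat in enumerate(categories):
            lexicon = config.cue_lexicon.get(cat, [])
            if gold[i, j] and config.insert_cues:
                n_mentions = 1 + int(rng.integers(0, 2))
                for _ in range(n_mentions):
                    phrase = lexicon[int(rng.integers(0, len(lexicon)))]
                    sentences.append(("shows " + phrase, cat, phrase))
            if lexicon and rng.random() < config.negation_rate:
                phrase = lexicon[int(rng.integers(0, len(lexicon)))]
                neg = config.negation_cues[int(rng.integers(0, len(config.negation_cues)))]
                sentences.append((f"{neg} {phrase}", None, None))
        order = rng.permutation(len(sentences))
        text_parts: list[str] = []
        cue_spans: list[tuple[NpsCategory, int, int]] = []
        offset = 0
        for k in order:
            sent, cat, phrase = sentences[int(k)]
            rendered = sent.capitalize() + "."
            if cat is not None and phrase is not None:
                start = offset + len(rendered) - 1 - len(phrase)
                cue_spans.append((cat, start, start + len(phrase)))
            text_parts.append(rendered)
            offset += len(rendered) + 1
        text = " ".join(text_parts)

        offsets = np.sort(
            rng.integers(0, config.note_span_days + 1, size=config.notes_per_patient)
        )
        first = base_date + datetime.timedelta(days=int(rng.integers(0, 1500)))
        dates = [first + datetime.timedelta(days=int(d)) for d in offsets]
        documents.append(
            Document(doc_id, patient_id, config.center, text, dates, cue_spans)
        )

    labels = pd.DataFrame(
        gold,
        index=pd.Index([d.doc_id for d in documents], name="doc_id"),
        columns=[c.value for c in categories],
    )
    return documents, labels


def generate_annotator_views(
    gold: pd.DataFrame, config: SyntheticConfig
) -> tuple[pd.DataFrame, ...]:
    """Produce per-rater document-level label matrices.

    Each rater's label is the gold label flipped independently per
    document/category with rates ``1 - sensitivity`` (on positives) and
    ``1 - specificity`` (on negatives); raters are conditionally independent
    given gold.
    """
    config.validate()
    rng = _rng(config, 1)
    views = []
    for rater in sorted(config.annotator_sensitivity):
        sens = config.annotator_sensitivity[rater]
        spec = config.annotator_specificity[rater]
        u = rng.random(gold.shape)
        arr = gold.to_numpy()
        noisy = np.where(arr == 1, (u < sens), (u >= spec)).astype(np.int8)
        view = pd.DataFrame(noisy, index=gold.index, columns=gold.columns)
        view.attrs["rater_id"] = rater
        views.append(view)
    return tuple(views)


def generate_npi_assessments(
    gold: pd.DataFrame,
    config: SyntheticConfig,
    patient_ids: pd.Series | list[str] | None = None,
) -> pd.DataFrame:
    """Generate a long-format NPI domain-score table from gold labels.

    A domain scores > 0 with probability ``npi_report_prob_given_present``
    when gold is positive and ``npi_report_prob_given_absent`` otherwise;
    reported scores are uniform on {1..12}. The ``available`` flag simulates
    partial NPI coverage at rate ``npi_availability``.
    """
    config.validate()
    rng = _rng(config, 2)
    if patient_ids is None:
        patient_ids = list(gold.index)
    domains = [c.value for c in NPI_DOMAINS]
    records = []
    for row_idx, pid in enumerate(patient_ids):
        available = bool(rng.random() < config.npi_availability)
        for d in domains:
            g = int(gold.iloc[row_idx][d]) if d in gold.columns else 0
            p = (
                config.npi_report_prob_given_present
                if g
                else config.npi_report_prob_given_absent
            )
            reported = rng.random() < p
            score = int(rng.integers(1, 13)) if reported else 0
            records.append(
                {"patient_id": pid, "domain": d, "score": score, "available": available}
            )
    return pd.DataFrame.from_records(records)


def write_corpus(
    documents: list[Document],
    gold: pd.DataFrame,
    out_dir,
) -> None:
    """Write one UTF-8 ``.txt`` per document plus ``gold_labels.csv``."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for doc in documents:
        (out / f"{doc.doc_id}.txt").write_text(doc.text, encoding="utf-8")
    gold.to_csv(out / "gold_labels.csv")


def config_from_dict(data: dict) -> SyntheticConfig:
    """Build a :class:`SyntheticConfig` from a plain (YAML-loaded) mapping."""
    known = {f.name for f in dataclasses.fields(SyntheticConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown synthetic-config keys: {sorted(unknown)}")
    return SyntheticConfig(**data)
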