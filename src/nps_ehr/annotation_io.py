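"""Reading and writing brat standoff annotations.

Only text-bound ("T") annotations are interpreted; relation, event, and
attribute lines are ignored with a warning. Offsets are 0-based, end
exclusive, counted in Unicode code points, and verified against the
document text on every parse.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .categories import ALL_CATEGORIES, NpsCategory, resolve_category

logger = logging.getLogger(__name__)


class BratParseError(ValueError):
    """A line of a .ann file could not be interpreted."""


class AnnotationConsistencyError(ValueError):
    """Span offsets or surface text disagree with the document."""


@dataclass(frozen=True)
class AnnotationSpan:
    """A character-offset span labelled with one NPS category."""

    span_id: str
    doc_id: str
    category: NpsCategory
    start: int
    end: int
    surface_text: str

    def validate(self, doc_text: str) -> None:
        if not 0 <= self.start < self.end <= len(doc_text):
            raise AnnotationConsistencyError(
                f"span {self.span_id} offsets [{self.start}, {self.end}) fall "
                f"outside document {self.doc_id!r} of length {len(doc_text)}"
            )
        actual = doc_text[self.start : self.end]
        if actual != self.surface_text:
            raise AnnotationConsistencyError(
                f"span {self.span_id}: surface text {self.surface_text!r} does "
                f"not match document substring {actual!r}"
            )


@dataclass
class AnnotationSet:
    """All spans produced by one rater for one document."""

    rater_id: str
    spans: list[AnnotationSpan] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [s.span_id for s in self.spans]
        if len(ids) != len(set(ids)):
            raise ValueError(f"duplicate span ids in set for rater {self.rater_id}")


def _sort_key(span_id: str) -> tuple:
    # T2 before T10: numeric ordering when the id follows the Tn convention.
    if span_id[:1] == "T" and span_id[1:].isdigit():
        return (0, int(span_id[1:]))
    return (1, span_id)


def read_brat(
    ann_content: str,
    doc_text: str,
    doc_id: str,
    rater_id: str = "rater",
    synonyms: dict[str, NpsCategory] | None = None,
) -> AnnotationSet:
    """Parse brat standoff content into an :class:`AnnotationSet`.

    Discontinuous spans (``start end;start end``) are reduced to their
    minimal covering interval. Unknown categories raise :class:`KeyError`
    listing the valid names; offset or surface mismatches raise
    :class:`AnnotationConsistencyError`.
    """
    spans: list[AnnotationSpan] = []
    for lineno, raw in enumerate(ann_content.splitlines(), start=1):
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        if not line.startswith("T"):
            logger.warning(
                "%s: ignoring non-text-bound annotation line %d: %r",
                doc_id, lineno, line,
            )
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise BratParseError(
                f"{doc_id}: malformed annotation line {lineno}: {raw!r}"
            )
        span_id = parts[0]
        surface = parts[2] if len(parts) > 2 else ""
        header = parts[1]
        try:
            category_name, offsets = header.split(" ", 1)
            fragments = [
                (int(s), int(e))
                for s, e in (frag.split() for frag in offsets.split(";"))
            ]
        except ValueError as exc:
            raise BratParseError(
                f"{doc_id}: malformed annotation line {lineno}: {raw!r}"
            ) from exc
        category = resolve_category(category_name, synonyms)
        start = min(s for s, _ in fragments)
        end = max(e for _, e in fragments)
        if len(fragments) > 1:
            # covering interval: surface must be re-read from the document
            if not 0 <= start < end <= len(doc_text):
                raise AnnotationConsistencyError(
                    f"span {span_id} offsets outside document {doc_id!r}"
                )
            surface = doc_text[start:end]
        span = AnnotationSpan(span_id, doc_id, category, start, end, surface)
        span.validate(doc_text)
        spans.append(span)
    return AnnotationSet(rater_id=rater_id, spans=spans)


def write_brat(annotations: AnnotationSet, doc_text: str) -> str:
    """Serialize an :class:`AnnotationSet` as brat standoff text.

    Spans are validated against ``doc_text`` first and written in span-id
    order regardless of insertion order, so output is canonical and
    ``read_brat(write_brat(x)) == x``.
    """
    for span in annotations.spans:
        span.validate(doc_text)
    lines = []
    for span in sorted(annotations.spans, key=lambda s: _sort_key(s.span_id)):
        label = span.category.value
        lines.append(f"{span.span_id}\t{label} {span.start} {span.end}\t{span.surface_text}")
    return "\n".join(lines) + ("\n" if lines else "")


def labels_from_spans(
    annotations: AnnotationSet | list[AnnotationSpan],
    doc_ids: list[str],
) -> pd.DataFrame:
    """Reduce spans to a document × category presence matrix.

    Cell (d, c) is 1 iff at least one span of category c exists in document
    d; documents without spans yield all-zero rows. Span doc_ids must all
    appear in ``doc_ids``.
    """
    spans = annotations.spans if isinstance(annotations, AnnotationSet) else annotations
    known = set(doc_ids)
    labels = pd.DataFrame(
        0,
        index=pd.Index(list(doc_ids), name="doc_id"),
        columns=[c.value for c in ALL_CATEGORIES],
        dtype=np.int8,
    )
    for span in spans:
        if span.doc_id not in known:
            raise KeyError(
                f"span {span.span_id} references unknown document {span.doc_id!r}"
            )
        labels.loc[span.doc_id, span.category.value] = 1
    return labels


def read_annotation_dir(
    ann_dir, txt_dir=None, rater_id: str = "rater"
) -> tuple[list[AnnotationSpan], list[str]]:
    """Read every ``.ann``/``.txt`` pair in a directory.

    Returns all spans (doc_id = file stem) and the sorted list of document
    ids, including documents that have a ``.txt`` but no spans.
    """
    ann_dir = Path(ann_dir)
    txt_dir = Path(txt_dir) if txt_dir is not None else ann_dir
    doc_ids = sorted(p.stem for p in txt_dir.glob("*.txt"))
    spans: list[AnnotationSpan] = []
    for doc_id in doc_ids:
        ann_path = ann_dir / f"{doc_id}.ann"
        if not ann_path.exists():
            continue
        doc_text = (txt_dir / f"{doc_id}.txt").read_text(encoding="utf-8")
        ann_set = read_brat(
            ann_path.read_text(encoding="utf-8"), doc_text, doc_id, rater_id
        )
        spans.extend(ann_set.spans)
    return spans, doc_ids


def spans_from_view(
    documents, view: pd.DataFrame, rater_id: str
) -> dict[str, AnnotationSet]:
    """Render a document-level label matrix as per-document span sets.

    For a positive (doc, category) cell the span covers a generated cue
    phrase when one exists (true positive) and otherwise the first word of
    the document (an annotator over-call has no true cue to anchor on).
    """
    out: dict[str, AnnotationSet] = {}
    for doc in documents:
        spans = []
        counter = 1
        cue_by_cat: dict[NpsCategory, tuple[int, int]] = {}
        for cat, start, end in doc.cue_spans:
            cue_by_cat.setdefault(cat, (start, end))
        for col in view.columns:
            if not view.loc[doc.doc_id, col]:
                continue
            cat = NpsCategory(col)
            if cat in cue_by_cat:
                start, end = cue_by_cat[cat]
            else:
                first_word = doc.text.split(" ", 1)[0]
                start, end = 0, len(first_word)
            spans.append(
                AnnotationSpan(
                    f"T{counter}", doc.doc_id, cat, start, end,
                    doc.text[start:end],
                )
            )
            counter += 1
        out[doc.doc_id] = AnnotationSet(rater_id=rater_id, spans=spans)
    return out
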