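"""Inter-annotator agreement and EHR-versus-NPI comparison statistics.

All agreement is computed at the document/patient × category level with
Cohen's kappa and raw accuracy. Degenerate marginals follow explicit
conventions: if chance agreement is exactly 1 (both raters constant and
identical), kappa is defined as 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .categories import NPI_DOMAINS, NpsCategory


@dataclass
class NpiAssessment:
    """One patient's NPI domain scores plus an availability flag."""

    patient_id: str
    domain_scores: dict[str, int]
    available: bool = True

    def __post_init__(self) -> None:
        expected = {c.value for c in NPI_DOMAINS}
        got = set(self.domain_scores)
        if got != expected:
            missing = expected - got
            extra = got - expected
            raise ValueError(
                f"NPI assessment for {self.patient_id} must cover exactly the "
                f"12 NPI domains (missing {sorted(missing)}, extra {sorted(extra)})"
            )
        if any(v < 0 for v in self.domain_scores.values()):
            raise ValueError("domain scores must be nonnegative")


@dataclass
class AgreementResult:
    category: str
    accuracy: float
    kappa: float
    n: int


@dataclass
class EhrNpiComparison:
    category: str
    kappa: float
    prop_ehr_pos_npi_neg: float  # NaN when no EHR-positive patients
    prop_ehr_neg_npi_pos: float  # NaN when no NPI-positive patients
    n: int


def cohen_kappa(labels_a: Sequence[int], labels_b: Sequence[int]) -> float:
    """Cohen's kappa for two binary labelings.

    Chance agreement uses product marginals; p_e = 1 (both raters constant
    and equal) yields kappa = 1 by convention.
    """
    a = np.asarray(labels_a, dtype=int)
    b = np.asarray(labels_b, dtype=int)
    if a.shape != b.shape:
        raise ValueError(f"label vectors differ in length: {a.shape} vs {b.shape}")
    if a.size == 0:
        raise ValueError("kappa undefined on empty vectors")
    n = a.size
    p_o = float(np.mean(a == b))
    pa, pb = a.mean(), b.mean()
    p_e = pa * pb + (1 - pa) * (1 - pb)
    if p_e >= 1.0 - 1e-15:
        return 1.0 if p_o == 1.0 else 0.0
    return float((p_o - p_e) / (1.0 - p_e))


def accuracy(labels_a: Sequence[int], labels_b: Sequence[int]) -> float:
    a = np.asarray(labels_a, dtype=int)
    b = np.asarray(labels_b, dtype=int)
    if a.shape != b.shape:
        raise ValueError("label vectors differ in length")
    return float(np.mean(a == b))


def pairwise_annotation_agreement(
    view_a: pd.DataFrame, view_b: pd.DataFrame
) -> list[AgreementResult]:
    """Per-category document-level agreement between two annotator views.

    Appends two summary rows: ``overall_median`` (median accuracy and kappa
    across categories) and ``overall_micro`` (accuracy pooled over all
    document × category cells; kappa likewise pooled).
    """
    if set(view_a.index) != set(view_b.index):
        raise ValueError("annotator views cover different document sets")
    view_b = view_b.reindex(view_a.index)
    common = [c for c in view_a.columns if c in view_b.columns]
    results = []
    for cat in common:
        a, b = view_a[cat].to_numpy(), view_b[cat].to_numpy()
        results.append(
            AgreementResult(
                category=cat,
                accuracy=accuracy(a, b),
                kappa=cohen_kappa(a, b),
                n=len(a),
            )
        )
    accs = np.array([r.accuracy for r in results])
    kaps = np.array([r.kappa for r in results])
    results.append(
        AgreementResult(
            category="overall_median",
            accuracy=float(np.median(accs)),
            kappa=float(np.median(kaps)),
            n=len(view_a),
        )
    )
    flat_a = view_a[common].to_numpy().ravel()
    flat_b = view_b[common].to_numpy().ravel()
    results.append(
        AgreementResult(
            category="overall_micro",
            accuracy=accuracy(flat_a, flat_b),
            kappa=cohen_kappa(flat_a, flat_b),
            n=flat_a.size,
        )
    )
    return results


def npi_presence(assessment: NpiAssessment, threshold: int = 1) -> pd.Series:
    """Binary presence per NPI domain: score >= threshold.

    ``threshold=4`` gives the clinically-relevant sensitivity analysis.
    """
    if not assessment.available:
        raise ValueError(
            f"NPI assessment for {assessment.patient_id} is unavailable"
        )
    domains = [c.value for c in NPI_DOMAINS]
    return pd.Series(
        {d: int(assessment.domain_scores[d] >= threshold) for d in domains},
        name=assessment.patient_id,
    )


def assessments_from_table(table: pd.DataFrame) -> list[NpiAssessment]:
    """Build assessments from a long table (patient_id, domain, score, available)."""
    out = []
    for pid, group in table.groupby("patient_id", sort=True):
        scores = dict(zip(group["domain"], group["score"].astype(int)))
        available = bool(group["available"].iloc[0])
        out.append(NpiAssessment(str(pid), scores, available))
    return out


def npi_presence_matrix(
    assessments: Sequence[NpiAssessment], threshold: int = 1
) -> pd.DataFrame:
    """Patients × 12 NPI domains presence matrix (available patients only)."""
    rows = [npi_presence(a, threshold) for a in assessments if a.available]
    if not rows:
        raise ValueError("no available NPI assessments")
    mat = pd.DataFrame(rows)
    mat.index.name = "patient_id"
    return mat


def compare_ehr_npi(
    ehr_labels: pd.DataFrame,
    npi_matrix: pd.DataFrame,
    categories: Sequence[str] | None = None,
) -> tuple[list[EhrNpiComparison], dict[str, float]]:
    """Per-category agreement between note-derived labels and NPI presence.

    Restricted to patients present in both tables and to NPI-mappable
    categories. Returns the per-category comparisons plus median prevalence
    by source. Proportions with a zero denominator are reported as NaN, not
    zero.
    """
    patients = [p for p in ehr_labels.index if p in set(npi_matrix.index)]
    if not patients:
        raise ValueError("no patients with both EHR labels and NPI assessments")
    ehr = ehr_labels.loc[patients]
    npi = npi_matrix.loc[patients]
    if categories is None:
        categories = [
            c.value for c in NPI_DOMAINS
            if c.value in ehr.columns and c.value in npi.columns
        ]
    if NpsCategory.NPS_GENERAL.value in categories:
        raise ValueError("nps_general has no NPI counterpart")

    comparisons = []
    for cat in categories:
        e = ehr[cat].to_numpy()
        q = npi[cat].to_numpy()
        n_ehr_pos = int(e.sum())
        n_npi_pos = int(q.sum())
        pos_neg = int(np.sum((e == 1) & (q == 0)))
        neg_pos = int(np.sum((e == 0) & (q == 1)))
        comparisons.append(
            EhrNpiComparison(
                category=cat,
                kappa=cohen_kappa(e, q),
                prop_ehr_pos_npi_neg=(
                    pos_neg / n_ehr_pos if n_ehr_pos else float("nan")
                ),
                prop_ehr_neg_npi_pos=(
                    neg_pos / n_npi_pos if n_npi_pos else float("nan")
                ),
                n=len(e),
            )
        )
    medians = {
        "median_prevalence_ehr": float(
            np.median([ehr[c].mean() for c in categories])
        ),
        "median_prevalence_npi": float(
            np.median([npi[c].mean() for c in categories])
        ),
    }
    return comparisons, medians
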