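"""Misclassification-corrected prevalence estimation and group comparisons.

The point estimate is the Rogan-Gladen correction
``(observed + specificity - 1) / (sensitivity + specificity - 1)``; the
confidence interval is an adjusted-Wald (Agresti-Coull-style) construction
that also propagates the sampling uncertainty of sensitivity and
specificity estimated from validation-set confusion counts. Intervals are
deliberately left unclamped by default, so corrected estimates near the
boundary can produce limits outside [0, 1].
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .classification import ClassifierEvaluation

logger = logging.getLogger(__name__)


class EstimatorUndefinedError(ValueError):
    """sensitivity + specificity <= 1: the classifier is uninformative."""


class RoganGladenResult(NamedTuple):
    raw: float
    clamped: float


@dataclass
class PrevalenceEstimate:
    category: str
    n: int
    observed: float
    adjusted: float
    adjusted_clamped: float
    ci_low: float
    ci_high: float
    sensitivity_used: float
    specificity_used: float
    gate_passed: bool


@dataclass
class GroupComparison:
    category: str
    group_a: str
    group_b: str
    prevalence_a: float
    prevalence_b: float
    p_raw: float
    p_fdr: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_raw <= 1.0 and 0.0 <= self.p_fdr <= 1.0):
            raise ValueError("p values must lie in [0, 1]")
        if self.p_fdr < self.p_raw - 1e-12:
            raise ValueError("FDR-adjusted p cannot be below the raw p")


def rogan_gladen(
    observed: float, sensitivity: float, specificity: float
) -> RoganGladenResult:
    """Correct an observed proportion for imperfect sensitivity/specificity."""
    denom = sensitivity + specificity - 1.0
    if denom <= 0:
        raise EstimatorUndefinedError(
            "sensitivity + specificity must exceed 1 for the Rogan-Gladen "
            f"estimator (got {sensitivity} + {specificity})"
        )
    raw = (observed + specificity - 1.0) / denom
    return RoganGladenResult(raw=raw, clamped=min(1.0, max(0.0, raw)))


def adjusted_prevalence_ci(
    positives: int,
    n: int,
    sens_tp: int,
    sens_fn: int,
    spec_tn: int,
    spec_fp: int,
    level: float = 0.95,
    clamp: bool = False,
) -> tuple[float, float]:
    """Adjusted-Wald CI for a misclassification-corrected prevalence.

    The observed proportion receives an Agresti-Coull adjustment
    (add z^2/2 successes and z^2 trials); sensitivity and specificity enter
    as maximum-likelihood rates from validation confusion counts, and their
    binomial sampling variance is propagated by the delta method. With
    perfectly estimated rates (sens = spec = 1) the interval reduces exactly
    to the adjusted-Wald binomial interval for the observed proportion.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    n_sens = sens_tp + sens_fn
    n_spec = spec_tn + spec_fp
    if n_sens <= 0 or n_spec <= 0:
        raise ValueError("validation confusion counts must be non-empty")
    sens = sens_tp / n_sens
    spec = spec_tn / n_spec
    denom = sens + spec - 1.0
    if denom <= 0:
        raise EstimatorUndefinedError(
            "sensitivity + specificity must exceed 1 for a corrected interval"
        )
    z = stats.norm.ppf(0.5 + level / 2.0)
    n_tilde = n + z * z
    p_tilde = (positives + z * z / 2.0) / n_tilde
    var_p = p_tilde * (1.0 - p_tilde) / n_tilde
    var_sens = sens * (1.0 - sens) / n_sens
    var_spec = spec * (1.0 - spec) / n_spec
    theta = (p_tilde + spec - 1.0) / denom
    var_theta = (
        var_p + theta**2 * var_sens + (1.0 - theta) ** 2 * var_spec
    ) / denom**2
    half = z * math.sqrt(var_theta)
    lo, hi = theta - half, theta + half
    if clamp:
        lo, hi = max(0.0, lo), min(1.0, hi)
    return lo, hi


def estimate_all(
    labels: pd.DataFrame,
    evaluations: Sequence[ClassifierEvaluation],
    gate: float = 0.80,
    level: float = 0.95,
) -> list[PrevalenceEstimate]:
    """Observed and corrected prevalence per category, AUC-gated.

    ``labels`` holds per-document binary classifier output (documents ×
    categories). Categories whose evaluation AUC falls below ``gate`` are
    flagged ``gate_passed=False`` and receive no corrected estimate,
    mirroring exclusion of low-AUC classifiers from downstream reporting.
    """
    estimates: list[PrevalenceEstimate] = []
    for ev in evaluations:
        if ev.category not in labels.columns:
            raise KeyError(f"no classified labels for category {ev.category!r}")
        col = labels[ev.category].to_numpy()
        n = len(col)
        positives = int(col.sum())
        observed = positives / n
        if ev.auc < gate:
            estimates.append(
                PrevalenceEstimate(
                    category=ev.category, n=n, observed=observed,
                    adjusted=float("nan"), adjusted_clamped=float("nan"),
                    ci_low=float("nan"), ci_high=float("nan"),
                    sensitivity_used=ev.sensitivity,
                    specificity_used=ev.specificity,
                    gate_passed=False,
                )
            )
            continue
        rg = rogan_gladen(observed, ev.sensitivity, ev.specificity)
        ci_low, ci_high = adjusted_prevalence_ci(
            positives, n, ev.tp, ev.fn, ev.tn, ev.fp, level=level
        )
        # the CI is centred on the Agresti-Coull-adjusted estimate; widen
        # marginally if the raw point estimate sits outside
        ci_low = min(ci_low, rg.raw)
        ci_high = max(ci_high, rg.raw)
        if rg.raw > 1.0 or rg.raw < 0.0:
            logger.warning(
                "corrected prevalence for %s is %.3f before clamping",
                ev.category, rg.raw,
            )
        estimates.append(
            PrevalenceEstimate(
                category=ev.category, n=n, observed=observed,
                adjusted=rg.raw, adjusted_clamped=rg.clamped,
                ci_low=ci_low, ci_high=ci_high,
                sensitivity_used=ev.sensitivity,
                specificity_used=ev.specificity,
                gate_passed=True,
            )
        )
    return estimates


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """Step-up BH adjustment; monotone and never below the raw values."""
    p = np.asarray(p_values, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adjusted = np.empty(m)
    running_min = 1.0
    for rank_from_end, idx in enumerate(order[::-1]):
        rank = m - rank_from_end
        value = p[idx] * m / rank
        running_min = min(running_min, value)
        adjusted[idx] = min(running_min, 1.0)
    return np.maximum(adjusted, p)


def compare_groups(
    labels: pd.DataFrame,
    grouping: pd.Series,
    categories: Sequence[str] | None = None,
) -> list[GroupComparison]:
    """Two-group prevalence comparison per category with BH correction.

    Uses a chi-square test without continuity correction, switching to
    Fisher's exact test when any expected cell count is below 5. The BH
    family is the set of categories within this one comparison.
    """
    grouping = grouping.reindex(labels.index)
    if grouping.isna().any():
        raise ValueError("grouping must cover every document")
    groups = sorted(grouping.unique())
    if len(groups) != 2:
        raise ValueError(f"exactly two groups required, got {groups}")
    a_mask = (grouping == groups[0]).to_numpy()
    b_mask = ~a_mask
    if a_mask.sum() == 0 or b_mask.sum() == 0:
        raise ValueError("both groups must be nonempty")
    if categories is None:
        categories = list(labels.columns)

    raw_ps, prevs = [], []
    for cat in categories:
        col = labels[cat].to_numpy()
        pos_a, pos_b = int(col[a_mask].sum()), int(col[b_mask].sum())
        n_a, n_b = int(a_mask.sum()), int(b_mask.sum())
        table = np.array(
            [[pos_a, n_a - pos_a], [pos_b, n_b - pos_b]], dtype=float
        )
        expected = stats.contingency.expected_freq(table)
        if (expected < 5).any():
            _, p = stats.fisher_exact(table)
        else:
            _, p, _, _ = stats.chi2_contingency(table, correction=False)
        raw_ps.append(float(p))
        prevs.append((pos_a / n_a, pos_b / n_b))
    fdr = benjamini_hochberg(raw_ps)
    return [
        GroupComparison(
            category=cat,
            group_a=str(groups[0]), group_b=str(groups[1]),
            prevalence_a=pa, prevalence_b=pb,
            p_raw=p, p_fdr=float(q),
        )
        for cat, (pa, pb), p, q in zip(categories, prevs, raw_ps, fdr)
    ]


def estimates_to_frame(estimates: Sequence[PrevalenceEstimate]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "category": e.category,
                "n": e.n,
                "observed": e.observed,
                "adjusted": e.adjusted,
                "adjusted_clamped": e.adjusted_clamped,
                "ci_low": e.ci_low,
                "ci_high": e.ci_high,
                "sensitivity_used": e.sensitivity_used,
                "specificity_used": e.specificity_used,
                "gate_passed": e.gate_passed,
            }
            for e in estimates
        ]
    )
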