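"""Per-category elastic-net logistic classifiers with Youden cutoffs.

One binary classifier is trained per NPS category on n-gram counts,
evaluated by stratified tenfold cross-validation (hyperparameters chosen by
out-of-fold AUC) and on an external corpus featurized with the frozen
training vocabulary. Probability cutoffs maximize the Youden index on
out-of-fold scores.

The penalized objective is

    mean logistic deviance + lambda * (alpha*||b||_1 + (1-alpha)/2*||b||_2^2)

with an unpenalized intercept. Features are standardized to unit variance
internally; coefficients are reported on the original count scale.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.sparse as sp
from scipy.stats import rankdata
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from .preprocessing import DocTermMatrix

#: Minimum positive (and negative) documents required to attempt training.
MIN_POSITIVES = 10

DEFAULT_ALPHA_GRID = (0.1, 0.55, 1.0)


class SingleClassError(ValueError):
    """Labels contain only one class; the model is unidentifiable."""


class UntrainableCategoryError(ValueError):
    """Too few positives (or negatives) to train and stratify."""


class VocabularyMismatchError(ValueError):
    """Feature matrix was built with a different vocabulary than the model."""


@dataclass
class ElasticNetModel:
    category: str
    coefficients: dict[str, float]
    intercept: float
    mixing_alpha: float
    lam: float
    vocabulary_hash: str

    def decision_scores(self, X: DocTermMatrix) -> np.ndarray:
        if X.vocabulary_hash != self.vocabulary_hash:
            raise VocabularyMismatchError(
                f"matrix vocabulary hash {X.vocabulary_hash[:12]}... does not "
                f"match model hash {self.vocabulary_hash[:12]}..."
            )
        beta = np.zeros(len(X.vocabulary))
        index = {f: j for j, f in enumerate(X.vocabulary)}
        for feature, weight in self.coefficients.items():
            j = index.get(feature)
            if j is None:
                raise VocabularyMismatchError(
                    f"model feature {feature!r} missing from matrix vocabulary"
                )
            beta[j] = weight
        return self.intercept + np.asarray(X.matrix @ beta).ravel()

    def predict_proba(self, X: DocTermMatrix) -> np.ndarray:
        z = self.decision_scores(X)
        return 1.0 / (1.0 + np.exp(-z))

    def to_json(self) -> str:
        return json.dumps(
            {
                "category": self.category,
                "intercept": self.intercept,
                "coefficients": self.coefficients,
                "mixing_alpha": self.mixing_alpha,
                "lambda": self.lam,
                "vocabulary_hash": self.vocabulary_hash,
            },
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, payload: str) -> "ElasticNetModel":
        data = json.loads(payload)
        return cls(
            category=data["category"],
            coefficients={k: float(v) for k, v in data["coefficients"].items()},
            intercept=float(data["intercept"]),
            mixing_alpha=float(data["mixing_alpha"]),
            lam=float(data["lambda"]),
            vocabulary_hash=data["vocabulary_hash"],
        )


@dataclass
class ClassifierEvaluation:
    category: str
    auc: float
    sensitivity: float
    specificity: float
    youden: float
    cutoff: float
    split: str  # "internal_cv" | "external"
    n: int = 0
    tp: int = 0
    fn: int = 0
    tn: int = 0
    fp: int = 0

    def __post_init__(self) -> None:
        if abs(self.youden - (self.sensitivity + self.specificity - 1.0)) > 1e-12:
            raise ValueError("youden must equal sensitivity + specificity - 1")
        if self.split not in ("internal_cv", "external"):
            raise ValueError(f"unknown split {self.split!r}")


def _column_scales(matrix: sp.csr_matrix) -> np.ndarray:
    """Per-feature standard deviation (ddof=0); zero-variance columns -> 1."""
    m = matrix.shape[0]
    mean = np.asarray(matrix.mean(axis=0)).ravel()
    mean_sq = np.asarray(matrix.multiply(matrix).mean(axis=0)).ravel()
    var = np.maximum(mean_sq - mean**2, 0.0)
    scale = np.sqrt(var)
    scale[scale == 0] = 1.0
    return scale


def fit_elastic_net_logistic(
    X: DocTermMatrix,
    y: Sequence[int],
    mixing_alpha: float,
    lam: float,
    category: str = "",
    tol: float = 1e-7,
    max_iter: int = 5000,
    seed: int = 0,
) -> ElasticNetModel:
    """Fit one elastic-net-penalized logistic regression.

    ``lam = 0`` falls back to an unpenalized maximum-likelihood fit.
    """
    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) < 2:
        raise SingleClassError(
            f"labels for {category or 'category'} contain a single class"
        )
    if not 0.0 <= mixing_alpha <= 1.0:
        raise ValueError("mixing_alpha must lie in [0, 1]")
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    n = X.matrix.shape[0]
    scale = _column_scales(X.matrix)
    X_std = X.matrix.multiply(1.0 / scale).tocsr()
    if lam == 0:
        clf = LogisticRegression(
            C=np.inf, solver="lbfgs", tol=tol, max_iter=max_iter
        )
    else:
        clf = LogisticRegression(
            solver="saga",
            l1_ratio=mixing_alpha,
            C=1.0 / (n * lam),
            tol=tol,
            max_iter=max_iter,
            random_state=seed,
        )
    clf.fit(X_std, y)
    beta_std = clf.coef_.ravel()
    beta = beta_std / scale
    coefficients = {
        X.vocabulary[j]: float(beta[j]) for j in np.nonzero(beta)[0]
    }
    intercept = float(clf.intercept_[0])
    if not coefficients:
        # with every coefficient shrunk to zero the unpenalized intercept
        # has a closed form that saga's tiny step size cannot reach
        base = y.mean()
        intercept = float(np.log(base / (1.0 - base)))
    return ElasticNetModel(
        category=category,
        coefficients=coefficients,
        intercept=intercept,
        mixing_alpha=float(mixing_alpha),
        lam=float(lam),
        vocabulary_hash=X.vocabulary_hash,
    )


def lambda_grid_from_data(
    X: DocTermMatrix,
    y: Sequence[int],
    mixing_alpha: float,
    n_lambda: int = 10,
    lambda_min_ratio: float = 1e-4,
) -> np.ndarray:
    """Log-spaced penalty grid from lambda_max down by ``lambda_min_ratio``.

    ``lambda_max`` is the smallest penalty zeroing every coefficient for the
    L1 part (alpha floored at 0.01 so ridge-leaning mixes get a finite
    grid).
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    scale = _column_scales(X.matrix)
    X_std = X.matrix.multiply(1.0 / scale).tocsr()
    resid = y - y.mean()
    grad = np.abs(np.asarray(X_std.T @ resid)).ravel() / n
    lam_max = float(grad.max()) / max(mixing_alpha, 1e-2)
    if lam_max <= 0:
        lam_max = 1.0
    return np.geomspace(lam_max, lam_max * lambda_min_ratio, n_lambda)


@dataclass
class CrossValidationResult:
    oof_scores: np.ndarray
    best_alpha: float
    best_lambda: float
    best_auc: float
    fold_assignment: np.ndarray
    grid_aucs: dict = field(default_factory=dict)


def cross_validate(
    X: DocTermMatrix,
    y: Sequence[int],
    k: int = 10,
    alpha_grid: Sequence[float] = DEFAULT_ALPHA_GRID,
    lambda_grid: Sequence[float] | None = None,
    n_lambda: int = 10,
    seed: int = 0,
    category: str = "",
    tol: float = 1e-7,
    max_iter: int = 5000,
) -> CrossValidationResult:
    """Stratified k-fold CV over a hyperparameter grid.

    Every document is scored exactly once out-of-fold; the (alpha, lambda)
    pair maximizing out-of-fold AUC wins (first grid point on ties, so the
    result is deterministic given the seed).
    """
    y = np.asarray(y, dtype=int)
    n_pos = int(y.sum())
    n_neg = int(len(y) - n_pos)
    if min(n_pos, n_neg) < max(k, MIN_POSITIVES):
        raise UntrainableCategoryError(
            f"category {category or '?'} is untrainable: {n_pos} positive and "
            f"{n_neg} negative documents; need at least "
            f"{max(k, MIN_POSITIVES)} of each for stratified {k}-fold CV"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = list(skf.split(np.zeros(len(y)), y))
    fold_assignment = np.empty(len(y), dtype=int)
    for fold_id, (_, test_idx) in enumerate(folds):
        fold_assignment[test_idx] = fold_id

    best = None
    grid_aucs: dict[tuple[float, float], float] = {}
    for alpha in alpha_grid:
        lams = (
            np.asarray(lambda_grid, dtype=float)
            if lambda_grid is not None
            else lambda_grid_from_data(X, y, alpha, n_lambda=n_lambda)
        )
        for lam in lams:
            oof = np.empty(len(y))
            for train_idx, test_idx in folds:
                sub = DocTermMatrix(
                    X.matrix[train_idx].tocsr(),
                    [X.doc_ids[i] for i in train_idx],
                    X.vocabulary,
                )
                model = fit_elastic_net_logistic(
                    sub, y[train_idx], alpha, float(lam),
                    category=category, tol=tol, max_iter=max_iter, seed=seed,
                )
                test = DocTermMatrix(
                    X.matrix[test_idx].tocsr(),
                    [X.doc_ids[i] for i in test_idx],
                    X.vocabulary,
                )
                oof[test_idx] = model.predict_proba(test)
            auc = compute_auc(oof, y)
            grid_aucs[(float(alpha), float(lam))] = auc
            if best is None or auc > best[0]:
                best = (auc, float(alpha), float(lam), oof)
    assert best is not None
    best_auc, best_alpha, best_lambda, oof = best
    return CrossValidationResult(
        oof_scores=oof,
        best_alpha=best_alpha,
        best_lambda=best_lambda,
        best_auc=best_auc,
        fold_assignment=fold_assignment,
        grid_aucs=grid_aucs,
    )


def compute_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Mann-Whitney AUC: concordant pairs plus half the ties, over all pairs."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise SingleClassError("AUC undefined: labels contain a single class")
    ranks = rankdata(scores)
    rank_sum_pos = ranks[labels == 1].sum()
    return float((rank_sum_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def confusion_at_cutoff(
    scores: Sequence[float], labels: Sequence[int], cutoff: float
) -> tuple[float, float, tuple[int, int, int, int]]:
    """Sensitivity, specificity, and (tp, fn, tn, fp) at a probability cutoff.

    Predictions are positive iff score >= cutoff.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pred = scores >= cutoff
    tp = int(np.sum(pred & (labels == 1)))
    fn = int(np.sum(~pred & (labels == 1)))
    tn = int(np.sum(~pred & (labels == 0)))
    fp = int(np.sum(pred & (labels == 0)))
    if tp + fn == 0:
        raise SingleClassError("sensitivity undefined: no positive labels")
    if tn + fp == 0:
        raise SingleClassError("specificity undefined: no negative labels")
    return tp / (tp + fn), tn / (tn + fp), (tp, fn, tn, fp)


def select_youden_cutoff(
    oof_scores: Sequence[float],
    labels: Sequence[int],
    category: str = "",
) -> tuple[float, ClassifierEvaluation]:
    """Pick the cutoff maximizing J = sensitivity + specificity - 1.

    Candidates are midpoints between adjacent distinct out-of-fold scores;
    ties favour the smallest cutoff. Degenerate constant scores fall back to
    a 0.5 cutoff.
    """
    scores = np.asarray(oof_scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    distinct = np.unique(scores)
    if len(distinct) < 2:
        candidates = np.array([0.5])
    else:
        candidates = (distinct[:-1] + distinct[1:]) / 2.0
    best_cutoff = None
    best_j = -math.inf
    best_stats = None
    for c in candidates:
        sens, spec, counts = confusion_at_cutoff(scores, labels, float(c))
        j = sens + spec - 1.0
        if j > best_j + 1e-15:
            best_j = j
            best_cutoff = float(c)
            best_stats = (sens, spec, counts)
    assert best_cutoff is not None and best_stats is not None
    sens, spec, (tp, fn, tn, fp) = best_stats
    evaluation = ClassifierEvaluation(
        category=category,
        auc=compute_auc(scores, labels),
        sensitivity=sens,
        specificity=spec,
        youden=sens + spec - 1.0,
        cutoff=best_cutoff,
        split="internal_cv",
        n=len(labels),
        tp=tp, fn=fn, tn=tn, fp=fp,
    )
    return best_cutoff, evaluation


def evaluate_external(
    model: ElasticNetModel,
    cutoff: float,
    X_ext: DocTermMatrix,
    y_ext: Sequence[int],
) -> ClassifierEvaluation:
    """Score an external corpus with a frozen model and cutoff.

    No refitting and no cutoff re-selection; a vocabulary hash mismatch is a
    hard error to prevent silent feature misalignment.
    """
    probs = model.predict_proba(X_ext)  # raises on hash mismatch
    y_ext = np.asarray(y_ext, dtype=int)
    sens, spec, (tp, fn, tn, fp) = confusion_at_cutoff(probs, y_ext, cutoff)
    return ClassifierEvaluation(
        category=model.category,
        auc=compute_auc(probs, y_ext),
        sensitivity=sens,
        specificity=spec,
        youden=sens + spec - 1.0,
        cutoff=cutoff,
        split="external",
        n=len(y_ext),
        tp=tp, fn=fn, tn=tn, fp=fp,
    )
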