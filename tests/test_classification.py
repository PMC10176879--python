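import math

import numpy as np
import pytest
import scipy.optimize
import scipy.sparse as sp

from nps_ehr.classification import (
    ClassifierEvaluation,
    ElasticNetModel,
    SingleClassError,
    UntrainableCategoryError,
    VocabularyMismatchError,
    compute_auc,
    confusion_at_cutoff,
    cross_validate,
    evaluate_external,
    fit_elastic_net_logistic,
    lambda_grid_from_data,
    select_youden_cutoff,
)
from nps_ehr.preprocessing import DocTermMatrix

from conftest import make_dtm


def logistic_data(n=80, p=4, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    beta = np.resize([1.5, -2.0, 0.8, 0.0], p)
    z = X @ beta + 0.3
    y = (rng.random(n) < 1 / (1 + np.exp(-z))).astype(int)
    return make_dtm(X), y


class TestFit:
    def test_huge_lambda_fully_shrunk(self):
        X, y = logistic_data()
        model = fit_elastic_net_logistic(X, y, 1.0, 1e6)
        assert model.coefficients == {}
        base = y.mean()
        assert model.intercept == pytest.approx(math.log(base / (1 - base)))

    def test_lambda_zero_matches_generic_optimizer(self):
        X, y = logistic_data(n=60, p=3, seed=1)
        model = fit_elastic_net_logistic(X, y, 0.5, 0.0, tol=1e-10, max_iter=20000)
        dense = X.matrix.toarray()

        def nll(params):
            b0, b = params[0], params[1:]
            z = b0 + dense @ b
            return np.sum(np.logaddexp(0, z) - y * z)

        res = scipy.optimize.minimize(
            nll, np.zeros(4), method="BFGS", options={"gtol": 1e-10}
        )
        fitted = np.array(
            [model.intercept] + [model.coefficients.get(f, 0.0) for f in X.vocabulary]
        )
        assert np.allclose(fitted, res.x, atol=1e-4)

    def test_l1_norm_non_increasing_in_lambda(self):
        X, y = logistic_data(n=100, p=5, seed=2)
        grid = lambda_grid_from_data(X, y, 1.0, n_lambda=8)
        norms = []
        for lam in sorted(grid):
            model = fit_elastic_net_logistic(
                X, y, 1.0, float(lam), tol=1e-9, max_iter=50000
            )
            norms.append(sum(abs(v) for v in model.coefficients.values()))
        # lambda ascending -> ||beta||_1 non-increasing (solver slack 1e-6)
        for small, large in zip(norms, norms[1:]):
            assert large <= small + 1e-6

    def test_single_class_rejected(self):
        X, _ = logistic_data()
        with pytest.raises(SingleClassError):
            fit_elastic_net_logistic(X, np.zeros(80, dtype=int), 0.5, 0.1)

    def test_serialization_round_trip_bit_identical_predictions(self):
        X, y = logistic_data(seed=3)
        model = fit_elastic_net_logistic(X, y, 0.55, 0.01)
        clone = ElasticNetModel.from_json(model.to_json())
        assert (clone.predict_proba(X) == model.predict_proba(X)).all()


class TestCrossValidate:
    def test_partition_property(self):
        X, y = logistic_data(n=100, p=4, seed=4)
        # force both classes common enough
        y = np.array([i % 2 for i in range(100)])
        cv = cross_validate(
            X, y, k=10, alpha_grid=(0.55,), n_lambda=2, seed=1, tol=1e-3, max_iter=50
        )
        assert len(cv.oof_scores) == 100
        assert np.isfinite(cv.oof_scores).all()
        sizes = np.bincount(cv.fold_assignment)
        assert len(sizes) == 10
        assert all(abs(s - 10) <= 1 for s in sizes)

    def test_too_few_positives_refused_as_untrainable(self):
        X, _ = logistic_data(n=500, p=4, seed=5)
        y = np.zeros(500, dtype=int)
        y[:5] = 1
        with pytest.raises(UntrainableCategoryError, match="untrainable"):
            cross_validate(X, y, k=10, category="euphoria")

    def test_determinism(self):
        X, y = logistic_data(n=80, p=4, seed=6)
        kwargs = dict(
            k=5, alpha_grid=(0.55, 1.0), n_lambda=3, seed=9, tol=1e-3, max_iter=60
        )
        cv1 = cross_validate(X, y, **kwargs)
        cv2 = cross_validate(X, y, **kwargs)
        assert (cv1.fold_assignment == cv2.fold_assignment).all()
        assert (cv1.best_alpha, cv1.best_lambda) == (cv2.best_alpha, cv2.best_lambda)
        assert (cv1.oof_scores == cv2.oof_scores).all()


def brute_force_auc(scores, labels):
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


class TestAuc:
    def test_perfect_separation(self):
        assert compute_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_hand_enumerated_pairs(self):
        assert compute_auc([0.9, 0.8, 0.3, 0.2], [1, 0, 1, 0]) == pytest.approx(0.75)

    def test_all_ties(self):
        assert compute_auc([0.5] * 10, [1, 0] * 5) == pytest.approx(0.5)

    def test_single_class_error(self):
        with pytest.raises(SingleClassError):
            compute_auc([0.1, 0.2], [1, 1])

    def test_matches_brute_force_on_random_sets(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            n = int(rng.integers(4, 50))
            scores = np.round(rng.random(n), 2)  # induce ties
            labels = rng.integers(0, 2, n)
            if labels.sum() in (0, n):
                labels[0] = 1 - labels[0]
            assert compute_auc(scores, labels) == pytest.approx(
                brute_force_auc(scores, labels), abs=1e-12
            )

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(7)
        scores = rng.random(60)
        labels = rng.integers(0, 2, 60)
        labels[0], labels[1] = 0, 1
        transformed = np.exp(3 * scores) + 5
        assert compute_auc(scores, labels) == pytest.approx(
            compute_auc(transformed, labels), abs=1e-12
        )


class TestConfusion:
    def test_cutoff_below_all_scores(self):
        sens, spec, _ = confusion_at_cutoff([0.4, 0.6], [1, 0], 0.1)
        assert (sens, spec) == (1.0, 0.0)

    def test_cutoff_above_all_scores(self):
        sens, spec, _ = confusion_at_cutoff([0.4, 0.6], [1, 0], 0.9)
        assert (sens, spec) == (0.0, 1.0)

    def test_depression_training_operating_point(self):
        # TP=71, FN=29, TN=97, FP=3 -> sens 0.71, spec 0.97, J 0.68
        scores = np.r_[np.full(71, 0.9), np.full(29, 0.1),
                       np.full(97, 0.1), np.full(3, 0.9)]
        labels = np.r_[np.ones(100, dtype=int), np.zeros(100, dtype=int)]
        sens, spec, (tp, fn, tn, fp) = confusion_at_cutoff(scores, labels, 0.5)
        assert (tp, fn, tn, fp) == (71, 29, 97, 3)
        assert sens == pytest.approx(0.71)
        assert spec == pytest.approx(0.97)
        assert sens + spec - 1 == pytest.approx(0.68)

    def test_no_positives_error(self):
        with pytest.raises(SingleClassError):
            confusion_at_cutoff([0.2, 0.4], [0, 0], 0.3)


class TestYoudenCutoff:
    def test_perfect_separation_j_one(self):
        scores = [0.9, 0.8, 0.2, 0.1]
        labels = [1, 1, 0, 0]
        cutoff, ev = select_youden_cutoff(scores, labels)
        assert ev.youden == pytest.approx(1.0)
        assert 0.2 < cutoff < 0.8

    def test_youden_identity_enforced(self):
        with pytest.raises(ValueError, match="youden"):
            ClassifierEvaluation(
                category="x", auc=0.9, sensitivity=0.8, specificity=0.7,
                youden=0.4, cutoff=0.5, split="internal_cv",
            )

    def test_matches_exhaustive_scan(self):
        rng = np.random.default_rng(11)
        for _ in range(25):
            n = int(rng.integers(10, 60))
            scores = np.round(rng.random(n), 2)
            labels = rng.integers(0, 2, n)
            if labels.sum() in (0, n):
                labels[0] = 1 - labels[0]
            cutoff, ev = select_youden_cutoff(scores, labels)
            distinct = np.unique(scores)
            best_j, best_c = -np.inf, None
            for c in (distinct[:-1] + distinct[1:]) / 2 if len(distinct) > 1 else [0.5]:
                s, p, _ = confusion_at_cutoff(scores, labels, c)
                if s + p - 1 > best_j + 1e-15:
                    best_j, best_c = s + p - 1, c
            assert cutoff == pytest.approx(best_c)
            assert ev.youden == pytest.approx(best_j)

    def test_ties_broken_toward_smallest_cutoff(self):
        # J identical at every midpoint below the single informative split
        scores = [0.1, 0.2, 0.8, 0.9]
        labels = [0, 0, 1, 1]
        cutoff, _ = select_youden_cutoff(scores, labels)
        assert cutoff == pytest.approx(0.5)


class TestExternalEvaluation:
    def test_memorizing_model_same_operating_point(self):
        X, y = logistic_data(n=100, p=4, seed=8)
        model = fit_elastic_net_logistic(X, y, 0.1, 1e-4, tol=1e-8, max_iter=20000)
        probs = model.predict_proba(X)
        cutoff, internal = select_youden_cutoff(probs, y)
        external = evaluate_external(model, cutoff, X, y)
        assert external.sensitivity == pytest.approx(internal.sensitivity)
        assert external.specificity == pytest.approx(internal.specificity)
        assert external.auc == pytest.approx(internal.auc)

    def test_vocabulary_hash_mismatch_rejected(self):
        X, y = logistic_data(n=60, p=3, seed=9)
        model = fit_elastic_net_logistic(X, y, 0.5, 0.01)
        other = make_dtm(X.matrix.toarray(), vocabulary=["g0", "g1", "g2"])
        with pytest.raises(VocabularyMismatchError):
            evaluate_external(model, 0.5, other, y)

    def test_distribution_shift_reduces_auc(self):
        from nps_ehr.categories import ALL_CATEGORIES, NpsCategory
        from nps_ehr.preprocessing import (
            PreprocessConfig,
            build_doc_term_matrix,
            featurize_with_vocabulary,
        )
        from nps_ehr.synthetic_corpus import SyntheticConfig, generate_corpus

        prev = {c: 0.0 for c in ALL_CATEGORIES}
        prev[NpsCategory.ANXIETY] = 0.4
        train_cfg = SyntheticConfig(n_patients=150, true_prevalence=prev, seed=21)
        shifted_lexicon = {k: list(v) for k, v in train_cfg.cue_lexicon.items()}
        shifted_lexicon[NpsCategory.ANXIETY] = ["nervous tension", "worried affect"]
        ext_cfg = SyntheticConfig(
            n_patients=150, true_prevalence=prev, cue_lexicon=shifted_lexicon,
            center="B", seed=22,
        )
        docs_a, gold_a = generate_corpus(train_cfg)
        docs_b, gold_b = generate_corpus(ext_cfg)
        pc = PreprocessConfig(min_document_frequency=2)
        dtm_a = build_doc_term_matrix(docs_a, pc)
        dtm_b = featurize_with_vocabulary(docs_b, pc, dtm_a.vocabulary)
        y_a, y_b = gold_a["anxiety"].to_numpy(), gold_b["anxiety"].to_numpy()
        cv = cross_validate(
            X=dtm_a, y=y_a, k=5, alpha_grid=(0.55,), n_lambda=3,
            seed=0, tol=1e-3, max_iter=80,
        )
        model = fit_elastic_net_logistic(
            dtm_a, y_a, cv.best_alpha, cv.best_lambda, tol=1e-3, max_iter=200
        )
        cutoff, _ = select_youden_cutoff(cv.oof_scores, y_a)
        external = evaluate_external(model, cutoff, dtm_b, y_b)
        assert external.auc < cv.best_auc
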