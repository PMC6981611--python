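"""Metric identities, AUC vs the pairwise oracle, grid search, CV harness."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from iqsp.featurize import FeatureMatrix, standardize
from iqsp.svm_model import (
    GRID_EXPONENTS,
    EvalMetrics,
    ModelSpec,
    _make_folds,
    confusion_metrics,
    cross_validate_10fold,
    grid_search_svm,
    predict_scores,
    repeated_rounds,
    roc_auc,
    train,
)
from iqsp.synthetic import PlantedDataSpec, generate_planted, generate_two_class_set


def pairwise_auc(y, scores):
    """Brute-force Mann-Whitney oracle: ties between classes count one half."""
    pos = [s for yy, s in zip(y, scores) if yy == 1]
    neg = [s for yy, s in zip(y, scores) if yy == -1]
    total = 0.0
    for p, q in itertools.product(pos, neg):
        total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


class TestConfusionMetrics:
    def test_perfect_prediction(self):
        m = confusion_metrics([1] * 5 + [-1] * 5, [1] * 5 + [-1] * 5)
        assert (m.tp, m.tn, m.fp, m.fn) == (5, 5, 0, 0)
        assert (m.ac, m.sn, m.sp, m.mcc) == (1.0, 1.0, 1.0, 1.0)

    def test_complement_prediction(self):
        y = [1] * 4 + [-1] * 4
        m = confusion_metrics(y, [-v for v in y])
        assert m.ac == 0.0 and m.mcc == -1.0

    def test_hand_evaluated_mixed_case(self):
        # TP=3, FN=1, TN=2, FP=2 -> MCC = (6-2)/sqrt(5*4*4*3)
        y_true = [1, 1, 1, 1, -1, -1, -1, -1]
        y_pred = [1, 1, 1, -1, 1, 1, -1, -1]
        m = confusion_metrics(y_true, y_pred)
        assert (m.tp, m.fn, m.tn, m.fp) == (3, 1, 2, 2)
        assert m.ac == pytest.approx(0.625)
        assert m.sn == pytest.approx(0.75)
        assert m.sp == pytest.approx(0.5)
        assert m.mcc == pytest.approx(4 / np.sqrt(240), abs=1e-12)

    def test_degenerate_denominator_defines_mcc_zero(self):
        m = confusion_metrics([1, 1], [1, 1])
        assert m.mcc == 0.0

    @settings(deadline=None, derandomize=True)
    @given(
        counts=st.tuples(*[st.integers(0, 30)] * 4).filter(
            lambda c: c[0] + c[3] > 0 and c[1] + c[2] > 0
        )
    )
    def test_derived_values_recompute_from_counts(self, counts):
        tp, tn, fp, fn = counts
        m = EvalMetrics(tp, tn, fp, fn)
        assert m.ac == pytest.approx((tp + tn) / (tp + tn + fp + fn), abs=1e-12)
        assert m.sn == pytest.approx(tp / (tp + fn), abs=1e-12)
        assert m.sp == pytest.approx(tn / (tn + fp), abs=1e-12)
        denom = np.sqrt(
            float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
        )
        expected = 0.0 if denom == 0 else (tp * tn - fp * fn) / denom
        assert m.mcc == pytest.approx(expected, abs=1e-12)


class TestAUC:
    def test_perfectly_ordered_and_anti_ordered(self):
        y = [1, 1, -1, -1]
        assert roc_auc(y, [0.9, 0.8, 0.2, 0.1]) == 1.0
        assert roc_auc(y, [0.1, 0.2, 0.8, 0.9]) == 0.0

    def test_cross_class_tie_counts_one_half(self):
        y = [1, 1, -1, -1]
        scores = [0.9, 0.5, 0.5, 0.1]
        assert roc_auc(y, scores) == pytest.approx(pairwise_auc(y, scores))
        assert roc_auc(y, scores) == pytest.approx(0.875)

    def test_matches_pairwise_oracle_on_random_instances(self):
        rng = np.random.default_rng(123)
        for _ in range(30):
            n = int(rng.integers(4, 51))
            n_pos = int(rng.integers(1, n))
            y = np.array([1] * n_pos + [-1] * (n - n_pos))
            scores = rng.choice(np.linspace(0, 1, 11), size=n)  # forces ties
            assert roc_auc(y, scores) == pytest.approx(
                pairwise_auc(y, scores), abs=1e-12
            )


@pytest.fixture(scope="module")
def separable():
    fm, y, _ = generate_planted(PlantedDataSpec(30, 6, (0, 1), delta=6.0, seed=21))
    return standardize(fm), y


class TestGridSearch:
    def test_grid_covers_nine_exponents_per_parameter(self):
        assert GRID_EXPONENTS == tuple(range(-8, 9, 2))

    def test_separable_data_reaches_high_cv_accuracy(self, separable):
        z, y = separable
        spec = grid_search_svm(z, y, cv_seed=0)
        metrics = cross_validate_10fold(z, y, seed=0, spec=spec)
        assert metrics.ac >= 0.95

    def test_same_seed_gives_identical_hyperparameters(self, separable):
        z, y = separable
        a = grid_search_svm(z, y, cv_seed=5)
        b = grid_search_svm(z, y, cv_seed=5)
        assert (a.C, a.gamma) == (b.C, b.gamma)

    def test_single_class_labels_are_rejected(self, separable):
        z, _ = separable
        with pytest.raises(ValueError, match="both classes"):
            grid_search_svm(z, np.ones(z.n_samples, dtype=int))


class TestTrainPredict:
    def test_training_set_accuracy_on_separable_data(self, separable):
        z, y = separable
        spec = ModelSpec(1.0, 0.25, z.feature_names)
        model = train(spec, z, y, seed=0)
        probs = predict_scores(model, z)
        pred = np.where(probs[:, 1] >= 0.5, 1, -1)
        assert confusion_metrics(y, pred).ac >= 0.95

    def test_probabilities_sum_to_one_and_duplicates_agree(self, separable):
        z, y = separable
        model = train(ModelSpec(1.0, 0.25, z.feature_names), z, y, seed=0)
        rng = np.random.default_rng(0)
        queries = rng.normal(size=(1000, z.n_features))
        doubled = FeatureMatrix(z.feature_names, np.vstack([queries, queries]))
        probs = predict_scores(model, doubled)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-9)
        assert np.allclose(probs[:1000], probs[1000:])

    def test_column_mismatch_is_rejected(self, separable):
        z, y = separable
        model = train(ModelSpec(1.0, 0.25, z.feature_names), z, y, seed=0)
        wrong = FeatureMatrix(
            tuple(reversed(z.feature_names)), z.values, z.sample_ids
        )
        with pytest.raises(ValueError, match="match"):
            predict_scores(model, wrong)


class TestCrossValidation:
    def test_ten_folds_of_forty_for_n_400(self):
        y = np.array([1, -1] * 200)
        folds = _make_folds(y, seed=0)
        assert len(folds) == 10
        assert all(len(te) == 40 for _, te in folds)
        seen = np.concatenate([te for _, te in folds])
        assert sorted(seen) == list(range(400))  # each sample tested once

    def test_row_permutation_does_not_change_results(self, separable):
        z, y = separable
        ids = tuple(f"s{i:03d}" for i in range(z.n_samples))
        fm = FeatureMatrix(z.feature_names, z.values, ids)
        spec = ModelSpec(1.0, 0.25, z.feature_names)
        base = cross_validate_10fold(fm, y, seed=3, spec=spec)
        perm = np.random.default_rng(0).permutation(z.n_samples)
        fm_p = FeatureMatrix(z.feature_names, z.values[perm],
                             tuple(ids[i] for i in perm))
        shuffled = cross_validate_10fold(fm_p, y[perm], seed=3, spec=spec)
        assert (base.tp, base.tn, base.fp, base.fn) == (
            shuffled.tp, shuffled.tn, shuffled.fp, shuffled.fn
        )


class TestRepeatedRounds:
    def test_report_shape_and_summary(self, scales18):
        pool = generate_two_class_set(35, 35, seed=13)
        report = repeated_rounds(
            pool, scales18, n_rounds=2, seed=1,
            n_benchmark_per_class=28, n_independent_per_class=5,
        )
        assert len(report.cv_rounds) == 2
        assert len(report.independent_rounds) == 2
        for key, (mean, sd) in report.independent_summary.items():
            assert sd >= 0
            assert 0 <= mean <= 1
        tsv = report.to_tsv("independent")
        assert tsv.splitlines()[-1].startswith("mean\t")
        assert "±" in tsv

    def test_pool_too_small_raises(self, scales18):
        pool = generate_two_class_set(10, 10, seed=13)
        with pytest.raises(ValueError, match="pool too small"):
            repeated_rounds(pool, scales18, n_rounds=1)
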