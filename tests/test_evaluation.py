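"""Metrics and protocol: confusion rates, AUC, sweeps, folds, subsampling."""

from __future__ import annotations

import numpy as np
import pytest

from pcgscreen.evaluation import (
    ConfusionMatrix2,
    balanced_subsample,
    confusion,
    grouped_kfold,
    parameter_fingerprint,
    rates,
    roc_auc,
    split_patients,
    threshold_sweep,
    weighted_accuracy,
    zero_shot_eval,
)
from pcgscreen.io_formats import DatasetCatalog, PatientRecord, ValidationError

# confusion matrices as printed for the held-out murmur and outcome models
MURMUR_HOLDOUT = ConfusionMatrix2(tp=17, fp=0, fn=8, tn=70)
OUTCOME_HOLDOUT = ConfusionMatrix2(tp=25, fp=10, fn=22, tn=38)


def pairwise_auc_oracle(labels: np.ndarray, scores: np.ndarray) -> float:
    """Exhaustive O(n^2) pairwise statistic, ties counted one half."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return float(wins / (len(pos) * len(neg)))


def make_catalog(n_per_class: dict[int, int]) -> tuple[DatasetCatalog, dict[str, int]]:
    patients, labels = [], {}
    i = 0
    for cls, count in n_per_class.items():
        for _ in range(count):
            pid = f"p{i:05d}"
            patients.append(PatientRecord(patient_id=pid))
            labels[pid] = cls
            i += 1
    return DatasetCatalog(patients=patients, schema="synthetic", root="."), labels


class TestConfusionAndRates:
    def test_threshold_convention_ge(self):
        m = confusion(np.array([1, 0, 1]), np.array([0.5, 0.5, 0.2]), 0.5)
        assert (m.tp, m.fp, m.fn, m.tn) == (1, 1, 1, 0)

    def test_threshold_zero_everything_positive(self):
        m = confusion(np.array([1, 0, 0]), np.array([0.1, 0.9, 0.0]), 0.0)
        assert m.fn == 0 and m.tn == 0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            confusion(np.array([1, 0]), np.array([0.5]))

    def test_murmur_holdout_matrix_rates(self):
        rep = rates(MURMUR_HOLDOUT)
        assert rep.fnr == pytest.approx(8 / 25)  # = 0.32 exactly
        assert rep.acc_positive == pytest.approx(17 / 25)
        assert rep.acc_overall == pytest.approx(87 / 95)
        assert rep.fpr == 0.0

    def test_outcome_holdout_matrix_rates(self):
        rep = rates(OUTCOME_HOLDOUT)
        assert rep.fnr == pytest.approx(22 / 47, abs=5e-4)  # 0.468 at 3 d.p.
        assert rep.acc_overall == pytest.approx(63 / 95)

    def test_perfect_matrix(self):
        rep = rates(ConfusionMatrix2(tp=5, fp=0, fn=0, tn=5))
        assert rep.acc_overall == rep.acc_positive == rep.acc_negative == 1.0

    def test_empty_class_reported_as_nan_with_flag(self):
        rep = rates(ConfusionMatrix2(tp=0, fp=3, fn=0, tn=7))
        assert np.isnan(rep.acc_positive) and np.isnan(rep.fnr)
        assert "no_positive_examples" in rep.flags


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc(np.array([0, 0, 1, 1]), np.array([0.1, 0.2, 0.8, 0.9])) == 1.0

    def test_tie_counted_half(self):
        assert roc_auc(np.array([0, 1, 1]), np.array([0.5, 0.5, 0.9])) == pytest.approx(0.75)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(0)
        y = rng.integers(0, 2, 50)
        y[0], y[1] = 0, 1
        s = rng.random(50)
        assert roc_auc(y, s) == pytest.approx(roc_auc(y, s**2))

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError):
            roc_auc(np.ones(5), np.random.default_rng(1).random(5))

    def test_matches_pairwise_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(100):
            n = int(rng.integers(5, 200))
            y = rng.integers(0, 2, n)
            if y.min() == y.max():
                y[0] = 1 - y[0]
            s = np.round(rng.random(n), 2)  # rounding forces ties
            assert roc_auc(y, s) == pytest.approx(pairwise_auc_oracle(y, s))


class TestWeightedAccuracy:
    def test_equal_weights_reduce_to_accuracy(self):
        assert weighted_accuracy(MURMUR_HOLDOUT, (1, 1)) == pytest.approx(87 / 95)

    def test_screening_weights_hand_arithmetic(self):
        # positives weighted 5: (5*17 + 70) / (5*25 + 70) = 155/195
        assert weighted_accuracy(MURMUR_HOLDOUT, (5, 1)) == pytest.approx(155 / 195)

    def test_all_correct_any_weights(self):
        m = ConfusionMatrix2(tp=4, fp=0, fn=0, tn=9)
        assert weighted_accuracy(m, (7, 2)) == 1.0

    def test_three_class_matrix(self):
        m = np.array([[8, 1, 1], [2, 6, 2], [0, 0, 10]])
        w = (5, 3, 1)
        expected = (5 * 8 + 3 * 6 + 1 * 10) / (5 * 10 + 3 * 10 + 1 * 10)
        assert weighted_accuracy(m, w) == pytest.approx(expected)

    def test_weight_count_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            weighted_accuracy(MURMUR_HOLDOUT, (1, 2, 3))

    def test_nonpositive_weights_rejected(self):
        with pytest.raises(ValidationError):
            weighted_accuracy(MURMUR_HOLDOUT, (0, 1))


class TestThresholdSweep:
    def test_separable_scores_on_coarse_grid(self):
        y = np.array([0, 0, 1, 1])
        s = np.array([0.1, 0.2, 0.8, 0.9])
        curve = threshold_sweep(y, s, np.array([0.0, 0.5, 1.0]))
        at = {t: i for i, t in enumerate(curve.thresholds)}
        assert curve.fpr[at[0.0]] == 1.0 and curve.fnr[at[0.0]] == 0.0
        assert curve.fpr[at[0.5]] == 0.0 and curve.fnr[at[0.5]] == 0.0
        assert curve.fpr[at[1.0]] == 0.0 and curve.fnr[at[1.0]] == 1.0

    def test_constant_scores_all_positive_at_half(self):
        y = np.array([0, 1, 0])
        curve = threshold_sweep(y, np.full(3, 0.7), np.array([0.5]))
        assert curve.at(0.5)["fnr"] == 0.0 and curve.at(0.5)["fpr"] == 1.0

    def test_monotone_error_rates(self):
        rng = np.random.default_rng(3)
        y = rng.integers(0, 2, 60)
        y[:2] = [0, 1]
        s = rng.random(60)
        curve = threshold_sweep(y, s)
        assert np.all(np.diff(curve.fnr) >= 0)
        assert np.all(np.diff(curve.fpr) <= 0)

    def test_accuracy_extremes_match_class_priors(self):
        rng = np.random.default_rng(4)
        y = rng.integers(0, 2, 80)
        y[:2] = [0, 1]
        curve = threshold_sweep(y, rng.uniform(0.05, 0.95, 80), np.array([0.0, 1.0]))
        assert curve.accuracy[0] == pytest.approx(y.mean())  # all positive
        assert curve.accuracy[-1] == pytest.approx(1 - y.mean())  # all negative

    def test_denser_grid_agrees_at_shared_thresholds(self):
        rng = np.random.default_rng(5)
        y = rng.integers(0, 2, 40)
        y[:2] = [0, 1]
        s = rng.random(40)
        coarse = threshold_sweep(y, s, np.linspace(0, 1, 11))
        fine = threshold_sweep(y, s, np.linspace(0, 1, 21))
        for i, t in enumerate(coarse.thresholds):
            j = int(np.argmin(np.abs(fine.thresholds - t)))
            assert fine.accuracy[j] == coarse.accuracy[i]

    def test_grid_always_includes_half(self):
        y, s = np.array([0, 1]), np.array([0.2, 0.9])
        assert 0.5 in threshold_sweep(y, s, np.array([0.1, 0.9])).thresholds

    def test_empty_grid_rejected(self):
        with pytest.raises(ValidationError):
            threshold_sweep(np.array([0, 1]), np.array([0.2, 0.9]), np.array([]))


class TestFoldsAndSplits:
    def test_partition_and_disjointness(self):
        catalog, labels = make_catalog({0: 74, 1: 26})
        folds = grouped_kfold(catalog, labels, k=10, seed=1)
        all_test = [pid for _, te in folds for pid in te]
        assert sorted(all_test) == sorted(labels)  # partition
        for tr, te in folds:
            assert not set(tr) & set(te)
            assert len(te) == 10

    def test_same_seed_identical_folds(self):
        catalog, labels = make_catalog({0: 40, 1: 20})
        a = grouped_kfold(catalog, labels, k=5, seed=7)
        b = grouped_kfold(catalog, labels, k=5, seed=7)
        assert a == b

    def test_stratification_counts(self):
        catalog, labels = make_catalog({0: 74, 1: 19, 2: 7})
        # binarise the three-way mix: classes 1 and 2 positive
        binary = {pid: int(v > 0) for pid, v in labels.items()}
        folds = grouped_kfold(catalog, binary, k=10, seed=2)
        global_pos = sum(binary.values()) / len(binary)
        for _, te in folds:
            n_pos = sum(binary[p] for p in te)
            assert abs(n_pos - global_pos * len(te)) <= 2

    def test_k_larger_than_n_rejected(self):
        catalog, labels = make_catalog({0: 3, 1: 3})
        with pytest.raises(ValidationError):
            grouped_kfold(catalog, labels, k=10)

    def test_split_fraction_and_determinism(self):
        catalog, labels = make_catalog({0: 70, 1: 30})
        tr1, te1 = split_patients(catalog, labels, train_fraction=0.7, seed=3)
        tr2, te2 = split_patients(catalog, labels, train_fraction=0.7, seed=3)
        assert (tr1, te1) == (tr2, te2)
        assert len(tr1) == 70 and len(te1) == 30
        assert not set(tr1) & set(te1)


class TestBalancedSubsample:
    def test_majority_downsampled_to_minority(self):
        catalog, labels = make_catalog({0: 2488, 1: 665})
        balanced = balanced_subsample(catalog, labels, seed=0)
        counts = {0: 0, 1: 0}
        for p in balanced.patients:
            counts[labels[p.patient_id]] += 1
        assert counts == {0: 665, 1: 665}
        assert len(balanced) == 1330

    def test_already_balanced_unchanged_sizes(self):
        catalog, labels = make_catalog({0: 30, 1: 30})
        assert len(balanced_subsample(catalog, labels, seed=1)) == 60

    def test_two_seeds_same_sizes_different_membership(self):
        catalog, labels = make_catalog({0: 200, 1: 50})
        a = balanced_subsample(catalog, labels, seed=1)
        b = balanced_subsample(catalog, labels, seed=2)
        assert len(a) == len(b) == 100
        assert {p.patient_id for p in a} != {p.patient_id for p in b}

    def test_empty_class_rejected(self):
        catalog, labels = make_catalog({0: 10})
        with pytest.raises(ValidationError):
            balanced_subsample(catalog, labels, seed=0)


class _FakeModel:
    def __init__(self):
        self.w = np.arange(4.0)

    def state_dict(self):
        return {"w": self.w.copy()}


class _FakePipeline:
    """Minimal stand-in exposing the model/evaluate surface of the pipeline."""

    def __init__(self, mutate=False):
        self.model = _FakeModel()
        self.mutate = mutate

    def evaluate(self, catalog, threshold=0.5):
        if self.mutate:
            self.model.w += 1.0
        from pcgscreen.evaluation import MetricsReport

        return MetricsReport(
            acc_overall=1.0, acc_positive=1.0, acc_negative=1.0, fnr=0.0, fpr=0.0, n=1
        )


class TestZeroShotGuard:
    def test_mutation_detected(self):
        with pytest.raises(ValidationError, match="mutated"):
            zero_shot_eval(_FakePipeline(mutate=True), None)

    def test_clean_evaluation_passes(self):
        report = zero_shot_eval(_FakePipeline(mutate=False), None)
        assert report.acc_overall == 1.0

    def test_fingerprint_sensitive_to_values(self):
        a = {"w": np.zeros(3)}
        b = {"w": np.zeros(3)}
        assert parameter_fingerprint(a) == parameter_fingerprint(b)
        b["w"][0] = 1e-12
        assert parameter_fingerprint(a) != parameter_fingerprint(b)
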