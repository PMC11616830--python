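"""Metrics and the evaluation protocol.

Conventions: a score is called positive when ``score >= threshold``; the
positive class is Present/Unknown murmur or Abnormal outcome depending on the
task.  Per-class accuracies are recalls (``acc_positive = tp / (tp + fn)``),
FNR/FPR their complements, and AUC is the Mann-Whitney rank statistic with ties
counted one half.  Cross-validated reports carry per-fold values plus their
mean and standard deviation.  An empty class makes the affected rate NaN with a
flag rather than silently zero.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold

from .io_formats import DatasetCatalog, MurmurLabel, OutcomeLabel, PatientRecord, ValidationError


@dataclass(frozen=True)
class ConfusionMatrix2:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValidationError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass
class MetricsReport:
    acc_overall: float
    acc_positive: float
    acc_negative: float
    fnr: float
    fpr: float
    auc: float | None = None
    weighted_accuracy: float | None = None
    n: int = 0
    flags: tuple[str, ...] = ()
    fold_values: dict[str, list[float]] = field(default_factory=dict)

    def fold_mean_std(self, metric: str) -> tuple[float, float]:
        values = np.asarray(self.fold_values[metric], dtype=np.float64)
        return float(np.nanmean(values)), float(np.nanstd(values))

    def as_dict(self) -> dict:
        out = {
            "acc_overall": self.acc_overall,
            "acc_positive": self.acc_positive,
            "acc_negative": self.acc_negative,
            "fnr": self.fnr,
            "fpr": self.fpr,
            "auc": self.auc,
            "weighted_accuracy": self.weighted_accuracy,
            "n": self.n,
            "flags": list(self.flags),
        }
        if self.fold_values:
            out["folds"] = {
                m: {"values": v, "mean": float(np.nanmean(v)), "std": float(np.nanstd(v))}
                for m, v in self.fold_values.items()
            }
        return out


def confusion(
    labels: np.ndarray, scores: np.ndarray, threshold: float = 0.5
) -> ConfusionMatrix2:
    """Confusion matrix at a decision threshold (``score >= t`` is positive)."""
    labels = np.asarray(labels).astype(int)
    scores = np.asarray(scores, dtype=np.float64)
    if labels.shape != scores.shape:
        raise ValidationError("labels and scores must have equal length")
    pred = scores >= threshold
    pos = labels == 1
    return ConfusionMatrix2(
        tp=int(np.sum(pred & pos)),
        fp=int(np.sum(pred & ~pos)),
        fn=int(np.sum(~pred & pos)),
        tn=int(np.sum(~pred & ~pos)),
    )


def rates(matrix: ConfusionMatrix2) -> MetricsReport:
    """Accuracy triple and error rates from a confusion matrix."""
    if matrix.total == 0:
        raise ValidationError("empty confusion matrix")
    flags = []
    n_pos = matrix.tp + matrix.fn
    n_neg = matrix.tn + matrix.fp
    acc_pos = matrix.tp / n_pos if n_pos else float("nan")
    acc_neg = matrix.tn / n_neg if n_neg else float("nan")
    if n_pos == 0:
        flags.append("no_positive_examples")
    if n_neg == 0:
        flags.append("no_negative_examples")
    return MetricsReport(
        acc_overall=(matrix.tp + matrix.tn) / matrix.total,
        acc_positive=acc_pos,
        acc_negative=acc_neg,
        fnr=matrix.fn / n_pos if n_pos else float("nan"),
        fpr=matrix.fp / n_neg if n_neg else float("nan"),
        n=matrix.total,
        flags=tuple(flags),
    )


def roc_auc(labels: np.ndarray, scores: np.ndarray) -> float:
    """AUC as the Mann-Whitney pairwise statistic with ties counted 1/2.

    Invariant under strictly monotone transforms of the scores; raises when a
    class is absent.
    """
    labels = np.asarray(labels).astype(int)
    scores = np.asarray(scores, dtype=np.float64)
    n_pos = int(np.sum(labels == 1))
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("AUC needs both classes present")
    ranks = rankdata(scores)  # average ranks handle ties as 1/2
    pos_rank_sum = ranks[labels == 1].sum()
    return float((pos_rank_sum - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def weighted_accuracy(matrix, weights) -> float:
    """Class-weighted accuracy: sum_i w_i*correct_i / sum_i w_i*total_i.

    ``matrix`` is either a :class:`ConfusionMatrix2` (weights ordered positive,
    negative) or a square array with rows = true classes and columns =
    predicted classes.  Equal weights reduce to plain accuracy.
    """
    weights = np.asarray(weights, dtype=np.float64)
    if np.any(weights <= 0):
        raise ValidationError("weights must be positive")
    if isinstance(matrix, ConfusionMatrix2):
        correct = np.array([matrix.tp, matrix.tn], dtype=np.float64)
        totals = np.array([matrix.tp + matrix.fn, matrix.tn + matrix.fp], dtype=np.float64)
    else:
        m = np.asarray(matrix, dtype=np.float64)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValidationError("matrix must be square (rows = true classes)")
        correct = np.diag(m)
        totals = m.sum(axis=1)
    if weights.size != correct.size:
        raise ValidationError("one weight per true class required")
    return float((weights * correct).sum() / (weights * totals).sum())


#: 2022-challenge murmur weights (Present, Unknown, Absent), shipped as config.
CHALLENGE_MURMUR_WEIGHTS = (5.0, 3.0, 1.0)


@dataclass
class ThresholdCurve:
    thresholds: np.ndarray
    accuracy: np.ndarray
    fpr: np.ndarray
    fnr: np.ndarray

    def at(self, threshold: float) -> dict[str, float]:
        i = int(np.argmin(np.abs(self.thresholds - threshold)))
        return {
            "threshold": float(self.thresholds[i]),
            "accuracy": float(self.accuracy[i]),
            "fpr": float(self.fpr[i]),
            "fnr": float(self.fnr[i]),
        }


def threshold_sweep(
    labels: np.ndarray, scores: np.ndarray, grid: np.ndarray | None = None
) -> ThresholdCurve:
    """Accuracy/FPR/FNR over a threshold grid (always including 0.5).

    FNR is non-decreasing and FPR non-increasing in the threshold under the
    ``score >= t`` convention.
    """
    if grid is None:
        grid = np.linspace(0.0, 1.0, 101)
    grid = np.asarray(grid, dtype=np.float64)
    if grid.size == 0:
        raise ValidationError("empty threshold grid")
    if np.any(grid < 0) or np.any(grid > 1):
        raise ValidationError("thresholds must lie in [0, 1]")
    grid = np.unique(np.append(grid, 0.5))
    acc, fpr, fnr = [], [], []
    for t in grid:
        rep = rates(confusion(labels, scores, t))
        acc.append(rep.acc_overall)
        fpr.append(rep.fpr)
        fnr.append(rep.fnr)
    return ThresholdCurve(
        thresholds=grid,
        accuracy=np.asarray(acc),
        fpr=np.asarray(fpr),
        fnr=np.asarray(fnr),
    )


# ---------------------------------------------------------------------------
# protocol: folds, subsampling, splits
# ---------------------------------------------------------------------------

def binary_murmur_target(record: PatientRecord, positive_unknown: bool = True) -> int | None:
    """Binary murmur target: Present (and by default Unknown) = positive."""
    if record.murmur == MurmurLabel.PRESENT:
        return 1
    if record.murmur == MurmurLabel.UNKNOWN:
        return 1 if positive_unknown else 0
    if record.murmur == MurmurLabel.ABSENT:
        return 0
    return None


def binary_outcome_target(record: PatientRecord) -> int | None:
    if record.outcome == OutcomeLabel.ABNORMAL:
        return 1
    if record.outcome == OutcomeLabel.NORMAL:
        return 0
    return None


def grouped_kfold(
    catalog: DatasetCatalog,
    labels: dict[str, int],
    k: int = 10,
    seed: int = 0,
) -> list[tuple[list[str], list[str]]]:
    """Patient-level stratified k-fold: ``(train_ids, test_ids)`` per fold.

    Folds partition patients, so every window of a patient lands in exactly one
    fold; stratification approximately preserves label proportions.
    """
    ids = [p.patient_id for p in catalog.patients if p.patient_id in labels]
    if k > len(ids):
        raise ValidationError(f"k={k} exceeds {len(ids)} labelled patients")
    y = np.array([labels[i] for i in ids])
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = []
    ids_arr = np.array(ids)
    for tr, te in skf.split(ids_arr, y):
        folds.append((list(ids_arr[tr]), list(ids_arr[te])))
    return folds


def balanced_subsample(
    catalog: DatasetCatalog, labels: dict[str, int], seed: int = 0
) -> DatasetCatalog:
    """Equalise class counts by sampling the majority class down (no replacement)."""
    by_class: dict[int, list[str]] = {}
    for p in catalog.patients:
        if p.patient_id in labels:
            by_class.setdefault(labels[p.patient_id], []).append(p.patient_id)
    if len(by_class) < 2 or any(len(v) == 0 for v in by_class.values()):
        raise ValidationError("balanced subsampling needs both classes present")
    n_min = min(len(v) for v in by_class.values())
    rng = np.random.default_rng(seed)
    keep: list[str] = []
    for cls in sorted(by_class):
        members = sorted(by_class[cls])
        keep.extend(rng.choice(members, size=n_min, replace=False))
    return catalog.subset(keep)


def split_patients(
    catalog: DatasetCatalog,
    labels: dict[str, int],
    train_fraction: float = 0.7,
    seed: int = 0,
) -> tuple[list[str], list[str]]:
    """Seeded stratified patient-level split (the 70/30 fine-tune convention)."""
    if not 0 < train_fraction < 1:
        raise ValidationError("train_fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    train: list[str] = []
    test: list[str] = []
    by_class: dict[int, list[str]] = {}
    for p in catalog.patients:
        if p.patient_id in labels:
            by_class.setdefault(labels[p.patient_id], []).append(p.patient_id)
    for cls in sorted(by_class):
        members = sorted(by_class[cls])
        perm = rng.permutation(len(members))
        n_train = int(round(train_fraction * len(members)))
        train.extend(members[i] for i in perm[:n_train])
        test.extend(members[i] for i in perm[n_train:])
    return sorted(train), sorted(test)


# ---------------------------------------------------------------------------
# zero-shot transfer
# ---------------------------------------------------------------------------

def parameter_fingerprint(state: dict[str, np.ndarray]) -> str:
    digest = hashlib.sha256()
    for name in sorted(state):
        digest.update(name.encode())
        digest.update(np.ascontiguousarray(state[name]).tobytes())
    return digest.hexdigest()


def zero_shot_eval(
    pipeline,
    foreign_catalog: DatasetCatalog,
    threshold: float = 0.5,
) -> MetricsReport:
    """Evaluate a trained pipeline on a foreign catalog with no adaptation.

    The foreign data run through the identical preprocessing; a parameter
    fingerprint taken before and after prediction guards against any mutation.
    The report carries (overall, positive-class, negative-class) accuracies —
    the transfer-matrix convention.
    """
    before = parameter_fingerprint(pipeline.model.state_dict())
    report = pipeline.evaluate(foreign_catalog, threshold=threshold)
    after = parameter_fingerprint(pipeline.model.state_dict())
    if before != after:
        raise ValidationError("zero-shot evaluation mutated model parameters")
    return report
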