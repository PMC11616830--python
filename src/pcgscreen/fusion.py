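"""Patient-level aggregation and multimodal late fusion.

Window probabilities are averaged in two stages — windows within a recording,
then recordings within the patient — so that a patient with many windows at one
auscultation site is not over-weighted (a pooled single-stage mean is available
as ``mode="pooled"``).  The aggregated deep score is then fused with imputed
demographics and patient-level signal features by a gradient-boosted tree
classifier (XGBoost), optionally with inverse-class-frequency sample weights.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import xgboost as xgb
from xgboost import XGBClassifier

from .bbres import WindowPrediction
from .io_formats import ValidationError


class Task(str, enum.Enum):
    MURMUR = "murmur_binary"
    OUTCOME = "outcome_binary"


@dataclass
class PatientPrediction:
    patient_id: str
    p_deep: float
    p_deep_std: float
    task: Task = Task.MURMUR
    p_fused: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_deep <= 1.0 or self.p_deep_std < 0:
            raise ValidationError(f"{self.patient_id}: invalid aggregated prediction")

    @property
    def score(self) -> float:
        """Final screening score: fused when available, else the deep score."""
        return self.p_fused if self.p_fused is not None else self.p_deep


def aggregate_patient(
    patient_id: str,
    window_predictions: list[WindowPrediction],
    task: Task = Task.MURMUR,
    mode: str = "two_stage",
) -> PatientPrediction:
    """Arithmetic-mean aggregation of window predictions to patient level.

    ``two_stage`` (default): mean over windows within each recording, then mean
    over recordings.  ``pooled``: plain mean over all windows.  MC standard
    deviations are propagated by the same averaging.  Permutation-invariant and
    bounded by the window-score extremes.
    """
    if not window_predictions:
        raise ValidationError(f"{patient_id}: no window predictions to aggregate")
    if mode == "pooled":
        p = float(np.mean([w.p_mean for w in window_predictions]))
        s = float(np.mean([w.p_std for w in window_predictions]))
    elif mode == "two_stage":
        by_rec: dict[int, list[WindowPrediction]] = {}
        for w in window_predictions:
            by_rec.setdefault(w.recording_index, []).append(w)
        rec_means = [np.mean([w.p_mean for w in ws]) for ws in by_rec.values()]
        rec_stds = [np.mean([w.p_std for w in ws]) for ws in by_rec.values()]
        p, s = float(np.mean(rec_means)), float(np.mean(rec_stds))
    else:
        raise ValidationError(f"unknown aggregation mode {mode!r}")
    return PatientPrediction(patient_id=patient_id, p_deep=p, p_deep_std=s, task=task)


def _margin_logit(rows: np.ndarray, column: int) -> np.ndarray:
    """Clamped logit of the deep-score column, used as the boosting offset."""
    p = np.clip(rows[:, column], 1e-6, 1 - 1e-6)
    return np.log(p / (1 - p))


@dataclass
class FusionModel:
    """Fitted boosted-tree fusion classifier plus its column manifest.

    When ``margin_column`` is set, the trees were fitted as residual
    corrections on top of the deep score's logit (supplied as XGBoost base
    margin); fused probabilities then stay anchored to — and vary continuously
    with — the deep score instead of re-binning it.
    """

    booster: XGBClassifier | xgb.Booster
    columns: tuple[str, ...]
    task: Task = Task.MURMUR
    margin_column: int | None = None

    def _raw_booster(self) -> xgb.Booster:
        return (
            self.booster.get_booster()
            if isinstance(self.booster, XGBClassifier)
            else self.booster
        )

    def positive_probability(self, rows: np.ndarray, margin: np.ndarray | None) -> np.ndarray:
        raw = self._raw_booster()
        dmat = xgb.DMatrix(rows, base_margin=margin)
        best = getattr(raw, "best_iteration", None)
        kwargs = {} if best is None else {"iteration_range": (0, best + 1)}
        return np.asarray(raw.predict(dmat, **kwargs), dtype=np.float64)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        self._raw_booster().save_model(path.with_suffix(".ubj"))
        path.with_suffix(".manifest.json").write_text(
            json.dumps(
                {
                    "columns": list(self.columns),
                    "task": self.task.value,
                    "margin_column": self.margin_column,
                }
            )
        )

    @classmethod
    def load(cls, path: str | Path) -> "FusionModel":
        path = Path(path)
        booster = xgb.Booster()
        booster.load_model(str(path.with_suffix(".ubj")))
        meta = json.loads(path.with_suffix(".manifest.json").read_text())
        return cls(
            booster=booster,
            columns=tuple(meta["columns"]),
            task=Task(meta["task"]),
            margin_column=meta.get("margin_column"),
        )


@dataclass
class FusionConfig:
    """Non-canonical boosted-tree defaults: shallow trees, few rounds."""

    max_depth: int = 3
    n_estimators: int = 200
    learning_rate: float = 0.1
    early_stopping_rounds: int = 20
    val_fraction: float = 0.2
    seed: int = 0
    include_std: bool = False


def train_fusion(
    rows: np.ndarray,
    labels: np.ndarray,
    columns: tuple[str, ...],
    config: FusionConfig | None = None,
    class_weighting: bool = False,
    task: Task = Task.MURMUR,
    margin_column: int | None = None,
) -> FusionModel:
    """Fit the fusion classifier on training-fold rows only.

    ``rows`` must contain no missing values (imputation happens upstream).  A
    seeded validation slice drives early stopping; with ``class_weighting`` the
    samples carry inverse-class-frequency weights.  ``margin_column`` names the
    deep-score column whose logit anchors the boosting (residual stacking).
    """
    config = config or FusionConfig()
    rows = np.asarray(rows, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.int64)
    if rows.ndim != 2 or rows.shape[0] != labels.size:
        raise ValidationError("rows and labels must align")
    if rows.shape[1] != len(columns):
        raise ValidationError("rows and column manifest disagree on width")
    if np.isnan(rows).any():
        raise ValidationError("fusion rows contain missing values")
    if len(np.unique(labels)) < 2:
        raise ValidationError("fusion training needs both classes")

    rng = np.random.default_rng(config.seed)
    n = labels.size
    n_val = int(round(config.val_fraction * n))
    order = rng.permutation(n)
    val_idx, tr_idx = order[:n_val], order[n_val:]
    # early stopping needs both classes on each side; fall back to no stopping
    use_es = (
        n_val > 0
        and len(np.unique(labels[tr_idx])) == 2
        and len(np.unique(labels[val_idx])) == 2
    )

    weights = None
    if class_weighting:
        pos = labels.mean()
        weights = np.where(labels == 1, 0.5 / max(pos, 1e-9), 0.5 / max(1 - pos, 1e-9))
    margin = None if margin_column is None else _margin_logit(rows, margin_column)

    booster = XGBClassifier(
        max_depth=config.max_depth,
        n_estimators=config.n_estimators,
        learning_rate=config.learning_rate,
        random_state=config.seed,
        n_jobs=1,
        eval_metric="logloss",
        early_stopping_rounds=config.early_stopping_rounds if use_es else None,
        tree_method="hist",
    )
    if use_es:
        booster.fit(
            rows[tr_idx],
            labels[tr_idx],
            sample_weight=None if weights is None else weights[tr_idx],
            eval_set=[(rows[val_idx], labels[val_idx])],
            base_margin=None if margin is None else margin[tr_idx],
            base_margin_eval_set=None if margin is None else [margin[val_idx]],
            verbose=False,
        )
    else:
        booster.fit(rows, labels, sample_weight=weights, base_margin=margin, verbose=False)
    return FusionModel(
        booster=booster, columns=tuple(columns), task=task, margin_column=margin_column
    )


def predict_fused(model: FusionModel, rows: np.ndarray) -> np.ndarray:
    """Fused probabilities for feature rows matching the training manifest."""
    rows = np.atleast_2d(np.asarray(rows, dtype=np.float64))
    if rows.shape[1] != len(model.columns):
        raise ValidationError(
            f"row width {rows.shape[1]} != trained width {len(model.columns)}"
        )
    margin = (
        None if model.margin_column is None else _margin_logit(rows, model.margin_column)
    )
    return model.positive_probability(rows, margin)


def build_fusion_columns(
    demographic_columns: tuple[str, ...],
    signal_columns: tuple[str, ...],
    include_std: bool = False,
) -> tuple[str, ...]:
    cols: tuple[str, ...] = ("p_deep",)
    if include_std:
        cols += ("p_deep_std",)
    return cols + demographic_columns + signal_columns
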