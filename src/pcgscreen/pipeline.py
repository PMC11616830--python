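"""End-to-end screening pipeline.

``train_pipeline`` wires the stages together for one task (murmur or outcome):
read and preprocess every labelled patient's recordings into log-mel windows,
train the Bayesian ResNet at window level (labels inherited from the patient),
aggregate Monte-Carlo window predictions to patient scores, and fit the XGBoost
fusion model on the aggregated score plus imputed demographics and signal
features.  The returned :class:`TrainedPipeline` predicts and evaluates any
catalog through the identical preprocessing, which is what the zero-shot
transfer protocol requires.

A single pipeline seed fans out to per-stage seeds (model init/batching,
validation split, fusion, MC inference) through ``numpy.random.SeedSequence``
spawn keys, so each stage is independently reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .bbres import BBResConfig, WindowPrediction, build_bbres, predict_window_mc, train_bbres
from .evaluation import (
    MetricsReport,
    binary_murmur_target,
    binary_outcome_target,
    confusion,
    grouped_kfold,
    rates,
    roc_auc,
    split_patients,
)
from .features import (
    DEMOGRAPHIC_COLUMNS,
    SIGNAL_FEATURE_COLUMNS,
    ImputerStats,
    apply_imputer,
    encode_demographics,
    fit_imputer,
    patient_signal_features,
)
from .fusion import (
    FusionConfig,
    FusionModel,
    PatientPrediction,
    Task,
    aggregate_patient,
    build_fusion_columns,
    predict_fused,
    train_fusion,
)
from .io_formats import DatasetCatalog, ValidationError, read_recording
from .preprocess import SpectrogramParams, normalize_amplitude, preprocess_recording, resample


@dataclass
class PipelineConfig:
    task: Task = Task.MURMUR
    spectrogram: SpectrogramParams = field(default_factory=SpectrogramParams)
    model: BBResConfig = field(default_factory=BBResConfig)
    fusion: FusionConfig = field(default_factory=FusionConfig)
    use_fusion: bool = True
    aggregation_mode: str = "two_stage"
    threshold: float = 0.5
    val_fraction: float = 0.2
    positive_unknown: bool = True
    seed: int = 0

    def stage_seed(self, stage: int) -> int:
        return int(
            np.random.SeedSequence(self.seed, spawn_key=(stage,)).generate_state(1)[0]
            % 2**31
        )


def task_labels(catalog: DatasetCatalog, task: Task, positive_unknown: bool = True) -> dict[str, int]:
    """Binary patient labels for a task; unlabelled patients are omitted."""
    labels: dict[str, int] = {}
    for p in catalog.patients:
        y = (
            binary_murmur_target(p, positive_unknown)
            if task == Task.MURMUR
            else binary_outcome_target(p)
        )
        if y is not None:
            labels[p.patient_id] = y
    return labels


@dataclass
class PatientData:
    """Preprocessed per-patient artefacts."""

    windows: np.ndarray  # (n_windows, n_mels, n_frames) float32
    recording_indices: np.ndarray
    offsets: np.ndarray
    demographics: np.ndarray  # raw (pre-imputation) DemographicVector values
    demographics_mask: np.ndarray
    signal: np.ndarray


def prepare_patients(
    catalog: DatasetCatalog, params: SpectrogramParams
) -> dict[str, PatientData]:
    """Read, resample, normalise and window every patient's recordings.

    Patients with zero usable recordings are excluded with a warning — the
    evaluation protocol has no defined place for them.
    """
    out: dict[str, PatientData] = {}
    for patient in catalog.patients:
        recs = []
        for ref in patient.recordings:
            try:
                recs.append(read_recording(ref.path, location=ref.location))
            except (FileNotFoundError, OSError) as exc:
                warnings.warn(f"{patient.patient_id}: skipping {ref.path} ({exc})", stacklevel=2)
        if not recs:
            warnings.warn(
                f"{patient.patient_id}: no usable recordings; excluded", stacklevel=2
            )
            continue
        windows, rec_idx, offsets = [], [], []
        resampled = []
        for k, rec in enumerate(recs):
            for w in preprocess_recording(
                rec, params, patient_id=patient.patient_id, recording_index=k
            ):
                windows.append(w.image)
                rec_idx.append(k)
                offsets.append(w.offset_s)
            r = resample(rec, params.target_fs_hz)
            samples, _ = normalize_amplitude(r.samples)
            resampled.append(
                type(r)(samples=samples, fs_hz=r.fs_hz, location=r.location)
            )
        demo = encode_demographics(patient)
        sig = patient_signal_features(resampled, params)
        out[patient.patient_id] = PatientData(
            windows=np.stack(windows).astype(np.float32),
            recording_indices=np.asarray(rec_idx),
            offsets=np.asarray(offsets, dtype=np.float64),
            demographics=demo.values,
            demographics_mask=demo.missing_mask,
            signal=sig.values,
        )
    return out


def _window_matrix(
    data: dict[str, PatientData], patient_ids: list[str]
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    xs, groups, recs, offs = [], [], [], []
    for pid in patient_ids:
        d = data[pid]
        xs.append(d.windows)
        groups.append(np.full(d.windows.shape[0], pid))
        recs.append(d.recording_indices)
        offs.append(d.offsets)
    return (
        np.concatenate(xs),
        np.concatenate(groups),
        np.concatenate(recs),
        np.concatenate(offs),
    )


@dataclass
class TrainedPipeline:
    config: PipelineConfig
    model: object  # ResNet
    imputer: ImputerStats | None
    fusion_model: FusionModel | None

    def _window_predictions(
        self, data: dict[str, PatientData], patient_ids: list[str]
    ) -> dict[str, list[WindowPrediction]]:
        x, groups, recs, offs = _window_matrix(data, patient_ids)
        rng = np.random.default_rng(self.config.stage_seed(3))
        p_mean, p_std = predict_window_mc(
            self.model,
            x,
            self.config.model.mc_passes,
            rng,
            in_channels=self.config.model.in_channels,
        )
        by_patient: dict[str, list[WindowPrediction]] = {pid: [] for pid in patient_ids}
        for pm, ps, pid, rk, off in zip(p_mean, p_std, groups, recs, offs):
            by_patient[pid].append(
                WindowPrediction(
                    p_mean=float(pm),
                    p_std=float(ps),
                    patient_id=str(pid),
                    recording_index=int(rk),
                    offset_s=float(off),
                )
            )
        return by_patient

    def _fusion_rows(
        self,
        data: dict[str, PatientData],
        preds: dict[str, PatientPrediction],
        patient_ids: list[str],
    ) -> np.ndarray:
        rows = []
        for pid in patient_ids:
            d = data[pid]
            demo = apply_imputer(self.imputer, _vector(d.demographics, d.demographics_mask))
            base = [preds[pid].p_deep]
            if self.config.fusion.include_std:
                base.append(preds[pid].p_deep_std)
            rows.append(np.concatenate([base, demo.values, d.signal]))
        return np.asarray(rows, dtype=np.float64)

    def predict_prepared(
        self, data: dict[str, PatientData], patient_ids: list[str] | None = None
    ) -> list[PatientPrediction]:
        ids = sorted(data) if patient_ids is None else list(patient_ids)
        window_preds = self._window_predictions(data, ids)
        preds = {
            pid: aggregate_patient(
                pid, window_preds[pid], self.config.task, self.config.aggregation_mode
            )
            for pid in ids
        }
        if self.fusion_model is not None:
            rows = self._fusion_rows(data, preds, ids)
            fused = predict_fused(self.fusion_model, rows)
            for pid, pf in zip(ids, fused):
                preds[pid].p_fused = float(pf)
        return [preds[pid] for pid in ids]

    def predict(self, catalog: DatasetCatalog) -> list[PatientPrediction]:
        data = prepare_patients(catalog, self.config.spectrogram)
        return self.predict_prepared(data)

    def evaluate(
        self,
        catalog: DatasetCatalog,
        threshold: float | None = None,
        use_fused: bool = True,
    ) -> MetricsReport:
        data = prepare_patients(catalog, self.config.spectrogram)
        labels = task_labels(catalog, self.config.task, self.config.positive_unknown)
        ids = [pid for pid in sorted(data) if pid in labels]
        preds = self.predict_prepared(data, ids)
        return evaluate_predictions(
            preds, labels, threshold=self.config.threshold if threshold is None else threshold,
            use_fused=use_fused,
        )


def _vector(values: np.ndarray, mask: np.ndarray):
    from .features import DemographicVector

    return DemographicVector(values=values.copy(), missing_mask=mask.copy())


def evaluate_predictions(
    preds: list[PatientPrediction],
    labels: dict[str, int],
    threshold: float = 0.5,
    use_fused: bool = True,
) -> MetricsReport:
    """Score patient predictions against binary labels."""
    scored = [(labels[p.patient_id], p.score if use_fused else p.p_deep) for p in preds]
    if not scored:
        raise ValidationError("no labelled patients to evaluate")
    y = np.array([s[0] for s in scored])
    s = np.array([s[1] for s in scored])
    report = rates(confusion(y, s, threshold))
    if len(np.unique(y)) == 2:
        report.auc = roc_auc(y, s)
    return report


def train_pipeline(
    catalog: DatasetCatalog,
    config: PipelineConfig,
    data: dict[str, PatientData] | None = None,
    train_ids: list[str] | None = None,
) -> tuple[TrainedPipeline, dict]:
    """Train the full pipeline on (a subset of) a catalog.

    ``data`` may carry pre-computed windows (e.g. shared across CV folds);
    ``train_ids`` restricts training to those patients.  A patient-level
    stratified slice of the training set (``val_fraction``) drives deep-model
    checkpoint selection; imputer and fusion statistics are fitted on training
    patients only.
    """
    labels = task_labels(catalog, config.task, config.positive_unknown)
    if data is None:
        data = prepare_patients(catalog, config.spectrogram)
    ids = [pid for pid in sorted(data) if pid in labels]
    if train_ids is not None:
        ids = [pid for pid in ids if pid in set(train_ids)]
    if len(ids) < 4:
        raise ValidationError("too few labelled patients to train")

    sub_labels = {pid: labels[pid] for pid in ids}
    sub_catalog = catalog.subset(ids)
    tr_ids, val_ids = split_patients(
        sub_catalog, sub_labels, train_fraction=1 - config.val_fraction,
        seed=config.stage_seed(1),
    )

    x, groups, _, _ = _window_matrix(data, ids)
    y = np.array([sub_labels[str(pid)] for pid in groups], dtype=np.float64)

    model_cfg = config.model
    if model_cfg.seed == 0:
        model_cfg = replace(model_cfg, seed=config.stage_seed(0))
    model = build_bbres(model_cfg)
    model, history = train_bbres(model, x, y, groups, model_cfg, frozenset(val_ids))

    pipeline = TrainedPipeline(config=config, model=model, imputer=None, fusion_model=None)

    if config.use_fusion:
        pipeline.imputer = fit_imputer([_vector(data[pid].demographics, data[pid].demographics_mask) for pid in ids])
        window_preds = pipeline._window_predictions(data, ids)
        agg = {
            pid: aggregate_patient(pid, window_preds[pid], config.task, config.aggregation_mode)
            for pid in ids
        }
        rows = pipeline._fusion_rows(data, agg, ids)
        columns = build_fusion_columns(
            DEMOGRAPHIC_COLUMNS, SIGNAL_FEATURE_COLUMNS, config.fusion.include_std
        )
        fusion_cfg = replace(config.fusion, seed=config.stage_seed(2))
        pipeline.fusion_model = train_fusion(
            rows,
            np.array([sub_labels[pid] for pid in ids]),
            columns,
            fusion_cfg,
            class_weighting=config.model.class_weighting,
            task=config.task,
            margin_column=columns.index("p_deep"),
        )
    else:
        # imputer still fitted so predict() can build rows if asked later
        pipeline.imputer = fit_imputer(
            [_vector(data[pid].demographics, data[pid].demographics_mask) for pid in ids]
        )
    return pipeline, history


def cross_validate(
    catalog: DatasetCatalog,
    config: PipelineConfig,
    k: int = 10,
    data: dict[str, PatientData] | None = None,
) -> dict:
    """Grouped, stratified k-fold cross-validation of the full pipeline.

    Preprocessing is shared across folds; training and fusion statistics are
    re-fitted per fold on that fold's training patients only.  Returns per-fold
    reports plus mean/std summaries.
    """
    labels = task_labels(catalog, config.task, config.positive_unknown)
    if data is None:
        data = prepare_patients(catalog, config.spectrogram)
    usable = catalog.subset([pid for pid in sorted(data) if pid in labels])
    folds = grouped_kfold(usable, labels, k=k, seed=config.stage_seed(4))
    fold_reports: list[MetricsReport] = []
    fold_assignments = []
    for fold_idx, (train_ids, test_ids) in enumerate(folds):
        if set(train_ids) & set(test_ids):
            raise ValidationError("fold leakage: train and test patients overlap")
        fold_cfg = replace(config, seed=config.stage_seed(100 + fold_idx))
        pipeline, _ = train_pipeline(usable, fold_cfg, data=data, train_ids=train_ids)
        preds = pipeline.predict_prepared(data, test_ids)
        fold_reports.append(
            evaluate_predictions(preds, labels, threshold=config.threshold)
        )
        fold_assignments.append({"fold": fold_idx, "train": train_ids, "test": test_ids})

    metrics = ("acc_overall", "acc_positive", "acc_negative", "auc", "fnr", "fpr")
    summary = {}
    for m in metrics:
        vals = [getattr(r, m) for r in fold_reports]
        vals = [v for v in vals if v is not None]
        summary[m] = {
            "values": vals,
            "mean": float(np.nanmean(vals)),
            "std": float(np.nanstd(vals)),
        }
    return {"folds": [r.as_dict() for r in fold_reports], "summary": summary,
            "assignments": fold_assignments}
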