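"""Tabular features for the fusion stage.

Demographics are encoded the way the challenge baselines do: age categories map
to approximate months (Neonate 0.5, Infant 6, Child 72, Adolescent 180), sex is
one-hot, pregnancy is binary.  Missing numeric fields are mean-imputed with
statistics fitted on training folds only; categorical missingness is encoded as
all-zero one-hot columns and is never imputed.

Audio summary features cover the time domain (mean, std, skewness, kurtosis,
RMS, zero-crossing rate) and the frequency domain (frame-wise spectral
centroid, 85%-roll-off and bandwidth — mean and std of each — plus the dominant
frequency of the average magnitude spectrum).  Spectral moments are in Hz.
Per-patient vectors are the unweighted mean over recordings.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_formats import AgeGroup, PatientRecord, Recording, Sex, ValidationError
from .preprocess import SpectrogramParams, stft_power

#: Approximate age-category midpoints in months (challenge-baseline convention).
AGE_MONTHS = {
    AgeGroup.NEONATE: 0.5,
    AgeGroup.INFANT: 6.0,
    AgeGroup.CHILD: 72.0,
    AgeGroup.ADOLESCENT: 180.0,
}

DEMOGRAPHIC_COLUMNS = (
    "age_months",
    "sex_female",
    "sex_male",
    "pregnant",
    "height_cm",
    "weight_kg",
)
#: Numeric columns subject to mean imputation.
IMPUTED_COLUMNS = ("age_months", "height_cm", "weight_kg")

SIGNAL_FEATURE_COLUMNS = (
    "td_mean",
    "td_std",
    "td_skewness",
    "td_kurtosis",
    "td_rms",
    "td_zcr",
    "sp_centroid_mean",
    "sp_centroid_std",
    "sp_rolloff_mean",
    "sp_rolloff_std",
    "sp_bandwidth_mean",
    "sp_bandwidth_std",
    "sp_dominant_hz",
)

ROLLOFF_FRACTION = 0.85


@dataclass
class DemographicVector:
    """Encoded demographics with explicit missingness markers."""

    values: np.ndarray  # aligned with DEMOGRAPHIC_COLUMNS; NaN marks missing
    missing_mask: np.ndarray  # boolean, same alignment

    def as_dict(self) -> dict[str, float]:
        return dict(zip(DEMOGRAPHIC_COLUMNS, self.values))


def encode_demographics(record: PatientRecord) -> DemographicVector:
    """Encode one patient's demographics (pre-imputation).

    Missing age/height/weight are NaN with the mask set; missing sex yields
    all-zero one-hot columns; missing pregnancy maps to 0.
    """
    values = np.zeros(len(DEMOGRAPHIC_COLUMNS), dtype=np.float64)
    mask = np.zeros(len(DEMOGRAPHIC_COLUMNS), dtype=bool)
    cols = {c: i for i, c in enumerate(DEMOGRAPHIC_COLUMNS)}

    if record.age_group in AGE_MONTHS:
        values[cols["age_months"]] = AGE_MONTHS[record.age_group]
    else:
        values[cols["age_months"]] = np.nan
        mask[cols["age_months"]] = True

    values[cols["sex_female"]] = 1.0 if record.sex == Sex.FEMALE else 0.0
    values[cols["sex_male"]] = 1.0 if record.sex == Sex.MALE else 0.0
    if record.sex == Sex.MISSING:
        mask[cols["sex_female"]] = mask[cols["sex_male"]] = True

    values[cols["pregnant"]] = 1.0 if record.pregnant else 0.0
    if record.pregnant is None:
        mask[cols["pregnant"]] = True

    for attr, col in (("height_cm", "height_cm"), ("weight_kg", "weight_kg")):
        raw = getattr(record, attr)
        if raw is None:
            values[cols[col]] = np.nan
            mask[cols[col]] = True
        else:
            values[cols[col]] = raw
    return DemographicVector(values=values, missing_mask=mask)


@dataclass(frozen=True)
class ImputerStats:
    """Per-column training means for the numeric demographic fields."""

    means: dict[str, float]


def fit_imputer(vectors: list[DemographicVector]) -> ImputerStats:
    """Fit column means on training vectors only.

    Raises if a numeric column is missing in every training row — there is then
    no defensible fill value.
    """
    if not vectors:
        raise ValidationError("cannot fit an imputer on zero rows")
    matrix = np.stack([v.values for v in vectors])
    means: dict[str, float] = {}
    for col in IMPUTED_COLUMNS:
        i = DEMOGRAPHIC_COLUMNS.index(col)
        observed = matrix[:, i][~np.isnan(matrix[:, i])]
        if observed.size == 0:
            raise ValidationError(f"column {col!r} is missing in all training rows")
        means[col] = float(observed.mean())
    return ImputerStats(means=means)


def apply_imputer(stats: ImputerStats, vector: DemographicVector) -> DemographicVector:
    """Replace missing numeric fields by the fitted training means."""
    values = vector.values.copy()
    for col, mean in stats.means.items():
        i = DEMOGRAPHIC_COLUMNS.index(col)
        if np.isnan(values[i]):
            values[i] = mean
    return DemographicVector(values=values, missing_mask=vector.missing_mask.copy())


# ---------------------------------------------------------------------------
# signal features
# ---------------------------------------------------------------------------

@dataclass
class SignalFeatureVector:
    values: np.ndarray  # aligned with SIGNAL_FEATURE_COLUMNS
    degenerate: bool = False

    def as_dict(self) -> dict[str, float]:
        return dict(zip(SIGNAL_FEATURE_COLUMNS, self.values))


def _spectral_moments(power: np.ndarray, freqs: np.ndarray) -> tuple[np.ndarray, ...]:
    """Frame-wise centroid, roll-off and bandwidth from a power spectrogram."""
    mag = np.sqrt(power)
    total = mag.sum(axis=0)
    ok = total > 0
    centroid = np.zeros(power.shape[1])
    centroid[ok] = (freqs[:, None] * mag[:, ok]).sum(axis=0) / total[ok]
    # roll-off: lowest frequency below which ROLLOFF_FRACTION of energy lies
    energy = power
    cum = np.cumsum(energy, axis=0)
    tot_e = cum[-1]
    rolloff = np.zeros(power.shape[1])
    ok_e = tot_e > 0
    idx = np.argmax(cum[:, ok_e] >= ROLLOFF_FRACTION * tot_e[ok_e], axis=0)
    rolloff[ok_e] = freqs[idx]
    # bandwidth: magnitude-weighted std around the centroid
    bandwidth = np.zeros(power.shape[1])
    dev = (freqs[:, None] - centroid[None, :]) ** 2
    bandwidth[ok] = np.sqrt((dev[:, ok] * mag[:, ok]).sum(axis=0) / total[ok])
    return centroid, rolloff, bandwidth


def signal_features(
    recording: Recording, params: SpectrogramParams | None = None
) -> SignalFeatureVector:
    """Summary features of one (resampled, normalised) recording.

    Time-domain statistics plus frame-wise spectral moments: centroid
    ``sum(f*|S(f)|)/sum|S(f)|``, roll-off at 85% cumulative energy, and the
    energy-weighted standard deviation around the centroid.  An all-zero
    recording yields a zero vector flagged degenerate.
    """
    params = params or SpectrogramParams()
    x = np.asarray(recording.samples, dtype=np.float64)
    if not np.any(x):
        return SignalFeatureVector(
            values=np.zeros(len(SIGNAL_FEATURE_COLUMNS)), degenerate=True
        )
    std = x.std()
    centered = x - x.mean()
    if std > 0:
        skew = float(np.mean(centered**3) / std**3)
        kurt = float(np.mean(centered**4) / std**4 - 3.0)
    else:
        skew = kurt = 0.0
    zcr = float(np.mean(np.abs(np.diff(np.signbit(x).astype(np.int8)))))

    fs = recording.fs_hz
    win = params.stft_window_samples(fs)
    hop = params.stft_hop_samples(fs)
    if x.size < win:  # pad very short records to one analysis frame
        x_fft = np.zeros(win)
        x_fft[: x.size] = x
    else:
        n = 1 + (x.size - win) // hop
        x_fft = x[: win + (n - 1) * hop]
    seg_params = SpectrogramParams(
        window_s=len(x_fft) / fs,
        stride_s=params.stride_s,
        stft_window_ms=params.stft_window_ms,
        stft_hop_ms=params.stft_hop_ms,
        fmin_hz=params.fmin_hz,
        fmax_hz=min(params.fmax_hz, fs / 2),
        n_mels=params.n_mels,
        target_fs_hz=fs,
    )
    power = stft_power(x_fft, fs, seg_params)
    freqs = np.fft.rfftfreq(win, d=1.0 / fs)
    centroid, rolloff, bandwidth = _spectral_moments(power, freqs)
    dominant = float(freqs[int(np.argmax(power.mean(axis=1)))])

    values = np.array(
        [
            float(x.mean()),
            float(std),
            skew,
            kurt,
            float(np.sqrt(np.mean(x**2))),
            zcr,
            float(centroid.mean()),
            float(centroid.std()),
            float(rolloff.mean()),
            float(rolloff.std()),
            float(bandwidth.mean()),
            float(bandwidth.std()),
            dominant,
        ]
    )
    if not np.all(np.isfinite(values)):
        raise ValidationError("non-finite signal features")
    return SignalFeatureVector(values=values)


def patient_signal_features(
    recordings: list[Recording], params: SpectrogramParams | None = None
) -> SignalFeatureVector:
    """Unweighted mean of per-recording feature vectors (fixed width)."""
    if not recordings:
        raise ValidationError("patient has no recordings")
    vectors = [signal_features(r, params) for r in recordings]
    stacked = np.stack([v.values for v in vectors])
    return SignalFeatureVector(
        values=stacked.mean(axis=0),
        degenerate=all(v.degenerate for v in vectors),
    )
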