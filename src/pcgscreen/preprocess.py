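"""Waveform -> overlapping log-mel spectrogram windows.

Recordings are resampled to a common 4 kHz rate, peak-normalised to [-1, 1],
cut into overlapping 4 s segments with a 1 s stride, and each segment is turned
into a log-mel image: STFT with a 25 ms periodic Hann window and 10 ms hop (no
centering), a triangular mel filterbank spanning 10-2000 Hz, decibel scaling
with a power floor, then per-window min-max scaling to [0, 1].

The STFT is framed explicitly (no centering, no padding) so that the frame
count has the closed form ``1 + floor((n_samples - win) / hop)`` — 398 frames
for a 4 s segment at 4 kHz under the defaults.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .io_formats import Recording, ValidationError

#: Power floor used before the decibel transform.
LOG_FLOOR = 1e-10


@dataclass(frozen=True)
class SpectrogramParams:
    """Parameters of the windowed log-mel representation.

    Defaults follow the screening pipeline's configuration: 4 s segments with a
    1 s stride; a 25 ms periodic Hann analysis window with a 10 ms hop;
    mel band edges at 10 and 2000 Hz.  ``n_mels`` (the mel resolution) and the
    min-max scaling are implementation choices, configurable here.
    """

    window_s: float = 4.0
    stride_s: float = 1.0
    stft_window_ms: float = 25.0
    stft_hop_ms: float = 10.0
    fmin_hz: float = 10.0
    fmax_hz: float = 2000.0
    n_mels: int = 128
    log_floor: float = LOG_FLOOR
    target_fs_hz: int = 4000
    scale_01: bool = True

    def __post_init__(self) -> None:
        if not (0 <= self.fmin_hz < self.fmax_hz <= self.target_fs_hz / 2):
            raise ValidationError("need fmin < fmax <= target_fs/2")
        if self.stft_hop_ms > self.stft_window_ms:
            raise ValidationError("STFT hop must not exceed the analysis window")
        if self.window_s * 1000 < self.stft_window_ms:
            raise ValidationError("segment shorter than one analysis window")
        if self.n_mels < 1 or self.log_floor <= 0:
            raise ValidationError("n_mels >= 1 and log_floor > 0 required")

    def stft_window_samples(self, fs: int) -> int:
        return int(round(self.stft_window_ms * fs / 1000.0))

    def stft_hop_samples(self, fs: int) -> int:
        return int(round(self.stft_hop_ms * fs / 1000.0))

    def segment_samples(self, fs: int) -> int:
        return int(round(self.window_s * fs))

    def n_frames(self, fs: int) -> int:
        """Closed-form frame count of one segment under no-centering."""
        return 1 + (self.segment_samples(fs) - self.stft_window_samples(fs)) // self.stft_hop_samples(fs)


@dataclass
class SpectrogramWindow:
    """One 4 s log-mel image with provenance."""

    image: np.ndarray  # (n_mels, n_frames)
    patient_id: str
    recording_index: int
    offset_s: float
    flags: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.image)):
            raise ValidationError("spectrogram contains non-finite entries")


def resample(recording: Recording, target_fs: int) -> Recording:
    """Polyphase-resample a recording to ``target_fs`` (no-op when equal)."""
    if target_fs <= 0:
        raise ValidationError("target_fs must be positive")
    if recording.fs_hz == target_fs:
        return recording
    g = math.gcd(target_fs, recording.fs_hz)
    out = sps.resample_poly(recording.samples, target_fs // g, recording.fs_hz // g)
    return Recording(samples=out, fs_hz=target_fs, location=recording.location)


def normalize_amplitude(samples: np.ndarray) -> tuple[np.ndarray, bool]:
    """Peak-normalise to [-1, 1].

    Returns ``(normalised, degenerate)`` where ``degenerate`` flags an all-zero
    input returned unchanged.
    """
    samples = np.asarray(samples, dtype=np.float64)
    if not np.all(np.isfinite(samples)):
        raise ValidationError("samples must be finite")
    peak = np.max(np.abs(samples)) if samples.size else 0.0
    if peak == 0.0:
        return samples, True
    return samples / peak, False


def segment_windows(
    samples: np.ndarray, fs: int, params: SpectrogramParams
) -> list[tuple[np.ndarray, float, bool]]:
    """Cut a waveform into overlapping segments of ``window_s`` seconds.

    Returns ``(segment, offset_s, padded)`` triples with offsets 0, 1, 2, ... s.
    A recording shorter than one window yields a single zero-padded segment
    flagged ``padded=True`` (short records occur in the 2016/Yaseen-style data;
    dropping them would silently discard patients).
    """
    samples = np.asarray(samples, dtype=np.float64)
    seg_len = params.segment_samples(fs)
    hop = int(round(params.stride_s * fs))
    if samples.size < seg_len:
        padded = np.zeros(seg_len, dtype=np.float64)
        padded[: samples.size] = samples
        return [(padded, 0.0, True)]
    n = (samples.size - seg_len) // hop + 1
    return [
        (samples[i * hop : i * hop + seg_len], i * hop / fs, False)
        for i in range(n)
    ]


def hz_to_mel(f: np.ndarray | float) -> np.ndarray | float:
    return 2595.0 * np.log10(1.0 + np.asarray(f, dtype=np.float64) / 700.0)


def mel_to_hz(m: np.ndarray | float) -> np.ndarray | float:
    return 700.0 * (10.0 ** (np.asarray(m, dtype=np.float64) / 2595.0) - 1.0)


def mel_filterbank(
    n_mels: int, n_fft: int, fs: int, fmin: float, fmax: float
) -> tuple[np.ndarray, np.ndarray]:
    """Triangular mel filterbank (HTK mel scale).

    Returns ``(weights, centers_hz)`` with ``weights`` of shape
    ``(n_mels, n_fft // 2 + 1)`` and strictly increasing centre frequencies
    inside ``[fmin, fmax]``.
    """
    mel_pts = np.linspace(hz_to_mel(fmin), hz_to_mel(fmax), n_mels + 2)
    hz_pts = np.asarray(mel_to_hz(mel_pts))
    fft_freqs = np.fft.rfftfreq(n_fft, d=1.0 / fs)
    lower, center, upper = hz_pts[:-2], hz_pts[1:-1], hz_pts[2:]
    up = (fft_freqs[None, :] - lower[:, None]) / np.maximum(center - lower, 1e-12)[:, None]
    down = (upper[:, None] - fft_freqs[None, :]) / np.maximum(upper - center, 1e-12)[:, None]
    weights = np.maximum(0.0, np.minimum(up, down))
    return weights, center


def _frame(x: np.ndarray, win: int, hop: int) -> np.ndarray:
    n = 1 + (x.size - win) // hop
    idx = np.arange(win)[None, :] + hop * np.arange(n)[:, None]
    return x[idx]


def stft_power(segment: np.ndarray, fs: int, params: SpectrogramParams) -> np.ndarray:
    """Power spectrogram of one segment, shape ``(n_fft//2+1, n_frames)``."""
    win = params.stft_window_samples(fs)
    hop = params.stft_hop_samples(fs)
    window = sps.get_window("hann", win, fftbins=True)  # periodic Hann
    frames = _frame(np.asarray(segment, dtype=np.float64), win, hop) * window
    spec = np.fft.rfft(frames, axis=1)
    return (spec.real**2 + spec.imag**2).T


def log_mel(
    segment: np.ndarray,
    fs: int,
    params: SpectrogramParams,
    *,
    patient_id: str = "",
    recording_index: int = 0,
    offset_s: float = 0.0,
    flags: tuple[str, ...] = (),
) -> SpectrogramWindow:
    """Log-mel image of one fixed-length segment.

    STFT power -> mel filterbank -> 10*log10 with a power floor -> optional
    per-window min-max scaling to [0, 1].  A silent segment maps to a constant
    image (zero after scaling).
    """
    if params.fmax_hz > fs / 2:
        raise ValidationError("fmax exceeds Nyquist for this sampling rate")
    seg_len = params.segment_samples(fs)
    if len(segment) != seg_len:
        raise ValidationError(f"segment must hold exactly {seg_len} samples")
    power = stft_power(segment, fs, params)
    weights, _ = mel_filterbank(
        params.n_mels, params.stft_window_samples(fs), fs, params.fmin_hz, params.fmax_hz
    )
    mel_power = weights @ power
    image = 10.0 * np.log10(np.maximum(mel_power, params.log_floor))
    if params.scale_01:
        lo, hi = image.min(), image.max()
        image = (image - lo) / (hi - lo) if hi > lo else np.zeros_like(image)
    return SpectrogramWindow(
        image=image.astype(np.float32),
        patient_id=patient_id,
        recording_index=recording_index,
        offset_s=offset_s,
        flags=flags,
    )


def preprocess_recording(
    recording: Recording,
    params: SpectrogramParams,
    *,
    patient_id: str = "",
    recording_index: int = 0,
) -> list[SpectrogramWindow]:
    """Full per-recording chain: resample, peak-normalise, window, log-mel."""
    rec = resample(recording, params.target_fs_hz)
    samples, degenerate = normalize_amplitude(rec.samples)
    windows = []
    for segment, offset, padded in segment_windows(samples, rec.fs_hz, params):
        flags = tuple(
            f for f, on in (("degenerate", degenerate), ("padded", padded)) if on
        )
        windows.append(
            log_mel(
                segment,
                rec.fs_hz,
                params,
                patient_id=patient_id,
                recording_index=recording_index,
                offset_s=offset,
                flags=flags,
            )
        )
    return windows


def expected_window_count(duration_s: float, params: SpectrogramParams) -> int:
    """Closed-form segment count: ``floor((D - window)/stride) + 1`` (min 1)."""
    if duration_s < params.window_s:
        return 1
    return int(math.floor((duration_s - params.window_s) / params.stride_s)) + 1
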