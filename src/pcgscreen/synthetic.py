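"""Download-free synthetic phonocardiogram cohorts.

Waveforms are physiologically crude but controllable: each cardiac cycle is an
S1 and an S2 transient (damped sinusoids, 50-150 Hz centre, 30-50 ms) at a
heart rate drawn per recording; a murmur, when present, is band-limited
Gaussian noise (150-400 Hz) gated to systole at a configurable SNR relative to
the ambient noise floor; ambient white noise covers the whole record.  The
signal is peak-normalised and written as 16-bit PCM WAV in the 2022-style
layout, so generated cohorts scan back through :mod:`pcgscreen.io_formats`
unchanged.

Label statistics default to the murmur/outcome joint and the murmur-by-age
distribution of the 2022 training population (942 patients: 73.8% Absent,
7.2% Unknown, 19.0% Present; P(Abnormal | Present) = 150/179, etc.), with ~13%
concurrent age/height/weight missingness.  "Unknown" murmur patients are
generated as low-SNR murmurs, which is what makes the Present-or-Unknown
binary grouping learnable.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from scipy import signal as sps

from .io_formats import (
    LOCATIONS,
    AgeGroup,
    MurmurLabel,
    OutcomeLabel,
    PatientRecord,
    Recording,
    RecordingRef,
    Sex,
    ValidationError,
    format_patient_header,
    write_recording,
)
from .preprocess import normalize_amplitude

# 2022 training-population counts (murmur x outcome and murmur x age).
MURMUR_COUNTS = {"Absent": 695, "Unknown": 68, "Present": 179}  # of 942
ABNORMAL_GIVEN_MURMUR = {"Absent": 263 / 695, "Unknown": 43 / 68, "Present": 150 / 179}
# age rows (Neonate, Infant, Child, Adolescent) per murmur column, Missing row
# excluded: metadata missingness is applied as a separate concurrent mask.
AGE_GIVEN_MURMUR_COUNTS = {
    "Absent": {"Neonate": 4, "Infant": 76, "Child": 495, "Adolescent": 53},
    "Unknown": {"Neonate": 1, "Infant": 25, "Child": 37, "Adolescent": 3},
    "Present": {"Neonate": 1, "Infant": 25, "Child": 132, "Adolescent": 16},
}
# height/weight means and spreads by age group (crude paediatric anthropometry)
ANTHROPOMETRY = {
    AgeGroup.NEONATE: (50.0, 4.0, 3.5, 0.6),
    AgeGroup.INFANT: (68.0, 6.0, 8.0, 1.5),
    AgeGroup.CHILD: (115.0, 15.0, 22.0, 6.0),
    AgeGroup.ADOLESCENT: (158.0, 10.0, 48.0, 9.0),
}


@dataclass(frozen=True)
class SimConfig:
    """Acoustic simulation parameters for one cohort."""

    fs_hz: int = 4000
    duration_range_s: tuple[float, float] = (5.0, 80.0)
    heart_rate_bpm: tuple[float, float] = (70.0, 140.0)
    s1_freq_hz: tuple[float, float] = (50.0, 150.0)
    transient_dur_s: tuple[float, float] = (0.03, 0.05)
    systole_fraction: float = 0.35
    murmur_band_hz: tuple[float, float] = (150.0, 400.0)
    murmur_snr_db: float = 10.0
    unknown_snr_offset_db: float = -12.0
    ambient_noise_db: float = -20.0
    n_locations: tuple[int, int] = (1, 6)

    def __post_init__(self) -> None:
        if self.fs_hz % 2 or self.fs_hz <= 0:
            raise ValidationError("fs must be a positive even integer")
        if self.duration_range_s[0] > self.duration_range_s[1]:
            raise ValidationError("bad duration range")
        if not np.isfinite(self.murmur_snr_db) or not np.isfinite(self.ambient_noise_db):
            raise ValidationError("SNR and noise level must be finite")
        if not 1 <= self.n_locations[0] <= self.n_locations[1] <= 6:
            raise ValidationError("locations per patient must lie in 1..6")


@dataclass(frozen=True)
class CohortConfig:
    """Cohort-level label and demographic statistics."""

    n_patients: int = 100
    murmur_prevalence: tuple[float, float, float] = (
        MURMUR_COUNTS["Absent"] / 942,
        MURMUR_COUNTS["Unknown"] / 942,
        MURMUR_COUNTS["Present"] / 942,
    )  # (Absent, Unknown, Present)
    abnormal_given_murmur: dict[str, float] = field(
        default_factory=lambda: dict(ABNORMAL_GIVEN_MURMUR)
    )
    missingness_rate: float = 0.13
    pregnancy_rate_adolescent_female: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.murmur_prevalence) - 1.0) > 1e-9:
            raise ValidationError("murmur prevalence must sum to 1")
        if any(not 0 <= p <= 1 for p in self.abnormal_given_murmur.values()):
            raise ValidationError("conditionals must lie in [0, 1]")
        if not 0 <= self.missingness_rate <= 1:
            raise ValidationError("missingness rate must lie in [0, 1]")


def _damped_sinusoid(fs: int, freq: float, duration: float) -> np.ndarray:
    t = np.arange(int(round(duration * fs))) / fs
    return np.sin(2 * np.pi * freq * t) * np.exp(-t / (duration / 3.0))


def simulate_recording(
    simcfg: SimConfig,
    murmur_present: bool,
    rng: np.random.Generator,
    *,
    snr_db: float | None = None,
    duration_s: float | None = None,
    location: str = "Phc",
) -> Recording:
    """Synthesise one auscultation recording.

    ``snr_db`` overrides the config murmur SNR (used for the low-SNR "Unknown"
    class); with ``murmur_present=False`` no murmur band is added regardless.
    Deterministic for a fixed generator state.
    """
    fs = simcfg.fs_hz
    if duration_s is None:
        duration_s = float(rng.uniform(*simcfg.duration_range_s))
    n = int(round(duration_s * fs))
    hr = rng.uniform(*simcfg.heart_rate_bpm)
    cycle = 60.0 / hr
    systole = simcfg.systole_fraction * cycle
    s1_freq = rng.uniform(*simcfg.s1_freq_hz)
    s2_freq = s1_freq * rng.uniform(1.1, 1.5)

    x = np.zeros(n)
    gate = np.zeros(n)  # systolic gate for the murmur band
    t0 = 0.0
    while t0 < duration_s:
        for onset, freq, amp in ((t0, s1_freq, 1.0), (t0 + systole, s2_freq, 0.8)):
            dur = rng.uniform(*simcfg.transient_dur_s)
            pulse = amp * _damped_sinusoid(fs, freq, dur)
            i = int(round(onset * fs))
            j = min(i + pulse.size, n)
            if i < n:
                x[i:j] += pulse[: j - i]
        gi = int(round((t0 + 0.06) * fs))  # open the gate after S1 rings down
        gj = min(int(round((t0 + systole) * fs)), n)
        if gi < gj:
            ramp = min(int(0.01 * fs), max((gj - gi) // 4, 1))
            g = np.ones(gj - gi)
            g[:ramp] = np.linspace(0, 1, ramp)
            g[-ramp:] = np.linspace(1, 0, ramp)
            gate[gi:gj] = np.maximum(gate[gi:gj], g)
        t0 += cycle

    sigma_ambient = 10.0 ** (simcfg.ambient_noise_db / 20.0)
    x += rng.normal(0.0, sigma_ambient, size=n)

    if murmur_present:
        snr = simcfg.murmur_snr_db if snr_db is None else snr_db
        sigma_m = sigma_ambient * 10.0 ** (snr / 20.0)
        if sigma_m > 0:
            sos = sps.butter(
                4, simcfg.murmur_band_hz, btype="bandpass", fs=fs, output="sos"
            )
            band = sps.sosfilt(sos, rng.normal(0.0, 1.0, size=n))
            band_std = band.std()
            if band_std > 0:
                x += gate * band * (sigma_m / band_std)

    samples, _ = normalize_amplitude(x)
    return Recording(samples=samples, fs_hz=fs, location=location)


def sample_labels(
    cohortcfg: CohortConfig, rng: np.random.Generator
) -> tuple[MurmurLabel, OutcomeLabel]:
    """Draw one (murmur, outcome) pair from the configured joint."""
    murmur_names = ("Absent", "Unknown", "Present")
    m = rng.choice(3, p=np.asarray(cohortcfg.murmur_prevalence))
    murmur = MurmurLabel(murmur_names[m])
    p_abn = cohortcfg.abnormal_given_murmur[murmur.value]
    outcome = OutcomeLabel.ABNORMAL if rng.random() < p_abn else OutcomeLabel.NORMAL
    return murmur, outcome


def _sample_age(murmur: MurmurLabel, rng: np.random.Generator) -> AgeGroup:
    counts = AGE_GIVEN_MURMUR_COUNTS[murmur.value]
    names = list(counts)
    p = np.asarray([counts[a] for a in names], dtype=np.float64)
    return AgeGroup(names[rng.choice(len(names), p=p / p.sum())])


def sample_patient(
    cohortcfg: CohortConfig,
    simcfg: SimConfig,
    patient_id: str,
    rng: np.random.Generator,
) -> tuple[PatientRecord, list[Recording]]:
    """Sample one patient: labels, demographics with missingness, recordings."""
    murmur, outcome = sample_labels(cohortcfg, rng)
    age = _sample_age(murmur, rng)
    sex = Sex.FEMALE if rng.random() < 0.5 else Sex.MALE
    h_mu, h_sd, w_mu, w_sd = ANTHROPOMETRY[age]
    height = float(np.clip(rng.normal(h_mu, h_sd), 30.0, 210.0))
    weight = float(np.clip(rng.normal(w_mu, w_sd), 1.0, 120.0))
    pregnant = bool(
        age == AgeGroup.ADOLESCENT
        and sex == Sex.FEMALE
        and rng.random() < cohortcfg.pregnancy_rate_adolescent_female
    )

    if rng.random() < cohortcfg.missingness_rate:  # concurrent age/height/weight
        age_out: AgeGroup = AgeGroup.MISSING
        height_out: float | None = None
        weight_out: float | None = None
    else:
        age_out, height_out, weight_out = age, round(height, 1), round(weight, 1)

    n_loc = int(rng.integers(simcfg.n_locations[0], simcfg.n_locations[1] + 1))
    sites = list(rng.permutation(LOCATIONS))[: min(n_loc, len(LOCATIONS))]
    while len(sites) < n_loc:  # a sixth recording repeats a site
        sites.append(sites[len(sites) - len(LOCATIONS)])

    murmur_present = murmur != MurmurLabel.ABSENT
    snr = (
        simcfg.murmur_snr_db + simcfg.unknown_snr_offset_db
        if murmur == MurmurLabel.UNKNOWN
        else simcfg.murmur_snr_db
    )
    recordings, refs = [], []
    for k, site in enumerate(sites):
        rec = simulate_recording(
            simcfg, murmur_present, rng, snr_db=snr, location=site
        )
        recordings.append(rec)
        suffix = f"_{k}" if sites.index(site) != k else ""
        refs.append(
            RecordingRef(location=site, path=Path(f"{patient_id}_{site}{suffix}.wav"))
        )
    record = PatientRecord(
        patient_id=patient_id,
        age_group=age_out,
        sex=sex,
        height_cm=height_out,
        weight_kg=weight_out,
        pregnant=pregnant,
        murmur=murmur,
        outcome=outcome,
        recordings=refs,
    )
    return record, recordings


def generate_cohort(
    cohortcfg: CohortConfig,
    simcfg: SimConfig,
    outdir: str | Path,
    force: bool = False,
) -> Path:
    """Write a synthetic cohort to ``outdir`` in the 2022-dialect layout.

    Refuses a non-empty output directory unless ``force``.  A manifest JSON
    records both configs and the seed; re-scanning the tree reproduces every
    label and demographic field exactly.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    existing = [p for p in outdir.iterdir() if p.name != "manifest.json"]
    if existing and not force:
        raise ValidationError(f"output directory {outdir} is not empty (use force)")
    rng = np.random.default_rng(cohortcfg.seed)
    width = max(4, len(str(cohortcfg.n_patients)))
    for i in range(cohortcfg.n_patients):
        pid = f"S{i:0{width}d}"
        record, recordings = sample_patient(cohortcfg, simcfg, pid, rng)
        for ref, rec in zip(record.recordings, recordings):
            write_recording(rec, outdir / ref.path.name)
        (outdir / f"{pid}.txt").write_text(format_patient_header(record, simcfg.fs_hz))
    manifest = {
        "schema": "synthetic",
        "cohort": asdict(cohortcfg),
        "sim": asdict(simcfg),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return outdir
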