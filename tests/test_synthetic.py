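"""Synthetic cohort generator: acoustics, label statistics, round-trips."""

from __future__ import annotations

import hashlib
import json

import numpy as np
import pytest
from scipy import signal as sps
from scipy.stats import chisquare

from pcgscreen.io_formats import (
    MurmurLabel,
    OutcomeLabel,
    ValidationError,
    read_recording,
    scan_dataset,
)
from pcgscreen.synthetic import (
    CohortConfig,
    SimConfig,
    generate_cohort,
    sample_labels,
    sample_patient,
    simulate_recording,
)

# fixed heart rate makes systole/diastole timing reconstructible in tests
GATED_SIM = SimConfig(
    duration_range_s=(10.0, 10.0), heart_rate_bpm=(60.0, 60.0), n_locations=(1, 1)
)


def band_power_by_phase(samples: np.ndarray, fs: int, sim: SimConfig):
    """Band-power oracle: murmur-band power in systolic vs diastolic gates.

    At 60 bpm the cycle is 1 s with systole spanning [0, 0.35] s of each cycle;
    we sample the interior of each phase to avoid the S1/S2 transients.
    """
    sos = sps.butter(4, sim.murmur_band_hz, btype="bandpass", fs=fs, output="sos")
    band = sps.sosfilt(sos, samples)
    t = np.arange(samples.size) / fs
    phase = t % 1.0
    systolic = (phase > 0.12) & (phase < 0.30)
    diastolic = (phase > 0.50) & (phase < 0.90)
    return float(np.mean(band[systolic] ** 2)), float(np.mean(band[diastolic] ** 2))


class TestSimulateRecording:
    def test_murmur_raises_systolic_band_power(self):
        rec = simulate_recording(GATED_SIM, True, np.random.default_rng(0), snr_db=10.0)
        sys_p, dia_p = band_power_by_phase(rec.samples, rec.fs_hz, GATED_SIM)
        assert sys_p > 3.0 * dia_p

    def test_no_murmur_band_power_at_ambient_level(self):
        rec = simulate_recording(GATED_SIM, False, np.random.default_rng(1))
        sys_p, dia_p = band_power_by_phase(rec.samples, rec.fs_hz, GATED_SIM)
        assert sys_p == pytest.approx(dia_p, rel=0.5)

    def test_numerically_absent_murmur_still_valid(self):
        rec = simulate_recording(GATED_SIM, True, np.random.default_rng(2), snr_db=-200.0)
        sys_p, dia_p = band_power_by_phase(rec.samples, rec.fs_hz, GATED_SIM)
        assert sys_p == pytest.approx(dia_p, rel=0.5)

    def test_deterministic_per_seed(self):
        a = simulate_recording(GATED_SIM, True, np.random.default_rng(3))
        b = simulate_recording(GATED_SIM, True, np.random.default_rng(3))
        assert np.array_equal(a.samples, b.samples)

    def test_peak_normalised_and_duration(self):
        rec = simulate_recording(GATED_SIM, True, np.random.default_rng(4))
        assert np.max(np.abs(rec.samples)) == pytest.approx(1.0)
        assert rec.duration_s == pytest.approx(10.0)


class TestLabelSampling:
    def test_murmur_prevalence_binomial_ci(self):
        rng = np.random.default_rng(5)
        cfg = CohortConfig(n_patients=1)
        draws = [sample_labels(cfg, rng)[0] for _ in range(10_000)]
        present = sum(m == MurmurLabel.PRESENT for m in draws) / 10_000
        assert present == pytest.approx(179 / 942, abs=0.012)  # ~3 sigma

    def test_outcome_conditional_on_present(self):
        rng = np.random.default_rng(6)
        cfg = CohortConfig(n_patients=1)
        draws = [sample_labels(cfg, rng) for _ in range(20_000)]
        present = [(m, o) for m, o in draws if m == MurmurLabel.PRESENT]
        abn = sum(o == OutcomeLabel.ABNORMAL for _, o in present) / len(present)
        assert abn == pytest.approx(150 / 179, abs=0.02)

    def test_joint_chi_square_not_rejected(self):
        rng = np.random.default_rng(7)
        cfg = CohortConfig(n_patients=1)
        cells = {}
        n = 10_000
        for _ in range(n):
            m, o = sample_labels(cfg, rng)
            cells[(m.value, o.value)] = cells.get((m.value, o.value), 0) + 1
        expected, observed = [], []
        for i, m in enumerate(("Absent", "Unknown", "Present")):
            p_m = cfg.murmur_prevalence[i]
            p_abn = cfg.abnormal_given_murmur[m]
            for o, p_o in (("Abnormal", p_abn), ("Normal", 1 - p_abn)):
                expected.append(n * p_m * p_o)
                observed.append(cells.get((m, o), 0))
        _, p_value = chisquare(observed, expected)
        assert p_value > 0.01

    def test_zero_missingness_leaves_no_gaps(self):
        rng = np.random.default_rng(8)
        cfg = CohortConfig(n_patients=1, missingness_rate=0.0)
        sim = SimConfig(duration_range_s=(5.0, 5.0), n_locations=(1, 1))
        for i in range(20):
            record, _ = sample_patient(cfg, sim, f"q{i}", rng)
            assert record.age_group.value != "Missing"
            assert record.height_cm is not None and record.weight_kg is not None

    def test_missingness_is_concurrent(self):
        rng = np.random.default_rng(9)
        cfg = CohortConfig(n_patients=1, missingness_rate=0.5)
        sim = SimConfig(duration_range_s=(5.0, 5.0), n_locations=(1, 1))
        for i in range(30):
            record, _ = sample_patient(cfg, sim, f"q{i}", rng)
            missing = (
                record.age_group.value == "Missing",
                record.height_cm is None,
                record.weight_kg is None,
            )
            assert len(set(missing)) == 1  # all three together or none


def tree_digest(root):
    digest = hashlib.sha256()
    for path in sorted(root.iterdir()):
        digest.update(path.name.encode())
        digest.update(path.read_bytes())
    return digest.hexdigest()


class TestGenerateCohort:
    SIM = SimConfig(duration_range_s=(5.0, 6.0), n_locations=(1, 2))

    def test_file_counts(self, tmp_path):
        cfg = CohortConfig(n_patients=8, seed=21)
        generate_cohort(cfg, self.SIM, tmp_path / "c")
        headers = list((tmp_path / "c").glob("*.txt"))
        wavs = list((tmp_path / "c").glob("*.wav"))
        assert len(headers) == 8
        catalog = scan_dataset(tmp_path / "c", schema="synthetic")
        assert len(wavs) == sum(len(p.recordings) for p in catalog.patients)

    def test_roundtrip_reproduces_sampled_records(self, tmp_path):
        cfg = CohortConfig(n_patients=6, seed=22)
        generate_cohort(cfg, self.SIM, tmp_path / "c")
        catalog = scan_dataset(tmp_path / "c", schema="synthetic")
        # independent replay of the generator's sampling sequence
        rng = np.random.default_rng(cfg.seed)
        for i, scanned in enumerate(catalog.patients):
            expected, _ = sample_patient(cfg, self.SIM, f"S{i:04d}", rng)
            assert scanned.patient_id == expected.patient_id
            assert scanned.murmur == expected.murmur
            assert scanned.outcome == expected.outcome
            assert scanned.age_group == expected.age_group
            assert scanned.sex == expected.sex
            assert scanned.height_cm == expected.height_cm
            assert scanned.weight_kg == expected.weight_kg
            assert scanned.pregnant == expected.pregnant
            assert [r.location for r in scanned.recordings] == [
                r.location for r in expected.recordings
            ]

    def test_same_seed_byte_identical_trees(self, tmp_path):
        cfg = CohortConfig(n_patients=4, seed=23)
        generate_cohort(cfg, self.SIM, tmp_path / "a")
        generate_cohort(cfg, self.SIM, tmp_path / "b")
        assert tree_digest(tmp_path / "a") == tree_digest(tmp_path / "b")

    def test_every_wav_passes_validation(self, tiny_cohort_dir, tiny_catalog):
        for p in tiny_catalog.patients:
            for ref in p.recordings:
                rec = read_recording(ref.path, expected_fs=4000, location=ref.location)
                assert rec.duration_s >= 4.9

    def test_nonempty_outdir_refused_without_force(self, tmp_path):
        cfg = CohortConfig(n_patients=2, seed=24)
        generate_cohort(cfg, self.SIM, tmp_path / "c")
        with pytest.raises(ValidationError, match="not empty"):
            generate_cohort(cfg, self.SIM, tmp_path / "c")
        generate_cohort(cfg, self.SIM, tmp_path / "c", force=True)

    def test_manifest_records_configs(self, tmp_path):
        cfg = CohortConfig(n_patients=2, seed=25)
        generate_cohort(cfg, self.SIM, tmp_path / "c")
        manifest = json.loads((tmp_path / "c" / "manifest.json").read_text())
        assert manifest["cohort"]["seed"] == 25
        assert manifest["sim"]["fs_hz"] == 4000
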