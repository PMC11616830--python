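"""Reading and writing PhysioNet-challenge-style heart-sound datasets.

A dataset is a directory of plain-text patient headers plus one RIFF/PCM WAV
file per auscultation-location recording.  Two on-disk dialects are supported:

* ``circor2022`` / ``synthetic`` — one ``<patient_id>.txt`` header per subject
  in the 2022-challenge key:value dialect, carrying demographics plus murmur
  {Present, Absent, Unknown} and outcome {Normal, Abnormal} labels, and one WAV
  per recording location (up to six locations per patient).
* ``cinc2016`` — one WAV per record plus a ``REFERENCE.csv`` of
  ``record,label`` rows (1 = abnormal, -1 = normal).  Subject identifiers are
  mostly unavailable in that collection, so each recording is mapped to its own
  single-recording patient.

Audio goes through :mod:`scipy.io.wavfile`; headers and label lists are parsed
here.  Label tallies never require decoding audio.
"""

from __future__ import annotations

import csv
import enum
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.io import wavfile


class ParseError(ValueError):
    """A header or label file could not be parsed."""


class ValidationError(ValueError):
    """A parsed value falls outside its documented domain."""


class AgeGroup(str, enum.Enum):
    NEONATE = "Neonate"
    INFANT = "Infant"
    CHILD = "Child"
    ADOLESCENT = "Adolescent"
    MISSING = "Missing"


class Sex(str, enum.Enum):
    FEMALE = "Female"
    MALE = "Male"
    MISSING = "Missing"


class MurmurLabel(str, enum.Enum):
    PRESENT = "Present"
    ABSENT = "Absent"
    UNKNOWN = "Unknown"
    MISSING = "Missing"


class OutcomeLabel(str, enum.Enum):
    NORMAL = "Normal"
    ABNORMAL = "Abnormal"
    MISSING = "Missing"


#: Valve listening points; ``Phc`` is the unspecified / other chest location.
LOCATIONS = ("AV", "PV", "TV", "MV", "Phc")


@dataclass(frozen=True)
class RecordingRef:
    """Pointer to one on-disk recording: location tag plus WAV path."""

    location: str
    path: Path

    def __post_init__(self) -> None:
        if self.location not in LOCATIONS:
            raise ValidationError(f"unknown auscultation location {self.location!r}")


@dataclass
class PatientRecord:
    """One subject: demographics, labels, and recording references."""

    patient_id: str
    age_group: AgeGroup = AgeGroup.MISSING
    sex: Sex = Sex.MISSING
    height_cm: float | None = None
    weight_kg: float | None = None
    pregnant: bool | None = None
    murmur: MurmurLabel = MurmurLabel.MISSING
    outcome: OutcomeLabel = OutcomeLabel.MISSING
    recordings: list[RecordingRef] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.height_cm is not None and not self.height_cm > 0:
            raise ValidationError(f"{self.patient_id}: height must be positive")
        if self.weight_kg is not None and not self.weight_kg > 0:
            raise ValidationError(f"{self.patient_id}: weight must be positive")
        if len(self.recordings) > 6:
            raise ValidationError(
                f"{self.patient_id}: more than six recording locations"
            )


@dataclass
class Recording:
    """One auscultation-location waveform."""

    samples: np.ndarray
    fs_hz: int
    location: str = "Phc"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1 or self.samples.size < 1:
            raise ValidationError("recording must be a non-empty 1-D sample vector")
        if self.fs_hz <= 0:
            raise ValidationError("sampling rate must be positive")
        if self.location not in LOCATIONS:
            raise ValidationError(f"unknown auscultation location {self.location!r}")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs_hz


@dataclass
class DatasetCatalog:
    """In-memory index of a dataset tree: patients, schema, root."""

    patients: list[PatientRecord]
    schema: str
    root: Path

    def __post_init__(self) -> None:
        ids = [p.patient_id for p in self.patients]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate patient ids in catalog: {dupes}")
        if self.schema == "cinc2016":
            for p in self.patients:
                if len(p.recordings) != 1:
                    raise ValidationError(
                        f"{p.patient_id}: cinc2016 patients hold exactly one recording"
                    )

    def __len__(self) -> int:
        return len(self.patients)

    def __iter__(self):
        return iter(self.patients)

    def murmur_tally(self) -> dict[str, int]:
        tally = {m.value: 0 for m in MurmurLabel}
        for p in self.patients:
            tally[p.murmur.value] += 1
        return tally

    def outcome_tally(self) -> dict[str, int]:
        tally = {o.value: 0 for o in OutcomeLabel}
        for p in self.patients:
            tally[p.outcome.value] += 1
        return tally

    def summary(self) -> dict:
        return {
            "schema": self.schema,
            "root": str(self.root),
            "n_patients": len(self.patients),
            "n_recordings": sum(len(p.recordings) for p in self.patients),
            "murmur": self.murmur_tally(),
            "outcome": self.outcome_tally(),
        }

    def write_summary(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.summary(), indent=2))

    def subset(self, patient_ids: Iterable[str]) -> "DatasetCatalog":
        wanted = set(patient_ids)
        kept = [p for p in self.patients if p.patient_id in wanted]
        missing = wanted - {p.patient_id for p in kept}
        if missing:
            raise ValidationError(f"unknown patient ids: {sorted(missing)}")
        return DatasetCatalog(patients=kept, schema=self.schema, root=self.root)


# ---------------------------------------------------------------------------
# header parsing (2022 dialect)
# ---------------------------------------------------------------------------

_ENUM_FIELDS = {
    "age": ("age_group", AgeGroup),
    "sex": ("sex", Sex),
    "murmur": ("murmur", MurmurLabel),
    "outcome": ("outcome", OutcomeLabel),
}
_NUMERIC_FIELDS = {"height": "height_cm", "weight": "weight_kg"}


def _parse_optional_float(raw: str) -> float | None:
    # "NA"/"nan"/empty are expected states (~13% of subjects), not errors.
    raw = raw.strip()
    if raw in ("", "NA", "nan", "NaN", "None", "Missing"):
        return None
    try:
        value = float(raw)
    except ValueError:
        return None
    return value if np.isfinite(value) else None


def _parse_optional_bool(raw: str) -> bool | None:
    raw = raw.strip().lower()
    if raw in ("true", "yes", "1"):
        return True
    if raw in ("false", "no", "0"):
        return False
    return None


def parse_patient_header(text: str, schema: str = "circor2022") -> PatientRecord:
    """Parse one 2022-dialect patient header into a :class:`PatientRecord`.

    The dialect is: a first line ``patient_id n_locations fs``; one line per
    recording naming the location tag and its WAV file; then ``#Key: value``
    metadata lines.  Absent metadata lines map to Missing/None; label values
    outside their enum domain raise :class:`ValidationError`.
    """
    if schema not in ("circor2022", "synthetic"):
        raise ParseError(f"schema {schema!r} has no text-header dialect")
    lines = [ln.rstrip() for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise ParseError("empty header")

    head = lines[0].split()
    if len(head) < 2:
        raise ParseError(f"malformed header first line: {lines[0]!r}")
    patient_id = head[0]
    try:
        n_loc = int(head[1])
    except ValueError as exc:
        raise ParseError(f"malformed header first line: {lines[0]!r}") from exc

    refs: list[RecordingRef] = []
    for line in lines[1 : 1 + n_loc]:
        tokens = line.split()
        wavs = [t for t in tokens if t.lower().endswith(".wav")]
        if not tokens or tokens[0] not in LOCATIONS or not wavs:
            raise ParseError(f"malformed recording line: {line!r}")
        refs.append(RecordingRef(location=tokens[0], path=Path(wavs[0])))
    if len(refs) != n_loc:
        raise ParseError(
            f"{patient_id}: header declares {n_loc} recordings, found {len(refs)}"
        )

    record = PatientRecord(patient_id=patient_id, recordings=refs)
    for line in lines[1 + n_loc :]:
        if not line.startswith("#"):
            raise ParseError(f"malformed metadata line: {line!r}")
        key, _, raw = line[1:].partition(":")
        key = key.strip().lower()
        raw = raw.strip()
        if key in _ENUM_FIELDS:
            attr, enum_cls = _ENUM_FIELDS[key]
            if raw in ("", "NA", "nan", "None"):
                continue  # stays Missing
            try:
                setattr(record, attr, enum_cls(raw))
            except ValueError as exc:
                raise ValidationError(
                    f"{patient_id}: invalid {key} value {raw!r}"
                ) from exc
        elif key in _NUMERIC_FIELDS:
            setattr(record, _NUMERIC_FIELDS[key], _parse_optional_float(raw))
        elif key in ("pregnancy status", "pregnant"):
            record.pregnant = _parse_optional_bool(raw)
        # unknown keys are ignored: real headers carry campaign metadata
    # re-run invariant checks now that numeric fields are set
    PatientRecord.__post_init__(record)
    return record


def format_patient_header(record: PatientRecord, fs_hz: int) -> str:
    """Serialise a :class:`PatientRecord` back to the 2022 text dialect."""
    lines = [f"{record.patient_id} {len(record.recordings)} {fs_hz}"]
    for ref in record.recordings:
        lines.append(f"{ref.location} {ref.path.name}")
    lines.append(f"#Age: {record.age_group.value if record.age_group != AgeGroup.MISSING else 'nan'}")
    lines.append(f"#Sex: {record.sex.value if record.sex != Sex.MISSING else 'nan'}")
    lines.append(f"#Height: {record.height_cm if record.height_cm is not None else 'nan'}")
    lines.append(f"#Weight: {record.weight_kg if record.weight_kg is not None else 'nan'}")
    lines.append(f"#Pregnancy status: {record.pregnant if record.pregnant is not None else 'nan'}")
    lines.append(f"#Murmur: {record.murmur.value}")
    lines.append(f"#Outcome: {record.outcome.value}")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# audio
# ---------------------------------------------------------------------------

_PCM_SCALE = {
    np.dtype(np.int16): 32768.0,
    np.dtype(np.int32): 2147483648.0,
    np.dtype(np.uint8): 128.0,
}


def read_recording(
    path: str | Path,
    expected_fs: int | None = None,
    location: str = "Phc",
) -> Recording:
    """Read one WAV recording, converting PCM integers to floats in [-1, 1].

    Stereo (or any multi-channel) audio is collapsed to mono by channel mean.
    ``expected_fs`` asserts the container sampling rate when given.
    """
    path = Path(path)
    try:
        fs, data = wavfile.read(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # truncated/undecodable container
        raise IOError(f"cannot decode WAV file {path}: {exc}") from exc
    if data.size == 0:
        raise ValidationError(f"{path}: zero-length audio")
    if data.ndim > 1:
        data = data.astype(np.float64).mean(axis=1)
    scale = _PCM_SCALE.get(np.dtype(data.dtype))
    samples = data.astype(np.float64)
    if scale is not None:
        if np.dtype(data.dtype) == np.uint8:
            samples = (samples - 128.0) / scale
        else:
            samples = samples / scale
    if expected_fs is not None and fs != expected_fs:
        raise ValidationError(
            f"{path}: sampling rate {fs} Hz, expected {expected_fs} Hz"
        )
    return Recording(samples=samples, fs_hz=int(fs), location=location)


def write_recording(recording: Recording, path: str | Path) -> None:
    """Write a recording as 16-bit PCM WAV."""
    peak = np.max(np.abs(recording.samples))
    scaled = recording.samples / peak if peak > 1 else recording.samples
    pcm = np.clip(np.round(scaled * 32767.0), -32768, 32767).astype(np.int16)
    wavfile.write(Path(path), recording.fs_hz, pcm)


# ---------------------------------------------------------------------------
# dataset scanning
# ---------------------------------------------------------------------------

def scan_dataset(root: str | Path, schema: str = "circor2022") -> DatasetCatalog:
    """Build a :class:`DatasetCatalog` from a dataset tree.

    Patients are ordered lexicographically by id so that every downstream
    seeded operation sees a stable ordering.  Label tallies are available
    without decoding any audio.
    """
    root = Path(root)
    if schema in ("circor2022", "synthetic"):
        patients = _scan_2022(root)
    elif schema == "cinc2016":
        patients = _scan_2016(root)
    else:
        raise ValidationError(f"unknown dataset schema {schema!r}")
    if not patients:
        warnings.warn(f"no patients found under {root}", stacklevel=2)
    patients.sort(key=lambda p: p.patient_id)
    return DatasetCatalog(patients=patients, schema=schema, root=root)


def _scan_2022(root: Path) -> list[PatientRecord]:
    patients = []
    for header_path in sorted(root.glob("*.txt")):
        record = parse_patient_header(header_path.read_text(), schema="circor2022")
        record.recordings = [
            RecordingRef(location=r.location, path=root / r.path.name)
            for r in record.recordings
        ]
        patients.append(record)
    return patients


def _scan_2016(root: Path) -> list[PatientRecord]:
    ref = root / "REFERENCE.csv"
    if not ref.exists():
        return []
    patients = []
    with ref.open() as fh:
        for row in csv.reader(fh):
            if not row or not row[0].strip():
                continue
            name = row[0].strip()
            if len(row) < 2:
                raise ParseError(f"REFERENCE.csv: malformed row {row!r}")
            raw = row[1].strip()
            if raw not in ("1", "-1"):
                raise ValidationError(f"REFERENCE.csv: unknown label {raw!r} for {name}")
            outcome = OutcomeLabel.ABNORMAL if raw == "1" else OutcomeLabel.NORMAL
            patients.append(
                PatientRecord(
                    patient_id=name,
                    outcome=outcome,
                    recordings=[RecordingRef(location="Phc", path=root / f"{name}.wav")],
                )
            )
    return patients


# ---------------------------------------------------------------------------
# prediction output
# ---------------------------------------------------------------------------

PREDICTION_COLUMNS = ["patient_id", "task", "score", "label_at_threshold", "mc_std"]


def write_predictions(
    catalog: DatasetCatalog,
    predictions: Sequence[Mapping],
    path: str | Path,
) -> None:
    """Write per-patient predictions as CSV.

    Each prediction is a mapping with keys ``patient_id``, ``task``, ``score``,
    ``label_at_threshold`` and ``mc_std``.  Scores round-trip at 1e-6.
    """
    known = {p.patient_id for p in catalog.patients}
    rows = []
    for pred in predictions:
        pid = pred["patient_id"]
        if pid not in known:
            raise ValidationError(f"prediction for unknown patient id {pid!r}")
        rows.append({col: pred[col] for col in PREDICTION_COLUMNS})
    frame = pd.DataFrame(rows, columns=PREDICTION_COLUMNS)
    frame.to_csv(path, index=False, float_format="%.8f")


def read_predictions(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    missing = set(PREDICTION_COLUMNS) - set(frame.columns)
    if missing:
        raise ParseError(f"prediction file lacks columns {sorted(missing)}")
    return frame
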