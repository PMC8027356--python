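"""Reading, validation and writing of oxygenscan traces and biomarker tables.

An *oxygenscan* trace is one oxygen-gradient-ektacytometry measurement cycle:
parallel series of time (s), oxygen partial pressure pO2 (mmHg) and elongation
index EI (dimensionless), recorded while a sheared red-blood-cell suspension is
deoxygenated and then reoxygenated.

On-disk dialect (``oxyscan-csv``)
---------------------------------
A UTF-8 comma-separated file with '.' decimal separator and the exact header::

    time_s,pO2_mmHg,EI

plus an optional JSON metadata sidecar ``<stem>.meta.json`` whose keys are the
:class:`TraceMetadata` field names.  Native instrument exports are proprietary
and are expected to be converted to this dialect with a one-off mapping.

Biomarker tables are CSV files with header
``sample_id,hbf_pct,fcells_pct,drbc_pct,hb_g_dl,rbc_count_1e6_ul``.
Percentages are on the 0-100 scale throughout (never fractions).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

TRACE_HEADER = ("time_s", "pO2_mmHg", "EI")
BIOMARKER_COLUMNS = (
    "sample_id",
    "hbf_pct",
    "fcells_pct",
    "drbc_pct",
    "hb_g_dl",
    "rbc_count_1e6_ul",
)

#: Float format used when writing traces; round-trips IEEE doubles exactly.
FLOAT_FORMAT = "%.17g"


class TraceIOError(Exception):
    """Base class for trace/biomarker file errors."""


class TraceParseError(TraceIOError):
    """Malformed trace file (bad header, non-numeric cell, bad time axis)."""


class EmptyTraceFileError(TraceIOError):
    """The trace file contains no data at all."""


class ValidationError(ValueError):
    """An in-memory object violates a domain invariant."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TraceMetadata:
    """Instrument and sample-handling metadata for one measurement.

    Nominal values follow the standard protocol: 30 Pa shear stress, 37 deg C,
    a 1,300 s deoxygenation ramp and a 280 s reoxygenation.  The suspension
    viscosity is stored verbatim as a value-with-unit string, exactly as
    recorded, and is never normalised or unit-corrected.
    """

    sample_id: str = "unknown"
    shear_stress_Pa: float = 30.0
    temperature_C: float = 37.0
    deox_duration_s: float | None = 1300.0
    reox_duration_s: float | None = 280.0
    suspension_viscosity: str | None = None
    buffer_osmolality_mOsm_kg: float | None = None
    buffer_pH: float | None = None
    collection_to_run_hours: float | None = None
    defaults_assumed: bool = False

    def __post_init__(self) -> None:
        if not self.shear_stress_Pa > 0:
            raise ValidationError("shear_stress_Pa must be > 0")
        if not (0 < self.temperature_C < 45):
            raise ValidationError("temperature_C must lie in (0, 45)")
        for name in ("deox_duration_s", "reox_duration_s"):
            v = getattr(self, name)
            if v is not None and not v > 0:
                raise ValidationError(f"{name} must be positive when present")
        if (
            self.collection_to_run_hours is not None
            and self.collection_to_run_hours < 0
        ):
            raise ValidationError("collection_to_run_hours must be non-negative")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass(frozen=True, eq=False)
class OxygenscanTrace:
    """One oxygenscan cycle: time, pO2 and EI series plus metadata.

    Invariants: the three series have equal length >= 2, time is strictly
    increasing, pO2 lies in [0, 200] mmHg and EI in [0, 1).
    """

    time_s: np.ndarray
    pO2_mmHg: np.ndarray
    ei: np.ndarray
    metadata: TraceMetadata = field(default_factory=TraceMetadata)

    def __post_init__(self) -> None:
        for name in ("time_s", "pO2_mmHg", "ei"):
            arr = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, arr)
        n = len(self.time_s)
        if n < 2 or len(self.pO2_mmHg) != n or len(self.ei) != n:
            raise ValidationError(
                "time_s, pO2_mmHg and ei must have equal length >= 2"
            )
        if not np.all(np.diff(self.time_s) > 0):
            raise ValidationError("time_s must be strictly increasing")
        if np.any(self.pO2_mmHg < 0) or np.any(self.pO2_mmHg > 200):
            raise ValidationError("pO2_mmHg must lie within [0, 200]")
        if np.any(self.ei < 0) or np.any(self.ei >= 1):
            raise ValidationError("ei must lie within [0, 1)")

    def __len__(self) -> int:
        return len(self.time_s)

    def equals(self, other: "OxygenscanTrace") -> bool:
        """Exact (bitwise) equality of all three series and the metadata."""
        return (
            np.array_equal(self.time_s, other.time_s)
            and np.array_equal(self.pO2_mmHg, other.pO2_mmHg)
            and np.array_equal(self.ei, other.ei)
            and self.metadata == other.metadata
        )


@dataclass(frozen=True)
class BiomarkerTable:
    """Per-patient biomarker measurements, one row per sample.

    Columns: %HbF (fetal hemoglobin), %F-cells (RBCs containing HbF),
    %DRBCs (dense RBCs, MCHC > 41 g/dl), Hb (g/dl) and RBC count (10^6/ul).
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.frame
        missing = [c for c in BIOMARKER_COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"missing biomarker column(s): {missing}")
        object.__setattr__(
            self, "frame", df.loc[:, list(BIOMARKER_COLUMNS)].reset_index(drop=True)
        )
        df = self.frame
        if len(df) == 0:
            return
        dup = df["sample_id"][df["sample_id"].duplicated()]
        if len(dup):
            raise ValidationError(
                f"duplicate sample_id(s): {sorted(set(dup.astype(str)))}"
            )
        for col in ("hbf_pct", "fcells_pct", "drbc_pct"):
            bad = df.loc[(df[col] < 0) | (df[col] > 100), "sample_id"]
            if len(bad):
                raise ValidationError(
                    f"{col} out of [0, 100] for sample_id(s): "
                    f"{sorted(bad.astype(str))}"
                )

    def __len__(self) -> int:
        return len(self.frame)


# ---------------------------------------------------------------------------
# Trace I/O
# ---------------------------------------------------------------------------

def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".meta.json")


def read_trace(path: str | Path, dialect: str = "oxyscan-csv") -> OxygenscanTrace:
    """Read a trace CSV (plus optional ``<stem>.meta.json`` sidecar).

    A missing sidecar yields nominal-protocol metadata with the
    ``defaults_assumed`` flag set.  Errors name 1-based file line numbers.
    """
    if dialect != "oxyscan-csv":
        raise ValueError(f"unknown trace dialect: {dialect!r}")
    path = Path(path)
    raw = path.read_text(encoding="utf-8")
    if raw.strip() == "":
        raise EmptyTraceFileError(f"{path}: file is empty")
    lines = raw.splitlines()
    header = tuple(h.strip() for h in lines[0].split(","))
    if header != TRACE_HEADER:
        raise TraceParseError(
            f"{path}: malformed header at line 1: expected "
            f"{','.join(TRACE_HEADER)!r}, got {lines[0]!r}"
        )
    try:
        df = pd.read_csv(path, dtype=str, skip_blank_lines=False)
    except pd.errors.EmptyDataError:  # header only
        df = pd.DataFrame(columns=list(TRACE_HEADER))
    num = {}
    for col in TRACE_HEADER:
        try:
            # numpy's string->float conversion is correctly rounded
            # (pd.to_numeric is not), preserving the 17-digit round-trip
            num[col] = df[col].to_numpy(dtype=float)
        except (TypeError, ValueError):
            for row, cell in enumerate(df[col]):
                try:
                    float(cell)
                except (TypeError, ValueError):
                    line = row + 2  # +1 header, +1 1-based
                    raise TraceParseError(
                        f"{path}: non-numeric value {cell!r} in column "
                        f"{col} at line {line}"
                    ) from None
            raise TraceParseError(f"{path}: could not parse column {col}")
        bad = np.flatnonzero(~np.isfinite(num[col]))
        if len(bad):
            raise TraceParseError(
                f"{path}: missing or non-finite value in column {col} "
                f"at line {int(bad[0]) + 2}"
            )
    t = num["time_s"]
    if len(t) >= 2:
        dec = np.flatnonzero(np.diff(t) <= 0)
        if len(dec):
            line = int(dec[0]) + 3  # violation is at the *second* row of the pair
            raise TraceParseError(f"{path}: time not strictly increasing at line {line}")
    meta = _read_metadata_sidecar(path)
    try:
        return OxygenscanTrace(t, num["pO2_mmHg"], num["EI"], meta)
    except ValidationError as exc:
        raise TraceParseError(f"{path}: {exc}") from exc


def _read_metadata_sidecar(path: Path) -> TraceMetadata:
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        return TraceMetadata(sample_id=path.stem, defaults_assumed=True)
    payload = json.loads(sidecar.read_text(encoding="utf-8"))
    known = {f.name for f in dataclasses.fields(TraceMetadata)}
    unknown = set(payload) - known
    if unknown:
        raise TraceParseError(f"{sidecar}: unknown metadata key(s): {sorted(unknown)}")
    payload.setdefault("sample_id", path.stem)
    return TraceMetadata(**payload)


def write_trace(trace: OxygenscanTrace, path: str | Path) -> None:
    """Write ``trace`` as dialect CSV plus JSON metadata sidecar.

    Floats are formatted with 17 significant digits so that
    ``read_trace(write_trace(x))`` reproduces every series bitwise.
    """
    path = Path(path)
    df = pd.DataFrame(
        {"time_s": trace.time_s, "pO2_mmHg": trace.pO2_mmHg, "EI": trace.ei}
    )
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)
    _sidecar_path(path).write_text(
        json.dumps(trace.metadata.to_dict(), indent=1, sort_keys=True),
        encoding="utf-8",
    )


# ---------------------------------------------------------------------------
# Biomarker tables
# ---------------------------------------------------------------------------

def read_biomarkers(path: str | Path) -> BiomarkerTable:
    """Read and validate a biomarker CSV (five named columns, unique ids)."""
    path = Path(path)
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError as exc:
        raise ValidationError(f"{path}: empty biomarker file (no header)") from exc
    missing = [c for c in BIOMARKER_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing column(s): {missing}")
    df["sample_id"] = df["sample_id"].astype(str)
    for col in BIOMARKER_COLUMNS[1:]:
        try:
            df[col] = df[col].astype(float)
        except (TypeError, ValueError) as exc:
            raise ValidationError(
                f"{path}: non-numeric value in column {col}: {exc}"
            ) from exc
    return BiomarkerTable(df)


def write_biomarkers(table: BiomarkerTable, path: str | Path) -> None:
    table.frame.to_csv(path, index=False, float_format=FLOAT_FORMAT)
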