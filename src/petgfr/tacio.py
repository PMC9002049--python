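"""File formats: TAC tables, VOI measurement tables, cohort manifests, fixtures.

Everything is plain comma-separated text with a mandatory header row.  Lines
starting with ``#`` carry units and provenance (a config hash) and are
skipped on read.  TAC files have columns ``frame_start_s, frame_duration_s,
value_kBq_per_ml``.
"""

from __future__ import annotations

import hashlib
import json
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .aif import AortaVoiMeasurement
from .frames import FrameSchedule, SampledCurve, ValidationError

__all__ = [
    "read_tac",
    "write_tac",
    "read_voi_table",
    "write_voi_table",
    "load_table1",
    "load_table2",
    "load_table4",
    "provenance_hash",
]

TAC_COLUMNS = ["frame_start_s", "frame_duration_s", "value_kBq_per_ml"]


class ParseError(ValueError):
    """Raised on malformed input files, naming the offending row."""


def provenance_hash(obj: object) -> str:
    """Short, stable hash of a configuration object for output-file headers."""
    payload = json.dumps(obj, default=str, sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def _read_table(path: str | Path, required: list[str]) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing column(s) {missing}")
    if df.empty:
        raise ParseError(f"{path}: empty data section")
    return df


def _check_numeric(df: pd.DataFrame, cols: list[str], path: Path) -> pd.DataFrame:
    for col in cols:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ParseError(
                f"{path}: malformed value {df[col].iloc[row]!r} in column "
                f"{col!r}, data row {row + 1}"
            )
        if coerced.isna().any():
            row = int(np.flatnonzero(coerced.isna().to_numpy())[0])
            raise ParseError(f"{path}: missing value in column {col!r}, data row {row + 1}")
        df[col] = coerced
    return df


def read_tac(path: str | Path) -> SampledCurve:
    """Read a TAC file; raises ParseError naming the row on malformed input."""
    path = Path(path)
    df = _check_numeric(_read_table(path, TAC_COLUMNS), TAC_COLUMNS, path)
    try:
        schedule = FrameSchedule(
            df["frame_start_s"].to_numpy(), df["frame_duration_s"].to_numpy()
        )
    except ValidationError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    return SampledCurve(schedule, df["value_kBq_per_ml"].to_numpy())


def write_tac(
    curve: SampledCurve, path: str | Path, provenance: str | None = None
) -> None:
    """Write a TAC file (lossless full-precision round trip)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("# units: time s, value kBq/ml (frame-average, decay-corrected)\n")
        if provenance:
            fh.write(f"# provenance: {provenance}\n")
        fh.write(",".join(TAC_COLUMNS) + "\n")
        for s, d, v in zip(curve.schedule.starts, curve.schedule.durations, curve.values):
            fh.write(f"{float(s)!r},{float(d)!r},{float(v)!r}\n")


VOI_COLUMNS = [
    "frame_start_s",
    "frame_duration_s",
    "A_oversized_kBq",
    "C_background_kBq_per_ml",
]


def write_voi_table(
    m: AortaVoiMeasurement, path: str | Path, provenance: str | None = None
) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("# units: time s, activity kBq, concentration kBq/ml\n")
        fh.write(f"# V_oversized_ml: {m.v_oversized_ml!r}\n")
        fh.write(f"# V_aorta_ml: {m.v_aorta_ml!r}\n")
        if provenance:
            fh.write(f"# provenance: {provenance}\n")
        fh.write(",".join(VOI_COLUMNS) + "\n")
        for s, d, a, b in zip(
            m.schedule.starts, m.schedule.durations, m.a_oversized_kbq, m.c_background_kbq_ml
        ):
            fh.write(f"{float(s)!r},{float(d)!r},{float(a)!r},{float(b)!r}\n")


def read_voi_table(
    path: str | Path,
    v_aorta_ml: float | None = None,
    v_oversized_ml: float | None = None,
) -> AortaVoiMeasurement:
    """Read a VOI table; volumes come from the file header unless overridden."""
    path = Path(path)
    header_vols: dict[str, float] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            for key in ("V_oversized_ml", "V_aorta_ml"):
                if f"{key}:" in line:
                    header_vols[key] = float(line.split(":", 1)[1])
    v_over = v_oversized_ml if v_oversized_ml is not None else header_vols.get("V_oversized_ml")
    v_aorta = v_aorta_ml if v_aorta_ml is not None else header_vols.get("V_aorta_ml")
    if v_over is None or v_aorta is None:
        raise ParseError(f"{path}: VOI volumes missing from header and arguments")
    df = _check_numeric(_read_table(path, VOI_COLUMNS), VOI_COLUMNS, path)
    try:
        schedule = FrameSchedule(
            df["frame_start_s"].to_numpy(), df["frame_duration_s"].to_numpy()
        )
        return AortaVoiMeasurement(
            schedule=schedule,
            a_oversized_kbq=df["A_oversized_kBq"].to_numpy(),
            c_background_kbq_ml=df["C_background_kBq_per_ml"].to_numpy(),
            v_oversized_ml=float(v_over),
            v_aorta_ml=float(v_aorta),
        )
    except ValidationError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def _load_fixture(name: str) -> pd.DataFrame:
    with resources.files("petgfr.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


def load_table1() -> pd.DataFrame:
    """Clinical cohort characteristics (12 patients: demographics, labs, activities)."""
    return _load_fixture("table1_patients.csv")


def load_table2() -> pd.DataFrame:
    """Visual-interpretation results (urinary obstruction status per patient)."""
    return _load_fixture("table2_obstruction.csv")


def load_table4() -> pd.DataFrame:
    """Published GFR results: creatinine reference and the four PET variants."""
    return _load_fixture("table4_gfr.csv")


def unobstructed_ids(table2: pd.DataFrame | None = None) -> list[int]:
    """Patient ids with undisturbed urinary efflux (the n = 9 subgroup)."""
    t2 = table2 if table2 is not None else load_table2()
    ok = t2["pet_result"].str.strip() == "no urinary obstruction"
    return t2.loc[ok, "patient_id"].astype(int).tolist()
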