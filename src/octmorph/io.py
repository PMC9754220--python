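"""On-disk artifacts: scans, cohort metadata, sector tables, pit parameter
tables, effect and bias tables.  CSV throughout, YAML for configs.

Writers are deterministic (sorted keys, fixed column order, 6 significant
digits); readers validate rather than coerce and name the offending row.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd

from .config import LAYERS, TRT
from .sectors import SectorSummary
from .synthetic import SegmentedScan, SubjectRecord

SCAN_COLUMNS = ("x_mm", "y_mm", "RNFL", "GCIPL", "INL", "ONPL", "ELM_BM", "TRT")
METADATA_COLUMNS = ("subject_id", "eye", "age_years", "sex", "scan_focus_D", "protocol")
TRT_TOLERANCE_UM = 0.01
_FMT = "%.6g"


class SchemaError(ValueError):
    """A file violates the expected schema."""


def _fmt_frame(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    for c in out.columns:
        if pd.api.types.is_float_dtype(out[c]):
            out[c] = out[c].map(lambda v: _FMT % v if np.isfinite(v) else "")
    return out


# ---------------------------------------------------------------------------
# Scans

def write_scan(scan: SegmentedScan, path: str | os.PathLike) -> None:
    df = pd.DataFrame({
        "x_mm": scan.x, "y_mm": scan.y,
        **{c: scan.layers[c] for c in SCAN_COLUMNS[2:]},
    })
    _fmt_frame(df).to_csv(path, index=False)


def read_scan(path: str | os.PathLike, subject_id: str = "", eye: str = "OD",
              protocol: str = "standard") -> SegmentedScan:
    """Read and validate a scan CSV; enforces non-negative thicknesses and
    the layer-additivity invariant (TRT == sum of the five layers)."""
    try:
        df = pd.read_csv(path)
    except OSError as err:
        raise SchemaError(f"cannot read scan {path}: {err}") from err
    missing = [c for c in SCAN_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    thick = df[list(SCAN_COLUMNS[2:])].to_numpy(float)
    neg = np.argwhere(thick < 0)
    if neg.size:
        row, col = neg[0]
        raise SchemaError(f"{path}: negative thickness in row {row} "
                          f"({SCAN_COLUMNS[2:][col]})")
    layer_sum = df[list(LAYERS)].to_numpy(float).sum(axis=1)
    err = np.abs(layer_sum - df[TRT].to_numpy(float))
    bad = int(np.argmax(err))
    if err[bad] > TRT_TOLERANCE_UM:
        raise SchemaError(f"{path}: TRT differs from layer sum by "
                          f"{err[bad]:.4g} um in row {bad}")
    return SegmentedScan(
        subject_id=subject_id, eye=eye, protocol=protocol,
        x=df["x_mm"].to_numpy(float), y=df["y_mm"].to_numpy(float),
        layers={c: df[c].to_numpy(float) for c in SCAN_COLUMNS[2:]},
    )


# ---------------------------------------------------------------------------
# Cohort metadata

def write_metadata(rows: list[tuple[SubjectRecord, str, str]],
                   path: str | os.PathLike) -> None:
    """rows: (subject, eye, protocol) per scanned eye."""
    df = pd.DataFrame(
        [(s.subject_id, eye, s.age, s.sex, s.scan_focus, protocol)
         for s, eye, protocol in rows],
        columns=METADATA_COLUMNS,
    )
    df = df.sort_values(["subject_id", "eye"], kind="stable")
    _fmt_frame(df).to_csv(path, index=False)


def read_metadata(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    dup = df.duplicated(subset=["subject_id", "eye"])
    if dup.any():
        raise SchemaError(f"{path}: duplicate (subject, eye) in row {int(dup.idxmax())}")
    return df


# ---------------------------------------------------------------------------
# Sector tables

def write_sector_table(summaries: list[SectorSummary], path: str | os.PathLike) -> None:
    """Sector means keyed by (layer, scheme, sector_id), sorted for stable
    diffs.  ETDRS ids: C0, N1/S1/T1/I1, N2/S2/T2/I2; grid ids g_row_col with
    row 0 superior and col 0 temporal (right-eye frame after
    normalization)."""
    known = {"whole", "etdrs", "grid20"}
    for s in summaries:
        if s.scheme not in known:
            raise ValueError(f"unknown scheme {s.scheme!r}")
    df = pd.DataFrame(
        [(s.layer, s.scheme, s.sector_id, s.mean, s.n_nodes, s.excluded, s.reason)
         for s in summaries],
        columns=["layer", "scheme", "sector_id", "mean_um", "n_nodes",
                 "excluded", "reason"],
    )
    df = df.sort_values(["layer", "scheme", "sector_id"], kind="stable")
    _fmt_frame(df).to_csv(path, index=False)


def read_sector_table(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path)
    needed = {"layer", "scheme", "sector_id", "mean_um", "n_nodes"}
    missing = needed - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing columns {sorted(missing)}")
    return df


# ---------------------------------------------------------------------------
# Pit / effects / bias tables

def write_pit_table(df: pd.DataFrame, path: str | os.PathLike) -> None:
    """Pit parameters per eye and direction; direction 'ALL' is the
    whole-macula aggregate."""
    cols = ["subject_id", "eye", "direction_deg", "cft_um", "rim_height_um",
            "rim_radius_mm", "mean_slope_deg", "flags"]
    df = df[cols].sort_values(["subject_id", "eye", "direction_deg"], kind="stable")
    _fmt_frame(df).to_csv(path, index=False)


def write_effects_table(df: pd.DataFrame, path: str | os.PathLike) -> None:
    _fmt_frame(df.sort_values("parameter", kind="stable")).to_csv(path, index=False)


def write_bias_table(df: pd.DataFrame, path: str | os.PathLike) -> None:
    _fmt_frame(df.sort_values("parameter", kind="stable")).to_csv(path, index=False)


def ensure_dir(path: str | os.PathLike) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
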