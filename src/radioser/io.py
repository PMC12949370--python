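"""Delimited-text I/O and schema validation for the analysis inputs.

All tables are comma-delimited with named header columns:

* colony records: modality, dose_rate_gy_min, arm, dose_gy, replicate,
  n_seeded, n_colonies (doses optionally in cGy via ``dose_unit="cgy"``);
* foci records: modality, dose_rate_gy_min, arm, cell_id, n_foci;
* dwell plans: dwell_index, x_cm, y_cm, z_cm, time_s.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .clonogenic import ColonyRecord, SurvivalCurve
from .doserate import DwellPlan
from .foci import FociRecord

__all__ = [
    "Finding",
    "read_colony_records",
    "write_colony_records",
    "read_foci_records",
    "write_foci_records",
    "read_dwell_plan",
    "write_survival_curve",
    "validate_colony_table",
    "validate_foci_table",
]

COLONY_COLUMNS = [
    "modality", "dose_rate_gy_min", "arm", "dose_gy", "replicate",
    "n_seeded", "n_colonies",
]
FOCI_COLUMNS = ["modality", "dose_rate_gy_min", "arm", "cell_id", "n_foci"]
DWELL_COLUMNS = ["dwell_index", "x_cm", "y_cm", "z_cm", "time_s"]


@dataclass(frozen=True)
class Finding:
    """One machine-readable validation finding; ``row`` is the 1-based data
    row in the file (None for file-level findings)."""

    row: int | None
    message: str


def read_colony_records(path, dose_unit: str = "gy") -> list[ColonyRecord]:
    """Read colony records; ``dose_unit="cgy"`` converts doses to Gy."""
    if dose_unit not in ("gy", "cgy"):
        raise ValueError("dose_unit must be 'gy' or 'cgy'")
    df = pd.read_csv(path)
    missing = set(COLONY_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    scale = 0.01 if dose_unit == "cgy" else 1.0
    return [
        ColonyRecord(
            modality=str(r.modality),
            dose_rate=float(r.dose_rate_gy_min),
            arm=str(r.arm),
            dose=float(r.dose_gy) * scale,
            replicate=int(r.replicate),
            n_seeded=int(r.n_seeded),
            n_colonies=int(r.n_colonies),
        )
        for r in df.itertuples()
    ]


def write_colony_records(records: Iterable[ColonyRecord], path) -> None:
    pd.DataFrame(
        [
            {
                "modality": r.modality,
                "dose_rate_gy_min": r.dose_rate,
                "arm": r.arm,
                "dose_gy": r.dose,
                "replicate": r.replicate,
                "n_seeded": r.n_seeded,
                "n_colonies": r.n_colonies,
            }
            for r in records
        ]
    ).to_csv(path, index=False)


def read_foci_records(path) -> list[FociRecord]:
    df = pd.read_csv(path)
    missing = set(FOCI_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return [
        FociRecord(
            modality=str(r.modality),
            dose_rate=float(r.dose_rate_gy_min),
            arm=str(r.arm),
            cell_id=int(r.cell_id),
            n_foci=int(r.n_foci),
        )
        for r in df.itertuples()
    ]


def write_foci_records(records: Iterable[FociRecord], path) -> None:
    pd.DataFrame(
        [
            {
                "modality": r.modality,
                "dose_rate_gy_min": r.dose_rate,
                "arm": r.arm,
                "cell_id": r.cell_id,
                "n_foci": r.n_foci,
            }
            for r in records
        ]
    ).to_csv(path, index=False)


def read_dwell_plan(path) -> DwellPlan:
    df = pd.read_csv(path)
    missing = set(DWELL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    df = df.sort_values("dwell_index")
    return DwellPlan(
        positions=df[["x_cm", "y_cm", "z_cm"]].to_numpy(dtype=float),
        times=df["time_s"].to_numpy(dtype=float),
    )


def write_survival_curve(curve: SurvivalCurve, path) -> None:
    out = curve.table.copy()
    out["pe"] = curve.plating_efficiency
    out.to_csv(path, index=False)


def _check_numeric(df: pd.DataFrame, col: str, findings: list) -> pd.Series:
    vals = pd.to_numeric(df[col], errors="coerce")
    for idx in df.index[vals.isna()]:
        findings.append(Finding(int(idx) + 1, f"{col}: non-numeric value {df[col][idx]!r}"))
    return vals


def validate_colony_table(path) -> list[Finding]:
    """Schema and invariant checks for a colony-record file."""
    findings: list[Finding] = []
    try:
        df = pd.read_csv(path)
    except OSError as exc:
        return [Finding(None, f"unreadable file {path}: {exc}")]
    missing = set(COLONY_COLUMNS) - set(df.columns)
    if missing:
        return [Finding(None, f"missing columns {sorted(missing)}")]
    dose = _check_numeric(df, "dose_gy", findings)
    seeded = _check_numeric(df, "n_seeded", findings)
    colonies = _check_numeric(df, "n_colonies", findings)
    ok = dose.notna() & seeded.notna() & colonies.notna()
    for idx in df.index[ok & (dose < 0)]:
        findings.append(Finding(int(idx) + 1, "dose_gy < 0"))
    for idx in df.index[ok & (seeded < 1)]:
        findings.append(Finding(int(idx) + 1, "n_seeded < 1"))
    for idx in df.index[ok & ((colonies < 0) | (colonies > seeded))]:
        findings.append(Finding(int(idx) + 1, "n_colonies outside [0, n_seeded]"))
    dup = df.duplicated(subset=["modality", "dose_rate_gy_min", "arm", "dose_gy", "replicate"])
    for idx in df.index[dup]:
        findings.append(Finding(int(idx) + 1, "duplicate (group, dose, replicate)"))
    for key, sub in df[ok].groupby(["modality", "dose_rate_gy_min", "arm"]):
        if not (pd.to_numeric(sub["dose_gy"]) == 0).any():
            findings.append(Finding(None, f"group {key}: no dose-0 control plates"))
    return findings


def validate_foci_table(path) -> list[Finding]:
    findings: list[Finding] = []
    try:
        df = pd.read_csv(path)
    except OSError as exc:
        return [Finding(None, f"unreadable file {path}: {exc}")]
    missing = set(FOCI_COLUMNS) - set(df.columns)
    if missing:
        return [Finding(None, f"missing columns {sorted(missing)}")]
    foci = _check_numeric(df, "n_foci", findings)
    for idx in df.index[foci.notna() & (foci < 0)]:
        findings.append(Finding(int(idx) + 1, "n_foci < 0"))
    return findings
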