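"""Clonogenic assay bookkeeping: plating efficiency and survival curves.

A clonogenic assay seeds a known number of cells per plate and counts the
colonies (clusters of >= 50 cells) that grow out. The plating efficiency
(PE) is the colony yield of unirradiated plates; the survival fraction (SF)
of an irradiated plate is its colony yield normalized by PE. This module
turns raw per-plate colony counts into normalized survival curves for one
experimental group (modality x dose rate x arm).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ColonyRecord",
    "SurvivalCurve",
    "MissingControlError",
    "DegenerateControlError",
    "DuplicateReplicateError",
    "InvalidPEError",
    "compute_plating_efficiency",
    "compute_survival_fraction",
    "build_survival_curve",
]


class MissingControlError(ValueError):
    """No unirradiated (dose 0) plates available to estimate PE."""


class DegenerateControlError(ValueError):
    """Unirradiated plates formed zero colonies; PE would be zero."""


class DuplicateReplicateError(ValueError):
    """Two records share the same (dose, replicate) identity."""


class InvalidPEError(ValueError):
    """Plating efficiency must be strictly positive."""


@dataclass(frozen=True)
class ColonyRecord:
    """One plate's outcome: cells seeded and colonies counted at a dose.

    modality : irradiation modality label, e.g. "HDR-BT" or "LINAC".
    dose_rate : average delivered dose rate in Gy/min (group label).
    arm : treatment arm label, e.g. "CTRL" or "GNP".
    """

    modality: str
    dose_rate: float
    arm: str
    dose: float
    replicate: int
    n_seeded: int
    n_colonies: int

    def __post_init__(self) -> None:
        if self.n_seeded < 1:
            raise ValueError("n_seeded must be >= 1")
        if self.n_colonies < 0:
            raise ValueError("n_colonies must be >= 0")
        if self.n_colonies > self.n_seeded:
            raise ValueError("n_colonies cannot exceed n_seeded")
        if self.dose < 0:
            raise ValueError("dose must be >= 0")


@dataclass
class SurvivalCurve:
    """Per-dose survival summary for one group.

    ``table`` has columns dose_gy, sf_mean, sf_sd, n_replicates (sf_sd is
    NaN where only a single replicate exists — unknown, not zero).
    ``replicates`` has one row per plate: dose_gy, replicate, sf. The dose-0
    entry of ``table`` is pinned at sf_mean = 1 by construction.
    """

    modality: str
    dose_rate: float
    arm: str
    plating_efficiency: float
    table: pd.DataFrame
    replicates: pd.DataFrame = field(repr=False, default=None)

    @property
    def group(self) -> tuple:
        return (self.modality, self.dose_rate, self.arm)

    def points(self, use_replicates: bool = True, max_dose: float | None = None) -> np.ndarray:
        """(dose, sf) array for model fitting: all replicate plates jointly
        (default) or the per-dose means."""
        if use_replicates:
            pts = self.replicates[["dose_gy", "sf"]].to_numpy(dtype=float)
        else:
            pts = self.table[["dose_gy", "sf_mean"]].to_numpy(dtype=float)
        if max_dose is not None:
            pts = pts[pts[:, 0] <= max_dose]
        return pts


def compute_plating_efficiency(records: Iterable[ColonyRecord]) -> float:
    """Pooled plating efficiency over unirradiated plates.

    Total colonies divided by total cells seeded across all dose-0
    replicates (weights plates by their seeding density).
    """
    controls = [r for r in records if r.dose == 0]
    if not controls:
        raise MissingControlError("no dose-0 records in group")
    colonies = sum(r.n_colonies for r in controls)
    seeded = sum(r.n_seeded for r in controls)
    if colonies == 0:
        raise DegenerateControlError("zero colonies on unirradiated plates")
    return colonies / seeded


def compute_survival_fraction(record: ColonyRecord, pe: float) -> float:
    """PE-normalized survival fraction (n_colonies / n_seeded) / pe."""
    if pe <= 0:
        raise InvalidPEError("plating efficiency must be > 0")
    return (record.n_colonies / record.n_seeded) / pe


def build_survival_curve(
    records: Sequence[ColonyRecord],
    control_records: Sequence[ColonyRecord] | None = None,
) -> SurvivalCurve:
    """Normalize one group's colony counts into a survival curve.

    ``control_records`` supplies the unirradiated plates when the group
    shares a control with another group (e.g. two dose rates delivered on
    the same day from one cell passage); otherwise the group's own dose-0
    plates are used.
    """
    records = list(records)
    if not records:
        raise ValueError("no records supplied")
    seen = set()
    for r in records:
        key = (r.dose, r.replicate)
        if key in seen:
            raise DuplicateReplicateError(f"duplicate (dose, replicate) {key}")
        seen.add(key)

    controls = list(control_records) if control_records is not None else records
    pe = compute_plating_efficiency(controls)

    pool = records
    if control_records is not None and not any(r.dose == 0 for r in records):
        pool = records + [r for r in controls if r.dose == 0]

    rep_rows = [
        {"dose_gy": r.dose, "replicate": r.replicate, "sf": compute_survival_fraction(r, pe)}
        for r in pool
    ]
    reps = pd.DataFrame(rep_rows).sort_values(["dose_gy", "replicate"], ignore_index=True)

    grouped = reps.groupby("dose_gy")["sf"]
    table = pd.DataFrame(
        {
            "dose_gy": grouped.mean().index,
            "sf_mean": grouped.mean().to_numpy(),
            "sf_sd": grouped.std(ddof=1).to_numpy(),  # NaN for single replicate
            "n_replicates": grouped.size().to_numpy(),
        }
    ).reset_index(drop=True)
    # normalization pins the unirradiated point at exactly 1
    table.loc[table["dose_gy"] == 0, "sf_mean"] = 1.0

    first = records[0]
    return SurvivalCurve(
        modality=first.modality,
        dose_rate=first.dose_rate,
        arm=first.arm,
        plating_efficiency=pe,
        table=table,
        replicates=reps,
    )
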