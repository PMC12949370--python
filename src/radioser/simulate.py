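"""Synthetic clonogenic-assay and foci datasets with known truths.

The clonogenic generator emulates the study design this package targets:
triplicate plates seeded at escalating density for escalating dose
(100, 300, 500, 1000, 4000, 5000, 8000, 10000 cells at 0-8 Gy), survival
governed by a chosen dose-response model, colony formation as independent
Bernoulli successes per seeded cell with probability PE * SF(dose)
(binomial plate counts; beta-binomial when plate-to-plate overdispersion
is requested). Foci counts are Poisson or negative-binomial per cell.

Every generator is deterministic given its seed and emits records in the
exact schemas the analysis modules consume, so a full pipeline can be
exercised end-to-end with known ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .clonogenic import ColonyRecord
from .doserate import DwellPlan
from .foci import FociRecord
from .models import LQParams, lq_sf, mtsh_sf, tc_sf

__all__ = [
    "ModelTruth",
    "ClonogenicSimConfig",
    "FociSimConfig",
    "generate_clonogenic",
    "generate_foci",
    "generate_dwell_plan",
    "study_design_config",
]

_SF_FUNCS = {"lq": lq_sf, "mtsh": mtsh_sf, "tc": tc_sf}

DEFAULT_DOSES = (0.0, 1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 8.0)
DEFAULT_SEEDED = (100, 300, 500, 1000, 4000, 5000, 8000, 10000)


@dataclass(frozen=True)
class ModelTruth:
    """Ground-truth survival model for one arm."""

    kind: str
    params: object

    def sf(self, dose: float) -> float:
        return float(_SF_FUNCS[self.kind](dose, self.params))


@dataclass
class ClonogenicSimConfig:
    """Design of one simulated clonogenic experiment.

    ``arms`` maps arm label -> ModelTruth. ``overdispersion`` > 0 switches
    plate counts to beta-binomial: the per-plate success probability is
    drawn from Beta with mean PE*SF and concentration 1/overdispersion, so
    the binomial model is recovered continuously as overdispersion -> 0.
    """

    arms: dict
    plating_efficiency: float = 0.5
    doses: tuple = DEFAULT_DOSES
    seeded: tuple = DEFAULT_SEEDED
    replicates: int = 3
    overdispersion: float = 0.0
    modality: str = "HDR-BT"
    dose_rate: float = 1.1

    def __post_init__(self) -> None:
        if len(self.doses) != len(self.seeded):
            raise ValueError("doses and seeded lists must have equal length")
        if not 0 < self.plating_efficiency <= 1:
            raise ValueError("plating efficiency must lie in (0, 1]")
        if self.overdispersion < 0:
            raise ValueError("overdispersion must be >= 0")
        if self.replicates < 1:
            raise ValueError("need >= 1 replicate")


def study_design_config(
    ctrl: LQParams,
    treat: LQParams | None = None,
    plating_efficiency: float = 0.5,
    overdispersion: float = 0.0,
    modality: str = "HDR-BT",
    dose_rate: float = 1.1,
) -> ClonogenicSimConfig:
    """Convenience config at the study's plating design with LQ truths for
    a CTRL arm and (optionally) a sensitized GNP arm."""
    arms = {"CTRL": ModelTruth("lq", ctrl)}
    if treat is not None:
        arms["GNP"] = ModelTruth("lq", treat)
    return ClonogenicSimConfig(
        arms=arms,
        plating_efficiency=plating_efficiency,
        overdispersion=overdispersion,
        modality=modality,
        dose_rate=dose_rate,
    )


def generate_clonogenic(config: ClonogenicSimConfig, seed=None) -> list[ColonyRecord]:
    """Draw one synthetic colony-count dataset.

    Each plate's colony count is Binomial(n_seeded, PE * SF_true(dose)),
    or beta-binomial under overdispersion. Raises if PE * SF exceeds 1.
    """
    rng = np.random.default_rng(seed)
    records = []
    for arm in sorted(config.arms):
        truth = config.arms[arm]
        for dose, n_seeded in zip(config.doses, config.seeded):
            p = config.plating_efficiency * truth.sf(dose)
            if p > 1:
                raise ValueError(f"PE * SF = {p:.3f} > 1 at dose {dose}")
            for rep in range(1, config.replicates + 1):
                if config.overdispersion > 0 and 0 < p < 1:
                    kappa = 1.0 / config.overdispersion
                    p_plate = rng.beta(p * kappa, (1.0 - p) * kappa)
                else:
                    p_plate = p
                n_col = int(rng.binomial(n_seeded, p_plate))
                records.append(
                    ColonyRecord(
                        modality=config.modality,
                        dose_rate=config.dose_rate,
                        arm=arm,
                        dose=float(dose),
                        replicate=rep,
                        n_seeded=int(n_seeded),
                        n_colonies=n_col,
                    )
                )
    return records


@dataclass
class FociSimConfig:
    """Per-condition foci-count simulation.

    ``means`` maps arm label -> mean foci per cell. ``distribution`` is
    "poisson" or "nbinom"; the negative binomial uses ``dispersion`` k > 0
    with variance mean + mean^2/k (counts are frequently overdispersed).
    """

    means: dict
    cells_per_condition: int = 500
    distribution: str = "poisson"
    dispersion: float = float("nan")
    modality: str = "HDR-BT"
    dose_rate: float = 1.1

    def __post_init__(self) -> None:
        if any(m < 0 for m in self.means.values()):
            raise ValueError("foci means must be >= 0")
        if self.cells_per_condition < 1:
            raise ValueError("need >= 1 cell per condition")
        if self.distribution not in ("poisson", "nbinom"):
            raise ValueError("distribution must be 'poisson' or 'nbinom'")
        if self.distribution == "nbinom" and not self.dispersion > 0:
            raise ValueError("negative binomial requires dispersion > 0")


def generate_foci(config: FociSimConfig, seed=None) -> list[FociRecord]:
    """Draw per-cell foci counts for each configured condition."""
    rng = np.random.default_rng(seed)
    records = []
    for arm in sorted(config.means):
        mean = config.means[arm]
        n = config.cells_per_condition
        if mean == 0:
            counts = np.zeros(n, dtype=int)
        elif config.distribution == "poisson":
            counts = rng.poisson(mean, size=n)
        else:
            k = config.dispersion
            counts = rng.negative_binomial(k, k / (k + mean), size=n)
        records.extend(
            FociRecord(
                modality=config.modality,
                dose_rate=config.dose_rate,
                arm=arm,
                cell_id=i,
                n_foci=int(c),
            )
            for i, c in enumerate(counts)
        )
    return records


def generate_dwell_plan(
    n_dwells: int,
    step_cm: float = 0.5,
    time_per_dwell_s: float = 10.0,
    channel_height_cm: float = 1.5,
) -> DwellPlan:
    """Equally spaced collinear dwells along x, symmetric about the origin,
    at the source-channel height above the scoring plane."""
    if n_dwells < 1:
        raise ValueError("need >= 1 dwell")
    if n_dwells > 1 and step_cm <= 0:
        raise ValueError("step_cm must be > 0 for multiple dwells")
    xs = (np.arange(n_dwells) - (n_dwells - 1) / 2.0) * step_cm
    positions = np.column_stack([xs, np.zeros(n_dwells), np.full(n_dwells, channel_height_cm)])
    times = np.full(n_dwells, float(time_per_dwell_s))
    return DwellPlan(positions=positions, times=times)
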