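"""Delivery-physics calculators for HDR brachytherapy and LINAC beams.

Covers the bookkeeping around dose-rate delivery:

* particle-history budgeting for a stepping-source plan from the source's
  air kerma strength and an air kerma rate constant;
* dwell and average dose rates (dose over time, in Gy/s and Gy/min);
* LINAC pulse structure: dose per pulse and the intra-pulse instantaneous
  dose rate, which exceeds the average rate by orders of magnitude;
* inverse-square source-to-sample distance matching at fixed depth;
* a simplified point-source dwell-timeline simulator that scores maximum,
  time-averaged and total dose rate maps over a planar grid. The kernel is
  pure inverse-square with a configurable dose-rate constant and unit
  anisotropy/radial-dose functions — an explicit approximation, not a
  transport calculation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SourceSpec",
    "DwellPlan",
    "PulseSpec",
    "GridSpec",
    "DoseRateMap",
    "particle_histories",
    "dwell_dose_rate",
    "average_dose_rate",
    "dose_per_pulse",
    "pulse_instantaneous_dose_rate",
    "distance_for_dose_rate_factor",
    "point_source_rate",
    "simulate_dwell_timeline",
    "map_summary",
]

CI_TO_DECAYS_PER_S = 3.7e10  # 1 Ci = 3.7e10 decays/s


@dataclass(frozen=True)
class SourceSpec:
    """HDR source description.

    air_kerma_strength : S_k in mGy*m^2/h as printed on source certificates.
    gamma_constant : air kerma rate constant in cGy*cm^2/h/mCi.
    dose_rate_constant : TG-43-style Lambda in cGy/h per U (1 U =
        1 uGy*m^2/h) at 1 cm, used only by the point-source kernel.
    """

    air_kerma_strength: float
    gamma_constant: float = 4.037
    dose_rate_constant: float = 1.109

    def __post_init__(self) -> None:
        if min(self.air_kerma_strength, self.gamma_constant, self.dose_rate_constant) <= 0:
            raise ValueError("source parameters must be strictly positive")

    @property
    def sk_u(self) -> float:
        """S_k in U (uGy*m^2/h): explicit x1000 from the mGy*m^2/h input."""
        return self.air_kerma_strength * 1000.0


@dataclass
class DwellPlan:
    """Ordered dwell positions (cm) and times (s) of a stepping source."""

    positions: np.ndarray  # (n, 3) x,y,z in cm
    times: np.ndarray  # (n,) seconds

    def __post_init__(self) -> None:
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        self.times = np.atleast_1d(np.asarray(self.times, dtype=float))
        if self.positions.shape != (self.times.size, 3):
            raise ValueError("positions must be (n, 3) matching n dwell times")
        if self.times.size < 1:
            raise ValueError("a dwell plan needs at least one entry")
        if np.any(self.times < 0):
            raise ValueError("dwell times must be >= 0")

    @property
    def total_time(self) -> float:
        return float(self.times.sum())


@dataclass(frozen=True)
class PulseSpec:
    """LINAC pulse structure.

    Defaults reproduce the consistent worked chain for a 6 MV beam:
    0.08 MU/pulse with a 200 cGy / 220 MU calibration gives 0.0727 cGy per
    4 us pulse and ~180 Gy/s inside the pulse.
    """

    pulse_width: float = 4e-6  # s
    mu_per_pulse: float = 0.08  # MU
    machine_output: float = 100.0  # MU/min
    calibration: float = 200.0 / 220.0  # cGy/MU at the sample point

    def __post_init__(self) -> None:
        if min(self.pulse_width, self.mu_per_pulse, self.machine_output, self.calibration) <= 0:
            raise ValueError("pulse parameters must be strictly positive")


@dataclass(frozen=True)
class GridSpec:
    """Planar scoring grid: ``bins`` x ``bins`` voxels over ``extent_cm``
    square centred on the origin at z = 0, values scored at voxel centres."""

    extent_cm: float = 3.5
    bins: int = 50

    def centers(self) -> np.ndarray:
        edges = np.linspace(-self.extent_cm / 2.0, self.extent_cm / 2.0, self.bins + 1)
        return 0.5 * (edges[:-1] + edges[1:])


def particle_histories(source: SourceSpec, dwell_time: float) -> float:
    """Decay (particle-history) budget for one dwell.

    S_k in mGy*m^2/h converts to cGy*cm^2/h (x0.1 cGy/mGy x 1e4 cm^2/m^2 =
    x1000); dividing by the air kerma rate constant gives the apparent
    activity in mCi, converted to Ci and multiplied by 3.7e10 decays/s and
    the dwell time.
    """
    if dwell_time < 0:
        raise ValueError("dwell_time must be >= 0")
    sk_cgy_cm2_h = source.air_kerma_strength * 1000.0
    activity_ci = sk_cgy_cm2_h / source.gamma_constant / 1000.0
    return activity_ci * CI_TO_DECAYS_PER_S * dwell_time


def dwell_dose_rate(dose_to_voxel: float, dwell_time: float) -> float:
    """Dose rate in Gy/s: dose delivered to a voxel over the dwell time."""
    if dwell_time <= 0:
        raise ValueError("dwell_time must be > 0")
    return dose_to_voxel / dwell_time


def average_dose_rate(total_dose: float, delivery_time: float) -> float:
    """Average delivered dose rate in Gy/min: total plan dose over the
    reported delivery time."""
    if delivery_time <= 0:
        raise ValueError("delivery_time must be > 0")
    return 60.0 * total_dose / delivery_time


def dose_per_pulse(pulse: PulseSpec) -> float:
    """Dose per pulse in cGy: calibration (cGy/MU) times MU per pulse."""
    return pulse.calibration * pulse.mu_per_pulse


def pulse_instantaneous_dose_rate(dose_per_pulse_cgy: float, pulse_width: float) -> float:
    """Intra-pulse instantaneous dose rate in Gy/s."""
    if pulse_width <= 0:
        raise ValueError("pulse_width must be > 0")
    return (dose_per_pulse_cgy / 100.0) / pulse_width


def distance_for_dose_rate_factor(reference_distance: float, factor: float) -> float:
    """Source-to-sample distance scaling a reference dose rate by ``factor``.

    Pure inverse-square at fixed depth: d = d_ref / sqrt(factor). Halving
    the rate from 91 cm gives 128.7 cm (~129 cm).
    """
    if reference_distance <= 0 or factor <= 0:
        raise ValueError("reference_distance and factor must be > 0")
    return reference_distance / np.sqrt(factor)


def point_source_rate(source: SourceSpec, distance):
    """Water dose rate (Gy/min) of an ideal point source at ``distance`` cm.

    rate = S_k[U] * Lambda / r^2 in cGy/h, converted to Gy/min (/6000).
    Anisotropy and radial dose functions are taken as unity; this is a
    geometric approximation, not a transport result.
    """
    r = np.asarray(distance, dtype=float)
    if np.any(r <= 0):
        raise ZeroDivisionError("distance must be > 0 (point-source singularity)")
    rate = source.sk_u * source.dose_rate_constant / (r * r) / 6000.0
    return float(rate) if rate.ndim == 0 else rate


@dataclass
class DoseRateMap:
    """Planar dose-rate scoring of a dwell plan.

    2-D arrays are indexed [ix, iy] on the voxel-centre grids ``x``/``y``.
    ``rates`` keeps the per-dwell rate stack (n_dwells, bins, bins) so the
    delivery timeline at any voxel can be extracted.
    """

    x: np.ndarray
    y: np.ndarray
    max_rate: np.ndarray  # Gy/min
    avg_rate: np.ndarray  # Gy/min, time-weighted over dwells
    total_dose: np.ndarray  # Gy
    dwell_times: np.ndarray  # s
    rates: np.ndarray = field(repr=False, default=None)

    def timeline(self, ix: int, iy: int) -> pd.DataFrame:
        """Delivery timeline at voxel (ix, iy): one row per dwell with its
        start time (s) and the dose rate (Gy/min) during that dwell."""
        starts = np.concatenate([[0.0], np.cumsum(self.dwell_times)[:-1]])
        return pd.DataFrame(
            {"time_s": starts, "dwell_time_s": self.dwell_times,
             "dose_rate_gy_min": self.rates[:, ix, iy]}
        )


def simulate_dwell_timeline(
    plan: DwellPlan, source: SourceSpec, grid: GridSpec = GridSpec()
) -> DoseRateMap:
    """Score a dwell plan on a planar grid with the point-source kernel.

    Per voxel: the rate during each dwell, the maximum and time-weighted
    average rate over the plan, and the total dose (sum of rate x time).
    """
    centers = grid.centers()
    gx, gy = np.meshgrid(centers, centers, indexing="ij")
    voxels = np.stack([gx, gy, np.zeros_like(gx)], axis=-1)  # z = 0 plane
    diffs = plan.positions[:, None, None, :] - voxels[None, :, :, :]
    dists = np.sqrt(np.sum(diffs * diffs, axis=-1))
    if np.any(dists <= 0):
        raise ZeroDivisionError("dwell position coincides with a scoring voxel")
    rates = point_source_rate(source, dists)  # (n, bins, bins) Gy/min
    times = plan.times
    total_dose = np.tensordot(times, rates, axes=1) / 60.0
    total_time = times.sum()
    avg = np.tensordot(times, rates, axes=1) / total_time if total_time > 0 else rates.mean(0)
    return DoseRateMap(
        x=centers,
        y=centers,
        max_rate=rates.max(axis=0),
        avg_rate=avg,
        total_dose=total_dose,
        dwell_times=times,
        rates=rates,
    )


def map_summary(m: DoseRateMap) -> dict:
    """Min/max/mean of the maximum-rate map plus plan totals."""
    return {
        "max_rate_min_gy_min": float(m.max_rate.min()),
        "max_rate_max_gy_min": float(m.max_rate.max()),
        "max_rate_mean_gy_min": float(m.max_rate.mean()),
        "total_dose_max_gy": float(m.total_dose.max()),
        "total_time_s": float(m.dwell_times.sum()),
    }
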