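"""Dose-response survival models and nonlinear least-squares fitting.

Implements the three classical cell-survival models used for clonogenic
dose-response data:

* linear-quadratic (LQ): ``SF = exp(-alpha*D - beta*D^2)``
* multi-target single-hit (MTSH): ``SF = 1 - (1 - exp(-D/D0))^n``
* two-component (TC): ``SF = exp(-D/D1) * [1 - (1 - exp(-D/Dn))^n]``

together with bounded least-squares fitting on the linear survival-fraction
scale, iso-survival dose solving (e.g. the dose giving 10% survival, D10),
and the sensitization enhancement ratio

    SER = D10(control) / D10(sensitized),

the headline statistic for radiosensitizer experiments: SER > 1 means the
sensitizer lowers the dose needed to reach the same cell kill.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize

__all__ = [
    "LQParams",
    "MTSHParams",
    "TCParams",
    "ModelFit",
    "FitError",
    "UnderdeterminedError",
    "UnattainableSurvivalError",
    "lq_sf",
    "mtsh_sf",
    "tc_sf",
    "fit_model",
    "dose_at_sf",
    "lq_dose_at_sf",
    "compute_ser",
    "alpha_beta_ratio",
    "fit_report",
]


class FitError(RuntimeError):
    """Nonlinear fit failed to converge."""


class UnderdeterminedError(ValueError):
    """Fewer distinct doses than the model can identify."""


class UnattainableSurvivalError(ValueError):
    """The requested survival level is never reached by the fitted model."""


@dataclass(frozen=True)
class LQParams:
    """Linear-quadratic parameters.

    alpha : Gy^-1, lethal single-track damage coefficient.
    beta  : Gy^-2, sublethal two-track damage coefficient.
    """

    alpha: float
    beta: float

    def __post_init__(self) -> None:
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("LQ parameters must be non-negative")


@dataclass(frozen=True)
class MTSHParams:
    """Multi-target single-hit parameters: mean lethal dose d0 (Gy) and a
    real-valued target number n_targets >= 1."""

    d0: float
    n_targets: float

    def __post_init__(self) -> None:
        if self.d0 <= 0:
            raise ValueError("d0 must be positive")
        if self.n_targets < 1:
            raise ValueError("n_targets must be >= 1")


@dataclass(frozen=True)
class TCParams:
    """Two-component parameters: single-hit dose d1 (Gy), multi-target dose
    dn (Gy), and target number n_targets >= 1."""

    d1: float
    dn: float
    n_targets: float

    def __post_init__(self) -> None:
        if self.d1 <= 0 or self.dn <= 0:
            raise ValueError("d1 and dn must be positive")
        if self.n_targets < 1:
            raise ValueError("n_targets must be >= 1")


def _check_dose(dose):
    d = np.asarray(dose, dtype=float)
    if np.any(d < 0):
        raise ValueError("dose must be non-negative")
    return d


def lq_sf(dose, params: LQParams):
    """Survival fraction exp(-(alpha*D + beta*D^2)); scalar in, scalar out."""
    d = _check_dose(dose)
    out = np.exp(-(params.alpha * d + params.beta * d * d))
    return float(out) if np.isscalar(dose) or out.ndim == 0 else out


def mtsh_sf(dose, params: MTSHParams):
    """Multi-target single-hit survival 1 - (1 - exp(-D/D0))^n."""
    d = _check_dose(dose)
    out = 1.0 - np.power(-np.expm1(-d / params.d0), params.n_targets)
    return float(out) if np.isscalar(dose) or out.ndim == 0 else out


def tc_sf(dose, params: TCParams):
    """Two-component survival exp(-D/D1) * [1 - (1 - exp(-D/Dn))^n]."""
    d = _check_dose(dose)
    multi = 1.0 - np.power(-np.expm1(-d / params.dn), params.n_targets)
    out = np.exp(-d / params.d1) * multi
    return float(out) if np.isscalar(dose) or out.ndim == 0 else out


_PREDICT = {
    "lq": lambda theta, d: np.exp(-(theta[0] * d + theta[1] * d * d)),
    "mtsh": lambda theta, d: 1.0 - np.power(-np.expm1(-d / theta[0]), theta[1]),
    "tc": lambda theta, d: np.exp(-d / theta[0])
    * (1.0 - np.power(-np.expm1(-d / theta[1]), theta[2])),
}

# defaults chosen to cover reported photon-beam parameter ranges with margin
_INIT = {"lq": (0.3, 0.03), "mtsh": (1.5, 3.0), "tc": (5.0, 1.5, 3.0)}
_BOUNDS = {
    "lq": ([0.0, 0.0], [3.0, 1.0]),
    "mtsh": ([1e-3, 1.0], [50.0, 50.0]),
    "tc": ([1e-3, 1e-3, 1.0], [100.0, 50.0, 50.0]),
}
_MIN_DOSES = {"lq": 3, "mtsh": 4, "tc": 4}


def _params_from_theta(model: str, theta):
    if model == "lq":
        return LQParams(float(theta[0]), float(theta[1]))
    if model == "mtsh":
        return MTSHParams(float(theta[0]), float(theta[1]))
    return TCParams(float(theta[0]), float(theta[1]), float(theta[2]))


def _theta_from_params(params) -> tuple:
    if isinstance(params, LQParams):
        return (params.alpha, params.beta)
    if isinstance(params, MTSHParams):
        return (params.d0, params.n_targets)
    return (params.d1, params.dn, params.n_targets)


@dataclass
class ModelFit:
    """Result of a least-squares dose-response fit.

    ``dose_sds`` holds the replicate standard deviation of the observed
    survival fractions at each dose with at least two observations;
    ``pooled_sigma`` is the residual standard deviation sqrt(SSR/(n-p)).
    Both feed the parametric bootstrap's noise model.
    """

    model: str
    params: object
    doses: np.ndarray
    sf_obs: np.ndarray
    residuals: np.ndarray
    dose_sds: dict = field(default_factory=dict)
    pooled_sigma: float = float("nan")
    r_squared: float = float("nan")
    converged: bool = False
    group: tuple | None = None
    input_digest: str = ""

    @property
    def theta(self) -> tuple:
        return _theta_from_params(self.params)

    def predict(self, dose):
        return _PREDICT[self.model](self.theta, np.asarray(dose, dtype=float))

    def sigma_at(self, dose: float) -> float:
        """Per-dose replicate SD, falling back to the pooled residual SD."""
        sd = self.dose_sds.get(float(dose))
        if sd is None or not np.isfinite(sd):
            return self.pooled_sigma
        return sd


def _points_digest(doses: np.ndarray, sf: np.ndarray) -> str:
    payload = np.ascontiguousarray(np.column_stack([doses, sf]))
    return hashlib.sha256(payload.tobytes()).hexdigest()[:16]


def fit_model(
    curve_points: Sequence[tuple],
    model: str = "lq",
    init: Sequence[float] | None = None,
    bounds: tuple | None = None,
    max_dose: float | None = None,
    group: tuple | None = None,
) -> ModelFit:
    """Fit a survival model to (dose, sf) points by bounded least squares.

    The objective is the unweighted sum of squared residuals on the linear
    SF scale; replicate points at the same dose are fitted jointly.

    Parameters
    ----------
    curve_points : sequence of (dose_gy, sf) pairs, replicates allowed.
    model : "lq", "mtsh" or "tc".
    init, bounds : optional override of the default start and box bounds.
    max_dose : if given, points above this dose are excluded before fitting
        (the LQ model is conventionally restricted to moderate doses).
    """
    if model not in _PREDICT:
        raise ValueError(f"unknown model {model!r}")
    pts = np.asarray(curve_points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("curve_points must be (dose, sf) pairs")
    if max_dose is not None:
        pts = pts[pts[:, 0] <= max_dose]
    doses, sf = pts[:, 0], pts[:, 1]
    if np.any(doses < 0):
        raise ValueError("dose must be non-negative")
    if np.any(sf < 0):
        raise ValueError("survival fractions must be >= 0")
    n_param = len(_INIT[model])
    if len(np.unique(doses)) < _MIN_DOSES[model]:
        raise UnderdeterminedError(
            f"{model} fit needs >= {_MIN_DOSES[model]} distinct doses"
        )

    x0 = np.asarray(init if init is not None else _INIT[model], dtype=float)
    lo, hi = bounds if bounds is not None else _BOUNDS[model]
    x0 = np.clip(x0, lo, hi)
    predict = _PREDICT[model]

    def resid(theta):
        return predict(theta, doses) - sf

    try:
        sol = optimize.least_squares(
            resid, x0, bounds=(lo, hi), method="trf",
            ftol=1e-15, xtol=1e-15, gtol=1e-15,
        )
    except Exception as exc:  # pragma: no cover - scipy-internal failures
        raise FitError(f"least-squares failure: {exc}") from exc
    if not sol.success:
        raise FitError(f"fit did not converge: {sol.message}")

    residuals = sol.fun
    ssr = float(residuals @ residuals)
    sst = float(np.sum((sf - sf.mean()) ** 2))
    r2 = 1.0 - ssr / sst if sst > 0 else float("nan")
    dof = len(sf) - n_param
    pooled = math.sqrt(ssr / dof) if dof > 0 else float("nan")
    dose_sds = {}
    for d in np.unique(doses):
        vals = sf[doses == d]
        if len(vals) >= 2:
            dose_sds[float(d)] = float(np.std(vals, ddof=1))

    return ModelFit(
        model=model,
        params=_params_from_theta(model, sol.x),
        doses=doses,
        sf_obs=sf,
        residuals=residuals,
        dose_sds=dose_sds,
        pooled_sigma=pooled,
        r_squared=r2,
        converged=True,
        group=group,
        input_digest=_points_digest(doses, sf),
    )


def lq_dose_at_sf(params: LQParams, target_sf: float = 0.1) -> float:
    """Closed-form dose at which LQ survival equals ``target_sf``.

    Positive root of beta*D^2 + alpha*D + ln(target_sf) = 0.
    """
    if not 0 < target_sf < 1:
        raise ValueError("target_sf must lie in (0, 1)")
    a, b = params.alpha, params.beta
    ln_s = math.log(target_sf)
    if a == 0 and b == 0:
        raise UnattainableSurvivalError("alpha = beta = 0 never reaches target")
    # stable form of the positive quadratic root: avoids the catastrophic
    # cancellation of (-a + sqrt(a^2 - 4b*ln_s))/(2b) at tiny b, and reduces
    # to -ln_s/a as b -> 0
    return -2.0 * ln_s / (a + math.sqrt(a * a - 4.0 * b * ln_s))


_ROOT_DOSE_MAX = 50.0  # Gy; generous ceiling for bracketing iso-survival doses


def dose_at_sf(fit: ModelFit, target_sf: float = 0.1) -> float:
    """Dose at which the fitted model's survival equals ``target_sf``.

    LQ uses the closed form; MTSH/TC use a bracketing root-finder on
    [0, 50] Gy to 1e-6 Gy.
    """
    if not 0 < target_sf < 1:
        raise ValueError("target_sf must lie in (0, 1)")
    if fit.model == "lq":
        return lq_dose_at_sf(fit.params, target_sf)
    f = lambda d: float(fit.predict(d)) - target_sf
    if f(_ROOT_DOSE_MAX) > 0:
        raise UnattainableSurvivalError(
            f"survival stays above {target_sf} up to {_ROOT_DOSE_MAX} Gy"
        )
    return float(optimize.brentq(f, 0.0, _ROOT_DOSE_MAX, xtol=1e-6))


def compute_ser(fit_ctrl: ModelFit, fit_treat: ModelFit, target_sf: float = 0.1) -> float:
    """Sensitization enhancement ratio: iso-survival dose of the control arm
    over that of the sensitized arm, default at 10% survival."""
    if not (fit_ctrl.converged and fit_treat.converged):
        raise FitError("SER requires two converged fits")
    return dose_at_sf(fit_ctrl, target_sf) / dose_at_sf(fit_treat, target_sf)


def alpha_beta_ratio(params: LQParams) -> float:
    """alpha/beta ratio in Gy; NaN when beta = 0 (ratio unavailable)."""
    if params.beta == 0:
        return float("nan")
    return params.alpha / params.beta


def fit_report(fit: ModelFit, target_sf: float = 0.1) -> str:
    """Key-value text report for a fit, including the input digest."""
    lines = [
        f"model: {fit.model}",
        f"group: {fit.group}",
        f"converged: {fit.converged}",
        f"n_points: {len(fit.sf_obs)}",
        f"input_digest: {fit.input_digest}",
    ]
    for name, val in zip(_PARAM_NAMES[fit.model], fit.theta):
        lines.append(f"{name}: {val:.10g}")
    if fit.model == "lq":
        ab = alpha_beta_ratio(fit.params)
        lines.append(f"alpha_beta_gy: {'unavailable' if math.isnan(ab) else f'{ab:.10g}'}")
    try:
        lines.append(f"d{target_sf * 100:g}_gy: {dose_at_sf(fit, target_sf):.10g}")
    except UnattainableSurvivalError:
        lines.append("d10_gy: unavailable")
    lines.append(f"r_squared: {fit.r_squared:.10g}")
    lines.append(f"pooled_sigma: {fit.pooled_sigma:.10g}")
    return "\n".join(lines) + "\n"


_PARAM_NAMES = {
    "lq": ("alpha_per_gy", "beta_per_gy2"),
    "mtsh": ("d0_gy", "n_targets"),
    "tc": ("d1_gy", "dn_gy", "n_targets"),
}
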