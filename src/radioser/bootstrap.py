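"""Parametric bootstrap inference for dose-response parameters and SER.

The protocol: from a converged fit, repeatedly synthesize survival-fraction
datasets at the original design points (model prediction plus zero-mean
Gaussian noise with the per-dose replicate SD, falling back to the pooled
residual SD), refit each synthetic dataset, and summarize the resulting
parameter / SER distributions with percentile confidence intervals and a
two-sided bootstrap p-value ("twice the smaller tail fraction" relative to
the null reference: 1 for SER, 0 for a SER difference).

Point estimates are always taken from the measured dataset's fit, never
from the bootstrap mean. All randomness flows from a single seed through
spawned, per-arm generator streams, so results are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .models import (
    FitError,
    ModelFit,
    alpha_beta_ratio,
    compute_ser,
    dose_at_sf,
    fit_model,
)

__all__ = [
    "BootstrapSummary",
    "BootstrapDistribution",
    "parametric_bootstrap",
    "design_from_records",
    "bootstrap_ser",
    "compare_ser",
    "two_sided_bootstrap_p",
    "percentile_ci",
]

_FAILURE_WARN_FRACTION = 0.10


@dataclass
class BootstrapSummary:
    """Summary of one bootstrapped statistic.

    ``p_value`` may be exactly 0 when no resample crossed the reference;
    ``p_display`` then reports the resolution floor "< 2/n_boot" instead of
    a bare zero.
    """

    statistic: str
    point_estimate: float
    ci_low: float
    ci_high: float
    p_value: float | None
    n_boot: int
    seed: object
    n_failed_refits: int = 0
    warning: str | None = None

    @property
    def p_display(self) -> str:
        if self.p_value is None:
            return "n/a"
        if self.p_value == 0.0:
            return f"< {2.0 / self.n_boot:g}"
        return f"{self.p_value:g}"

    @property
    def significant(self) -> bool:
        """Reference value excluded from the 95% CI (the interval rule)."""
        ref = 1.0 if self.statistic == "ser" else 0.0
        return not (self.ci_low <= ref <= self.ci_high)


@dataclass
class BootstrapDistribution:
    """Raw bootstrap draws of (alpha, beta, alpha_beta) plus bookkeeping."""

    samples: pd.DataFrame
    n_boot: int
    n_failed_refits: int
    seed: object

    def summarize(self, statistic: str, point_estimate: float, level: float = 0.95) -> BootstrapSummary:
        vals = self.samples[statistic].to_numpy()
        vals = vals[np.isfinite(vals)]
        lo, hi = percentile_ci(vals, level)
        warning = None
        if self.n_failed_refits >= self.n_boot * _FAILURE_WARN_FRACTION:
            warning = f"{self.n_failed_refits}/{self.n_boot} refits failed; inference degraded"
        return BootstrapSummary(
            statistic=statistic,
            point_estimate=point_estimate,
            ci_low=lo,
            ci_high=hi,
            p_value=None,
            n_boot=self.n_boot,
            seed=self.seed,
            n_failed_refits=self.n_failed_refits,
            warning=warning,
        )


def two_sided_bootstrap_p(samples: Sequence[float], reference: float) -> float:
    """Two-sided bootstrap p: twice the smaller fraction of draws strictly
    above / below the reference, capped at 1.

    Draws exactly equal to the reference are excluded from both one-sided
    counts; a distribution consisting entirely of ties (a degenerate,
    zero-noise bootstrap) carries no evidence against the reference and
    returns 1.
    """
    s = np.asarray(samples, dtype=float)
    if s.size == 0:
        raise ValueError("no bootstrap samples")
    above = int(np.sum(s > reference))
    below = int(np.sum(s < reference))
    if above + below == 0:
        return 1.0
    return min(1.0, 2.0 * min(above, below) / s.size)


def percentile_ci(samples: Sequence[float], level: float = 0.95) -> tuple[float, float]:
    """Equal-tailed percentile interval with linear interpolation."""
    if not 0 < level < 1:
        raise ValueError("level must lie in (0, 1)")
    s = np.asarray(samples, dtype=float)
    if s.size < 20:
        raise ValueError("need >= 20 samples for a percentile CI")
    tail = (1.0 - level) / 2.0
    lo, hi = np.quantile(s, [tail, 1.0 - tail])
    return float(lo), float(hi)


def _as_seedseq(seed) -> np.random.SeedSequence:
    if isinstance(seed, np.random.SeedSequence):
        return seed
    return np.random.SeedSequence(seed)


def _design_from_fit(fit: ModelFit) -> list[tuple[float, int]]:
    doses, counts = np.unique(fit.doses, return_counts=True)
    return [(float(d), int(c)) for d, c in zip(doses, counts)]


def design_from_records(records, max_dose: float | None = None) -> list[tuple[float, int, int]]:
    """Bootstrap design (dose, n_replicates, n_seeded) from colony records,
    as needed by the colony-level (binomial) noise model."""
    by_dose: dict[float, list[int]] = {}
    for r in records:
        if max_dose is not None and r.dose > max_dose:
            continue
        by_dose.setdefault(float(r.dose), []).append(r.n_seeded)
    return [
        (dose, len(seeds), int(round(np.mean(seeds))))
        for dose, seeds in sorted(by_dose.items())
    ]


def _synthesize_points(fit: ModelFit, design, rng: np.random.Generator) -> np.ndarray:
    """One synthetic (dose, sf) dataset: prediction + truncated Gaussian noise."""
    doses_out = []
    sf_out = []
    for entry in design:
        dose, n_rep = entry[0], entry[1]
        mu = float(fit.predict(dose))
        sigma = fit.sigma_at(dose)
        if sigma > 0 and np.isfinite(sigma):
            vals = mu + rng.normal(0.0, sigma, size=n_rep)
        else:
            vals = np.full(n_rep, mu)
        np.clip(vals, 0.0, None, out=vals)  # no negative survival
        doses_out.append(np.full(n_rep, dose))
        sf_out.append(vals)
    return np.column_stack([np.concatenate(doses_out), np.concatenate(sf_out)])


def _synthesize_points_binomial(
    fit: ModelFit, design, pe: float, rng: np.random.Generator
) -> np.ndarray | None:
    """One synthetic (dose, sf) dataset at the colony level.

    Colonies are drawn Binomial(n_seeded, pe * prediction) per plate, the
    plating efficiency is re-estimated from the synthetic dose-0 plates,
    and survival fractions are re-normalized by it — so the normalization
    error of the real pipeline propagates into the bootstrap distribution.
    Returns None when the synthetic control yields zero colonies.
    """
    doses_out, col_out, seed_out = [], [], []
    for entry in design:
        if len(entry) != 3:
            raise ValueError("binomial noise model needs (dose, n_rep, n_seeded) design entries")
        dose, n_rep, n_seeded = entry
        p = min(1.0, max(0.0, pe * float(fit.predict(dose))))
        cols = rng.binomial(n_seeded, p, size=n_rep)
        doses_out.append(np.full(n_rep, dose, dtype=float))
        col_out.append(cols)
        seed_out.append(np.full(n_rep, n_seeded, dtype=float))
    doses = np.concatenate(doses_out)
    cols = np.concatenate(col_out).astype(float)
    seeds = np.concatenate(seed_out)
    at_zero = doses == 0
    if at_zero.any():
        pe_hat = cols[at_zero].sum() / seeds[at_zero].sum()
    else:
        pe_hat = pe
    if pe_hat <= 0:
        return None
    return np.column_stack([doses, (cols / seeds) / pe_hat])


def _make_synthesizer(fit: ModelFit, design, noise_model: str, pe: float | None):
    if noise_model == "gaussian":
        return lambda rng: _synthesize_points(fit, design, rng)
    if noise_model == "binomial":
        if pe is None:
            raise ValueError("binomial noise model requires the measured plating efficiency")
        return lambda rng: _synthesize_points_binomial(fit, design, pe, rng)
    raise ValueError("noise_model must be 'gaussian' or 'binomial'")


def _refit(fit: ModelFit, points: np.ndarray) -> ModelFit | None:
    try:
        return fit_model(points, model=fit.model, init=fit.theta)
    except (FitError, ValueError):
        return None


def parametric_bootstrap(
    fit: ModelFit,
    design: Sequence[tuple] | None = None,
    n_boot: int = 1000,
    seed=None,
    noise_model: str = "gaussian",
    pe: float | None = None,
) -> BootstrapDistribution:
    """Bootstrap the fitted parameters of one arm.

    ``noise_model="gaussian"`` (default) perturbs model-predicted survival
    fractions with per-dose Gaussian noise; ``"binomial"`` resamples colony
    counts (requires (dose, n_rep, n_seeded) design entries and the
    measured plating efficiency ``pe``) and so also propagates the PE
    normalization error. Returns the n_boot-row distribution of alpha,
    beta and alpha/beta (for an LQ fit; other models record their native
    parameters). Iterations whose refit fails are dropped and counted.
    """
    if not fit.converged:
        raise FitError("cannot bootstrap an unconverged fit")
    if design is None:
        design = _design_from_fit(fit)
    synthesize = _make_synthesizer(fit, design, noise_model, pe)
    rng = np.random.default_rng(_as_seedseq(seed))
    rows = []
    n_failed = 0
    for _ in range(n_boot):
        pts = synthesize(rng)
        refit = _refit(fit, pts) if pts is not None else None
        if refit is None:
            n_failed += 1
            continue
        if fit.model == "lq":
            rows.append(
                {
                    "alpha": refit.params.alpha,
                    "beta": refit.params.beta,
                    "alpha_beta": alpha_beta_ratio(refit.params),
                }
            )
        else:
            rows.append(dict(zip(("p1", "p2", "p3"), list(refit.theta) + [np.nan] * 3)))
    if not rows:
        raise FitError("all bootstrap refits failed")
    return BootstrapDistribution(
        samples=pd.DataFrame(rows),
        n_boot=n_boot,
        n_failed_refits=n_failed,
        seed=seed,
    )


def _ser_samples(
    fit_ctrl: ModelFit,
    fit_treat: ModelFit,
    designs,
    n_boot: int,
    rng_ctrl: np.random.Generator,
    rng_treat: np.random.Generator,
    target_sf: float,
    noise_model: str = "gaussian",
    pes: tuple = (None, None),
) -> tuple[np.ndarray, int]:
    design_c, design_t = designs
    synth_c = _make_synthesizer(fit_ctrl, design_c, noise_model, pes[0])
    synth_t = _make_synthesizer(fit_treat, design_t, noise_model, pes[1])
    out = []
    n_failed = 0
    for _ in range(n_boot):
        pts_c = synth_c(rng_ctrl)
        pts_t = synth_t(rng_treat)
        rc = _refit(fit_ctrl, pts_c) if pts_c is not None else None
        rt = _refit(fit_treat, pts_t) if pts_t is not None else None
        if rc is None or rt is None:
            n_failed += 1
            continue
        try:
            out.append(dose_at_sf(rc, target_sf) / dose_at_sf(rt, target_sf))
        except ValueError:
            n_failed += 1
    return np.asarray(out), n_failed


def _resolve_designs(fit_ctrl, fit_treat, designs):
    if designs is None:
        return (_design_from_fit(fit_ctrl), _design_from_fit(fit_treat))
    return designs


def bootstrap_ser(
    fit_ctrl: ModelFit,
    fit_treat: ModelFit,
    designs=None,
    n_boot: int = 1000,
    seed=None,
    target_sf: float = 0.1,
    noise_model: str = "gaussian",
    pes: tuple = (None, None),
) -> BootstrapSummary:
    """SER with percentile CI and two-sided bootstrap p against SER = 1.

    Both arms are independently re-synthesized and refitted each iteration
    (separate generator streams spawned from the seed); the point estimate
    is the SER of the measured fits. See ``parametric_bootstrap`` for the
    two noise models; ``pes`` carries the measured (ctrl, treat) plating
    efficiencies for the colony-level model.
    """
    if not (fit_ctrl.converged and fit_treat.converged):
        raise FitError("SER bootstrap requires converged fits")
    designs = _resolve_designs(fit_ctrl, fit_treat, designs)
    ss_c, ss_t = _as_seedseq(seed).spawn(2)
    samples, n_failed = _ser_samples(
        fit_ctrl, fit_treat, designs, n_boot,
        np.random.default_rng(ss_c), np.random.default_rng(ss_t), target_sf,
        noise_model=noise_model, pes=pes,
    )
    if samples.size == 0:
        raise FitError("all bootstrap iterations failed")
    lo, hi = percentile_ci(samples, 0.95)
    summary = BootstrapSummary(
        statistic="ser",
        point_estimate=compute_ser(fit_ctrl, fit_treat, target_sf),
        ci_low=lo,
        ci_high=hi,
        p_value=two_sided_bootstrap_p(samples, 1.0),
        n_boot=n_boot,
        seed=seed,
        n_failed_refits=n_failed,
    )
    if n_failed >= n_boot * _FAILURE_WARN_FRACTION:
        summary.warning = f"{n_failed}/{n_boot} iterations failed; inference degraded"
    summary.samples = samples
    return summary


def compare_ser(
    group_a: tuple[ModelFit, ModelFit],
    group_b: tuple[ModelFit, ModelFit],
    designs_a=None,
    designs_b=None,
    n_boot: int = 1000,
    seed=None,
    target_sf: float = 0.1,
    arm_seeds: tuple | None = None,
    noise_model: str = "gaussian",
    pes: tuple = ((None, None), (None, None)),
) -> BootstrapSummary:
    """Paired SER difference Delta = SER_A - SER_B with CI and p against 0.

    Each iteration independently re-synthesizes all four arms. ``arm_seeds``
    optionally pins the per-group seed sequences (two entries, group A then
    group B), which makes mirrored comparisons exactly antisymmetric.
    ``pes`` carries ((pe_a_ctrl, pe_a_treat), (pe_b_ctrl, pe_b_treat)) for
    the colony-level noise model.
    """
    fits = (*group_a, *group_b)
    if not all(f.converged for f in fits):
        raise FitError("Delta-SER bootstrap requires four converged fits")
    designs_a = _resolve_designs(*group_a, designs_a)
    designs_b = _resolve_designs(*group_b, designs_b)
    if arm_seeds is None:
        ss_a, ss_b = _as_seedseq(seed).spawn(2)
    else:
        ss_a, ss_b = (_as_seedseq(s) for s in arm_seeds)
    sa_c, sa_t = ss_a.spawn(2)
    sb_c, sb_t = ss_b.spawn(2)
    samples_a, fail_a = _ser_samples(
        *group_a, designs_a, n_boot,
        np.random.default_rng(sa_c), np.random.default_rng(sa_t), target_sf,
        noise_model=noise_model, pes=pes[0],
    )
    samples_b, fail_b = _ser_samples(
        *group_b, designs_b, n_boot,
        np.random.default_rng(sb_c), np.random.default_rng(sb_t), target_sf,
        noise_model=noise_model, pes=pes[1],
    )
    n = min(samples_a.size, samples_b.size)
    if n == 0:
        raise FitError("all bootstrap iterations failed")
    delta = samples_a[:n] - samples_b[:n]
    lo, hi = percentile_ci(delta, 0.95)
    point = compute_ser(*group_a, target_sf) - compute_ser(*group_b, target_sf)
    n_failed = fail_a + fail_b
    summary = BootstrapSummary(
        statistic="delta_ser",
        point_estimate=point,
        ci_low=lo,
        ci_high=hi,
        p_value=two_sided_bootstrap_p(delta, 0.0),
        n_boot=n_boot,
        seed=seed,
        n_failed_refits=n_failed,
    )
    if n_failed >= n_boot * _FAILURE_WARN_FRACTION:
        summary.warning = f"{n_failed}/{n_boot} iterations failed; inference degraded"
    summary.samples = delta
    return summary
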