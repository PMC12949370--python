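"""End-to-end analysis: records in, fits / SERs / comparisons out.

``run_full_analysis`` binds the pipeline together: group colony records by
(modality, dose rate, arm); normalize each group to a survival curve; fit
the chosen dose-response model; bootstrap parameter CIs; compute SER with
CI and p for every CTRL/GNP pair; compare SERs (Delta) across dose rates
within each modality; and run the foci t-tests when foci data are given.
Every stochastic step draws from generator streams spawned deterministically
from the single master seed, so a report is reproducible bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as rio
from .bootstrap import bootstrap_ser, compare_ser, design_from_records, parametric_bootstrap
from .clonogenic import ColonyRecord, build_survival_curve
from .foci import compare_foci
from .models import alpha_beta_ratio, fit_model, fit_report

__all__ = ["RunConfig", "run_full_analysis", "group_records", "fit_groups"]


@dataclass
class RunConfig:
    """Configuration of one full analysis run.

    ``shared_controls`` maps a group key "modality|dose_rate|arm" to the
    group key whose unirradiated plates serve as its control (used when two
    conditions irradiated on the same day share one plating control).
    """

    colony_path: str
    foci_path: str | None = None
    model: str = "lq"
    max_dose: float | None = 6.0
    n_boot: int = 1000
    seed: int = 0
    out_dir: str | None = None
    dose_unit: str = "gy"
    ctrl_label: str = "CTRL"
    treat_label: str = "GNP"
    target_sf: float = 0.1
    alpha_level: float = 0.05
    noise_model: str = "gaussian"
    shared_controls: dict = field(default_factory=dict)


def _key(group: tuple) -> str:
    modality, dose_rate, arm = group
    return f"{modality}|{dose_rate:g}|{arm}"


def group_records(records) -> dict[tuple, list[ColonyRecord]]:
    groups: dict[tuple, list[ColonyRecord]] = {}
    for r in records:
        groups.setdefault((r.modality, r.dose_rate, r.arm), []).append(r)
    return groups


def fit_groups(records, model="lq", max_dose=6.0, shared_controls=None):
    """Survival curves and model fits for every group in the records."""
    groups = group_records(records)
    shared = shared_controls or {}
    curves, fits = {}, {}
    for group in sorted(groups):
        ctrl_key = shared.get(_key(group))
        control_records = None
        if ctrl_key is not None:
            donors = [g for g in groups if _key(g) == ctrl_key]
            if not donors:
                raise ValueError(f"shared control group {ctrl_key!r} not found")
            control_records = groups[donors[0]]
        curve = build_survival_curve(groups[group], control_records=control_records)
        curves[group] = curve
        fits[group] = fit_model(
            curve.points(use_replicates=True),
            model=model,
            max_dose=max_dose,
            group=group,
        )
    return curves, fits


def run_full_analysis(config: RunConfig) -> dict:
    """Run the complete clonogenic (and optional foci) analysis.

    Returns a bundle dict with curves, fits, parameter CIs, SER and
    Delta-SER summaries, foci comparisons, and the master seed; writes the
    same content as delimited/key-value text under ``config.out_dir`` when
    set. Point estimates are seed-free; only CI/p inherit randomness.
    """
    records = rio.read_colony_records(config.colony_path, dose_unit=config.dose_unit)
    curves, fits = fit_groups(
        records,
        model=config.model,
        max_dose=config.max_dose,
        shared_controls=config.shared_controls,
    )

    groups = group_records(records)
    designs = {
        g: design_from_records(groups[g], max_dose=config.max_dose) for g in groups
    }
    pes = {g: curves[g].plating_efficiency for g in curves}

    master = np.random.SeedSequence(config.seed)
    param_cis = {}
    for group in sorted(fits):
        (child,) = master.spawn(1)
        dist = parametric_bootstrap(
            fits[group], design=designs[group], n_boot=config.n_boot, seed=child,
            noise_model=config.noise_model, pe=pes[group],
        )
        if config.model == "lq":
            p = fits[group].params
            param_cis[group] = {
                name: dist.summarize(name, point)
                for name, point in (
                    ("alpha", p.alpha),
                    ("beta", p.beta),
                    ("alpha_beta", alpha_beta_ratio(p)),
                )
            }

    # SER per (modality, dose rate) with both arms present
    sers = {}
    pairs = sorted(
        {(m, dr) for (m, dr, a) in fits}
    )
    for modality, dose_rate in pairs:
        ctrl = fits.get((modality, dose_rate, config.ctrl_label))
        treat = fits.get((modality, dose_rate, config.treat_label))
        if ctrl is None or treat is None:
            continue
        g_c = (modality, dose_rate, config.ctrl_label)
        g_t = (modality, dose_rate, config.treat_label)
        (child,) = master.spawn(1)
        sers[(modality, dose_rate)] = bootstrap_ser(
            ctrl, treat,
            designs=(designs[g_c], designs[g_t]),
            n_boot=config.n_boot, seed=child, target_sf=config.target_sf,
            noise_model=config.noise_model, pes=(pes[g_c], pes[g_t]),
        )

    # Delta-SER between dose rates within each modality (high minus low)
    delta_sers = {}
    by_modality: dict[str, list[float]] = {}
    for modality, dose_rate in sers:
        by_modality.setdefault(modality, []).append(dose_rate)
    for modality, rates in sorted(by_modality.items()):
        if len(rates) < 2:
            continue
        hi, lo = max(rates), min(rates)
        (child,) = master.spawn(1)
        gh_c = (modality, hi, config.ctrl_label)
        gh_t = (modality, hi, config.treat_label)
        gl_c = (modality, lo, config.ctrl_label)
        gl_t = (modality, lo, config.treat_label)
        delta_sers[(modality, hi, lo)] = compare_ser(
            (fits[gh_c], fits[gh_t]),
            (fits[gl_c], fits[gl_t]),
            designs_a=(designs[gh_c], designs[gh_t]),
            designs_b=(designs[gl_c], designs[gl_t]),
            n_boot=config.n_boot,
            seed=child,
            target_sf=config.target_sf,
            noise_model=config.noise_model,
            pes=((pes[gh_c], pes[gh_t]), (pes[gl_c], pes[gl_t])),
        )

    foci_results = {}
    if config.foci_path:
        foci_records = rio.read_foci_records(config.foci_path)
        conditions = sorted({(r.modality, r.dose_rate) for r in foci_records})
        for modality, dose_rate in conditions:
            sub = [r for r in foci_records if (r.modality, r.dose_rate) == (modality, dose_rate)]
            foci_results[(modality, dose_rate)] = compare_foci(
                sub, ctrl_label=config.ctrl_label, treat_label=config.treat_label
            )

    bundle = {
        "seed": config.seed,
        "curves": curves,
        "fits": fits,
        "param_cis": param_cis,
        "ser": sers,
        "delta_ser": delta_sers,
        "foci": foci_results,
    }
    if config.out_dir:
        _write_bundle(bundle, config)
    return bundle


def _write_bundle(bundle: dict, config: RunConfig) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for group, curve in bundle["curves"].items():
        rio.write_survival_curve(curve, out / f"curve_{_key(group).replace('|', '_')}.csv")
    with open(out / "fits.txt", "w") as fh:
        for group in sorted(bundle["fits"]):
            fh.write(fit_report(bundle["fits"][group], config.target_sf))
            fh.write("\n")
    rows = []
    for (modality, dose_rate), s in sorted(bundle["ser"].items()):
        rows.append(
            {
                "modality": modality,
                "dose_rate_gy_min": dose_rate,
                "ser": s.point_estimate,
                "ci_low": s.ci_low,
                "ci_high": s.ci_high,
                "p_value": s.p_value,
                "p_display": s.p_display,
                "n_boot": s.n_boot,
                "n_failed_refits": s.n_failed_refits,
            }
        )
    pd.DataFrame(rows).to_csv(out / "ser.csv", index=False)
    rows = []
    for (modality, hi, lo), s in sorted(bundle["delta_ser"].items()):
        rows.append(
            {
                "modality": modality,
                "dose_rate_high": hi,
                "dose_rate_low": lo,
                "delta_ser": s.point_estimate,
                "ci_low": s.ci_low,
                "ci_high": s.ci_high,
                "p_value": s.p_value,
                "p_display": s.p_display,
            }
        )
    pd.DataFrame(rows).to_csv(out / "delta_ser.csv", index=False)
    if bundle["foci"]:
        rows = []
        for (modality, dose_rate), c in sorted(bundle["foci"].items()):
            rows.append(
                {
                    "modality": modality,
                    "dose_rate_gy_min": dose_rate,
                    "mean_ctrl": round(c.mean_ctrl, 1),
                    "mean_treat": round(c.mean_treat, 1),
                    "relative_increase_pct": c.relative_increase_pct,
                    "t": c.t_statistic,
                    "df": c.degrees_of_freedom,
                    "p_value": c.p_value,
                }
            )
        pd.DataFrame(rows).to_csv(out / "foci.csv", index=False)
    with open(out / "summary.txt", "w") as fh:
        fh.write(f"seed: {config.seed}\n")
        fh.write(f"model: {config.model}\n")
        fh.write(f"max_dose_gy: {config.max_dose}\n")
        fh.write(f"n_boot: {config.n_boot}\n")
        fh.write(f"alpha_level: {config.alpha_level}\n")
        for group in sorted(bundle["fits"]):
            fh.write(f"digest {_key(group)}: {bundle['fits'][group].input_digest}\n")
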