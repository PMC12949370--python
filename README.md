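# radioser

Clonogenic survival analysis and bootstrap inference for radiosensitizer
dose-rate studies, with the delivery-physics bookkeeping of HDR ¹⁹²Ir
brachytherapy and pulsed 6 MV LINAC beams.

The package is written for radiobiology and medical-physics groups that
quantify a radiosensitizer (here, gold nanoparticles) from colony-formation
assays run under different irradiation modalities and dose rates. It covers
the full chain: raw per-plate colony counts → plating-efficiency-normalized
survival curves → dose-response model fits → sensitization enhancement
ratio (SER) with parametric-bootstrap confidence intervals and p-values →
cross-dose-rate comparisons, plus DNA double-strand-break foci statistics
and the dose-rate calculators needed to describe the deliveries themselves.

## Model and statistics

Survival after dose *D* (Gy) is modeled by the linear-quadratic (LQ) form

    SF(D) = exp(−αD − βD²),   α [Gy⁻¹], β [Gy⁻²]

with multi-target single-hit, `SF = 1 − (1 − e^{−D/D₀})ⁿ`, and
two-component, `SF = e^{−D/D₁}·[1 − (1 − e^{−D/Dₙ})ⁿ]`, models available
for the wider 0–8 Gy range. Fits minimize the unweighted sum of squared
residuals on the linear SF scale over all replicate plates jointly.

Radiosensitization is summarized by the sensitization enhancement ratio

    SER = D₁₀(control) / D₁₀(sensitized)

where D₁₀ is the dose giving 10% survival on the fitted curve (closed form
for LQ, bracketing root-finder otherwise). Uncertainty comes from a
parametric bootstrap: each iteration re-synthesizes both arms from their
fitted curves, refits, and recomputes SER; the 95% CI is the percentile
interval and the two-sided p-value is twice the smaller tail fraction
relative to SER = 1 (or Δ = 0 for paired dose-rate comparisons). Two noise
models are provided — Gaussian on SF with per-dose replicate SDs (default)
and a colony-level binomial resampler that also re-estimates plating
efficiency per iteration; see `docs/methods.md` for why the latter is the
better-calibrated choice.

## Worked example

Generate a synthetic experiment at the study design (triplicate plates,
seeding densities 100–10 000 for 0–8 Gy, plating efficiency 0.5) with a
control arm (α = 0.45, β = 0.05) and a sensitized arm (α = 0.5686,
β = 0.06), then fit and infer:

```
$ radioser simulate --out demo.csv --seed 3 --gnp-alpha 0.5686 --gnp-beta 0.06
wrote 48 colony records to demo.csv
$ radioser ser --input demo.csv --boot 1000 --seed 11
HDR-BT 1.1 Gy/min: SER 1.149 [95% CI 1.084-1.231] p < 0.002
```

The analytic SER of the generating truths is 1.190; this one simulated
experiment lands at 1.149 (the median over many replications recovers
1.19), the CI excludes 1 (significant radiosensitization), and the p-value
is reported against its bootstrap resolution floor (2/n_boot). The
same library calls are available in Python via `radioser.fit_model`,
`radioser.compute_ser`, `radioser.bootstrap_ser`, and
`radioser.run_full_analysis`.

Delivery-physics verbs mirror the calculators:

```
$ radioser doserate pulse
dose_per_pulse_cgy: 0.07273
instantaneous_rate_gy_s: 181.8
instantaneous_rate_gy_min: 1.091e+04
$ radioser doserate distance --factor 0.5
distance_cm: 128.69 (nearest cm: 129)
```

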