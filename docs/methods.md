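# Methods

## Clonogenic normalization

A colony record is one plate: `n_seeded` cells plated, `n_colonies`
clusters of ≥ 50 cells counted after incubation. Plating efficiency (PE)
pools the unirradiated plates of a group — total colonies over total cells
seeded — which weights plates by their seeding density rather than
averaging per-plate ratios. The survival fraction of an irradiated plate is
`(n_colonies / n_seeded) / PE`. Groups are keyed by
(modality, dose rate, arm); a group may borrow another group's
unirradiated plates as its control (`shared_controls` in `RunConfig`),
which is how two dose rates irradiated on the same day from one cell
passage are handled. The dose-0 entry of a summarized curve is pinned at
SF = 1 exactly; with unequal control seeding the mean of per-plate SFs is
not identically 1, but the normalization convention is. A dose with a
single replicate reports its SF spread as missing (not zero); plates with
zero colonies at positive dose keep SF = 0 and participate in fitting on
the linear scale, so no log transform (and no log(0)) is involved anywhere.

## Dose-response models and fitting

Three standard cell-survival models are implemented:

* linear-quadratic `SF = exp(−αD − βD²)`, α ≥ 0 Gy⁻¹, β ≥ 0 Gy⁻²;
* multi-target single-hit `SF = 1 − (1 − e^{−D/D₀})ⁿ`, D₀ > 0 Gy, n ≥ 1
  (real-valued);
* two-component `SF = e^{−D/D₁}·[1 − (1 − e^{−D/Dₙ})ⁿ]`.

Fits minimize the unweighted residual sum of squares on the linear SF
scale with all replicate plates entered jointly. With balanced replication
this is equivalent to fitting the per-dose means (the joint objective is
the mean objective scaled by the replicate count plus a parameter-free
constant); the `use_replicates=False` mode exists for unbalanced designs.
The optimizer is a bounded trust-region least-squares solver
(`scipy.optimize.least_squares`, method `trf`) — the bounded variant of
the classical damped least-squares family; box bounds are α ∈ [0, 3] Gy⁻¹,
β ∈ [0, 1] Gy⁻² for LQ (generous for photon-beam survival data), start
point (0.3, 0.03), and termination tolerances 1e-15 so that boundary
solutions (e.g. a truly linear survival curve, β = 0) converge onto the
bound rather than stalling at ~1e-6. LQ fits default to doses ≤ 6 Gy,
where the model is conventionally trusted; MTSH/TC default to the full
0–8 Gy range. Noiseless inputs are recovered to better than 1e-6.

The dose at survival level *s* (default 0.1, i.e. D₁₀) uses the positive
root of `βD² + αD + ln s = 0` in the numerically stable form

    D = −2·ln s / (α + √(α² − 4β·ln s)),

because the textbook `(−α + √(α² − 4β·ln s)) / 2β` cancels catastrophically
when a bounded fit returns β of order 1e-17 — in that regime it evaluates
to exactly 0 and silently corrupts every downstream SER. The stable form
reduces continuously to `−ln s / α` as β → 0. For MTSH/TC the level is
solved by bracketing on [0, 50] Gy to 1e-6 Gy. The sensitization
enhancement ratio is `SER = D₁₀(control) / D₁₀(treated)`; the α/β ratio is
reported as unavailable (NaN) when β = 0.

## Parametric bootstrap

Inference follows a parametric bootstrap: each of `n_boot` (default 1000)
iterations synthesizes a dataset at the original design points from the
fitted curve, refits it, and records α, β, α/β and (for arm pairs) SER,
with both arms re-synthesized independently per iteration. Point estimates
are always those of the measured dataset, never bootstrap means. The 95%
interval is the equal-tailed percentile interval (linear interpolation
between order statistics); significance is declared when the reference
(SER = 1, or Δ = 0 for the paired difference of two SERs) falls outside
it. The two-sided p-value is twice the smaller of the strictly-above /
strictly-below tail fractions, capped at 1. Draws exactly equal to the
reference are excluded from both counts; if *every* draw ties the
reference (a zero-noise degenerate bootstrap) the distribution carries no
evidence against it and p = 1 — the literal "twice the smaller count" rule
would give the absurd p = 0 there. A p of exactly 0 is displayed as
`< 2/n_boot` rather than as zero. Refits that fail to converge are dropped
and counted; more than 10% failures attaches a degraded-inference warning.

Two synthesis noise models are provided:

* **gaussian** (default): SF = model prediction + zero-mean Gaussian noise
  with the per-dose replicate SD (pooled residual SD where a dose has a
  single replicate), truncated at 0.
* **binomial** (colony-level): colony counts are redrawn per plate as
  Binomial(n_seeded, PE·SF_model), the plating efficiency is re-estimated
  from the synthetic dose-0 plates, and SFs are re-normalized by it.

The binomial model is the mechanistically faithful bootstrap for this
assay and is noticeably better calibrated. The reason is structural: the
measured SFs all share one estimated PE, so PE error is a common
multiplicative factor across the whole curve. Per-point Gaussian noise
cannot represent that shared factor — and because the LQ model is pinned
at SF(0) = 1, synthetic dose-0 points have parameter-independent residuals
and contribute nothing to the refit spread. Simulation at the default
design shows the Gaussian model's 95% α interval covering the truth in
only ≈ 65% of experiments (≈ 74% even with exact binomial σ), while the
colony-level model achieves ≈ 95% coverage, keeps p > 0.05 in ≈ 96% of
null-truth experiments, and covers SER = 1 in ≈ 96%. The Gaussian model
remains the default for continuity with the minimal reading of a
"parametric bootstrap on SF"; calibration-sensitive work should pass
`noise_model="binomial"` (CLI: `--noise-model binomial`).

All randomness flows from one master seed through spawned
`numpy.random.SeedSequence` streams — one per arm per analysis step, in a
fixed order — so every CI and p-value reproduces bit-identically, and the
paired comparison consumes the same per-arm streams whether run alone or
inside the full pipeline. Swapping the two groups of a comparison while
swapping their seed streams negates the Δ distribution exactly.

## Foci statistics

DNA double-strand-break foci are counted per nucleus. A condition is
summarized by its arithmetic mean foci/cell; the sensitizer effect is the
percent increase of the treated mean over control, tested with a
pooled-variance two-sample t-test on the per-cell counts
(df = n₁ + n₂ − 2). Cells are the sampling unit — the only reading that
yields usable degrees of freedom from microscopy data; testing replicate
means instead is available by pre-aggregating. Two constant equal samples
return (t = 0, p = 1); constant unequal samples are infinitely separated.
Reported means are displayed to one decimal, full precision retained
internally.

## Delivery physics

The calculators are exact unit arithmetic, with one deliberate
approximation:

* Particle-history budgeting for a stepping ¹⁹²Ir source: S_k in mGy·m²/h
  converts to cGy·cm²/h (×1000), divides by the air kerma rate constant
  Γ = 4.037 cGy·cm²/h/mCi (manufacturer value for this source) to give
  apparent activity, then ×3.7×10¹⁰ decays/s/Ci × dwell time. 37.95
  mGy·m²/h for 1 s gives 3.478×10¹¹ histories.
* Dwell dose rate (Gy/s) is dose-to-voxel over dwell time; average
  delivered rate (Gy/min) is plan dose over delivery time.
* LINAC pulse structure: dose/pulse = calibration (cGy/MU) × MU/pulse;
  the intra-pulse instantaneous rate is dose/pulse over the 4 µs pulse
  width. The defaults (0.08 MU/pulse with a 200 cGy/220 MU calibration)
  give 0.0727 cGy/pulse and ≈ 180 Gy/s = 1.09×10⁴ Gy/min. Vendor
  documentation also circulates a 0.03 MU/pulse figure; both are
  configurable, and only the 0.08 chain is internally consistent with the
  0.072 cGy/pulse and 180 Gy/s values it is meant to reproduce. (Note
  that 180 Gy/s is 1.08×10⁴ Gy/min, not 1.1×10³ — the code converts units
  exactly.)
* Dose-rate matching by distance assumes pure inverse-square scaling at
  fixed depth and field size: d = d_ref/√factor, so halving the rate from
  91 cm gives 128.7 ≈ 129 cm. Tissue-maximum-ratio variation with SSD is
  neglected — at fixed depth it is a second-order correction.
* The dwell-timeline simulator scores a planar 50 × 50 grid over 3.5 cm
  (voxel centers, source channel 1.5 cm above the plane by default) with a
  point-source kernel: rate = S_k[U]·Λ/r², Λ = 1.109 cGy·h⁻¹·U⁻¹ (the
  standard dose-rate constant for this source type), unit anisotropy and
  radial dose functions. This is a geometric approximation that preserves
  the structure of interest — per-voxel maxima vs time-weighted averages,
  hot/cold source ratios, conservation of total dose as the time-integral
  of the timeline — but it is not a transport calculation and its absolute
  values should not be compared against Monte Carlo dosimetry.

## Synthetic data

The clonogenic generator reproduces the statistical structure of the
targeted study design: triplicate plates at doses 0, 1, …, 6, 8 Gy seeded
at 100, 300, 500, 1000, 4000, 5000, 8000, 10 000 cells respectively, true
plating efficiency 0.5, survival governed by a per-arm truth model. Each
plate's colony count is Binomial(n_seeded, PE·SF_truth(dose)) — every
seeded cell forms a colony independently — the natural mechanistic noise
model for this assay. Plate-to-plate heterogeneity is available as a
beta-binomial option (per-plate success probability drawn from a Beta with
mean PE·SF and concentration 1/overdispersion, recovering the binomial
continuously as overdispersion → 0); the default is 0 since replicate-level
dispersion estimates are not available for the real data. Foci counts are
Poisson by default with a negative-binomial alternative (variance
mean + mean²/k) because real foci counts are frequently overdispersed.

What the generator deliberately does not emulate: day effects shared
across an experiment, counting error in colony scoring, mechanistic GNP
dose enhancement (truths are specified directly as survival parameters),
and spatial dose non-uniformity across a plate. Passing recovery tests
therefore demonstrates that the estimation chain is unbiased and
well-calibrated under the assumed noise structure, not that the assay
itself is free of systematic effects.

## Problem sizes in tests and the acceptance script

Truth-recovery summaries use 200 independently seeded experiments per
configuration — enough to pin medians of the SER distribution (per-dataset
SD ≈ 0.08) to well inside the ±0.03 bands being checked. Calibration
properties use 80–100 outer replications with 150–200 bootstrap iterations
each and assert within three binomial standard errors of the nominal
rates; these sizes keep the whole suite in a few minutes on one CPU while
leaving the checks statistically meaningful. The acceptance script runs
the four recovery configurations at 200 datasets each in ~10 s.

## Known limitations

* The LQ model is only fitted to ≤ 6 Gy by default; extrapolating its D₁₀
  outside the fitted range is not guarded against beyond the 50 Gy root
  bracket.
* Percentile intervals (not BCa) are used; for strongly skewed bootstrap
  distributions near a parameter bound the interval need not contain the
  point estimate, and this is reported rather than corrected.
* The Gaussian bootstrap's undercoverage (above) is inherent to modeling
  normalized quantities with independent per-point noise; use the
  colony-level model when calibration matters.
* No multiple-testing correction is applied across group comparisons, and
  no dose-protraction (dose-rate) correction enters the survival models —
  dose rate is an experimental label, not a model covariate.
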