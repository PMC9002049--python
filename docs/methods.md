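# Methods

## Model and assumptions

The kinetic core is a 1-tissue compartment model for a freely filtered,
non-protein-bound, non-reabsorbed tracer: plasma-to-cortex influx at rate
`K1` (glomerular filtration per unit extravascular cortical volume) and
first-order urinary washout at rate `k2`. Its assumptions — linear transfer,
a single well-mixed cortical compartment, no tubular handling — are adequate
for kidneys with undisturbed urinary efflux; with obstruction the TAC
plateaus and a linear `k2` describes efflux poorly, which is why agreement
statistics are reported both for the full cohort and the unobstructed
subgroup. Protein binding of the tracer (a few percent) is ignored in the
plasma conversion `C_P = C_aorta/(1 − HCT)`, matching the printed correction
chain.

All curves are decay-corrected concentrations (kBq/ml at injection time) and
carry the frame-average value, plotted and fitted at the frame mid-time.
Internally, time is in seconds; rate constants cross the API boundary in
1/min.

## Forward solution and fitting

`C_EC = K1 · C_P ⊗ e^(−k2 t)` is evaluated exactly for a piecewise-linear
plasma input (linear between frame mid-times, with a (0, 0) node prepended:
tracer-free blood before bolus arrival). Per-interval integrals use
`φ1(x) = (1 − e^(−x))/x` and `ψ(x) = (1 − φ1)/x` with series expansions below
x = 1e−6/1e−4, so the recursion is exact and stable down to k2 = 0 (where it
degenerates to the running trapezoid integral). The solver is verified
against an independent stiff ODE integration (`scipy.solve_ivp`, LSODA,
rtol 1e−10) to < 0.1 % of the curve peak across K1 ∈ [0.01, 0.5]/min,
k2 ∈ [0, 0.3]/min.

Fitting minimizes the weighted residual sum of squares
`χ² = Σ wᵢ (yᵢ − C_model(tᵢ))²` over bounded (K1, k2, vB) ∈
[0, 2] × [0, 1] × [0, 1] with `scipy.optimize.least_squares` from 8
deterministic starts (log-spaced K1 × k2 grid, vB start 0.1); ties break to
lowest χ², then lowest K1. Multi-start matters because urine spill-over makes
the objective multi-modal. Weights default to uniform; frame-duration weights
are available (`wᵢ = Δtᵢ`). The reference software's weighting and convergence
settings are unknown, so published per-patient χ²/AIC values are not
reproduction targets.

Goodness of fit: `χ²` as above and `AIC = n ln(χ²/n) + 2k` with k = 3, which
can be negative; a perfect fit reports AIC = −∞. The AIC form is a standard
least-squares variant chosen because published values are negative for some
patients; other variants would shift all comparisons by a constant and do not
change model ranking. At least `k + 1 = 4` residuals are required (the
documented worked example uses exactly 4); fits separately require ≥ 6 frames.

Window variants: `t_max` = 1800 s (PET-30) or 900 s (PET-15), optionally
excluding frames with mid-time in the closed interval [120, 600] s ("without
minutes 2 to 10" — read as inclusive). On the 72-frame schedule this removes
the 18×10 s and 10×30 s frames (28 frames), leaving 44; the 15-min variants
retain 57 and 29 frames. The forward model is always evaluated on the full
schedule so the convolution sees the complete plasma history; only the
residuals are masked.

## Input function

The oversized-VOI background correction is a per-frame scalar identity and
is implemented exactly as printed; VOI geometry (1.5× diameter, 15 slices)
is provenance, not computation. Negative corrected frames (possible under
noise) are kept, not clipped — clipping would bias early-frame residuals —
and a warning is logged.

## CKD-EPI reference

2009 creatinine equation without race coefficient, in the tabulated
sex-specific form: constant 141 (male, κ = 0.9, α = −0.411) / 144 (female,
κ = 0.7, α = −0.329), exponent −1.209 above κ, age factor 0.993^age; then
de-normalized by × BSA/1.73. The tabulated female constant 144 (rather than
141 × 1.018 = 143.538) is what reproduces the packaged clinical values to
one decimal; with it, all 12 cohort rows agree within ±0.09 ml/min (one row
prints 80.6 where the inputs compute to 80.67, presumably a rounding
artefact of unrounded source BSA). BSA is taken from the cohort table, not
recomputed. Reported GFRs round half away from zero to one decimal.

## Synthetic data: what it emulates, what it does not

The generator states a world in which every downstream claim is checkable:

- **Input function** — the tracer's plasma kinetics are never modelled in
  the clinical analysis (the AIF is measured), so the generator uses a
  plausible parametric stand-in: linear rise over 6–12 s starting 10–20 s
  after injection, peak ≈ 40–80 kBq/ml scaled with injected activity
  (79–137 MBq, cohort mean ≈ 112), then biexponential washout (70 % at
  0.35/min vascular mixing, 30 % at 0.012/min renal clearance). Frame values
  are analytic frame averages (verified against 0.1-s quadrature to <0.1 %).
- **Kidneys** — K1 ∈ [0.15, 0.45]/min, k2 ∈ [0.02, 0.15]/min,
  vB ∈ [0.10, 0.30], V_RC ∈ [100, 180] ml, giving total GFR ≈ 40–120
  ml/min. Obstruction = k2 ≈ 0 (plateau TAC); by default 1 patient in 4
  (3 of 12: two both-sided, one right-sided, echoing the clinical pattern).
- **Urine spill-over** — the pelvis VOI holds the accumulated cortical
  outflow `∫ k2·A_EC dt`, delayed by 30–120 s and normalized to the
  10-mm-sphere volume (0.524 ml); a fraction 5e−4–2e−3 of it contaminates
  the cortical TAC (peaking at ~10–40 % of the cortical peak). This is a
  deliberate simplification: real pelvis activity also drains to the
  bladder, so the synthetic contaminant is monotone non-decreasing rather
  than transient. It reproduces the delayed onset and the fit-quality
  benefit of excluding minutes 2–10, not urodynamics.
- **Noise** — additive zero-mean Gaussian with
  SD = σ₀·√(max(value, 1 kBq/ml)/Δt): variance grows with activity and
  shrinks with frame duration, a standard surrogate for reconstructed-PET
  count statistics. σ₀ = 1 (the default "moderate" level) gives ≈ 6 %
  relative noise at the bolus peak in 5-s frames. Poisson voxel noise,
  reconstruction correlations and respiratory motion are not modelled.
- **Demographics** — sampled in cohort-like ranges (10/12 male, ages 46–79,
  BSA ~ N(1.95, 0.2²), HCT 0.26–0.41). Serum creatinine is *derived* by
  inverting the CKD-EPI equation from the truth total GFR perturbed by a
  lognormal factor (SD 0.12), so reference-vs-PET agreement on synthetic
  cohorts is meaningful but imperfect by construction.

A green synthetic test therefore establishes internal correctness
(estimator recovers the stated world) — not clinical accuracy, image
segmentation quality, or the validity of the compartment model in patients.

The noise-free cortical curve is produced by the same piecewise-linear
convolution the fitter uses: the model *defines* the noise-free curve, so
noise-free recovery is a consistency check of the estimator, while solver
correctness is established separately against the independent ODE and
quadrature oracles.

## Agreement statistics

Pearson r (scipy) with Fisher-z 95 % CI; Bland–Altman bias (second method
minus first), t-based bias CI and 1.96·SD limits of agreement; ICC from the
two-way ANOVA mean squares, single measures: consistency ICC(3,1) =
(MSR − MSE)/(MSR + MSE) by default (the two-way mixed model), agreement
ICC(2,1) by flag, each with F-distribution 95 % bounds (Shrout–Fleiss /
McGraw–Wong) and Koo categories (<0.50 poor, <0.75 moderate, <0.90 good,
else excellent). The implementation is hand-computed mean squares and is
cross-checked against `pingouin.intraclass_corr` in the tests.

One caution documented here because it is often mis-stated: for two raters,
ICC(3,1) = 2·cov/(var_x + var_y) equals Pearson's r **only when the two
sample variances are equal** (in general ICC ≤ r by AM–GM). The test suite
asserts the identity to 1e−9 on variance-matched pairs and the inequality on
generic data.

## Numerical choices and degenerate inputs

- Exclusion interval endpoints closed: mid-time ∈ [120, 600] s removed.
- k2 → 0 handled analytically (no catastrophic cancellation).
- Zero TAC with positive input: K1 driven to its lower bound, χ² ≈ 0.
- Perfect fits report AIC = −∞ rather than failing on log(0).
- Degenerate agreement inputs (zero variance, <3 pairs, <4 for Pearson CI)
  raise validation errors rather than returning NaN.
- All randomness flows through `numpy.random.default_rng(seed)`; identical
  config + seed yields byte-identical output files (the provenance hash
  excludes the output directory for this reason).

## Known limitations

- The spill-over contaminant does not drain; late-frame contamination is
  overstated relative to a real pelvis.
- The input-function family is smooth by construction; dispersion, delay
  between aorta and kidney, and partial-volume residuals beyond the scalar
  background correction are not simulated.
- The expanded dual spill-over-corrected model (which performed worse in
  clinical evaluation) and voxel-level segmentation are intentionally out of
  scope; the pipeline starts at per-frame VOI aggregates.
- Published per-patient kinetic parameters are not reproducible without the
  original image data; clinical-table checks are limited to the CKD-EPI
  column, the recomputable correlations, and the cohort summary.
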