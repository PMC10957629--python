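# Methods

This note documents the statistical models, numerical choices and known
limitations of `prandial`. It describes what the code does and why; every
empirical statement here is one the test suite or `scripts/acceptance.py`
computes.

## The Wood curve and its fitting

A postprandial amino-acid time course rises from a fasting baseline to a
single peak and decays back. We model it as `y(t) = d + a·t^{b}·e^{−ct}`
with `b = m·c`, so that `m` is exactly the time of the peak maximum and
`d` the baseline. `b` is always derived, never a free parameter: the
optimizer works in a four-dimensional space in which `m` is directly the
Time2Max summary.

**Parameterization.** Internally the optimizer uses the equivalent
coordinates `(h, m, c, d)` with `h = a·(b/c)^b·e^{−b}` the peak height.
Over a liberal `(m, c)` box the raw amplitude `a` spans hundreds of orders
of magnitude (it can even underflow double precision), whereas `h` stays
on the scale of the data; the conversion back to `a` is exact in log
space. Fitted `a` values are clamped to the smallest positive double on
underflow — such fits describe absurd shapes and are removed by curation.

**Multi-start strategy.** The residual surface is multimodal, so the fit
runs many random starts: `m` uniform on [5 min, 1.5·t_max], `c`
log-uniform on [1e−4, 1] /min, `d` uniform on [0, max(y)], `h` log-uniform
on 0.01–10× the observed data range. For fixed `(m, c)` the model is
linear in `(h, d)`, so every start is first scored by a closed-form 2×2
least-squares solve, vectorized over all starts; the best `n_refine`
candidates (default 10 of 500) are then polished by a bounded
Levenberg–Marquardt iteration on all four parameters (Marquardt diagonal
scaling, steps projected onto the box, convergence when an accepted step
improves the residual sum of squares by less than `ftol = 1e−10`
relative). The refiner is vectorized over a batch of problems, and each
problem's trajectory is independent of the batch, so fitting a whole study
at once is bit-identical to refitting any single series.

**Seeding.** One study-level seed; each series derives its own seed as
CRC-32 of `"{seed}|{participant}|{intervention}|{analyte}"`, so a
single-series refit reproduces the pipeline's result exactly (asserted in
the tests).

**Bounds philosophy.** The box above is deliberately liberal: narrow
optimizer bounds cause convergence failures, so implausibility is policed
afterwards by curation, not by the optimizer. A solution sitting on a
bound still counts as converged. At least five non-missing points are
required (four parameters), eight or more recommended; missing values are
deleted pairwise per series, never interpolated.

On noiseless synthetic curves spanning the plausible box (10 time points
over 180 min), 50 starts recover all four parameters to better than 1e−3
relative in 100/100 random cases; with noise at 5% of the peak height the
median Time2Max error is ~2% and AUC/Height biases are ~0.1%
(`scripts/acceptance.py`).

## Parameters of interest

- `Time2Max = m` (minutes).
- `Height = a·(b/c)^b·e^{−b}` = curve maximum minus baseline, computed in
  log space; its `b → 0` limit is not used anywhere — the identity
  `Height = y(m) − d` is what the tests assert.
- `AUC(t_f) = ∫₀^{t_f} a·t^b e^{−ct} dt = a·γ(b+1, c·t_f)/c^{b+1}`, the
  lower incomplete gamma function with shape `b+1` and limit `c·t_f`
  (scipy's regularized `gammainc` times `Γ(b+1)`, assembled with
  `gammaln` to avoid overflow). The form is forced by direct integration
  of the curve and verified against adaptive quadrature to better than
  1e−6 relative. The baseline contribution `d·t_f` is deliberately
  excluded: all PoIs are relative to baseline.
- `t_f` defaults to the last observed sampling time of each series, so
  the AUC never extrapolates beyond the data; a global override exists
  (e.g. 240 min) for protocols that define the endpoint a priori.

Trapezoid-rule AUC is intentionally absent from the API — the parametric
form exists precisely to smooth over outliers and missing points — and
appears only as the quadrature oracle inside tests.

## Curation

Values outside plausible ranges become missing, with a report row for
every removal (quantity, value, violated bound). Defaults: `AUC > 0`,
`Height ∈ (0, 1000)`, `Time2Max ∈ (15, 200)` min; ranges are open
intervals, so a value exactly on a bound is removed. Curve-parameter
limits default to bare positivity: the optimizer box is already liberal,
and experience says parameter-level cutoffs are study-specific. A
PoI violation removes only that PoI; a parameter violation discredits the
whole fit and removes all three PoIs of the series. Aggregated totals
(e.g. a summed essential-amino-acid trace) have far larger heights and
AUCs than single amino acids; no automatic rescaling of ranges is applied
— set them per study. Curation is idempotent and never alters in-range
values, both asserted as properties.

## Imputation of non-responders

A missing PoI may mean "no measurable uptake", which is information, not
noise. For AUC and Height (never Time2Max — a series without a peak has
no maximum), the package fits, per analyte, an ordinary least-squares line
of the observed PoI on the 0.2–0.8 quantile spread of the raw series
values (quantiles by linear interpolation between order statistics,
numpy's default, fixed package-wide), trains it on responders, and
predicts missing series, flooring predictions at 0. Only series whose
spread is below a configurable fraction (default 0.5) of the median
responder spread are treated as non-response; missingness with a
normal-sized spread is a data-quality problem and stays missing. At least
3 responders per analyte are required, otherwise the analyte is skipped
with a warning. Regressions are per analyte, not pooled. The pipeline
reports responders-only and imputed analyses explicitly (`analysis` field
of the run log); comparing the two is the recommended practice.

## Intervention comparison

Per analyte × PoI the model is `PoI ~ Intervention + Period +
(1 | Participant)`, REML-fitted with statsmodels' MixedLM. Period is a
categorical fixed effect, on by default (crossover periods are far apart,
carryover is not modelled, but a period check is cheap). Contrasts of each
test intervention against the reference come from treatment coding with
the reference as base level.

**Ratio vs difference.** AUC is compared as a ratio (uptake relative to
the reference), Height and Time2Max as differences. Ratios are obtained
by log-transforming the response *before* fitting and exponentiating the
estimate and CI afterwards — not by delta-method ratios of means — so the
back-transformed interval is exact and the ratio equals
`exp(log-scale difference)` to floating point (asserted replicate-wise).
Non-positive values cannot enter the log and are dropped with a warning;
curation should already have removed them.

**Degrees of freedom.** Small-sample inference uses the Satterthwaite
approximation, computed from the REML information matrix of the two
variance components (`σ²_participant`, `σ²_residual`): for a contrast
`ℓ'β`, `df = 2(ℓ'Cℓ)² / (g'A g)` with `C = (X'V⁻¹X)⁻¹`, `g` the gradient
of `ℓ'Cℓ` in the variance components and `A` the inverse of the REML
information `I_jk = tr(P V_j P V_k)/2`. For the random-intercept structure
used here Satterthwaite and Kenward–Roger coincide on balanced complete
designs with the classical residual df (20 for the default 12 × 3
crossover), which the tests assert. If the information matrix degenerates
(e.g. zero residual variance on noiseless data) the classical
fixed-participant residual df is substituted. When MixedLM itself fails on
degenerate data, a fixed-participant least-squares fallback supplies the
coefficients with `σ²_participant = 0`.

**Multiplicity.** p-values are Holm-adjusted within each PoI family
(across analytes and contrasts); Bonferroni and no adjustment are
configurable. Holm dominates Bonferroni without independence assumptions.
The family boundary (per PoI) is a package default, not a universal
convention.

Calibration on the full pipeline (simulate → fit → curate → compare, 200
replicates of the null 12-participant design, raw p-values/unadjusted
CIs): rejection rate 5.1% at α = 0.05, CI coverage 94.9%; under a true
AUC ratio of 0.7 the mean estimated ratio over 100 replicates is 0.696.

## The synthetic-study generator

The generator emulates the standard protein-uptake crossover: 12
participants, three interventions (one reference; the two test proteins
default to 15%/30% lower amplitude and 8/15 min slower peaks), three
periods in a balanced rotation (Period ⟂ Intervention), ten samples in
[0, 180] min, and the nine essential amino acids with fasting baselines
and postprandial excursions in the ranges reported for adults after a
protein meal (e.g. Leu: baseline 130 µmol/L, peak +180 at ~40 min).
Participant heterogeneity enters exactly where the analysis model expects
it: an additive Gaussian baseline shift on `d` (sd 10 µmol/L) and a
multiplicative log-normal shift on `a` (sd 0.15 on the log scale), both
shared across a participant's interventions — i.e. a random intercept.
Measurement noise is additive Gaussian, sd 5 µmol/L, constant per analyte.
Non-responder series (off by default) draw their amplitude near zero per
participant × analyte. Ground truth (true parameters and true PoIs,
computed with the same closed forms the analysis uses) accompanies every
simulated study.

What the generator does **not** emulate: heteroscedastic or correlated
measurement error, within-series outliers and compromised samples,
carryover between periods, circadian drift, or physiological absorption
kinetics — it is a statistical twin of the analysis model, not a
digestion simulator. Passing calibration tests therefore shows the
pipeline is correct and well-calibrated *when its model assumptions hold*,
not that real trials are free of model misfit; the curation and
visualization stages exist precisely for the features the generator
omits.

Effect scenarios scale the test intervention's amplitude: AUC and Height
are both linear in `a`, so a target AUC ratio is exact by construction,
and an independently requested height difference can only be honored when
consistent; on conflict the AUC constraint wins and the realized height
difference is recorded in the ground truth.

## Problem sizes and defaults used in checks

The shipped checks use 500 starts only where the fit count is small;
simulation studies use 25–50 starts with 2–3 refined candidates per
series, which on clean synthetic data changes recovered parameters by
less than 1e−3 relative (asserted). The calibration experiments use 200
null replicates and 100 effect replicates of the full 324-series design;
the oracle comparisons use 100 random parameter sets and the noisy
recovery 200 series. All seeds are fixed and documented in the tests and
accepted at the command line by `scripts/acceptance.py`.

## Known limitations

- Single Wood component: bimodal responses (e.g. mixed fast/slow protein
  blends) fit poorly by design; curation flags them rather than modelling
  them.
- No uncertainty propagation from the curve fit into the mixed model: PoIs
  enter as plain data, as is standard in this analysis tradition.
- Imputed values likewise carry no extra variance (no multiple
  imputation).
- Heterogeneous-variance mixed models (different variability per protein)
  are out of scope; the random-intercept model is the only one fitted.
- The PCA view supports per-row centering or none; no scaling variants.
- Technical replicates (duplicate measurements at one time point) are
  rejected at I/O rather than averaged — deduplicate upstream if your lab
  exports them.
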