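# Methods

## The photosynthesis model

Net CO2 assimilation of a C4 leaf is modelled with the reduced
enzyme-limited form

    A(ci) = min( Vpmax · ci / (ci + Kp),  Vmax ) − Rd

with mesophyll CO2 taken equal to the intercellular mole fraction ci
(no mesophyll conductance term) and a hard minimum between the two
branches. The PEPC-limited branch is a rectangular hyperbola whose
initial slope is Vpmax/Kp; the saturated branch is flat at Vmax − Rd,
treating Vmax strictly as the asymptote of the A/ci curve (no curvature
parameter softening the transition). The branches meet at the
inflection ci\* = Vmax·Kp/(Vpmax − Vmax), which is finite only when
Vpmax > Vmax. This minimal form carries exactly the two quantities the
fit is asked to report — the initial-slope capacity Vpmax and the
asymptote Vmax — and deliberately omits bundle-sheath leakiness,
light-limited branches, and temperature response. Measurements are
taken at a single controlled cuvette state (27 °C, 65% RH,
1800 µmol m⁻² s⁻¹ PPFD), so temperature and light dependence never
enter the estimation problem.

Parameters, units, defaults:

| parameter | meaning | unit | default |
|---|---|---|---|
| Vpmax | apparent maximum PEPC carboxylation | µmol m⁻² s⁻¹ | fitted (bound (0, 500]) |
| Vmax  | asymptote of the A/ci curve | µmol m⁻² s⁻¹ | fitted (bound (0, 200]) |
| Kp    | PEPC Michaelis constant for CO2 | µmol mol⁻¹ | 80, fixed |
| Rd    | day respiration | µmol m⁻² s⁻¹ | 2, fitted by default (bound [0, 10]) |

Kp = 80 µmol mol⁻¹ and Rd = 2 µmol m⁻² s⁻¹ are typical C4-literature
values at the measurement temperature; both are configuration, not
estimates. µmol mol⁻¹ and µbar are treated as interchangeable at
ambient pressure. Conductance to CO2 is gs/1.6 (diffusivity ratio);
iWUE is always reported against the water-vapour gs.

## Operating point and stomatal limitation

The operating point couples biochemical demand with diffusive supply:
A(ci) = gs_co2·(ca − ci). Demand is non-decreasing and supply strictly
decreasing in ci, so the root is unique; the solver first checks the
saturated-branch closed form ci = ca − (Vmax − Rd)/gs_co2 (valid when
that ci is at or above the inflection) and otherwise brackets the root
with Brent's method to |supply − demand| ≤ 1e−8. An equilibrium with
A ≤ 0 (leaf at or below compensation) is returned flagged rather than
raised, since sub-compensation steps occur at the 50-ppm protocol step.

Stomatal limitation compares assimilation at the operating point with a
hypothetical leaf whose ci equals ambient ca:

    SL = (A(ca) − A(ci_op)) / A(ca)

Both terms use the **fitted** curve, so measurement noise at the
ambient step cannot produce negative SL; SL < 0 can then arise only if
ci_op > ca (a physically inverted gradient), which is clipped to zero
with a warning. SL is undefined (raised) when A(ca) ≤ 0. When the
analysis pipeline computes per-plant SL it takes the operating point
from the observed ambient-CO2 steps (mean ci and A of the ~400-ppm
visits) and the curve from that plant's fit.

## A/ci estimation

Each curve is fit by bounded trust-region least squares on
Σ(a_obs − A(ci))². The hard minimum makes the objective only piecewise
smooth, so the optimizer is restarted from (i) a data-driven initial
guess (Vmax₀ = max A + Rd; Vpmax₀ from the secant through the two
lowest-ci points inverted through the hyperbola at fixed Kp, falling
back to 2·Vmax₀ for flat data), (ii) a breakpoint scan that assigns the
k lowest-ci points to the PEPC branch and estimates each branch in
closed form for every k — with clean data one split is the true branch
assignment, so the polish starts in the global basin — and (iii)
seeded lognormal perturbations of the guess (5 starts by default). The
best rss wins; convergence tolerance is 1e−10 on relative rss change.
Both 400-ppm protocol visits are retained as data (the repeat is a
stability check, flagged when A drifts by more than 10%, not
deduplicated).

Vmax is flagged non-identifiable when the data never constrain the
asymptote. The flag requires two conditions: the fitted inflection lies
within the observed ci range, and a pure PEPC hyperbola (no asymptote)
fits detectably worse than the full model (rss difference above
1e−6 × total SS). The second condition matters because a curve entirely
on the sub-inflection branch has a continuum of exact fits, so any rule
reading only the fitted parameters would depend on which degenerate
solution the optimizer happened to return. With Rd free, a curve with a
single sub-inflection step is likewise degenerate (the offset trades
off exactly against the initial slope); Rd exists in the model mostly
to absorb such offsets, and fixing it restores identifiability when a
protocol yields too few low-CO2 steps.

Replicate fits for a genotype are summarized as the pointwise mean and
standard error of the fitted curves on a ci grid (the mean-fit ± SE
band); a single fit reports SE = 0 with a warning.

## Water budget

rSWC uses a dry-basis reference: the denominator is the plant-available
water between the saturated pot mass and (tare + dry soil + plant
mass), with plant mass a single destructive-harvest estimate treated as
constant over the 9-day window (no growth interpolation). Values
outside [0, 100] are clamped with a warning. Daily water use is the
day-over-day mass decrement, attributed entirely to the plant (no
bare-pot evaporation controls are modelled); negative decrements
(unlogged watering) clamp to zero with a warning, and when no clamp
fires the series satisfies exact mass balance,
Σ use = mass(0) − mass(end). Whole-plant leaf area is Σ width × length
over every leaf with no shape-correction factor.

## Statistics

The replicate plant (or pot) is the experimental unit: within-plant
subsamples (e.g. four fields of view) are averaged first and that mean
is the input to every test. One-way ANOVA is the classical
decomposition. Two-way factorial ANOVA uses sum-to-zero coding with
partial (Type-III) sums of squares — identical to the sequential
decomposition on balanced data, and a declared default for mildly
unbalanced tables; interaction terms require a full cell grid. The
repeated-measures analysis for dry-down trajectories is the univariate
split-plot-in-time: genotype is tested against the subject-within-
genotype mean square, day and genotype × day against the within-subject
residual; the design must be complete (every subject at every day) and
no sphericity correction is applied. Tukey HSD uses the Tukey–Kramer
statistic q = |mi − mj|/√(MSW/2·(1/ni + 1/nj)) with adjusted p from the
studentized-range distribution (numerically integrated CDF); for two
groups this reduces exactly to the pooled t-test via q = √2·|t|, which
the suite asserts to 1e−6. Letter displays are built by a greedy scan
over means in descending order: each maximal run of mutually
non-significant groups receives one letter, runs contained in an
earlier run are skipped, so two groups share a letter iff their pair is
non-significant. Least-squares means are unweighted means of design-
cell means with SE propagated from the pooled residual mean square;
planned contrasts act on those means with zero-sum weights and a t test
on the residual df. Per-day dry-down comparisons run an independent
one-way ANOVA + Tukey per day with no across-day multiplicity
correction.

## Synthetic experiment generator

The generator exists so the pipeline can be exercised end to end with
known truth. It emulates:

* **Gas exchange** — per plant, one gs drawn as the wild-type baseline
  × genotype scale × lognormal noise (CV 5%), held constant across the
  11 CO2 steps; each recorded (ci, A) is the exact supply–demand
  operating point at that step's cuvette CO2, with multiplicative
  lognormal noise (CV 2%) on the recorded A only. The wild-type
  baseline gs is set so the operating ci/ca is 0.4 at ambient
  400 µmol mol⁻¹ — on the saturated branch, as observed for
  well-watered C4 leaves.
* **Genotype panel** — wild type plus a strong line (gs ×0.68,
  Vpmax ×0.68, Vmax ×0.80, stomatal density ×0.31) and a moderate line
  (gs ×0.82, Vpmax ×0.79, density ×0.55), mirroring the reported effect
  ranges for engineered low-stomatal-density sorghum; these are
  configuration, not truth.
* **Dry-down** — a single-bucket model: daily decrement =
  potential use × gs scale × leaf-area scale × rt(FTSW) × lognormal
  noise, where rt = min(1, FTSW/threshold) at start of day and FTSW is
  the remaining fraction of transpirable water. Defaults
  (3000 g available water, 600 g day⁻¹ wild-type potential use,
  threshold 0.4, 9 days) put the deterministic wild-type pot near
  exhaustion by day 6 while a 0.68-gs line is still declining on day 9.
  Masses are reconstructed from decrements, so the bookkeeping
  identities hold exactly.
* **Stomatal patterning** — Poisson counts with mean density × 0.64 mm²
  per field (4 fields × 3 leaf positions × 2 surfaces), abaxial
  densities above adaxial; complex width/length from zero-truncated
  Gaussians (≈30 × 45 µm, CV 10%) with a mild size increase in the
  low-density lines.

All randomness flows from explicit seeds through numpy Generators, so
identical seeds give byte-identical CSVs.

What the generator does **not** emulate: gs–ca feedback within a curve,
leaf-to-leaf or diurnal drift, instrument matching errors, soil
evaporation separate from transpiration, soil water retention curves,
VPD dynamics, or any pleiotropy beyond the configured scale factors
(no leaf N, SLA, or reproductive effects). Passing tests therefore
demonstrate that the estimators and bookkeeping are correct under the
assumed error structure, not that the model is adequate for any given
real instrument log.

## Problem sizes and numerical choices

The test suite and acceptance checks run the generator at the study's
scale — 10 replicate plants per genotype, 11-step curves, 9-day
dry-downs — with 50–100 random parameter draws for solver/recovery
properties and a 20,000-draw permutation null for the one-way ANOVA
oracle. Operating-point roots are solved to xtol 1e−12; fits use
ftol 1e−10; the brute-force solver cross-check uses a 0.001 µmol mol⁻¹
ci grid. Degenerate inputs (empty curves, missing day 0, empty design
cells, sub-compensation leaves, single fits) raise or warn as
documented rather than returning silent values.

## Known limitations

* The hard-minimum A/ci form has no transition curvature; real curves
  with gradual transitions will load the mismatch onto Vpmax near the
  inflection.
* SL is computed against the fitted curve; with poorly fitting curves
  the SL estimate inherits the fit bias.
* The split-plot repeated-measures ANOVA assumes sphericity and a
  complete design; incomplete trajectories must be handled upstream.
* Type-III tests with sum-to-zero coding are a convention, not a
  uniquely correct choice, for unbalanced data.
* The bucket dry-down model has one pool and no evaporation term; it is
  a test harness for the bookkeeping and statistics, not a soil model.
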