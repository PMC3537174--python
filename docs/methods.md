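# Methods

## Carbonate system

Water pCO₂ is derived from DIC and pH through the carbonic-acid
speciation chain. The package treats potentiometric pH as the activity of
H⁺ directly (an electrode measures activity, so no further correction is
applied) and converts DIC from mg C L⁻¹ to mol L⁻¹ with a carbon molar
mass of 12.011 g mol⁻¹.

Ionic strength comes from field conductivity by the dilute-water
approximation IS = 1.6·10⁻⁵ × conductivity (μS cm⁻¹), valid for fresh
waters well below seawater strength; the package refuses ionic strengths
above 0.1 mol L⁻¹, where the Davies activity model degrades.

The thermodynamic dissociation constants K₁ and K₂ use the Plummer–
Busenberg freshwater temperature functions (valid 0–50 °C; pK₁ ≈ 6.35 and
pK₂ ≈ 10.33 at 25 °C). They are converted to apparent constants at the
sample ionic strength with the Davies equation (A = 0.509, 0.3·I linear
term): K₁' = K₁/γ₁ and K₂' = K₂·γ₁/γ₂, with the neutral CO₂* species
assigned unit activity coefficient. At IS = 0 the correction is the
identity. The CO₂ solubility K_H (mol L⁻¹ atm⁻¹) is the zero-salinity
Weiss-type fit ln K_H = −58.0931 + 90.5069(100/T_k) + 22.294 ln(T_k/100),
giving 0.0340 at 25 °C.

Because different published K₁/K₂ formulations differ in their third or
fourth significant figure, pCO₂ values computed here are reproducible
against any independent calculator only when that calculator is
configured with the same constants; the constants module is therefore a
single, documented, swappable location.

## Gas exchange

The flux equation fCO₂ = k_x·K_H·(pCO₂atm − pCO₂w) includes the
solubility factor K_H(T): a partial-pressure difference alone is not a
molar flux, so the solubility term is dimensionally required (unit chain:
cm h⁻¹ → m d⁻¹ ×0.24; mol L⁻¹ atm⁻¹ → mol m⁻³ atm⁻¹ ×1000; μatm → atm
×10⁻⁶; mol → mmol ×1000). Positive flux means invasion into the lake.

k600 uses the low-wind power law 2.07 + 0.215·U₁₀^1.7 (cm h⁻¹), rescaled
by (Sc/600)^(−x). The Schmidt exponent switches at 3.0 m s⁻¹; winds of
exactly 3.0 take the low-wind exponent 0.66 for continuity with the
smooth-surface regime (the discontinuity this leaves at 20 °C is below
0.2 % of the flux because Sc(20 °C) ≈ 599.4 ≈ 600). pCO₂atm defaults to
380 μatm and is a parameter. Wind is accepted as a single U₁₀ per record;
temporal aggregation of sub-daily wind is the caller's responsibility.

## Incubation metabolism

Respiration rates are linear two-point estimates (start minus end over
duration), consistent with assuming a constant respiratory rate over the
incubation; time-course slopes are offered only as descriptive summaries.
Oxygen converts to carbon respired with an O₂:CO₂ molar conversion factor
of 1.0 and molar masses 31.998 (O₂) and 12.011 (C). A rise of O₂ in a
dark bottle is reported as a negative rate with a warning, never clipped:
it indicates a measurement problem the analyst must see. Incubation
temperature defaults to 23 °C (thermal box) when not supplied. CO₂
accumulation is computed state-wise (α₀·DIC at each endpoint), so it is
a function of the endpoints only; it is reported both as mg CO₂ L⁻¹ and
mg C L⁻¹ since field conventions vary — downstream tables default to the
CO₂-mass convention.

## Permutation statistics

The zone contrast is a one-way permutational ANOVA on Euclidean
distances. In the univariate mode used throughout, the pseudo-F is
algebraically the classical one-way F; the implementation also accepts
multivariate observation vectors through the same distance-based
decomposition. Significance comes from free label permutations with the
add-one estimator p = (1 + #{F* ≥ F}) / (1 + n_perm), which cannot return
zero and counts ties as at-least-as-extreme (conservative). When the
number of distinct relabellings is at most 20,000 the test enumerates all
of them and reports the exact p instead. An optional month-stratified
permutation mode restricts relabelling to within campaigns; the default
is unrestricted, matching the common single-factor usage. Every
Monte-Carlo result records its seed.

Variables are z-scored within each sampling month (sample SD, n−1) before
pooled testing, so campaigns with different baselines contribute
comparable deviations. A stratum with zero spread standardizes to zero
with a warning. "Zero" spread is judged relative to the stratum mean
(SD ≤ 10⁻¹⁰·|mean|) because cancellation error leaves SDs of order 10⁻¹⁶
on identical values.

Each variable's zone test is a planned individual comparison and its
permutation p stands at face value. The Bonferroni correction (n·p,
capped at 1) is applied to a-posteriori pairwise group contrasts: with
two zones that is a single pair (the correction is the identity), and it
bites for multi-group factors such as a time effect across incubation
retrieval days, where n is the number of group pairs.

The respiration-vs-distance analyses use natural-log transformed rates:
a classical one-way ANOVA by zone and an OLS regression of ln(rate) on
ln(distance) with adjusted R² and a slope test. Non-positive rates cannot
be log-transformed and are excluded with a logged count; zero within-
group spread is flagged as degenerate rather than reported as a finite F.

## Regression trees

Anova CART: each split maximizes ΔSS = SS(parent) − SS(left) − SS(right)
over midpoints between consecutive distinct predictor values; records
with predictor < threshold go left, and a record exactly at a threshold
goes right. Defaults follow the conventions of the classical rpart
implementation: minimum 20 observations to attempt a split, minimum leaf
7, complexity parameter 0.01 (a split must recover at least cp × root SS),
unlimited depth, no cross-validation pruning, no surrogate splits (a
record missing a tested variable is an explicit error). Ties in ΔSS are
broken by predictor order in the schema, then by the smaller threshold,
making fits deterministic. Trees serialize to an indented plain-text rule
format with leaf means and sizes.

## Synthetic data generator

The generator emulates a two-year littoral/pelagic monitoring design: 12
littoral and 7 pelagic stations visited in seven campaigns (May/Aug/Nov
of year one; Mar/May/Aug/Nov of year two), 133 station-visits in total.
Station positions are fixed across campaigns, drawn uniformly at 50–950 m
(littoral) and 1000–5000 m (pelagic) from shore, straddling the 1000-m
zone threshold.

Per-zone means and SDs of the chemical/optical variables default to the
whole-period littoral/pelagic summaries of the emulated survey (e.g.
chl *a* 3.03 ± 1.09 vs 3.89 ± 1.49 μg L⁻¹; DOC 1.89 ± 1.23 vs
2.38 ± 1.51 mg L⁻¹; TP 0.033 ± 0.020 vs 0.037 ± 0.018 mg L⁻¹). Values are
drawn independently per station-visit from zero-truncated Gaussians.
Because plain resample-on-negative truncation inflates the realized mean
by several percent when the mean sits within ~2 SD of zero (about +7 %
for TP), the generator solves for the location of the underlying Gaussian
whose zero-truncated mean equals the configured mean; realized means then
match the configured ones (realized SDs shrink by a few percent at the
most truncated settings — matching both moments exactly would need a
two-parameter solve the package deliberately avoids for transparency).
A truncated Gaussian rather than a lognormal is used because the
summaries being emulated are arithmetic mean ± SD.

The Abs250:Abs365 ratio is always computed from the drawn absorbances,
never drawn itself, and the rare draw with Abs365 ≥ Abs250 is redrawn as
unphysical for waters whose ratio exceeds 1. Temperature follows a
southern-hemisphere seasonal cycle (13 °C in austral winter to ~25 °C in
late summer) with 1 °C station scatter; conductivity (300 ± 50 μS cm⁻¹)
and wind (5 ± 2 m s⁻¹) are zero-truncated Gaussians chosen as typical of
a large wind-exposed coastal freshwater lake. An optional shared month
intercept (in units of each variable's SD) emulates lake-wide
campaign-to-campaign shifts; an optional Gaussian copula induces
predictor correlation for tree-sensitivity studies. Both are off by
default for transparency.

What the generator does *not* emulate: spatial autocorrelation among
stations, within-station temporal autocorrelation across campaigns,
non-Gaussian tails, and the real covariance between chemistry and the
metabolic responses (O₂ consumption and CO₂ accumulation are drawn from
their zone summaries, not mechanistically coupled to DOC or nutrients).
Passing tests on synthetic data therefore demonstrate correctness of the
computational chain and calibration of the statistics under the design's
sample sizes and effect sizes — not that real-lake effects will be
detected at the same rates, nor that real trees will reproduce any
particular split constants.

The 14-day DIC experiment generator draws triplicate vials per water type
at retrieval days 0, 1, 3, 5, 7, 10 and 14 (42 vials), with no time
trend: the time-effect test's null is true by construction while the
water-type contrast carries the configured littoral/pelagic difference.

## Problem sizes and numerical choices

Monte-Carlo checks use sizes chosen to bound their own error well below
the margins they probe: 2000 null surveys at 999 permutations for type-I
calibration (binomial SE ≈ 0.005 against an accepted band of
0.035–0.065), 100–1000 replicate surveys for power and bias checks, and
1000-point random sweeps for oracle equivalence at 10⁻⁹–10⁻¹² relative
tolerance. Exhaustive permutation enumeration caps at 20,000
relabellings. Floating-point tie tolerance in permutation counting is
10⁻¹² relative to the observed statistic; split-gain ties use the same
relative tolerance.

## Known limitations

- Freshwater only: no borate/sulfate/fluoride alkalinity terms, no
  seawater constants, no carbonate-mineral saturation indices.
- No alkalinity-based speciation path; DIC and pH are the required pair.
- No chemical-enhancement correction of gas exchange at high pH.
- Single k600 parameterization (the low-wind power law).
- Univariate permutation tests are the supported mode; the distance-based
  decomposition admits multivariate input but multi-factor and nested
  designs are out of scope, as are non-Euclidean distances and
  dispersion (PERMDISP-style) tests.
- Trees are single fits; no ensembles, no cross-validated pruning.
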