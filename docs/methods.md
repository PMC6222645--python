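# Methods

## Design of experiments

The workflow studies five extraction variables over fixed working ranges
(SW 2.4–5.8 g, AM 5–95%, EV 8–16 mL, WC 1.5–4.5 mL, ET 1–3 min). Each is
coded linearly onto [−1, +1]; coding makes fitted coefficients directly
comparable across factors with different units. The design is a
face-centred central composite (CCF): the full 2⁵ factorial, one axial pair
per factor at the face centres (α = 1, so every factor is exercised at
exactly three levels), and three genuine centre replicates — 45 runs per
extraction system. Run order is deterministic (factorial corners in
lexicographic −1/+1 order, axial pairs per factor, centres last): no
randomization schedule is modelled, and reproducibility of simulated
tables requires a fixed order. Centre replicates are emitted as distinct
runs because they carry the replicate-error information.

A note on nomenclature: three-level face-centred composite designs are
sometimes described loosely as "3^k factorial" designs. A literal 3⁵
factorial would have 243 runs; the 45-run CCF is the standard design
consistent with three levels per factor, face centring, and the 90 total
conditions across the two extraction systems, and is what this package
implements. Rotatable-α composite designs, Box–Behnken and D-optimal
designs are out of scope.

## Recovery model

Per compound, recovery % is regressed on a fixed 31-term basis: intercept,
5 linear, 10 two-way and 10 three-way interaction terms, and 5 quadratic
terms (1 + k + C(k,2) + C(k,3) + k for k factors). The inclusion of
three-way interactions alongside a full quadratic makes the surface
degree 3, so multiple interior optima are possible; this motivates the
global-then-local optimizer below. The basis order (intercept, linear,
two-way, three-way, quadratic; combinations lexicographic in the factor
order SW, AM, EV, WC, ET) is identical in fitting, serialization and the
shipped coefficient fixtures.

Fitting is ordinary least squares, one compound at a time (no multivariate
error structure). Inference uses the pooled residual variance on
n − 31 = 14 degrees of freedom for the 45-run design: the centre replicates
contribute pure error, but no lack-of-fit decomposition is performed, so a
single residual-variance estimate scales the inverse Gram matrix for
coefficient standard errors. Two-sided t-tests give per-coefficient
p-values, summarized with the conventional letter code a/b/c/d for
p < 0.05/0.10/0.20/0.30 (95/90/80/70% confidence). Which statistic stands
behind the letters is a design choice here — the two-sided coefficient
t-test is the standard RSM convention. Goodness of fit is reported as the
multiple correlation coefficient R = √(1 − SSE/SST).

Degenerate inputs: the fit refuses designs with fewer runs than terms, and
declares rank deficiency when the expanded design matrix's smallest
singular value falls below 1e-10 of the largest. The OLS solve itself is
delegated to statsmodels; tests cross-check coefficients, standard errors
and p-values against an independent pseudo-inverse path.

## Term pruning and the deviation audit

Pruning at a minimum confidence level L ∈ {95, 90, 80, 70, 0} retains the
intercept plus every term whose letter meets L; level 0 is the identity.
Two modes:

- **truncate** (default): deleted terms are zeroed and the surviving
  coefficients keep their full-fit values. This mirrors how a published
  equation is actually simplified — and it is the mode under which an
  ill-chosen intercept can distort predictions, which is the scenario the
  audit exists to expose. The intercept is never prunable regardless of its
  letter: a recovery model with no mean level is meaningless.
- **refit**: the reduced basis is re-estimated by least squares (requires
  the training data).

The audit statistic is the range (min, max) of per-run absolute deviations
|predicted − observed|, in recovery percentage points — not relative error:
recoveries are themselves percentages near 100, and residual-scale
magnitudes are the quantity of interest. For truncated models R is reported
as the Pearson correlation between predictions and observations, because
the 1 − SSE/SST form can go negative once terms are deleted; for the full
model the two definitions coincide. Both the deviation range and R appear
in the report because neither alone suffices: a wide response range can
produce a high R while a single aberrant run keeps the worst-case deviation
large (the test suite constructs exactly this case with an outlying centre
replicate).

SSE is provably non-decreasing under pruning in either mode (full OLS
minimizes SSE over the richer basis), and retained-term sets are nested
across levels; both are enforced as tests.

## Condition optimization

The target is a single operating point where every compound's predicted
recovery lies within target ± tolerance (defaults 100 ± 2.5 recovery
points; the band is consistent with the spread of the published predicted
values, 97.6–100.1). Because the surfaces are cubic with possible multiple
optima, the solve is global-first: a dense grid over the coded cube
(default 21 points per axis, ≈ 4.1 M points, evaluated vectorized in
chunks), then a Nelder-Mead polish from the best grid point, constrained to
the cube — empirical polynomials are not trusted outside the studied
region, so no extrapolation is ever returned.

Among feasible points a secondary, lexicographic criterion selects the
minimum values of the experimental variables: minimize the unweighted sum
of per-factor positions scaled to [0, 1] from the low bound. The weighting
across factors is a design choice (no canonical trade-off exists between,
say, grams of soil and minutes of shaking); consequently the optimizer is
expected to find *a* feasible minimum-variable point, not to reproduce any
particular published operating point exactly — feasibility of the published
points is itself verified in the tests. During the polish, feasibility is
enforced by a penalty on (max deviation − tolerance)⁺; if the polish ever
leaves the feasible band the grid point is kept. If no grid point is
feasible the optimizer minimizes the worst-case deviation instead and says
so (`feasible=False`).

## Matrix effect

ME(%) = (Sₘ − Sₛ)/Sₛ · 100 from calibration slopes in matrix extract (Sₘ)
and solvent (Sₛ), fitted by unweighted OLS *with* intercept over at least
three concentration levels inside the linear range 0.005–0.1 mg/L —
forcing the line through zero would bias the slope under baseline offsets.
Negative ME is ionization suppression, positive is enhancement; |ME| > 20%
is flagged as significant. The threshold is the field's fixed rule of
thumb, not a statistical test: no slope-comparison t-test is layered on
top. ME is scale-invariant in the instrument response units and monotone in
Sₘ, both property-tested.

## Synthetic data generator

The raw per-run recovery tables behind the published models are not
available, so simulations stand in for them. `simulate_recoveries` draws

    Y(run, compound) = polynomial(true_coefficients, coded run) + N(0, σ²)

over the 45-run CCF design, clipped below at 0% (no upper clip: observed
recoveries above 110% do occur), deterministic given a seed. Defaults: the
true coefficient vectors are the published citrate/acetate tables — so
synthetic experiments inhabit the actual surface geometry, including the
acetate saddle behaviour in the AM×EV plane — and σ = 2 recovery points,
chosen once as commensurate with the published full-model residual ranges
(max ≈ 4.4 points on the acetate side). Homoscedastic Gaussian noise is the
simplest structure consistent with unweighted least squares; the true
replicate error of the assay is unknown, so σ is a parameter, not an
estimate.

What passing synthetic tests shows: the estimator recovers generating
coefficients exactly at σ = 0 and is unbiased with correctly calibrated
standard errors at σ = 2 (Monte Carlo, 200–500 replicates); the pruning
audit and optimizer behave as designed on surfaces with the published
geometry. What it does not show: anything about run-order drift,
heteroscedastic or non-Gaussian assay error, or matrix chemistry — and the
published deviation table itself is not reproducible without the original
raw recoveries, so the audit is validated by properties and oracles, not by
matching those printed numbers.

`simulate_calibration` generates paired solvent/matrix calibration series
with a known ME (matrix slope = solvent slope · (1 + ME/100)), five evenly
spaced levels across the linear range by default, additive Gaussian
response noise.

## Problem sizes and numerical choices

The test suite runs the full 45-run fits everywhere (they are milliseconds
each); Monte Carlo checks use 200–500 replicates, which bounds the
coefficient-mean standard error at ≈ analytic SE/14 and makes the 15%
SE-calibration tolerance comfortable. The acceptance script's deviation
bound uses a single 45-run table per compound at σ = 2, the same size as
the real experiment. The default optimizer grid (21 per axis) evaluates in
a few seconds; tests that only need feasibility use coarser grids.
Serialization writes coefficients at full precision (shortest round-trip
repr) and re-reads with round-trip float parsing, so write→read is
bit-identical; display formatting rounds to 4 significant figures for
coefficients and 1 decimal for recoveries.
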