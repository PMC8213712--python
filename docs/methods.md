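# Methods

This note records the models implemented in `cluesim`, the choices made
where the published workflow left the design open, what the synthetic
landscape does and does not emulate, and the limits of what the tests
demonstrate.

## Raster model and derived drivers

All layers live on one rectangular grid of square cells (row 0 =
north), carried as plain arrays with ESRI-ASCII-style metadata and a
nodata sentinel (−9999 by convention). Areas are accounted in hectares
(cellsize²/10⁴), matching the calibration tables. I/O is restricted to
the plain-text ESRI ASCII grid format; there is deliberately no
GeoTIFF/projection handling (out of scope — inputs are assumed
co-registered).

Choices pinned where the source workflow is silent:

- **Categorical aggregation** takes the majority class of each block,
  with ties broken by the smallest class code — deterministic and
  reproducible. Continuous layers aggregate by the block mean of valid
  cells. Trailing partial blocks are allowed.
- **Accessibility drivers** are centre-to-centre Euclidean distances to
  the nearest feature cell (scipy's exact Euclidean distance transform),
  the standard GIS derivation; network or cost distances are not
  attempted.
- **Slope** uses Horn's 3×3 weighted finite differences in degrees, the
  de-facto GIS standard; border cells use one-sided differences
  (implemented as linear extrapolation one cell outward, exact for
  planes).
- **Standardization** is zero-mean, unit *population* (divide-by-n)
  standard deviation over valid cells. Either sd convention rescales
  coefficients consistently; one is pinned for reproducibility, and the
  parameters are stored on the fitted model for prediction-time reuse.

## Suitability models

Occurrence of each of the six classes is fitted one-vs-rest by
unpenalised maximum-likelihood binary logistic regression (statsmodels,
Newton, tolerance 1e-8, 100 iterations; an L-BFGS fallback catches
Newton failures under near-separation). Non-convergence and separation
(|β| > 50 after fitting) are flagged on the returned model rather than
raised: a flagged model is still usable for ranking cells, which is all
the allocator needs. Structural exclusions — drivers a class's model
simply does not include, as in the packaged calibration where printed
cells are dashes — carry no coefficient and contribute zero to the
linear predictor.

All valid cells enter the fit (no subsampling): 40,000 cells at the
default geometry is comfortable, and the source workflow describes no
sampling design. AUC is computed by the Mann–Whitney rank statistic with
averaged ties, which equals the trapezoid area under the empirical ROC
curve exactly; the conventional 0.7 bar labels a class model adequate.
Collinearity diagnostics regress each driver on the others: tolerance
= 1 − R², VIF = 1/tolerance, with critical values 0.1 and 5.

The multi-scale comparison (`scale_selection`) aggregates the map
(majority) and drivers (mean) by factors 2–5, refits all six models per
scale and tabulates in-sample AUC — the operational form of the
resolution-choice analysis. A class too rare to fit at a coarse scale
yields NaN rather than failing the table.

## Synthetic landscape

The generator stands in for the interpreted satellite maps, providing a
landscape whose generative parameters are known exactly:

- **DEM**: Gaussian-filtered white noise rescaled to 30–60 m, a
  lake-plain relief; smoothness (filter sigma, default 8 cells) sets
  the autocorrelation length.
- **Features**: roads/rivers/ditches as rasterised random polylines
  (8-connected walks), mines as small patches, residential areas as
  scattered square patches. Distances to these five masks plus
  elevation and Horn slope give the seven-driver stack.
- **Land cover**: per-cell class sampled from a softmax over per-class
  linear scores on the standardized drivers, one majority-filter pass
  for patch structure, intercepts auto-tuned to hit the target class
  budget (defaults near the natural-development 2025 shares: 0.220,
  0.355, 0.056, 0.010, 0.333, 0.026). The tuning is two-stage: an inner
  fixed-point match of expected softmax shares, then a damped (step
  0.5, clamped ±1) outer correction against the *smoothed* realisation,
  keeping the best iterate — undamped correction oscillates because the
  majority filter's response is steep for rare clustered classes.
  Realised shares stay within ±3 percentage points of target (typically
  ±1).
- **Evolution**: a known row-stochastic matrix converts each source
  class's cells by largest-remainder destination quotas, most-suitable
  cells first (tiny seeded jitter breaks ties), yielding a map pair
  with known transition structure.

Every output is bit-reproducible from the seed.

Generating coefficients follow the published signed associations
(construction and farmland near settlement and roads, subsided seeper
tightly around mines, water pulled to rivers and away from ditches,
wetland along ditches), with magnitudes kept moderate (|β| ≤ 3, versus
−5.8 for the most extreme published value). Two identifiability points
are worth recording:

- A multinomial logit is invariant to adding one common vector to every
  class's coefficients, while the pipeline fits one-vs-rest binaries.
  Default coefficient columns are therefore centred by the
  prevalence-weighted mean, putting the generative β on the contrast
  scale the binary fits estimate.
- Even so, the one-vs-rest log-odds of a softmax field are not exactly
  linear in the drivers, so full-landscape recovery is a *sign*-level
  claim (asserted for every |β| ≥ 0.5 as the partial, fitted-coefficient
  sign — marginal correlations can flip under correlated distance
  drivers and are not used). Magnitude-level recovery (±0.1) is tested
  on landscapes where one focal class carries the coefficients and the
  other classes are driver-independent; there the focal one-vs-rest
  log-odds are exactly the generating linear predictor. Recovery
  experiments run without the majority-filter pass, which is a
  presentation perturbation relative to the sampling model the fit
  targets.

What the generator does not emulate: spectral/radiometric properties,
interpretation error, hydrology, realistic patch-size distributions
(the source study publishes no spatial statistics to calibrate
against). Passing tests therefore demonstrate the *pipeline's*
correctness and internal consistency, not accuracy on any real
landscape.

## Demand

`estimate_transition` is the row-normalised cross-tabulation of a map
pair; every class must be present at the start (its row is undefined
otherwise). Annualization takes the period-th matrix root by
eigendecomposition; complex or nonpositive eigenvalues raise with
advice to project at the period level instead. The raw root can carry
tiny negative entries (order 1e-4 for realistic matrices); they are
clipped and rows renormalised, which perturbs the root-power round trip
by the same order — the exact round trip holds pre-clipping and both
forms are exposed (`matrix_root` vs `annualize`).

Scenario rules multiply ruled off-diagonal entries by retention factors
in [0, 1] and return the removed mass to the source diagonal, keeping
rows stochastic and the adjustment auditable.

The single land-use dynamic degree is 100·ΔA/(A_start·T) percent per
year. The packaged change table's printed rates are internally
consistent with T = 5 years even though the table is captioned as a
2017–2025 horizon; the span is therefore an explicit argument
everywhere (default 5 in the packaged-table context), never silently
resolved.

The packaged demand trajectories interpolate linearly from the implied
2016 start areas (endpoint minus printed change, rescaled onto the
common total — the printed starts drift 4 ha from it through rounding)
to the published 2025 endpoints, with each year renormalised; the
published intermediate matrices behind the ecological and
farmland-protection budgets are not recoverable, so the fixtures
reproduce the endpoints, not the unstated path.

## Allocation

The allocator composes, for every cell and every class its current
class may convert to,

    TPROP = P(cell, class) + ELAS·[incumbent] + offset_class,

assigns each cell its argmax (ties: highest adjusted score, then
smallest class code, then cell index — no RNG anywhere), and updates
each offset by a damped relative deficit, damping halved when every
deficit flips sign (oscillation). Defaults: tolerance per class
max(one cell's area, 0.1% of demand), 2,000 iterations, damping 0.5.
Demand in hectares is converted to integer cell targets by
largest-remainder rounding, so targets sum exactly to the map size.

Two deliberate semantics:

- ELAS = 1 freezes a class's cells outright (never displaced), the
  fully-stable reading of the elasticity scale; a scalar-offset
  equilibrium could otherwise leak cells out of a unit-elasticity class.
  Cells whose current class allows no conversion are likewise frozen
  and excluded from the balancing arithmetic. Packaged scenarios use
  0.5–0.9 only.
- After the offset loop, a deterministic exact-finish phase greedily
  swaps the cheapest cells (smallest score loss) from over- to
  under-allocated classes until integer targets are met. This closes
  the last few cells that scalar offsets cannot resolve and makes
  convergence exact in cell counts; on 2-class problems the combined
  procedure provably maximises total TPROP subject to the demand, which
  the test suite checks by enumeration on 4-cell problems.

Scenario restriction is carried by the boolean allowed-conversion
matrix and the elasticities. In the packaged scenarios the ecological
variant forbids water and tidal wetland converting to construction land
and the farmland variant forbids farmland to construction; blanket bans
on all flows out of protected classes would contradict the published
2025 budgets, which still shrink those classes.

## Validation

Kappa uses the fixed-chance form κ = (Po − 1/n)/(Pp − 1/n) (Pc = 1/6
for six classes), as the calibration defines it; Cohen's kappa with the
marginal-product chance expectation is reported under a separate key to
avoid confusion between the two conventions. Kappa-for-quantity is
pinned to the proportion-disagreement form Kq = (Aq − 1/n)/(1 − 1/n)
with Aq = 1 − ½Σ|p_u − q_u| — the source names but never defines the
statistic, so its published value is treated as data-dependent and not
reproduced. Producer/user accuracies are diagonal shares of the
confusion matrix's columns/rows (rows = simulated). Percentages are
reported to 2 decimals and kappas to 3, the printed precision.

## Problem sizes and experiment design

The default landscape is 200×200 cells at 60 m (40,000 cells,
14,400 ha): large enough for stable regression and transition recovery
(coefficient standard errors ≲ 0.03; transition rows realised within
1/n_u of their quotas), small enough that the full suite runs in well
under a minute. Allocation experiments use 100×100; the brute-force
allocator oracle uses 4-cell problems where enumeration is exact. The
self-validation experiment (hindcast of the evolved map with the fitted
model) clears κ > 0.75 with margin (≈ 0.9), and the generating model's
AUC exceeds 0.7 for every class — the two published acceptance bars.

## Known limitations

- Elasticity calibration is manual in the source workflow and is not
  automated here; published values ship as fixtures.
- No decomposition of transitions into random vs systematic components,
  no neighbourhood-interaction terms, no region-specific restriction
  masks beyond the conversion matrix, no kappa significance tests.
- The annual-matrix construction assumes a real positive eigensystem;
  strongly cyclic transition structures have no real annual root and
  must be projected at the period level.
- Synthetic texture parameters (patch size, autocorrelation) are free
  knobs, not calibrated claims about the real landscape.
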