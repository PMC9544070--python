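# Methods

## Model structure and assumptions

The colony is modelled as a discrete-time map on a weekly grid — the
natural resolution of the husbandry cycle (weekly QC, weekly plant
rotation, 7-week iterations). Five compartments: leaf area `P`, viable
adults `A`, nymphs `N`, eggs `E`, cumulative adults `T`. Assumptions:

- **Synchronous update.** All right-hand sides use week-*i* values
  (standard discrete-map semantics).
- **Continuous-valued counts.** Compartments are reals; rounding happens
  only at reporting. The model describes mean dynamics, not demographic
  stochasticity.
- **Predator–prey coupling.** Insect load `A + E/4 + N/2` (eggs and nymphs
  weighted as fractional feeders) erodes leaf area; leaf area saturates
  egg-laying through the Monod factor `P/(K+P)`. No temperature dependence
  (rearing is held at 27–28 °C) and no sex structure: the available
  end-point observations cannot resolve either.
- **Survival denominators.** The `1/(1+μ)` factors divide the whole
  bracketed numerator in the adult, nymph and egg equations. The typeset
  source equations are typographically ambiguous on whether the factor
  applies to the last term only; the whole-numerator reading was chosen
  for consistency across the three equations and is the documented
  default. The alternate reading is available via
  `ModelParameters(denominator_scope="last_term")` and changes no
  structural property (delay, monotone sink, positivity).
- **Plant collapse.** The damage term is not positivity-preserving; if the
  map drives `P` below zero it is clamped at 0, the trajectory's collapse
  flag is set, and egg-laying shuts off (`P/(K+P) = 0` at `P = 0`).
- **Harvest convention.** "Harvest" is the state after 7 weekly steps, and
  harvest counts are compared to `T`, since brushed-out adults are counted
  without distinguishing dead from alive.

## Parameters

| name | units | default | origin |
|------|-------|---------|--------|
| μ_A  | wk⁻¹ | 0.565 | midpoint of literature bound region [0.43, 0.70] |
| δ    | wk⁻¹ | 0.505 | midpoint of [0.43, 0.58] (nymph→adult in 12–16 d) |
| γ    | wk⁻¹ | 0.89  | midpoint of [0.78, 1.0] (egg→nymph in 6–8 d) |
| μ_N  | wk⁻¹ | 0.30  | midpoint of [0.20, 0.40] |
| μ_E  | wk⁻¹ | 0.30  | midpoint of [0.20, 0.40] |
| r    | eggs·adult⁻¹·wk⁻¹ | 25 | 109 lifetime eggs ≈ 50/week over a 2-week adult life, halved for unfertilized (male) eggs |
| G_m  | fold·wk⁻¹ | 4^(1/6) ≈ 1.2599 | insect-free plants grow 4-fold over 6 weeks |
| K    | sq.in. | 0.25·P₀ = 31.25 | not experimentally determined; chosen so egg-laying starts at 80% of saturation, keeping low-density proliferation effectively unconstrained |
| β    | adult⁻¹·wk⁻¹ | 1.31676×10⁻⁵ | calibrated once by bisection so the standard 100-adult run ends at exactly 4-fold plant growth at harvest; frozen as `BETA_DEFAULT`, reproducible via `calibrate_beta()` |

Reference condition: 5 plants × 25 sq.in. (P₀ = 125), inoculum 100 adults,
harvest at week 7. Bound midpoints are used as defaults because the
fitted point values for the original dataset are not available; fits in
this package recover parameters from synthetic logs instead.

## Calibration

The objective is a normalized sum of squared end-point residuals over
records: `Σ [(T̂₇−harvest)/mean(harvest)]² + [(P̂₇−final area)/mean(final
area)]²`. Counts (~10³–10⁴) and areas (~10²–10³) are on different scales
and no explicit weighting is prescribed, so per-quantity observed means
normalize both to comparable magnitude.

Optimization: `scipy.optimize.least_squares` (trust-region reflective,
box constraints, tolerances 10⁻¹²) from the bound-box midpoint plus 8
multistart points drawn uniformly from the box with a seeded generator;
best objective wins, ties to first found. Point intervals (`lo == hi`)
pin a parameter without entering the optimizer. Identical records, bounds
and seed give bit-identical results.

**Free-parameter set.** Only `{μ_A, μ_N, μ_E, δ, γ, β}` may be freed; `r`
and `G_m` stay at their derived values (fecundity from the literature,
growth from insect-free plants). With just two observables per iteration,
freeing all six is under-determined; the recovery analyses and tests free
`{μ_A, δ, β}` — one death rate, one transition rate, the damage
coefficient — which is well identified by 6-iteration designs spanning
inocula 80–213 (noise-free recovery is exact to ~10⁻¹⁴ relative error).

**Lack of fit.** The residual sum of squares is partitioned into pure
(replicate) error within groups of replicated observations and the
left-out terms, LOT = residual − replicate error. `F_LOT` is the LOT mean
square over the pure-error mean square on `(g − p, n − g)` degrees of
freedom (`g` groups, `p` model parameters, default 1); model significance
is the one-way ANOVA F of model-explained variation about the grand mean
against residual variation. The replicate structure of the original data
is not published, so grouping and `p` are caller inputs and the report
always prints df next to each statistic. Critical values come from the F
quantile function, never tables; the classically tabulated 5.59 at (1, 7)
and 18.5 at (1, 2), α = 0.05, serve as frozen quantile checks in the
tests.

## Planning analyses

- **Deviation analysis.** One-at-a-time ±60% perturbations of initial
  leaf area and inoculum, ±1 week (≈15%) of duration; each reported as
  perturbed final `T` over standard final `T` (no change = 1). Duration
  perturbations round to whole weeks because the model has no sub-week
  resolution. "Total whitefly count" always means `T`.
- **Back-calculation.** Final `T` is monotone increasing in the inoculum
  `A₀` in the operating regime, so bisection inverts the forward map; the
  tolerance of 0.25 adults is far below the counting error of inoculation
  photographs. A ±25% harvest-uncertainty band (the observed run-to-run
  scatter) is propagated into an inoculum interval by inverting the band
  endpoints.
- **Recommendation.** A grid scan over inoculum sizes keeps sizes whose
  runs satisfy both a final-plant-area fold floor (plant health) and a
  final-`T` yield floor; the longest feasible interval is reported. It is
  model-derived and reported alongside, not replacing, the empirical
  80–110 adult practice.

## QC indices

- **Sticky-card index** = trapped count / (card area × exposure time),
  with the 4×4 cm card (16/6.4516 sq.in.) and 15 min exposure as defaults.
- **Exoskeleton density**: concentric circles grow from the
  punch-equivalent radius (0.78 sq.in. → 0.498 in) in 0.1 in steps until
  ≥25 exuviae are enclosed; density = count/(πr²). The 25-count floor
  bounds the relative counting noise; the step size is an implementation
  choice. Fewer than 25 points within the usable leaf radius raises an
  error that still carries the best-available density.
- **Image counting** is an explicit threshold + 8-connected component
  counter (minimum blob size 4 px): reproducible and dependency-light
  while matching the described thresholding procedure. The intensity
  threshold is deliberately a required input — no universal value exists
  across lighting setups. Manual-quadrant calibration reports
  `|auto − manual|/manual` and flags failure above 5%.
- **Leaf area** from an overhead mask is foreground pixels × (pixel
  size)²; no perspective correction.

## Synthetic data

The generator emulates the statistical structure of the colony logs: 5
plants near 25 sq.in. each (seeded uniform ±10% jitter), inocula spanning
80–213 including one deliberately doubled (~200) inoculation, 7-week
latent trajectories from the true model, and multiplicative lognormal
observation noise parameterized mean-unbiased (`σ² = ln(1+CV²)`,
`μ = −σ²/2`). Defaults: harvest CV 0.25 (the observed two-life-cycle
scatter); area CV half that, since plant inputs were visibly better
controlled than whitefly outputs. The lognormal form itself is a package
choice — no distributional form is reported for the measurement error —
made because harvests are positive with relative scatter. Weekly QC draws
are Poisson: sticky counts with mean κ_sticky·A_i (κ_sticky = 0.002 puts
counts in the observed 1–11 range at mid-run adult densities), exoskeleton
point fields homogeneous with intensity κ_exo·(T_i − A₀) — proportional to
cumulative emergences, one exuvia each (κ_exo = 0.005 reproduces the
observed 6–37 per 0.78 sq.in. end-of-run range). Count images place
elliptical bright blobs (radius 2–4 px) on a dark noisy background with a
minimum-separation rejection sampler; an `overlap_fraction` places blobs
as near-touching pairs, and blobs are kept off the manual-quadrant border
so quadrant ground truth is unambiguous.

What the generator does *not* emulate: week-to-week environmental drift,
the unstable pre-refinement colony era, plant-to-plant heterogeneity
beyond initial-area jitter, sexing, or imaging artifacts (shadows, glare,
instars). Passing tests therefore demonstrate correctness of the
algorithms under the stated noise model, not robustness to every failure
mode of real cage data.

## Numerical choices and problem sizes

Bisection tolerances: 10⁻¹² on β calibration, 0.25 adults on inoculum
inversion. Optimizer tolerances 10⁻¹² with 8 multistarts. The test-suite
problem sizes — 100 random parameter draws for the oracle-equivalence
check, 20 seeded datasets for recovery, 1000 replicates for the noise-CV
check, 200 replicates for the Poisson-density consistency check,
1024² rasters with 400–500 blobs for imaging — were chosen as the
smallest sizes at which the corresponding law-of-large-numbers bands
(±3 CV points, ±10% density, "a few percent" count error) are stable.

## Known limitations

- End-point-only calibration cannot identify all six free rates; weekly
  count data would be needed to free more than ~3 at once.
- The map is deterministic; it reproduces mean behaviour and the
  observation-noise model reproduces scatter, but true demographic
  stochasticity (small-population extinction risk) is out of scope.
- `K` and the denominator scope are structurally unidentifiable from the
  available end-point data; both are documented choices with switches.
- The claimed 1:80 per-female amplification ratio is not derivable from
  the printed parameters and is asserted nowhere in the package.
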