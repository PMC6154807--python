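# Methods

## Scope and data model

The package estimates small-area relative risks of mortality from
registry-style aggregated counts. Its canonical input is a stratified
table — one row per area × age band × gender with a midpoint population
and a death count — plus a neighbor structure over the areas. Age is fixed
to the 18 five-year bands `0-4 … 85+`; missing strata are implicit zeros
(registries commonly omit empty cells). All vectors in the package are
aligned to the lexicographic order of area identifiers; this single
ordering convention is what prevents silent misalignment between observed
counts, expected counts and the adjacency graph.

## Indirect standardization

Reference rates are the pooled stratum-specific rates of the analysis
table itself (deaths over midpoint population, per age band and gender,
over the whole study window — no per-year rates). Expected counts apply
those rates to each area's stratum populations. Two consequences are used
as invariants throughout the tests: internal standardization conserves the
observed total (`ΣE = ΣY` to 1e-9 relative), and the E-weighted mean SMR
is 1. Gender-specific analyses standardize within that gender's strata;
because rates are stratum-specific this is exactly the restriction of the
pooled computation, and each gender's expected counts conserve its own
observed total. A stratum with zero pooled population gets rate 0; an area
with `E = 0` but observed deaths is a hard error (the relative risk is
undefined — the advice given is to merge strata). External reference rates
may be supplied instead, in which case no conservation holds.

Direct (external-reference) standardization, age-standardized rates and
person-years are out of scope.

## Adjacency

Queen contiguity (boundaries sharing at least one point, snapping
tolerance 1e-9 in coordinate units) is the default rule, the de-facto
convention in disease mapping; polygons arrive as GeoJSON
FeatureCollections keyed by an `area_id` property and are tested with
shapely's `dwithin` predicate over an STR-tree. Plain-text adjacency lists
(`area: nbr1,nbr2,…`) are symmetrized on read, with a logged warning for
each repaired one-sided declaration. The graph is binary (no
distance-decay or k-nearest weights), symmetric, loop-free; connected
components are computed with scipy's csgraph and isolated areas are
permitted as singleton components.

## The BYM model and its sampler

`Y_i ~ Poisson(θ_i E_i)`, `log θ_i = α + u_i + v_i`, with an improper flat
prior on α, the intrinsic autoregression on `u` with precision `τ_u`, iid
`N(0, 1/τ_v)` on `v`, and Gamma(0.5, 0.0005) shape–rate hyperpriors on
both precisions — the long-standing default of the BUGS disease-mapping
lineage; both are configurable.

The ICAR log density is taken as
`((n−c)/2)·log τ_u − (τ_u/2) Σ_{i~j}(u_i−u_j)²` with `c` the number of
connected components: the intrinsic precision `τ_u(D−W)` has rank `n−c`,
and the component-count correction keeps the `τ_u` Gibbs draw calibrated
on disconnected maps.

Updates per sweep, in order:

1. each `u_i` by random-walk Metropolis against Poisson likelihood × the
   ICAR full-conditional `N(mean of neighbors, 1/(τ_u m_i))`;
2. each `v_i` likewise against likelihood × `N(0, 1/τ_v)`;
3. α by random-walk Metropolis against the full likelihood;
4. recentre `u` to mean zero, adding the removed mean to α;
5. conjugate Gibbs draws of `τ_u` and `τ_v`.

Pure Gibbs is impossible for the Poisson/log-normal conditionals, hence
Metropolis within Gibbs. The `u` updates are executed in graph-coloring
blocks: a greedy coloring partitions the sites into mutually non-adjacent
classes, and all sites of one class are proposed and accepted/rejected
simultaneously. Because same-color sites do not interact in either the
likelihood (site-separable) or the ICAR quadratic form, the block update
is exactly the corresponding sequence of per-site updates — a
vectorization, not an approximation. Proposals whose log-risk would
overflow `exp` are rejected outright.

Step sizes (per site for `u` and `v`, scalar for α) adapt every 50 sweeps
of burn-in by `step ← step·exp(rate − 0.44)` toward the classic ~44%
scalar random-walk target, and are frozen at the end of burn-in so the
post-burn-in kernel has the exact stationary target. Acceptance rates are
reported per block from post-burn-in sweeps only.

**Identifiability.** The ICAR prior is flat along per-component constants
and α is flat, so the joint posterior is improper along the single
direction `(α, u) → (α+δ, u−δ)`. Recentring `u` each sweep and absorbing
the mean into α removes it while leaving every θᵢ unchanged. **Islands**
(areas with no neighbors) have `u_i ≡ 0`: the ICAR conditional is
undefined at degree 0, the rank term already excludes them, and their
variation is carried entirely by `v_i`. When islands are present the
recentring step is skipped: an α-shift is then not likelihood-invariant
(island risks would move), and the flat direction does not exist in the
first place, the island likelihoods pinning α. On island-free graphs —
every analysis case the package targets — the recentring invariant
`|mean(u)| < 1e-10` holds after every sweep.

Initial state: `α = log(ΣY/ΣE)`, `u = v = 0`, `τ_u = τ_v = 1`. Defaults
20,000 iterations, 5,000 burn-in, thinning 5, single chain, mandatory
seed; a run is bit-reproducible given its seed. These lengths are desk
scale — the sampler mixes quickly on lattices of a few hundred areas, and
the validation checks (conjugate and quadrature oracles, recovery
coverage) pass at these defaults.

**Deviance and DIC.** The stored per-draw deviance is
`−2 Σ [Y log μ − μ − log Y!]` with `μ = θE`, i.e. including the data-only
log-factorial term; DIC = D̄ + pD with pD = D̄ − D(θ̄) at the
posterior-mean risks. Because the constant term and the plug-in convention
are implementation choices, DIC *levels* are not comparable across
implementations — only differences between models fitted to the same data
by this package are meaningful.

## Posterior summaries

Equal-tailed percentile intervals (2.5%–97.5%) rather than
highest-density, matching standard BUGS-lineage reporting; at least 40
retained draws are required so the tail quantiles are estimable. The
point estimate is the posterior mean (median also exported) — the BUGS
default where reporting conventions diverge. Exceedance is the fraction of
draws with θᵢ > 1. Risk classes bin the posterior-mean RR half-open
`[low, high)` with default edges 0.8, 0.95, 1.05, 1.25, 1.5 (six classes;
a value exactly at an edge goes up). Map export writes one GeoJSON feature
per area with the summary columns copied verbatim — no recomputation on
export; cartography beyond an optional matplotlib choropleth helper is out
of scope.

## Synthetic data

The generator draws from the model itself so that end-to-end recovery is a
meaningful test: `u` from the intrinsic autoregression via the spectral
route (eigenbasis of the graph Laplacian, null directions excluded, exact
per-component centring) — deliberately independent of the MCMC code it
validates — `v` iid Gaussian, `Y_i ~ Poisson(θ_i E_i)`.

Three expected-count regimes: `constant` (fixed E), `uniform`
(`E_i ~ U(a, b)`, used by the recovery validation at `U(50, 150)`), and
`strata`, which emulates a provincial cancer-registry setting: 81 areas
(9×9 queen lattice) by default, district populations uniform on
11,025–229,033 split over the 18×2 strata by a plausible age pyramid and a
48.5/51.5 gender split, with age-specific mortality rates rising
exponentially above age 30 and a 1.423× male excess (≈59% male deaths at
equal exposure). The rate scale is calibrated so the median district
expects about 100 deaths, matching the per-area count magnitudes of the
registry setting (the printed district population range and a ~100 median
death count cannot both be met at the published crude rate under uniform
populations; the generator prioritizes the death-count scale, which is
what drives the likelihood). Small female strata can realistically produce
zero-count districts. Area-level simulated deaths are distributed back to
strata multinomially proportional to population × rate, with a guard that
reallocates the (vanishingly rare) draw exceeding a stratum's population.

What the generator does not emulate: spatio-temporal drift, covariate
effects, registry ascertainment error, and irregular real-world adjacency
(lattices are used). Passing recovery tests therefore demonstrates
correctness of the inferential machinery under the model's own
assumptions, not robustness to their violation.

## Numerical choices and edge cases

- Poisson deviance uses `gammaln` for log-factorials and skips `Y log μ`
  at `Y = 0`.
- Overflow guard at `exp(700)`: proposals beyond it are rejected (counted
  as rejections), and a non-finite retained deviance aborts with
  diagnostics.
- Expected-count conservation is asserted at 1e-9 relative; ICAR shift
  invariance and recentring at 1e-9/1e-10 absolute.
- Ties at risk-class edges go to the upper bin; class edges must be
  strictly increasing.
- `AreaTable` admits `E = 0` only alongside `Y = 0`; model fitting
  requires `E > 0` everywhere.

## Validation design

The test suite layers: printed-arithmetic fixtures (the packaged
six-province table, whose observed/expected totals and SMRs are exact);
closed-form oracles (single-area conjugacy to Gamma(Y, E); 2-area grid
quadrature of the marginalized posterior with fixed precisions; Gamma
targets of the precision Gibbs draws; exact ICAR identities); and
simulation-based checks (parameter recovery on a 15×15 lattice with 95%
CrI coverage required in [0.90, 0.98], and the shrinkage property — the
posterior-mean RR must beat the raw SMR in MSE against the generating
risks, the testable form of "SMRs are unreliable for small areas").
Problem sizes (15×15 recovery at default chain lengths, 10⁴–10⁵ draws for
distributional comparisons) were chosen as the smallest at which the
Monte-Carlo tolerances are comfortably non-trivial.

## Known limitations

- No proper-CAR or Leroux alternatives, no covariates in the linear
  predictor, single-chain runs with no formal convergence diagnostics
  beyond acceptance rates and trace export.
- DIC levels are convention-dependent (see above).
- Polygon input is GeoJSON only.
- The BYM spatial fraction (`τ_u` vs `τ_v`) is weakly identified in small
  maps; recovery checks target α, θ and coverage, not the individual
  precisions.
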