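# Methods

This note documents the models, conventions and numerical choices behind
`nichetrack`, in the order the pipeline runs them.

## Specimen quality control

Filters run in a fixed order — georeferencing radius, reproductive
structures, disjunct coordinates, county subsampling — and each reconciles
its counts (`n_input = n_retained + Σ drops`).

- **Error radius.** Retained iff `error_radius_km ≤ 5` (inclusive
  boundary); an unknown radius drops the record. The 5-km default reflects
  the precision below which a monthly, ~270-m-scale climate lookup is still
  meaningful.
- **Reproductive structures.** Any of buds/flowers/fruits retains the
  record, so the sample represents plants that survived to reproduction.
- **Disjunct coordinates.** There is no unambiguous definition of a
  "disjunct" record, so the filter is a transparent heuristic: per species,
  a record is flagged when the distance to its k-th nearest conspecific
  (default k = 1) exceeds `mult` (default 10) times the species' median
  k-th-neighbour distance. An explicit manual drop list overrides the
  heuristic in both directions of caution. When all records of a species
  are coincident the median distance is 0 and nothing is flagged (a 10×0
  cutoff would otherwise flag everything). Distances use a local
  equirectangular approximation (`111.320·cos(lat)` km per degree
  longitude, `110.574` km per degree latitude), adequate at within-species
  scales.
- **County subsampling.** Species with more than `max_n` (default 200)
  records are capped by round-robin draws across counties — counties are
  visited cyclically, one seeded-random record per visit — which spreads
  retained records across the geographic range; counts per county differ by
  at most 1 until a county is exhausted.

## Germination and windows

The water year runs September 1 – August 30: collections in January–August
anchor on the *previous* September. Candidate germination months are
September–February of the specimen's water year, truncated at the
collection month (germination can never postdate collection; the truncation
also keeps the rule well-defined for hypothetical winter collections).

The germination month is the **first candidate with rainfall strictly
greater than 25 mm** — the threshold is strict because 25 mm is the
biological trigger amount, and it is configurable. If no candidate clears
the threshold, the wettest candidate month is used (`fallback_max`), with
ties broken to the **earliest** month: earlier germination gives the longer,
biologically conservative growing season and makes the rule deterministic.
If every candidate month has rainfall ≤ ε (default ε = 0 mm, exposed as a
parameter), the specimen is dropped (`dropped_no_rain`).

Three windows per specimen, all inclusive month intervals:

| kind              | span                                     | length |
|-------------------|------------------------------------------|--------|
| specimen_specific | germination month → collection month     | varies |
| annual            | Sep (water year) → Aug                   | 12 mo  |
| clade_seasonal    | Oct (water year) → Apr                   | 7 mo   |

Summaries sum precipitation and CWD and average monthly mean temperature,
unweighted by days per month. Species niches are specimen means; the
standard error is `sd/√n` with the n−1 divisor, reported as 0 for n = 1
with an explicit flag. The tracking statistic is
`ΔCWD = mean lived CWD − mean clade-seasonal CWD`; positive values mean the
lived season is more arid than the fixed Oct–Apr season.

## Window statistics

- **Levene's test** (scipy) with **median centering** (Brown–Forsythe) by
  default — the robust variant that the standard R implementation defaults
  to; mean centering is exposed. Test units are species means, one value
  per species, never raw specimens. Two identical groups produce a 0/0
  statistic; this is reported as F = 0, p = 1 (no evidence of unequal
  variances).
- **Sign test**: exact two-tailed binomial at p₀ = 0.5 (scipy `binomtest`,
  the point-probability two-tailed convention). Zeros are excluded; `k`
  counts negative deltas. For 13 of 14 negative the closed form is
  30/2¹⁴ ≈ 0.0018.
- **Variance and range** use the sample variance (n−1) of species means.

## Comparative methods (implemented from first principles)

Trait vectors are `{tip label: value}` maps; all operations validate that
the keys exactly match the tree tips. The Brownian covariance structure
`C` has `C[i,j]` = shared root-to-MRCA path length. None of these
operations assumes an ultrametric tree. Polytomies must be resolved first
(a zero-length resolution utility is provided on `Tree`); the zero-length
branches change nothing in `C`.

- **Independent contrasts** (Felsenstein pruning): contrast
  `(xᵢ − xⱼ)/√(bᵢ + bⱼ)` at each internal node; ancestral value is the
  1/b-weighted average; the ancestral branch is extended by
  `bᵢbⱼ/(bᵢ+bⱼ)`. The mean squared contrast equals the REML Brownian rate
  (asserted in tests against the BM fit). PIC correlation defaults to the
  ordinary Pearson correlation of the contrast vectors with a Fisher-z 95 %
  CI and a t-test on n−2 df, mirroring a plain `cor.test` on contrasts;
  the through-origin estimator (t on n−1 df) is provided because contrast
  signs are arbitrary and origin-constrained correlation is standard
  practice.
- **Blomberg's K**:
  `K = [MSE₀/MSE]_obs / [tr(C) − n/(1ᵀC⁻¹1)]·(n−1)⁻¹` with
  `â = (1ᵀC⁻¹x)/(1ᵀC⁻¹1)`, `MSE₀ = Σ(x−â)²/(n−1)`,
  `MSE = (x−â)ᵀC⁻¹(x−â)/(n−1)`. K = 1 exactly on equal-branch star trees
  and in expectation under Brownian motion; K is invariant to trait
  rescaling and to global branch rescaling.
- **K tests**: `p_perm` shuffles tip values (any-signal test); `p_gt1`
  compares K against Brownian simulations on the same tree (one-sided,
  K_null ≥ K_obs — "more conserved than Brownian"). The Brownian rate is
  irrelevant because K is scale-free. Both use the (b+1)/(m+1) correction
  so a Monte-Carlo p is never exactly 0; defaults are 1000 permutations and
  1000 simulations.
- **PGLS**: `β̂ = (XᵀC⁻¹X)⁻¹XᵀC⁻¹y` with an intercept column, computed via
  the Cholesky-whitened design. The residual scale uses the n−p divisor
  (the REML convention of the standard GLS implementation); β̂ is identical
  under ML and REML because the correlation structure is fixed. Coefficient
  tests are two-sided t with n−p df. A condition number above 1e12 on the
  whitened normal matrix raises a collinearity error.

## Evolutionary models

All three models are fit by maximum likelihood with the **ML (divisor n)**
variance convention so their AICs are comparable; the REML Brownian rate is
exposed separately for cross-checks against contrasts. AIC = 2k − 2logL;
models within 2 units of the minimum are "supported" (inclusive boundary).

- **BM** (k = 2: σ², z₀): closed form, `ẑ₀ = (1ᵀC⁻¹x)/(1ᵀC⁻¹1)`,
  `σ̂² = (x−ẑ₀)ᵀC⁻¹(x−ẑ₀)/n`.
- **OU** (k = 3: σ², α, θ): fixed root at the optimum, covariance
  `V = σ²/(2α)·e^(−α·dᵢⱼ)·(1 − e^(−2α·tᵢⱼ))` with dᵢⱼ the patristic
  distance and tᵢⱼ the root-to-MRCA depth; `expm1` keeps the α → 0 limit
  (which is exactly BM) numerically clean down to α = 1e−9. θ and σ² are
  profiled analytically for each α; α is optimized on a log scale by
  bounded minimization plus a documented grid of probes
  (1e−4, 1e−2, 0.1, 1, 10) against local optima, with an upper bound of
  1e4 flagged in the diagnostics when hit.
- **Bounded BM** (k = 2: σ² plus the root convention; bounds are treated as
  fixed by the data, not estimated): the trait interval is discretized into
  `n_bins` (default 100; 200 in convergence checks) states; internal
  branches propagate partial likelihoods through the spectral decomposition
  of the symmetric tridiagonal reflected-random-walk generator (rate
  σ²/(2h²), reflecting ends), at O(n_bins²) per branch. Two refinements
  keep the likelihood accurate where a plain grid cannot: terminal branches
  are integrated **analytically** (the exact reflected-diffusion transition
  density, by method of images for narrow kernels and the cosine
  eigenfunction series otherwise, evaluated at the observed continuous tip
  value for every bin-centre state), and cherries whose diffusion kernel is
  much narrower than a grid cell — and whose values sit ≥ 5 kernel-SDs from
  both bounds, where reflection is negligible — are collapsed by local
  Felsenstein pruning into a pseudo-tip. Without these, trees with very
  short branches miss the Brownian wide-bound limit by several tenths of a
  log unit at 200 bins.

  **Root convention:** the root state is profiled (maximized) over bins by
  default, so BBM nests BM exactly in the wide-bound limit and its AIC is
  comparable to BM/OU, whose root/optimum are also profiled; a flat-prior
  root (`root="uniform"`) is exposed. Bounds default to the observed trait
  min/max, with an optional padding fraction because point masses in the
  boundary bins are numerically delicate.

  A consequence worth knowing: with bounds clamped at the sample extremes,
  BBM systematically attains a higher likelihood than BM *even on Brownian
  data* — the bounds inject the information of the sample range without a
  parameter charge. This matches the reference implementation
  (`phytools::bounded_bm`, against which the likelihood is cross-checked in
  the tests) and means AIC support for BBM over BM should be read as
  "consistent with bounded evolution", not proof of it.

## Soil refugia

Random background points are **area-uniform** in the 20-km disk (radius
`R·√u`, uniform angle — uniform per unit area, not per unit radius, which
would oversample the centre), converted to geographic offsets by the local
equirectangular approximation with the cos-latitude correction (error well
under a cell at 20 km). Points landing outside the grid or on nodata are
**skipped, not redrawn** (the valid count is reported): redrawing would
bias the background toward the data-rich side for edge localities, and
skipping is reproducible. A locality whose own cell is nodata is omitted
and counted (`n_input = n_used + n_omitted`). Species means of the deltas
feed the sign test and two single-predictor PGLS fits (vs annual mean
temperature and annual summed CWD); field-soil coarse fractions are
averaged per species and get the same two PGLS fits.

## Synthetic data

The generator produces the statistical structure the analysis assumes,
with latitude as the only geographic driver of climate:

- **Tree**: Yule (pure-birth) via exponential waiting times, rescaled to
  unit root-to-tip height; tips labelled in preorder.
- **Temperature**: `T(lat, elev, m) = T₀ − λ·(lat − lat_south) +
  A·cos(2π(m−7)/12) − 6.5·elev_km`, defaults T₀ = 17 °C at the southern
  edge, λ = 0.7 °C per degree latitude, A = 8 °C (July peak), standard
  6.5 °C/km lapse; monthly noise SD 0.5 °C.
- **Rainfall**: a wet season from an onset month through April with a
  triangular monthly profile peaking in December, totalling 500 mm;
  May–August are exactly dry. Onset is October at the northern edge,
  delayed `round(0.25·Δlat_south)` months toward the south (clamped at
  February) — southern sites start later, the gradient the tracking
  analysis keys on. Rainfall noise (SD 10 mm) applies to wet months only,
  so the dry summer stays exactly dry. Every onset month exceeds the 25-mm
  germination threshold by construction, so with zero noise the germination
  estimator recovers the onset month exactly.
- **CWD proxy**: `cwd = max(0, PET − ppt)` with `PET = 5·max(T, 0)` mm per
  month. This is a deliberately simple stand-in for a full water-balance
  model; it preserves the monotone relations the analysis relies on
  (hotter and drier months have higher CWD) and nothing downstream depends
  on its absolute scale.
- **Specimens**: species mean latitudes evolve by Brownian motion on the
  tree and are mapped affinely onto the 33–41° band, so geography carries
  phylogenetic signal; specimens jitter around the centroid with SD 0.3°.
  Collection months are drawn per species from a two-point distribution on
  adjacent months in March–July whose **expected lived CWD** equals
  `(1−s)·CWD_May + s·target`, where s is `tracking_strength`, the target is
  the clade median, and lived CWD per candidate month comes from the
  noise-free climate closed form. s = 0 gives identical collection months
  across species; s = 1 equalizes expected lived CWD across species while
  the clade-seasonal CWD still follows the latitudinal gradient — the
  planted conservatism signal. An optional ±1-month jitter (p = 0.2,
  a noise term) roughens the distribution; all months stay within
  March–July, satisfying the ≥95 % March–July collection structure.
  Error radii are lognormal (median 0.5 km) clipped at 5 km; ~71 % of
  specimens carry fruits; all records pass QC by construction.
- **Soils**: white noise smoothed by a Gaussian kernel (range 0 gives
  i.i.d. cells), rescaled to mean 150 mm, SD 30 mm, clipped at 0. A planted
  effect shifts occupied cells by a fixed offset (optionally varying with
  species annual temperature); field-soil coarse fractions are
  40 % ± site noise with an optional slope against species annual
  temperature. Field sites number 3–6 per species (mean 4.5).

**What the generator does not emulate:** topography, coastlines and
longitude effects; real water-balance CWD (soil storage, radiation,
snow); year-to-year climate autocorrelation; collector behaviour
(roadside bias, duplicate sheets); taxonomic error. Passing the
signal-recovery tests therefore shows the *pipeline* is correct and
sensitive, not that real herbarium data meet its assumptions.

## Problem sizes and determinism

Simulation-based checks use 14 species × 50 specimens × 100 replicates for
end-to-end signal recovery, 1000 Brownian simulations on a 50-tip tree for
the K calibration (500 replicates for the rejection-rate check), and
100–200 bins for BBM fits — sizes at which every Monte-Carlo margin in the
tests is several times its standard error while the whole suite stays
quick. All randomness flows through `numpy.random.default_rng` seeds;
a fixed config + seed reproduces pipeline output byte for byte (the
manifest contains no timestamps).

## Known limitations

- Germination is monthly-resolution and rainfall-triggered only; no
  temperature gating or daily cueing.
- The collection date proxies end-of-life; specimens collected early in
  flower truncate the lived window.
- The disjunct-record heuristic is a stand-in for expert judgment.
- OU fitting assumes a fixed root at the single optimum; no multi-optimum
  or measurement-error variants.
- BBM AIC support depends on the documented bounds/k conventions (see
  above); bounds are fixed at the data range, never estimated.
- PGLS offers Brownian correlation only (no Pagel's λ).
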