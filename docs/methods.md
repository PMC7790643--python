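# Methods

`resurvey` analyses change between two surveys of a permanent forest grid
sampled by the point-centred-quarter method: around each grid stake the
nearest tree in each of four compass quadrants is recorded (species,
distance, dbh), separately for mature trees (dbh ≥ 10 cm) and saplings
(dbh < 10 cm). Stakes are grouped into fishnet cells, and cells are the
statistical sample units throughout.

## Community measures

For a cell *i* containing *m_i* sampled stakes in a period:

* **occurrence** of species *j*: fraction of the cell's sampled stakes at
  which *j* was recorded (the per-cell testing unit; "percentage of cells
  occupied" is exposed separately as a display summary);
* **relative abundance**: individuals of *j* ÷ all individuals in the cell;
* **basal area**: Σ π(dbh/2)² over trees of *j*, divided by *m_i* (cm² per
  sampled stake — a sampling-effort-stable quantity; a per-tree mean was
  the rejected alternative, as it confounds composition change with stem
  size).

Taxon pooling (e.g. a hybrid pooled into its parent species) is applied
first; species occurring at fewer than 1% of all surveyed stakes (both
periods pooled, cohorts combined) are then dropped, so the retained species
set is identical for every period and cohort.

### Fishnet construction

The stake lattice is covered by equal, axis-aligned, half-open rectangles.
The search scores every candidate (mesh size × origin offset): first the
number of cells holding at least `min_points` (default 10) stakes, then the
mean stakes per qualifying cell, then smaller mesh area, with a fixed
candidate order as the final deterministic tie-break. Only qualifying cells
are kept and the same fishnet serves both periods. On a perfectly regular
lattice this objective favours many exactly-minimal cells; when the
subsampling step should have stakes to leave out, pass the intended mesh
explicitly (the `simulate` command writes the generator's own mesh into the
analysis config for this reason).

## Subsampled significance testing

Cells hold unequal numbers of stakes, so every test is wrapped in a
subsampling loop: per replicate, draw *n* = 10 stakes without replacement
from each cell, recompute the per-cell statistic for both periods, run the
test, and record its p-value; after *r* = 1,000 replicates (configurable)
the mean of the p-value distribution is reported, with its 2.5/50/97.5%
quantiles as diagnostics. Species and guild change use the two-sided paired
Wilcoxon signed-rank test (exact null for ≤ 25 untied nonzero differences,
else the tie- and continuity-corrected normal approximation; zero
differences dropped; an all-zero replicate contributes p = 1 so the
distribution keeps length *r*). Community-trait change uses the paired *t*
test, with the community-weighted mean recomputed inside every replicate.

Pairing draws the *same* stake ids in both periods by default
(`matched_points`): stakes are the shared physical units of a resurvey.
An `independent` mode draws separately per period. Replicate *k* uses the
*k*-th child stream of the master seed, and each cell's draw stream is
keyed by a digest of its cell id, so results are invariant to cell ordering
and the first *k* replicates do not change when *r* grows.

Averaging p-values is deliberately conservative as a decision statistic:
under the null the mean of r replicate p-values concentrates near 0.5, so
"mean p < 0.05" rejects less often than a single exact test would.

## β-diversity machinery

All multivariate analyses use the Hellinger transform
y′_ij = √(y_ij / Σ_j y_ij) and Euclidean distances on transformed rows
(bounded by √2).

* **Dispersion (homogenization) test** — site distances to their period
  centroid are computed in principal-coordinate space, subtracting squared
  components on negative-eigenvalue axes and clamping at zero (the
  betadisper convention; centroids, not spatial medians). The one-way
  ANOVA F on those distances is compared with its distribution under
  permutation of period labels of the distances — with a single factor
  this matches permutation of residuals. A decline in mean distance from
  the first to the second period is reported as homogenization, an
  increase as differentiation.
* **PERMANOVA** — SS_total = (1/N)Σ_{i<j} d²_ij, within-group sums
  analogously, pseudo-F = (SS_B/(a−1))/(SS_W/(N−a)), free permutation of
  site labels. The temporal pairing of cells across periods is *not*
  encoded as permutation strata (mirroring common practice); output
  metadata carries this caveat.
* Both tests use p = (1 + #{F\* ≥ F})/(1 + n_perm) (never exactly zero),
  count ties as exceedances, and expose an exhaustive-enumeration mode
  that scores every distinct two-group assignment and returns the exact
  exceedance fraction; `method="auto"` enumerates when the assignment
  count is small.
* **LCBD/SCBD** — with s_ij = (y′_ij − ȳ′_j)², SS_total = ΣΣ s_ij equals
  (1/n)Σ_{i<j} d²_ij (verified internally on every call); LCBD_i and
  SCBD_j are the row and column shares. ΔLCBD_i = LCBD_i(T2) − LCBD_i(T1)
  is emitted with cell centroids for mapping and always sums to zero.
* **Replacement / richness-difference decomposition** — per site pair,
  with A the summed shared abundance and B, C the unshared parts,
  D = (B+C)/(2A+B+C); the Podani split (default) is Repl = 2·min(B,C) and
  RichDiff = |B−C| over the same denominator, the Baselga split
  (`family="baselga"`) uses min(B,C)/(A+min(B,C)) and its complement. On
  row-normalised (compositional) input B − C ≡ 0, so the quantitative
  richness-difference term vanishes identically; the pipeline therefore
  reports the presence–absence decomposition alongside.

## Traits

Species carry shade, drought and waterlogging tolerance (ordinal 1–5),
seed mass (mg, analysed as its natural log — base unspecified in common
usage, ln chosen), and a temperature preference (°C) computable as the
mean of a gridded mean-annual-temperature surface sampled at occurrence
points by nearest-cell lookup (no interpolation: a ~1 km² climate grid is
coarser than typical occurrence precision). Climate surfaces are read from
plain-text ESRI-style ASCII grids.

CWM_i = Σ_j p_ij t_j / Σ_j p_ij over species with a non-missing trait
value; missing traits renormalise the weights (no imputation), and the
contributing-mass fraction is logged. Guild-level change sums member
species' per-cell values before any normalisation, so the guild statistic
equals the sum of member columns. "Species contributions to trait change"
is formalised as the SCBD of the contribution matrix x_ij = p_ij·t_j
(weights renormalised over trait-scored species), per period, with the
change in shares reported — the quantity is named but not defined in the
source literature for this analysis style, and this definition is recorded
in output metadata.

## Synthetic resurvey generator

The generator defines the study conditions used by every calibration and
power experiment. Defaults: a 12-row × 20-stake lattice (50 m within rows,
100 m between rows — 240 stakes), grouped by a 200 × 300 m mesh into 20
cells of 12 stakes; tree density 0.035 m⁻² (mature) and 0.05 m⁻²
(saplings), realistic for temperate closed forest and giving
nearest-tree distances of a few metres; dbh lognormal(μ=3.2, σ=0.5)
truncated to ≥ 10 cm for mature stems and lognormal(μ=1.2, σ=0.5) on
(0, 10) cm for saplings.

Species composition varies across the landscape as a log-intensity field
with two parts: an iid **patch-mosaic** component per (species, 200 × 300 m
block) with σ = 0.8 — the upland/lowland mosaic that makes neighbouring
cells genuinely different — plus a fine smooth random-Fourier field
(length scale 25 m, σ = 0.4) for within-patch microsite variation. This
structure was chosen so that, under the null, cells are independent and
identically distributed: free-permutation tests are then calibrated by
construction, while between-cell heterogeneity stays large enough for
homogenization to be detectable. A single smooth field cannot do both — a
coarse field correlates neighbouring cells (inflating PERMANOVA's type-I
error), and a fine field alone leaves too little between-cell signal.

Scenarios transform the period-2 surfaces:

* **null** — independent redraw of the same process (both periods
  exchangeable; "identical process", not identical realisation);
* **homogenization** — the period-2 draw is shrunk toward its regional
  mean profile by λ; **differentiation** inflates deviations by 1 + λ;
  **turnover** mixes in a per-block cyclic relabelling of species with
  weight λ (preserving totals and local diversity). All three reduce
  bit-for-bit to the null at λ = 0.
* **abundance_shift** — target species' period-1 intensities are
  multiplied (others renormalised); **trait_shift** — period-1 weights are
  exponentially tilted per stake (solved by Brent's method in log space)
  so the community mean of a target trait moves by exactly δ. These two
  anchor period 2 to the period-1 surfaces so the injected effect is
  recoverable against sampling noise alone. Because a weighted mean cannot
  pass the most extreme species trait, per-stake tilt targets are clipped
  into the attainable range (0.1% margin); a shift that is more than 90%
  unreachable at some stake raises a configuration error.

Sampling realises trees as a marked Poisson process in a 25 m disc around
each start point (quadrant capture beyond that is negligible at these
densities) and records the nearest tree per quadrant and cohort; empty
quadrants yield no record, mirroring missing corners in field data. The
historical protocol's start-point offset (mean 7.41 m from the stake,
period 1 only) has one observable consequence at analysis scale — the two
periods sample different individuals around the same stake — which the
independent per-period realisation reproduces directly; an explicit
geometric offset would be invisible because the Poisson process is
translation-invariant and composition is evaluated at the stake.

The species pool draws shade and drought tolerance from a Gaussian copula
with correlation −ρ (default 0.5; shade-tolerant species tend to be
drought-intolerant), using stratified (Latin-hypercube) quantiles so every
pool spans the full 1–5 scale; waterlogging is independent, seed mass
log-normal around 20 mg, and temperature preference centres on the guild
(northern 5.0 °C, central 7.5 °C, carolinian 9.5 °C). Guild mix defaults
to 50/30/20% with dominance weights 2/1/0.5, reflecting a northern-
dominated stand with comparatively rare Carolinian species.

### What passing tests do and do not show

The generator has no demography (no persistent tree identities, growth or
mortality), no dispersal, and patch boundaries aligned with the default
mesh; its cells are exchangeable under the null by construction. Passing
calibration therefore shows the *test machinery* is correct, not that real
resurvey data satisfy exchangeability — real cells are spatially
autocorrelated and temporally paired, and the PERMANOVA caveat above
applies doubly there.

## Problem sizes and numerical choices

Calibration experiments run 200 null datasets (20 cells × 12 stakes,
mature cohort, 999 permutations per test); homogenization recovery runs
100 datasets at λ = 0.8; trait-shift recovery 50 datasets at δ = +0.5.
These sizes put the Monte-Carlo error of a rejection-rate estimate near
±0.03 while a full run stays in the minutes range. Eigenvalues within
1e−9·max|λ| of zero are treated as null axes in PCoA; permutation-F ties
are counted as exceedances with a 1e−12 float guard; distance matrices are
validated (symmetry, zero diagonal, non-negativity) on construction;
Hellinger input with a zero-sum row, an all-identical community matrix
(LCBD undefined), and a pair of empty sites (D undefined) raise errors
naming the offending cells rather than returning NaN.

## Known limitations

Occurrence-denominator stakes are inferred from records, so a stake
sampled but yielding zero trees (possible at very low density) is
invisible; the rarity screen is applied to cohorts jointly (the
per-cohort alternative remains an open choice); LCBD significance testing,
multi-factor PERMANOVA, other distance measures, density estimators of the
Cottam–Curtis family, and GeoTIFF climate input are out of scope.
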