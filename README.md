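# resurvey

Temporal β-diversity and community-trait analysis of resurveyed
point-centred-quarter forest grids.

Permanent stake grids sampled by the point-quarter method — the nearest
tree per compass quadrant around each stake, with species, distance and
dbh — are a classic way to monitor forests, and many such "legacy" grids
have now been resurveyed decades later. `resurvey` is a toolkit for asking,
from two such surveys, the questions community ecologists care about:

* Which species and range-based guilds (northern / central / Carolinian)
  changed in occurrence, relative abundance or basal area, treating mature
  trees (dbh ≥ 10 cm) and saplings (< 10 cm) as separate cohorts?
* Did the community homogenize (β-diversity decline) or differentiate, and
  did composition shift?
* Where did the change happen (which cells became more or less unique),
  and which species drove it?
* Did community-weighted trait means (shade/drought/waterlogging
  tolerance, seed mass, temperature preference) shift?

## Statistical core

Stakes are grouped into fishnet cells (≥ 10 stakes each); cells are the
sample units. Because cells hold unequal numbers of stakes, **every test
is subsampled**: per replicate, draw n = 10 stakes without replacement per
cell, recompute the per-cell statistic in both periods, run the paired
test, and keep its p-value; over r replicates the mean p-value is
reported. Species/guild change uses the paired Wilcoxon signed-rank test;
trait change uses the paired *t* test on community-weighted means
CWM_i = Σ_j p_ij t_j / Σ_j p_ij.

Multivariate change works on Hellinger-transformed abundances
y′_ij = √(y_ij/Σ_j y_ij) and their Euclidean (Hellinger) distances d_ij:

* homogeneity-of-dispersions test (betadisper-style): site distances z_i
  to the period centroid in principal-coordinate space, permutation F
  test; declining dispersion ⇒ biotic homogenization;
* PERMANOVA pseudo-F on the same distances for composition change;
* β-diversity partition: with s_ij = (y′_ij − ȳ′_j)², SS_total = ΣΣ s_ij,
  LCBD_i = Σ_j s_ij / SS_total (site uniqueness, mapped as
  ΔLCBD = LCBD_T2 − LCBD_T1) and SCBD_j = Σ_i s_ij / SS_total;
* pairwise dissimilarity split into replacement and richness-difference
  components (Podani or Baselga family).

Both permutation tests also provide exhaustive enumeration over all label
assignments for small designs. A bundled synthetic resurvey generator
(stake lattice, patch-mosaic composition surfaces, marked-Poisson
point-quarter sampling, scenarios for turnover, homogenization,
differentiation, abundance and trait shifts) drives calibration and power
experiments with no external data. See `docs/methods.md` for the model
details and assumptions.

## Worked example

Simulate a resurvey in which period-2 cell compositions are shrunk 60%
toward the regional mean (biotic homogenization), then analyse it:

```sh
resurvey simulate --scenario homogenization --effect 0.6 --seed 3 --out demo
resurvey analyze --config demo/config.yaml
```

which prints

```
analysis complete: demo/analysis/manifest.json
  mature: dispersion p=0.0010 (homogenization), PERMANOVA p=0.0850
  sapling: dispersion p=0.0010 (homogenization), PERMANOVA p=0.0150
```

The injected dispersion decline is detected in both cohorts (permutation
p = .001 with the homogenization direction), while composition change is
clear only for saplings. `demo/analysis/` then holds the full report:
community matrices per measure/cohort/period, subsampled test tables,
β-diversity results, LCBD/SCBD/ΔLCBD tables with cell coordinates, PCoA
coordinates, CWM tables and a run manifest. For example, the sapling
guild-level subsampled Wilcoxon tests (`tests_guilds.csv`, r = 50 here):

```
species_or_group            measure   mean_p     q025     q975  effect_sign
        northern         occurrence 0.181047 0.043370 0.351991            1
         central         occurrence 0.052947 0.013269 0.167325            1
      carolinian         occurrence 0.363273 0.106877 0.826388            1
        northern relative_abundance 0.737908 0.520635 0.983642           -1
         central relative_abundance 0.245525 0.098527 0.470324            1
      carolinian relative_abundance 0.767205 0.429333 0.993295           -1
```

`mean_p` is the mean of the 50 replicate p-values (the reporting
statistic), `q025`/`q975` bound the p-value distribution, and
`effect_sign` is the sign of the median period-2 minus period-1 change —
here no guild shifts significantly, as expected: homogenization moves
cells toward the mean without favouring a guild. `beta_results.json`
carries the corresponding multivariate summary, e.g. for saplings
dispersion F = 28.15, p = .001 (direction homogenization, subsampled mean
p = .010) and PERMANOVA F = 1.88, R² = 0.047, p = .015.

Calibration experiments run from the same CLI:

```sh
resurvey calibrate --scenario homogenization --effects 0,0.4,0.8 \
    --reps 50 --seed 1 --out rates.csv
```

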