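"""Subsampled significance testing for unevenly sampled cells.

Fishnet cells contain different numbers of sampled stakes, so a direct test
across cells would weight sampling effort unevenly. The engine equalises
effort by repeating, ``r`` times: (a) draw ``n`` stakes without replacement
from every cell, for both survey periods; (b) compute the per-cell
statistic on the drawn stakes; (c) run the paired test across cells;
(d) record the p-value. The reported statistic is the mean of the ``r``
p-values, with the 2.5/50/97.5 percent quantiles of the distribution kept
for diagnostics.

With ``pairing="matched_points"`` (default) each replicate draws one set of
stake ids per cell and uses it in both periods — stakes are the shared
physical units of the resurvey; ``pairing="independent"`` draws separately
from each period's sampled stakes.

Replicate k draws from the k-th child stream of the master seed, so results
for the first k replicates do not depend on ``r``.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from typing import Callable, NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from .survey import ConfigError, Fishnet, ValidationError, sampled_points

PAIRINGS = ("matched_points", "independent")


@dataclass(frozen=True)
class SubsampleSpec:
    """Parameters of the subsampling procedure."""
    n: int = 10          # stakes drawn per cell, without replacement
    r: int = 1000        # replicates
    seed: int | None = None
    pairing: str = "matched_points"

    def __post_init__(self):
        if self.n < 1:
            raise ConfigError("subsample size n must be >= 1")
        if self.r < 1:
            raise ConfigError("replicate count r must be >= 1")
        if self.pairing not in PAIRINGS:
            raise ConfigError(f"pairing must be one of {PAIRINGS}")


@dataclass
class PValueDistribution:
    """The r replicate p-values of a subsampled test."""
    p_values: np.ndarray
    mean_diffs: np.ndarray   # per-replicate mean paired difference (T2 - T1)
    n: int
    r: int
    seed: int | None
    test: str

    def __post_init__(self):
        p = np.asarray(self.p_values, float)
        if np.any((p < 0) | (p > 1)):
            raise ValidationError("p-values must lie in [0, 1]")
        self.p_values = p

    @property
    def mean_p(self) -> float:
        return float(self.p_values.mean())

    @property
    def quantiles(self) -> dict:
        q = np.quantile(self.p_values, [0.025, 0.5, 0.975])
        return {"q025": float(q[0]), "q500": float(q[1]), "q975": float(q[2])}

    @property
    def effect_sign(self) -> int:
        """Sign of the median across replicates of the mean T2 - T1 change."""
        return int(np.sign(np.median(self.mean_diffs)))

    def summary_row(self) -> dict:
        row = {"mean_p": self.mean_p, **self.quantiles,
               "effect_sign": self.effect_sign, "n": self.n, "r": self.r,
               "seed": self.seed, "test": self.test}
        return row


# ---------------------------------------------------------------------------
# paired tests


def paired_wilcoxon(x, y) -> float:
    """Two-sided Wilcoxon signed-rank p-value for paired samples.

    Zero differences are dropped (classical Wilcoxon treatment); if all
    differences are zero the test is undefined and p = 1 is returned. The
    exact null distribution is used for up to 25 nonzero, untied absolute
    differences, otherwise the normal approximation with tie and continuity
    corrections.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.size < 1:
        raise ValidationError("paired samples must have equal length >= 1")
    d = y - x
    d = d[d != 0]
    if d.size == 0:
        return 1.0
    has_ties = np.unique(np.abs(d)).size < d.size
    method = "exact" if (d.size <= 25 and not has_ties) else "approx"
    res = stats.wilcoxon(d, zero_method="wilcox", correction=True,
                         alternative="two-sided", method=method)
    return float(min(res.pvalue, 1.0))


def paired_t(x, y) -> float:
    """Two-sided paired Student t p-value on the mean difference.

    Degenerate case: if the differences have zero variance the p-value is 1
    when their mean is zero and 0 (a flagged certainty) otherwise.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.size < 2:
        raise ValidationError("paired t needs equal lengths >= 2")
    d = y - x
    if np.ptp(d) == 0:
        return 1.0 if d[0] == 0 else 0.0
    return float(stats.ttest_rel(y, x).pvalue)


TESTS: dict[str, Callable] = {"paired_wilcoxon": paired_wilcoxon,
                              "paired_t": paired_t}


# ---------------------------------------------------------------------------
# subsampling machinery


class CellRecords(NamedTuple):
    """One cell-period slice of the survey as flat arrays."""
    point_id: np.ndarray
    species: np.ndarray
    dbh_cm: np.ndarray


def _cell_slices(records: pd.DataFrame, fishnet: Fishnet, period: str
                 ) -> dict[str, CellRecords]:
    p2c = fishnet.point_to_cell()
    sub = records[records["period"] == period]
    sub = sub[sub["point_id"].isin(p2c)]
    cells = {cid: CellRecords(np.empty(0, object), np.empty(0, object),
                              np.empty(0))
             for cid in fishnet.cell_ids}
    for cid, grp in sub.groupby(sub["point_id"].map(p2c)):
        cells[cid] = CellRecords(grp["point_id"].to_numpy(),
                                 grp["species"].to_numpy(),
                                 grp["dbh_cm"].to_numpy(float))
    return cells


def _cell_point_sets(records, fishnet, period):
    pts = sampled_points(records, period)
    return {c.cell_id: np.array(sorted(set(c.point_ids) & pts))
            for c in fishnet.cells}


def _cell_rng(child: np.random.SeedSequence, cell_id: str
              ) -> np.random.Generator:
    """Replicate x cell stream keyed by the cell id, not by cell order.

    Keying on a digest of the id makes every per-cell draw — and hence the
    whole p-value distribution — invariant to the ordering of cells.
    """
    key = int.from_bytes(
        hashlib.blake2s(str(cell_id).encode(), digest_size=4).digest(), "big")
    return np.random.default_rng(np.random.SeedSequence(
        entropy=child.entropy, spawn_key=child.spawn_key + (key,)))


def subsample_test(records_t1: pd.DataFrame, records_t2: pd.DataFrame,
                   fishnet: Fishnet,
                   statistic: Callable[[CellRecords, np.ndarray], float],
                   test: str | Callable, spec: SubsampleSpec,
                   *, period_t1: str | None = None,
                   period_t2: str | None = None) -> PValueDistribution:
    """Run the subsampled paired test and collect the p-value distribution.

    ``statistic(cell_records, drawn_points) -> float`` computes the per-cell
    value from the cell's records restricted to the drawn stakes.
    ``records_t1``/``records_t2`` may be the same frame (periods are
    distinguished by their ``period`` column; pass ``period_t1``/``_t2`` to
    disambiguate when a frame holds several periods).
    """
    test_name = test if isinstance(test, str) else test.__name__
    test_fn = TESTS[test] if isinstance(test, str) else test
    p1 = period_t1 or sorted(records_t1["period"].unique())[0]
    p2 = period_t2 or sorted(records_t2["period"].unique())[-1]
    if p1 == p2:
        raise ValidationError("the two record sets are a single period")

    pts1 = _cell_point_sets(records_t1, fishnet, p1)
    pts2 = _cell_point_sets(records_t2, fishnet, p2)
    slices1 = _cell_slices(records_t1, fishnet, p1)
    slices2 = _cell_slices(records_t2, fishnet, p2)

    cell_ids = fishnet.cell_ids
    pools: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for cid in cell_ids:
        if spec.pairing == "matched_points":
            common = np.array(sorted(set(pts1[cid]) & set(pts2[cid])))
            if common.size < spec.n:
                raise ValidationError(
                    f"cell {cid}: {common.size} stakes sampled in both "
                    f"periods, need n={spec.n}")
            pools[cid] = (common, common)
        else:
            for pool, p in ((pts1[cid], p1), (pts2[cid], p2)):
                if pool.size < spec.n:
                    raise ValidationError(
                        f"cell {cid}: {pool.size} stakes sampled in period "
                        f"{p}, need n={spec.n}")
            pools[cid] = (pts1[cid], pts2[cid])

    children = np.random.SeedSequence(spec.seed).spawn(spec.r)
    p_values = np.empty(spec.r)
    mean_diffs = np.empty(spec.r)
    for k in range(spec.r):
        x = np.empty(len(cell_ids))
        y = np.empty(len(cell_ids))
        for i, cid in enumerate(cell_ids):
            rng = _cell_rng(children[k], cid)
            pool1, pool2 = pools[cid]
            draw1 = rng.choice(pool1, size=spec.n, replace=False)
            if spec.pairing == "matched_points":
                draw2 = draw1
            else:
                draw2 = rng.choice(pool2, size=spec.n, replace=False)
            x[i] = statistic(slices1[cid], draw1)
            y[i] = statistic(slices2[cid], draw2)
        p_values[k] = test_fn(x, y)
        mean_diffs[k] = (y - x).mean()
    return PValueDistribution(p_values=p_values, mean_diffs=mean_diffs,
                              n=spec.n, r=spec.r, seed=spec.seed,
                              test=test_name)


def subsample_multivariate(records_t1: pd.DataFrame, records_t2: pd.DataFrame,
                           fishnet: Fishnet,
                           analysis: Callable[[pd.DataFrame, pd.DataFrame],
                                              float],
                           spec: SubsampleSpec,
                           matrix_builder: Callable[[pd.DataFrame,
                                                     np.ndarray, str],
                                                    pd.DataFrame],
                           *, period_t1: str | None = None,
                           period_t2: str | None = None
                           ) -> PValueDistribution:
    """Subsampled version of a whole-community (multivariate) test.

    ``matrix_builder(records, drawn_points, period)`` must return the
    cells x species matrix computed on the drawn stakes only, and
    ``analysis(matrix_t1, matrix_t2) -> p`` runs the test (e.g. dispersion
    or PERMANOVA on Hellinger distances of the stacked matrices).
    """
    p1 = period_t1 or sorted(records_t1["period"].unique())[0]
    p2 = period_t2 or sorted(records_t2["period"].unique())[-1]
    pts1 = _cell_point_sets(records_t1, fishnet, p1)
    pts2 = _cell_point_sets(records_t2, fishnet, p2)
    cell_ids = fishnet.cell_ids
    for cid in cell_ids:
        pool = (set(pts1[cid]) & set(pts2[cid])
                if spec.pairing == "matched_points" else None)
        size = len(pool) if pool is not None else min(pts1[cid].size,
                                                      pts2[cid].size)
        if size < spec.n:
            raise ValidationError(f"cell {cid}: {size} usable stakes, "
                                  f"need n={spec.n}")

    children = np.random.SeedSequence(spec.seed).spawn(spec.r)
    p_values = np.empty(spec.r)
    for k in range(spec.r):
        draws1 = {}
        draws2 = {}
        for cid in cell_ids:
            rng = _cell_rng(children[k], cid)
            if spec.pairing == "matched_points":
                pool = np.array(sorted(set(pts1[cid]) & set(pts2[cid])))
                draws1[cid] = draws2[cid] = rng.choice(pool, spec.n,
                                                       replace=False)
            else:
                draws1[cid] = rng.choice(pts1[cid], spec.n, replace=False)
                draws2[cid] = rng.choice(pts2[cid], spec.n, replace=False)
        flat1 = np.concatenate([draws1[c] for c in cell_ids])
        flat2 = np.concatenate([draws2[c] for c in cell_ids])
        m1 = matrix_builder(records_t1, flat1, p1)
        m2 = matrix_builder(records_t2, flat2, p2)
        p_values[k] = analysis(m1, m2)
    return PValueDistribution(p_values=p_values,
                              mean_diffs=np.zeros(spec.r), n=spec.n,
                              r=spec.r, seed=spec.seed, test="multivariate")


# ---------------------------------------------------------------------------
# per-cell statistics


def species_statistic(species: str, measure: str
                      ) -> Callable[[CellRecords, np.ndarray], float]:
    """Per-cell statistic for one species under one measure."""
    return group_statistic((species,), measure)


def group_statistic(species_group, measure: str
                    ) -> Callable[[CellRecords, np.ndarray], float]:
    """Per-cell statistic for a set of species (e.g. a guild).

    Guild values are member-species values summed before any normalisation:
    occurrence counts stakes where any member occurs per member species,
    relative abundance is the summed member share of all individuals, and
    basal area is the summed member basal area per drawn stake.
    """
    group = set(species_group)

    def stat(cell: CellRecords, pts: np.ndarray) -> float:
        at = np.isin(cell.point_id, pts)
        member = at & np.isin(cell.species, list(group))
        if measure == "occurrence":
            total = 0.0
            for sp in group:
                total += len(set(cell.point_id[at & (cell.species == sp)]))
            return total / len(pts)
        if measure == "relative_abundance":
            n_all = int(at.sum())
            return member.sum() / n_all if n_all else 0.0
        if measure == "basal_area":
            d = cell.dbh_cm[member]
            return float(np.pi * ((d / 2.0) ** 2).sum() / len(pts))
        raise ConfigError(f"unknown measure {measure!r}")

    return stat
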