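"""Hellinger-distance beta-diversity machinery.

The analyses here all start from a cells x species abundance matrix Y:

* Hellinger transform ``y'_ij = sqrt(y_ij / sum_j y_ij)`` and the Euclidean
  (= Hellinger) distance matrix on the transformed rows, bounded by sqrt(2);
* principal coordinates analysis (PCoA) of a distance matrix;
* the multivariate homogeneity-of-dispersions test (betadisper-style): site
  distances to their group centroid in principal-coordinate space, compared
  between periods with a permutation F test — a decline in dispersion over
  time is biotic homogenization, an increase is differentiation;
* PERMANOVA (adonis-style pseudo-F on squared dissimilarities);
* the partition of the total community sum of squares into Local (per site,
  LCBD) and Species (per species, SCBD) Contributions to beta diversity;
* the pairwise decomposition of dissimilarity into replacement and
  richness/abundance-difference components (Podani or Baselga family).

Both permutation tests expose an exhaustive-enumeration mode that evaluates
every distinct assignment of sites to groups; for the sampled mode the
p-value convention is ``(1 + #{F* >= F}) / (1 + n_perm)``.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .survey import ConfigError, ValidationError

HELLINGER_MAX = math.sqrt(2.0)
_EIG_TOL = 1e-9


@dataclass(frozen=True)
class DissimilarityMatrix:
    """Symmetric non-negative dissimilarities with a zero diagonal."""
    labels: tuple
    data: np.ndarray

    def __post_init__(self):
        d = np.asarray(self.data, float)
        if d.shape != (len(self.labels), len(self.labels)):
            raise ValidationError("distance matrix shape does not match labels")
        if not np.allclose(d, d.T, atol=1e-12):
            raise ValidationError("distance matrix is not symmetric")
        if np.any(np.diag(d) != 0):
            raise ValidationError("distance matrix diagonal must be zero")
        if np.any(d < 0):
            raise ValidationError("distances must be non-negative")
        object.__setattr__(self, "data", d)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.data, index=list(self.labels),
                            columns=list(self.labels))


def hellinger_transform(values: pd.DataFrame) -> pd.DataFrame:
    """Row-wise Hellinger transform; each output row has unit 2-norm."""
    v = values.to_numpy(float)
    sums = v.sum(axis=1)
    if np.any(sums <= 0):
        bad = [str(values.index[i]) for i in np.flatnonzero(sums <= 0)]
        raise ValidationError(f"zero-sum rows (cells): {bad}")
    out = np.sqrt(v / sums[:, None])
    return pd.DataFrame(out, index=values.index, columns=values.columns)


def distance_matrix(transformed: pd.DataFrame) -> DissimilarityMatrix:
    """Euclidean distances between transformed rows (Hellinger distance)."""
    d = squareform(pdist(transformed.to_numpy(float), metric="euclidean"))
    return DissimilarityMatrix(labels=tuple(transformed.index), data=d)


# ---------------------------------------------------------------------------
# PCoA


@dataclass
class PcoaResult:
    eigenvalues: np.ndarray            # descending, full spectrum
    coordinates: pd.DataFrame          # sites x axes (positive axes only)
    proportion_explained: np.ndarray   # per retained axis
    negative_eigenvalues: np.ndarray


def _gower_eig(d: np.ndarray):
    """Eigendecomposition of the Gower-centred matrix -1/2 J D^2 J."""
    n = d.shape[0]
    a = -0.5 * d ** 2
    row = a.mean(axis=1, keepdims=True)
    g = a - row - row.T + a.mean()
    vals, vecs = np.linalg.eigh(g)
    order = np.argsort(vals)[::-1]
    return vals[order], vecs[:, order]


def pcoa(dm: DissimilarityMatrix) -> PcoaResult:
    """Principal coordinates of a dissimilarity matrix.

    Axes with eigenvalue above tolerance are scaled by sqrt(eigenvalue);
    negative eigenvalues are reported but their axes are excluded from the
    returned coordinates.
    """
    vals, vecs = _gower_eig(dm.data)
    tol = _EIG_TOL * max(1.0, float(np.abs(vals).max(initial=0.0)))
    keep = vals > tol
    coords = vecs[:, keep] * np.sqrt(vals[keep])
    pos_sum = vals[keep].sum()
    prop = vals[keep] / pos_sum if pos_sum > 0 else vals[keep]
    cols = [f"PCoA{i + 1}" for i in range(keep.sum())]
    return PcoaResult(
        eigenvalues=vals,
        coordinates=pd.DataFrame(coords, index=list(dm.labels), columns=cols),
        proportion_explained=prop,
        negative_eigenvalues=vals[vals < -tol])


# ---------------------------------------------------------------------------
# dispersion (homogenization) test


@dataclass
class DispersionResult:
    z: pd.Series                  # per-site distance to its group centroid
    group_means: pd.Series
    F: float
    p_perm: float
    n_perm: int
    method: str
    direction: str                # homogenization / differentiation / none
    period_order: tuple


def _anova_f(z: np.ndarray, codes: np.ndarray, n_groups: int) -> float:
    n = z.size
    grand = z.mean()
    ssb = 0.0
    ssw = 0.0
    for g in range(n_groups):
        zg = z[codes == g]
        ssb += zg.size * (zg.mean() - grand) ** 2
        ssw += ((zg - zg.mean()) ** 2).sum()
    if ssw <= 0:
        return 0.0 if ssb <= 0 else math.inf
    return (ssb / (n_groups - 1)) / (ssw / (n - n_groups))


def _resolve_groups(labels, groups, period_order):
    groups = np.asarray([str(g) for g in groups])
    if len(groups) != len(labels):
        raise ValidationError("group labels length mismatch")
    if period_order is None:
        period_order = tuple(sorted(set(groups)))
    codes = np.array([period_order.index(g) for g in groups])
    return codes, tuple(period_order)


def dispersion_test(dm: DissimilarityMatrix, groups, n_perm: int = 9999,
                    seed=None, method: str = "auto",
                    period_order=None) -> DispersionResult:
    """Permutation test for homogeneity of multivariate dispersions.

    Site distances to their period centroid are computed in the full
    principal-coordinate space, subtracting squared components on
    negative-eigenvalue axes (clamped at zero). The observed one-way ANOVA F
    on those distances is compared with its distribution under permutation
    of the period labels. With ``method="exhaustive"`` (or ``"auto"`` on
    small problems) every distinct two-group assignment is enumerated and
    the p-value is the exact exceedance fraction.
    """
    if n_perm < 1:
        raise ConfigError("n_perm must be >= 1")
    codes, period_order = _resolve_groups(dm.labels, groups, period_order)
    n_groups = len(period_order)
    counts = np.bincount(codes, minlength=n_groups)
    if np.any(counts < 2):
        raise ValidationError("each period needs >= 2 sites")

    vals, vecs = _gower_eig(dm.data)
    tol = _EIG_TOL * max(1.0, float(np.abs(vals).max(initial=0.0)))
    pos = vals > tol
    neg = vals < -tol
    cpos = vecs[:, pos] * np.sqrt(vals[pos])
    cneg = vecs[:, neg] * np.sqrt(-vals[neg])

    z = np.empty(len(codes))
    for g in range(n_groups):
        m = codes == g
        dp = ((cpos[m] - cpos[m].mean(axis=0)) ** 2).sum(axis=1)
        dn = ((cneg[m] - cneg[m].mean(axis=0)) ** 2).sum(axis=1) \
            if cneg.shape[1] else 0.0
        z[m] = np.sqrt(np.clip(dp - dn, 0.0, None))

    f_obs = _anova_f(z, codes, n_groups)
    p, method_used, n_used = _permutation_p(
        lambda c: _anova_f(z, c, n_groups), f_obs, codes, n_groups,
        n_perm, seed, method)

    gm = pd.Series({period_order[g]: z[codes == g].mean()
                    for g in range(n_groups)})
    delta = gm.iloc[-1] - gm.iloc[0]
    direction = ("none" if delta == 0 else
                 "homogenization" if delta < 0 else "differentiation")
    return DispersionResult(
        z=pd.Series(z, index=list(dm.labels), name="dist_to_centroid"),
        group_means=gm, F=f_obs, p_perm=p, n_perm=n_used,
        method=method_used, direction=direction, period_order=period_order)


def _permutation_p(f_of_codes, f_obs, codes, n_groups, n_perm, seed, method):
    """Shared permutation/enumeration machinery for label-permutation tests."""
    n = codes.size
    n_exhaustive = None
    if n_groups == 2:
        n_exhaustive = math.comb(n, int((codes == 0).sum()))
    if method == "auto":
        use_exh = n_exhaustive is not None and n_exhaustive <= min(n_perm, 10000)
    elif method == "exhaustive":
        if n_exhaustive is None:
            raise ConfigError("exhaustive mode requires exactly 2 groups")
        use_exh = True
    elif method == "permutation":
        use_exh = False
    else:
        raise ConfigError(f"unknown method {method!r}")

    eps = 1e-12
    if use_exh:
        n0 = int((codes == 0).sum())
        count = 0
        for comb in itertools.combinations(range(n), n0):
            c = np.ones(n, dtype=int)
            c[list(comb)] = 0
            if f_of_codes(c) >= f_obs - eps:
                count += 1
        return count / n_exhaustive, "exhaustive", n_exhaustive
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        c = rng.permutation(codes)
        if f_of_codes(c) >= f_obs - eps:
            count += 1
    return (1 + count) / (1 + n_perm), "permutation", n_perm


# ---------------------------------------------------------------------------
# PERMANOVA


@dataclass
class PermanovaResult:
    F: float
    r2: float
    p_perm: float
    n_perm: int
    method: str
    ss_between: float
    ss_within: float
    ss_total: float


def _permanova_f(d2: np.ndarray, codes: np.ndarray, n_groups: int,
                 ss_total: float):
    n = d2.shape[0]
    ssw = 0.0
    for g in range(n_groups):
        idx = np.flatnonzero(codes == g)
        if idx.size == 0:
            raise ValidationError("empty group in PERMANOVA")
        ssw += d2[np.ix_(idx, idx)].sum() / (2.0 * idx.size)
    ssb = ss_total - ssw
    if ssw <= 0:
        f = 0.0 if ssb <= 0 else math.inf
    else:
        f = (ssb / (n_groups - 1)) / (ssw / (n - n_groups))
    return f, ssb, ssw


def permanova(dm: DissimilarityMatrix, groups, n_perm: int = 9999,
              seed=None, method: str = "auto",
              period_order=None) -> PermanovaResult:
    """One-factor PERMANOVA on a dissimilarity matrix.

    ``SS_total = (1/N) sum_{i<j} d_ij^2``; within-group sums of squares are
    computed analogously per group, and the pseudo-F ratio is compared with
    its permutation distribution under free relabelling of sites (no pairing
    strata; the temporal pairing of cells is a caveat recorded by callers).
    """
    if n_perm < 1:
        raise ConfigError("n_perm must be >= 1")
    codes, period_order = _resolve_groups(dm.labels, groups, period_order)
    n_groups = len(period_order)
    if n_groups < 2:
        raise ValidationError("PERMANOVA needs >= 2 groups")
    d2 = dm.data ** 2
    n = d2.shape[0]
    ss_total = d2.sum() / (2.0 * n)
    f_obs, ssb, ssw = _permanova_f(d2, codes, n_groups, ss_total)

    p, method_used, n_used = _permutation_p(
        lambda c: _permanova_f(d2, c, n_groups, ss_total)[0], f_obs,
        codes, n_groups, n_perm, seed, method)
    r2 = ssb / ss_total if ss_total > 0 else 0.0
    return PermanovaResult(F=f_obs, r2=r2, p_perm=p, n_perm=n_used,
                           method=method_used, ss_between=ssb, ss_within=ssw,
                           ss_total=ss_total)


# ---------------------------------------------------------------------------
# LCBD / SCBD


@dataclass
class BetaPartition:
    ss_total: float
    bd_total: float              # SS_total / (n - 1)
    lcbd: pd.Series              # per-cell shares, sum 1
    scbd: pd.Series              # per-species shares, sum 1


def lcbd_scbd(transformed: pd.DataFrame) -> BetaPartition:
    """Partition the total sum of squares into site and species shares.

    With centred values ``s_ij = (y'_ij - mean_i y'_ij)^2``, the total sum
    of squares equals ``(1/n) sum_{i<j} d_ij^2`` on the same matrix (checked
    internally); LCBD_i and SCBD_j are row and column shares of it.
    """
    y = transformed.to_numpy(float)
    n = y.shape[0]
    if n < 2:
        raise ValidationError("LCBD/SCBD needs >= 2 cells")
    s = (y - y.mean(axis=0)) ** 2
    ss_total = s.sum()
    if ss_total <= 0:
        raise ValidationError(
            "all cells identical: beta-diversity partition undefined")
    d2 = pdist(y, metric="sqeuclidean").sum()
    if abs(ss_total - d2 / n) > 1e-8 * max(1.0, ss_total):
        raise RuntimeError("internal SS identity violated")  # pragma: no cover
    return BetaPartition(
        ss_total=float(ss_total), bd_total=float(ss_total / (n - 1)),
        lcbd=pd.Series(s.sum(axis=1) / ss_total, index=transformed.index,
                       name="lcbd"),
        scbd=pd.Series(s.sum(axis=0) / ss_total, index=transformed.columns,
                       name="scbd"))


def delta_lcbd(bp1: BetaPartition, bp2: BetaPartition,
               coords: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-cell change in LCBD (contemporary minus historical).

    ``coords`` (indexed by cell id, columns x/y) attaches cell centroids for
    mapping. The two partitions must cover the same cells in the same order.
    """
    if list(bp1.lcbd.index) != list(bp2.lcbd.index):
        raise ValidationError("LCBD partitions cover different cell sets")
    out = pd.DataFrame({
        "lcbd_t1": bp1.lcbd, "lcbd_t2": bp2.lcbd,
        "delta_lcbd": bp2.lcbd - bp1.lcbd})
    out["sign"] = np.sign(out["delta_lcbd"]).astype(int)
    if coords is not None:
        out = out.join(coords[["x", "y"]])
    return out


# ---------------------------------------------------------------------------
# replacement / richness-difference decomposition


@dataclass
class ComponentPartition:
    d: pd.DataFrame
    replacement: pd.DataFrame
    richness_difference: pd.DataFrame
    family: str
    quantitative: bool

    @property
    def totals(self) -> dict:
        n = len(self.d)
        iu = np.triu_indices(n, k=1)
        return {"D": float(self.d.to_numpy()[iu].mean()),
                "replacement": float(self.replacement.to_numpy()[iu].mean()),
                "richness_difference":
                    float(self.richness_difference.to_numpy()[iu].mean())}


def beta_components(values: pd.DataFrame, quantitative: bool = True,
                    family: str = "podani") -> ComponentPartition:
    """Decompose pairwise percentage-difference dissimilarity.

    For each site pair, with A the summed shared abundance and B/C the
    abundances unique to each site, ``D = (B+C)/(2A+B+C)``. The Podani
    family splits D additively into replacement ``2*min(B,C)/(2A+B+C)`` and
    richness/abundance difference ``|B-C|/(2A+B+C)``; the Baselga family
    uses balanced variation ``min(B,C)/(A+min(B,C))`` and its complement.
    With ``quantitative=False`` abundances are reduced to presence/absence
    (Sorensen-based forms).
    """
    if family not in ("podani", "baselga"):
        raise ConfigError(f"unknown decomposition family {family!r}")
    y = values.to_numpy(float)
    if not quantitative:
        y = (y > 0).astype(float)
    n = y.shape[0]
    d = np.zeros((n, n))
    repl = np.zeros((n, n))
    rich = np.zeros((n, n))
    for i in range(n):
        for k in range(i + 1, n):
            a = np.minimum(y[i], y[k]).sum()
            b = np.clip(y[i] - y[k], 0, None).sum()
            c = np.clip(y[k] - y[i], 0, None).sum()
            denom = 2 * a + b + c
            if denom == 0:
                raise ValidationError(
                    f"sites {values.index[i]!r} and {values.index[k]!r} are "
                    "both empty: dissimilarity undefined")
            dd = (b + c) / denom
            if family == "podani":
                rp = 2 * min(b, c) / denom
                rd = abs(b - c) / denom
            else:
                rp = min(b, c) / (a + min(b, c)) if (a + min(b, c)) > 0 else dd
                rd = dd - rp
            d[i, k] = d[k, i] = dd
            repl[i, k] = repl[k, i] = rp
            rich[i, k] = rich[k, i] = rd
    idx = values.index
    return ComponentPartition(
        d=pd.DataFrame(d, index=idx, columns=idx),
        replacement=pd.DataFrame(repl, index=idx, columns=idx),
        richness_difference=pd.DataFrame(rich, index=idx, columns=idx),
        family=family, quantitative=quantitative)
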