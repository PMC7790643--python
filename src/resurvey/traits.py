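"""Functional traits, guilds, and community-weighted means.

Each species carries tolerance scores for shade, drought and waterlogging
(ordinal 1 = very intolerant to 5 = very tolerant), a seed mass in mg
(entering analyses as its natural log), and a temperature preference in
deg C (the mean annual temperature over the species' occurrence records).
Species are also assigned to one of three range-based guilds — northern,
central or carolinian — ordered from broad boreal-reaching ranges to ranges
confined to the Carolinian zone.

The community-weighted mean (CWM) of a trait in a cell is the
abundance-weighted average over the species present; species with a missing
trait value are dropped and the weights renormalised. Temporal change in
CWMs is tested with subsampled paired t tests, and per-species
contributions to trait change are summarised with an SCBD-style share of
the variance of the abundance x trait contribution matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from .resample import (CellRecords, PValueDistribution, SubsampleSpec,
                       group_statistic, subsample_test)
from .survey import CommunityMatrix, ConfigError, Fishnet, ValidationError

logger = logging.getLogger(__name__)

GUILDS = ("northern", "central", "carolinian")

TRAIT_COLUMNS = ("shade", "drought", "waterlogging", "seed_mass_mg",
                 "temp_pref_c")

#: Analysis trait names; seed mass is analysed on the natural-log scale.
ANALYSIS_TRAITS = ("shade", "drought", "waterlogging", "log_seed_mass",
                   "temp_pref_c")

TOLERANCE_TRAITS = ("shade", "drought", "waterlogging")


def read_traits(path) -> pd.DataFrame:
    """Read the species trait table (CSV, indexed by species code)."""
    df = pd.read_csv(path)
    if "species" not in df.columns:
        raise ValidationError(f"trait table {path} needs a 'species' column")
    df = df.set_index("species")
    missing = [c for c in TRAIT_COLUMNS if c not in df.columns
               and c != "temp_pref_c"]
    if missing:
        raise ValidationError(f"trait table {path} missing columns {missing}")
    return validate_traits(df)


def validate_traits(df: pd.DataFrame) -> pd.DataFrame:
    for col in TOLERANCE_TRAITS:
        vals = df[col].dropna()
        if ((vals < 1) | (vals > 5)).any():
            raise ValidationError(f"{col} tolerance scores must be in [1, 5]")
    if "seed_mass_mg" in df.columns:
        sm = df["seed_mass_mg"].dropna()
        if (sm <= 0).any():
            raise ValidationError("seed_mass_mg must be positive")
    n_missing = int(df.isna().sum().sum())
    if n_missing:
        logger.info("trait table has %d missing values", n_missing)
    return df


def read_guilds(path) -> pd.Series:
    """Read the species -> guild table."""
    df = pd.read_csv(path)
    for col in ("species", "guild"):
        if col not in df.columns:
            raise ValidationError(f"guild table {path} needs column {col!r}")
    bad = set(df["guild"]) - set(GUILDS)
    if bad:
        raise ValidationError(f"unknown guilds {sorted(bad)}; "
                              f"expected one of {GUILDS}")
    if df["species"].duplicated().any():
        raise ValidationError("species assigned to more than one guild")
    return df.set_index("species")["guild"]


def trait_values(traits: pd.DataFrame, trait: str) -> pd.Series:
    """Per-species values of an analysis trait (log scale for seed mass)."""
    if trait == "log_seed_mass":
        return np.log(traits["seed_mass_mg"])
    if trait in traits.columns:
        return traits[trait]
    raise ConfigError(f"unknown trait {trait!r}")


# ---------------------------------------------------------------------------
# community-weighted means


def cwm(matrix: CommunityMatrix | pd.DataFrame, traits: pd.DataFrame,
        trait: str) -> pd.Series:
    """Community-weighted mean of a trait per cell.

    ``CWM_i = sum_j p_ij t_j / sum_j p_ij`` over species with a non-missing
    trait value; a cell whose entire abundance lies on trait-missing species
    is an error.
    """
    values = matrix.values if isinstance(matrix, CommunityMatrix) else matrix
    t = trait_values(traits, trait).reindex(values.columns)
    ok = t.notna().to_numpy()
    w = values.to_numpy(float)[:, ok]
    tv = t.to_numpy(float)[ok]
    wsum = w.sum(axis=1)
    empty = wsum <= 0
    if empty.any():
        bad = [str(values.index[i]) for i in np.flatnonzero(empty)]
        raise ValidationError(
            f"cells with no abundance on trait-scored species for "
            f"{trait!r}: {bad}")
    covered = wsum / values.to_numpy(float).sum(axis=1)
    if (covered < 1.0 - 1e-9).any():
        logger.info("trait %s: min contributing-mass fraction %.3f",
                    trait, covered.min())
    out = (w * tv).sum(axis=1) / wsum
    return pd.Series(out, index=values.index, name=f"cwm_{trait}")


def cwm_table(matrix: CommunityMatrix, traits: pd.DataFrame,
              trait_names: Sequence[str] = ANALYSIS_TRAITS) -> pd.DataFrame:
    """CWMs for several traits as a cells x traits table."""
    return pd.DataFrame({tr: cwm(matrix, traits, tr) for tr in trait_names})


def cwm_statistic(traits: pd.DataFrame, trait: str
                  ) -> Callable[[CellRecords, np.ndarray], float]:
    """Per-cell CWM statistic for the subsampling engine.

    The CWM is recomputed inside each subsample replicate from the drawn
    stakes' individuals, with counts as abundance weights.
    """
    t = trait_values(traits, trait)
    tmap = t.dropna().to_dict()

    def stat(cell: CellRecords, pts: np.ndarray) -> float:
        at = np.isin(cell.point_id, pts)
        sp = cell.species[at]
        vals = np.array([tmap.get(s, np.nan) for s in sp], float)
        ok = ~np.isnan(vals)
        if not ok.any():
            raise ValidationError(
                f"subsample has no individuals with a {trait!r} value")
        return float(vals[ok].mean())

    return stat


# ---------------------------------------------------------------------------
# temperature-preference index


@dataclass(frozen=True)
class AsciiRaster:
    """A plain-text gridded surface (ESRI ASCII-grid conventions).

    ``values[0, :]`` is the northernmost (top) row; cell (row i, col j)
    covers ``x in [xll + j*cs, xll + (j+1)*cs)`` and the matching y band.
    """
    xll: float
    yll: float
    cell_size: float
    values: np.ndarray  # 2-D, top row first

    @property
    def shape(self):
        return self.values.shape

    @classmethod
    def from_file(cls, path) -> "AsciiRaster":
        header = {}
        with open(path) as fh:
            lines = fh.read().split("\n")
        i = 0
        while i < len(lines):
            parts = lines[i].split()
            if len(parts) == 2 and parts[0].lower() in (
                    "ncols", "nrows", "xllcorner", "yllcorner", "cellsize",
                    "nodata_value"):
                header[parts[0].lower()] = float(parts[1])
                i += 1
            else:
                break
        vals = np.loadtxt(lines[i:], ndmin=2)
        if vals.shape != (int(header["nrows"]), int(header["ncols"])):
            raise ValidationError(f"raster {path}: grid does not match header")
        if "nodata_value" in header:
            vals = np.where(vals == header["nodata_value"], np.nan, vals)
        return cls(xll=header["xllcorner"], yll=header["yllcorner"],
                   cell_size=header["cellsize"], values=vals)

    def to_file(self, path) -> None:
        nrows, ncols = self.values.shape
        with open(path, "w") as fh:
            fh.write(f"ncols {ncols}\nnrows {nrows}\n"
                     f"xllcorner {self.xll}\nyllcorner {self.yll}\n"
                     f"cellsize {self.cell_size}\n")
            np.savetxt(fh, self.values, fmt="%.6g")

    def sample(self, x, y) -> np.ndarray:
        """Nearest-cell values at the given points; NaN outside the extent."""
        x = np.asarray(x, float)
        y = np.asarray(y, float)
        nrows, ncols = self.values.shape
        col = np.floor((x - self.xll) / self.cell_size).astype(int)
        row_up = np.floor((y - self.yll) / self.cell_size).astype(int)
        row = nrows - 1 - row_up
        out = np.full(x.shape, np.nan)
        ok = (col >= 0) & (col < ncols) & (row >= 0) & (row < nrows)
        out[ok] = self.values[row[ok], col[ok]]
        return out


def temperature_index(occurrences: pd.DataFrame, raster: AsciiRaster
                      ) -> tuple[float, int]:
    """Mean raster temperature over a species' occurrence points.

    Returns ``(index_degC, n_dropped)`` where dropped points fall outside
    the raster extent or on no-data cells.
    """
    vals = raster.sample(occurrences["x"].to_numpy(),
                         occurrences["y"].to_numpy())
    ok = ~np.isnan(vals)
    n_dropped = int((~ok).sum())
    if not ok.any():
        raise ValidationError("no occurrence falls inside the raster extent")
    if n_dropped:
        logger.info("temperature index: dropped %d out-of-extent points",
                    n_dropped)
    return float(vals[ok].mean()), n_dropped


# ---------------------------------------------------------------------------
# change tests


def guild_change_tests(records_t1: pd.DataFrame, records_t2: pd.DataFrame,
                       fishnet: Fishnet, guilds: pd.Series, measure: str,
                       spec: SubsampleSpec,
                       retained_species: Iterable[str] | None = None,
                       **kwargs) -> dict[str, PValueDistribution]:
    """Subsampled paired Wilcoxon tests of guild-level change.

    The per-cell guild value is the sum of member-species values (counts and
    basal area are summed before any normalisation). Guilds with no retained
    species are skipped with a warning.
    """
    if retained_species is not None:
        guilds = guilds[guilds.index.isin(set(retained_species))]
    out = {}
    for guild in GUILDS:
        members = tuple(guilds.index[guilds == guild])
        if not members:
            logger.warning("guild %s has no retained species; skipped", guild)
            continue
        out[guild] = subsample_test(
            records_t1, records_t2, fishnet,
            group_statistic(members, measure), "paired_wilcoxon", spec,
            **kwargs)
    return out


def trait_change_tests(records_t1: pd.DataFrame, records_t2: pd.DataFrame,
                       fishnet: Fishnet, traits: pd.DataFrame,
                       spec: SubsampleSpec,
                       trait_names: Sequence[str] = ANALYSIS_TRAITS,
                       **kwargs) -> dict[str, PValueDistribution]:
    """Subsampled paired t tests of CWM change, one per trait."""
    return {tr: subsample_test(records_t1, records_t2, fishnet,
                               cwm_statistic(traits, tr), "paired_t", spec,
                               **kwargs)
            for tr in trait_names}


def cwm_change_table(mat_t1: CommunityMatrix, mat_t2: CommunityMatrix,
                     traits: pd.DataFrame,
                     trait_names: Sequence[str] = ANALYSIS_TRAITS,
                     coords: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-cell CWM change (T2 - T1) for mapping, one column per trait."""
    c1 = cwm_table(mat_t1, traits, trait_names)
    c2 = cwm_table(mat_t2, traits, trait_names)
    out = c2 - c1
    out.columns = [f"delta_cwm_{tr}" for tr in trait_names]
    if coords is not None:
        out = out.join(coords[["x", "y"]])
    return out


def trait_scbd(mat_t1: CommunityMatrix, mat_t2: CommunityMatrix,
               traits: pd.DataFrame, trait: str) -> pd.DataFrame:
    """Per-species shares of community-trait variation, per period.

    The contribution matrix is ``x_ij = p_ij * t_j`` with abundance weights
    renormalised over trait-scored species; the share of species j in a
    period is its column share of the total centred sum of squares of that
    matrix (the SCBD of the contribution matrix). The change column is the
    contemporary minus the historical share.
    """
    shares = {}
    for label, mat in (("t1", mat_t1), ("t2", mat_t2)):
        values = mat.values
        t = trait_values(traits, trait).reindex(values.columns)
        ok = t.notna()
        w = values.loc[:, ok].to_numpy(float)
        wsum = w.sum(axis=1, keepdims=True)
        if np.any(wsum <= 0):
            bad = [str(values.index[i])
                   for i in np.flatnonzero(wsum.ravel() <= 0)]
            raise ValidationError(
                f"cells with no abundance on trait-scored species: {bad}")
        x = (w / wsum) * t[ok].to_numpy(float)
        s = (x - x.mean(axis=0)) ** 2
        total = s.sum()
        if total <= 0:
            raise ValidationError(
                f"no variation in {trait!r} contributions in period {label}")
        shares[label] = pd.Series(s.sum(axis=0) / total,
                                  index=values.columns[ok])
    out = pd.DataFrame({"share_t1": shares["t1"], "share_t2": shares["t2"]})
    out["change"] = out["share_t2"] - out["share_t1"]
    out.index.name = "species"
    return out
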