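"""Ingestion and aggregation of point-centred-quarter survey data.

A survey table has one row per sampled tree: the grid stake it was sampled
from (``point_id``, with planar ``x``/``y`` in metres), the survey ``period``
(e.g. ``T1``/``T2``), the compass ``quadrant`` (1-4) around the sampling
start point, the ``species`` code, the stem diameter at breast height
(``dbh_cm``) and the ``distance_m`` from the sampling start point.

Stakes are grouped into rectangular fishnet cells (the statistical sample
units); per-cell community matrices are then assembled for three measures:

occurrence
    fraction of the cell's sampled stakes at which the species was recorded;
relative_abundance
    individuals of the species divided by all individuals in the cell;
basal_area
    summed stem basal area ``pi * (dbh/2)**2`` (cm^2) divided by the number
    of sampled stakes in the cell.

Trees are split into two size cohorts at 10 cm dbh: ``mature`` (>= 10 cm)
and ``sapling`` (< 10 cm).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("point_id", "x", "y", "period", "quadrant", "species",
                    "dbh_cm", "distance_m")

MEASURES = ("occurrence", "relative_abundance", "basal_area")

#: dbh threshold (cm) separating the mature cohort (>= threshold) from saplings.
MATURE_MIN_DBH = 10.0

COHORTS = ("mature", "sapling")

#: Default taxon pooling: the hybrid Acer x freemanii is pooled with
#: A. saccharinum and Fraxinus profunda with F. pennsylvanica.
DEFAULT_POOLING = {"ACFR": "ACSA2", "FRPR": "FRPE"}


class SchemaError(ValueError):
    """The input table does not have the required columns."""


class ValidationError(ValueError):
    """Row-level content of an input violates the data contract."""


class ConfigError(ValueError):
    """An analysis parameter is outside its allowed range."""


def basal_area_cm2(dbh_cm):
    """Stem basal area pi*(dbh/2)^2 in cm^2 for dbh in cm."""
    dbh_cm = np.asarray(dbh_cm, dtype=float)
    return np.pi * (dbh_cm / 2.0) ** 2


def assign_cohort(dbh_cm, threshold: float = MATURE_MIN_DBH) -> np.ndarray:
    """Label each dbh as ``mature`` (>= threshold) or ``sapling``."""
    dbh_cm = np.asarray(dbh_cm, dtype=float)
    return np.where(dbh_cm >= threshold, "mature", "sapling")


# ---------------------------------------------------------------------------
# reading / validation


def read_survey(path, *, delimiter: str = ",",
                cohort_threshold: float = MATURE_MIN_DBH,
                known_species: Iterable[str] | None = None,
                ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read and validate a survey table.

    Returns ``(grid_points, records)``: one row per stake with its
    coordinates and the periods it was sampled in, and one validated row per
    tree with a derived ``cohort`` column.

    Raises
    ------
    SchemaError
        if a required column is missing.
    ValidationError
        if any row has a non-numeric or out-of-range value; the message
        lists the offending row numbers (1-based, excluding the header).
    """
    df = pd.read_csv(path, delimiter=delimiter)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"survey table {path} is missing columns: {missing}")

    rows = df.index.to_numpy() + 1  # 1-based data-row numbers
    bad: dict[int, str] = {}

    def flag(mask, reason):
        for r in rows[np.asarray(mask)]:
            bad.setdefault(int(r), reason)

    num = {}
    for col in ("x", "y", "dbh_cm", "distance_m", "quadrant"):
        num[col] = pd.to_numeric(df[col], errors="coerce")
        flag(num[col].isna().to_numpy(), f"non-numeric {col}")

    with np.errstate(invalid="ignore"):
        flag((num["dbh_cm"] <= 0).to_numpy(), "dbh_cm must be > 0")
        flag((num["distance_m"] < 0).to_numpy(), "distance_m must be >= 0")
        q = num["quadrant"]
        flag((~q.isin([1, 2, 3, 4]) & q.notna()).to_numpy(),
             "quadrant must be in {1,2,3,4}")
    if bad:
        listing = "; ".join(f"row {r}: {reason}" for r, reason in
                            sorted(bad.items())[:20])
        raise ValidationError(
            f"survey table {path}: {len(bad)} invalid rows ({listing})")

    records = pd.DataFrame({
        "point_id": df["point_id"].astype(str),
        "period": df["period"].astype(str),
        "quadrant": num["quadrant"].astype(int),
        "species": df["species"].astype(str),
        "dbh_cm": num["dbh_cm"].astype(float),
        "distance_m": num["distance_m"].astype(float),
    })
    records["cohort"] = assign_cohort(records["dbh_cm"], cohort_threshold)

    dup = records.duplicated(["point_id", "period", "quadrant", "cohort"],
                             keep=False)
    if dup.any():
        offenders = records.loc[dup, ["point_id", "period", "quadrant"]]
        raise ValidationError(
            "duplicate (point, period, quadrant, cohort) records: "
            f"{offenders.head(10).to_dict('records')}")

    coords = pd.DataFrame({"point_id": records["point_id"],
                           "x": num["x"].astype(float),
                           "y": num["y"].astype(float)})
    per_point = coords.groupby("point_id")[["x", "y"]].nunique()
    inconsistent = per_point[(per_point > 1).any(axis=1)]
    if len(inconsistent):
        raise ValidationError(
            f"points with inconsistent coordinates: {list(inconsistent.index)}")
    if not np.isfinite(coords[["x", "y"]].to_numpy()).all():
        raise ValidationError("non-finite stake coordinates")

    grid_points = coords.drop_duplicates("point_id").reset_index(drop=True)
    sampled = records.groupby("point_id")["period"].agg(
        lambda s: tuple(sorted(set(s))))
    grid_points["sampled_in"] = grid_points["point_id"].map(sampled)

    if known_species is not None:
        unknown = sorted(set(records["species"]) - set(known_species))
        if unknown:
            logger.warning("unknown species codes in %s: %s", path, unknown)

    for period, sub in records.groupby("period"):
        n_full = (sub.groupby(["point_id", "cohort"])["quadrant"].nunique()
                  == 4).sum()
        logger.info("period %s: %d records at %d points; %d complete "
                    "(point, cohort) quartets", period, len(sub),
                    sub["point_id"].nunique(), n_full)
    return grid_points, records


def write_survey(grid_points: pd.DataFrame, records: pd.DataFrame, path
                 ) -> None:
    """Write records joined with stake coordinates in the survey CSV schema."""
    out = records.merge(grid_points[["point_id", "x", "y"]], on="point_id")
    out = out[list(REQUIRED_COLUMNS)]
    out.to_csv(path, index=False)


def sampled_points(records: pd.DataFrame, period: str) -> set[str]:
    """Stakes with at least one record (any cohort) in the given period."""
    return set(records.loc[records["period"] == period, "point_id"])


# ---------------------------------------------------------------------------
# cohorts / pooling / rarity


def split_cohorts(records: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Partition records into the mature and sapling cohorts."""
    return {c: records[records["cohort"] == c].copy() for c in COHORTS}


def pool_taxa(records: pd.DataFrame,
              pooling_map: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Relabel species codes according to ``pooling_map`` (source -> target).

    The map must be flat: no code may appear both as a source and as a
    target (chained or cyclic pooling is rejected). Record counts are
    conserved.
    """
    if pooling_map is None:
        pooling_map = DEFAULT_POOLING
    chained = set(pooling_map) & set(pooling_map.values())
    if chained:
        raise ConfigError(f"pooling map is chained/cyclic through {sorted(chained)}")
    out = records.copy()
    out["species"] = out["species"].map(lambda s: pooling_map.get(s, s))
    return out


def filter_rare(records: pd.DataFrame, grid_points: pd.DataFrame,
                min_fraction: float = 0.01) -> list[str]:
    """Species occurring at >= ``min_fraction`` of all surveyed stakes.

    The occupied-stake share is computed on the cohort-pooled dataset over
    both survey periods, so the retained species set is identical for every
    period and cohort.
    """
    if not 0.0 <= min_fraction <= 1.0:
        raise ConfigError(f"min_fraction must be in [0, 1], got {min_fraction}")
    n_points = grid_points["point_id"].nunique()
    occ = records.groupby("species")["point_id"].nunique()
    frac = occ / n_points
    retained = sorted(frac.index[frac >= min_fraction])
    removed = sorted(set(frac.index) - set(retained))
    if removed:
        logger.info("rare-species filter (<%g of %d points) removed %s",
                    min_fraction, n_points, removed)
    return retained


# ---------------------------------------------------------------------------
# fishnet


@dataclass(frozen=True)
class FishnetCell:
    """One axis-aligned fishnet cell with its member stakes.

    Boxes are half-open (``[xmin, xmax) x [ymin, ymax)``) so every stake
    belongs to exactly one cell.
    """
    cell_id: str
    xmin: float
    ymin: float
    xmax: float
    ymax: float
    point_ids: tuple[str, ...]


@dataclass(frozen=True)
class Fishnet:
    cells: tuple[FishnetCell, ...]
    mesh: tuple[float, float]
    origin: tuple[float, float]

    @property
    def cell_ids(self) -> list[str]:
        return [c.cell_id for c in self.cells]

    def point_to_cell(self) -> dict[str, str]:
        return {p: c.cell_id for c in self.cells for p in c.point_ids}

    def assign(self, grid_points: pd.DataFrame) -> pd.Series:
        """Cell id for each point by half-open box containment (NaN outside)."""
        out = pd.Series(pd.NA, index=grid_points["point_id"], dtype=object)
        x = grid_points["x"].to_numpy(float)
        y = grid_points["y"].to_numpy(float)
        for c in self.cells:
            inside = ((x >= c.xmin) & (x < c.xmax)
                      & (y >= c.ymin) & (y < c.ymax))
            out.iloc[np.flatnonzero(inside)] = c.cell_id
        return out

    def cell_centroids(self, grid_points: pd.DataFrame) -> pd.DataFrame:
        """Mean member-stake coordinates per cell (for mapping outputs)."""
        gp = grid_points.set_index("point_id")
        rows = []
        for c in self.cells:
            xy = gp.loc[list(c.point_ids), ["x", "y"]].mean()
            rows.append({"cell_id": c.cell_id, "x": xy["x"], "y": xy["y"]})
        return pd.DataFrame(rows).set_index("cell_id")


def _assign_bins(x, y, origin, mesh):
    ix = np.floor((x - origin[0]) / mesh[0]).astype(int)
    iy = np.floor((y - origin[1]) / mesh[1]).astype(int)
    return ix, iy


DEFAULT_MESH_SIZES = tuple(
    (mx, my) for mx in (100.0, 150.0, 200.0, 250.0, 300.0, 350.0, 400.0)
    for my in (100.0, 150.0, 200.0, 250.0, 300.0, 350.0, 400.0))
DEFAULT_OFFSETS = (0.0, 0.25, 0.5, 0.75)


def build_fishnet(grid_points: pd.DataFrame,
                  mesh_sizes: Sequence = DEFAULT_MESH_SIZES,
                  offsets: Sequence[float] = DEFAULT_OFFSETS,
                  min_points: int = 10) -> Fishnet:
    """Choose the fishnet maximising the number of qualifying cells.

    Candidates are the cross product of ``mesh_sizes`` (scalars or
    ``(mesh_x, mesh_y)`` pairs) and origin offsets expressed as fractions of
    the mesh in each axis. A cell qualifies when it contains at least
    ``min_points`` stakes; only qualifying cells are returned, and the same
    fishnet is reused for every period. Ties are broken by larger mean
    stakes-per-cell, then smaller mesh area, then deterministically by
    candidate order.
    """
    if min_points < 1:
        raise ConfigError("min_points must be >= 1")
    x = grid_points["x"].to_numpy(float)
    y = grid_points["y"].to_numpy(float)
    pids = grid_points["point_id"].to_numpy()
    if len(x) < min_points:
        raise ValidationError(
            f"only {len(x)} grid points; need at least {min_points}")

    best = None
    best_key = None
    for mesh in mesh_sizes:
        mx, my = (float(mesh), float(mesh)) if np.isscalar(mesh) else (
            float(mesh[0]), float(mesh[1]))
        for fx in offsets:
            for fy in offsets:
                origin = (x.min() - fx * mx, y.min() - fy * my)
                ix, iy = _assign_bins(x, y, origin, (mx, my))
                cells, counts = np.unique(np.stack([ix, iy], axis=1),
                                          axis=0, return_counts=True)
                qual = counts >= min_points
                n_qual = int(qual.sum())
                if n_qual == 0:
                    continue
                mean_occ = float(counts[qual].mean())
                key = (n_qual, mean_occ, -mx * my, -mx, -fx, -fy)
                if best_key is None or key > best_key:
                    best_key = key
                    best = ((mx, my), origin, (fx, fy))
    if best is None:
        raise ValidationError(
            f"no fishnet candidate yields a cell with >= {min_points} points")

    (mx, my), origin, _ = best
    ix, iy = _assign_bins(x, y, origin, (mx, my))
    cells = []
    for (bx, by) in sorted({(int(a), int(b)) for a, b in zip(ix, iy)}):
        member = pids[(ix == bx) & (iy == by)]
        if len(member) < min_points:
            continue
        cells.append(FishnetCell(
            cell_id=f"c{bx}_{by}",
            xmin=origin[0] + bx * mx, ymin=origin[1] + by * my,
            xmax=origin[0] + (bx + 1) * mx, ymax=origin[1] + (by + 1) * my,
            point_ids=tuple(sorted(member))))
    return Fishnet(cells=tuple(cells), mesh=(mx, my), origin=origin)


# ---------------------------------------------------------------------------
# community matrices


@dataclass
class CommunityMatrix:
    """Cells x species values for one measure, period and cohort."""
    values: pd.DataFrame          # index: cell_id, columns: species
    measure: str
    period: str
    cohort: str
    n_points_per_cell: pd.Series  # sampled stakes per cell in this period

    def percent_cells_occupied(self) -> pd.Series:
        """Reporting summary: percentage of cells where each species occurs."""
        return (self.values > 0).mean(axis=0) * 100.0

    def to_csv(self, path, sidecar: bool = True) -> None:
        self.values.to_csv(path, index_label="cell_id")
        if sidecar:
            meta = {"measure": self.measure, "period": self.period,
                    "cohort": self.cohort,
                    "n_points_per_cell": {str(k): int(v) for k, v in
                                          self.n_points_per_cell.items()}}
            with open(str(path) + ".json", "w") as fh:
                json.dump(meta, fh, indent=1, sort_keys=True)


def community_matrix(records: pd.DataFrame, fishnet: Fishnet, measure: str,
                     *, period: str, cohort: str,
                     points_in_period: Iterable[str] | None = None,
                     species: Sequence[str] | None = None) -> CommunityMatrix:
    """Aggregate records into a per-cell community matrix.

    ``points_in_period`` is the set of stakes actually sampled in the period
    (defaults to stakes with any record, either cohort, in that period); it
    is the denominator for occurrence and basal area. A cell none of whose
    member stakes was sampled in the period is an error.
    """
    if measure not in MEASURES:
        raise ConfigError(f"unknown measure {measure!r}; expected {MEASURES}")
    if points_in_period is None:
        points_in_period = sampled_points(records, period)
    points_in_period = set(points_in_period)

    sub = records[(records["period"] == period)
                  & (records["cohort"] == cohort)]
    # `species` selects output columns only; relative-abundance denominators
    # count every individual in the cell (drop unwanted taxa upstream, e.g.
    # with the rarity filter, if they should not contribute)
    if species is None:
        species = sorted(sub["species"].unique())
    else:
        species = list(species)

    cell_pts = {}
    for cell in fishnet.cells:
        pts = [p for p in cell.point_ids if p in points_in_period]
        if not pts:
            raise ValidationError(
                f"cell {cell.cell_id} has no sampled grid points in period "
                f"{period}")
        cell_pts[cell.cell_id] = pts

    p2c = {p: cid for cid, pts in cell_pts.items() for p in pts}
    sub = sub[sub["point_id"].isin(p2c)].copy()
    sub["cell_id"] = sub["point_id"].map(p2c)
    cell_ids = list(cell_pts)
    n_points = pd.Series({cid: len(pts) for cid, pts in cell_pts.items()},
                         name="n_points")[cell_ids]

    if measure == "occurrence":
        pres = (sub.drop_duplicates(["cell_id", "species", "point_id"])
                .groupby(["cell_id", "species"]).size())
        mat = pres.unstack(fill_value=0).reindex(index=cell_ids,
                                                 columns=species, fill_value=0)
        mat = mat.div(n_points, axis=0)
    elif measure == "relative_abundance":
        counts = sub.groupby(["cell_id", "species"]).size()
        mat = counts.unstack(fill_value=0).reindex(index=cell_ids,
                                                   fill_value=0).astype(float)
        totals = mat.sum(axis=1)  # every individual, before column selection
        nonzero = totals > 0
        mat.loc[nonzero] = mat.loc[nonzero].div(totals[nonzero], axis=0)
        mat = mat.reindex(columns=species, fill_value=0.0)
    else:  # basal_area
        sub = sub.assign(ba=basal_area_cm2(sub["dbh_cm"]))
        ba = sub.groupby(["cell_id", "species"])["ba"].sum()
        mat = ba.unstack(fill_value=0.0).reindex(index=cell_ids,
                                                 columns=species,
                                                 fill_value=0.0)
        mat = mat.div(n_points, axis=0)

    mat.index.name = "cell_id"
    return CommunityMatrix(values=mat.astype(float), measure=measure,
                           period=period, cohort=cohort,
                           n_points_per_cell=n_points)
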