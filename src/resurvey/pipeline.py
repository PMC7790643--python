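"""End-to-end analysis orchestration.

``run_analysis`` drives the full resurvey workflow for each size cohort:
ingest and validate the survey, pool taxa, drop rare species, build the
fishnet, assemble community matrices for the three measures, run subsampled
paired Wilcoxon tests per species and guild, run the homogenization
(dispersion) and composition (PERMANOVA) tests on Hellinger distances both
directly and under the subsampled protocol, partition beta diversity into
LCBD/SCBD with temporal LCBD differences, decompose pairwise dissimilarity
into replacement and richness-difference parts, and compute
community-weighted trait means with subsampled paired t tests.

Every output is written under the configured output directory together with
a run manifest (config echo, config hash, seeds, package version); rerunning
with the same config and inputs reproduces the outputs byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, beta, traits as traits_mod
from .resample import SubsampleSpec, species_statistic, subsample_multivariate, subsample_test
from .survey import (DEFAULT_MESH_SIZES, DEFAULT_OFFSETS, DEFAULT_POOLING,
                     MEASURES, CommunityMatrix, ConfigError, build_fishnet,
                     community_matrix, filter_rare, pool_taxa, read_survey,
                     sampled_points)

logger = logging.getLogger(__name__)


@dataclass
class AnalysisConfig:
    """Declarative description of one analysis run (YAML-serialisable)."""
    survey: str
    traits: str
    guilds: str
    output_dir: str = "resurvey_out"
    seed: int = 0
    cohort_threshold_cm: float = 10.0
    pooling: dict = field(default_factory=lambda: dict(DEFAULT_POOLING))
    rare_min_fraction: float = 0.01
    fishnet_mesh_sizes: list = field(
        default_factory=lambda: [list(m) for m in DEFAULT_MESH_SIZES])
    fishnet_offsets: list = field(
        default_factory=lambda: list(DEFAULT_OFFSETS))
    fishnet_min_points: int = 10
    subsample_n: int = 10
    subsample_r: int = 1000
    pairing: str = "matched_points"
    n_perm: int = 9999             # direct multivariate tests
    n_perm_subsampled: int = 199   # per-replicate permutations
    multivariate_r: int = 100      # replicates for subsampled multivariate
    measures: list = field(default_factory=lambda: list(MEASURES))
    trait_names: list = field(
        default_factory=lambda: list(traits_mod.ANALYSIS_TRAITS))
    cohorts: list = field(default_factory=lambda: ["mature", "sapling"])
    species_tests: bool = True
    component_family: str = "podani"

    @classmethod
    def from_yaml(cls, path, **overrides) -> "AnalysisConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ConfigError(f"unknown config keys in {path}: {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()


@dataclass
class ReportBundle:
    """In-memory handles to everything ``run_analysis`` computed."""
    config: AnalysisConfig
    fishnet: object
    matrices: dict          # (cohort, measure, period) -> CommunityMatrix
    species_tests: pd.DataFrame
    guild_tests: pd.DataFrame
    beta_results: dict      # cohort -> dict of test results
    lcbd_tables: dict       # cohort -> DataFrame
    scbd_tables: dict
    cwm_tables: dict        # (cohort, period) -> DataFrame
    trait_tests: pd.DataFrame
    manifest: dict
    output_dir: Path


def _stack_matrices(m1: CommunityMatrix, m2: CommunityMatrix):
    cols = sorted(set(m1.values.columns) | set(m2.values.columns))
    stacked = pd.concat([
        m1.values.reindex(columns=cols, fill_value=0.0)
          .rename(index=lambda c: f"{c}|{m1.period}"),
        m2.values.reindex(columns=cols, fill_value=0.0)
          .rename(index=lambda c: f"{c}|{m2.period}")])
    groups = [lbl.rsplit("|", 1)[1] for lbl in stacked.index]
    return stacked, groups


def temporal_beta_tests(m1: CommunityMatrix, m2: CommunityMatrix,
                        n_perm: int = 9999, seed=None) -> dict:
    """Dispersion and PERMANOVA tests on the stacked Hellinger distances."""
    stacked, groups = _stack_matrices(m1, m2)
    dm = beta.distance_matrix(beta.hellinger_transform(stacked))
    k1, k2 = np.random.SeedSequence(seed).spawn(2)
    return {
        "distance_matrix": dm,
        "dispersion": beta.dispersion_test(dm, groups, n_perm=n_perm,
                                           seed=k1, method="permutation"),
        "permanova": beta.permanova(dm, groups, n_perm=n_perm, seed=k2,
                                    method="permutation"),
        "pcoa": beta.pcoa(dm),
    }


def _file_sha(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _pdist_row(name: str, cohort: str, measure: str, dist) -> dict:
    row = {"species_or_group": name, "cohort": cohort, "measure": measure}
    row.update(dist.summary_row())
    return row


def run_analysis(config: AnalysisConfig) -> ReportBundle:
    """Execute the full pipeline and write all outputs."""
    out = Path(config.output_dir)
    (out / "matrices").mkdir(parents=True, exist_ok=True)

    for key in ("survey", "traits", "guilds"):
        p = getattr(config, key)
        if not Path(p).exists():
            raise FileNotFoundError(f"{key} file not found: {p}")

    trait_table = traits_mod.read_traits(config.traits)
    guilds = traits_mod.read_guilds(config.guilds)
    grid_points, records = read_survey(
        config.survey, cohort_threshold=config.cohort_threshold_cm,
        known_species=trait_table.index)

    records = pool_taxa(records, config.pooling)
    retained = filter_rare(records, grid_points, config.rare_min_fraction)
    records = records[records["species"].isin(retained)]
    periods = sorted(records["period"].unique())
    if len(periods) != 2:
        raise ConfigError(f"expected 2 survey periods, found {periods}")
    p1, p2 = periods

    mesh_sizes = [tuple(m) if isinstance(m, (list, tuple)) else float(m)
                  for m in config.fishnet_mesh_sizes]
    fishnet = build_fishnet(grid_points, mesh_sizes=mesh_sizes,
                            offsets=config.fishnet_offsets,
                            min_points=config.fishnet_min_points)
    coords = fishnet.cell_centroids(grid_points)
    coords.to_csv(out / "cell_centroids.csv")
    pts_in = {p: sampled_points(records, p) for p in periods}

    seed_root = np.random.SeedSequence(config.seed)
    matrices = {}
    sp_rows, guild_rows, trait_rows = [], [], []
    beta_results, lcbd_tables, scbd_tables, cwm_tables = {}, {}, {}, {}

    for ci, cohort in enumerate(config.cohorts):
        logger.info("analysing cohort %s", cohort)
        cohort_seed = np.random.SeedSequence(config.seed, spawn_key=(ci,))
        kid = iter(cohort_seed.spawn(8))

        for measure in config.measures:
            for p in periods:
                mat = community_matrix(records, fishnet, measure, period=p,
                                       cohort=cohort,
                                       points_in_period=pts_in[p],
                                       species=retained)
                matrices[(cohort, measure, p)] = mat
                mat.to_csv(out / "matrices" / f"{cohort}_{measure}_{p}.csv")

        # --- univariate subsampled tests -------------------------------
        spec = SubsampleSpec(
            n=config.subsample_n, r=config.subsample_r,
            seed=int(next(kid).generate_state(1)[0] & 0x7FFFFFFF),
            pairing=config.pairing)
        if config.species_tests:
            for measure in config.measures:
                for sp in retained:
                    dist = subsample_test(
                        records, records, fishnet,
                        species_statistic(sp, measure), "paired_wilcoxon",
                        spec, period_t1=p1, period_t2=p2)
                    sp_rows.append(_pdist_row(sp, cohort, measure, dist))
        for measure in config.measures:
            gdists = traits_mod.guild_change_tests(
                records, records, fishnet, guilds, measure, spec,
                retained_species=retained, period_t1=p1, period_t2=p2)
            for guild, dist in gdists.items():
                guild_rows.append(_pdist_row(guild, cohort, measure, dist))

        # --- beta diversity --------------------------------------------
        m1 = matrices[(cohort, "relative_abundance", p1)]
        m2 = matrices[(cohort, "relative_abundance", p2)]
        direct = temporal_beta_tests(
            m1, m2, n_perm=config.n_perm,
            seed=int(next(kid).generate_state(1)[0] & 0x7FFFFFFF))

        sub_spec = SubsampleSpec(
            n=config.subsample_n, r=config.multivariate_r,
            seed=int(next(kid).generate_state(1)[0] & 0x7FFFFFFF),
            pairing=config.pairing)

        def builder(recs, pts, period):
            return community_matrix(
                recs, fishnet, "relative_abundance", period=period,
                cohort=cohort, points_in_period=set(pts),
                species=retained).values

        def make_analysis(which, seed):
            rng_seq = iter(np.random.SeedSequence(seed).spawn(
                sub_spec.r * 2))

            def analysis(v1, v2):
                cols = sorted(set(v1.columns) | set(v2.columns))
                stacked = pd.concat([
                    v1.reindex(columns=cols, fill_value=0.0)
                      .rename(index=lambda c: f"{c}|a"),
                    v2.reindex(columns=cols, fill_value=0.0)
                      .rename(index=lambda c: f"{c}|b")])
                groups = [lbl.rsplit("|", 1)[1] for lbl in stacked.index]
                dm = beta.distance_matrix(beta.hellinger_transform(stacked))
                fn = (beta.dispersion_test if which == "dispersion"
                      else beta.permanova)
                res = fn(dm, groups, n_perm=config.n_perm_subsampled,
                         seed=next(rng_seq), method="permutation")
                return res.p_perm

            return analysis

        subsampled = {}
        for which in ("dispersion", "permanova"):
            dist = subsample_multivariate(
                records, records, fishnet, make_analysis(
                    which, int(next(kid).generate_state(1)[0] & 0x7FFFFFFF)),
                sub_spec, builder, period_t1=p1, period_t2=p2)
            subsampled[which] = dist

        h1 = beta.hellinger_transform(m1.values)
        h2 = beta.hellinger_transform(m2.values)
        bp1, bp2 = beta.lcbd_scbd(h1), beta.lcbd_scbd(h2)
        lcbd = beta.delta_lcbd(bp1, bp2, coords)
        scbd = pd.DataFrame({"scbd_t1": bp1.scbd, "scbd_t2": bp2.scbd})
        scbd["change"] = scbd["scbd_t2"] - scbd["scbd_t1"]
        # on row-normalised profiles the abundance-difference part vanishes
        # (B - C = 0 for compositions), so the presence-absence variant is
        # reported alongside as the informative richness-difference view
        comp = {p: {"quantitative": beta.beta_components(
                        matrices[(cohort, "relative_abundance", p)].values,
                        family=config.component_family).totals,
                    "presence_absence": beta.beta_components(
                        matrices[(cohort, "relative_abundance", p)].values,
                        quantitative=False,
                        family=config.component_family).totals}
                for p in periods}

        disp, perm = direct["dispersion"], direct["permanova"]
        beta_results[cohort] = {
            "dispersion": {
                "F": disp.F, "p_perm": disp.p_perm, "n_perm": disp.n_perm,
                "direction": disp.direction,
                "group_mean_dispersion": disp.group_means.to_dict(),
                "subsampled_mean_p": subsampled["dispersion"].mean_p,
                "subsampled_quantiles": subsampled["dispersion"].quantiles,
            },
            "permanova": {
                "F": perm.F, "R2": perm.r2, "p_perm": perm.p_perm,
                "n_perm": perm.n_perm, "SS_between": perm.ss_between,
                "SS_within": perm.ss_within, "SS_total": perm.ss_total,
                "subsampled_mean_p": subsampled["permanova"].mean_p,
                "subsampled_quantiles": subsampled["permanova"].quantiles,
                "caveat": "free permutation; cells are temporally paired",
            },
            "bd_total": {p1: bp1.bd_total, p2: bp2.bd_total},
            "components": comp,
            "seed": config.seed,
        }
        direct["pcoa"].coordinates.to_csv(out / f"pcoa_{cohort}.csv",
                                          index_label="site")
        lcbd.to_csv(out / f"lcbd_{cohort}.csv", index_label="cell_id")
        scbd.to_csv(out / f"scbd_{cohort}.csv", index_label="species")
        lcbd_tables[cohort] = lcbd
        scbd_tables[cohort] = scbd

        # --- traits ----------------------------------------------------
        for p in periods:
            ct = traits_mod.cwm_table(
                matrices[(cohort, "relative_abundance", p)], trait_table,
                config.trait_names)
            cwm_tables[(cohort, p)] = ct
            ct.to_csv(out / f"cwm_{cohort}_{p}.csv", index_label="cell_id")
        change = traits_mod.cwm_change_table(
            m1, m2, trait_table, config.trait_names, coords)
        change.to_csv(out / f"cwm_change_{cohort}.csv", index_label="cell_id")

        tdists = traits_mod.trait_change_tests(
            records, records, fishnet, trait_table,
            dataclasses.replace(spec, seed=int(
                next(kid).generate_state(1)[0] & 0x7FFFFFFF)),
            config.trait_names, period_t1=p1, period_t2=p2)
        for tr, dist in tdists.items():
            trait_rows.append(_pdist_row(tr, cohort, "cwm", dist))

        tscbd = pd.concat(
            {tr: traits_mod.trait_scbd(m1, m2, trait_table, tr)
             for tr in config.trait_names}, names=["trait", "species"])
        tscbd.to_csv(out / f"trait_scbd_{cohort}.csv")

    species_tests = pd.DataFrame(sp_rows)
    guild_tests = pd.DataFrame(guild_rows)
    trait_tests = pd.DataFrame(trait_rows)
    species_tests.to_csv(out / "tests_species.csv", index=False)
    guild_tests.to_csv(out / "tests_guilds.csv", index=False)
    trait_tests.to_csv(out / "tests_traits.csv", index=False)
    with open(out / "beta_results.json", "w") as fh:
        json.dump(beta_results, fh, indent=1, sort_keys=True, default=float)

    manifest = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "inputs": {k: _file_sha(getattr(config, k))
                   for k in ("survey", "traits", "guilds")},
        "retained_species": retained,
        "n_cells": len(fishnet.cells),
        "fishnet_mesh": list(fishnet.mesh),
        "periods": periods,
        "version": __version__,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)

    return ReportBundle(config=config, fishnet=fishnet, matrices=matrices,
                        species_tests=species_tests, guild_tests=guild_tests,
                        beta_results=beta_results, lcbd_tables=lcbd_tables,
                        scbd_tables=scbd_tables, cwm_tables=cwm_tables,
                        trait_tests=trait_tests, manifest=manifest,
                        output_dir=out)
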