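"""Synthetic two-period point-quarter resurvey generator.

The generator emulates the field design the analysis pipeline expects: a
permanent lattice of stakes laid out in parallel rows (50 m between stakes
within a row, 100 m between rows), surveyed in two periods by the
point-centred-quarter protocol — around each sampling start point the
nearest tree in each compass quadrant is recorded with species, distance
and dbh, separately for the mature (>= 10 cm dbh) and sapling cohorts.
Period-1 start points are displaced from the stakes by a random offset with
mean length 7.41 m (the historical surveyors avoided the stake itself);
period-2 sampling starts at the stakes.

Trees are realised as a marked Poisson process in a disc around each start
point. Species composition varies across the landscape through smooth
log-intensity random fields; a scenario then defines how period-2 surfaces
relate to period-1:

``null``
    both periods are independent draws of the same spatial process;
``homogenization``
    period-2 cell profiles are shrunk toward the regional mean profile by a
    factor ``effect`` (lambda = 1 leaves every stake at the regional mean);
``differentiation``
    period-2 deviations from the regional mean are inflated by
    ``1 + effect``;
``turnover``
    species identities are cyclically relabelled within spatial blocks,
    preserving total abundance and local diversity, mixed in with weight
    ``effect``;
``abundance_shift``
    target species' period-1 intensities are multiplied by ``effect``
    (others renormalised), against otherwise unchanged surfaces;
``trait_shift``
    period-1 weights are exponentially tilted per stake so the community
    mean of a target trait increases by exactly ``effect`` trait units.

The first three scenarios reduce exactly to ``null`` at ``effect = 0``; the
two injection scenarios anchor period 2 to the period-1 surfaces so the
injected effect is recoverable against sampling noise alone.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from . import beta, traits as traits_mod
from .survey import ConfigError, ValidationError, write_survey

SCENARIOS = ("null", "turnover", "homogenization", "differentiation",
             "abundance_shift", "trait_shift")

PERIODS = ("T1", "T2")


# ---------------------------------------------------------------------------
# species pool


@dataclass
class SpeciesPool:
    """Regional species pool with traits, guilds and baseline intensities."""
    codes: tuple[str, ...]
    traits: pd.DataFrame          # indexed by code, trait-table schema
    guilds: pd.Series             # code -> guild
    base_intensity: np.ndarray    # relative, sums to 1

    @property
    def n_species(self) -> int:
        return len(self.codes)


#: Guild temperature-preference centres (deg C): boreal-reaching species are
#: cooler-ranged than Carolinian-zone specialists.
GUILD_TEMP_C = {"northern": 5.0, "central": 7.5, "carolinian": 9.5}

#: Guild dominance multipliers: resurveyed Great Lakes forests are dominated
#: by the northern guild, with Carolinian species comparatively rare.
GUILD_WEIGHT = {"northern": 2.0, "central": 1.0, "carolinian": 0.5}


def make_species_pool(n_species: int = 24,
                      guild_mix: Sequence[float] = (0.5, 0.3, 0.2),
                      rho: float = 0.5, seed=None) -> SpeciesPool:
    """Draw a species pool with correlated tolerance traits.

    Shade and drought tolerance are drawn from a Gaussian copula with
    correlation ``-rho`` (shade-tolerant species tend to be drought
    intolerant), mapped onto the [1, 5] tolerance scale; waterlogging is
    independent; seed masses are log-normal; temperature preference centres
    on the species' guild.
    """
    if n_species < 2:
        raise ConfigError("need at least 2 species")
    if not 0.0 <= rho <= 1.0:
        raise ConfigError(f"trait correlation rho must be in [0, 1], got {rho}")
    rng = np.random.default_rng(seed)
    codes = tuple(f"SP{i + 1:02d}" for i in range(n_species))

    # stratified (Latin-hypercube) quantiles so every pool spans the full
    # 1-5 tolerance scale, as real tolerance classifications do
    u1 = (rng.permutation(n_species) + rng.random(n_species)) / n_species
    z1 = stats.norm.ppf(u1)
    z2 = -rho * z1 + np.sqrt(1 - rho ** 2) * rng.standard_normal(n_species)
    shade = 1 + 4 * stats.norm.cdf(z1)
    drought = 1 + 4 * stats.norm.cdf(z2)
    waterlogging = rng.uniform(1, 5, n_species)
    seed_mass = rng.lognormal(mean=np.log(20.0), sigma=1.2, size=n_species)

    mix = np.asarray(guild_mix, float)
    if mix.size != 3 or mix.sum() <= 0:
        raise ConfigError("guild_mix must be three nonnegative weights")
    counts = np.floor(mix / mix.sum() * n_species).astype(int)
    while counts.sum() < n_species:
        counts[np.argmax(mix / mix.sum() * n_species - counts)] += 1
    guild_arr = np.repeat(list(traits_mod.GUILDS), counts)
    guild_arr = guild_arr[rng.permutation(n_species)]
    temp = np.array([GUILD_TEMP_C[g] for g in guild_arr]) \
        + rng.normal(0, 0.8, n_species)

    base = np.exp(rng.normal(0, 1.0, n_species)) \
        * np.array([GUILD_WEIGHT[g] for g in guild_arr])
    base = base / base.sum()

    tdf = pd.DataFrame({"shade": shade, "drought": drought,
                        "waterlogging": waterlogging,
                        "seed_mass_mg": seed_mass, "temp_pref_c": temp},
                       index=pd.Index(codes, name="species"))
    return SpeciesPool(codes=codes, traits=traits_mod.validate_traits(tdf),
                       guilds=pd.Series(guild_arr, index=list(codes),
                                        name="guild"),
                       base_intensity=base)


# ---------------------------------------------------------------------------
# scenario configuration


@dataclass(frozen=True)
class ScenarioConfig:
    """Everything needed to generate one two-period synthetic survey."""
    scenario: str = "null"
    effect: float = 0.0
    target_species: tuple[str, ...] | None = None
    target_guild: str | None = None
    target_trait: str = "shade"
    n_rows: int = 12              # lattice rows, 100 m apart
    stakes_per_row: int = 20      # stakes per row, 50 m apart
    row_spacing: float = 100.0
    stake_spacing: float = 50.0
    jitter_t1_mean: float = 7.41  # mean period-1 start-point offset (m)
    density: tuple[float, float] = (0.035, 0.05)   # mature, sapling per m^2
    dbh_mature: tuple[float, float] = (3.2, 0.5)   # lognormal mu, sigma (cm)
    dbh_sapling: tuple[float, float] = (1.2, 0.5)
    field_length: float = 25.0    # fine-scale composition length scale (m)
    field_sigma: float = 0.4      # fine-scale log-intensity amplitude
    patch_sigma: float = 0.8      # patch-mosaic log-intensity amplitude
    window_radius: float = 25.0   # Poisson realisation disc per start point
    block_size: tuple[float, float] = (200.0, 300.0)  # patch/turnover blocks
    cohorts: tuple[str, ...] = ("mature", "sapling")
    seed: int | None = None

    def __post_init__(self):
        if self.scenario not in SCENARIOS:
            raise ConfigError(f"unknown scenario {self.scenario!r}")
        if self.scenario in ("homogenization", "differentiation", "turnover") \
                and not 0.0 <= self.effect <= 1.0:
            raise ConfigError(
                f"{self.scenario} effect must be in [0, 1], got {self.effect}")
        if self.scenario == "abundance_shift" and self.effect <= 0:
            raise ConfigError("abundance_shift effect is a multiplier > 0")

    def default_mesh(self) -> tuple[float, float]:
        """Mesh grouping 4 stakes x 3 rows (matches the default lattice)."""
        return (4 * self.stake_spacing, 3 * self.row_spacing)


def stake_lattice(cfg: ScenarioConfig) -> pd.DataFrame:
    xs = np.arange(cfg.stakes_per_row) * cfg.stake_spacing
    ys = np.arange(cfg.n_rows) * cfg.row_spacing
    xx, yy = np.meshgrid(xs, ys)
    n = xx.size
    return pd.DataFrame({
        "point_id": [f"P{i + 1:04d}" for i in range(n)],
        "x": xx.ravel(), "y": yy.ravel()})


# ---------------------------------------------------------------------------
# intensity surfaces


def _smooth_fields(xy: np.ndarray, n_species: int, length: float,
                   sigma: float, rng, n_features: int = 32) -> np.ndarray:
    """Gaussian-process-like log-intensity fields via random Fourier bases."""
    n = xy.shape[0]
    out = np.empty((n, n_species))
    for j in range(n_species):
        omega = rng.normal(0.0, 1.0 / length, size=(n_features, 2))
        phase = rng.uniform(0, 2 * np.pi, n_features)
        amp = rng.standard_normal(n_features)
        proj = xy @ omega.T + phase
        out[:, j] = sigma * np.sqrt(2.0 / n_features) * (
            np.cos(proj) * amp).sum(axis=1)
    return out


def _normalise_rows(p: np.ndarray) -> np.ndarray:
    p = np.clip(p, 0.0, None)
    s = p.sum(axis=1, keepdims=True)
    if np.any(s <= 0):
        raise ValidationError("a stake lost all species intensity")
    return p / s


def _draw_profiles(pool, cfg, xy, rng):
    """One period's relative composition profiles at every stake.

    The log-intensity of each species is the sum of an iid patch-mosaic
    component (one draw per species and habitat patch of ``block_size`` —
    the upland/lowland mosaic that makes neighbouring cells genuinely
    different) and a fine-scale smooth field (within-patch microsite
    variation at ``field_length``).
    """
    bx = np.floor(xy[:, 0] / cfg.block_size[0]).astype(int)
    by = np.floor(xy[:, 1] / cfg.block_size[1]).astype(int)
    blocks, block_of = np.unique(np.stack([bx, by], 1), axis=0,
                                 return_inverse=True)
    patch = cfg.patch_sigma * rng.standard_normal(
        (len(blocks), pool.n_species))
    f = patch[block_of] + _smooth_fields(
        xy, pool.n_species, cfg.field_length, cfg.field_sigma, rng)
    return _normalise_rows(pool.base_intensity[None, :] * np.exp(f))


def _tilt_for_trait_shift(p: np.ndarray, t: np.ndarray, delta: float
                          ) -> np.ndarray:
    """Exponentially tilt each row of p so sum(p t)/sum(p) rises by delta."""
    out = np.zeros_like(p)
    for s in range(p.shape[0]):
        ps = p[s]
        present = ps > 0
        tp = t[present]
        logp = np.log(ps[present])
        cur = float(ps @ t / ps.sum())
        tmax, tmin = tp.max(), tp.min()
        # a weighted mean cannot pass the most extreme species trait; clip
        # the per-stake target into the attainable range (tiny margin) and
        # refuse only when most of the requested shift is out of reach
        margin = 1e-3 * (tmax - tmin)
        target = float(np.clip(cur + delta, tmin + margin, tmax - margin))
        if abs(target - cur) < 0.1 * abs(delta):
            raise ConfigError(
                f"trait shift {delta:+g} unreachable at a stake "
                f"(attainable range {tmin:.3g}..{tmax:.3g}, current {cur:.3g})")

        def gap(b):
            logw = logp + b * tp
            w = np.exp(logw - logw.max())
            return float(w @ tp / w.sum()) - target

        lo, hi = -1.0, 1.0  # gap is monotone increasing in the tilt
        while gap(hi) < 0 and hi < 1e6:
            hi *= 2
        while gap(lo) > 0 and lo > -1e6:
            lo *= 2
        b = optimize.brentq(gap, lo, hi)
        logw = logp + b * tp
        out[s, present] = np.exp(logw - logw.max())
    return _normalise_rows(out)


@dataclass
class SimulatedLandscape:
    """Stakes plus per-period, per-species relative intensity profiles."""
    stakes: pd.DataFrame
    profiles: dict[str, np.ndarray]   # period -> (n_stakes, n_species)
    pool: SpeciesPool
    config: ScenarioConfig

    def true_dispersion(self, period: str) -> float:
        """Mean Hellinger distance of stake profiles to their centroid."""
        y = np.sqrt(self.profiles[period])
        c = y.mean(axis=0)
        return float(np.sqrt(((y - c) ** 2).sum(axis=1)).mean())


def simulate_intensities(pool: SpeciesPool, cfg: ScenarioConfig,
                         rng_t1=None, rng_t2=None) -> SimulatedLandscape:
    """Build the two periods' species intensity surfaces for a scenario."""
    ss = np.random.SeedSequence(cfg.seed)
    kids = ss.spawn(2)
    rng_t1 = rng_t1 if rng_t1 is not None else np.random.default_rng(kids[0])
    rng_t2 = rng_t2 if rng_t2 is not None else np.random.default_rng(kids[1])

    stakes = stake_lattice(cfg)
    xy = stakes[["x", "y"]].to_numpy()
    p1 = _draw_profiles(pool, cfg, xy, rng_t1)
    lam = cfg.effect

    if cfg.scenario in ("null", "homogenization", "differentiation",
                        "turnover"):
        p2 = _draw_profiles(pool, cfg, xy, rng_t2)
        # lam == 0 must reduce bit-for-bit to the null draw
        if cfg.scenario == "homogenization" and lam > 0:
            p2 = _normalise_rows((1 - lam) * p2
                                 + lam * p2.mean(axis=0, keepdims=True))
        elif cfg.scenario == "differentiation" and lam > 0:
            mean = p2.mean(axis=0, keepdims=True)
            p2 = _normalise_rows(mean + (1 + lam) * (p2 - mean))
        elif cfg.scenario == "turnover" and lam > 0:
            bx = np.floor(xy[:, 0] / cfg.block_size[0]).astype(int)
            by = np.floor(xy[:, 1] / cfg.block_size[1]).astype(int)
            nspecies = pool.n_species
            shift = 1 + (bx * 7 + by * 3) % (nspecies - 1)
            rotated = np.empty_like(p2)
            for s in range(p2.shape[0]):
                rotated[s] = np.roll(p2[s], shift[s])
            p2 = _normalise_rows((1 - lam) * p2 + lam * rotated)
    elif cfg.scenario == "abundance_shift":
        targets = _resolve_targets(pool, cfg)
        mult = np.ones(pool.n_species)
        mult[targets] = cfg.effect
        p2 = _normalise_rows(p1 * mult[None, :])
    else:  # trait_shift
        t = traits_mod.trait_values(pool.traits, cfg.target_trait)
        p2 = _tilt_for_trait_shift(p1, t.to_numpy(float), cfg.effect)

    return SimulatedLandscape(stakes=stakes,
                              profiles={"T1": p1, "T2": p2},
                              pool=pool, config=cfg)


def _resolve_targets(pool: SpeciesPool, cfg: ScenarioConfig) -> np.ndarray:
    if cfg.target_species:
        idx = [pool.codes.index(s) for s in cfg.target_species]
    elif cfg.target_guild:
        idx = [i for i, c in enumerate(pool.codes)
               if pool.guilds[c] == cfg.target_guild]
    else:
        idx = [int(np.argmax(pool.base_intensity))]
    if not idx:
        raise ConfigError("abundance_shift target matches no species")
    return np.asarray(idx)


# ---------------------------------------------------------------------------
# point-quarter sampling


def _truncated_lognormal(rng, mu, sigma, lo, hi, size):
    dist = stats.lognorm(s=sigma, scale=np.exp(mu))
    a, b = dist.cdf(lo), dist.cdf(hi)
    return dist.ppf(a + rng.random(size) * (b - a))


def sample_point_quarter(landscape: SimulatedLandscape, period: str,
                         rng) -> pd.DataFrame:
    """Realise one period's survey records from the intensity surfaces.

    Trees are a marked Poisson process in a ``window_radius`` disc around
    each start point; per compass quadrant the nearest tree is recorded.
    Quadrants in which the disc holds no tree yield no record (as in the
    field, where a missing corner simply goes unrecorded).
    """
    cfg = landscape.config
    stakes = landscape.stakes
    n_stakes = len(stakes)
    profiles = landscape.profiles[period]
    cum = np.cumsum(profiles, axis=1)
    area = np.pi * cfg.window_radius ** 2
    frames = []

    # The historical protocol started each point-quarter sample a short walk
    # from the stake (jitter_t1_mean); its observable consequence is that the
    # two periods sample different individuals around the same stake, which
    # the independent per-period Poisson realisation below reproduces
    # directly (tree positions are drawn relative to the start point, and
    # the offset is small against the composition field's length scale).
    for cohort in cfg.cohorts:
        dens = cfg.density[0] if cohort == "mature" else cfg.density[1]
        counts = rng.poisson(dens * area, n_stakes)
        total = int(counts.sum())
        stake_idx = np.repeat(np.arange(n_stakes), counts)
        rr = cfg.window_radius * np.sqrt(rng.random(total))
        ang = rng.uniform(0, 2 * np.pi, total)
        dx, dy = rr * np.cos(ang), rr * np.sin(ang)
        u = rng.random(total)
        sp_idx = (u[:, None] > cum[stake_idx]).sum(axis=1)
        sp_idx = np.minimum(sp_idx, landscape.pool.n_species - 1)
        if cohort == "mature":
            mu, sg = cfg.dbh_mature
            dbh = _truncated_lognormal(rng, mu, sg, 10.0, np.inf, total)
        else:
            mu, sg = cfg.dbh_sapling
            dbh = _truncated_lognormal(rng, mu, sg, 0.0, 10.0 - 1e-9, total)
        quadrant = np.where(dx >= 0, np.where(dy >= 0, 1, 4),
                            np.where(dy >= 0, 2, 3))
        dist = np.hypot(dx, dy)

        key = stake_idx * 4 + (quadrant - 1)
        order = np.lexsort((dist, key))
        first = np.ones(total, dtype=bool)
        first[1:] = key[order][1:] != key[order][:-1]
        sel = order[first]

        codes = np.array(landscape.pool.codes)
        frames.append(pd.DataFrame({
            "point_id": stakes["point_id"].to_numpy()[stake_idx[sel]],
            "period": period,
            "quadrant": quadrant[sel],
            "species": codes[sp_idx[sel]],
            "dbh_cm": dbh[sel],
            "distance_m": dist[sel],
            "cohort": cohort,
        }))
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(["point_id", "cohort", "quadrant"],
                           kind="stable").reset_index(drop=True)


# ---------------------------------------------------------------------------
# full survey generation


@dataclass
class SyntheticSurvey:
    grid_points: pd.DataFrame
    records: pd.DataFrame
    traits: pd.DataFrame
    guilds: pd.Series
    landscape: SimulatedLandscape
    ground_truth: dict

    def write(self, out_dir) -> dict[str, Path]:
        """Write the survey/trait/guild CSVs plus a ground-truth sidecar."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {"survey": out / "survey.csv", "traits": out / "traits.csv",
                 "guilds": out / "guilds.csv",
                 "ground_truth": out / "ground_truth.json"}
        write_survey(self.grid_points, self.records, paths["survey"])
        self.traits.to_csv(paths["traits"], index_label="species")
        self.guilds.rename("guild").to_csv(paths["guilds"],
                                           index_label="species")
        with open(paths["ground_truth"], "w") as fh:
            json.dump(self.ground_truth, fh, indent=1, sort_keys=True)
        return paths


def generate_survey(cfg: ScenarioConfig,
                    pool: SpeciesPool | None = None) -> SyntheticSurvey:
    """Generate a complete two-period synthetic resurvey dataset."""
    ss = np.random.SeedSequence(cfg.seed)
    k_pool, k_f1, k_f2, k_s1, k_s2 = ss.spawn(5)
    if pool is None:
        pool = make_species_pool(seed=k_pool)
    landscape = simulate_intensities(
        pool, cfg, rng_t1=np.random.default_rng(k_f1),
        rng_t2=np.random.default_rng(k_f2))
    rec1 = sample_point_quarter(landscape, "T1", np.random.default_rng(k_s1))
    rec2 = sample_point_quarter(landscape, "T2", np.random.default_rng(k_s2))
    records = pd.concat([rec1, rec2], ignore_index=True)

    grid_points = landscape.stakes.copy()
    sampled = records.groupby("point_id")["period"].agg(
        lambda s: tuple(sorted(set(s))))
    grid_points["sampled_in"] = grid_points["point_id"].map(sampled)

    truth = {
        "scenario": cfg.scenario, "effect": cfg.effect, "seed": cfg.seed,
        "n_stakes": len(grid_points),
        "regional_profile": {
            p: dict(zip(pool.codes,
                        np.round(landscape.profiles[p].mean(axis=0), 6)))
            for p in PERIODS},
        "true_dispersion": {p: landscape.true_dispersion(p) for p in PERIODS},
    }
    return SyntheticSurvey(grid_points=grid_points, records=records,
                           traits=pool.traits, guilds=pool.guilds,
                           landscape=landscape, ground_truth=truth)


# ---------------------------------------------------------------------------
# calibration / power experiments


def _wilson_ci(k: int, n: int, level: float = 0.95):
    z = stats.norm.ppf(0.5 + level / 2)
    p = k / n
    denom = 1 + z ** 2 / n
    centre = (p + z ** 2 / (2 * n)) / denom
    half = z * np.sqrt(p * (1 - p) / n + z ** 2 / (4 * n ** 2)) / denom
    return max(0.0, centre - half), min(1.0, centre + half)


def analyse_dataset(survey: SyntheticSurvey, *, n_perm: int = 999,
                    min_points: int = 10, cohort: str = "mature",
                    seed=None) -> dict:
    """Run the homogenization and composition tests on one dataset.

    Builds the fishnet on the survey's own lattice, assembles the two
    periods' relative-abundance matrices for the cohort, and runs the
    dispersion test and PERMANOVA on the stacked Hellinger distances.
    """
    from .survey import build_fishnet, community_matrix

    cfg = survey.landscape.config
    fishnet = build_fishnet(survey.grid_points,
                            mesh_sizes=[cfg.default_mesh()], offsets=[0.0],
                            min_points=min_points)
    sub = survey.records[survey.records["cohort"] == cohort]
    species = sorted(sub["species"].unique())
    mats = {p: community_matrix(survey.records, fishnet,
                                "relative_abundance", period=p,
                                cohort=cohort, species=species)
            for p in PERIODS}
    stacked = pd.concat(
        [mats[p].values.rename(index=lambda c, p=p: f"{c}|{p}")
         for p in PERIODS])
    groups = [lbl.split("|")[1] for lbl in stacked.index]
    dm = beta.distance_matrix(beta.hellinger_transform(stacked))
    ss = (seed if isinstance(seed, np.random.SeedSequence)
          else np.random.SeedSequence(seed))
    kids = ss.spawn(2)
    disp = beta.dispersion_test(dm, groups, n_perm=n_perm, seed=kids[0],
                                method="permutation")
    perm = beta.permanova(dm, groups, n_perm=n_perm, seed=kids[1],
                          method="permutation")
    return {"dispersion": disp, "permanova": perm, "fishnet": fishnet,
            "matrices": mats}


def run_calibration(scenario_grid: Sequence[tuple[str, float]],
                    n_datasets: int, seed=None, *, alpha: float = 0.05,
                    n_perm: int = 999, cohort: str = "mature",
                    min_points: int = 10,
                    cfg_base: ScenarioConfig | None = None) -> pd.DataFrame:
    """Rejection-rate experiment over a scenario x effect grid.

    For each grid cell, ``n_datasets`` independent surveys are generated and
    analysed; the returned table reports, per test, the fraction rejecting
    at ``alpha`` with a 95% Wilson interval, and for the dispersion test the
    fraction reporting the homogenization direction.
    """
    if cfg_base is None:
        cfg_base = ScenarioConfig()
    rows = []
    for scenario, effect in scenario_grid:
        # common random numbers: every grid cell reuses the same dataset
        # seeds, so scenarios differ only through their transformation
        # (fresh SeedSequence objects per cell: spawning is stateful)
        kids = np.random.SeedSequence(seed).spawn(n_datasets)
        rej = {"dispersion": 0, "permanova": 0}
        homog_dir = 0
        for k in range(n_datasets):
            dseed, aseed = kids[k].spawn(2)
            cfg = dataclasses.replace(
                cfg_base, scenario=scenario, effect=effect,
                seed=int(dseed.generate_state(1)[0] & 0x7FFFFFFF))
            survey = generate_survey(cfg)
            res = analyse_dataset(survey, n_perm=n_perm, cohort=cohort,
                                  min_points=min_points, seed=aseed)
            if res["dispersion"].p_perm < alpha:
                rej["dispersion"] += 1
            if res["permanova"].p_perm < alpha:
                rej["permanova"] += 1
            if res["dispersion"].direction == "homogenization":
                homog_dir += 1
        for test, k in rej.items():
            lo, hi = _wilson_ci(k, n_datasets)
            rows.append({"scenario": scenario, "effect": effect,
                         "test": test, "n_datasets": n_datasets,
                         "alpha": alpha, "rejection_rate": k / n_datasets,
                         "ci_low": lo, "ci_high": hi,
                         "homogenization_direction_rate":
                             homog_dir / n_datasets
                             if test == "dispersion" else np.nan})
    return pd.DataFrame(rows)


def cwm_shift_recovery(n_seeds: int, delta: float = 0.5,
                       trait: str = "shade", seed=None, *,
                       cohort: str = "mature", min_points: int = 10,
                       cfg_base: ScenarioConfig | None = None) -> np.ndarray:
    """Recovered mean CWM change under the trait_shift scenario.

    Returns the per-seed mean over cells of (CWM_T2 - CWM_T1) computed from
    the sampled records, for comparison with the injected ``delta``.
    """
    from .survey import build_fishnet, community_matrix

    if cfg_base is None:
        cfg_base = ScenarioConfig()
    kids = np.random.SeedSequence(seed).spawn(n_seeds)
    out = np.empty(n_seeds)
    for k in range(n_seeds):
        cfg = dataclasses.replace(
            cfg_base, scenario="trait_shift", effect=delta,
            target_trait=trait,
            seed=int(kids[k].generate_state(1)[0] & 0x7FFFFFFF))
        survey = generate_survey(cfg)
        fishnet = build_fishnet(survey.grid_points,
                                mesh_sizes=[cfg.default_mesh()],
                                offsets=[0.0], min_points=min_points)
        cwms = {}
        for p in PERIODS:
            mat = community_matrix(survey.records, fishnet,
                                   "relative_abundance", period=p,
                                   cohort=cohort)
            cwms[p] = traits_mod.cwm(mat, survey.traits, trait)
        out[k] = float((cwms["T2"] - cwms["T1"]).mean())
    return out
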