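"""Shared fixtures: tiny hand-written surveys and small synthetic landscapes."""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
import pytest

from resurvey.survey import build_fishnet
from resurvey.synthetic import ScenarioConfig, generate_survey, make_species_pool

TINY_SURVEY = """point_id,x,y,period,quadrant,species,dbh_cm,distance_m
P1,0,0,T1,1,ACRU,25.0,3.2
P1,0,0,T1,2,ACRU,12.0,4.1
P1,0,0,T1,3,PIST,30.5,2.0
P1,0,0,T1,4,QURU,15.0,5.5
P1,0,0,T2,1,ACRU,27.0,3.0
P1,0,0,T2,2,PIST,11.0,4.4
P1,0,0,T2,3,PIST,33.0,2.1
P1,0,0,T2,4,FAGR,18.0,1.9
"""


@pytest.fixture
def tiny_survey_path(tmp_path):
    """One grid point, two periods, four quadrants each: 8 mature trees."""
    path = tmp_path / "tiny.csv"
    path.write_text(TINY_SURVEY)
    return path


def grid_df(n_x=10, n_y=10, dx=50.0, dy=100.0):
    xx, yy = np.meshgrid(np.arange(n_x) * dx, np.arange(n_y) * dy)
    return pd.DataFrame({
        "point_id": [f"P{i:03d}" for i in range(xx.size)],
        "x": xx.ravel().astype(float), "y": yy.ravel().astype(float)})


def records_df(rows):
    """Build a records frame from (point_id, period, quadrant, species, dbh)."""
    df = pd.DataFrame(rows, columns=["point_id", "period", "quadrant",
                                     "species", "dbh_cm"])
    df["distance_m"] = 1.0
    df["cohort"] = np.where(df["dbh_cm"] >= 10.0, "mature", "sapling")
    return df


#: Small landscape used for resampling experiments: 10 cells x 12 stakes.
SMALL_CFG = ScenarioConfig(stakes_per_row=8, n_rows=15, cohorts=("mature",))


@pytest.fixture(scope="session")
def null_survey():
    """One deterministic null synthetic survey at the default study scale."""
    return generate_survey(ScenarioConfig(scenario="null", seed=101))


@pytest.fixture(scope="session")
def null_fishnet(null_survey):
    cfg = null_survey.landscape.config
    return build_fishnet(null_survey.grid_points,
                         mesh_sizes=[cfg.default_mesh()], offsets=[0.0])


@pytest.fixture(scope="session")
def species_pool():
    return make_species_pool(n_species=24, seed=5)


def small_survey(seed, scenario="null", effect=0.0, **kwargs):
    cfg = dataclasses.replace(SMALL_CFG, scenario=scenario, effect=effect,
                              seed=seed, **kwargs)
    return generate_survey(cfg)
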