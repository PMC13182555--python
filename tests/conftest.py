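import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("default", derandomize=True, deadline=None)
settings.load_profile("default")

from socialtuning.cohort import CohortConfig, generate_session, sample_cohort
from socialtuning.design import build_detection_design, build_discrimination_design
from socialtuning.sim import AnimationSpec, KinematicsConfig, WorldConfig


@pytest.fixture(scope="session")
def world():
    return WorldConfig()


@pytest.fixture(scope="session")
def world_disc():
    return WorldConfig(duration=8.0)


@pytest.fixture(scope="session")
def kin():
    return KinematicsConfig()


def chase_spec(directness: float, seed: int) -> AnimationSpec:
    return AnimationSpec(
        task="detection", condition="chase", attribute_value=directness, seed=seed
    )


def charge_spec(speed: float, seed: int) -> AnimationSpec:
    return AnimationSpec(
        task="discrimination", condition="charge", attribute_value=speed, seed=seed
    )


@pytest.fixture(scope="session")
def small_cohort():
    """12 observers with two sessions of detection + discrimination data."""
    cfg = CohortConfig(n_participants=12, seed=3)
    cohort = sample_cohort(cfg)
    det = {s: build_detection_design(12, seed=10 + s) for s in (1, 2)}
    dis = {s: build_discrimination_design(10, seed=20 + s) for s in (1, 2)}
    chunks = []
    for s in (1, 2):
        for table in (det[s], dis[s]):
            t = table.copy()
            t["stim_id"] = t["stim_id"] + f"_s{s}"
            for prof in cohort:
                chunks.append(generate_session(prof, t, s, {}, seed=99))
    return cfg, cohort, pd.concat(chunks, ignore_index=True)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
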