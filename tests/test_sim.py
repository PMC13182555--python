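"""Simulator: pursuit geometry, the mimic control, charge phases, features."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from socialtuning.sim import (
    AnimationSpec,
    ConfigError,
    KinematicsConfig,
    Trajectory,
    WorldConfig,
    directness_from_subtlety,
    mean_agent_distance,
    simulate_charge,
    simulate_chase,
    simulate_invisible_chase,
    subtlety_from_directness,
)

from conftest import charge_spec, chase_spec


class TestDirectness:
    @pytest.mark.parametrize("subtlety,expected", [(180.0, 0.0), (0.0, 1.0), (90.0, 0.5)])
    def test_endpoints_and_midpoint(self, subtlety, expected):
        assert directness_from_subtlety(subtlety) == expected

    @given(st.floats(0.0, 180.0, allow_subnormal=False))
    @settings(max_examples=50, deadline=None)
    def test_round_trip(self, subtlety):
        assert subtlety_from_directness(directness_from_subtlety(subtlety)) == pytest.approx(
            subtlety, abs=1e-12
        )

    @pytest.mark.parametrize("bad", [-1.0, 180.5, 1000.0])
    def test_domain_error(self, bad):
        with pytest.raises(ValueError):
            directness_from_subtlety(bad)


def displacements(traj: Trajectory, agent: str) -> np.ndarray:
    p = traj.positions(agent)
    return np.diff(p, axis=0)


def angular_deviation(traj: Trajectory, pursuer: str, target: str) -> np.ndarray:
    """|angle| between the pursuer's realized velocity and the bearing to the
    target's previous-frame position, per frame (radians)."""
    p = traj.positions(pursuer)
    q = traj.positions(target)
    v = np.diff(p, axis=0)
    b = q[:-1] - p[:-1]
    cross = v[:, 0] * b[:, 1] - v[:, 1] * b[:, 0]
    dot = np.sum(v * b, axis=1)
    return np.abs(np.arctan2(cross, dot))


class TestChase:
    def test_heat_seeking_at_full_directness(self):
        traj = simulate_chase(chase_spec(1.0, seed=5))
        clamped = traj.agent("predator")["clamped"].to_numpy()[1:]
        dev = angular_deviation(traj, "predator", "prey")
        assert np.all(dev[~clamped] <= 1e-6)

    def test_deviation_bounded_by_subtlety(self):
        traj = simulate_chase(chase_spec(0.5, seed=7))
        clamped = traj.agent("predator")["clamped"].to_numpy()[1:]
        dev = angular_deviation(traj, "predator", "prey")
        assert np.all(dev[~clamped] <= math.pi / 2 + 1e-6)

    @pytest.mark.parametrize("directness", [0.0, 1 / 3, 2 / 3, 1.0])
    def test_pursuit_bound_invariant(self, directness):
        bound = math.radians(180.0 * (1.0 - directness)) + 1e-6
        for seed in (0, 1):
            traj = simulate_chase(chase_spec(directness, seed=seed))
            clamped = traj.agent("predator")["clamped"].to_numpy()[1:]
            dev = angular_deviation(traj, "predator", "prey")
            assert np.all(dev[~clamped] <= bound)

    def test_direct_chases_close_the_distance(self):
        """Monte-Carlo oracle: fully direct chases end up much closer on
        average than fully indirect ones."""
        means = {}
        for d in (0.0, 1.0):
            vals = [
                mean_agent_distance(simulate_chase(chase_spec(d, seed=s))) for s in range(50)
            ]
            means[d] = np.mean(vals)
        assert means[1.0] < means[0.0]

    def test_frame_count_and_bounds(self, world, kin):
        traj = simulate_chase(chase_spec(0.5, seed=3), world, kin)
        for agent in ("predator", "prey"):
            p = traj.positions(agent)
            assert len(p) == round(world.duration * world.fps)
            r = world.agent_radius
            assert np.all(p[:, 0] >= r) and np.all(p[:, 0] <= world.width - r)
            assert np.all(p[:, 1] >= r) and np.all(p[:, 1] <= world.height - r)

    def test_speed_limits(self, kin):
        traj = simulate_chase(chase_spec(0.3, seed=11))
        pred = np.hypot(*displacements(traj, "predator").T)
        prey = np.hypot(*displacements(traj, "prey").T)
        assert pred.max() <= kin.predator_speed + 1e-6
        assert prey.max() <= max(kin.prey_speed, kin.wander_speed) + 1e-6

    def test_determinism_bitwise(self, tmp_path):
        paths = []
        for name in ("a.csv", "b.csv"):
            traj = simulate_chase(chase_spec(0.4, seed=9))
            traj.to_csv(tmp_path / name)
            paths.append((tmp_path / name).read_bytes())
        assert paths[0] == paths[1]

    def test_task_mismatch_rejected(self):
        spec = AnimationSpec(task="discrimination", condition="charge", attribute_value=3.0, seed=0)
        with pytest.raises(ConfigError):
            simulate_chase(spec)


def mimic_spec(directness, seed):
    return AnimationSpec(
        task="control", condition="invisible_chase", attribute_value=directness, seed=seed
    )


class TestInvisibleChase:
    def test_mimic_antisymmetry_exact(self):
        """Mimic and hidden-prey per-frame displacements sum to (0,0)
        exactly on frames where neither agent was wall-clamped."""
        traj = simulate_invisible_chase(mimic_spec(0.833, seed=3))
        dp = displacements(traj, "prey")
        dm = displacements(traj, "mimic")
        cl = (
            traj.agent("prey")["clamped"].to_numpy()[1:]
            | traj.agent("mimic")["clamped"].to_numpy()[1:]
        )
        s = (dp + dm)[~cl]
        assert np.all(s == 0.0)

    def test_mimic_equals_replay_oracle(self):
        """Replaying the saved prey path and negating displacements (with the
        same wall clamping) reproduces the mimic trajectory."""
        traj = simulate_invisible_chase(mimic_spec(0.833, seed=3))
        world = traj.world
        prey = traj.positions("prey")
        mimic = traj.positions("mimic")
        xmin, ymin, xmax, ymax = world.bounds
        grid = 2.0**22
        pos = mimic[0].copy()
        replay = [pos.copy()]
        for t in range(1, len(prey)):
            pos = pos - (prey[t] - prey[t - 1])
            pos[0] = min(max(pos[0], xmin), xmax)
            pos[1] = min(max(pos[1], ymin), ymax)
            pos = np.round(pos * grid) / grid
            replay.append(pos.copy())
        assert np.array_equal(np.array(replay), mimic)

    def test_three_agents_one_invisible(self):
        traj = simulate_invisible_chase(mimic_spec(0.5, seed=1))
        assert sorted(traj.agents) == ["mimic", "predator", "prey"]
        assert sorted(traj.visible_agents) == ["mimic", "predator"]

    def test_predator_chases_hidden_prey(self):
        traj = simulate_invisible_chase(mimic_spec(1.0, seed=2))
        clamped = traj.agent("predator")["clamped"].to_numpy()[1:]
        dev = angular_deviation(traj, "predator", "prey")
        assert np.all(dev[~clamped] <= 1e-6)


class TestCharge:
    def test_charge_displacement_equals_charge_speed(self, world_disc):
        traj = simulate_charge(charge_spec(9.0, seed=1), world_disc)
        for agent in ("agent_a", "agent_b"):
            a = traj.agent(agent)
            d = np.hypot(np.diff(a["x"]), np.diff(a["y"]))
            charging = (a["phase"] == "charge").to_numpy()[1:]
            assert charging.any()
            assert np.allclose(d[charging], 9.0, atol=1e-6)

    def test_slowest_charge_still_reaches_contact(self, world_disc, kin):
        traj = simulate_charge(charge_spec(1.5, seed=1), world_disc)
        a = traj.positions("agent_a")
        b = traj.positions("agent_b")
        dist = np.hypot(*(a - b).T)
        assert (dist <= kin.contact_distance).any()

    def test_wander_resumes_after_contact(self, world_disc, kin):
        traj = simulate_charge(charge_spec(6.0, seed=4), world_disc)
        a = traj.agent("agent_a")
        b = traj.agent("agent_b")
        dist = np.hypot(a["x"] - b["x"], a["y"] - b["y"]).to_numpy()
        in_charge = ((a["phase"] == "charge") | (b["phase"] == "charge")).to_numpy()
        contact_frames = np.where(in_charge & (dist <= kin.contact_distance))[0]
        assert len(contact_frames) > 0
        t = contact_frames[0]
        if t + 1 < len(a):
            assert a["phase"].iloc[t + 1] == "wander"
            assert b["phase"].iloc[t + 1] == "wander"

    def test_out_of_range_speed_warns_but_runs(self, world_disc):
        with pytest.warns(UserWarning):
            traj = simulate_charge(charge_spec(12.0, seed=0), world_disc)
        assert len(traj.positions("agent_a")) == world_disc.n_frames


class TestMeanAgentDistance:
    def test_stationary_agents(self, world):
        frames = pd.DataFrame(
            [
                (t, agent, x, 300.0, True, False, "wander")
                for t in range(10)
                for agent, x in (("predator", 250.0), ("prey", 550.0))
            ],
            columns=["frame", "agent", "x", "y", "visible", "clamped", "phase"],
        )
        spec = chase_spec(0.5, 0)
        traj = Trajectory(spec=spec, world=world, kin=KinematicsConfig(), frames=frames)
        assert mean_agent_distance(traj) == 300.0
        # symmetric under label swap
        swapped = frames.copy()
        swapped["agent"] = swapped["agent"].map({"predator": "prey", "prey": "predator"})
        traj2 = Trajectory(spec=spec, world=world, kin=KinematicsConfig(), frames=swapped)
        assert mean_agent_distance(traj2) == 300.0

    def test_control_uses_visible_pair(self):
        traj = simulate_invisible_chase(mimic_spec(0.5, seed=6))
        assert mean_agent_distance(traj) > 0  # predator vs mimic

    def test_rejects_wrong_visible_count(self):
        traj = simulate_invisible_chase(mimic_spec(0.5, seed=6))
        frames = traj.frames.copy()
        frames["visible"] = True  # three visible agents
        bad = Trajectory(spec=traj.spec, world=traj.world, kin=traj.kin, frames=frames)
        with pytest.raises(ValueError):
            mean_agent_distance(bad)


def test_directness_distance_correlation_negative(kin):
    """Across a 28-animation ladder, more direct chases have smaller mean
    inter-agent distance (the full-size stimulus-set statistic is checked in
    the acceptance suite)."""
    ds, md = [], []
    for li, d in enumerate(np.linspace(0, 1, 7)):
        for rep in range(4):
            ds.append(d)
            md.append(mean_agent_distance(simulate_chase(chase_spec(float(d), li * 4 + rep))))
    r = np.corrcoef(ds, md)[0, 1]
    assert r < 0


def test_world_config_validation():
    with pytest.raises(ConfigError):
        WorldConfig(start_left=(5.0, 300.0))  # within agent_radius of wall
    with pytest.raises(ConfigError):
        WorldConfig(start_left=(250.0, 300.0), start_right=(250.0, 300.0))
    with pytest.raises(ConfigError):
        KinematicsConfig(predator_speed=0.0)
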