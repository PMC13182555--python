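"""Two-agent animation simulator for social detection/discrimination stimuli.

Generates the three stimulus families used in the behavioral tasks:

* **chase** (detection): a predator pursues a prey with a controllable
  *chase directness* — the predator's heading each pursuit step is the exact
  bearing to the prey rotated by an angle drawn uniformly from
  ``[-subtlety, +subtlety]`` degrees, where ``subtlety = 180*(1-directness)``.
  The prey flees when the predator comes within a safety distance and
  wanders otherwise.
* **invisible chase** (control): the predator chases a prey that is present
  but invisible; a visible "mimic" agent replays the hidden prey's per-frame
  displacements rotated by 180 degrees, preserving correlated motion between
  the two visible agents without genuine pursuit.
* **charge** (discrimination): two agents alternate between wandering and
  charging directly at each other at a fixed *charge speed*; the responder
  joins a charge after a short delay and contact ends the charge phase.

Coordinates follow the screen convention: origin top-left, x rightward,
y downward, float pixels.  All stored positions are quantized to a fine
binary grid (2^-22 px) so that per-frame displacements are exact in double
precision; this makes the mimic anti-symmetry an exact identity rather than
an approximate one.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

__all__ = [
    "WorldConfig",
    "KinematicsConfig",
    "AnimationSpec",
    "Trajectory",
    "directness_from_subtlety",
    "subtlety_from_directness",
    "simulate_chase",
    "simulate_invisible_chase",
    "simulate_charge",
    "simulate",
    "mean_agent_distance",
]

# Grid spacing for position quantization.  Coarse enough that coordinates
# below 1024 px stay exactly representable, fine enough (2^-22 px) that the
# per-frame displacement error is < 5e-7 px.
_GRID = 2.0 ** 22


def _quantize(v: float) -> float:
    return round(v * _GRID) / _GRID


class ConfigError(ValueError):
    """Raised when a spec/config combination is inconsistent."""


@dataclass(frozen=True)
class WorldConfig:
    """Screen geometry and timing of one animation."""

    width: float = 800.0
    height: float = 600.0
    agent_radius: float = 12.0
    fps: int = 60
    duration: float = 6.0  # seconds; 6 for detection, 8 for discrimination
    start_left: tuple[float, float] = (250.0, 300.0)
    start_right: tuple[float, float] = (550.0, 300.0)

    def __post_init__(self) -> None:
        if min(self.width, self.height, self.fps, self.duration) <= 0:
            raise ConfigError("width, height, fps and duration must be positive")
        r = self.agent_radius
        for x, y in (self.start_left, self.start_right):
            if not (r <= x <= self.width - r and r <= y <= self.height - r):
                raise ConfigError("start points must lie at least agent_radius from every wall")
        if self.start_left == self.start_right:
            raise ConfigError("start points must be distinct")

    @property
    def n_frames(self) -> int:
        return round(self.duration * self.fps)

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the legal region for agent centers."""
        r = self.agent_radius
        return (r, r, self.width - r, self.height - r)


@dataclass(frozen=True)
class KinematicsConfig:
    """Speeds (px/frame), distances (px) and cadences (frames) of the agents.

    The original stimulus-generation attribute values are not public; these
    defaults were calibrated once against the published macro-statistics of
    the stimulus set (a 6 s chase remains unresolved, so pursuit rather than
    capture drives the motion statistics; the directness/mean-distance
    correlation of a default 84-animation detection set lands near the
    reported r = -0.69) and then frozen.
    """

    predator_speed: float = 2.0
    prey_speed: float = 3.0
    wander_speed: float = 2.5
    wander_max_turn: float = 8.0  # degrees/frame
    safety_distance: float = 100.0
    heading_resample_interval: int = 60  # frames between deviation redraws
    charge_wander_min: int = 60
    charge_wander_max: int = 180
    charge_response_delay: int = 12
    contact_distance: float = 24.0

    def __post_init__(self) -> None:
        for name, v in asdict(self).items():
            if v <= 0:
                raise ConfigError(f"{name} must be strictly positive")


Task = Literal["detection", "discrimination", "control"]
Condition = Literal["chase", "invisible_chase", "charge"]


@dataclass(frozen=True)
class AnimationSpec:
    """Everything needed to (re)generate one animation deterministically."""

    task: Task
    condition: Condition
    attribute_value: float  # directness in [0,1] or charge speed in px/frame
    seed: int
    level_index: int = 0
    predator_color: str = "black"
    predator_side: str = "left"
    stim_id: str = ""

    def __post_init__(self) -> None:
        if self.task in ("detection", "control"):
            if not 0.0 <= self.attribute_value <= 1.0:
                raise ConfigError("chase directness must lie in [0, 1]")
        if self.predator_side not in ("left", "right"):
            raise ConfigError("predator_side must be 'left' or 'right'")
        if self.predator_color not in ("black", "gray"):
            raise ConfigError("predator_color must be 'black' or 'gray'")


@dataclass
class Trajectory:
    """Per-frame positions of every agent of one animation.

    ``frames`` has columns ``frame, agent, x, y, visible`` plus two
    bookkeeping columns that are not part of the on-disk format:
    ``clamped`` (the agent hit a wall this frame) and ``phase``
    (``wander``/``charge``/``pursue``/``flee``).
    """

    spec: AnimationSpec
    world: WorldConfig
    kin: KinematicsConfig
    frames: pd.DataFrame = field(repr=False)

    CSV_COLUMNS = ("frame", "agent", "x", "y", "visible")

    def agent(self, name: str) -> pd.DataFrame:
        out = self.frames[self.frames["agent"] == name]
        if out.empty:
            raise KeyError(f"no agent named {name!r}")
        return out.reset_index(drop=True)

    def positions(self, name: str) -> np.ndarray:
        """(n_frames, 2) array of an agent's positions."""
        a = self.agent(name)
        return a[["x", "y"]].to_numpy()

    @property
    def agents(self) -> list[str]:
        return list(dict.fromkeys(self.frames["agent"]))

    @property
    def visible_agents(self) -> list[str]:
        vis = self.frames[self.frames["visible"]]
        return list(dict.fromkeys(vis["agent"]))

    def to_csv(self, path: str | Path) -> None:
        df = self.frames.loc[:, list(self.CSV_COLUMNS)].copy()
        df["visible"] = df["visible"].astype(bool)
        df.to_csv(path, index=False, lineterminator="\n")

    def write(self, out_dir: str | Path) -> Path:
        """Write ``{stim_id}.csv`` plus a ``{stim_id}.json`` sidecar."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        stem = self.spec.stim_id or f"anim_{self.spec.seed}"
        csv_path = out_dir / f"{stem}.csv"
        self.to_csv(csv_path)
        sidecar = {
            "spec": asdict(self.spec),
            "world": asdict(self.world),
            "kinematics": asdict(self.kin),
        }
        (out_dir / f"{stem}.json").write_text(json.dumps(sidecar, indent=1) + "\n")
        return csv_path


def directness_from_subtlety(subtlety: float) -> float:
    """Convert a chase-subtlety angle (degrees in [0, 180]) to directness.

    ``directness = (180 - subtlety) / 180``: a subtlety of 0 deg is a
    heat-seeking chase (directness 1), a subtlety of 180 deg lets the
    predator head anywhere (directness 0).
    """
    if not 0.0 <= subtlety <= 180.0:
        raise ValueError(f"subtlety must be in [0, 180], got {subtlety}")
    return (180.0 - subtlety) / 180.0


def subtlety_from_directness(directness: float) -> float:
    """Inverse of :func:`directness_from_subtlety`."""
    if not 0.0 <= directness <= 1.0:
        raise ValueError(f"directness must be in [0, 1], got {directness}")
    return 180.0 - directness * 180.0


class _Agent:
    """Mutable state of one moving disc."""

    __slots__ = ("x", "y", "heading", "clamped")

    def __init__(self, xy: tuple[float, float], heading: float):
        self.x = _quantize(xy[0])
        self.y = _quantize(xy[1])
        self.heading = heading  # radians; screen convention (y down)
        self.clamped = False

    @property
    def pos(self) -> tuple[float, float]:
        return (self.x, self.y)

    def step(self, heading: float, speed: float, bounds) -> None:
        """Advance one frame along ``heading``, clamping to the legal box."""
        self.heading = heading
        nx = self.x + speed * math.cos(heading)
        ny = self.y + speed * math.sin(heading)
        xmin, ymin, xmax, ymax = bounds
        clamped = False
        if nx < xmin or nx > xmax:
            nx = min(max(nx, xmin), xmax)
            self.heading = math.pi - self.heading  # reflect x-component
            clamped = True
        if ny < ymin or ny > ymax:
            ny = min(max(ny, ymin), ymax)
            self.heading = -self.heading  # reflect y-component
            clamped = True
        self.x = _quantize(nx)
        self.y = _quantize(ny)
        self.clamped = clamped

    def move_by(self, dx: float, dy: float, bounds) -> None:
        """Displace by an exact vector, clamping to the legal box."""
        nx = self.x + dx
        ny = self.y + dy
        xmin, ymin, xmax, ymax = bounds
        cx = min(max(nx, xmin), xmax)
        cy = min(max(ny, ymin), ymax)
        self.clamped = (cx != nx) or (cy != ny)
        self.x = _quantize(cx)
        self.y = _quantize(cy)


def _bearing(src: _Agent, dst: _Agent) -> float:
    return math.atan2(dst.y - src.y, dst.x - src.x)


def _dist(a: _Agent, b: _Agent) -> float:
    return math.hypot(b.x - a.x, b.y - a.y)


class _Recorder:
    def __init__(self) -> None:
        self.rows: list[tuple] = []

    def record(self, frame: int, name: str, ag: _Agent, visible: bool, phase: str) -> None:
        self.rows.append((frame, name, ag.x, ag.y, visible, ag.clamped, phase))

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.rows, columns=["frame", "agent", "x", "y", "visible", "clamped", "phase"]
        )
        return df.sort_values(["agent", "frame"], kind="stable").reset_index(drop=True)


def _start_positions(spec: AnimationSpec, world: WorldConfig):
    """(predator_start, other_start) honoring the counterbalanced side."""
    if spec.predator_side == "left":
        return world.start_left, world.start_right
    return world.start_right, world.start_left


def _prey_move(prey: _Agent, predator: _Agent, kin: KinematicsConfig, rng, bounds) -> str:
    """Flee directly away from the predator inside the safety radius, else wander."""
    if _dist(predator, prey) < kin.safety_distance:
        away = _bearing(predator, prey)
        prey.step(away, kin.prey_speed, bounds)
        return "flee"
    turn = rng.uniform(-1.0, 1.0) * math.radians(kin.wander_max_turn)
    prey.step(prey.heading + turn, kin.wander_speed, bounds)
    return "wander"


def simulate_chase(
    spec: AnimationSpec, world: WorldConfig | None = None, kin: KinematicsConfig | None = None
) -> Trajectory:
    """Simulate a predator-prey chase at the spec's chase directness.

    Each pursuit step the predator heads along the exact bearing to the prey
    rotated by a deviation angle drawn uniformly from ``[-s, +s]`` where
    ``s = 180*(1 - directness)`` degrees.  The deviation is redrawn every
    ``heading_resample_interval`` frames and held in between (per-frame
    redraws at 60 Hz would average out and destroy the manipulation).  The
    prey flees straight away from the predator whenever it is within
    ``safety_distance`` and wanders otherwise.
    """
    world = world or WorldConfig()
    kin = kin or KinematicsConfig()
    if spec.task not in ("detection", "control") or spec.condition != "chase":
        raise ConfigError(f"simulate_chase needs a detection/control chase spec, got {spec.task}/{spec.condition}")
    rng = np.random.default_rng(spec.seed)
    subtlety = math.radians(subtlety_from_directness(spec.attribute_value))

    pred_xy, prey_xy = _start_positions(spec, world)
    predator = _Agent(pred_xy, 0.0)
    prey = _Agent(prey_xy, rng.uniform(0.0, 2.0 * math.pi))
    bounds = world.bounds
    rec = _Recorder()
    rec.record(0, "predator", predator, True, "pursue")
    rec.record(0, "prey", prey, True, "wander")

    deviation = 0.0
    for t in range(1, world.n_frames):
        if (t - 1) % kin.heading_resample_interval == 0:
            deviation = rng.uniform(-1.0, 1.0) * subtlety
        # order matters for determinism: predator aims at the prey's
        # position from the previous frame (simultaneous update)
        aim = _bearing(predator, prey) + deviation
        prey_phase = _prey_move(prey, predator, kin, rng, bounds)
        predator.step(aim, kin.predator_speed, bounds)
        rec.record(t, "predator", predator, True, "pursue")
        rec.record(t, "prey", prey, True, prey_phase)
    return Trajectory(spec=spec, world=world, kin=kin, frames=rec.to_frame())


def simulate_invisible_chase(
    spec: AnimationSpec, world: WorldConfig | None = None, kin: KinematicsConfig | None = None
) -> Trajectory:
    """Simulate the invisible-chase control stimulus.

    The prey starts at a random on-screen location and is invisible; the
    predator genuinely chases it at the spec's directness.  A visible mimic
    starts at the second regular start position and copies the hidden prey's
    realized per-frame displacement rotated by 180 degrees (negated), so the
    two *visible* agents show correlated motion without real pursuit.
    """
    world = world or WorldConfig()
    kin = kin or KinematicsConfig()
    if spec.condition != "invisible_chase":
        raise ConfigError("simulate_invisible_chase needs condition='invisible_chase'")
    rng = np.random.default_rng(spec.seed)
    subtlety = math.radians(subtlety_from_directness(spec.attribute_value))
    bounds = world.bounds
    xmin, ymin, xmax, ymax = bounds

    pred_xy, mimic_xy = _start_positions(spec, world)
    predator = _Agent(pred_xy, 0.0)
    mimic = _Agent(mimic_xy, 0.0)
    prey = _Agent(
        (rng.uniform(xmin, xmax), rng.uniform(ymin, ymax)),
        rng.uniform(0.0, 2.0 * math.pi),
    )
    rec = _Recorder()
    rec.record(0, "predator", predator, True, "pursue")
    rec.record(0, "prey", prey, False, "wander")
    rec.record(0, "mimic", mimic, True, "mimic")

    deviation = 0.0
    for t in range(1, world.n_frames):
        if (t - 1) % kin.heading_resample_interval == 0:
            deviation = rng.uniform(-1.0, 1.0) * subtlety
        aim = _bearing(predator, prey) + deviation
        px, py = prey.x, prey.y
        prey_phase = _prey_move(prey, predator, kin, rng, bounds)
        # realized (post-clamp) prey displacement, rotated 180 degrees;
        # positions are grid-quantized so the negation is exact
        mimic.move_by(-(prey.x - px), -(prey.y - py), bounds)
        predator.step(aim, kin.predator_speed, bounds)
        rec.record(t, "predator", predator, True, "pursue")
        rec.record(t, "prey", prey, False, prey_phase)
        rec.record(t, "mimic", mimic, True, "mimic")
    return Trajectory(spec=spec, world=world, kin=kin, frames=rec.to_frame())


def simulate_charge(
    spec: AnimationSpec, world: WorldConfig | None = None, kin: KinematicsConfig | None = None
) -> Trajectory:
    """Simulate the discrimination stimulus: wander/charge cycles.

    Both agents wander for a random period (uniform over
    ``[charge_wander_min, charge_wander_max]`` frames), then one agent
    charges straight at the other with per-frame displacement magnitude
    exactly ``charge_speed``; the other responds ``charge_response_delay``
    frames later.  Contact (inter-agent distance <= ``contact_distance``)
    returns both agents to wandering and schedules the next cycle.
    """
    world = world or WorldConfig()
    kin = kin or KinematicsConfig()
    if spec.task != "discrimination" or spec.condition != "charge":
        raise ConfigError("simulate_charge needs a discrimination/charge spec")
    charge_speed = float(spec.attribute_value)
    if not 1.5 <= charge_speed <= 9.0:
        import warnings

        warnings.warn(
            f"charge_speed {charge_speed} outside the standard stimulus range [1.5, 9] px/frame",
            stacklevel=2,
        )
    rng = np.random.default_rng(spec.seed)
    bounds = world.bounds

    a = _Agent(world.start_left, rng.uniform(0.0, 2.0 * math.pi))
    b = _Agent(world.start_right, rng.uniform(0.0, 2.0 * math.pi))
    agents = {"agent_a": a, "agent_b": b}
    names = ("agent_a", "agent_b")

    def schedule(now: int) -> tuple[int, str]:
        wait = int(rng.integers(kin.charge_wander_min, kin.charge_wander_max + 1))
        initiator = names[int(rng.integers(0, 2))]
        return now + wait, initiator

    charge_start, initiator = schedule(0)
    rec = _Recorder()
    rec.record(0, "agent_a", a, True, "wander")
    rec.record(0, "agent_b", b, True, "wander")

    for t in range(1, world.n_frames):
        charging = {}
        for name in names:
            is_init = name == initiator
            start = charge_start if is_init else charge_start + kin.charge_response_delay
            charging[name] = t >= start
        # simultaneous update from previous-frame positions
        prev = {n: agents[n].pos for n in names}
        for name in names:
            ag = agents[name]
            other = prev[names[1 - names.index(name)]]
            if charging[name]:
                heading = math.atan2(other[1] - ag.y, other[0] - ag.x)
                ag.step(heading, charge_speed, bounds)
                phase = "charge"
            else:
                turn = rng.uniform(-1.0, 1.0) * math.radians(kin.wander_max_turn)
                ag.step(ag.heading + turn, kin.wander_speed, bounds)
                phase = "wander"
            rec.record(t, name, ag, True, phase)
        if any(charging.values()) and _dist(a, b) <= kin.contact_distance:
            charge_start, initiator = schedule(t + 1)  # contact: back to wander
    return Trajectory(spec=spec, world=world, kin=kin, frames=rec.to_frame())


def simulate(
    spec: AnimationSpec, world: WorldConfig | None = None, kin: KinematicsConfig | None = None
) -> Trajectory:
    """Dispatch to the simulator matching ``spec.condition``."""
    if spec.condition == "chase":
        return simulate_chase(spec, world, kin)
    if spec.condition == "invisible_chase":
        return simulate_invisible_chase(spec, world, kin)
    if spec.condition == "charge":
        return simulate_charge(spec, world, kin)
    raise ConfigError(f"unknown condition {spec.condition!r}")


def mean_agent_distance(traj: Trajectory) -> float:
    """Mean over frames of the Euclidean distance between the two visible agents."""
    vis = traj.visible_agents
    if len(vis) != 2:
        raise ValueError(f"mean_agent_distance needs exactly 2 visible agents, found {len(vis)}")
    p = traj.positions(vis[0])
    q = traj.positions(vis[1])
    return float(np.mean(np.hypot(*(p - q).T)))
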