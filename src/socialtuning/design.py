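"""Counterbalanced, seeded trial tables for the behavioral sessions.

Four session layouts are supported:

* detection — 7 chase-directness levels x ``reps`` trials (default 84 trials),
* discrimination — 7 charge-speed levels x ``reps`` trials (default 70),
* mixed — detection and discrimination interleaved in six 14-trial blocks
  (block sequence 121212 or 212121, chosen per participant),
* control — chase and invisible-chase conditions fully crossed with the
  directness levels.

Predator color (black/gray) and starting side (left/right) are balanced
within task; the rating-scale label side is drawn once per participant and
carried as metadata (ratings are stored already coded to the canonical 0-1
axis, so it never enters the analysis).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .sim import ConfigError

__all__ = [
    "make_levels",
    "build_detection_design",
    "build_discrimination_design",
    "build_mixed_design",
    "build_control_design",
    "TRIAL_COLUMNS",
]

TRIAL_COLUMNS = [
    "trial_number",
    "block",
    "task",
    "condition",
    "level_index",
    "attribute_value",
    "stim_id",
    "predator_color",
    "predator_side",
    "label_side",
]

#: charge-speed stimulus range in px/frame
CHARGE_SPEED_MIN = 1.5
CHARGE_SPEED_MAX = 9.0
N_LEVELS = 7


def make_levels(task: str, n_levels: int = N_LEVELS) -> np.ndarray:
    """The attribute values of the 7 stimulus levels, varied linearly.

    Detection levels are chase-directness values equally spaced on [0, 1];
    discrimination levels are charge speeds equally spaced on [1.5, 9]
    px/frame.
    """
    if task in ("detection", "control"):
        return np.linspace(0.0, 1.0, n_levels)
    if task == "discrimination":
        return np.linspace(CHARGE_SPEED_MIN, CHARGE_SPEED_MAX, n_levels)
    raise ConfigError(f"unknown task {task!r}")


def _balanced_trials(task: str, condition: str, levels: np.ndarray, reps: int, prefix: str):
    """One row per (level, rep) with color/side cycled for balance."""
    combos = [("black", "left"), ("gray", "right"), ("black", "right"), ("gray", "left")]
    rows = []
    i = 0
    for li, val in enumerate(levels):
        for rep in range(reps):
            color, side = combos[i % 4]
            rows.append(
                dict(
                    task=task,
                    condition=condition,
                    level_index=li,
                    attribute_value=float(val),
                    stim_id=f"{prefix}_L{li}_{rep:02d}",
                    predator_color=color,
                    predator_side=side,
                )
            )
            i += 1
    return rows


def _finalize(rows: list[dict], rng: np.random.Generator, trials_per_block: int) -> pd.DataFrame:
    order = rng.permutation(len(rows))
    df = pd.DataFrame([rows[i] for i in order])
    df.insert(0, "trial_number", np.arange(1, len(df) + 1))
    df.insert(1, "block", (df["trial_number"] - 1) // trials_per_block + 1)
    df["label_side"] = "social_left" if rng.integers(0, 2) == 0 else "social_right"
    return df[TRIAL_COLUMNS]


def build_detection_design(reps: int = 12, seed: int = 0) -> pd.DataFrame:
    """84-trial detection session: 12 trials at each of 7 directness levels."""
    if reps < 1:
        raise ConfigError("reps must be >= 1")
    rng = np.random.default_rng(seed)
    rows = _balanced_trials("detection", "chase", make_levels("detection"), reps, "det")
    return _finalize(rows, rng, trials_per_block=12)


def build_discrimination_design(reps: int = 10, seed: int = 0) -> pd.DataFrame:
    """70-trial discrimination session: 10 trials at each of 7 charge speeds."""
    if reps < 1:
        raise ConfigError("reps must be >= 1")
    rng = np.random.default_rng(seed)
    rows = _balanced_trials("discrimination", "charge", make_levels("discrimination"), reps, "dis")
    return _finalize(rows, rng, trials_per_block=10)


def build_mixed_design(reps_per_task: int = 6, seed: int = 0) -> pd.DataFrame:
    """Mixed session: six alternating 14-trial blocks of detection/discrimination.

    Each task contributes ``7*reps_per_task`` trials randomized *across* its
    three blocks; the block sequence starts with a seed-chosen task
    (121212 or 212121).
    """
    if reps_per_task < 1:
        raise ConfigError("reps_per_task must be >= 1")
    n_task = N_LEVELS * reps_per_task
    if n_task % 3 != 0:
        raise ConfigError(f"7*reps_per_task = {n_task} must be divisible by 3 blocks")
    rng = np.random.default_rng(seed)
    per_block = n_task // 3

    det = _balanced_trials("detection", "chase", make_levels("detection"), reps_per_task, "mix_det")
    dis = _balanced_trials(
        "discrimination", "charge", make_levels("discrimination"), reps_per_task, "mix_dis"
    )
    det = [det[i] for i in rng.permutation(n_task)]
    dis = [dis[i] for i in rng.permutation(n_task)]

    first = "detection" if rng.integers(0, 2) == 0 else "discrimination"
    seq = [first, _other(first)] * 3
    rows: list[dict] = []
    taken = {"detection": 0, "discrimination": 0}
    for task in seq:
        pool = det if task == "detection" else dis
        rows.extend(pool[taken[task] : taken[task] + per_block])
        taken[task] += per_block
    df = pd.DataFrame(rows)
    df.insert(0, "trial_number", np.arange(1, len(df) + 1))
    df.insert(1, "block", (df["trial_number"] - 1) // per_block + 1)
    df["label_side"] = "social_left" if rng.integers(0, 2) == 0 else "social_right"
    return df[TRIAL_COLUMNS]


def _other(task: str) -> str:
    return "discrimination" if task == "detection" else "detection"


def build_control_design(reps: int = 6, seed: int = 0, n_levels: int = N_LEVELS) -> pd.DataFrame:
    """Control session: chase x invisible-chase fully crossed with levels.

    ``n_levels=7`` uses the full directness ladder (2 x 7 x reps rows); the
    6-level variant (``n_levels=6``) drops directness 0, replacing the
    directness 0.167-1 chases, and yields 2 x 6 x reps rows.
    """
    if reps < 1:
        raise ConfigError("reps must be >= 1")
    if n_levels not in (6, 7):
        raise ConfigError("the control design supports 6 or 7 levels")
    rng = np.random.default_rng(seed)
    levels = make_levels("detection")
    offset = N_LEVELS - n_levels  # 6-level variant starts at directness 1/6
    rows = []
    for cond, prefix in (("chase", "ctl_chase"), ("invisible_chase", "ctl_mimic")):
        sub = _balanced_trials("detection", cond, levels[offset:], reps, prefix)
        for r in sub:
            r["level_index"] += offset
        rows.extend(sub)
    return _finalize(rows, rng, trials_per_block=12)


def audit_counterbalance(table: pd.DataFrame) -> dict:
    """Max within-task imbalance of predator color and side (should be <= 1)."""
    out = {}
    for task, grp in table.groupby("task"):
        color = grp["predator_color"].value_counts()
        side = grp["predator_side"].value_counts()
        out[task] = {
            "color_imbalance": int(abs(color.get("black", 0) - color.get("gray", 0))),
            "side_imbalance": int(abs(side.get("left", 0) - side.get("right", 0))),
        }
    return out
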