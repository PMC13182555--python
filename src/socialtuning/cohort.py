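"""Synthetic observers with known tuning curves, session data and traits.

Every downstream stage (curve fitting, reliability, group models, trait
regressions) is validated by parameter recovery against cohorts generated
here.  An observer owns

* a ground-truth detection sigmoid and discrimination line (on the
  normalized [0, 1] attribute axis),
* a response model: additive Gaussian rating noise clipped to [0, 1], a
  small uniform-lapse rate, a missingness rate (trials that time out), and
  a logistic predator-identification model whose 2AFC accuracy rises from
  chance 0.5 with chase directness,
* a second-session model: the true curve parameters perturbed by small
  Gaussian jitter, emulating the small session-to-session drift seen in
  repeat testing,
* 14 trait scores (AQ subscales, PANAS, NEO-FFI, loneliness, number of
  friends) generated from a configurable linear linkage to the observer's
  true curve summaries plus noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm, truncnorm

from .curves import (
    FitResult,
    LinearParams,
    SigmoidParams,
    linear,
    normalize_attribute,
    sigmoid,
    summarize,
)
from .sim import AnimationSpec, ConfigError, KinematicsConfig, WorldConfig, mean_agent_distance, simulate

__all__ = [
    "ObserverProfile",
    "CohortConfig",
    "TRAIT_NAMES",
    "sample_cohort",
    "generate_session",
    "sample_traits",
    "truth_summary",
    "compute_features",
]

#: the 14 trait dimensions: AQ subscales, PANAS, NEO-FFI, loneliness, friends
TRAIT_NAMES = [
    "aq_soc",
    "aq_attn",
    "aq_img",
    "aq_det",
    "aq_comm",
    "panas_pos",
    "panas_neg",
    "neo_neur",
    "neo_extr",
    "neo_open",
    "neo_agree",
    "neo_consc",
    "lone",
    "num_fr",
]

#: latent curve-summary predictors a trait can load on
LATENT_NAMES = ["det_biaspse", "det_range", "dis_biaspse", "dis_range"]


@dataclass(frozen=True)
class ObserverProfile:
    """Ground truth and response model of one synthetic participant."""

    id: str
    detection_truth: SigmoidParams
    discrimination_truth: LinearParams
    rating_noise_sd: float = 0.08
    lapse_rate: float = 0.02
    miss_rate: float = 0.02
    id_alpha: float = 0.3  # directness of 75% identification accuracy
    id_beta: float = 8.0  # identification slope
    session2_jitter_sd: float = 0.03

    def __post_init__(self) -> None:
        if self.rating_noise_sd <= 0:
            raise ConfigError("rating_noise_sd must be > 0")
        for r in (self.lapse_rate, self.miss_rate):
            if not 0.0 <= r <= 0.2:
                raise ConfigError("lapse/miss rates must lie in [0, 0.2]")


def _trunc_field(mean: float, sd: float, lo: float, hi: float) -> tuple:
    return (mean, sd, lo, hi)


@dataclass
class CohortConfig:
    """Population distributions of the observer parameters.

    Each entry is ``(mean, sd, lower, upper)``; draws use a truncated
    normal (a plain normal when the bounds are infinite, a constant when
    sd = 0).  Defaults describe a mildly heterogeneous adult cohort: most
    observers have near-symmetric detection sigmoids of moderate steepness
    and upward-sloping discrimination lines.
    """

    n_participants: int = 100
    seed: int = 0
    gamma: tuple = _trunc_field(0.12, 0.12, 0.0, 0.45)
    lam: tuple = _trunc_field(0.12, 0.12, 0.0, 0.45)
    alpha: tuple = _trunc_field(0.50, 0.12, 0.05, 0.95)
    beta: tuple = _trunc_field(12.0, 4.0, 2.0, 30.0)
    c: tuple = _trunc_field(0.15, 0.08, 0.0, 0.5)
    m: tuple = _trunc_field(0.65, 0.15, 0.05, 1.0)
    rating_noise_sd: tuple = _trunc_field(0.08, 0.02, 0.02, 0.2)
    lapse_rate: tuple = _trunc_field(0.02, 0.01, 0.0, 0.2)
    miss_rate: tuple = _trunc_field(0.02, 0.01, 0.0, 0.2)
    id_alpha: tuple = _trunc_field(0.30, 0.10, 0.0, 0.8)
    id_beta: tuple = _trunc_field(8.0, 2.0, 1.0, 20.0)
    session2_jitter_sd: tuple = _trunc_field(0.03, 0.0, 0.0, 0.2)
    trait_linkage: dict = field(default_factory=dict)  # trait -> {latent: weight}
    trait_noise_sd: float = 1.0

    def __post_init__(self) -> None:
        if self.n_participants < 2:
            raise ConfigError("n_participants must be >= 2")
        for name in self._param_names():
            mean, sd, lo, hi = getattr(self, name)
            if sd < 0:
                raise ConfigError(f"{name}: sd must be >= 0")
            if sd > 0 and norm.cdf(hi, mean, sd) - norm.cdf(lo, mean, sd) < 1e-6:
                raise ConfigError(f"{name}: truncation bounds leave <1e-6 probability mass")

    @staticmethod
    def _param_names():
        return (
            "gamma", "lam", "alpha", "beta", "c", "m",
            "rating_noise_sd", "lapse_rate", "miss_rate",
            "id_alpha", "id_beta", "session2_jitter_sd",
        )


def _draw(rng: np.random.Generator, spec: tuple, size: int) -> np.ndarray:
    mean, sd, lo, hi = spec
    if sd == 0:
        return np.full(size, float(mean))
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def sample_cohort(config: CohortConfig) -> list[ObserverProfile]:
    """Seeded draw of ``n_participants`` observers from the population.

    Each parameter gets its own child RNG stream (keyed by parameter name),
    so reconfiguring one population distribution does not perturb the draws
    of the others.
    """
    import zlib

    n = config.n_participants
    draws = {
        name: _draw(
            np.random.default_rng(
                np.random.SeedSequence([config.seed, zlib.crc32(name.encode())])
            ),
            getattr(config, name),
            n,
        )
        for name in config._param_names()
    }
    # keep the sigmoid rising: gamma + lam must stay below 1 (bounds already
    # cap each at 0.45 by default, so this is a guard for custom configs)
    out = []
    for i in range(n):
        det = SigmoidParams(draws["gamma"][i], draws["lam"][i], draws["alpha"][i], draws["beta"][i])
        dis = LinearParams(draws["c"][i], draws["m"][i])
        out.append(
            ObserverProfile(
                id=f"p{i:03d}",
                detection_truth=det,
                discrimination_truth=dis,
                rating_noise_sd=draws["rating_noise_sd"][i],
                lapse_rate=draws["lapse_rate"][i],
                miss_rate=draws["miss_rate"][i],
                id_alpha=draws["id_alpha"][i],
                id_beta=draws["id_beta"][i],
                session2_jitter_sd=draws["session2_jitter_sd"][i],
            )
        )
    return out


def session_truth(profile: ObserverProfile, session: int, rng: np.random.Generator):
    """True curves for a session: session 2 adds small parameter jitter."""
    det, dis = profile.detection_truth, profile.discrimination_truth
    if session == 1 or profile.session2_jitter_sd == 0:
        return det, dis
    sd = profile.session2_jitter_sd
    det = SigmoidParams(
        gamma=float(np.clip(det.gamma + rng.normal(0, sd), 0.0, 0.9)),
        lam=float(np.clip(det.lam + rng.normal(0, sd), 0.0, 0.9)),
        alpha=float(det.alpha + rng.normal(0, sd)),
        beta=float(max(det.beta * (1.0 + rng.normal(0, sd)), 0.5)),
    )
    dis = LinearParams(
        c=float(np.clip(dis.c + rng.normal(0, sd), 0.0, 0.9)),
        m=float(dis.m + rng.normal(0, sd)),
    )
    return det, dis


def _truth_rating(det, dis, task, x):
    if task == "detection":
        return float(sigmoid(x, det))
    return float(linear(x, dis))


def generate_session(
    profile: ObserverProfile,
    table: pd.DataFrame,
    session: int,
    features: Mapping[str, float] | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Simulate one session of responses for one observer.

    Ratings are ``clip(truth(x) + Normal(0, noise_sd), 0, 1)``; with
    probability ``lapse_rate`` the rating is replaced by Uniform(0, 1), and
    with probability ``miss_rate`` it is missing (the response page timed
    out).  Detection trials additionally draw a 2AFC predator-identification
    outcome from ``Bernoulli(0.5 + 0.5*logistic(id_beta*(x - id_alpha)))``,
    which is chance 0.5 for a directness-0 stimulus (no chase to identify).

    ``features`` maps stim_id to the animation's mean inter-agent distance;
    missing features are recorded as NaN.
    """
    if session not in (1, 2):
        raise ConfigError("session must be 1 or 2")
    import zlib

    # fold the observer id in so sessions differ across the cohort even
    # when the caller passes one base seed for everybody
    rng = np.random.default_rng(
        np.random.SeedSequence([0 if seed is None else seed, session, zlib.crc32(profile.id.encode())])
    )
    det, dis = session_truth(profile, session, rng)
    features = features or {}
    rows = []
    for rec in table.itertuples(index=False):
        x = float(normalize_attribute(rec.attribute_value, rec.task))
        truth = _truth_rating(det, dis, rec.task, x)
        if rng.random() < profile.miss_rate:
            rating = np.nan
        elif rng.random() < profile.lapse_rate:
            rating = float(rng.random())
        else:
            rating = float(np.clip(truth + rng.normal(0.0, profile.rating_noise_sd), 0.0, 1.0))
        if rec.task == "detection":
            p_correct = 0.5 + 0.5 * expit(profile.id_beta * (x - profile.id_alpha))
            choice = int(rng.random() < p_correct) if np.isfinite(rating) else np.nan
        else:
            choice = np.nan
        rows.append(
            dict(
                participant=profile.id,
                session=session,
                trial_number=rec.trial_number,
                task=rec.task,
                condition=rec.condition,
                level_index=rec.level_index,
                attribute_value=rec.attribute_value,
                stim_id=rec.stim_id,
                mean_dist=features.get(rec.stim_id, np.nan),
                rating=rating,
                predator_choice_correct=choice,
            )
        )
    return pd.DataFrame(rows)


def truth_summary(profile: ObserverProfile, task: str):
    """CurveSummary of an observer's *true* curve (the recovery oracle)."""
    if task == "detection":
        fit = FitResult("sigmoid", profile.detection_truth, 0.0, 7, 5, 0.0)
    else:
        fit = FitResult("linear", profile.discrimination_truth, 0.0, 7, 3, 0.0)
    return summarize(fit)


def _zscore(v: np.ndarray) -> np.ndarray:
    sd = v.std()
    return (v - v.mean()) / sd if sd > 0 else np.zeros_like(v)


def sample_traits(
    cohort: list[ObserverProfile],
    config: CohortConfig,
    seed: int | None = None,
) -> pd.DataFrame:
    """Generate the 14-dimension trait table from true curve summaries.

    Each trait is a weighted sum of the z-scored latent curve summaries
    (bias-PSE composite and range, per task) plus Gaussian noise:
    ``trait_j = sum_k W_jk * z(latent_k) + Normal(0, trait_noise_sd^2)``.
    ``num_fr`` (number of close friends) is converted to a count through a
    monotone transform of its latent score.  A zero linkage matrix yields a
    null cohort with traits independent of behavior.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    latents = {name: [] for name in LATENT_NAMES}
    for prof in cohort:
        for task, prefix in (("detection", "det"), ("discrimination", "dis")):
            s = truth_summary(prof, task)
            latents[f"{prefix}_biaspse"].append(s.bias - s.pse)  # z-scored below
            latents[f"{prefix}_range"].append(s.range_)
    z = {k: _zscore(np.asarray(v)) for k, v in latents.items()}
    # the bias-PSE composite is defined on z-scores of each part; at the
    # generative level the single z of the difference is an adequate latent
    n = len(cohort)
    table = {}
    for trait in TRAIT_NAMES:
        weights = config.trait_linkage.get(trait, {})
        unknown = set(weights) - set(LATENT_NAMES)
        if unknown:
            raise ConfigError(f"trait_linkage[{trait!r}] names unknown latents {sorted(unknown)}")
        score = np.zeros(n)
        for latent, w in weights.items():
            score += w * z[latent]
        score += rng.normal(0.0, config.trait_noise_sd, size=n)
        if trait == "num_fr":
            table[trait] = np.floor(np.exp(1.6 + 0.4 * score)).astype(int)
        else:
            table[trait] = score
    df = pd.DataFrame(table, index=[p.id for p in cohort])
    df.index.name = "participant"
    return df


def exclude_high_missingness(data: pd.DataFrame, max_miss_rate: float = 0.2) -> pd.DataFrame:
    """Exclusion hook: drop participants whose missing-response rate exceeds
    ``max_miss_rate`` in any session (the only data-quality criterion the
    synthetic pipeline can express)."""
    miss = data.assign(miss=data["rating"].isna()).groupby(["participant", "session"])["miss"].mean()
    bad = set(miss[miss > max_miss_rate].index.get_level_values("participant"))
    return data[~data["participant"].isin(bad)].reset_index(drop=True)


def compute_features(
    table: pd.DataFrame,
    world_by_task: Mapping[str, WorldConfig] | None = None,
    kin: KinematicsConfig | None = None,
) -> dict[str, float]:
    """Simulate each unique stimulus in a trial table; return stim_id -> mean_dist.

    Invisible-chase stimuli have three agents of which two are visible
    (predator and mimic); the distance is between the visible pair.
    """
    if world_by_task is None:
        world_by_task = {
            "detection": WorldConfig(duration=6.0),
            "discrimination": WorldConfig(duration=8.0),
        }
    kin = kin or KinematicsConfig()
    out: dict[str, float] = {}
    stim = table.drop_duplicates("stim_id")
    for rec in stim.itertuples(index=False):
        spec = AnimationSpec(
            task=rec.task if rec.task in ("detection", "discrimination") else "detection",
            condition=rec.condition,
            attribute_value=float(rec.attribute_value),
            seed=_stim_seed(rec.stim_id),
            level_index=int(rec.level_index),
            predator_color=rec.predator_color,
            predator_side=rec.predator_side,
            stim_id=rec.stim_id,
        )
        out[rec.stim_id] = mean_agent_distance(simulate(spec, world_by_task[rec.task], kin))
    return out


def _stim_seed(stim_id: str) -> int:
    """Stable per-stimulus seed derived from the stimulus identifier."""
    import zlib

    return zlib.crc32(stim_id.encode()) % (2**31)
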