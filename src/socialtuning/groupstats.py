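"""Group-level models of ratings and 2AFC identification accuracy.

The rating model is a linear mixed-effects regression

    rating ~ level + mean_dist + trial_number + (1|participant) + (1|stim_id)

with crossed random intercepts for participant and stimulus.  The accuracy
model uses the same predictors with a logistic link; because a frequentist
crossed-random-effects logistic model is not available in the stack, it is
fit as a fixed-effects logistic regression with participant-clustered
robust standard errors (the group-level coefficient of interest is
consistent under that estimator).

Covariates are rescaled to comparable [0, 1] ranges before fitting: the
motion attribute to its normalized level axis, mean inter-agent distance by
the world diagonal, and trial number by the session length.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .curves import normalize_attribute

__all__ = ["GroupModelResult", "fit_rating_model", "fit_accuracy_model"]


@dataclass
class GroupModelResult:
    model: str  # "rating" | "accuracy"
    fixed_effects: pd.DataFrame  # index: term; columns: estimate, se, p
    random_variances: dict
    aic: float
    n_obs: int
    flags: set[str] = field(default_factory=set)

    def coef(self, term: str) -> float:
        return float(self.fixed_effects.loc[term, "estimate"])

    def pvalue(self, term: str) -> float:
        return float(self.fixed_effects.loc[term, "p"])


def _prepare(data: pd.DataFrame, world_diagonal: float) -> pd.DataFrame:
    df = data.copy()
    df["x"] = [
        float(normalize_attribute(v, t)) for v, t in zip(df["attribute_value"], df["task"])
    ]
    df["mean_dist_s"] = df["mean_dist"] / world_diagonal
    tmax = df["trial_number"].max()
    df["trial_s"] = df["trial_number"] / (tmax if tmax > 0 else 1)
    return df


def fit_rating_model(
    data: pd.DataFrame,
    include_mean_dist: bool = True,
    world_diagonal: float = math.hypot(800.0, 600.0),
) -> GroupModelResult:
    """Linear mixed model of ratings with crossed random intercepts.

    Estimated by REML using variance components for participant and
    stimulus on a single grouping level (the standard trick for crossed
    random effects).  The AIC (from the fitted likelihood) supports the
    with/without mean-distance model comparison.
    """
    df = _prepare(data, world_diagonal).dropna(subset=["rating"])
    if df["participant"].nunique() < 2 or df["stim_id"].nunique() < 2:
        raise ValueError("need >= 2 participants and >= 2 stimuli")
    terms = ["x"] + (["mean_dist_s"] if include_mean_dist else []) + ["trial_s"]
    if include_mean_dist:
        df = df.dropna(subset=["mean_dist_s"])
    formula = "rating ~ " + " + ".join(terms)
    df = df.assign(_all=1)
    vc = {"participant": "0 + C(participant)", "stim": "0 + C(stim_id)"}
    model = smf.mixedlm(formula, df, groups="_all", vc_formula=vc, re_formula="0")
    flags: set[str] = set()
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(reml=True)
    if not res.converged:
        flags.add("not_converged")
    if getattr(res, "cov_re", None) is not None and np.any(np.asarray(res.vcomp) <= 1e-12):
        flags.add("singular_fit")
    fe = pd.DataFrame(
        {
            "estimate": res.fe_params,
            "se": res.bse_fe,
            "p": res.pvalues.loc[res.fe_params.index],
        }
    )
    k = len(res.fe_params) + len(res.vcomp) + 1
    aic = float(-2 * res.llf + 2 * k)
    rv = {name: float(v) for name, v in zip(vc.keys(), np.asarray(res.vcomp))}
    rv["residual"] = float(res.scale)
    return GroupModelResult("rating", fe, rv, aic, int(res.nobs), flags)


def fit_accuracy_model(
    data: pd.DataFrame,
    include_mean_dist: bool = True,
    world_diagonal: float = math.hypot(800.0, 600.0),
) -> GroupModelResult:
    """Logistic model of predator-identification accuracy.

    Fixed-effects logistic regression with participant-clustered robust
    standard errors on the detection trials that have a recorded choice.
    """
    df = _prepare(data, world_diagonal)
    df = df[(df["task"] == "detection") & df["predator_choice_correct"].notna()]
    if df.empty:
        raise ValueError("no detection trials with recorded choices")
    terms = ["x"] + (["mean_dist_s"] if include_mean_dist else []) + ["trial_s"]
    if include_mean_dist:
        df = df.dropna(subset=["mean_dist_s"])
    df = df.assign(acc=df["predator_choice_correct"].astype(float))
    formula = "acc ~ " + " + ".join(terms)
    flags: set[str] = set()
    model = smf.glm(formula, df, family=sm.families.Binomial())
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = model.fit(
                cov_type="cluster", cov_kwds={"groups": df["participant"].to_numpy()}
            )
        except Exception:
            flags.add("separation")
            res = model.fit_regularized(alpha=1e-6)
    if np.any(~np.isfinite(np.asarray(res.params))) or np.max(np.abs(res.params)) > 50:
        flags.add("separation")
    fe = pd.DataFrame(
        {
            "estimate": res.params,
            "se": getattr(res, "bse", pd.Series(np.nan, index=res.params.index)),
            "p": getattr(res, "pvalues", pd.Series(np.nan, index=res.params.index)),
        }
    )
    aic = float(getattr(res, "aic", np.nan))
    return GroupModelResult("accuracy", fe, {}, aic, len(df), flags)


def marginal_accuracy(result: GroupModelResult, x: float, trial_s: float = 0.5, mean_dist_s: float | None = None) -> float:
    """Predicted identification accuracy at attribute value ``x``."""
    eta = result.coef("Intercept") + result.coef("x") * x + result.coef("trial_s") * trial_s
    if "mean_dist_s" in result.fixed_effects.index and mean_dist_s is not None:
        eta += result.coef("mean_dist_s") * mean_dist_s
    return float(1.0 / (1.0 + math.exp(-eta)))
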