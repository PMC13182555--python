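"""Stability and uniqueness of tuning curves across two sessions.

Three complementary views:

* **NRMSE transfer** — how well a curve fit to one session's data predicts
  the level means of another session.  The *within*-participant transfer
  (own parameters from the other session) is compared against the
  *across*-participant baseline (leave-one-out average of all other
  participants' parameters from the *target* session) with a paired t-test;
  a reliable and individually distinctive measure makes within < across.
* **ICC(2, 1)** — two-way random-effects, absolute-agreement, single-measure
  intraclass correlation per curve parameter between sessions.
* **Session-shift tests** — paired t-test per parameter for systematic
  session-to-session drift.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .curves import FitResult, LinearParams, SigmoidParams

__all__ = [
    "nrmse",
    "within_vs_across",
    "icc2",
    "session_shift_tests",
    "NRMSEComparison",
]


def nrmse(fit: FitResult, x, y, normalizer: float = 1.0) -> float:
    """Normalized root-mean-square error of a fitted curve on observed points.

    The default normalizer is the rating-scale width (1.0), which keeps
    values comparable across participants; pass the observed range for
    range-normalized values.
    """
    pred = fit.predict(np.asarray(x, dtype=float))
    obs = np.asarray(y, dtype=float)
    return float(np.sqrt(np.mean((pred - obs) ** 2)) / normalizer)


@dataclass
class NRMSEComparison:
    """Paired within- vs across-participant NRMSE for one transfer direction."""

    direction: str  # e.g. "s1_params_to_s2_data"
    participants: list
    within: np.ndarray
    across: np.ndarray
    mean_difference: float  # mean(within - across); negative favors within
    t_statistic: float
    p_value: float


def _mean_params(fits: list[FitResult]) -> FitResult:
    """Average curve *parameter values* across participants (same family)."""
    family = fits[0].family
    if any(f.family != family for f in fits):
        raise ValueError("cannot average fits of mixed families")
    if family == "sigmoid":
        g, l, a, b = (float(np.mean([getattr(f.params, k) for f in fits]))
                      for k in ("gamma", "lam", "alpha", "beta"))
        params = SigmoidParams(g, l, a, b)
        k = 5
    else:
        c, m = (float(np.mean([getattr(f.params, k) for f in fits])) for k in ("c", "m"))
        params = LinearParams(c, m)
        k = 3
    return FitResult(family, params, np.nan, 0, k, np.nan)


def _mean_prediction_fit(fits: list[FitResult]):
    """Alternative baseline: average the *predictions* rather than parameters."""

    class _Avg:
        family = fits[0].family

        @staticmethod
        def predict(x):
            return np.mean([f.predict(x) for f in fits], axis=0)

    return _Avg()


def within_vs_across(
    fits_s1: dict,
    fits_s2: dict,
    points_s1: dict,
    points_s2: dict,
    normalizer: float = 1.0,
    average: str = "parameters",
) -> list[NRMSEComparison]:
    """Within- vs across-participant NRMSE, both transfer directions.

    ``fits_sN``: participant -> FitResult fitted on session N;
    ``points_sN``: participant -> (x, y) level means of session N.
    The across baseline for participant p on session-N data averages the
    parameters of all *other* participants' session-N fits
    (``average="predictions"`` averages their predicted curves instead).
    """
    common = sorted(set(fits_s1) & set(fits_s2) & set(points_s1) & set(points_s2))
    if len(common) < 3:
        raise ValueError(f"need >= 3 participants with both sessions, got {len(common)}")
    out = []
    for src_fits, (tgt_fits, tgt_points, direction) in (
        (fits_s1, (fits_s2, points_s2, "s1_params_to_s2_data")),
        (fits_s2, (fits_s1, points_s1, "s2_params_to_s1_data")),
    ):
        within, across = [], []
        for p in common:
            x, y = tgt_points[p]
            within.append(nrmse(src_fits[p], x, y, normalizer))
            others = [tgt_fits[q] for q in common if q != p]
            baseline = (
                _mean_params(others) if average == "parameters" else _mean_prediction_fit(others)
            )
            across.append(float(np.sqrt(np.mean((baseline.predict(np.asarray(x)) - y) ** 2)) / normalizer))
        within = np.asarray(within)
        across = np.asarray(across)
        t, p_val = stats.ttest_rel(within, across)
        out.append(
            NRMSEComparison(
                direction=direction,
                participants=common,
                within=within,
                across=across,
                mean_difference=float(np.mean(within - across)),
                t_statistic=float(t),
                p_value=float(p_val),
            )
        )
    return out


def icc2(values_s1, values_s2) -> float:
    """ICC(2,1): two-way random effects, absolute agreement, single measure.

    Computed from the ANOVA mean squares of the n x 2 (participant x
    session) table: ``(MSR - MSE) / (MSR + (k-1) MSE + (k/n)(MSC - MSE))``
    with k = 2 raters (sessions).  Returns NaN when both the between- and
    within-participant variance vanish (the coefficient is undefined).
    """
    y1 = np.asarray(values_s1, dtype=float)
    y2 = np.asarray(values_s2, dtype=float)
    if y1.shape != y2.shape or y1.ndim != 1:
        raise ValueError("paired 1-d arrays required")
    mask = np.isfinite(y1) & np.isfinite(y2)
    y1, y2 = y1[mask], y2[mask]
    n = len(y1)
    if n < 3:
        raise ValueError("need >= 3 paired values")
    k = 2
    data = np.column_stack([y1, y2])
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ssr = k * np.sum((row_means - grand) ** 2)
    ssc = n * np.sum((col_means - grand) ** 2)
    sse = np.sum((data - row_means[:, None] - col_means[None, :] + grand) ** 2)
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    if denom == 0.0:
        return float("nan")
    return float((msr - mse) / denom)


def session_shift_tests(param_matrix: pd.DataFrame) -> pd.DataFrame:
    """Paired t-test per curve parameter for systematic session drift.

    ``param_matrix`` is tidy with columns ``participant, session, <params...>``
    (sessions 1 and 2, one row per participant per session).  Returns one
    row per parameter: mean difference (s2 - s1), 95% CI, t, p, n.
    """
    params = [c for c in param_matrix.columns if c not in ("participant", "session")]
    s1 = param_matrix[param_matrix["session"] == 1].set_index("participant")
    s2 = param_matrix[param_matrix["session"] == 2].set_index("participant")
    common = s1.index.intersection(s2.index)
    rows = []
    for name in params:
        d = (s2.loc[common, name] - s1.loc[common, name]).to_numpy(dtype=float)
        d = d[np.isfinite(d)]
        n = len(d)
        mean_d = float(np.mean(d))
        if n > 1 and np.std(d, ddof=1) > 0:
            t, p = stats.ttest_1samp(d, 0.0)
            half = stats.t.ppf(0.975, n - 1) * np.std(d, ddof=1) / np.sqrt(n)
        else:
            t, p, half = np.nan, np.nan, 0.0
        rows.append(
            dict(
                parameter=name,
                n=n,
                mean_difference=mean_d,
                ci_low=mean_d - half,
                ci_high=mean_d + half,
                t_statistic=float(t),
                p_value=float(p),
            )
        )
    return pd.DataFrame(rows)
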