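"""Cross-task structure and trait associations of the curve parameters.

* Pearson correlations between every pair of the robust curve parameters
  across tasks (detection: bias, range, PSE; discrimination: bias, PSE)
  with Benjamini-Hochberg FDR over the 6 cross-task cells.
* The bias - PSE composite: both measures z-scored across participants,
  then PSE_z subtracted from bias_z.  Higher values index greater
  sensitivity to social (detection) or aggressive (discrimination) content.
* Four multiple regressions of the composites/ranges on the 14 trait
  dimensions, with participant-bootstrap percentile CIs per coefficient and
  a permutation test of the model R^2 (outcome shuffled, traits fixed,
  p = fraction of permuted R^2 strictly above the observed one).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "composite_bias_minus_pse",
    "cross_task_correlations",
    "regress_traits",
    "bootstrap_cis",
    "permutation_r2",
    "CrossTaskMatrix",
    "TraitRegressionResult",
]

DETECTION_PARAMS = ["bias", "range_", "pse"]
DISCRIMINATION_PARAMS = ["bias", "pse"]


def _z(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    sd = v.std()
    if sd == 0:
        raise ValueError("zero variance; cannot z-score")
    return (v - v.mean()) / sd


def composite_bias_minus_pse(bias, pse) -> np.ndarray:
    """z(bias) - z(PSE) per participant.

    bias lives on the rating axis and PSE on the attribute axis, so both
    are z-scored across participants before differencing; the composite has
    mean 0 by construction.
    """
    bias = np.asarray(bias, dtype=float)
    pse = np.asarray(pse, dtype=float)
    if bias.shape != pse.shape or bias.ndim != 1 or len(bias) < 3:
        raise ValueError("paired 1-d arrays with n >= 3 required")
    if not (np.all(np.isfinite(bias)) and np.all(np.isfinite(pse))):
        raise ValueError("non-finite values in bias/PSE")
    return _z(bias) - _z(pse)


@dataclass
class CrossTaskMatrix:
    r: pd.DataFrame  # full 5x5 Pearson matrix (det_* x dis_* labels)
    p: pd.DataFrame
    cross_cells: pd.DataFrame  # tidy: det param, dis param, r, p, q, significant


def cross_task_correlations(
    det_summaries: pd.DataFrame, dis_summaries: pd.DataFrame, fdr_alpha: float = 0.05
) -> CrossTaskMatrix:
    """Pearson r between all pairs of robust curve parameters across tasks.

    Inputs are per-participant summary tables (indexed by participant, with
    columns bias/range_/pse); only participants present and non-excluded in
    both tasks enter.  BH-FDR is applied to the 6 detection x
    discrimination cells.
    """
    common = det_summaries.index.intersection(dis_summaries.index)
    if len(common) < 3:
        raise ValueError("need >= 3 participants with both tasks")
    cols = {f"det_{p}": det_summaries.loc[common, p] for p in DETECTION_PARAMS}
    cols.update({f"dis_{p}": dis_summaries.loc[common, p] for p in DISCRIMINATION_PARAMS})
    df = pd.DataFrame(cols)
    names = list(df.columns)
    k = len(names)
    r = pd.DataFrame(np.eye(k), index=names, columns=names)
    p = pd.DataFrame(np.zeros((k, k)), index=names, columns=names)
    for i in range(k):
        for j in range(i + 1, k):
            res = stats.pearsonr(df[names[i]], df[names[j]])
            r.iloc[i, j] = r.iloc[j, i] = res.statistic
            p.iloc[i, j] = p.iloc[j, i] = res.pvalue
    rows = []
    for dp in DETECTION_PARAMS:
        for qp in DISCRIMINATION_PARAMS:
            rows.append(
                dict(
                    detection=dp,
                    discrimination=qp,
                    r=float(r.loc[f"det_{dp}", f"dis_{qp}"]),
                    p=float(p.loc[f"det_{dp}", f"dis_{qp}"]),
                )
            )
    cross = pd.DataFrame(rows)
    rej, q, _, _ = multipletests(cross["p"], alpha=fdr_alpha, method="fdr_bh")
    cross["q"] = q
    cross["significant"] = rej
    return CrossTaskMatrix(r=r, p=p, cross_cells=cross)


@dataclass
class TraitRegressionResult:
    outcome: str
    coefficients: pd.Series  # index: trait names
    intercept: float
    r2: float
    n: int
    ci_low: pd.Series | None = None
    ci_high: pd.Series | None = None
    significant: pd.Series | None = None
    permutation_p: float | None = None
    n_redrawn: int = 0


def _design(traits: pd.DataFrame) -> np.ndarray:
    X = np.column_stack([_z(traits[c].to_numpy()) for c in traits.columns])
    return np.column_stack([np.ones(len(X)), X])


def _check_rank(X: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name the columns whose removal restores full rank
        bad = []
        for j in range(1, X.shape[1]):
            keep = [c for c in range(X.shape[1]) if c != j]
            if np.linalg.matrix_rank(X[:, keep]) == rank:
                bad.append(names[j - 1])
        raise ValueError(f"rank-deficient trait design; collinear columns: {bad or 'unknown'}")


def _ols_r2(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    yc = y - y.mean()
    tss = float(yc @ yc)
    r2 = 1.0 - float(resid @ resid) / tss if tss > 0 else 0.0
    return beta, r2


def regress_traits(outcome, traits: pd.DataFrame, outcome_name: str = "outcome") -> TraitRegressionResult:
    """OLS of one curve-parameter outcome on all 14 z-scored traits at once."""
    y = np.asarray(outcome, dtype=float)
    if len(y) != len(traits):
        raise ValueError("outcome and trait table lengths differ")
    if len(y) <= traits.shape[1]:
        raise ValueError(f"need n > {traits.shape[1]} participants")
    if np.std(y) == 0:
        coefs = pd.Series(0.0, index=list(traits.columns))
        return TraitRegressionResult(outcome_name, coefs, float(y.mean()), 0.0, len(y))
    X = _design(traits)
    _check_rank(X, list(traits.columns))
    beta, r2 = _ols_r2(X, y)
    return TraitRegressionResult(
        outcome_name,
        pd.Series(beta[1:], index=list(traits.columns)),
        float(beta[0]),
        r2,
        len(y),
    )


def bootstrap_cis(
    outcome, traits: pd.DataFrame, reps: int = 1000, seed: int = 0, ci: float = 0.95
) -> TraitRegressionResult:
    """Percentile bootstrap CIs for the trait coefficients.

    Participants are resampled with replacement ``reps`` times and the full
    regression refit each time; a coefficient is *significant* when its CI
    excludes 0.  Rank-deficient resamples are redrawn (and counted).
    """
    base = regress_traits(outcome, traits)
    y = np.asarray(outcome, dtype=float)
    n = len(y)
    rng = np.random.default_rng(seed)
    draws = np.empty((reps, traits.shape[1]))
    redrawn = 0
    r = 0
    while r < reps:
        idx = rng.integers(0, n, size=n)
        tb = traits.iloc[idx]
        yb = y[idx]
        try:
            res = regress_traits(yb, tb)
        except ValueError:
            redrawn += 1
            if redrawn > 100 * reps:
                raise RuntimeError("too many degenerate bootstrap resamples")
            continue
        draws[r] = res.coefficients.to_numpy()
        r += 1
    lo = (1.0 - ci) / 2.0
    ci_low = pd.Series(np.quantile(draws, lo, axis=0), index=base.coefficients.index)
    ci_high = pd.Series(np.quantile(draws, 1.0 - lo, axis=0), index=base.coefficients.index)
    base.ci_low = ci_low
    base.ci_high = ci_high
    base.significant = (ci_low > 0) | (ci_high < 0)
    base.n_redrawn = redrawn
    return base


def permutation_r2(outcome, traits: pd.DataFrame, reps: int = 10000, seed: int = 0) -> float:
    """Permutation p-value of the regression R^2.

    The outcome vector is shuffled across participants ``reps`` times with
    the trait matrix fixed; p is the fraction of permuted models whose R^2
    strictly exceeds the observed one (no add-one smoothing).
    """
    y = np.asarray(outcome, dtype=float)
    X = _design(traits)
    _check_rank(X, list(traits.columns))
    _, r2_obs = _ols_r2(X, y)
    # R^2 of a permuted outcome only needs the projection onto the design:
    # with Q an orthonormal basis of X, R^2 = ||Q'yc||^2 / ||yc||^2
    Q, _ = np.linalg.qr(X)
    rng = np.random.default_rng(seed)
    yc = y - y.mean()
    tss = float(yc @ yc)
    if tss == 0:
        return 1.0
    exceed = 0
    for _ in range(reps):
        yp = rng.permutation(y)
        ypc = yp - yp.mean()
        proj = Q.T @ ypc
        r2_perm = float(proj @ proj) / tss
        if r2_perm > r2_obs:
            exceed += 1
    return exceed / reps
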