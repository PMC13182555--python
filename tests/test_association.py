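"""Cross-task correlations, the bias-PSE composite, and trait regressions."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from socialtuning.association import (
    bootstrap_cis,
    composite_bias_minus_pse,
    cross_task_correlations,
    permutation_r2,
    regress_traits,
)
from socialtuning.cohort import TRAIT_NAMES


def trait_frame(rng, n, signal=None):
    """Random 14-trait table; ``signal`` maps trait -> latent weight column."""
    df = pd.DataFrame({t: rng.normal(0, 1, n) for t in TRAIT_NAMES})
    return df


class TestComposite:
    def test_zero_at_joint_mean(self, rng):
        bias = rng.normal(0.5, 0.1, 20)
        pse = rng.normal(0.5, 0.1, 20)
        bias[0], pse[0] = bias[1:].mean(), pse[1:].mean()
        # recenter so participant 0 sits exactly at both means
        bias[0] = bias.mean() + (bias[0] - bias.mean()) * 0  # == overall mean? no:
        comp = composite_bias_minus_pse(bias, pse)
        assert comp.mean() == pytest.approx(0.0, abs=1e-12)

    def test_variance_identity(self, rng):
        """var(bias_z - pse_z) = 2 - 2*corr(bias, pse)."""
        bias = rng.normal(0.5, 0.1, 200)
        pse = 0.6 - 0.5 * bias + rng.normal(0, 0.05, 200)
        comp = composite_bias_minus_pse(bias, pse)
        r = np.corrcoef(bias, pse)[0, 1]
        assert comp.var() == pytest.approx(2 - 2 * r, rel=1e-10)

    def test_matches_direct_recomputation(self, rng):
        bias = rng.uniform(0, 1, 50)
        pse = rng.uniform(0, 1, 50)
        comp = composite_bias_minus_pse(bias, pse)
        manual = (bias - bias.mean()) / bias.std() - (pse - pse.mean()) / pse.std()
        assert np.allclose(comp, manual, atol=1e-12)

    def test_monotone_in_both_arguments(self, rng):
        """Higher bias and lower PSE always give a higher composite."""
        bias = rng.uniform(0, 1, 30)
        pse = rng.uniform(0, 1, 30)
        comp = composite_bias_minus_pse(bias, pse)
        i, j = 3, 17
        if bias[i] > bias[j] and pse[i] < pse[j]:
            assert comp[i] > comp[j]
        # force the configuration too
        bias[0], bias[1] = 0.9, 0.2
        pse[0], pse[1] = 0.1, 0.8
        comp = composite_bias_minus_pse(bias, pse)
        assert comp[0] > comp[1]

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            composite_bias_minus_pse(np.ones(10), np.arange(10.0))


def summaries(rng, n, shared=0.0):
    """Two per-task summary frames with an optional shared latent in range."""
    idx = [f"p{i}" for i in range(n)]
    conf = rng.normal(0, 1, n)
    det = pd.DataFrame(
        {
            "bias": rng.normal(0.5, 0.1, n),
            "range_": np.clip(0.7 + shared * 0.15 * conf + rng.normal(0, 0.05, n), 0, 1),
            "pse": rng.normal(0.5, 0.1, n),
        },
        index=idx,
    )
    dis = pd.DataFrame(
        {
            "bias": rng.normal(0.5, 0.1, n),
            "range_": np.clip(0.6 + shared * 0.15 * conf + rng.normal(0, 0.05, n), 0, 1),
            "pse": rng.normal(0.5, 0.1, n),
        },
        index=idx,
    )
    return det, dis


class TestCrossTask:
    def test_structure_and_self_correlation(self, rng):
        det, dis = summaries(rng, 50)
        m = cross_task_correlations(det, dis)
        assert len(m.cross_cells) == 6
        for name in m.r.index:
            assert m.r.loc[name, name] == 1.0
        assert (m.r.abs() <= 1).all().all()

    def test_null_cohorts_rarely_significant(self):
        """Across 200 independent null cohorts, the fraction with any
        FDR-significant cross-task cell stays near the nominal level."""
        any_sig = 0
        n_sims = 500
        for seed in range(n_sims):
            rs = np.random.default_rng(seed)
            det, dis = summaries(rs, 60)
            m = cross_task_correlations(det, dis)
            any_sig += m.cross_cells["significant"].any()
        assert any_sig / n_sims <= 0.07

    def test_shared_latent_detected(self):
        """A latent 'confidence' trait loading on detection range and
        discrimination bias produces a significant cross-task cell."""
        rs = np.random.default_rng(5)
        n = 120
        idx = [f"p{i}" for i in range(n)]
        conf = rs.normal(0, 1, n)
        det = pd.DataFrame(
            {
                "bias": rs.normal(0.5, 0.1, n),
                "range_": np.clip(0.7 + 0.1 * conf + rs.normal(0, 0.05, n), 0, 1),
                "pse": rs.normal(0.5, 0.1, n),
            },
            index=idx,
        )
        dis = pd.DataFrame(
            {
                "bias": np.clip(0.5 + 0.08 * conf + rs.normal(0, 0.04, n), 0, 1),
                "pse": rs.normal(0.5, 0.1, n),
                "range_": rs.normal(0.6, 0.05, n),
            },
            index=idx,
        )
        m = cross_task_correlations(det, dis)
        cell = m.cross_cells.query("detection == 'range_' and discrimination == 'bias'")
        assert cell["r"].iloc[0] > 0.5
        assert bool(cell["significant"].iloc[0])

    def test_bh_q_monotone_in_p(self, rng):
        det, dis = summaries(rng, 40)
        m = cross_task_correlations(det, dis)
        cells = m.cross_cells.sort_values("p")
        assert cells["q"].is_monotonic_increasing

    def test_small_n_rejected(self, rng):
        det, dis = summaries(rng, 2)
        with pytest.raises(ValueError):
            cross_task_correlations(det, dis)


class TestRegressTraits:
    def test_single_linked_trait_recovered(self, rng):
        n = 250
        traits = trait_frame(rng, n)
        y = 0.5 * (traits["neo_extr"] - traits["neo_extr"].mean()) / traits["neo_extr"].std()
        y = y + rng.normal(0, 0.3, n)
        res = regress_traits(y.to_numpy(), traits)
        coefs = res.coefficients.abs().sort_values(ascending=False)
        assert coefs.index[0] == "neo_extr"
        assert res.coefficients["neo_extr"] == pytest.approx(0.5, abs=0.1)

    def test_constant_outcome(self, rng):
        traits = trait_frame(rng, 40)
        res = regress_traits(np.full(40, 0.7), traits)
        assert (res.coefficients == 0).all()
        assert res.r2 == 0.0

    def test_r2_equals_squared_correlation_of_fitted(self, rng):
        n = 60
        traits = trait_frame(rng, n)
        y = rng.normal(0, 1, n)
        res = regress_traits(y, traits)
        X = np.column_stack(
            [(traits[c] - traits[c].mean()) / traits[c].std() for c in traits.columns]
        )
        fitted = res.intercept + X @ res.coefficients.to_numpy()
        assert res.r2 == pytest.approx(np.corrcoef(fitted, y)[0, 1] ** 2, abs=1e-10)

    def test_collinear_columns_named(self, rng):
        traits = trait_frame(rng, 50)
        traits["lone"] = 2 * traits["neo_neur"]
        with pytest.raises(ValueError, match="lone|neo_neur"):
            regress_traits(rng.normal(0, 1, 50), traits)

    def test_too_few_participants(self, rng):
        traits = trait_frame(rng, 10)
        with pytest.raises(ValueError):
            regress_traits(rng.normal(0, 1, 10), traits)


class TestBootstrap:
    def test_fixed_seed_reproducible(self, rng):
        traits = trait_frame(rng, 60)
        y = rng.normal(0, 1, 60)
        a = bootstrap_cis(y, traits, reps=50, seed=9)
        b = bootstrap_cis(y, traits, reps=50, seed=9)
        assert np.allclose(a.ci_low, b.ci_low) and np.allclose(a.ci_high, b.ci_high)

    def test_strong_effect_detected(self):
        """Power: a standardized coefficient of 0.5 at n=250 is flagged
        significant in nearly every simulation."""
        hits = 0
        reps = 20
        for seed in range(reps):
            rs = np.random.default_rng(seed)
            traits = trait_frame(rs, 250)
            z = (traits["neo_extr"] - traits["neo_extr"].mean()) / traits["neo_extr"].std()
            y = (0.5 * z + rs.normal(0, 1, 250)).to_numpy()
            res = bootstrap_cis(y, traits, reps=200, seed=seed)
            hits += bool(res.significant["neo_extr"])
        assert hits / reps >= 0.95

    def test_null_coverage(self):
        """A null coefficient's 95% CI contains 0 in roughly 95% of sims."""
        contains = 0
        reps = 40
        for seed in range(reps):
            rs = np.random.default_rng(1000 + seed)
            traits = trait_frame(rs, 100)
            y = rs.normal(0, 1, 100)
            res = bootstrap_cis(y, traits, reps=200, seed=seed)
            contains += not res.significant["panas_pos"]
        assert contains / reps >= 0.85


class TestPermutation:
    def test_reproducible_small_reps(self, rng):
        traits = trait_frame(rng, 50)
        y = rng.normal(0, 1, 50)
        assert permutation_r2(y, traits, reps=10, seed=3) == permutation_r2(
            y, traits, reps=10, seed=3
        )

    def test_affine_outcome_invariance(self, rng):
        traits = trait_frame(rng, 50)
        y = rng.normal(0, 1, 50)
        p1 = permutation_r2(y, traits, reps=200, seed=4)
        p2 = permutation_r2(3.0 * y - 7.0, traits, reps=200, seed=4)
        assert p1 == p2

    def test_null_p_uniform(self):
        """Kolmogorov-Smirnov check: under the null the permutation p-value
        is approximately Uniform(0, 1) across simulated cohorts."""
        ps = []
        for seed in range(200):
            rs = np.random.default_rng(seed)
            traits = trait_frame(rs, 40)
            y = rs.normal(0, 1, 40)
            ps.append(permutation_r2(y, traits, reps=99, seed=seed))
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_strong_signal_power(self):
        hits = 0
        reps = 20
        for seed in range(reps):
            rs = np.random.default_rng(seed)
            traits = trait_frame(rs, 250)
            z = (traits["neo_extr"] - traits["neo_extr"].mean()) / traits["neo_extr"].std()
            y = (0.5 * z + rs.normal(0, 1, 250)).to_numpy()
            hits += permutation_r2(y, traits, reps=200, seed=seed) < 0.05
        assert hits / reps >= 0.95
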