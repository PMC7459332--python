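"""Encoding GLM, variable-group contributions and the statistics layer."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mlipop import glm
from mlipop.config import PeriodWindows
from mlipop.session import HIT, SMINUS, SPLUS


@pytest.fixture(scope="module")
def design(proficient_session, proficient_dff):
    return glm.build_design(proficient_session, proficient_dff)


class TestBuildDesign:
    def test_reinforcement_history_follows_hits(self, proficient_session,
                                                design):
        s = proficient_session
        col = design.columns.index("reinforcement_history")
        prev = {tr.index: s.trials[i - 1].outcome == HIT
                for i, tr in enumerate(s.trials) if i > 0}
        for idx, expected in prev.items():
            rows = design.row_trial == idx
            if not rows.any():
                continue
            assert np.all(design.X[rows, col] == float(expected))

    def test_odor_columns_exclusive(self, proficient_session, design):
        s = proficient_session
        i_sp = design.columns.index("odor_splus")
        i_sm = design.columns.index("odor_sminus")
        valence = {tr.index: tr.valence for tr in s.trials}
        for idx in np.unique(design.row_trial):
            rows = design.row_trial == idx
            if valence[idx] == SMINUS:
                assert np.all(design.X[rows, i_sp] == 0.0)
                assert design.X[rows, i_sm].max() == 1.0
            else:
                assert np.all(design.X[rows, i_sm] == 0.0)

    def test_odor_indicator_active_during_application_only(self, design):
        i_sp = design.columns.index("odor_splus")
        i_sm = design.columns.index("odor_sminus")
        on = (design.X[:, i_sp] + design.X[:, i_sm]) > 0
        assert np.all(design.row_t_rel[on] >= 0.0)
        assert np.all(design.row_t_rel[on] <= 4.0 + 0.2)

    def test_unscored_trials_raise(self, proficient_session, proficient_dff):
        import copy
        s = copy.deepcopy(proficient_session)
        s.trials[0].outcome = None
        with pytest.raises(ValueError):
            glm.build_design(s, proficient_dff)

    def test_hamming_filter_is_zero_phase_and_unit_gain(self):
        x = np.ones(100)
        y = glm.hamming_lowpass(x, 5.3)
        assert np.allclose(y[5:-5], 1.0)
        # symmetric impulse response => no phase shift of a peak
        imp = np.zeros(101)
        imp[50] = 1.0
        y = glm.hamming_lowpass(imp, 20.0)
        assert y.argmax() == 50


class TestEncodingFit:
    def test_exact_recovery_noise_free(self, design):
        """y built from the design is recovered to solver tolerance."""
        rng = np.random.default_rng(0)
        beta = rng.uniform(-1, 1, size=len(design.columns))
        d2 = glm.DesignMatrix(X=design.X, columns=design.columns,
                              y=design.X @ beta + 0.3,
                              row_trial=design.row_trial,
                              row_t_rel=design.row_t_rel)
        fit = glm.fit_encoding_glm(d2)
        got = np.array([fit.coefficients[c] for c in design.columns])
        np.testing.assert_allclose(got, beta, atol=1e-8)
        assert fit.intercept == pytest.approx(0.3, abs=1e-8)
        assert fit.r_squared() == pytest.approx(100.0, abs=1e-6)

    def test_null_response_near_zero_r2(self, design, windows):
        rng = np.random.default_rng(1)
        d2 = glm.DesignMatrix(X=design.X, columns=design.columns,
                              y=rng.normal(0, 1, size=design.y.size),
                              row_trial=design.row_trial,
                              row_t_rel=design.row_t_rel)
        fit = glm.fit_encoding_glm(d2)
        assert fit.r_squared() < 5.0

    def test_aliased_column_dropped(self, design):
        X = np.column_stack([design.X, design.X[:, 0]])
        d2 = glm.DesignMatrix(X=X, columns=design.columns + ["dup"],
                              y=design.y, row_trial=design.row_trial,
                              row_t_rel=design.row_t_rel)
        fit = glm.fit_encoding_glm(d2)
        assert fit.dropped_columns
        assert np.isfinite(fit.fitted).all()

    def test_real_session_fits_odor_period_well(self, design, windows):
        fit = glm.fit_encoding_glm(design)
        ve = glm.variance_explained(fit, windows)
        assert ve["odorant"] > 50.0
        assert ve["outcome"] > 20.0


class TestVarianceExplained:
    def test_perfect_fit_100_everywhere(self, design, windows):
        d2 = glm.DesignMatrix(X=design.X, columns=design.columns,
                              y=design.X @ np.ones(design.X.shape[1]),
                              row_trial=design.row_trial,
                              row_t_rel=design.row_t_rel)
        fit = glm.fit_encoding_glm(d2)
        for period, val in glm.variance_explained(fit, windows).items():
            assert val == pytest.approx(100.0, abs=1e-6)

    def test_shuffled_response_near_zero(self, design, windows):
        rng = np.random.default_rng(2)
        d2 = glm.DesignMatrix(X=design.X, columns=design.columns,
                              y=rng.permutation(design.y),
                              row_trial=design.row_trial,
                              row_t_rel=design.row_t_rel)
        fit = glm.fit_encoding_glm(d2)
        for period, val in glm.variance_explained(fit, windows).items():
            assert val < 10.0


class TestGroupContributions:
    def synthetic_design(self, n=4000, seed=0):
        rng = np.random.default_rng(seed)
        X = rng.normal(0, 1, size=(n, 4))
        cols = ["a1", "a2", "b1", "b2"]
        groups = {"A": ["a1", "a2"], "B": ["b1", "b2"]}
        t_rel = np.resize(np.linspace(-2, 5.5, 40), n)
        return X, cols, groups, t_rel

    def test_single_group_dependence(self, windows):
        X, cols, groups, t_rel = self.synthetic_design()
        y = X[:, 0] + X[:, 1]
        d = glm.DesignMatrix(X=X, columns=cols, y=y,
                             row_trial=np.zeros(len(y)), row_t_rel=t_rel)
        contrib = glm.group_contributions(d, windows, groups)
        assert np.allclose(contrib.loc["A"], 100.0)
        assert np.allclose(contrib.loc["B"], 0.0)

    def test_equal_orthogonal_groups_split_evenly(self, windows):
        X, cols, groups, t_rel = self.synthetic_design(seed=3)
        rng = np.random.default_rng(4)
        y = X[:, 0] + X[:, 2] + rng.normal(0, 0.1, X.shape[0])
        d = glm.DesignMatrix(X=X, columns=cols, y=y,
                             row_trial=np.zeros(len(y)), row_t_rel=t_rel)
        contrib = glm.group_contributions(d, windows, groups)
        for period in contrib.columns:
            assert contrib.loc["A", period] == pytest.approx(50.0, abs=10.0)

    def test_contributions_sum_to_100(self, design, windows):
        contrib = glm.group_contributions(design, windows)
        sums = contrib.sum(axis=0)
        assert np.allclose(sums.values, 100.0)

    def test_period_specific_drivers_recovered(self, proficient_session,
                                               design, windows):
        """Odor-period signal from odor columns and outcome-period signal
        from lick columns are attributed to the right groups."""
        rng = np.random.default_rng(5)
        i_sp = design.columns.index("odor_splus")
        i_sm = design.columns.index("odor_sminus")
        i_lick = design.columns.index("lick_rate")
        masks = glm.period_masks(design.row_t_rel, windows)
        y = rng.normal(0, 0.05, design.X.shape[0])
        # odor presence on both valences: not reconstructible from licking
        odorish = design.X[:, i_sp] + design.X[:, i_sm]
        lickish = design.X[:, i_lick].copy()
        lickish[~masks["outcome"]] = 0.0
        odorish[~masks["odorant"]] = 0.0
        y += odorish + 0.5 * lickish
        d2 = glm.DesignMatrix(X=design.X, columns=design.columns, y=y,
                              row_trial=design.row_trial,
                              row_t_rel=design.row_t_rel)
        contrib = glm.group_contributions(d2, windows)
        assert contrib["odorant"].idxmax() == "odorants"
        assert contrib.loc["licks", "outcome"] > contrib.loc[
            "reinforcement_history", "outcome"]

    def test_fewer_than_two_groups_raises(self, design, windows):
        with pytest.raises(ValueError):
            glm.group_contributions(design, windows, {"only": ["lick_rate"]})


class TestGlmTest:
    def test_single_factor_F_equals_t_squared(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, 40)
        y = rng.normal(0.8, 1, 40)
        F, p, table = glm.glm_test(np.concatenate([x, y]),
                                   {"g": ["a"] * 40 + ["b"] * 40})
        t = stats.ttest_ind(x, y)
        assert F == pytest.approx(t.statistic ** 2, rel=1e-9)
        assert p == pytest.approx(t.pvalue, rel=1e-9)

    def test_null_term_pvalues_uniform(self):
        ps = []
        for seed in range(200):
            rng = np.random.default_rng(seed)
            vals = rng.normal(0, 1, 50)
            _, p, _ = glm.glm_test(vals, {"g": ["a", "b"] * 25})
            ps.append(p)
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_interaction_effect_detected(self):
        rng = np.random.default_rng(1)
        f1 = np.repeat(["a", "b"], 60)
        f2 = np.tile(np.repeat(["x", "y"], 30), 2)
        vals = rng.normal(0, 1, 120)
        vals[(f1 == "b") & (f2 == "y")] += 1.5    # interaction-only effect
        vals[(f1 == "b") & (f2 == "x")] -= 1.5
        vals[(f1 == "a") & (f2 == "y")] -= 1.5
        vals[(f1 == "a") & (f2 == "x")] += 1.5
        F, p, table = glm.glm_test(vals, {"f1": f1, "f2": f2})
        assert table.loc["C(f1):C(f2)", "PR(>F)"] < 0.01

    def test_saturated_model_raises(self):
        with pytest.raises(ValueError):
            glm.glm_test([1.0, 2.0], {"g": ["a", "b"]})


class TestPosthocFdr:
    def test_step_up_hand_example(self):
        """p = {.01,.02,.03,.04}, m=4, q=.05: all pass, pFDR = 0.04.

        By the step-up rule p_(k) <= k/m * q: 0.04 <= 4/4*0.05."""
        rej, pfdr = glm.posthoc_fdr([0.01, 0.02, 0.03, 0.04], q=0.05)
        assert rej.all() and pfdr == 0.04

    def test_none_significant(self):
        rej, pfdr = glm.posthoc_fdr([1.0, 1.0, 0.9], q=0.05)
        assert not rej.any() and pfdr == 0.0

    def test_single_p_reduces_to_threshold(self):
        rej, pfdr = glm.posthoc_fdr([0.001], q=0.05)
        assert rej[0] and pfdr == 0.001
        rej, pfdr = glm.posthoc_fdr([0.07], q=0.05)
        assert not rej[0]

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            glm.posthoc_fdr([])

    def test_normality_gate_switches_test(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 1, 100)
        b = rng.normal(0.5, 1, 100)
        p_norm = glm.gated_pairwise_pvalue(a, b)
        assert p_norm == pytest.approx(stats.ttest_ind(a, b).pvalue)
        c = rng.lognormal(0, 2, 100)      # clearly non-normal
        d = rng.lognormal(0.8, 2, 100)
        p_rs = glm.gated_pairwise_pvalue(c, d)
        assert p_rs == pytest.approx(stats.ranksums(c, d).pvalue)

    def test_pairwise_table(self):
        rng = np.random.default_rng(1)
        samples = {"a": rng.normal(0, 1, 50), "b": rng.normal(3, 1, 50),
                   "c": rng.normal(0, 1, 50)}
        table, pfdr = glm.posthoc_pairwise_fdr(samples)
        ab = table[(table.a == "a") & (table.b == "b")].iloc[0]
        assert ab.significant


class TestBootstrapCi:
    def test_constant_sample(self):
        lo, hi = glm.bootstrap_ci(np.full(10, 3.7))
        assert lo == hi == 3.7

    def test_contains_sample_mean_heavy_tails(self):
        rng = np.random.default_rng(0)
        x = rng.standard_cauchy(50)
        lo, hi = glm.bootstrap_ci(x)
        assert lo <= np.mean(x) <= hi

    def test_too_small_raises(self):
        with pytest.raises(ValueError):
            glm.bootstrap_ci([1.0])
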