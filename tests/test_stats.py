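"""Statistical procedures against independent oracles and closed forms."""

import itertools

import numpy as np
import pytest
import scipy.stats as sps
from hypothesis import given, settings
from hypothesis import strategies as st

from electrotick import (
    ContingencyTable,
    bootstrap_median_ci,
    chi_square_independence,
    levene_test,
    mann_whitney_permutation,
    regression_through_origin,
    wald_binomial_ci,
)

# the published lift-outcome table: rows treatment/control,
# columns fully / partially / not lifted
OUTCOME_TABLE = ContingencyTable.from_string(
    "15,3,2;0,1,19",
    row_labels=("treatment", "control"),
    col_labels=("fully_lifted", "partially_lifted", "not_lifted"),
)


def direct_chi2(obs):
    """Independent Sum (O-E)^2 / E oracle."""
    obs = np.asarray(obs, float)
    e = np.outer(obs.sum(1), obs.sum(0)) / obs.sum()
    return float(((obs - e) ** 2 / e).sum())


class TestChiSquare:
    def test_outcome_table_matches_direct_formula(self):
        res = chi_square_independence(OUTCOME_TABLE)
        assert res.statistic == pytest.approx(direct_chi2(OUTCOME_TABLE.counts))
        assert res.statistic == pytest.approx(29.7619, abs=1e-4)
        assert res.p_value < 1e-4
        assert res.df == (2,)

    def test_adjusted_residuals_and_bonferroni(self):
        res = chi_square_independence(OUTCOME_TABLE)
        # (15 - 7.5) / sqrt(7.5 * (1 - 1/2) * (1 - 15/40))
        assert res.residuals[0, 0] == pytest.approx(4.8990, abs=1e-4)
        raw = 2 * sps.norm.sf(abs(res.residuals[0, 0]))
        assert res.residual_p[0, 0] == pytest.approx(min(6 * raw, 1.0))
        assert res.residual_p[0, 0] < 1e-4
        assert res.residuals.shape == OUTCOME_TABLE.counts.shape

    def test_identical_rows_give_zero(self):
        t = ContingencyTable.from_string("5,7,8;5,7,8")
        res = chi_square_independence(t)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_2x2_closed_form(self):
        # N (ad - bc)^2 / (r1 r2 c1 c2) = 20 * 100^2 / 10^4 = 20
        t = ContingencyTable.from_string("10,0;0,10")
        assert chi_square_independence(t).statistic == pytest.approx(20.0)

    def test_invariant_under_row_and_column_permutation(self):
        base = chi_square_independence(OUTCOME_TABLE).statistic
        t_rows = ContingencyTable.from_string("0,1,19;15,3,2")
        t_cols = ContingencyTable.from_string("2,15,3;19,0,1")
        assert chi_square_independence(t_rows).statistic == pytest.approx(base)
        assert chi_square_independence(t_cols).statistic == pytest.approx(base)

    def test_zero_marginal_rejected(self):
        t = ContingencyTable.from_string("5,0,3;7,0,2")
        with pytest.raises(ValueError):
            chi_square_independence(t)

    def test_table_validation(self):
        with pytest.raises(ValueError):
            ContingencyTable(np.array([[1, 2]]), ("a",), ("x", "y"))
        with pytest.raises(ValueError):
            ContingencyTable(np.array([[0, 0], [0, 0]]), ("a", "b"), ("x", "y"))


class TestWaldCI:
    def test_treatment_proportion(self):
        res = wald_binomial_ci(15, 20)
        assert res.statistic == pytest.approx(0.75)
        # 1.96 * sqrt(0.75 * 0.25 / 20)
        assert res.extra["half_width"] == pytest.approx(0.18977, abs=1e-4)

    def test_degenerate_at_zero(self):
        res = wald_binomial_ci(0, 20)
        assert res.ci == (0.0, 0.0)

    def test_symmetric_at_half(self):
        res = wald_binomial_ci(10, 20)
        assert res.ci[0] + res.ci[1] == pytest.approx(1.0)

    def test_bounds_checked(self):
        with pytest.raises(ValueError):
            wald_binomial_ci(21, 20)


class TestBootstrapMedianCI:
    def test_constant_vector_collapses(self):
        res = bootstrap_median_ci([4.2] * 12, seed=0)
        assert res.ci == (4.2, 4.2)

    def test_ci_contains_the_sample_median(self):
        res = bootstrap_median_ci(np.arange(1, 1001), n_boot=10_000, seed=1)
        assert res.ci[0] <= 500.5 <= res.ci[1]

    def test_matches_exhaustive_enumeration_for_tiny_n(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 6.0])
        all_medians = np.array(
            [np.median(x[list(c)]) for c in itertools.product(range(5), repeat=5)]
        )
        exact = np.quantile(all_medians, [0.025, 0.975])
        res = bootstrap_median_ci(x, n_boot=50_000, seed=0)
        assert res.ci[0] == pytest.approx(exact[0], abs=0.5)
        assert res.ci[1] == pytest.approx(exact[1], abs=0.5)

    def test_seed_reproducibility(self):
        x = np.random.default_rng(3).normal(size=30)
        a = bootstrap_median_ci(x, seed=7).ci
        b = bootstrap_median_ci(x, seed=7).ci
        assert a == b

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_median_ci([])


class TestMannWhitneyPermutation:
    def test_identical_multisets_give_p_one(self):
        res = mann_whitney_permutation([3.0, 1.0, 2.0], [2.0, 3.0, 1.0])
        assert res.p_value == pytest.approx(1.0)

    def test_small_exhaustive_example(self):
        res = mann_whitney_permutation([1.0, 2.0], [3.0, 4.0])
        assert res.exhaustive
        assert res.p_value == pytest.approx(2 / 6)
        assert res.statistic == 0.0

    def test_ties_use_midranks_and_match_enumeration(self):
        x, y = [1.0, 1.0, 2.0], [1.0, 2.0, 2.0]
        res = mann_whitney_permutation(x, y)
        ranks = sps.rankdata(np.concatenate([x, y]))
        u_obs = ranks[:3].sum() - 6
        assert res.statistic == pytest.approx(u_obs)
        # independent enumeration of all C(6,3) label assignments
        mu = 9 / 2
        devs = [
            abs(ranks[list(c)].sum() - 6 - mu)
            for c in itertools.combinations(range(6), 3)
        ]
        exact = np.mean([d >= abs(u_obs - mu) - 1e-12 for d in devs])
        assert res.p_value == pytest.approx(exact)

    def test_random_mode_agrees_with_exhaustive_within_3_mc_se(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, 5)
        y = rng.normal(0.8, 1, 5)
        exact = mann_whitney_permutation(x, y).p_value
        approx = mann_whitney_permutation(
            x, y, n_perm=4000, seed=11, exhaustive_limit=1
        )
        assert not approx.exhaustive
        se = np.sqrt(exact * (1 - exact) / 4000)
        assert abs(approx.p_value - exact) <= 3 * se + 1 / 4001

    def test_seed_reproducibility_in_random_mode(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(size=30), rng.normal(size=30)
        a = mann_whitney_permutation(x, y, n_perm=500, seed=5).p_value
        b = mann_whitney_permutation(x, y, n_perm=500, seed=5).p_value
        assert a == b

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_permutation([], [1.0])


class TestLevene:
    def test_identical_multisets_give_zero(self):
        res = levene_test([1.0, 2.0, 5.0], [5.0, 1.0, 2.0])
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_matches_hand_rolled_anova_on_absolute_deviations(self):
        rng = np.random.default_rng(2)
        x = rng.normal(0, 1, 20)
        y = rng.normal(0, 3, 25)
        res = levene_test(x, y)
        # independent two-pass ANOVA on |value - group mean|
        dx, dy = np.abs(x - x.mean()), np.abs(y - y.mean())
        grand = np.concatenate([dx, dy]).mean()
        ss_between = len(dx) * (dx.mean() - grand) ** 2 + len(dy) * (
            dy.mean() - grand
        ) ** 2
        ss_within = ((dx - dx.mean()) ** 2).sum() + ((dy - dy.mean()) ** 2).sum()
        f = ss_between / (ss_within / (len(dx) + len(dy) - 2))
        assert res.statistic == pytest.approx(f, rel=1e-10)
        assert res.df == (1, 43)

    def test_direction_larger_spread_gives_positive_f(self):
        res = levene_test([0.0, 2.0], [-5.0, 5.0])
        assert res.statistic > 0

    def test_degenerate_rejected(self):
        with pytest.raises(ValueError):
            levene_test([1.0, 1.0], [2.0, 2.0])
        with pytest.raises(ValueError):
            levene_test([1.0], [2.0, 3.0])


class TestRegressionThroughOrigin:
    def test_exact_proportionality(self):
        x = np.arange(1.0, 11.0)
        fit = regression_through_origin(x, 2 * x)
        assert fit.slope == pytest.approx(2.0)
        assert fit.r_squared == pytest.approx(1.0)

    @settings(max_examples=30, deadline=None)
    @given(st.integers(0, 10_000))
    def test_slope_matches_grid_search_on_random_data(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.uniform(0.5, 4.0, 30)
        y = 3.0 * x + rng.normal(0, 0.5, 30)
        fit = regression_through_origin(x, y)
        grid = np.linspace(fit.slope * 0.9, fit.slope * 1.1, 8001)
        sse = ((y[None, :] - grid[:, None] * x[None, :]) ** 2).sum(axis=1)
        assert abs(fit.slope - grid[np.argmin(sse)]) <= grid[1] - grid[0]

    def test_true_nonzero_intercept_detected_by_anova(self):
        rng = np.random.default_rng(3)
        x = rng.uniform(1, 5, 30)
        y = x + 10 + rng.normal(0, 0.5, 30)
        fit = regression_through_origin(x, y)
        assert fit.anova_p < 0.05
        assert not (fit.free_intercept_ci[0] <= 0 <= fit.free_intercept_ci[1])

    def test_zero_intercept_data_keeps_zero_tenable(self):
        rng = np.random.default_rng(4)
        x = np.repeat([1.5, 2.0, 2.5, 3.0, 3.5, 4.0], 12)
        y = 290 * x + rng.normal(0, 30, 72)
        fit = regression_through_origin(x, y)
        assert fit.free_intercept_ci[0] <= 0 <= fit.free_intercept_ci[1]
        assert fit.df == (1, 71)

    def test_rank_deficiency_rejected(self):
        with pytest.raises(ValueError):
            regression_through_origin([0.0, 0.0], [1.0, 2.0])

    def test_results_serialize_to_plain_types(self):
        fit = regression_through_origin([1.0, 2.0, 3.0], [2.1, 3.9, 6.2])
        d = fit.to_dict()
        import json

        json.dumps(d)  # must be JSON-serializable
        assert d["df"] == [1, 2]
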