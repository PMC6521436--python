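"""Confirmatory statistics: trend, rank-sum, chi-squared, interaction, matching."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from mofsync.stats import (
    batch_chisq,
    compare_groups_wilcoxon,
    interaction_anova,
    matched_subset_rerun,
    mof_trend_test,
    propensity_match,
)


class TestMofTrend:
    def test_flat_scores(self):
        slope, t, p = mof_trend_test([0, 1, 2, 3], [2, 2, 2, 2])
        assert slope == 0.0 and t == 0.0

    def test_closed_form_small_case(self):
        slope, t, p = mof_trend_test([0, 1, 2], [1, 3, 2])
        assert slope == pytest.approx(0.5)
        assert t == pytest.approx(0.57735, abs=1e-4)
        assert p == pytest.approx(2 / 3, abs=1e-3)

    def test_identical_days_rejected(self):
        with pytest.raises(ValueError):
            mof_trend_test([2, 2, 2], [1, 2, 3])

    def test_synchronized_cohort_rises_before_acute(self, planted_cohort):
        """The aligned pre-acute MOF scores rise steeply toward the peak."""
        from mofsync.pipeline import _synchronized_scores
        from mofsync.sync import find_acute_window, trajectories_from_table

        trajs = trajectories_from_table(planted_cohort.trajectory_table)
        windows = {p: find_acute_window(t) for p, t in trajs.items()}
        scores = _synchronized_scores(trajs, windows, None)
        pre = scores[scores["offset"] <= 0]
        slope, t, p = mof_trend_test(pre["offset"], pre["score"])
        assert slope > 0
        assert p < 0.0001


def wilcoxon_exact_oracle(a, b):
    """Two-sided rank-sum p by full enumeration of group assignments."""
    pooled = np.asarray(list(a) + list(b), dtype=float)
    n_a = len(a)
    ranks = sps.rankdata(pooled)
    observed = ranks[:n_a].sum()
    mu = n_a * (len(pooled) + 1) / 2.0
    count = 0
    total = 0
    for idx in combinations(range(len(pooled)), n_a):
        total += 1
        w = ranks[list(idx)].sum()
        if abs(w - mu) >= abs(observed - mu) - 1e-9:
            count += 1
    return count / total


class TestWilcoxon:
    def test_exact_small_case(self):
        w, p = compare_groups_wilcoxon([1, 2, 3], [4, 5, 6])
        assert w == 6.0  # ranks 1+2+3
        assert p == pytest.approx(0.1)

    def test_identical_groups(self):
        _, p = compare_groups_wilcoxon([1, 2, 3], [1, 2, 3])
        assert p == pytest.approx(1.0)

    def test_symmetric_in_group_order(self, rng):
        a, b = rng.normal(size=5), rng.normal(size=7)
        _, p1 = compare_groups_wilcoxon(a, b)
        _, p2 = compare_groups_wilcoxon(b, a)
        assert p1 == pytest.approx(p2)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            compare_groups_wilcoxon([], [1.0])

    def test_matches_enumeration_for_all_small_sizes(self, rng):
        """Exact p equals the full-enumeration oracle for all sizes <= 6."""
        for n_a in range(1, 7):
            for n_b in range(1, 7):
                a = rng.normal(size=n_a)
                b = rng.normal(size=n_b)
                _, p = compare_groups_wilcoxon(a, b)
                assert p == pytest.approx(wilcoxon_exact_oracle(a, b), abs=1e-12)


class TestBatchChisq:
    def test_balanced_table(self):
        chi2, p = batch_chisq([[10, 10], [10, 10]])
        assert chi2 == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_proportional_rows(self):
        chi2, _ = batch_chisq([[10, 20, 30], [20, 40, 60]])
        assert chi2 == pytest.approx(0.0)

    def test_hand_computed_2x2(self):
        chi2, _ = batch_chisq([[20, 10], [10, 20]])
        assert chi2 == pytest.approx(6.6667, abs=1e-3)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            batch_chisq([[0, 0], [1, 2]])


class TestInteractionModel:
    def test_f_equals_squared_t(self, rng):
        n = 40
        mof = rng.integers(2, 12, size=n).astype(float)
        sex = np.where(rng.random(n) < 0.5, "female", "male")
        y = 0.3 * mof + rng.normal(size=n)
        res = interaction_anova(y, mof, sex)
        import statsmodels.api as sm

        sex_num = (sex == "female").astype(float)
        X = np.column_stack([np.ones(n), mof, sex_num, mof * sex_num])
        fit = sm.OLS(y, X).fit()
        for name, t_p in zip(
            ["intercept", "mof_effect", "sex_effect", "interaction_effect"],
            fit.pvalues,
        ):
            assert res.f_pvalues[name] == pytest.approx(t_p, abs=1e-10)

    def test_constant_response(self, rng):
        n = 20
        mof = rng.integers(2, 12, size=n).astype(float)
        sex = np.array(["female", "male"] * 10)
        res = interaction_anova(np.ones(n), mof, sex)
        for name in ("mof_effect", "sex_effect", "interaction_effect"):
            assert res.coefficients[name] == pytest.approx(0.0, abs=1e-10)

    def test_slope_recovery(self, rng):
        n = 200
        mof = rng.integers(2, 12, size=n).astype(float)
        sex = np.where(rng.random(n) < 0.5, "female", "male")
        y = 1.0 + 0.5 * mof + rng.normal(size=n, scale=0.5)
        res = interaction_anova(y, mof, sex)
        assert res.coefficients["mof_effect"] == pytest.approx(0.5, abs=0.15)

    def test_null_interaction_calibration(self, rng):
        """With no true interaction, its F-test rejects at ~5%."""
        hits = 0
        n_rep = 400
        for _ in range(n_rep):
            n = 30
            mof = rng.integers(2, 12, size=n).astype(float)
            sex = np.array(["female"] * 15 + ["male"] * 15)
            y = 0.2 * mof + 0.3 * (sex == "female") + rng.normal(size=n)
            res = interaction_anova(y, mof, sex)
            hits += res.f_pvalues["interaction_effect"] < 0.05
        rate = hits / n_rep
        assert abs(rate - 0.05) < 3 * np.sqrt(0.05 * 0.95 / n_rep) + 0.01

    def test_rank_deficient_design_rejected(self):
        with pytest.raises(ValueError):
            interaction_anova(
                [1.0, 2.0, 3.0, 4.0], [5, 5, 5, 5], ["female", "female", "male", "male"]
            )


class TestPropensityMatch:
    def test_identical_covariates_match_everyone(self):
        cov = pd.DataFrame(
            {"ais": [3.0] * 6, "mof": [8.0] * 6},
            index=[f"s{i}" for i in range(6)],
        )
        sex = {f"s{i}": ("female" if i < 2 else "male") for i in range(6)}
        match = propensity_match(cov, sex)
        assert len(match.pairs) == 2
        assert all(v == pytest.approx(0.0) for v in match.smd_after.values())

    def test_disjoint_ranges_with_caliper_yield_no_pairs(self):
        cov = pd.DataFrame(
            {"mof": [2.0, 2.5, 3.0, 20.0, 20.5, 21.0]},
            index=[f"s{i}" for i in range(6)],
        )
        sex = {"s0": "female", "s1": "female", "s2": "female",
               "s3": "male", "s4": "male", "s5": "male"}
        match = propensity_match(cov, sex, caliper=0.2)
        assert match.pairs == []

    def test_balance_improves_on_biased_cohort(self, rng):
        """Greedy matching reduces every covariate SMD when overlap exists."""
        worsened = 0
        for seed in range(50):
            local = np.random.default_rng(seed)
            n = 60
            sex = np.array(["female"] * 20 + ["male"] * 40)
            mof = np.where(
                sex == "female",
                local.normal(7, 2, size=n),
                local.normal(9, 2, size=n),
            )
            ais = local.normal(3, 1, size=n) + 0.2 * (sex == "male")
            cov = pd.DataFrame(
                {"mof": mof, "ais": ais}, index=[f"s{i}" for i in range(n)]
            )
            match = propensity_match(cov, dict(zip(cov.index, sex)))
            assert len(match.pairs) > 0
            if max(match.smd_after.values()) > max(match.smd_before.values()) + 1e-9:
                worsened += 1
        assert worsened == 0

    def test_single_sex_rejected(self):
        cov = pd.DataFrame({"mof": [1.0, 2.0]}, index=["a", "b"])
        with pytest.raises(ValueError):
            propensity_match(cov, {"a": "female", "b": "female"})


class TestMatchedRerun:
    def test_too_few_pairs_rejected(self):
        from mofsync.stats import MatchResult

        match = MatchResult([("a", "b")], pd.Series(dtype=float),
                            pd.Series(dtype=float), {}, {}, 0.2)
        with pytest.raises(ValueError):
            matched_subset_rerun(match, pd.DataFrame(), {}, pd.DataFrame(),
                                 None, n_perm=10)
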