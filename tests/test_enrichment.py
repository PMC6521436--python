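"""Gene-wise t-statistics, permutation enrichment and BH correction."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from statsmodels.stats.multitest import multipletests

from mofsync.enrichment import bh_adjust, gsea_mean_perm, phase_ttests, run_all_phases
from mofsync.genesets import GeneSet, GeneSetCollection


def make_phase_frame(samples):
    return pd.DataFrame(
        {
            "sample_id": samples,
            "patient_id": samples,
            "day": 0,
            "offset": 0,
            "phase": "acute",
        }
    )


def two_group_inputs(female_rows, male_rows):
    """Build expression/labels/phase tables for one gene and two sexes."""
    f_ids = [f"f{i}" for i in range(len(female_rows))]
    m_ids = [f"m{i}" for i in range(len(male_rows))]
    expr = pd.DataFrame(
        [female_rows + male_rows], index=["g1"], columns=f_ids + m_ids, dtype=float
    )
    sex = {s: "female" for s in f_ids} | {s: "male" for s in m_ids}
    return expr, sex, make_phase_frame(f_ids + m_ids)


class TestPhaseTTests:
    def test_pooled_t_matches_scipy(self):
        expr, sex, phases = two_group_inputs([2, 3, 4], [1, 2, 3])
        out = phase_ttests(expr, sex, phases, "acute")
        assert out.loc["g1", "t"] == pytest.approx(1.224745, abs=1e-6)
        ref, _ = stats.ttest_ind([2, 3, 4], [1, 2, 3], equal_var=True)
        assert out.loc["g1", "t"] == pytest.approx(ref)

    def test_orientation_is_female_minus_male(self):
        expr, sex, phases = two_group_inputs([1, 2, 3], [2, 3, 4])
        out = phase_ttests(expr, sex, phases, "acute")
        assert out.loc["g1", "t"] == pytest.approx(-1.224745, abs=1e-6)

    def test_identical_groups_give_zero(self):
        expr, sex, phases = two_group_inputs([1, 2, 3], [1, 2, 3])
        assert phase_ttests(expr, sex, phases, "acute").loc["g1", "t"] == 0.0

    def test_constant_equal_rows_give_zero(self):
        expr, sex, phases = two_group_inputs([2, 2, 2], [2, 2, 2])
        assert phase_ttests(expr, sex, phases, "acute").loc["g1", "t"] == 0.0

    def test_constant_unequal_rows_dropped(self):
        expr, sex, phases = two_group_inputs([2, 2, 2], [3, 3, 3])
        with pytest.warns(UserWarning):
            out = phase_ttests(expr, sex, phases, "acute")
        assert "g1" not in out.index

    def test_too_few_samples_is_error(self):
        expr, sex, phases = two_group_inputs([2, 3], [1])
        with pytest.raises(ValueError, match="acute"):
            phase_ttests(expr, sex, phases, "acute")


def toy_universe():
    t = pd.Series([2.0, 1.0, 0.0, -1.0, -2.0], index=list("ABCDE"))
    sets = GeneSetCollection()
    sets.add(GeneSet("top2", "", ("A", "B")))
    sets.add(GeneSet("all", "", tuple("ABCDE")))
    return t, sets


class TestGseaMeanPerm:
    def test_exact_enumeration(self):
        t, sets = toy_universe()
        out = gsea_mean_perm(t, sets, n_perm=10, exact=True).set_index("set")
        assert out.loc["top2", "mean_stat"] == pytest.approx(1.5)
        assert out.loc["top2", "p_up"] == pytest.approx(1 / 10)
        assert out.loc["top2", "p_dn"] == pytest.approx(1.0)
        # the whole universe admits a single subset
        assert out.loc["all", "p_up"] == pytest.approx(1.0)
        assert out.loc["all", "p_dn"] == pytest.approx(1.0)

    def test_tails_overlap(self):
        """Inclusive counting on both tails forces p_up + p_dn >= 1."""
        rng = np.random.default_rng(3)
        t = pd.Series(rng.normal(size=40), index=[f"g{i}" for i in range(40)])
        sets = GeneSetCollection()
        for i in range(10):
            genes = rng.choice(t.index, size=5, replace=False)
            sets.add(GeneSet(f"s{i}", "", tuple(genes)))
        out = gsea_mean_perm(t, sets, n_perm=500, rng=np.random.default_rng(4))
        assert np.all(out["p_up"] + out["p_dn"] >= 1.0)

    def test_antisymmetry_exact(self):
        t, sets = toy_universe()
        up = gsea_mean_perm(t, sets, n_perm=10, exact=True).set_index("set")
        dn = gsea_mean_perm(-t, sets, n_perm=10, exact=True).set_index("set")
        assert up.loc["top2", "p_up"] == dn.loc["top2", "p_dn"]
        assert up.loc["top2", "p_dn"] == dn.loc["top2", "p_up"]

    def test_monte_carlo_converges_to_exact(self):
        """MC p-values agree with exhaustive enumeration within 3 MC SEs."""
        rng = np.random.default_rng(10)
        t = pd.Series(rng.normal(size=10), index=[f"g{i}" for i in range(10)])
        sets = GeneSetCollection()
        for i, size in enumerate([2, 3, 4]):
            sets.add(GeneSet(f"s{i}", "", tuple(rng.choice(t.index, size, replace=False))))
        exact = gsea_mean_perm(t, sets, n_perm=1, exact=True).set_index("set")
        n_perm = 20_000
        mc = gsea_mean_perm(
            t, sets, n_perm=n_perm, rng=np.random.default_rng(11)
        ).set_index("set")
        for name in exact.index:
            for tail in ("p_up", "p_dn"):
                p = exact.loc[name, tail]
                se = np.sqrt(p * (1 - p) / n_perm)
                assert abs(mc.loc[name, tail] - p) <= 3 * se + 2 / n_perm

    def test_direction_follows_sign(self):
        t, sets = toy_universe()
        out = gsea_mean_perm(-t, sets, n_perm=10, exact=True).set_index("set")
        assert out.loc["top2", "direction"] == "down_in_female"

    def test_empty_universe_is_error(self):
        _, sets = toy_universe()
        with pytest.raises(ValueError):
            gsea_mean_perm(pd.Series(dtype=float), sets, n_perm=10)


class TestBHAdjust:
    def test_hand_worked_example(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.04]), [0.03, 0.03, 0.04])

    def test_single_and_ties(self):
        assert bh_adjust([1.0]) == pytest.approx([1.0])
        assert np.allclose(bh_adjust([0.05, 0.05]), [0.05, 0.05])

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([0.0, 0.5])
        with pytest.raises(ValueError):
            bh_adjust([1.5])

    @given(
        st.lists(
            st.floats(min_value=1e-9, max_value=1.0, exclude_min=False),
            min_size=1,
            max_size=50,
        )
    )
    @settings(max_examples=200, deadline=None)
    def test_matches_reference_and_invariants(self, pvals):
        ours = bh_adjust(pvals)
        _, ref, _, _ = multipletests(pvals, method="fdr_bh")
        assert np.allclose(ours, ref, atol=1e-12)
        p = np.asarray(pvals)
        assert np.all(ours >= p - 1e-15)
        assert np.all(ours <= np.minimum(p * len(p), 1.0) + 1e-15)
        # order invariance
        order = np.argsort(p)[::-1]
        assert np.allclose(bh_adjust(p[order]), ours[order], atol=1e-12)


class TestRunAllPhases:
    def test_planted_effect_recovered(self, planted_cohort):
        from mofsync.sync import assign_phases, find_acute_window, trajectories_from_table

        cohort = planted_cohort
        trajs = trajectories_from_table(cohort.trajectory_table)
        windows = {p: find_acute_window(t) for p, t in trajs.items()}
        phases = assign_phases(cohort.sample_meta, windows)
        sex = dict(zip(cohort.clinical.patient_id, cohort.clinical.sex))
        out = run_all_phases(
            cohort.expression, sex, phases, cohort.gene_sets,
            n_perm=2000, rng=np.random.default_rng(0),
        )
        acute = out[(out["set"] == "SET_0000") & (out["phase"] == "acute")].iloc[0]
        assert acute["direction"] == "up_in_female"
        assert acute["adj_p_up"] < 0.025
        pre = out[(out["set"] == "SET_0001") & (out["phase"] == "pre_acute")].iloc[0]
        assert pre["direction"] == "down_in_female"
        assert pre["adj_p_dn"] < 0.025

    def test_adjusted_not_below_raw(self, planted_cohort):
        from mofsync.sync import assign_phases, find_acute_window, trajectories_from_table

        cohort = planted_cohort
        trajs = trajectories_from_table(cohort.trajectory_table)
        windows = {p: find_acute_window(t) for p, t in trajs.items()}
        phases = assign_phases(cohort.sample_meta, windows)
        sex = dict(zip(cohort.clinical.patient_id, cohort.clinical.sex))
        out = run_all_phases(
            cohort.expression, sex, phases, cohort.gene_sets,
            n_perm=200, rng=np.random.default_rng(1),
        )
        assert set(out["phase"]) == {
            "early_pre_acute", "pre_acute", "acute", "post_acute", "late_post_acute"
        }
        assert np.all(out["adj_p_up"] >= out["p_up"] - 1e-15)
        assert np.all(out["adj_p_dn"] >= out["p_dn"] - 1e-15)

    def test_no_analyzable_phase_is_error(self):
        expr, sex, phases = two_group_inputs([1.0, 2.0], [3.0])
        sets = GeneSetCollection()
        sets.add(GeneSet("s", "", ("g1",)))
        with pytest.raises(ValueError):
            with pytest.warns(UserWarning):
                run_all_phases(expr, sex, phases, sets, n_perm=10, min_size=1)
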