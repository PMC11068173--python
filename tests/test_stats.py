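"""Cohort statistics: rank tests against enumeration oracles, RM-ANOVA,
Bonferroni post hoc, and the cohort simulator feeding them."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from toftskit import (
    CohortSpec,
    analyze_cohort,
    kruskal_wallis,
    mann_whitney,
    pairwise_posthoc,
    percent_change,
    rm_anova,
    simulate_cohort,
    summarize_table,
)
from toftskit.phantom import DEFAULT_TRAJECTORIES
from toftskit.stats_report import bonferroni, validate_cohort


def exact_mw_p(a, b):
    """Permutation-enumeration oracle for the two-sided Mann–Whitney p."""
    pooled = np.concatenate([a, b])
    n, na = len(pooled), len(a)

    def u_stat(sample_a, sample_b):
        return sum((x > y) + 0.5 * (x == y) for x in sample_a for y in sample_b)

    u_obs = u_stat(a, b)
    mu = na * (n - na) / 2
    count = total = 0
    for idx in combinations(range(n), na):
        mask = np.zeros(n, bool)
        mask[list(idx)] = True
        u = u_stat(pooled[mask], pooled[~mask])
        count += abs(u - mu) >= abs(u_obs - mu) - 1e-12
        total += 1
    return count / total


class TestMannWhitney:
    def test_separated_samples_exact_p(self):
        r = mann_whitney([1, 2, 3], [4, 5, 6])
        assert r.statistic == 0.0
        assert r.p_value == pytest.approx(0.1, abs=1e-12)

    def test_identical_samples_give_p_one(self):
        r = mann_whitney([1.0, 2.0, 5.0], [1.0, 2.0, 5.0], mode="exact")
        assert r.p_value == pytest.approx(1.0)

    def test_exact_equals_enumeration_on_all_small_no_tie_instances(self):
        # every partition of distinct ranks with n_a + n_b <= 8
        for n in range(2, 9):
            vals = np.arange(1.0, n + 1)
            for na in range(1, n):
                for idx in combinations(range(n), na):
                    a = vals[list(idx)]
                    b = np.delete(vals, list(idx))
                    r = mann_whitney(a, b, mode="exact")
                    assert r.p_value == pytest.approx(exact_mw_p(a, b), abs=1e-12)

    def test_asymptotic_within_3se_of_permutation_mc(self):
        rng = np.random.default_rng(4)
        a = rng.normal(0, 1, 25)
        b = rng.normal(0.6, 1, 25)
        r = mann_whitney(a, b, mode="asymptotic")
        pooled = np.concatenate([a, b])
        mu = len(a) * len(b) / 2
        u_obs = sum((x > y) for x in a for y in b)
        n_perm = 20_000
        hits = 0
        for _ in range(n_perm):
            perm = rng.permutation(pooled)
            u = sum((x > y) for x in perm[:25] for y in perm[25:])
            hits += abs(u - mu) >= abs(u_obs - mu)
        p_mc = hits / n_perm
        se = np.sqrt(max(p_mc, 1 / n_perm) * (1 - p_mc) / n_perm)
        assert abs(r.p_value - p_mc) < 3 * se + 1e-3

    @given(shift=st.floats(-5, 5), scale=st.floats(0.1, 10))
    def test_invariant_under_monotone_transform(self, shift, scale):
        a = np.array([0.2, 1.4, 3.3, 4.1])
        b = np.array([0.9, 2.2, 5.0])
        p0 = mann_whitney(a, b).p_value
        p1 = mann_whitney(a * scale + shift, b * scale + shift).p_value
        assert p1 == pytest.approx(p0, abs=1e-12)


class TestKruskalWallis:
    def test_invariant_to_group_order(self):
        g1, g2, g3 = [1.0, 4.0], [2.0, 5.0], [3.0, 6.0]
        assert kruskal_wallis([g1, g2, g3]).statistic == pytest.approx(
            kruskal_wallis([g3, g1, g2]).statistic)

    def test_matches_direct_rank_formula(self):
        groups = [[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]]
        n = 6
        # H = 12/(N(N+1)) Σ R_i²/n_i − 3(N+1), no ties
        ranks = {v: r for r, v in enumerate(sorted(sum(groups, [])), start=1)}
        h = 12 / (n * (n + 1)) * sum(
            sum(ranks[v] for v in g) ** 2 / len(g) for g in groups) - 3 * (n + 1)
        assert kruskal_wallis(groups).statistic == pytest.approx(h, rel=1e-12)

    def test_all_identical_values_flagged_undefined(self):
        r = kruskal_wallis([[2.0, 2.0], [2.0, 2.0]])
        assert not r.defined and np.isnan(r.statistic)

    def test_power_above_alpha_for_shifted_groups(self):
        rng = np.random.default_rng(0)
        rejections = 0
        n_rep = 200
        for _ in range(n_rep):
            groups = [rng.normal(0, 1, 8), rng.normal(0, 1, 8), rng.normal(1, 1, 8)]
            rejections += kruskal_wallis(groups).p_value < 0.05
        assert rejections / n_rep > 0.05  # well above the nominal level

    def test_monotone_transform_invariance(self):
        groups = [[0.1, 0.9, 2.0], [0.5, 1.5, 3.0], [0.2, 2.5, 4.0]]
        h0 = kruskal_wallis(groups).statistic
        h1 = kruskal_wallis([list(np.exp(g)) for g in groups]).statistic
        assert h1 == pytest.approx(h0, rel=1e-12)


class TestRmAnova:
    def test_identical_values_across_days_give_f_zero(self):
        v = np.tile(np.array([[3.0], [5.0], [7.0]]), (1, 3))
        r = rm_anova(v)
        assert r.statistic == 0.0

    def test_matches_hand_computed_sums_of_squares(self):
        # classic 3-condition within-subject table
        v = np.array([[30.0, 28.0, 16.0],
                      [14.0, 18.0, 10.0],
                      [24.0, 20.0, 18.0],
                      [38.0, 34.0, 20.0],
                      [26.0, 28.0, 14.0]])
        n, k = v.shape
        grand = v.mean()
        ss_cond = n * ((v.mean(axis=0) - grand) ** 2).sum()
        ss_subj = k * ((v.mean(axis=1) - grand) ** 2).sum()
        ss_tot = ((v - grand) ** 2).sum()
        ss_err = ss_tot - ss_cond - ss_subj
        f_hand = (ss_cond / (k - 1)) / (ss_err / ((k - 1) * (n - 1)))
        r = rm_anova(v)
        assert r.statistic == pytest.approx(f_hand, rel=1e-9)
        assert r.df == (k - 1, (k - 1) * (n - 1))

    def test_single_subject_flagged_no_test(self):
        r = rm_anova(np.array([[1.0, 2.0, 3.0]]))
        assert not r.defined

    def test_incomplete_subjects_excluded_and_counted(self):
        v = np.array([[1.0, 2.0, 3.0], [2.0, np.nan, 4.0],
                      [3.0, 1.0, 5.0], [2.0, 2.0, 6.0]])
        r = rm_anova(v)
        assert "excluded=1" in r.note

    def test_null_rejection_rate_calibrated(self):
        # permuting day labels: rejection rate should sit near alpha
        rng = np.random.default_rng(1)
        n_rep, hits = 300, 0
        base = rng.normal(0, 1, (8, 1)) + rng.normal(0, 0.5, (8, 3))
        for _ in range(n_rep):
            v = np.take_along_axis(base, np.argsort(
                rng.uniform(size=base.shape), axis=1), axis=1)
            hits += rm_anova(v).p_value < 0.05
        rate = hits / n_rep
        assert 0.01 < rate < 0.12


class TestPosthocAndPercentChange:
    @staticmethod
    def cohort(seed=0, **kw):
        return simulate_cohort(CohortSpec(seed=seed, **kw))

    def test_bonferroni_caps_at_one(self):
        assert bonferroni(0.3, 6) == 1.0

    def test_bonferroni_scales_raw_p(self):
        assert bonferroni(0.005, 6) == pytest.approx(0.03)

    def test_identically_distributed_groups_flag_nothing(self):
        # same within-group values in every group: no pair can be significant
        rows = []
        vals = [0.30, 0.38, 0.45, 0.52, 0.61]
        for g in ("IA-T", "IV-T", "IA-S", "Sham"):
            for i, v in enumerate(vals):
                rows.append((f"{g}-{i}", g, 0, "Ktrans", v))
        table = pd.DataFrame(rows, columns=["subject", "group", "day",
                                            "metric", "value"])
        res = pairwise_posthoc(table, "Ktrans", 0, policy="always")
        pairs = [r for r in res if "vs" in r.label]
        assert len(pairs) == 6
        assert all(r.p_adjusted > 0.05 for r in pairs)

    def test_adjusted_p_bounded_by_raw_and_one(self):
        table = self.cohort(seed=3)
        res = pairwise_posthoc(table, "Ktrans", 14, policy="always")
        for r in res:
            assert r.p_adjusted >= r.p_raw - 1e-15
            assert r.p_adjusted <= 1.0

    def test_treated_vs_sham_detected_at_day14_in_most_replicates(self):
        # power of the default study conditions (n = 8 per arm)
        hits = 0
        n_rep = 200
        for seed in range(n_rep):
            table = self.cohort(seed=seed)
            sel = table[(table["metric"] == "Ktrans") & (table["day"] == 14)]
            a = sel[sel["group"] == "IA-T"]["value"].to_numpy()
            b = sel[sel["group"] == "Sham"]["value"].to_numpy()
            hits += mann_whitney(a, b).p_value < 0.05
        assert hits / n_rep >= 0.8

    def test_unknown_correction_rejected(self):
        with pytest.raises(ValueError, match="correction"):
            pairwise_posthoc(self.cohort(), "Ktrans", 0, correction="holm")

    def test_percent_change_examples(self):
        assert percent_change(1.0, 0.409) == pytest.approx(-59.1)
        assert percent_change(2.5, 2.5) == 0.0
        assert percent_change(0.47, 0.38) == pytest.approx(-19.1, abs=0.05)
        with pytest.raises(ValueError, match="baseline"):
            percent_change(0.0, 1.0)


class TestCohortSimulatorAndSummary:
    def test_zero_dispersion_reproduces_medians_exactly(self):
        table = simulate_cohort(CohortSpec(between_sigma=0.0, within_sigma=0.0))
        for group, traj in DEFAULT_TRAJECTORIES.items():
            for metric, days in traj.items():
                for day, med in days.items():
                    vals = table[(table["group"] == group)
                                 & (table["metric"] == metric)
                                 & (table["day"] == day)]["value"]
                    np.testing.assert_allclose(vals, med, rtol=1e-12)

    def test_default_treated_arm_ktrans_declines_59_percent(self):
        traj = DEFAULT_TRAJECTORIES["IA-T"]["Ktrans"]
        assert traj[14] / traj[0] == pytest.approx(0.409, abs=1e-3)

    def test_kep_rows_satisfy_kinetic_identity(self):
        table = simulate_cohort(CohortSpec(seed=9))
        wide = table.pivot_table(index=["subject", "day"], columns="metric",
                                 values="value")
        np.testing.assert_allclose(wide["Kep"], wide["Ktrans"] / wide["Ve"],
                                   rtol=1e-12)

    def test_seed_determinism_and_unknown_group_error(self):
        a = simulate_cohort(CohortSpec(seed=5))
        b = simulate_cohort(CohortSpec(seed=5))
        pd.testing.assert_frame_equal(a, b)
        with pytest.raises(ValueError, match="unknown group"):
            CohortSpec(groups=("IA-T", "Mystery"))

    def test_summary_grid_single_subject_and_sort_oracle(self):
        table = simulate_cohort(CohortSpec(n_per_group=1, seed=2))
        grid = summarize_table(table)
        one = grid[(grid["metric"] == "Ktrans") & (grid["day"] == 0)
                   & (grid["group"] == "IA-T")].iloc[0]
        val = table[(table["group"] == "IA-T") & (table["metric"] == "Ktrans")
                    & (table["day"] == 0)]["value"].iloc[0]
        assert one["median"] == one["q1"] == one["q3"] == pytest.approx(val)

        vals = np.array([3.56, 4.85, 7.70])
        t = pd.DataFrame({"subject": ["s1", "s2", "s3"], "group": "IA-T",
                          "day": 0, "metric": "vol", "value": vals})
        g = summarize_table(t)
        assert g.iloc[0]["median"] == pytest.approx(4.85)

    def test_duplicate_rows_rejected(self):
        t = pd.DataFrame({"subject": ["a", "a"], "group": "IA-T", "day": 0,
                          "metric": "Ktrans", "value": [1.0, 2.0]})
        with pytest.raises(ValueError, match="duplicate"):
            validate_cohort(t)

    def test_analyze_cohort_reports_branch_per_cell(self):
        table = simulate_cohort(CohortSpec(seed=0, n_per_group=6))
        rep = analyze_cohort(table, force_branch="kruskal")
        assert set(rep["branches"].values()) == {"kruskal"}
        assert not rep["summary"].empty
        assert (rep["between_group"]["p_adjusted"]
                >= rep["between_group"]["p_raw"] - 1e-15).all()
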