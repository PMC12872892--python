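"""Tests for the repeated-measures statistical layer against independent oracles."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from fertimass.errors import (
    DegenerateInputError,
    InvalidInputError,
    UnbalancedDesignError,
)
from fertimass.stats import (
    RMDesign,
    bonferroni_adjust,
    cell_means_design_matrix,
    influence_diagnostics,
    pairwise_emmeans_bonferroni,
    rm_anova,
    welch_t_test,
    PairwiseComparison,
)

from oracles import cooks_distance_loo, split_plot_projection_ss, welch_closed_form


def make_design(g=2, n=4, t=5, seed=0, group_shift=0.0, noise=1.0, subj_sd=1.0):
    rng = np.random.default_rng(seed)
    rows = []
    for gi in range(g):
        for si in range(n):
            subj = f"g{gi}s{si}"
            offset = subj_sd * rng.standard_normal() + (group_shift if gi == 0 else 0)
            for ti in range(t):
                rows.append(
                    {
                        "subject": subj,
                        "group": f"cv{gi}",
                        "time": ti,
                        "value": offset + 0.5 * ti + noise * rng.standard_normal(),
                    }
                )
    return RMDesign(pd.DataFrame(rows))


class TestWelch:
    def test_identical_samples(self):
        a = [10.0, 12.0, 14.0, 16.0]
        res = welch_t_test(a, a)
        assert res.t == 0.0
        assert res.p == pytest.approx(1.0)

    def test_location_invariance(self):
        a = np.array([10.0, 12.0, 14.0, 16.0])
        b = np.array([11.0, 13.0, 15.0, 18.0])
        r1 = welch_t_test(a, b)
        r2 = welch_t_test(a + 100.0, b + 100.0)
        assert (r1.t, r1.df, r1.p) == pytest.approx((r2.t, r2.df, r2.p))

    def test_matches_closed_form_oracle(self):
        a = [10.0, 12.0, 14.0, 16.0]
        b = [11.0, 13.0, 15.0, 17.0]
        res = welch_t_test(a, b)
        t, df, p = welch_closed_form(a, b)
        assert res.t == pytest.approx(t, abs=1e-10)
        assert res.df == pytest.approx(df, abs=1e-10)
        assert res.p == pytest.approx(p, abs=1e-10)

    def test_equal_sizes_and_variances_reduce_to_student_df(self):
        a = [1.0, 2.0, 3.0, 4.0]
        b = [2.0, 3.0, 4.0, 5.0]
        assert welch_t_test(a, b).df == pytest.approx(len(a) + len(b) - 2)

    def test_zero_variance_is_degenerate(self):
        with pytest.raises(DegenerateInputError):
            welch_t_test([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_tiny_samples_rejected(self):
        with pytest.raises(InvalidInputError):
            welch_t_test([1.0], [1.0, 2.0])


class TestRMAnova:
    def test_constant_response_degenerate(self):
        df = make_design(noise=0.0, subj_sd=0.0).data.assign(value=3.0)
        res = rm_anova(RMDesign(df))
        assert res.degenerate
        assert np.allclose(res.table["SS"], 0.0, atol=1e-18)
        assert np.isnan(res.table.loc["group", "F"])

    def test_pure_group_shift_forces_zero_time_effects(self):
        design = make_design(noise=0.0, subj_sd=0.0, group_shift=2.5)
        df = design.data.copy()
        df["value"] = df["value"] - 0.5 * df["time"]  # remove the time trend
        res = rm_anova(RMDesign(df))
        assert res.table.loc["time", "SS"] == pytest.approx(0.0, abs=1e-18)
        assert res.table.loc["group:time", "SS"] == pytest.approx(0.0, abs=1e-18)
        assert res.table.loc["group", "SS"] > 0

    @pytest.mark.parametrize("seed", [0, 1, 2])
    @pytest.mark.parametrize("shape", [(2, 4, 5), (3, 3, 4)])
    def test_matches_projection_oracle(self, seed, shape):
        g, n, t = shape
        design = make_design(g=g, n=n, t=t, seed=seed, group_shift=1.0)
        res = rm_anova(design)
        oracle = split_plot_projection_ss(design.data)
        for effect, ss in oracle.items():
            assert res.table.loc[effect, "SS"] == pytest.approx(ss, abs=1e-8)

    def test_matches_pingouin_mixed_anova(self):
        pingouin = pytest.importorskip("pingouin")
        design = make_design(seed=3, group_shift=1.5)
        res = rm_anova(design)
        pg = pingouin.mixed_anova(
            data=design.data,
            dv="value",
            within="time",
            subject="subject",
            between="group",
        ).set_index("Source")
        assert res.table.loc["group", "F"] == pytest.approx(
            pg.loc["group", "F"], rel=1e-6
        )
        assert res.table.loc["time", "F"] == pytest.approx(
            pg.loc["time", "F"], rel=1e-6
        )
        assert res.table.loc["group:time", "F"] == pytest.approx(
            pg.loc["Interaction", "F"], rel=1e-6
        )

    def test_ss_decomposition_totals(self):
        design = make_design(seed=5)
        res = rm_anova(design)
        y = design.data["value"].to_numpy()
        total = ((y - y.mean()) ** 2).sum()
        assert res.table["SS"].sum() == pytest.approx(total, rel=1e-9)

    def test_gg_epsilon_in_valid_range(self):
        design = make_design(seed=7, t=6)
        res = rm_anova(design)
        t = len(design.times)
        assert 1.0 / (t - 1) - 1e-12 <= res.gg_epsilon <= 1.0 + 1e-12

    def test_unbalanced_design_rejected(self):
        df = make_design().data.iloc[:-1]
        with pytest.raises(UnbalancedDesignError):
            RMDesign(df)

    def test_subject_in_two_groups_rejected(self):
        df = make_design().data.copy()
        df.loc[df.index[0], "subject"] = df["subject"].iloc[-1]
        with pytest.raises(UnbalancedDesignError):
            RMDesign(df)


class TestPairwiseContrasts:
    def test_bonferroni_direct_product_and_cap(self):
        base = PairwiseComparison("c", 0.0, 1.0, 10.0, 0.0, 0.01, 0.01)
        adj = bonferroni_adjust([base], m=10)[0]
        assert adj.p_adjusted == pytest.approx(0.10)
        base2 = PairwiseComparison("c", 0.0, 1.0, 10.0, 0.0, 0.2, 0.2)
        assert bonferroni_adjust([base2], m=10)[0].p_adjusted == 1.0

    def test_adjusted_monotone_in_family_size(self):
        base = PairwiseComparison("c", 0.0, 1.0, 10.0, 0.0, 0.02, 0.02)
        adj = [bonferroni_adjust([base], m=m)[0].p_adjusted for m in (1, 5, 20, 100)]
        assert adj == sorted(adj)
        assert all(a <= 1.0 for a in adj)

    def test_empty_family_rejected(self):
        with pytest.raises(InvalidInputError):
            bonferroni_adjust([])

    def test_injected_difference_ranks_first_vs_permutation_oracle(self):
        """A group difference injected at one date must carry the smallest
        adjusted p, and the exact permutation distribution must agree on
        the ranking."""
        rng = np.random.default_rng(11)
        g, n, t, hot = 2, 4, 5, 2
        rows = []
        for gi in range(g):
            for si in range(n):
                subj = f"g{gi}s{si}"
                offset = 0.3 * rng.standard_normal()
                for ti in range(t):
                    val = offset + 0.5 * rng.standard_normal()
                    if gi == 0 and ti == hot:
                        val += 6.0
                    rows.append(
                        {"subject": subj, "group": f"cv{gi}", "time": ti, "value": val}
                    )
        design = RMDesign(pd.DataFrame(rows))
        comps = pairwise_emmeans_bonferroni(design, family="group_within_time")
        by_time = {i: c for i, c in enumerate(comps)}
        assert min(by_time, key=lambda i: by_time[i].p_adjusted) == hot

        # exact permutation oracle over all 8-choose-4 group assignments
        cube = design.cube()  # (2, 4, 5)
        profiles = cube.reshape(8, t)
        observed = np.abs(profiles[:4].mean(axis=0) - profiles[4:].mean(axis=0))
        perm_ps = np.zeros(t)
        assignments = list(combinations(range(8), 4))
        for combo in assignments:
            sel = np.zeros(8, dtype=bool)
            sel[list(combo)] = True
            diff = np.abs(profiles[sel].mean(axis=0) - profiles[~sel].mean(axis=0))
            perm_ps += diff >= observed - 1e-12
        perm_ps /= len(assignments)
        assert int(np.argmin(perm_ps)) == hot

    def test_time_within_group_family(self):
        design = make_design(seed=13)
        comps = pairwise_emmeans_bonferroni(design, family="time_within_group")
        t, g = len(design.times), len(design.groups)
        assert len(comps) == g * t * (t - 1) // 2
        assert all(c.p_adjusted >= c.p_raw for c in comps)


class TestInfluence:
    def test_balanced_one_way_leverage_trace_identity(self):
        g, n = 3, 4
        x = np.kron(np.eye(g), np.ones((n, 1)))
        y = np.arange(g * n, dtype=float)
        diag = influence_diagnostics(x, y)
        assert np.allclose(diag["leverage"], 1.0 / n)
        assert diag["leverage"].sum() == pytest.approx(g)

    def test_duplicating_an_observation_reduces_its_leverage(self):
        rng = np.random.default_rng(3)
        x = np.column_stack([np.ones(8), rng.standard_normal(8)])
        y = rng.standard_normal(8)
        before = influence_diagnostics(x, y)["leverage"].iloc[0]
        x2 = np.vstack([x, x[0]])
        y2 = np.append(y, y[0])
        after = influence_diagnostics(x2, y2)["leverage"].iloc[0]
        assert after < before

    def test_cooks_distance_matches_loo_oracle(self):
        rng = np.random.default_rng(9)
        design = make_design(seed=9, group_shift=1.0)
        x, y = cell_means_design_matrix(design)
        y = y + 0.01 * rng.standard_normal(len(y))
        ours = influence_diagnostics(x, y)["cooks_distance"].to_numpy()
        oracle = cooks_distance_loo(x, y)
        assert np.allclose(ours, oracle, atol=1e-8)

    def test_rank_deficient_design_rejected(self):
        x = np.ones((6, 2))
        with pytest.raises(InvalidInputError):
            influence_diagnostics(x, np.arange(6.0))
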