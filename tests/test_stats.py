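"""Cohort statistics: Mann-Whitney, Spearman, delta-delta-Ct, summaries."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import ntquant as nq


def exact_mwu_oracle(x, y):
    """Enumerate all assignments of ranks to group x: U and two-sided p."""
    pooled = sorted(x + y)
    n1, n2 = len(x), len(y)
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    r1 = sum(ranks[v] for v in x)
    u1 = r1 - n1 * (n1 + 1) / 2
    u_obs = min(u1, n1 * n2 - u1)
    us = []
    for combo in combinations(range(1, n1 + n2 + 1), n1):
        r = sum(combo)
        u = r - n1 * (n1 + 1) / 2
        us.append(min(u, n1 * n2 - u))
    p = sum(1 for u in us if u <= u_obs) / len(us)
    return u1, min(p, 1.0)


class TestMannWhitney:
    def test_separated_pairs_exact_enumeration(self):
        # all of {1,2} below {3,4}: U=0; 2 of the 6 assignments are as extreme
        cmp = nq.mann_whitney_u([1, 2], [3, 4])
        assert cmp.u_statistic == 0.0
        assert cmp.p_value == pytest.approx(2 / 6, abs=1e-10)
        assert cmp.method == "exact"

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        st.lists(st.integers(0, 1000), min_size=2, max_size=6, unique=True),
        st.lists(st.integers(1001, 2000), min_size=2, max_size=6, unique=True),
    )
    def test_exact_path_matches_enumeration_oracle(self, x, y):
        cmp = nq.mann_whitney_u(x, y)
        u_oracle, p_oracle = exact_mwu_oracle(x, y)
        assert cmp.method == "exact"
        assert cmp.u_statistic == pytest.approx(u_oracle)
        assert cmp.p_value == pytest.approx(p_oracle, abs=1e-9)

    def test_swap_symmetry(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(0, 1, 12), rng.normal(0.5, 1, 15)
        a = nq.mann_whitney_u(x, y)
        b = nq.mann_whitney_u(y, x)
        assert a.u_statistic + b.u_statistic == pytest.approx(a.n_a * a.n_b)
        assert a.p_value == pytest.approx(b.p_value)

    def test_identical_large_samples_near_null_p(self):
        x = list(np.linspace(0, 1, 40))
        cmp = nq.mann_whitney_u(x, x)
        assert cmp.method == "normal_approx_tie_corrected"
        assert cmp.p_value > 0.9

    def test_ties_route_to_approximation(self):
        cmp = nq.mann_whitney_u([1, 2, 2], [2, 3, 4])
        assert cmp.method == "normal_approx_tie_corrected"

    def test_exact_vs_approx_agree_on_tie_free_n8(self):
        rng = np.random.default_rng(8)
        for _ in range(10):
            x = rng.normal(0, 1, 8)
            y = rng.normal(0.8, 1, 8)
            exact = nq.mann_whitney_u(x, y)
            assert exact.method == "exact"
            from scipy.stats import mannwhitneyu

            approx_p = mannwhitneyu(
                x, y, alternative="two-sided", method="asymptotic"
            ).pvalue
            assert abs(exact.p_value - approx_p) < 0.02

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            nq.mann_whitney_u([], [1.0])


class TestSpearman:
    def test_perfect_monotone(self):
        res = nq.spearman_correlation([1, 2, 3, 4], [10, 20, 30, 40])
        assert res.rs == pytest.approx(1.0)

    def test_antitone(self):
        res = nq.spearman_correlation([1, 2, 3, 4], [40, 30, 20, 10])
        assert res.rs == pytest.approx(-1.0)

    def test_five_point_closed_form(self):
        # d = (0,1,-1,1,-1), sum d^2 = 4 -> rs = 1 - 24/120 = 0.8
        res = nq.spearman_correlation([1, 2, 3, 4, 5], [2, 1, 4, 3, 5])
        assert res.rs == pytest.approx(0.8)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        st.lists(
            st.floats(min_value=-100, max_value=100, allow_nan=False),
            min_size=4,
            max_size=25,
            unique=True,
        )
    )
    def test_rank_formula_equivalence_on_tie_free_data(self, y):
        # mid-rank Pearson path equals 1 - 6*sum(d^2)/(n(n^2-1)) exactly
        x = list(range(len(y)))
        res = nq.spearman_correlation(x, y)
        rx = np.argsort(np.argsort(x)) + 1
        ry = np.argsort(np.argsort(y)) + 1
        n = len(y)
        d2 = float(((rx - ry) ** 2).sum())
        closed = 1 - 6 * d2 / (n * (n**2 - 1))
        assert res.rs == pytest.approx(closed, abs=1e-12)

    def test_matches_scipy(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=30)
        y = x + rng.normal(size=30)
        res = nq.spearman_correlation(x, y)
        from scipy.stats import spearmanr

        ref = spearmanr(x, y)
        assert res.rs == pytest.approx(ref.statistic)
        assert res.p_value == pytest.approx(ref.pvalue, rel=1e-6)

    def test_exact_permutation_small_n(self):
        res = nq.spearman_correlation([1, 2, 3, 4], [1, 2, 4, 3], exact=True)
        assert res.method == "exact_permutation"
        assert 0 < res.p_value <= 1

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            nq.spearman_correlation([1, 1, 1], [1, 2, 3])

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            nq.spearman_correlation([1, 2], [3, 4])


class TestDeltaDeltaCt:
    def make_table(self, rows):
        return pd.DataFrame(rows, columns=["sample_id", "group", "gene", "ct"])

    def test_worked_example_fold_change_four(self):
        # target 2 cycles lower than calibrator at equal reference -> FC 4
        table = self.make_table(
            [
                ("s1", "case", "OAS1", 25.0),
                ("s1", "case", "GAPDH", 20.0),
                ("c1", "ctrl", "OAS1", 27.0),
                ("c1", "ctrl", "GAPDH", 20.0),
            ]
        )
        rel = nq.delta_delta_ct(table, "GAPDH", "ctrl")
        s1 = rel[rel.sample_id == "s1"].iloc[0]
        assert s1.delta_delta_ct == pytest.approx(-2.0)
        assert s1.fold_change == pytest.approx(4.0)
        c1 = rel[rel.sample_id == "c1"].iloc[0]
        assert c1.fold_change == pytest.approx(1.0)

    def test_one_extra_cycle_halves_fold_change(self):
        table = self.make_table(
            [
                ("s1", "case", "OAS1", 25.0),
                ("s1", "case", "GAPDH", 20.0),
                ("s2", "case", "OAS1", 26.0),
                ("s2", "case", "GAPDH", 20.0),
                ("c1", "ctrl", "OAS1", 27.0),
                ("c1", "ctrl", "GAPDH", 20.0),
            ]
        )
        rel = nq.delta_delta_ct(table, "GAPDH", "ctrl").set_index("sample_id")
        assert rel.loc["s2", "fold_change"] == pytest.approx(
            rel.loc["s1", "fold_change"] / 2
        )

    def test_fold_change_identity_invariant(self):
        # fold_change = 2^(-ddCt) exactly, on simulated noisy data
        cfg = nq.QpcrSimConfig(
            genes=["MX1", "GAPDH"],
            reference_gene="GAPDH",
            true_fold_changes={"MX1": {"ctrl": 1.0, "case": 2.5}},
            n_samples_per_group={"ctrl": 5, "case": 5},
            ct_noise_sd=0.3,
            seed=4,
        )
        rel = nq.delta_delta_ct(nq.simulate_qpcr(cfg), "GAPDH", "ctrl")
        np.testing.assert_allclose(rel.fold_change, 2.0 ** (-rel.delta_delta_ct))

    def test_missing_reference_names_sample(self):
        table = self.make_table(
            [("s1", "case", "OAS1", 25.0), ("c1", "ctrl", "OAS1", 27.0),
             ("c1", "ctrl", "GAPDH", 20.0)]
        )
        with pytest.raises(ValueError, match="s1"):
            nq.delta_delta_ct(table, "GAPDH", "ctrl")

    def test_empty_calibrator_rejected(self):
        table = self.make_table(
            [("s1", "case", "OAS1", 25.0), ("s1", "case", "GAPDH", 20.0)]
        )
        with pytest.raises(ValueError, match="calibrator"):
            nq.delta_delta_ct(table, "GAPDH", "ctrl")


class TestSummaries:
    def test_identical_values_collapse_quartiles(self):
        df = pd.DataFrame({"group": ["a"] * 4, "v": [3.0] * 4})
        out = nq.summarize_groups(df, "v")
        assert out.iloc[0][["median", "q1", "q3"]].tolist() == [3.0, 3.0, 3.0]

    def test_interpolated_median(self):
        df = pd.DataFrame({"group": ["a"] * 4, "v": [1.0, 2.0, 3.0, 4.0]})
        assert nq.summarize_groups(df, "v").iloc[0]["median"] == pytest.approx(2.5)

    def test_against_sort_based_oracle(self):
        rng = np.random.default_rng(9)
        v = rng.normal(size=37)
        df = pd.DataFrame({"group": "g", "v": v})
        out = nq.summarize_groups(df, "v").iloc[0]
        assert out["q1"] == pytest.approx(np.quantile(np.sort(v), 0.25))
        assert out["q3"] == pytest.approx(np.quantile(np.sort(v), 0.75))
        assert out["n"] == 37

    def test_unknown_column_rejected(self):
        with pytest.raises(ValueError, match="unknown column"):
            nq.summarize_groups(pd.DataFrame({"group": ["a"]}), "nope")


class TestTTestsAndHolm:
    def test_t_variants_match_scipy(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(0, 1, 20), rng.normal(0.5, 2, 20)
        from scipy import stats as sps

        assert nq.t_test(x, y, "student").p_value == pytest.approx(
            sps.ttest_ind(x, y).pvalue
        )
        assert nq.t_test(x, y, "welch").p_value == pytest.approx(
            sps.ttest_ind(x, y, equal_var=False).pvalue
        )
        assert nq.t_test(x, y, "paired").p_value == pytest.approx(
            sps.ttest_rel(x, y).pvalue
        )

    def test_paired_requires_equal_lengths(self):
        with pytest.raises(ValueError):
            nq.t_test([1, 2, 3], [1, 2], "paired")

    def test_holm_adjustment_monotone_and_bounded(self):
        p = [0.01, 0.04, 0.03, 0.5]
        adj = nq.holm_adjust(p)
        assert (adj >= np.asarray(p)).all()
        assert (adj <= 1).all()
        # smallest raw p gets multiplied by the full test count
        assert adj[0] == pytest.approx(0.04)
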