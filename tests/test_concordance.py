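"""Concordance statistics, rank comparisons, Cq summaries and the DE filter."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from conftest import make_matrix
from ffpeqc import (
    ConcordanceConfig,
    CqTable,
    InvalidInputError,
    cq_summary,
    de_filter,
    delta_cq_rank,
    group_mean_concordance,
    ratio_pair_matches,
    replicate_ratio_concordance,
    top_n_rank_comparison,
)
from oracles import (
    concordance_oracle,
    group_mean_concordance_oracle,
    rank_bin_oracle,
    ttest_cohens_d_oracle,
)

ALL_CUTOFFS = (1.3, 1.5, 1.7, 2.0)


def frame(rows, n_cols, prefix="r"):
    arr = np.asarray(rows, dtype=float)
    return pd.DataFrame(
        arr, index=[f"g{i}" for i in range(arr.shape[0])],
        columns=[f"{prefix}{j}" for j in range(n_cols)],
    )


class TestRatioPairClassification:
    @pytest.mark.parametrize(
        "r1,r2,cutoff,expected",
        [
            (1.2, 1.4, 1.5, True),   # both within the band
            (0.8, 1.1, 1.5, True),   # both within, one below 1
            (2.5, 3.0, 1.5, True),   # both up
            (0.3, 0.5, 1.5, True),   # both down
            (2.5, 0.4, 1.5, False),  # opposite directions
            (1.2, 2.5, 1.5, False),  # one within, one beyond -> strict mismatch
            (0.4, 1.0, 1.5, False),  # one below band, one within
            (1.5, 1.5, 1.5, True),   # boundary counts as within (closed band)
            (1.0 / 1.5, 1.5, 1.5, True),
            (1.6, 3.0, 1.5, True),   # matches at 1.5 ...
            (1.6, 3.0, 2.0, False),  # ... but NOT at 2.0 (non-monotone in cutoff)
        ],
    )
    def test_condition_table(self, r1, r2, cutoff, expected):
        assert ratio_pair_matches(r1, r2, cutoff) is expected


class TestReplicateRatioConcordance:
    def test_identical_groups_are_fully_concordant_at_every_cutoff(self):
        rng = np.random.default_rng(0)
        a = frame(rng.uniform(1, 100, (20, 3)), 3)
        for c in ALL_CUTOFFS:
            res = replicate_ratio_concordance(a, a.copy(), ConcordanceConfig(cutoff=c))
            assert res.overall == pytest.approx(100.0)
            assert all(v == pytest.approx(100.0) for v in res.per_basis_rate.values())

    def test_hand_enumerated_concordant_gene(self):
        # basis 1: pairs (2.0, 3.0) both up and (1.0, 1.0) both within at c=1.5
        a = frame([[10.0, 20.0, 10.0]], 3)
        b = frame([[3.0, 9.0, 3.0]], 3)
        res = replicate_ratio_concordance(a, b, ConcordanceConfig(cutoff=1.5))
        assert bool(res.gene_flags.loc["g0", 1]) is True

    def test_hand_enumerated_discordant_gene(self):
        # basis 1: pair (2.0, 0.333) has opposite directions at c=1.5
        a = frame([[10.0, 20.0, 10.0]], 3)
        b = frame([[9.0, 3.0, 9.0]], 3)
        res = replicate_ratio_concordance(a, b, ConcordanceConfig(cutoff=1.5))
        assert bool(res.gene_flags.loc["g0", 1]) is False

    def test_overall_is_mean_over_bases(self):
        rng = np.random.default_rng(1)
        a = frame(np.exp(rng.normal(3, 1, (30, 3))), 3)
        b = frame(np.exp(rng.normal(3, 1, (30, 3))), 3)
        res = replicate_ratio_concordance(a, b, ConcordanceConfig(cutoff=1.5))
        assert res.overall == pytest.approx(np.mean(list(res.per_basis_rate.values())))

    @pytest.mark.parametrize("cutoff", ALL_CUTOFFS)
    def test_matches_exhaustive_enumeration_oracle(self, cutoff):
        rng = np.random.default_rng(int(cutoff * 10))
        a = frame(np.exp(rng.normal(3, 0.6, (5, 3))), 3)
        b = frame(np.exp(rng.normal(3, 0.6, (5, 3))), 3)
        res = replicate_ratio_concordance(a, b, ConcordanceConfig(cutoff=cutoff))
        expected = concordance_oracle(a, b, cutoff)
        assert res.per_basis_rate == pytest.approx(expected)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        scale=st.floats(min_value=1e-3, max_value=1e3),
        seed=st.integers(min_value=0, max_value=9999),
    )
    def test_invariant_under_scaling_one_group(self, scale, seed):
        rng = np.random.default_rng(seed)
        a = frame(np.exp(rng.normal(3, 1, (10, 3))), 3)
        b = frame(np.exp(rng.normal(3, 1, (10, 3))), 3)
        cfg = ConcordanceConfig(cutoff=1.5)
        base = replicate_ratio_concordance(a, b, cfg)
        scaled = replicate_ratio_concordance(a * scale, b, cfg)
        assert scaled.per_basis_rate == pytest.approx(base.per_basis_rate)

    def test_per_pair_aggregation_at_least_as_high_as_strict(self):
        rng = np.random.default_rng(2)
        a = frame(np.exp(rng.normal(3, 1, (50, 3))), 3)
        b = frame(np.exp(rng.normal(3, 1, (50, 3))), 3)
        strict = replicate_ratio_concordance(a, b, ConcordanceConfig(1.5, "all"))
        loose = replicate_ratio_concordance(a, b, ConcordanceConfig(1.5, "per_pair"))
        assert loose.overall >= strict.overall - 1e-9

    def test_unequal_replicate_counts_rejected(self):
        a = frame(np.ones((3, 3)), 3)
        b = frame(np.ones((3, 2)), 2)
        with pytest.raises(InvalidInputError):
            replicate_ratio_concordance(a, b, ConcordanceConfig(1.5))

    def test_nonpositive_values_rejected(self):
        a = frame([[1.0, 2.0, 0.0]], 3)
        b = frame([[1.0, 2.0, 3.0]], 3)
        with pytest.raises(InvalidInputError):
            replicate_ratio_concordance(a, b, ConcordanceConfig(1.5))


class TestGroupMeanConcordance:
    def build(self, ratios1, ratios2):
        """Construct case/control slices with the desired mean ratios."""
        n = len(ratios1)
        control = np.ones((n, 2))
        case1 = np.outer(ratios1, np.ones(2))
        case2 = np.outer(ratios2, np.ones(2))
        return (
            frame(case1, 2), frame(control, 2), frame(case2, 2), frame(control, 2)
        )

    @pytest.mark.parametrize(
        "r1,r2,expected",
        [
            (1.2, 1.4, 100.0),  # both within at 1.5
            (2.5, 3.0, 100.0),  # both up
            (2.5, 0.4, 0.0),    # opposite directions
        ],
    )
    def test_condition_table(self, r1, r2, expected):
        res = group_mean_concordance(*self.build([r1], [r2]), ConcordanceConfig(1.5))
        assert res.overall == pytest.approx(expected)

    def test_matches_enumeration_oracle_on_random_ratios(self):
        rng = np.random.default_rng(3)
        n = 40
        r1 = np.exp(rng.normal(0, 0.8, n))
        r2 = np.exp(rng.normal(0, 0.8, n))
        res = group_mean_concordance(*self.build(r1, r2), ConcordanceConfig(1.5))
        expected = group_mean_concordance_oracle(r1, np.ones(n), r2, np.ones(n), 1.5)
        assert res.overall == pytest.approx(expected)

    def test_intersects_gene_sets(self):
        c1 = frame(np.ones((4, 2)), 2)
        o1 = frame(np.ones((4, 2)), 2)
        c2 = frame(np.ones((3, 2)), 2)  # g0..g2 only
        o2 = frame(np.ones((3, 2)), 2)
        res = group_mean_concordance(c1, o1, c2, o2, ConcordanceConfig(1.5))
        assert res.gene_flags.shape[0] == 3

    def test_empty_intersection_rejected(self):
        c1 = frame(np.ones((2, 2)), 2)
        c2 = frame(np.ones((2, 2)), 2)
        c2.index = ["h0", "h1"]
        with pytest.raises(InvalidInputError):
            group_mean_concordance(c1, c1, c2, c2, ConcordanceConfig(1.5))


class TestTopNRankComparison:
    def test_identical_means_are_fully_within_top_n(self):
        rng = np.random.default_rng(4)
        means = pd.Series(rng.uniform(1, 100, 50), index=[f"g{i}" for i in range(50)])
        res = top_n_rank_comparison(means, means.copy(), n_top=10, bin_edges=(5,))
        assert (res.table["abs_rank_diff"] == 0).all()
        assert res.bins["within_top_n"] == 10
        assert sum(res.bins.values()) == 10

    def test_adjacent_swap_shifts_exactly_two_ranks_by_one(self):
        means = pd.Series(
            np.arange(50, 0, -1, dtype=float), index=[f"g{i:02d}" for i in range(50)]
        )
        swapped = means.copy()
        swapped.iloc[[2, 3]] = swapped.iloc[[3, 2]].to_numpy()
        res = top_n_rank_comparison(means, swapped, n_top=10, bin_edges=(5,))
        diffs = res.table["abs_rank_diff"]
        assert sorted(diffs[diffs > 0].tolist()) == [1, 1]
        assert res.bins["within_top_n"] == 10

    def test_bin_counts_match_brute_force_recount(self):
        rng = np.random.default_rng(5)
        genes = [f"g{i:04d}" for i in range(1000)]
        means_a = pd.Series(rng.uniform(1, 1000, 1000), index=genes)
        means_b = pd.Series(rng.permutation(means_a.to_numpy()), index=genes)
        edges = (100, 400)
        res = top_n_rank_comparison(means_a, means_b, n_top=100, bin_edges=edges)
        assert res.bins == rank_bin_oracle(means_a, means_b, 100, edges)
        assert sum(res.bins.values()) == 100

    def test_n_larger_than_universe_rejected(self):
        means = pd.Series([1.0, 2.0], index=["g0", "g1"])
        with pytest.raises(InvalidInputError):
            top_n_rank_comparison(means, means, n_top=5)

    def test_ties_broken_lexicographically(self):
        means = pd.Series([5.0, 5.0, 1.0], index=["b", "a", "c"])
        res = top_n_rank_comparison(means, means, n_top=2, bin_edges=(1,))
        assert list(res.table.index) == ["a", "b"]


class TestCqOperations:
    @staticmethod
    def cq(values, ref="Gapdh"):
        df = pd.DataFrame.from_dict(values, orient="index").astype(float)
        df.index.name = "gene_id"
        return CqTable(values=df, reference_gene=ref)

    def test_geometric_mean_of_four_and_sixteen_is_eight(self):
        t = self.cq({"Gapdh": [4.0, 16.0]})
        assert cq_summary(t)["geo_mean_cq"].loc["Gapdh"] == pytest.approx(8.0)

    def test_single_replicate_mean_with_undefined_sd(self):
        t = self.cq({"Gapdh": [20.0]})
        row = cq_summary(t).loc["Gapdh"]
        assert row["geo_mean_cq"] == pytest.approx(20.0)
        assert np.isnan(row["sd_cq"])

    def test_geometric_mean_matches_exp_mean_log_oracle(self):
        vals = np.array([18.1, 18.3, 18.5])
        t = self.cq({"Gapdh": vals})
        summ = cq_summary(t)
        assert summ["geo_mean_cq"].loc["Gapdh"] == pytest.approx(
            np.exp(np.log(vals).mean()), rel=1e-12
        )
        assert summ["sd_cq"].loc["Gapdh"] == pytest.approx(vals.std(ddof=1), rel=1e-12)

    def test_delta_cq_zero_for_gene_equal_to_reference(self):
        t = self.cq({"Gapdh": [20.0, 20.0], "Pgk1": [20.0, 20.0]})
        assert delta_cq_rank(t).loc["Pgk1", "delta_cq"] == pytest.approx(0.0)

    def test_delta_cq_negative_for_less_abundant_gene(self):
        t = self.cq({"Gapdh": [20.0], "Gfap": [25.0]})
        assert delta_cq_rank(t).loc["Gfap", "delta_cq"] == pytest.approx(-5.0)

    def test_ranks_sorted_descending_by_delta_cq(self):
        gene_cq = {"a": 25.0, "b": 18.0, "c": 22.0, "d": 30.0, "e": 19.0}
        t = self.cq({"Gapdh": [20.0], **{g: [v] for g, v in gene_cq.items()}})
        res = delta_cq_rank(t)
        deltas = {g: 20.0 - v for g, v in gene_cq.items()}
        expected_order = sorted(deltas, key=lambda g: (-deltas[g], g))
        assert list(res.index) == expected_order
        assert res["rank"].tolist() == [1, 2, 3, 4, 5]

    def test_missing_reference_rejected(self):
        df = pd.DataFrame({"rep_1": [20.0]}, index=["Pgk1"])
        with pytest.raises(InvalidInputError):
            CqTable(values=df, reference_gene="Gapdh")

    def test_nonpositive_cq_rejected(self):
        df = pd.DataFrame({"rep_1": [0.0]}, index=["Gapdh"])
        with pytest.raises(InvalidInputError):
            CqTable(values=df, reference_gene="Gapdh")


class TestDeFilter:
    @staticmethod
    def matrix(case_rows, control_rows):
        case = np.asarray(case_rows, float)
        ctrl = np.asarray(control_rows, float)
        vals = np.hstack([case, ctrl])
        groups = {f"c{j}": "case" for j in range(case.shape[1])}
        groups.update({f"k{j}": "control" for j in range(ctrl.shape[1])})
        return make_matrix(vals, groups, scale="log2")

    def test_identical_groups_select_nothing(self):
        rng = np.random.default_rng(6)
        vals = rng.normal(8, 1, (20, 3))
        res = de_filter(self.matrix(vals, vals), "case", "control")
        assert not res["selected"].any()

    def test_fourfold_change_with_small_noise_selected(self):
        m = self.matrix([[5.0, 5.1, 4.9]], [[3.0, 3.1, 2.9]])
        res = de_filter(m, "case", "control")
        row = res.iloc[0]
        assert row["fold_change"] == pytest.approx(4.0, rel=1e-6)
        assert row["p"] < 0.05 and bool(row["selected"])
        # cross-check t statistic with the textbook oracle
        t_exp, _ = ttest_cohens_d_oracle(
            np.array([5.0, 5.1, 4.9]), np.array([3.0, 3.1, 2.9])
        )
        assert row["t"] == pytest.approx(t_exp, rel=1e-10)

    def test_small_fold_change_fails_gate_despite_significance(self):
        rng = np.random.default_rng(7)
        shift = np.log2(1.5)
        ctrl = 8.0 + rng.normal(0, 0.01, (1, 10))
        case = ctrl + shift
        res = de_filter(self.matrix(case, ctrl), "case", "control")
        assert res.iloc[0]["p"] < 0.001
        assert not bool(res.iloc[0]["selected"])

    def test_downregulation_encoded_as_negative_reciprocal(self):
        m = self.matrix([[3.0, 3.1, 2.9]], [[5.0, 5.1, 4.9]])
        res = de_filter(m, "case", "control")
        assert res.iloc[0]["fold_change"] == pytest.approx(-4.0, rel=1e-6)
        assert bool(res.iloc[0]["selected"])

    def test_zero_variance_in_both_groups_flagged_degenerate(self):
        m = self.matrix([[5.0, 5.0, 5.0]], [[3.0, 3.0, 3.0]])
        res = de_filter(m, "case", "control")
        assert bool(res.iloc[0]["degenerate"])
        assert not bool(res.iloc[0]["selected"])

    def test_p_values_match_scipy_on_random_data(self):
        rng = np.random.default_rng(8)
        case = rng.normal(8, 1, (30, 3))
        ctrl = rng.normal(8, 1, (30, 3))
        res = de_filter(self.matrix(case, ctrl), "case", "control")
        for i in range(30):
            t, p = stats.ttest_ind(case[i], ctrl[i], equal_var=True)
            assert res.loc[f"g{i}", "p"] == pytest.approx(p, rel=1e-10)
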