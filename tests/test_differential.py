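import numpy as np
import pandas as pd
import pytest
from hypothesis import assume, given
from hypothesis import strategies as st

import oracle_utils as oracle
from nucleofoot import (
    AnalysisThresholds,
    average_linkage_order,
    benjamini_hochberg,
    call_differential,
    log_fold_change,
    wilcoxon_rank_sum,
)
from nucleofoot.differential import classify_call
from nucleofoot.errors import ParameterError, ValidationError


class TestWilcoxon:
    def test_exact_separated_triples(self):
        assert wilcoxon_rank_sum([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)

    def test_all_tied_no_rank_information(self):
        assert wilcoxon_rank_sum([5, 5], [5, 5]) == 1.0

    def test_small_groups_rejected(self):
        with pytest.raises(ParameterError):
            wilcoxon_rank_sum([1], [2, 3])

    def test_exact_matches_enumeration_oracle(self, rng):
        for _ in range(5):
            x = rng.permutation(np.arange(20.0))[:4]
            pool = set(range(40)) - set(x.astype(int))
            y = rng.choice(sorted(pool), 5, replace=False).astype(float) + 0.5
            assert wilcoxon_rank_sum(x, y) == pytest.approx(
                oracle.exact_wilcoxon_p(x, y))

    def test_approximation_close_to_exact_at_12v12(self, rng):
        vals = rng.permutation(np.arange(24.0) + rng.random(24))
        x, y = vals[:12], vals[12:]
        approx = wilcoxon_rank_sum(x, y)
        exact = oracle.exact_wilcoxon_p_dp(x, y)
        assert abs(approx - exact) < 0.02

    @given(st.lists(st.floats(-100, 100, allow_nan=False), min_size=2, max_size=8),
           st.lists(st.floats(-100, 100, allow_nan=False), min_size=2, max_size=8))
    def test_invariant_under_monotone_transform(self, x, y):
        f = lambda v: np.exp(np.asarray(v) / 50.0)  # strictly increasing
        pooled = np.concatenate([x, y])
        # transform must stay faithful in float arithmetic (no new ties)
        assume(len(np.unique(f(pooled))) == len(np.unique(pooled)))
        p1 = wilcoxon_rank_sum(x, y)
        p2 = wilcoxon_rank_sum(f(x), f(y))
        assert p1 == pytest.approx(p2)


class TestFoldChange:
    def test_basic_ratio(self):
        fc, lfc = log_fold_change([3, 3], [1.5, 1.5], pseudocount=0)
        assert fc == pytest.approx(2.0) and lfc == pytest.approx(1.0)

    def test_equal_means_identity(self):
        fc, lfc = log_fold_change([2, 4], [3, 3], pseudocount=0)
        assert fc == pytest.approx(1.0) and lfc == pytest.approx(0.0)

    def test_zero_denominator_guarded_by_pseudocount(self):
        with pytest.raises(ParameterError):
            log_fold_change([1.0, 2.0], [0.0, 0.0], pseudocount=0)
        fc, _ = log_fold_change([1.0, 2.0], [0.0, 0.0], pseudocount=0.01)
        assert np.isfinite(fc)


class TestBenjaminiHochberg:
    def test_textbook_stepup(self):
        q = benjamini_hochberg([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(benjamini_hochberg([0.3]), [0.3])

    def test_matches_stepup_oracle(self, rng):
        p = rng.random(100)
        np.testing.assert_allclose(benjamini_hochberg(p), oracle.bh_stepup(p))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            benjamini_hochberg([0.5, 1.2])


class TestCallRule:
    thresholds = AnalysisThresholds(p_max=0.01, fc_min=1.5)

    @pytest.mark.parametrize("p,fc,expected", [
        (0.005, 1.6, "up_in_a"),
        (0.005, 1.4, "ns"),
        (0.02, 3.0, "ns"),
        (0.005, 1.0 / 1.6, "down_in_a"),
    ])
    def test_p_and_fold_change_thresholds(self, p, fc, expected):
        assert classify_call(p, fc, None, self.thresholds) == expected

    def test_fdr_criterion_applies_only_when_set(self):
        with_fdr = AnalysisThresholds(p_max=0.01, fc_min=1.2, fdr_max=0.1)
        assert classify_call(0.005, 2.0, 0.2, with_fdr) == "ns"
        assert classify_call(0.005, 2.0, 0.05, with_fdr) == "up_in_a"


def two_group_matrix(rng, n_tss=30, n_a=6, n_b=6, shifted=()):
    vals = rng.gamma(5.0, 2.0, size=(n_tss, n_a + n_b))
    for i in shifted:
        vals[i, :n_a] *= 4.0
    cols = [f"A{i}" for i in range(n_a)] + [f"B{i}" for i in range(n_b)]
    df = pd.DataFrame(vals, index=[f"T{i}" for i in range(n_tss)], columns=cols)
    labels = {c: ("a" if c.startswith("A") else "b") for c in cols}
    return df, labels


class TestCallDifferential:
    def test_planted_shift_called_up_in_a(self, rng):
        df, labels = two_group_matrix(rng, shifted=(0, 1))
        table = call_differential(df, labels, AnalysisThresholds(p_max=0.01,
                                                                fc_min=1.5))
        assert table.loc["T0", "call"] == "up_in_a"
        assert table.loc["T1", "call"] == "up_in_a"

    def test_group_swap_mirrors_calls(self, rng):
        df, labels = two_group_matrix(rng, shifted=(0,))
        thr = AnalysisThresholds(p_max=0.05, fc_min=1.2)
        fwd = call_differential(df, labels, thr, group_a="a", group_b="b")
        rev = call_differential(df, labels, thr, group_a="b", group_b="a")
        flip = {"up_in_a": "down_in_a", "down_in_a": "up_in_a", "ns": "ns"}
        assert list(rev["call"]) == [flip[c] for c in fwd["call"]]
        np.testing.assert_allclose(rev["fold_change"], 1.0 / fwd["fold_change"])
        np.testing.assert_allclose(rev["p_value"], fwd["p_value"])

    def test_unknown_sample_in_labels_rejected(self, rng):
        df, labels = two_group_matrix(rng)
        labels["GHOST"] = "a"
        with pytest.raises(ValidationError, match="unknown"):
            call_differential(df, labels, AnalysisThresholds())

    def test_single_sample_group_rejected(self, rng):
        df, labels = two_group_matrix(rng, n_b=2)
        labels = {k: v for k, v in labels.items() if k != "B1"}
        df = df.drop(columns="B1")
        with pytest.raises(ParameterError):
            call_differential(df, labels, AnalysisThresholds())

    def test_fdr_column_filled_only_when_requested(self, rng):
        df, labels = two_group_matrix(rng)
        no_fdr = call_differential(df, labels, AnalysisThresholds())
        assert no_fdr["fdr_q"].isna().all()
        with_fdr = call_differential(
            df, labels, AnalysisThresholds(fc_min=1.2, fdr_max=0.1))
        np.testing.assert_allclose(
            with_fdr["fdr_q"], oracle.bh_stepup(with_fdr["p_value"].to_numpy()))


class TestAverageLinkage:
    def test_identical_columns_merge_first(self, rng):
        df = pd.DataFrame(rng.random((10, 4)),
                          columns=["S1", "S2", "S3", "S4"])
        df["S3"] = df["S1"]
        order, Z = average_linkage_order(df, axis="columns")
        first = {int(Z[0, 0]), int(Z[0, 1])}
        assert first == {0, 2} and Z[0, 2] == pytest.approx(0.0)

    def test_hand_computed_upgma_heights(self):
        df = pd.DataFrame({"v": [0.0, 1.0, 10.0]}, index=["a", "b", "c"])
        order, Z = average_linkage_order(df, axis="rows", standardize=False)
        assert Z[0, 2] == pytest.approx(1.0)
        assert Z[1, 2] == pytest.approx(9.5)
        assert {int(Z[0, 0]), int(Z[0, 1])} == {0, 1}

    def test_matches_bruteforce_upgma_on_random_points(self, rng):
        pts = rng.random((6, 3)) * 10
        df = pd.DataFrame(pts, index=[f"P{i}" for i in range(6)])
        _, Z = average_linkage_order(df, axis="rows", standardize=False)
        expected = oracle.upgma_reference(list(pts))
        # reconstruct leaf membership of each scipy merge
        members = {i: frozenset([i]) for i in range(6)}
        for step, (i, j, h, _) in enumerate(Z):
            new = members[int(i)] | members[int(j)]
            members[6 + step] = new
            exp_members, exp_h = expected[step]
            assert new == exp_members
            assert h == pytest.approx(exp_h)

    def test_constant_row_standardization_guard(self, rng):
        df = pd.DataFrame(rng.random((4, 5)), index=list("abcd"))
        df.loc["a"] = 3.14  # zero variance
        order, _ = average_linkage_order(df, axis="rows")
        assert set(order) == set("abcd")

    def test_single_item_rejected(self):
        df = pd.DataFrame({"x": [1.0]}, index=["only"])
        with pytest.raises(ParameterError):
            average_linkage_order(df, axis="rows")
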