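"""Two-group differential diversity: centrals, tests, FDR, assembly."""

import math

import numpy as np
import pandas as pd
import pytest

import splicediversity as sd
from splicediversity import DifferentialConfig, SampleGroups, SpliceDiversityError
from splicediversity.differential import bh_adjust

from oracles import o_bh, o_mwu_exact_pvalue, o_perm_pvalue


def series(groups, v1, v2):
    lab1, lab2 = groups.labels
    idx = groups.samples_in(lab1) + groups.samples_in(lab2)
    return pd.Series(list(v1) + list(v2), index=idx)


class TestCentralDifference:
    def test_identical_groups_zero_difference(self, two_groups):
        vals = series(two_groups, [0.5, 0.5, 0.5], [0.5, 0.5, 0.5])
        assert sd.group_central_difference(vals, two_groups, "mean") == (0.5, 0.5, 0.0)

    def test_mean_difference(self):
        groups = SampleGroups(
            assignment=pd.Series(["A", "A", "B", "B"], index=["a1", "a2", "b1", "b2"])
        )
        vals = pd.Series([0.2, 0.4, 0.7, 0.9], index=["a1", "a2", "b1", "b2"])
        c1, c2, diff = sd.group_central_difference(vals, groups, "mean")
        assert (c1, c2, diff) == (pytest.approx(0.3), pytest.approx(0.8), pytest.approx(0.5))

    def test_median_robust_to_outlier(self, two_groups):
        vals = series(two_groups, [0.1, 0.1, 0.9], [0.1, 0.1, 0.1])
        _, _, diff = sd.group_central_difference(vals, two_groups, "median")
        assert diff == 0.0

    def test_empty_group_returns_nan(self, two_groups):
        vals = series(two_groups, [np.nan] * 3, [0.5, 0.5, 0.5])
        out = sd.group_central_difference(vals, two_groups, "mean")
        assert all(math.isnan(v) for v in out)


class TestLog2FoldChange:
    @pytest.mark.parametrize(
        "c1,c2,expected", [(1.0, 2.0, 1.0), (2.0, 1.0, -1.0), (0.5, 0.5, 0.0)]
    )
    def test_values(self, c1, c2, expected):
        assert sd.log2_fold_change(c1, c2) == pytest.approx(expected)

    @pytest.mark.parametrize("c1,c2", [(0.0, 0.5), (0.5, 0.0), (np.nan, 1.0), (-1.0, 2.0)])
    def test_undefined_ratio_is_nan(self, c1, c2):
        assert math.isnan(sd.log2_fold_change(c1, c2))


class TestWilcoxon:
    def test_identical_groups_p_one(self):
        assert sd.wilcoxon_rank_sum([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)
        assert sd.wilcoxon_rank_sum([2, 2], [2, 2, 2]) == 1.0

    def test_complete_separation_three_vs_three(self):
        assert sd.wilcoxon_rank_sum([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)

    def test_matches_exhaustive_enumeration_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(25):
            n1 = int(rng.integers(2, 5))
            n2 = int(rng.integers(2, 5))
            pooled = rng.permutation(np.arange(1.0, n1 + n2 + 1))  # tie-free
            a, b = pooled[:n1], pooled[n1:]
            assert sd.wilcoxon_rank_sum(a, b) == pytest.approx(
                o_mwu_exact_pvalue(list(a), list(b)), abs=1e-12
            )


class TestLabelShuffling:
    def test_all_values_equal_p_one(self, two_groups):
        vals = series(two_groups, [0.3] * 3, [0.3] * 3)
        assert sd.label_shuffling_test(vals, two_groups, exhaustive=True) == 1.0

    def test_complete_separation_exhaustive(self, two_groups):
        vals = series(two_groups, [0.1, 0.2, 0.3], [0.7, 0.8, 0.9])
        p = sd.label_shuffling_test(vals, two_groups, exhaustive=True)
        assert p == pytest.approx(2 / 20)

    def test_small_designs_fall_back_to_enumeration_automatically(self):
        groups = SampleGroups(
            assignment=pd.Series(["A", "A", "B", "B"], index=list("abcd"))
        )
        vals = pd.Series([0.1, 0.2, 0.8, 0.9], index=list("abcd"))
        # C(4,2)=6 < 20 distinct assignments -> exhaustive result even
        # without asking for it
        assert sd.label_shuffling_test(vals, groups) == pytest.approx(2 / 6)

    def test_seed_determinism_and_monte_carlo_consistency(self, two_groups):
        rng = np.random.default_rng(3)
        vals = series(two_groups, rng.normal(0, 1, 3), rng.normal(1, 1, 3))
        exact = sd.label_shuffling_test(vals, two_groups, exhaustive=True)
        p1 = sd.label_shuffling_test(vals, two_groups, n_permutations=4000, seed=11,
                                     exhaustive=False)
        p2 = sd.label_shuffling_test(vals, two_groups, n_permutations=4000, seed=11,
                                     exhaustive=False)
        p3 = sd.label_shuffling_test(vals, two_groups, n_permutations=4000, seed=12,
                                     exhaustive=False)
        assert p1 == p2
        assert abs(p1 - exact) < 0.05
        assert abs(p3 - exact) < 0.05

    def test_exhaustive_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(7)
        for _ in range(30):
            n1 = int(rng.integers(2, 6))
            n2 = int(rng.integers(2, 6))
            v1 = rng.normal(size=n1).round(2)
            v2 = rng.normal(size=n2).round(2)
            groups = SampleGroups(
                assignment=pd.Series(
                    ["A"] * n1 + ["B"] * n2,
                    index=[f"s{i}" for i in range(n1 + n2)],
                )
            )
            vals = pd.Series(np.concatenate([v1, v2]),
                             index=[f"s{i}" for i in range(n1 + n2)])
            for central in ("mean", "median"):
                mine = sd.label_shuffling_test(vals, groups, central=central,
                                               exhaustive=True)
                assert mine == pytest.approx(
                    o_perm_pvalue(list(v1), list(v2), central), abs=1e-12
                )


class TestBH:
    def test_single_and_stepup_examples(self):
        assert bh_adjust([0.03]).tolist() == [0.03]
        out = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(out, [0.04, 0.04, 0.04, 0.04])

    def test_matches_independent_stepup_on_random_vectors(self):
        rng = np.random.default_rng(17)
        for _ in range(200):
            p = rng.random(int(rng.integers(1, 40)))
            assert np.allclose(bh_adjust(p), o_bh(list(p)), atol=1e-12)

    def test_nan_preserved_and_not_counted(self):
        out = bh_adjust([0.01, np.nan, 0.04])
        assert math.isnan(out[1])
        # m = 2 non-NA tests, not 3
        assert np.allclose(out[[0, 2]], o_bh([0.01, 0.04]))

    def test_adjusted_never_below_raw(self):
        rng = np.random.default_rng(23)
        p = rng.random(100)
        assert np.all(bh_adjust(p) >= p - 1e-15)

    def test_out_of_range_rejected(self):
        with pytest.raises(SpliceDiversityError):
            bh_adjust([0.5, 1.2])


class TestCalculateDifference:
    def _matrix(self, data, samples):
        values = pd.DataFrame(data, columns=samples)
        values.index = pd.Index([f"g{i}" for i in range(len(values))], name="gene_id")
        return sd.DiversityMatrix(values=values, metric="naive", normalized=True)

    def test_insufficient_samples_excluded_with_reason(self, two_groups):
        samples = ["a1", "a2", "a3", "b1", "b2", "b3"]
        div = self._matrix([[0.5, np.nan, np.nan, 0.4, 0.5, 0.6]], samples)
        out = sd.calculate_difference(div, two_groups)
        row = out.iloc[0]
        assert row["excluded_reason"] == "insufficient_samples"
        assert math.isnan(row["p_value"]) and math.isnan(row["adjusted_p"])
        assert not row["significant"]

    def test_difference_equals_centrals(self, two_groups):
        samples = ["a1", "a2", "a3", "b1", "b2", "b3"]
        div = self._matrix(
            [[0.2, 0.3, 0.4, 0.6, 0.7, 0.8], [0.5, 0.5, 0.5, 0.5, 0.5, 0.5]], samples
        )
        out = sd.calculate_difference(div, two_groups)
        assert out["difference"].iloc[0] == pytest.approx(
            out["central_2"].iloc[0] - out["central_1"].iloc[0]
        )
        assert out["difference"].iloc[1] == 0.0

    def test_label_swap_negates_effects_keeps_pvalues(self, two_groups):
        rng = np.random.default_rng(31)
        samples = ["a1", "a2", "a3", "b1", "b2", "b3"]
        div = self._matrix(rng.uniform(0.1, 0.9, size=(20, 6)), samples)
        fwd = sd.calculate_difference(div, two_groups)
        swapped = SampleGroups(assignment=two_groups.assignment, reference="B")
        rev = sd.calculate_difference(div, swapped)
        assert np.allclose(fwd["difference"], -rev["difference"])
        assert np.allclose(
            fwd["log2_fold_change"], -rev["log2_fold_change"], equal_nan=True
        )
        assert np.allclose(fwd["p_value"], rev["p_value"])

    def test_shuffle_test_route(self, two_groups):
        samples = ["a1", "a2", "a3", "b1", "b2", "b3"]
        div = self._matrix([[0.1, 0.2, 0.3, 0.7, 0.8, 0.9]], samples)
        config = DifferentialConfig(test="shuffle", n_permutations=2000, seed=4)
        out = sd.calculate_difference(div, two_groups, config)
        # exact permutation p is 2/20; Monte Carlo should land close
        assert abs(out["p_value"].iloc[0] - 0.1) < 0.04

    def test_samples_missing_from_groups_rejected(self, two_groups):
        div = self._matrix([[0.1, 0.2]], ["a1", "zz"])
        with pytest.raises(SpliceDiversityError, match="zz"):
            sd.calculate_difference(div, two_groups)

    def test_significance_rule(self, two_groups):
        samples = ["a1", "a2", "a3", "b1", "b2", "b3"]
        # complete separation, |diff| = 0.6 > 0.1, exact p = 0.1 -> NOT
        # significant at adjusted p < 0.05; with relaxed threshold it is
        div = self._matrix([[0.1, 0.15, 0.2, 0.7, 0.75, 0.8]], samples)
        strict = sd.calculate_difference(div, two_groups)
        assert not strict["significant"].iloc[0]
        relaxed = sd.calculate_difference(
            div, two_groups, DifferentialConfig(adj_p_threshold=0.2)
        )
        assert relaxed["significant"].iloc[0]


def test_type_one_error_near_nominal_under_null():
    """Both tests hold their size: i.i.d. groups give ~5% raw p < 0.05."""
    rng = np.random.default_rng(8)
    n_genes, n = 400, 8
    samples = [f"a{i}" for i in range(n)] + [f"b{i}" for i in range(n)]
    groups = SampleGroups(
        assignment=pd.Series(["A"] * n + ["B"] * n, index=samples)
    )
    values = pd.DataFrame(
        rng.uniform(0, 1, size=(n_genes, 2 * n)), columns=samples,
        index=pd.Index([f"g{i}" for i in range(n_genes)], name="gene_id"),
    )
    div = sd.DiversityMatrix(values=values, metric="naive", normalized=True)
    out = sd.calculate_difference(div, groups)
    frac = (out["p_value"] < 0.05).mean()
    assert 0.02 < frac < 0.08
    assert out["significant"].sum() <= n_genes * 0.01
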