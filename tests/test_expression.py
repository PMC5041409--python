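"""TPM normalisation, top-N profiling, clustering, and the tag-count test."""

import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest

from pirnakit.expression import (
    de_table,
    hierarchical_cluster,
    poisson_de,
    top_n_union,
    tpm_matrix,
)
from pirnakit.synthetic import simulate_de_counts, simulate_profile_groups


def exact_two_sided_p(x, y, total_a, total_b):
    """Exact-rational tail sum of the conditional binomial test."""
    n = x + y
    if n == 0:
        return 1.0
    p = Fraction(total_a, total_a + total_b)
    q = 1 - p

    def pmf(k):
        return Fraction(math.comb(n, k)) * p**k * q**(n - k)

    lower = sum(pmf(k) for k in range(0, x + 1))
    upper = sum(pmf(k) for k in range(x, n + 1))
    return float(min(1, 2 * min(lower, upper)))


class TestTpm:
    def test_count_over_total_arithmetic(self):
        counts = pd.DataFrame({"E": [7]}, index=["t1"])
        mat = tpm_matrix(counts, {"E": 7_000_000})
        assert mat.loc["t1", "E"] == pytest.approx(1.0)

    def test_all_zero_row_retained(self):
        counts = pd.DataFrame({"E": [0, 5]}, index=["t1", "t2"])
        mat = tpm_matrix(counts, {"E": 100})
        assert mat.loc["t1", "E"] == 0.0

    def test_column_sums_normalise_to_one_million(self):
        rng = np.random.default_rng(0)
        counts = pd.DataFrame(
            {"E": rng.integers(0, 100, 500), "L": rng.integers(0, 100, 500)}
        )
        totals = {c: int(counts[c].sum()) for c in counts}
        mat = tpm_matrix(counts, totals)
        assert np.allclose(mat.sum(axis=0), 1e6, rtol=1e-9)

    def test_zero_total_library_excluded(self):
        counts = pd.DataFrame({"E": [5], "L": [0]})
        mat = tpm_matrix(counts, {"E": 5, "L": 0})
        assert list(mat.columns) == ["E"]


class TestTopN:
    def test_identical_tops_union_is_n(self):
        mat = pd.DataFrame(
            np.outer(np.arange(200, 0, -1), np.ones(6)),
            index=[f"t{i}" for i in range(200)],
            columns=list("ABCDEF"),
        )
        assert len(top_n_union(mat, 100)) == 100

    def test_disjoint_tops_union_is_n_times_libraries(self):
        mat = pd.DataFrame(0.0, index=[f"t{i}" for i in range(60)],
                           columns=list("ABC"))
        for j, lib in enumerate("ABC"):
            mat.iloc[20 * j: 20 * (j + 1), j] = 100.0
        assert len(top_n_union(mat, 20)) == 60

    def test_matches_set_union_oracle(self):
        rng = np.random.default_rng(4)
        mat = pd.DataFrame(
            rng.lognormal(0, 1, size=(300, 4)),
            index=[f"t{i}" for i in range(300)], columns=list("ABCD"),
        )
        expected = set()
        for lib in mat.columns:
            expected |= set(mat[lib].sort_values(ascending=False).index[:50])
        got = top_n_union(mat, 50)
        assert set(got.index) == expected


class TestHierarchical:
    def test_identical_rows_merge_first(self):
        mat = pd.DataFrame(
            [[1, 2, 3, 4], [2, 4, 6, 8], [4, 3, 2, 1], [1.1, 2.2, 3.1, 4.2]],
            index=list("abcd"), columns=list("WXYZ"),
        )
        res = hierarchical_cluster(mat, n_groups=2)
        # rows a, b, d share a profile shape; c is anti-correlated
        assert res.groups["a"] == res.groups["b"] == res.groups["d"]
        assert res.groups["c"] != res.groups["a"]

    def test_constant_row_falls_back_without_error(self):
        mat = pd.DataFrame(
            [[5, 5, 5, 5], [1, 2, 3, 4], [1, 2, 3, 5]],
            index=list("abc"), columns=list("WXYZ"),
        )
        res = hierarchical_cluster(mat, n_groups=2)
        assert set(res.groups.index) == {"a", "b", "c"}

    def test_newick_export_contains_all_leaves(self):
        mat, _ = simulate_profile_groups(4, seed=0)
        nwk = hierarchical_cluster(mat, n_groups=3).to_newick()
        assert nwk.endswith(";")
        for label in mat.index:
            assert label in nwk

    def test_planted_groups_recovered_across_seeds(self):
        from sklearn.metrics import adjusted_rand_score
        hits = 0
        n_seeds = 20
        for seed in range(n_seeds):
            mat, labels = simulate_profile_groups(15, seed=seed)
            res = hierarchical_cluster(mat, n_groups=3)
            hits += adjusted_rand_score(labels, res.groups.to_numpy()) == 1.0
        assert hits >= 0.95 * n_seeds

    def test_single_row_rejected(self):
        with pytest.raises(ValueError):
            hierarchical_cluster(pd.DataFrame([[1.0, 2.0]], index=["a"]))


class TestPoissonDe:
    def test_both_zero(self):
        assert poisson_de(0, 100, 0, 100) == (1.0, 0.0)

    def test_symmetry_of_equal_counts(self):
        p, lr = poisson_de(5, 1000, 5, 1000)
        assert lr == 0.0
        assert p >= 0.9

    def test_exact_tail_sum_oracle(self):
        p, _ = poisson_de(20, 10_000, 2, 10_000)
        assert p == pytest.approx(exact_two_sided_p(20, 2, 10_000, 10_000), abs=1e-12)

    def test_symmetry_property(self):
        for x, y, na, nb in [(3, 9, 100, 300), (0, 7, 55, 44), (12, 12, 10, 90)]:
            pa, _ = poisson_de(x, na, y, nb)
            pb, _ = poisson_de(y, nb, x, na)
            assert pa == pytest.approx(pb, abs=1e-12)

    def test_scale_invariance(self):
        p1, lr1 = poisson_de(8, 1000, 3, 2000)
        p2, lr2 = poisson_de(8, 100_000, 3, 200_000)
        assert p1 == pytest.approx(p2, abs=1e-12)
        assert lr1 == pytest.approx(lr2, abs=1e-12)

    def test_zero_count_uses_pseudocount(self):
        _, lr = poisson_de(30, 1000, 0, 1000)
        assert lr == pytest.approx(math.log2(31.0))

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            poisson_de(-1, 10, 0, 10)
        with pytest.raises(ValueError):
            poisson_de(1, 0, 0, 10)


class TestDeTable:
    def test_agrees_with_scalar_test(self):
        counts, _ = simulate_de_counts(200, seed=1)
        df = de_table(counts, "A", "B")
        for tag in counts.index[:50]:
            p, lr = poisson_de(
                int(counts.loc[tag, "A"]), int(counts["A"].sum()),
                int(counts.loc[tag, "B"]), int(counts["B"].sum()),
            )
            assert df.loc[tag, "p_value"] == pytest.approx(p, abs=1e-12)
            assert df.loc[tag, "log2_ratio"] == pytest.approx(lr, abs=1e-12)

    def test_bh_adjustment_is_monotone_and_above_raw(self):
        counts, _ = simulate_de_counts(500, fold=3.0, frac_up=0.1, seed=2)
        df = de_table(counts, "A", "B").sort_values("p_value")
        assert (df["adjusted_p"] >= df["p_value"] - 1e-12).all()
        assert df["adjusted_p"].is_monotonic_increasing

    def test_specific_flag_for_zero_count_significant_tag(self):
        counts = pd.DataFrame(
            {"A": [30] + [10] * 50, "B": [0] + [10] * 50},
            index=[f"t{i}" for i in range(51)],
        )
        df = de_table(counts, "A", "B")
        assert bool(df.loc["t0", "specific_flag"])
        assert df.loc["t0", "direction"] == "a_up"

    def test_direction_requires_both_thresholds(self):
        counts = pd.DataFrame({"A": [12], "B": [8]}, index=["t0"])
        df = de_table(counts, "A", "B", total_a=100, total_b=100)
        assert df.loc["t0", "direction"] == "ns"
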