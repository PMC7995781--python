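import io

import numpy as np
import pandas as pd
import pytest

from archrep.expression import (
    differential_rank,
    filter_bottom_mean,
    fold_change_de,
    hypergeometric_overlap,
    keep_top_expressed,
    mean_threshold_filter,
    permutation_de,
    rank_normalize,
    read_expression,
    read_labels,
)


def matrix_from(values: dict[str, list[float]], samples=None) -> pd.DataFrame:
    df = pd.DataFrame(values).T
    df.columns = samples or [f"s{i + 1}" for i in range(df.shape[1])]
    return df


class TestFilters:
    def test_bottom_quartile_removed(self):
        m = matrix_from({"a": [1.0], "b": [2.0], "c": [3.0], "d": [4.0]})
        out = filter_bottom_mean(m, 0.25)
        assert set(out.index) == {"b", "c", "d"}

    def test_keep_top_half_count(self):
        m = matrix_from({f"g{i}": [float(i)] for i in range(100)})
        assert len(keep_top_expressed(m, 0.5)) == 50

    def test_cutoff_ties_break_by_gene_id(self):
        m = matrix_from({"b": [1.0], "a": [1.0], "c": [5.0], "d": [6.0]})
        out = filter_bottom_mean(m, 0.25)
        # "a" sorts before "b" at the tied mean, so "a" is the one dropped
        assert set(out.index) == {"b", "c", "d"}

    def test_mean_threshold_is_strict(self):
        m = matrix_from({"at": [2.0, 2.0], "above": [2.01, 2.01], "below": [0.0, 1.0]})
        out = mean_threshold_filter(m, 2.0)
        assert list(out.index) == ["above"]

    def test_threshold_filter_idempotent_and_order_independent(self):
        rng = np.random.default_rng(0)
        m = pd.DataFrame(rng.uniform(0, 5, (50, 4)), index=[f"g{i}" for i in range(50)])
        once = mean_threshold_filter(m, 2.0)
        assert mean_threshold_filter(once, 2.0).equals(once)
        shuffled = m.sample(frac=1.0, random_state=1)
        assert set(mean_threshold_filter(shuffled, 2.0).index) == set(once.index)
        assert set(filter_bottom_mean(shuffled, 0.25).index) == set(
            filter_bottom_mean(m, 0.25).index
        )


class TestFoldChange:
    def test_equal_means_empty(self):
        m = matrix_from({"g": [3.0, 3.0, 3.0, 3.0]})
        up, down = fold_change_de(m, ["s1", "s2"], ["s3", "s4"])
        assert up == set() and down == set()

    def test_planted_fold_and_swap_symmetry(self):
        m = matrix_from({"up4x": [1.0, 1.0, 4.2, 4.2], "flat": [2.0, 2.0, 2.1, 2.0]})
        up, down = fold_change_de(m, ["s1", "s2"], ["s3", "s4"])
        assert up == {"up4x"} and down == set()
        up2, down2 = fold_change_de(m, ["s3", "s4"], ["s1", "s2"])
        assert (up2, down2) == (down, up)

    def test_groups_must_be_disjoint(self):
        m = matrix_from({"g": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError):
            fold_change_de(m, ["s1"], ["s1", "s2"])


class TestPermutationDe:
    def test_constant_identical_groups_nothing_significant(self):
        m = matrix_from({f"g{i}": [5.0] * 8 for i in range(20)})
        res = permutation_de(m, [f"s{i}" for i in range(1, 5)], [f"s{i}" for i in range(5, 9)])
        assert res.up == set() and res.down == set()
        assert (res.table["p"] >= 0.99).all()  # degenerate genes get p = 1

    def test_planted_shift_recovered(self):
        # 3-sd shifts in 10% of genes, 5 vs 5; power is compared against an
        # independent oracle (Welch t + BH) on the same data, averaged over
        # replicate datasets
        from scipy import stats as sps

        from archrep.enrichment import bh_fdr

        recalls, oracle_recalls, fdps = [], [], []
        for rep in range(5):
            rng = np.random.default_rng(100 + rep)
            n_genes, n = 200, 5
            data = rng.normal(10, 1, (n_genes, 2 * n))
            planted = {f"g{i}" for i in range(20)}
            data[:20, n:] += 3.0  # 3-sd shift in group B
            m = pd.DataFrame(data, index=[f"g{i}" for i in range(n_genes)])
            m.columns = [f"s{i}" for i in range(2 * n)]
            res = permutation_de(
                m, [f"s{i}" for i in range(n)], [f"s{i}" for i in range(n, 2 * n)],
                n_perm=2000, seed=2,
            )
            called = res.up | res.down
            recalls.append(len(res.up & planted) / len(planted))
            fdps.append(len(called - planted) / max(1, len(called)))
            _, p = sps.ttest_ind(data[:, n:], data[:, :n], axis=1)
            q = bh_fdr(p)
            oracle_recalls.append((q[:20] <= 0.05).mean())
        # at least as powerful as the oracle (small slack), controlled FDR
        assert np.mean(recalls) >= np.mean(oracle_recalls) - 0.05
        assert np.mean(recalls) >= 0.6
        assert np.mean(fdps) <= 0.1

    def test_label_swap_flips_effects(self):
        rng = np.random.default_rng(3)
        m = pd.DataFrame(rng.normal(5, 1, (30, 8)), index=[f"g{i}" for i in range(30)])
        m.columns = [f"s{i}" for i in range(8)]
        a, b = [f"s{i}" for i in range(4)], [f"s{i}" for i in range(4, 8)]
        r1 = permutation_de(m, a, b, n_perm=200, seed=4)
        r2 = permutation_de(m, b, a, n_perm=200, seed=4)
        assert np.allclose(r1.table["effect"], -r2.table["effect"])

    def test_exhaustive_enumeration_small_design(self):
        rng = np.random.default_rng(5)
        m = pd.DataFrame(rng.normal(0, 1, (10, 6)), index=[f"g{i}" for i in range(10)])
        m.columns = [f"s{i}" for i in range(6)]
        res = permutation_de(m, ["s0", "s1", "s2"], ["s3", "s4", "s5"], n_perm=5000)
        assert res.n_permutations == 20  # C(6,3)

    def test_seeded_determinism(self):
        rng = np.random.default_rng(6)
        m = pd.DataFrame(rng.normal(0, 1, (15, 10)), index=[f"g{i}" for i in range(15)])
        m.columns = [f"s{i}" for i in range(10)]
        a, b = [f"s{i}" for i in range(5)], [f"s{i}" for i in range(5, 10)]
        r1 = permutation_de(m, a, b, n_perm=300, seed=7)
        r2 = permutation_de(m, a, b, n_perm=300, seed=7)
        pd.testing.assert_frame_equal(r1.table, r2.table)


class TestRanks:
    def test_rank_direction_and_ties(self):
        m = matrix_from({"a": [10.0], "b": [30.0], "c": [20.0]})
        r = rank_normalize(m)
        assert list(r["s1"]) == [3.0, 1.0, 2.0]
        tied = matrix_from({"a": [5.0], "b": [5.0], "c": [1.0]})
        rt = rank_normalize(tied)
        assert list(rt["s1"]) == [1.5, 1.5, 3.0]

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(8)
        m = pd.DataFrame(rng.lognormal(1, 1, (40, 6)), index=[f"g{i}" for i in range(40)])
        r1 = rank_normalize(m)
        r2 = rank_normalize(m**2 + 1)
        pd.testing.assert_frame_equal(r1, r2)

    def test_differential_rank_invariance_and_recovery(self):
        rng = np.random.default_rng(9)
        n_genes, n_planted, ns = 300, 8, 10
        genes = [f"g{i}" for i in range(n_genes)]
        base = rng.lognormal(2, 1, n_genes)
        a = pd.DataFrame(
            base[:, None] * rng.lognormal(0, 0.1, (n_genes, ns)), index=genes,
            columns=[f"a{i}" for i in range(ns)],
        )
        b = pd.DataFrame(
            base[:, None] * rng.lognormal(0, 0.1, (n_genes, ns)), index=genes,
            columns=[f"b{i}" for i in range(ns)],
        )
        # plant a uniform upward rank displacement: boost mid-baseline genes
        mid = np.argsort(base)[n_genes // 2 - n_planted // 2 : n_genes // 2 + n_planted // 2]
        planted = {genes[i] for i in mid}
        b.iloc[mid] *= 20.0
        res = differential_rank(a, b, n_perm=1500, seed=10)
        assert res.up == planted
        assert res.down == set()
        # per-sample rescaling of the raw values must not change anything
        scaled_a = a * rng.uniform(0.5, 2.0, ns)
        res2 = differential_rank(scaled_a, b, n_perm=1500, seed=10)
        pd.testing.assert_frame_equal(res.table, res2.table)

    def test_identical_matrices_no_calls(self):
        rng = np.random.default_rng(11)
        m = pd.DataFrame(rng.lognormal(1, 1, (30, 5)), index=[f"g{i}" for i in range(30)])
        m2 = m.copy()
        m2.columns = [f"x{i}" for i in range(5)]
        res = differential_rank(m, m2, n_perm=500, seed=12)
        assert res.up == set() and res.down == set()


class TestHypergeometric:
    def test_complete_overlap_in_universe(self):
        u = [f"g{i}" for i in range(10)]
        assert hypergeometric_overlap(u, u, u) == pytest.approx(1.0)

    def test_closed_form_five_of_five(self):
        u = [f"g{i}" for i in range(10)]
        p = hypergeometric_overlap(u[:5], u[:5], u)
        assert p == pytest.approx(1 / 252)  # 1 / C(10,5)

    def test_disjoint_sets_near_one(self):
        u = [f"g{i}" for i in range(1000)]
        p = hypergeometric_overlap(u[:5], u[5:10], u)
        assert p == pytest.approx(1.0, abs=0.05)

    def test_validation(self):
        with pytest.raises(ValueError):
            hypergeometric_overlap(["a"], ["b"], [])
        with pytest.raises(ValueError):
            hypergeometric_overlap(["x"], ["a"], ["a", "b"])


def test_readers_roundtrip():
    text = "gene_id\ts1\ts2\ng1\t1.5\t2.0\ng2\t0.0\t3.0\n"
    m = read_expression(io.StringIO(text))
    assert m.shape == (2, 2) and m.loc["g2", "s2"] == 3.0
    labels = read_labels(io.StringIO("sample\ttissue\ns1\tliver\ns2\tbrain\n"))
    assert labels["s2"] == "brain"
    with pytest.raises(ValueError, match="negative"):
        read_expression(io.StringIO("gene_id\ts1\ng1\t-1.0\n"))
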