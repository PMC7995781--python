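import io

import numpy as np
import pandas as pd
import pytest

from archrep.genes import GeneModel
from archrep.intervals import GenomicInterval
from archrep.pyknon import (
    FamilyAttribution,
    MotifHit,
    PyknonMotif,
    attribute_to_families,
    compare_density_groups,
    compare_family_distributions,
    exonic_hit_table,
    find_motif_hits,
    gene_density_profile,
    partition_motifs,
    read_motifs,
)
from archrep.repeats import RepeatAnnotation, RepeatInstance


def naive_scan(seq: str, motif: str) -> list[int]:
    """Position-wise numpy oracle, independent of the string-search path."""
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    pat = np.frombuffer(motif.encode(), dtype=np.uint8)
    m = len(pat)
    if len(arr) < m:
        return []
    windows = np.lib.stride_tricks.sliding_window_view(arr, m)
    return np.nonzero((windows == pat).all(axis=1))[0].tolist()


class TestMotifSearch:
    def test_validation(self):
        with pytest.raises(ValueError):
            PyknonMotif("m", "ACG")  # too short
        with pytest.raises(ValueError):
            PyknonMotif("m", "ACGTAN")

    def test_simple_and_overlapping_occurrences(self):
        hits = find_motif_hits([PyknonMotif("m1", "ACGTAC")], {"c": "ACGTACGTACGTAC"})
        assert [h.interval.start for h in hits] == naive_scan("ACGTACGTACGTAC", "ACGTAC")
        hits = find_motif_hits([PyknonMotif("m2", "AAAAAA")], {"c": "AAAAAAAA"})
        assert [h.interval.start for h in hits] == [0, 1, 2]  # overlapping counted

    def test_absent_motif_and_n_never_matches(self):
        assert find_motif_hits([PyknonMotif("m", "ACGTGT")], {"c": "TTTTTTTTTT"}) == []
        assert find_motif_hits([PyknonMotif("m", "ACGTGT")], {"c": "ACGNGTACGTGA"}) == []

    def test_matches_naive_oracle_on_random_sequence(self):
        rng = np.random.default_rng(0)
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 5_000))
        motifs = [
            PyknonMotif(f"m{i}", "".join("ACGT"[j] for j in rng.integers(0, 4, 6)))
            for i in range(30)
        ]
        hits = find_motif_hits(motifs, {"c": seq})
        got = {}
        for h in hits:
            got.setdefault(h.motif_id, []).append(h.interval.start)
        for m in motifs:
            assert sorted(got.get(m.motif_id, [])) == naive_scan(seq, m.sequence)

    def test_both_strands_option(self):
        hits = find_motif_hits(
            [PyknonMotif("m", "AAACCC")], {"c": "GGGTTTAA"}, both_strands=True
        )
        assert len(hits) == 1 and hits[0].interval.strand == "-"

    def test_read_motifs_formats(self):
        two_col = read_motifs(io.StringIO("p1\tACGTAC\np2\tGGGCCC\n"))
        assert [m.motif_id for m in two_col] == ["p1", "p2"]
        bare = read_motifs(io.StringIO("acgtac\n"))
        assert bare[0].sequence == "ACGTAC"


def toy_gene(gid, start, end, exons, chrom="c", strand="+"):
    return GeneModel(
        gid,
        GenomicInterval(chrom, start, end, strand),
        [GenomicInterval(chrom, s, e, strand) for s, e in exons],
    )


class TestPartitionAndDensity:
    def hits_df(self, pairs):
        return pd.DataFrame(
            [(m, g, 0, 6) for m, g in pairs], columns=["motif_id", "gene_id", "start", "end"]
        )

    def test_exonic_hit_mapping(self):
        genes = {"g1": toy_gene("g1", 0, 100, [(10, 30)]), "g2": toy_gene("g2", 200, 300, [(200, 300)])}
        hits = find_motif_hits(
            [PyknonMotif("m", "ACGTAC")],
            {"c": "T" * 12 + "ACGTAC" + "T" * 300},
        )
        table = exonic_hit_table(hits, genes)
        assert list(table["gene_id"]) == ["g1"]

    def test_partition_set_algebra(self):
        hits = self.hits_df(
            [("a", "g1"), ("b", "g1"), ("c", "g1"), ("b", "g2"), ("c", "g2"), ("d", "g2")]
        )
        cells = partition_motifs({"up": ["g1"], "down": ["g2"]}, hits)
        assert cells[frozenset(["up"])] == {"a"}
        assert cells[frozenset(["down"])] == {"d"}
        assert cells[frozenset(["up", "down"])] == {"b", "c"}

    def test_partition_conservation_three_sets(self):
        rng = np.random.default_rng(1)
        pairs = [(f"m{rng.integers(30)}", f"g{rng.integers(6)}") for _ in range(120)]
        hits = self.hits_df(pairs)
        sets = {"A": ["g0", "g1"], "B": ["g2", "g3"], "C": ["g4", "g5"]}
        cells = partition_motifs(sets, hits)
        union = set().union(*cells.values())
        assert sum(len(v) for v in cells.values()) == len(union)

    def test_partition_unknown_gene_warns(self):
        hits = self.hits_df([("a", "g1")])
        with pytest.warns(UserWarning, match="unknown gene"):
            cells = partition_motifs({"up": ["g1", "gX"]}, hits, known_genes=["g1"])
        assert cells[frozenset(["up"])] == {"a"}

    def test_density_profile_arithmetic(self):
        hits = self.hits_df([("a", "g1"), ("a", "g1"), ("b", "g1"), ("c", "g2")])
        prof = gene_density_profile("g1", 10_000, {"a", "b"}, hits)
        assert prof.distinct_motifs == 2
        assert prof.instances == 3
        assert prof.density == pytest.approx(2.0)  # per 10 kb
        assert prof.density_alt == pytest.approx(0.3)  # per 1 kb
        empty = gene_density_profile("g3", 5_000, {"a"}, hits)
        assert empty.density == 0.0


class TestAttribution:
    def annotation(self):
        return RepeatAnnotation(
            [
                RepeatInstance(GenomicInterval("c", 100, 400, "+"), "SINE/Alu", "AluY"),
                RepeatInstance(GenomicInterval("c", 600, 900, "-"), "LINE/L1", "L1M"),
            ]
        )

    def hit(self, mid, start):
        return MotifHit(mid, GenomicInterval("c", start, start + 10, "+"))

    def test_single_and_multi_family_membership(self):
        attr = attribute_to_families(
            [self.hit("m1", 150), self.hit("m2", 150), self.hit("m2", 650), self.hit("m3", 950)],
            self.annotation(),
        )
        assert attr.motif_families["m1"] == {"SINE/Alu"}
        assert attr.motif_families["m2"] == {"SINE/Alu", "LINE/L1"}
        assert attr.motif_families["m3"] == set()
        assert attr.family_counts == {"LINE/L1": 1, "SINE/Alu": 2}
        # percentages are over motifs, so multi-membership can push sums past 100
        assert sum(attr.family_percentages.values()) == pytest.approx(100.0)

    def test_opposite_strand_hit_still_attributed(self):
        # L1 instance is on '-', hit recorded on '+': either strand counts
        attr = attribute_to_families([self.hit("m", 700)], self.annotation())
        assert attr.motif_families["m"] == {"LINE/L1"}

    def test_monotone_under_added_instances(self):
        hits = [self.hit("m", 150)]
        small = attribute_to_families(hits, RepeatAnnotation([]))
        assert small.motif_families["m"] == set()
        grown = attribute_to_families(hits, self.annotation())
        assert small.motif_families["m"] <= grown.motif_families["m"]


class TestGroupComparisons:
    def test_mwu_identical_groups(self):
        with pytest.warns(UserWarning):
            _, p = compare_density_groups([1.0, 1.0, 1.0], [1.0, 1.0])
        assert p == 1.0

    def test_mwu_shift_detected_and_symmetric(self):
        rng = np.random.default_rng(2)
        a = rng.uniform(0, 1, 25)
        b = a + 5.0
        _, p1 = compare_density_groups(a, b)
        _, p2 = compare_density_groups(b, a)
        assert p1 < 0.05
        assert p1 == pytest.approx(p2)

    def test_chi2_proportional_is_null(self):
        stat, p = compare_family_distributions(
            {"Alu": 10, "L1": 20, "MIR": 30}, {"Alu": 20, "L1": 40, "MIR": 60}
        )
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_chi2_matches_closed_form(self):
        counts_a = {"x": 30, "y": 10, "z": 20}
        counts_b = {"x": 10, "y": 30, "z": 20}
        stat, p = compare_family_distributions(counts_a, counts_b)
        table = np.array([[30, 10, 20], [10, 30, 20]], dtype=float)
        expected = np.outer(table.sum(1), table.sum(0)) / table.sum()
        oracle = ((table - expected) ** 2 / expected).sum()
        assert stat == pytest.approx(oracle)

    def test_chi2_strong_divergence(self):
        _, p = compare_family_distributions({"Alu": 500, "L1": 50}, {"Alu": 50, "L1": 500})
        assert p < 1e-5

    def test_chi2_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            compare_family_distributions({"Alu": 0}, {"Alu": 5})
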