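"""Consensus tiers, Venn accounting, nearest-gene annotation."""

import numpy as np
import pandas as pd
import pytest

from broodscan.consensus_annot import (
    ConsensusError,
    build_consensus,
    nearest_genes,
    venn_counts,
)
from broodscan.datamodel import GeneRecord, LocusAlignment
from oracles import nearest_genes_oracle


def frame(locus_ids, flags):
    """(locus_id, outlier) frame; flags: True/False/None (None = not tested)."""
    return pd.DataFrame({
        "locus_id": locus_ids,
        "outlier": pd.array(flags, dtype="boolean"),
    })


LOCI = [f"L{i}" for i in range(10)]


def crafted_results():
    """Hand-designed 10-locus fixture across 2 methods x 3 broodlines.

    L0: temporal-B and fst-B              -> broodline-B consensus + highly sig
    L1: temporal-A only                   -> candidate only
    L2: fst-A and fst-C                   -> highly significant (2 tests)
    L3: nothing                           -> none
    L4: temporal-A, temporal-B, temporal-C -> highly significant, all broodlines
    L5: fst-C only                        -> candidate
    L6: not tested by fst anywhere, temporal-C sig -> candidate
    L7-9: nothing
    """
    def flags(sig, untested=()):
        return [True if l in sig else (None if l in untested else False)
                for l in LOCI]

    return {
        ("temporal", "A"): frame(LOCI, flags({"L1", "L4"})),
        ("temporal", "B"): frame(LOCI, flags({"L0", "L4"})),
        ("temporal", "C"): frame(LOCI, flags({"L4", "L6"})),
        ("fst", "A"): frame(LOCI, flags({"L2"}, untested={"L6"})),
        ("fst", "B"): frame(LOCI, flags({"L0"}, untested={"L6"})),
        ("fst", "C"): frame(LOCI, flags({"L2", "L5"}, untested={"L6"})),
    }


class TestConsensus:
    def test_hand_computed_tiers(self):
        table = build_consensus(crafted_results())
        assert set(table.candidates()) == {"L0", "L1", "L2", "L4", "L5", "L6"}
        assert set(table.highly_significant()) == {"L0", "L2", "L4"}
        bc = table.broodline_consensus()
        assert bc["B"] == ["L0"]
        assert bc["A"] == [] and bc["C"] == []
        assert set(table.shared_across_broodlines(2)) == {"L2", "L4"}
        assert set(table.shared_across_broodlines(3)) == {"L4"}

    def test_tier_nesting(self):
        table = build_consensus(crafted_results())
        assert set(table.highly_significant()) <= set(table.candidates())

    def test_not_tested_distinct_from_not_significant(self):
        table = build_consensus(crafted_results())
        col = table.matrix[("fst", "A")]
        assert col["L6"] == -1          # never scanned
        assert col["L3"] == 0           # scanned, not significant
        assert col["L2"] == 1

    def test_single_test_is_candidate_only(self):
        table = build_consensus(crafted_results())
        assert "L1" in table.candidates()
        assert "L1" not in table.highly_significant()

    def test_mismatched_universe_raises(self):
        results = crafted_results()
        results[("fst", "A")] = frame(LOCI[:5], [True] * 5)
        with pytest.raises(ConsensusError, match="missing"):
            build_consensus(results)

    def test_fewer_than_two_tests_raises(self):
        with pytest.raises(ConsensusError, match=">= 2"):
            build_consensus({("temporal", "A"): frame(LOCI, [False] * 10)})


class TestVenn:
    def test_disjoint_and_triple(self):
        table = build_consensus(crafted_results())
        by_method = venn_counts(table, "method")
        # temporal-only: L1, L4, L6; fst-only: L2, L5; both: L0
        assert by_method["temporal"] == 3
        assert by_method["fst"] == 2
        assert by_method["temporal+fst"] == 1
        by_brood = venn_counts(table, "broodline")
        assert by_brood["A+B+C"] == 1   # L4 in all three broodlines
        assert sum(by_brood.values()) == len(table.candidates())

    def test_partition_identity_random(self, rng):
        for _ in range(20):
            loci = [f"x{i}" for i in range(40)]
            results = {}
            for m in ("temporal", "fst"):
                for b in "ABC":
                    flags = rng.random(40) < 0.15
                    results[(m, b)] = frame(loci, [bool(f) for f in flags])
            table = build_consensus(results)
            for axis in ("method", "broodline"):
                counts = venn_counts(table, axis)
                assert sum(counts.values()) == len(table.candidates())


GENES = [
    GeneRecord("g1", "scn1", "chr1", 10000, 12000, "+"),
    GeneRecord("g2", "g2", "chr1", 20000, 25000, "-"),
    GeneRecord("g3", "g3", "chr1", 120000, 125000, "+"),
    GeneRecord("g4", "g4", "chr2", 500, 900, "+"),
]


def aln(locus, chrom, pos):
    return LocusAlignment(locus, chrom, pos, 42, "+")


class TestNearestGenes:
    def test_inside_gene_rank1_distance0(self):
        rows = nearest_genes([aln("t1", "chr1", 11000)], GENES)
        assert rows[0].gene_id == "g1" and rows[0].distance == 0 and rows[0].rank == 1

    def test_window_boundary_inclusive(self):
        # g3 starts at 120000: position 20000 is exactly 100000 away -> included
        rows = nearest_genes([aln("t2", "chr1", 20000)], GENES, window=100000)
        assert any(r.gene_id == "g3" and r.distance == 100000 for r in rows)
        # one base further: excluded
        rows = nearest_genes([aln("t3", "chr1", 19999)], GENES, window=100000)
        assert all(r.gene_id != "g3" for r in rows)

    def test_absent_chromosome_warns_zero_rows(self):
        with pytest.warns(UserWarning, match="absent"):
            rows = nearest_genes([aln("t4", "chrZ", 100)], GENES)
        assert rows == []

    def test_multimapped_locus_annotated_everywhere(self):
        rows = nearest_genes([aln("t5", "chr1", 11000), aln("t5", "chr2", 600)], GENES)
        chroms = {r.chrom for r in rows}
        assert chroms == {"chr1", "chr2"}

    def test_ties_break_by_start_then_id(self):
        genes = [
            GeneRecord("gb", "gb", "c", 200, 300, "+"),
            GeneRecord("ga", "ga", "c", 200, 300, "+"),
            GeneRecord("gc", "gc", "c", 100, 300, "+"),
        ]
        rows = nearest_genes([aln("t6", "c", 350)], genes, k=3)
        # equal distance 50 for all three: smaller start wins, then gene id
        assert [r.gene_id for r in rows] == ["gc", "ga", "gb"]

    def test_matches_bruteforce_oracle(self, rng):
        """200 random gene/position fixtures vs the all-pairs scan."""
        for _ in range(200):
            genes = []
            for i in range(int(rng.integers(5, 50))):
                start = int(rng.integers(1, 500000))
                genes.append(GeneRecord(
                    f"g{i}", f"g{i}", f"chr{rng.integers(1, 4)}",
                    start, start + int(rng.integers(100, 20000)), "+"))
            pos = int(rng.integers(1, 500000))
            chrom = f"chr{rng.integers(1, 4)}"
            rows = nearest_genes([aln("t", chrom, pos)], genes, window=100000, k=3)
            want = nearest_genes_oracle(pos, chrom, genes, 100000, 3)
            assert [(r.distance, r.gene_id) for r in rows] == \
                [(d, gid) for d, _, gid in want]
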