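"""Alignment I/O, anchor-coordinate masking, p-distance, NJ sanity tree."""

from __future__ import annotations

import random

import dendropy
import pytest

from museomito.aligndist import (
    MultipleAlignment,
    distance_matrix,
    map_anchor_to_columns,
    mask_columns,
    nj_tree,
    p_distance,
    read_alignment,
    ungapped_length,
    write_alignment,
)
from museomito.simgen import evolve, simulate_genome
from museomito.types import MaskRegion

INTERLEAVED_NEXUS = """#NEXUS
BEGIN DATA;
DIMENSIONS NTAX=3 NCHAR=12;
FORMAT DATATYPE=DNA MISSING=? GAP=- INTERLEAVE=YES;
MATRIX
tax1 ACGTAC
tax2 ACGTAC
tax3 A-GTAC

tax1 GTACGT
tax2 GTACGA
tax3 GTAC??
;
END;
"""

SEQUENTIAL_NEXUS = """#NEXUS
BEGIN DATA;
DIMENSIONS NTAX=3 NCHAR=12;
FORMAT DATATYPE=DNA MISSING=? GAP=-;
MATRIX
tax1 ACGTACGTACGT
tax2 ACGTACGTACGA
tax3 A-GTACGTAC??
;
END;
"""


class TestAlignmentIO:
    def test_interleaved_equals_sequential(self, tmp_path):
        p1 = tmp_path / "i.nex"
        p2 = tmp_path / "s.nex"
        p1.write_text(INTERLEAVED_NEXUS)
        p2.write_text(SEQUENTIAL_NEXUS)
        a1 = read_alignment(p1)
        a2 = read_alignment(p2)
        assert a1.taxa == a2.taxa
        assert a1.rows == a2.rows

    def test_fasta_dimensions(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text(">x\nACGTACGTAC\n>y\nACGTACGTAA\n")
        aln = read_alignment(p)
        assert len(aln.taxa) == 2
        assert aln.n_columns == 10

    def test_round_trip(self, tmp_path):
        aln = MultipleAlignment(["a", "b"], ["ACGT-CGT", "ACGTNC?T"])
        for fmt, name in (("fasta", "rt.fasta"), ("nexus", "rt.nex")):
            path = tmp_path / name
            write_alignment(aln, path, fmt)
            back = read_alignment(path)
            assert back.taxa == aln.taxa
            assert back.rows == aln.rows

    def test_ragged_rows_rejected(self):
        with pytest.raises(ValueError):
            MultipleAlignment(["a", "b"], ["ACGT", "ACG"])

    def test_duplicate_labels_rejected(self):
        with pytest.raises(ValueError):
            MultipleAlignment(["a", "a"], ["ACGT", "ACGT"])


class TestAnchorMapping:
    def test_gap_free_anchor_is_identity(self):
        aln = MultipleAlignment(["anchor", "other"], ["ACGT", "TTTT"])
        cols = map_anchor_to_columns(aln, MaskRegion("anchor", 2, 3))
        assert cols == {2, 3}

    def test_gaps_shift_columns(self):
        aln = MultipleAlignment(["anchor", "other"], ["A-CG", "TTTT"])
        assert map_anchor_to_columns(aln, MaskRegion("anchor", 2, 2)) == {3}

    def test_interior_gap_columns_included(self):
        aln = MultipleAlignment(["anchor", "other"], ["AC--GT", "TTTTTT"])
        assert map_anchor_to_columns(aln, MaskRegion("anchor", 2, 3)) == {2, 3, 4, 5}

    def test_matches_brute_force_scan(self):
        rng = random.Random(5)
        for _ in range(30):
            row = "".join(rng.choice("ACGT-") for _ in range(60))
            if ungapped_length(row.replace("-", "N")) == 0:
                continue
            n_nongap = sum(1 for ch in row if ch != "-")
            if n_nongap < 2:
                continue
            start = rng.randint(1, n_nongap - 1)
            end = rng.randint(start, n_nongap)
            aln = MultipleAlignment(["anchor"], [row])
            got = map_anchor_to_columns(aln, MaskRegion("anchor", start, end))
            # brute force: walk the row counting non-gap characters to
            # find the columns of the start-th and end-th characters,
            # then take every column between them
            seen = 0
            first_col = last_col = None
            for col, ch in enumerate(row, start=1):
                if ch != "-":
                    seen += 1
                    if seen == start and first_col is None:
                        first_col = col
                    if seen == end:
                        last_col = col
            cols = set(range(first_col, last_col + 1))
            assert got == cols

    def test_out_of_range_region_rejected(self):
        aln = MultipleAlignment(["anchor"], ["ACGT"])
        with pytest.raises(ValueError):
            map_anchor_to_columns(aln, MaskRegion("anchor", 2, 9))

    def test_missing_anchor_rejected(self):
        aln = MultipleAlignment(["x"], ["ACGT"])
        with pytest.raises(KeyError):
            map_anchor_to_columns(aln, MaskRegion("anchor", 1, 2))


class TestMaskColumns:
    def test_empty_region_list_is_identity(self):
        aln = MultipleAlignment(["a", "b"], ["ACGT", "TGCA"])
        masked, report = mask_columns(aln, [])
        assert masked.rows == aln.rows
        assert report.columns_removed == 0

    def test_overlapping_regions_removed_once(self):
        aln = MultipleAlignment(["a"], ["ACGTACGTAC"])
        masked, report = mask_columns(
            aln, [MaskRegion("a", 2, 5), MaskRegion("a", 4, 7)]
        )
        assert report.columns_removed == 6  # union of 2-5 and 4-7
        assert masked.rows[0] == "ATAC"  # columns 1, 8, 9, 10 survive

    def test_hypervariable_region_masking_arithmetic(self):
        """Masking the tRNA-Pro/D-loop, two 16S stretches and the OriL
        portion (coordinates on a gap-free anchor) removes
        2,111 + 42 + 15 + 18 = 2,186 columns."""
        n = 17610
        rng = random.Random(6)
        anchor = "".join(rng.choice("ACGT") for _ in range(n))
        other = "".join(rng.choice("ACGT") for _ in range(n))
        aln = MultipleAlignment(["AY789013.1", "other"], [anchor, other])
        regions = [
            MaskRegion("AY789013.1", 15500, 17610),
            MaskRegion("AY789013.1", 1099, 1140),
            MaskRegion("AY789013.1", 2214, 2228),
            MaskRegion("AY789013.1", 5231, 5248),
        ]
        masked, report = mask_columns(aln, regions)
        per_region = [count for _, count in report.per_region]
        assert per_region == [2111, 42, 15, 18]
        assert report.columns_removed == 2186
        assert masked.n_columns == n - 2186


class TestPDistance:
    def test_identical_rows(self):
        r = p_distance("ACGTAC", "ACGTAC")
        assert (r.mismatches, r.valid_positions, r.divergence) == (0, 6, 0.0)

    def test_missing_column_excluded(self):
        r = p_distance("ACGTACGN", "ACGAACGT")
        assert r.valid_positions == 7
        assert r.mismatches == 1
        assert r.divergence == pytest.approx(1 / 7)

    def test_gaps_ambiguity_and_question_marks_excluded(self):
        r = p_distance("ACGT-RN?", "ACGTAAAA")
        assert r.valid_positions == 4
        assert r.mismatches == 0

    def test_symmetry_and_self_distance(self):
        a, b = "ACGT-CGTNA", "ACTTACG-NA"
        r_ab = p_distance(a, b)
        r_ba = p_distance(b, a)
        assert (r_ab.mismatches, r_ab.valid_positions) == (
            r_ba.mismatches, r_ba.valid_positions,
        )
        r_aa = p_distance(a, a)
        assert r_aa.mismatches == 0
        assert r_aa.valid_positions == ungapped_length(a)

    def test_zero_valid_positions_raises(self):
        with pytest.raises(ZeroDivisionError):
            p_distance("NNNN", "ACGT")

    def test_recovers_simulated_divergence_exactly(self):
        import math

        from museomito.seq import hamming

        g = simulate_genome(14000, seed=96)
        for p, s in ((0.0011, 1), (0.02, 2), (0.045, 3)):
            d = evolve(g, p, seed=96 + s)
            r = p_distance(g, d)
            assert r.mismatches == hamming(g, d)
            assert r.valid_positions == 14000
            se = math.sqrt(p * (1 - p) / 14000)
            assert abs(r.divergence - p) <= 3 * se


class TestDistanceMatrix:
    def test_consistent_with_p_distance(self):
        aln = MultipleAlignment(["a", "b"], ["ACGTACGTAC", "ACGAACGTNC"])
        m = distance_matrix(aln)
        direct = p_distance(aln.rows[0], aln.rows[1])
        assert m.get("a", "b").divergence == direct.divergence
        assert m.get("a", "b").valid_positions == direct.valid_positions

    def test_taxon_order_invariance(self):
        rows = {"a": "ACGTACGTAC", "b": "ACGAACGTNC", "c": "AC-TACGAAC"}
        m1 = distance_matrix(MultipleAlignment(list(rows), list(rows.values())))
        order = ["c", "a", "b"]
        m2 = distance_matrix(MultipleAlignment(order, [rows[t] for t in order]))
        for x in rows:
            for y in rows:
                if x != y:
                    assert m1.get(x, y).divergence == m2.get(x, y).divergence

    def test_pair_without_valid_positions_is_flagged_not_fatal(self):
        aln = MultipleAlignment(["a", "b", "c"], ["ACGT", "NNNN", "ACGA"])
        m = distance_matrix(aln)
        assert ("a", "b") in m.failed_pairs and ("b", "c") in m.failed_pairs
        assert m.get("a", "c").mismatches == 1

    def test_long_table_shape(self):
        aln = MultipleAlignment(["a", "b", "c"], ["ACGT", "ACGA", "ACTT"])
        table = distance_matrix(aln).to_long_table()
        assert len(table) == 3
        assert set(table.columns) == {
            "taxon_a", "taxon_b", "mismatches", "valid_positions", "divergence",
        }


class TestUngappedLength:
    @pytest.mark.parametrize(
        "row,expected",
        [("AC-GN?", 3), ("----", 0), ("ACGTacgt", 8), ("RYKM", 0)],
    )
    def test_counts_unambiguous_bases_only(self, row, expected):
        assert ungapped_length(row) == expected


class TestNJTree:
    def _patristic(self, newick: str) -> dict[frozenset, float]:
        tree = dendropy.Tree.get(data=newick, schema="newick")
        pdm = tree.phylogenetic_distance_matrix()
        out = {}
        for t1 in tree.taxon_namespace:
            for t2 in tree.taxon_namespace:
                if t1.label < t2.label:
                    out[frozenset((t1.label, t2.label))] = pdm.patristic_distance(t1, t2)
        return out

    def test_additive_distances_recover_generating_tree(self):
        # distances generated from ((A:0.10,B:0.20):0.05,(C:0.03,D:0.04))
        newick = "((A:0.10,B:0.20):0.05,C:0.03,D:0.04);"
        truth = self._patristic(newick)
        taxa = ["A", "B", "C", "D"]
        from museomito.aligndist import DistanceMatrix
        from museomito.types import DistanceResult

        results = {}
        denom = 10**6
        for pair, d in truth.items():
            a, b = sorted(pair)
            results[pair] = DistanceResult(a, b, round(d * denom), denom)
        m = DistanceMatrix(taxa=taxa, results=results)
        out = nj_tree(m)
        got = self._patristic(out)
        for pair, d in truth.items():
            assert got[pair] == pytest.approx(d, abs=1e-6)

    def test_three_taxa_star(self):
        from museomito.aligndist import DistanceMatrix
        from museomito.types import DistanceResult

        results = {
            frozenset(("a", "b")): DistanceResult("a", "b", 2, 100),
            frozenset(("a", "c")): DistanceResult("a", "c", 4, 100),
            frozenset(("b", "c")): DistanceResult("b", "c", 4, 100),
        }
        out = nj_tree(DistanceMatrix(taxa=["a", "b", "c"], results=results))
        assert sorted(l for l in ("a", "b", "c") if l in out) == ["a", "b", "c"]

    def test_simulated_sister_pairs_topology(self):
        g = simulate_genome(12000, seed=97)
        l1 = evolve(g, 0.025, seed=98)
        l2 = evolve(g, 0.025, seed=99)
        rows = {
            "A": evolve(l1, 0.005, seed=100),
            "B": evolve(l1, 0.005, seed=101),
            "C": evolve(l2, 0.005, seed=102),
            "D": evolve(l2, 0.005, seed=103),
        }
        aln = MultipleAlignment(list(rows), list(rows.values()))
        out = nj_tree(distance_matrix(aln))
        tree = dendropy.Tree.get(data=out, schema="newick")
        tree.encode_bipartitions()
        splits = {
            frozenset(leaf.taxon.label for leaf in edge.head_node.leaf_iter())
            for edge in tree.preorder_edge_iter()
            if edge.head_node.parent_node
        }
        assert frozenset({"A", "B"}) in splits or frozenset({"C", "D"}) in splits

    def test_fewer_than_three_taxa_rejected(self):
        from museomito.aligndist import DistanceMatrix
        from museomito.types import DistanceResult

        results = {frozenset(("a", "b")): DistanceResult("a", "b", 1, 10)}
        with pytest.raises(ValueError):
            nj_tree(DistanceMatrix(taxa=["a", "b"], results=results))
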