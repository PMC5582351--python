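import pandas as pd
import pytest

from polysyn.aligntable import (
    AlignmentTable, allocate_columns, extract_region, fill_table,
    summarize_homology,
)
from polysyn.classify import EventLabel, LabeledBlock
from polysyn.collinearity import CollinearBlock
from polysyn.io import read_alignment_table, write_alignment_table
from polysyn.model import Gene, GenomeAnnotation
from polysyn.simulate import EventTree, TreeNode, Event


def _mini_tree():
    return EventTree(root=TreeNode(
        "root", 10.0, [TreeNode("ref"), TreeNode("other")],
        branch_wgds=[Event("gct", "wgd", 20.0)]))


def _ann(genome, chrom, ids, start_rank=1):
    genes = [
        Gene(g, genome, chrom, i, (i - 1) * 100 + 1, (i - 1) * 100 + 50)
        for i, g in enumerate(ids, start=start_rank)
    ]
    return GenomeAnnotation(genome, {chrom: genes})


def _labeled(genome_a, chrom_a, genome_b, chrom_b, pairs, relation,
             identity=90.0, block_id="b", track=1):
    anchors = [(ra, rb, identity, ga, gb) for (ra, ga, rb, gb) in pairs]
    block = CollinearBlock(genome_a, chrom_a, genome_b, chrom_b, anchors,
                           "parallel", block_id=block_id, pvalue=1e-9)
    event = {"ortholog": "root", "gct_paralog": "gct"}[relation]
    return LabeledBlock(block, EventLabel(relation, event, 1.0), track, "a")


class TestAllocateColumns:
    def test_poaceae9_has_24_columns(self, poaceae_tree):
        schema = allocate_columns(poaceae_tree, "rice")
        assert len(schema) == 24
        names = schema.column_names()
        assert names[0] == "rice.1" and names[1] == "rice.2"

    def test_reference_contributes_two_columns(self):
        schema = allocate_columns(_mini_tree(), "ref")
        ref_cols = [c for c in schema.columns if c.genome_id == "ref"]
        assert len(ref_cols) == 2

    def test_hexaploid_three_columns_per_reference_column(self, poaceae_tree):
        schema = allocate_columns(poaceae_tree, "rice")
        wheat_p1 = [c for c in schema.columns
                    if c.genome_id == "wheat" and c.parent == 1]
        wheat_p2 = [c for c in schema.columns
                    if c.genome_id == "wheat" and c.parent == 2]
        assert len(wheat_p1) == len(wheat_p2) == 3

    def test_tree_without_root_wgd_rejected(self):
        tree = EventTree(root=TreeNode(
            "root", 10.0, [TreeNode("a"), TreeNode("b")]))
        with pytest.raises(ValueError, match="root WGD"):
            allocate_columns(tree, "a")


class TestFillTable:
    def _setup(self):
        ref = _ann("ref", "c1", [f"r{i}" for i in range(1, 7)])
        other = _ann("other", "k1", [f"o{i}" for i in range(1, 7)])
        schema = allocate_columns(_mini_tree(), "ref")
        pairs = [(i, f"r{i}", i, f"o{i}") for i in range(1, 7)]
        lb = _labeled("ref", "c1", "other", "k1", pairs, "ortholog")
        return schema, [lb], {"ref": ref, "other": other}

    def test_complete_homology_fills_ortholog_column(self):
        schema, labeled, anns = self._setup()
        table = fill_table(schema, labeled, anns)
        col = schema.index_of("other", 1, 1)
        assert all(row.cells.get(col) for row in table.rows)

    def test_planted_deletion_yields_exactly_one_dot(self, tmp_path):
        schema, labeled, anns = self._setup()
        # drop one anchor: the target homolog of r4 is gone
        labeled[0].block.anchors = [
            a for a in labeled[0].block.anchors if a[0] != 4
        ]
        table = fill_table(schema, labeled, anns)
        path = tmp_path / "t.tsv"
        write_alignment_table(table, path)
        df = read_alignment_table(path)
        assert (df["other.p1.t1"] == ".").sum() == 1
        assert df.loc[df["ref.1"] == "r4", "other.p1.t1"].iloc[0] == "."

    def test_conflict_resolved_by_block_size(self):
        schema, _, anns = self._setup()
        pairs_big = [(i, f"r{i}", i, f"o{i}") for i in range(1, 6)]
        big = _labeled("ref", "c1", "other", "k1", pairs_big, "ortholog",
                       block_id="big")
        small = _labeled("ref", "c1", "other", "k1",
                         [(1, "r1", 3, "o3")], "ortholog", block_id="small")
        table = fill_table(schema, [small, big], anns)
        col = schema.index_of("other", 1, 1)
        assert table.rows[0].cells[col] == "o1"  # big block won the cell

    def test_unknown_reference_gene_rejected(self):
        schema, labeled, anns = self._setup()
        labeled[0].block.anchors.append((9, 9, 90.0, "ghost", "o9"))
        with pytest.raises(ValueError, match="ghost"):
            fill_table(schema, labeled, anns)

    def test_target_gene_occupies_one_cell_per_column(self):
        schema, _, anns = self._setup()
        dup = _labeled("ref", "c1", "other", "k1",
                       [(1, "r1", 2, "o2"), (3, "r3", 4, "o4")], "ortholog",
                       block_id="dup1")
        dup2 = _labeled("ref", "c1", "other", "k1",
                        [(5, "r5", 2, "o2")], "ortholog", block_id="dup2")
        table = fill_table(schema, [dup, dup2], anns)
        col = schema.index_of("other", 1, 1)
        cells = [row.cells.get(col) for row in table.rows]
        assert cells.count("o2") == 1


class TestExtractRegion:
    def _table(self):
        schema, labeled, anns = TestFillTable()._setup()
        return fill_table(schema, labeled, anns)

    def test_full_range_is_identity(self):
        table = self._table()
        sub = extract_region(table, "c1", rank_start=1, rank_end=6)
        assert [r.ref_gene for r in sub.rows] == [r.ref_gene for r in table.rows]

    def test_rank_interval_inclusive(self):
        table = self._table()
        sub = extract_region(table, "c1", rank_start=2, rank_end=4)
        assert len(sub.rows) == 3

    def test_bp_query_matches_equivalent_rank_query(self):
        table = self._table()
        by_rank = extract_region(table, "c1", rank_start=2, rank_end=4)
        bp_start = table.rows[1].ref_start_bp
        bp_end = table.rows[3].ref_end_bp
        by_bp = extract_region(table, "c1", bp_start=bp_start, bp_end=bp_end)
        assert [r.ref_gene for r in by_bp.rows] == [
            r.ref_gene for r in by_rank.rows]

    def test_empty_region_is_empty_table(self):
        sub = extract_region(self._table(), "c1", rank_start=50, rank_end=60)
        assert sub.rows == []


class TestSummarizeHomology:
    def _blocks(self):
        pairs6 = [(i, f"r{i}", i, f"o{i}") for i in range(1, 7)]
        pairs4 = [(i, f"r{i}", i + 1, f"p{i + 1}") for i in range(1, 5)]
        return [
            _labeled("ref", "c1", "other", "k1", pairs6, "ortholog",
                     block_id="x").block,
            _labeled("ref", "c1", "other", "k1", pairs4, "ortholog",
                     block_id="y").block,
        ]

    def _anns(self):
        return {
            "ref": _ann("ref", "c1", [f"r{i}" for i in range(1, 7)]),
            "other": _ann("other", "k1", [f"o{i}" for i in range(1, 7)]),
        }

    def test_counts_monotone_in_threshold(self):
        s = summarize_homology(self._blocks(), self._anns(),
                               thresholds=(4, 5, 6, 7))
        prev_blocks, prev_pairs = None, None
        for t in s.thresholds:
            b = s.block_counts[t].loc["ref", "other"]
            p = s.pair_counts[t].loc["ref", "other"]
            if prev_blocks is not None:
                assert b <= prev_blocks
                assert p <= prev_pairs
            prev_blocks, prev_pairs = b, p
        assert s.block_counts[4].loc["ref", "other"] == 2
        assert s.block_counts[5].loc["ref", "other"] == 1
        assert s.pair_counts[4].loc["ref", "other"] == 10

    def test_gene_counts_report_each_side(self):
        s = summarize_homology(self._blocks(), self._anns(), thresholds=(4,))
        assert s.gene_counts.loc["ref", "other"] == 6    # r1..r6
        assert s.gene_counts.loc["other", "ref"] == 10   # o1..o6 and p2..p5
        assert s.gene_pct.loc["ref", "other"] == pytest.approx(100.0)

    def test_zero_block_genome_all_zero(self):
        anns = self._anns()
        anns["lonely"] = _ann("lonely", "z1", ["l1", "l2"])
        s = summarize_homology(self._blocks(), anns, thresholds=(4,))
        assert (s.block_counts[4].loc["lonely"] == 0).all()
        assert (s.gene_pct.loc["lonely"] == 0).all()

    def test_matrices_symmetric(self):
        s = summarize_homology(self._blocks(), self._anns(), thresholds=(4,))
        for df in (s.block_counts[4], s.pair_counts[4]):
            pd.testing.assert_frame_equal(df, df.T)
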