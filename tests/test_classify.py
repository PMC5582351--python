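import pytest

from polysyn.classify import (
    EventLabel, LabeledBlock, classify_blocks, expected_multiplicity,
    karyotype_map, recovery_metrics,
)
from polysyn.collinearity import CollinearBlock


def _block(genome_a, chrom_a, genome_b, chrom_b, size, identity,
           ref_start=1, tgt_start=1, block_id="b", step=1):
    anchors = [
        (ref_start + i * step, tgt_start + i * step, identity,
         f"{genome_a}:{chrom_a}:{ref_start + i * step}",
         f"{genome_b}:{chrom_b}:{tgt_start + i * step}")
        for i in range(size)
    ]
    return CollinearBlock(genome_a, chrom_a, genome_b, chrom_b, anchors,
                          "parallel", block_id=block_id, pvalue=1e-6)


class TestExpectedMultiplicity:
    def test_paper_counts(self, poaceae_tree):
        assert expected_multiplicity("rice", poaceae_tree) == 2
        assert expected_multiplicity("maize", poaceae_tree) == 4
        assert expected_multiplicity("wheat", poaceae_tree) == 6

    def test_total_columns_over_preset(self, poaceae_tree):
        total = sum(expected_multiplicity(g, poaceae_tree)
                    for g in poaceae_tree.genome_ids())
        assert total == 24

    def test_unknown_genome_rejected(self, poaceae_tree):
        with pytest.raises(ValueError, match="unknown"):
            expected_multiplicity("tomato", poaceae_tree)


class TestClassifyBlocks:
    def test_big_similar_block_beats_small_diverged_block(self, poaceae_tree):
        big = _block("rice", "c1", "sorghum", "c1", 40, 92.0, block_id="big")
        # the diverged block covers the same reference segment, sparsely
        small = _block("rice", "c1", "sorghum", "c1-gct", 8, 78.0,
                       tgt_start=3, block_id="small", step=5)
        labeled = {lb.block.block_id: lb
                   for lb in classify_blocks([small, big], poaceae_tree, "rice")}
        assert labeled["big"].label.relation == "ortholog"
        assert labeled["small"].label.relation == "gct_paralog"
        assert labeled["big"].subgenome_track == 1

    def test_diploid_self_blocks_are_root_wgd_paralogs(self, poaceae_tree):
        blocks = [
            _block("sorghum", "c1", "sorghum", "c1-gct", 12, 61.0, block_id="x"),
            _block("sorghum", "c2", "sorghum", "c2-gct", 5, 60.0, block_id="y"),
        ]
        for lb in classify_blocks(blocks, poaceae_tree, "rice"):
            assert lb.label.relation == "gct_paralog"
            assert lb.label.event_id == "gct"

    def test_hexaploid_coorthologs_get_distinct_tracks(self, poaceae_tree):
        blocks = [
            _block("rice", "c1", "wheat", f"{sub}.c1", 30, 90.0 - i,
                   block_id=f"w{sub}")
            for i, sub in enumerate("ABD")
        ] + [
            _block("rice", "c1", "wheat", f"{sub}.c1-gct", 20, 60.0,
                   block_id=f"g{sub}")
            for sub in "ABD"
        ]
        labeled = classify_blocks(blocks, poaceae_tree, "rice")
        orth = [lb for lb in labeled if lb.label.relation == "ortholog"]
        assert len(orth) == 3
        assert sorted(lb.subgenome_track for lb in orth) == [1, 2, 3]
        rest = [lb for lb in labeled if lb.label.relation == "gct_paralog"]
        assert len(rest) == 3

    def test_classification_invariant_to_block_order(self, poaceae_tree):
        blocks = [
            _block("rice", "c1", "maize", "c1", 25, 82.0, block_id="m1"),
            _block("rice", "c1", "maize", "c1-mst", 22, 82.0, block_id="m2"),
            _block("rice", "c1", "maize", "c1-gct", 15, 61.0, block_id="m3"),
        ]
        fwd = classify_blocks(blocks, poaceae_tree, "rice")
        rev = classify_blocks(blocks[::-1], poaceae_tree, "rice")
        as_map = lambda ls: {lb.block.block_id: (lb.label.relation,
                                                 lb.subgenome_track)
                             for lb in ls}
        assert as_map(fwd) == as_map(rev)

    def test_exact_tie_at_quota_boundary_left_unassigned(self, poaceae_tree):
        tie1 = _block("rice", "c1", "sorghum", "c1", 10, 80.0, block_id="t1")
        tie2 = _block("rice", "c1", "sorghum", "c2", 10, 80.0, tgt_start=1,
                      block_id="t2")
        labeled = classify_blocks([tie1, tie2], poaceae_tree, "rice")
        assert {lb.label.relation for lb in labeled} == {"unassigned"}


class TestKaryotypeMap:
    def test_fraction_accounting(self, poaceae_tree, clean_sim):
        ref_ann = clean_sim.annotations["rice"]
        n = ref_ann.chromosome_length("c1")
        lb = LabeledBlock(
            _block("rice", "c1", "sorghum", "c1", n, 85.0),
            EventLabel("ortholog", "root", 1.0), 1, "a")
        df = karyotype_map([lb], ref_ann)
        assert len(df) == 1
        row = df.iloc[0]
        assert row["fraction"] == pytest.approx(1.0)
        assert not row["split"]

    def test_split_flag_for_two_strong_targets(self, poaceae_tree, clean_sim):
        ref_ann = clean_sim.annotations["rice"]
        n = ref_ann.chromosome_length("c1")
        half = n // 2
        lbs = [
            LabeledBlock(
                _block("rice", "c1", "brachypodium", "c1", half, 85.0),
                EventLabel("ortholog", "root", 1.0), 1, "a"),
            LabeledBlock(
                _block("rice", "c1", "brachypodium", "c1.fis", n - half, 85.0,
                       ref_start=half + 1),
                EventLabel("ortholog", "root", 1.0), 1, "a"),
        ]
        df = karyotype_map(lbs, ref_ann)
        assert df["split"].all()
        assert len(df) == 2


class TestRecoveryMetrics:
    def test_metrics_bounded(self, noisy_sim):
        # metrics computed on hand-made labels stay within [0, 1]
        lb = LabeledBlock(
            _block("rice", "c1", "sorghum", "c1", 5, 85.0),
            EventLabel("ortholog", "split_rice", 1.0), 1, "a")
        genome_of = {g.gene_id: ann.genome_id
                     for ann in noisy_sim.annotations.values() for g in ann}
        m = recovery_metrics([lb], noisy_sim.truth, genome_of)
        assert ((m[["precision", "recall", "f1"]] >= 0).all().all())
        assert ((m[["precision", "recall", "f1"]] <= 1).all().all())
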