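import dataclasses

import numpy as np
import pandas as pd
import pytest

from polysyn.simulate import (
    Event, EventTree, Merge, SimulationConfig, SimulationResult, TreeNode,
    apply_rearrangements, build_event_tree, emit_hits, evolve_genomes,
)


def _single_lineage_tree(with_wgd=True):
    wgds = [Event("wgd1", "wgd", 50.0)] if with_wgd else []
    return EventTree(root=TreeNode("only", 0.0, branch_wgds=wgds))


class TestBuildEventTree:
    def test_minimal_two_tip_tree(self):
        tree = build_event_tree({
            "topology": {"name": "root", "time": 10,
                         "children": [{"name": "a"}, {"name": "b"}]},
        })
        assert tree.tip_names() == ["a", "b"]
        assert not tree.has_root_wgd()
        assert tree.speciation_between("a", "b").time == 10

    def test_poaceae9_composition(self, poaceae_tree):
        genomes = poaceae_tree.genome_ids()
        assert len(genomes) == 9
        from polysyn.classify import expected_multiplicity

        mults = sorted(expected_multiplicity(g, poaceae_tree) for g in genomes)
        assert mults.count(4) == 1   # the extra-WGD (maize-like) genome
        assert mults.count(6) == 1   # the hexaploid
        assert mults.count(2) == 7

    def test_merge_younger_than_donor_speciations_accepted(self):
        spec = {
            "topology": {"name": "root", "time": 10, "children": [
                {"name": "a"}, {"name": "b"}]},
            "merges": [{"id": "mix", "time": 1, "genome": "poly",
                        "donors": {"X": "a", "Y": "b"}}],
        }
        tree = build_event_tree(spec)
        assert tree.genome_ids() == ["poly"]

    def test_reversed_times_rejected(self):
        with pytest.raises(ValueError, match="younger"):
            build_event_tree({
                "topology": {"name": "root", "time": 5, "children": [
                    {"name": "mid", "time": 8, "children": [
                        {"name": "a"}, {"name": "b"}]},
                    {"name": "c"}]},
            })
        with pytest.raises(ValueError, match="older"):
            build_event_tree({
                "topology": {"name": "root", "time": 5, "children": [
                    {"name": "a"}, {"name": "b"}]},
                "merges": [{"id": "mix", "time": 7, "genome": "p",
                            "donors": {"X": "a", "Y": "b"}}],
            })

    def test_single_donor_merge_rejected(self):
        with pytest.raises(ValueError, match=">= 2"):
            build_event_tree({
                "topology": {"name": "root", "time": 5, "children": [
                    {"name": "a"}, {"name": "b"}]},
                "merges": [{"id": "mix", "time": 1, "genome": "p",
                            "donors": {"X": "a"}}],
            })


class TestEvolveGenomes:
    def test_wgd_without_loss_doubles_gene_count(self):
        cfg = SimulationConfig(
            n_ancestral_genes=80, n_chromosomes=2, loss_rate_per_copy=0.0,
            tandem_rate=0.0, inversion_rate=0.0, translocation_rate=0.0,
            seed=1)
        res = evolve_genomes(_single_lineage_tree(), cfg)
        (ann,) = res.annotations.values()
        assert ann.n_genes == 160
        assert len(res.truth) == 80
        assert set(res.truth["relation"]) == {"wgd1_paralog"}

    def test_post_wgd_retention_is_binomial(self):
        """Duplicate pairs survive fractionation with probability (1-f)^2."""
        f, n = 0.3, 100
        retained = []
        for seed in range(120):
            cfg = SimulationConfig(
                n_ancestral_genes=n, n_chromosomes=1, loss_rate_per_copy=f,
                tandem_rate=0.0, inversion_rate=0.0, translocation_rate=0.0,
                seed=seed)
            res = evolve_genomes(_single_lineage_tree(), cfg)
            retained.append(len(res.truth))
        mean = np.mean(retained)
        expect = n * (1 - f) ** 2
        sd_of_mean = np.sqrt(n * (1 - f) ** 2 * (1 - (1 - f) ** 2) / len(retained))
        assert abs(mean - expect) <= 3 * sd_of_mean

    def test_same_seed_identical_outputs(self, poaceae_tree):
        cfg = SimulationConfig(n_ancestral_genes=60, seed=17)
        a = evolve_genomes(poaceae_tree, cfg)
        b = evolve_genomes(poaceae_tree, cfg)
        pd.testing.assert_frame_equal(a.truth, b.truth)
        for g in a.annotations:
            ga = [(x.gene_id, x.chromosome, x.rank) for x in a.annotations[g]]
            gb = [(x.gene_id, x.chromosome, x.rank) for x in b.annotations[g]]
            assert ga == gb
        pd.testing.assert_frame_equal(emit_hits(a), emit_hits(b))

    def test_extreme_loss_warns_not_crashes(self):
        cfg = SimulationConfig(
            n_ancestral_genes=5, n_chromosomes=1, loss_rate_per_copy=1.0,
            tandem_rate=0.0, inversion_rate=0.0, translocation_rate=0.0,
            seed=0)
        with pytest.warns(UserWarning, match="lost all genes"):
            res = evolve_genomes(_single_lineage_tree(), cfg)
        assert res.empty_genomes == ["only"]

    def test_truth_pairs_unique_and_canonical(self, noisy_sim):
        t = noisy_sim.truth
        assert (t["gene_a"] < t["gene_b"]).all()
        assert not t.duplicated(["gene_a", "gene_b"]).any()


class TestRearrangements:
    def test_zero_rates_identity(self, clean_sim):
        ann = clean_sim.annotations["rice"]
        out = apply_rearrangements(ann, 0, 0, 0, rng=0)
        assert [(g.gene_id, g.chromosome, g.rank) for g in out] == [
            (g.gene_id, g.chromosome, g.rank) for g in ann]

    def test_gene_content_conserved(self, clean_sim):
        ann = clean_sim.annotations["rice"]
        out = apply_rearrangements(ann, 5, 3, 2, rng=4)
        assert sorted(g.gene_id for g in out) == sorted(g.gene_id for g in ann)

    def test_fission_splits_named_chromosome(self, clean_sim):
        ann = clean_sim.annotations["rice"]
        out = apply_rearrangements(ann, 0, 0, ["c1"], rng=7)
        assert len(out.chromosomes) == len(ann.chromosomes) + 1
        assert "c1.fis" in out.chromosomes

    def test_fission_on_tiny_chromosome_skipped(self, caplog):
        from polysyn.model import Gene, GenomeAnnotation

        ann = GenomeAnnotation("g", {"c1": [Gene("a", "g", "c1", 1, 1, 10)]})
        out = apply_rearrangements(ann, 0, 0, ["c1"], rng=0)
        assert list(out.chromosomes) == ["c1"]


class TestEmitHits:
    def test_zero_divergence_zero_noise_gives_identity_100(self, poaceae_tree):
        cfg = SimulationConfig(identity_noise_sd=0.0, spurious_fraction=0.0)
        truth = pd.DataFrame(
            [("x_a", "x_b", "e", "ortholog", 0.0)],
            columns=["gene_a", "gene_b", "event_id", "relation",
                     "divergence_time"])
        res = SimulationResult(poaceae_tree, cfg, {}, truth)
        hits = emit_hits(res)
        assert (hits["identity"] == 100.0).all()

    def test_orthologs_more_similar_than_wgd_paralogs(self, noisy_sim):
        hits = emit_hits(noisy_sim)
        t = noisy_sim.truth
        merged = hits.merge(
            t, left_on=["query", "subject"], right_on=["gene_a", "gene_b"])
        means = merged.groupby("relation")["identity"].mean()
        assert means["ortholog"] > means["gct_paralog"]

    def test_all_true_pairs_pass_evalue_cutoff(self, noisy_sim):
        hits = emit_hits(noisy_sim)
        t = noisy_sim.truth
        merged = hits.merge(
            t, left_on=["query", "subject"], right_on=["gene_a", "gene_b"])
        assert len(merged) == len(t)
        assert (merged["evalue"] < 1e-5).all()

    def test_hits_symmetric_per_pair(self, noisy_sim):
        hits = emit_hits(noisy_sim)
        fwd = set(map(tuple, hits[["query", "subject"]].itertuples(index=False)))
        assert all((s, q) in fwd for q, s in fwd)

    def test_negative_noise_rejected(self):
        with pytest.raises(ValueError, match="identity_noise_sd"):
            SimulationConfig(identity_noise_sd=-1.0)
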