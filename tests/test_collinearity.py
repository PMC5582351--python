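import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from polysyn.anchors import AnchorSet
from polysyn.collinearity import (
    ChainParams, CollinearBlock, analytic_pvalue, block_pvalue, chain_anchors,
    export_dotplot, filter_blocks, permutation_pvalue, score_blocks,
)

from oracle import brute_force_max_chain


def _aset(pairs, len_a=100, len_b=100):
    anchors = sorted((ra, rb, 90.0, f"a{ra}", f"b{rb}") for ra, rb in pairs)
    return AnchorSet("A", "c1", "B", "k1", len_a, len_b, anchors)


def _max_chain(pairs, max_gap=50):
    params = ChainParams(max_gap=max_gap, min_size=2)
    blocks = chain_anchors(_aset(pairs, 2000, 2000), params)
    return blocks[0].size if blocks else min(1, len(pairs))


class TestChaining:
    def test_perfect_diagonal_single_parallel_block(self):
        blocks = chain_anchors(_aset([(1, 1), (2, 2), (3, 3), (4, 4)]))
        assert len(blocks) == 1
        assert blocks[0].orientation == "parallel"
        assert blocks[0].size == 4

    def test_gap_breaks_chain(self):
        pairs = [(1, 1), (2, 2), (3, 3), (60, 4)]
        # gap 60-3-1 = 56 > 50 between ranks 3 and 60 breaks the chain
        assert _max_chain(pairs) == 3
        assert chain_anchors(_aset(pairs), ChainParams(min_size=4)) == []

    def test_antidiagonal_single_inverted_block(self):
        blocks = chain_anchors(_aset([(1, 5), (2, 4), (3, 3), (4, 2), (5, 1)]))
        assert len(blocks) == 1
        assert blocks[0].orientation == "inverted"
        assert blocks[0].size == 5

    def test_blocks_are_anchor_disjoint(self):
        pairs = [(i, i) for i in range(1, 9)] + [(i, 20 - i) for i in range(1, 9)]
        blocks = chain_anchors(_aset(pairs), ChainParams(min_size=2))
        seen = set()
        for b in blocks:
            for a in b.anchors:
                key = (a[0], a[1])
                assert key not in seen
                seen.add(key)

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(42)
        for trial in range(250):
            n = int(rng.integers(1, 16))
            max_gap = int(rng.integers(1, 60))
            ra = rng.choice(np.arange(1, 40), size=n, replace=False)
            rb = rng.choice(np.arange(1, 40), size=n, replace=False)
            pairs = list(zip(ra.tolist(), rb.tolist()))
            expect = brute_force_max_chain(pairs, max_gap + 1)
            assert _max_chain(pairs, max_gap) == expect, (pairs, max_gap)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.lists(
        st.tuples(st.integers(1, 30), st.integers(1, 30)),
        min_size=1, max_size=12, unique_by=(lambda p: p[0], lambda p: p[1]),
    ))
    def test_chain_output_invariant_to_anchor_order(self, pairs):
        params = ChainParams(min_size=2)
        base = chain_anchors(_aset(pairs), params)
        rev = AnchorSet("A", "c1", "B", "k1", 100, 100,
                        list(reversed(_aset(pairs).anchors)))
        again = chain_anchors(rev, params)
        assert [b.anchors for b in again] == [b.anchors for b in base]


class TestSignificance:
    def test_single_anchor_block_has_p_one_both_methods(self):
        for method in ("analytic", "permutation"):
            params = ChainParams(pvalue_method=method, n_permutations=200)
            aset = _aset([(5, 5)])
            block = CollinearBlock("A", "c1", "B", "k1",
                                   [(5, 5, 90.0, "a", "b")], "parallel")
            assert block_pvalue(block, aset, params=params) == 1.0

    def test_long_diagonal_is_significant(self):
        p = permutation_pvalue(10, 10, (100, 100),
                               ChainParams(n_permutations=10000), seed=1)
        assert p < 0.05
        assert analytic_pvalue(10, 10, (100, 100)) < 0.05

    def test_permutation_reproducible_for_fixed_seed(self):
        params = ChainParams(n_permutations=500, seed=9)
        p1 = permutation_pvalue(20, 6, (120, 150), params)
        p2 = permutation_pvalue(20, 6, (120, 150), params)
        assert p1 == p2

    def test_exact_small_case_matches_permutation(self):
        # gap bound cannot bind on a 50-gene chromosome: the analytic value
        # is the exact RSK computation and must sit within Monte-Carlo error
        params = ChainParams(n_permutations=20000)
        pa = analytic_pvalue(10, 5, (50, 50), params)
        pp = permutation_pvalue(10, 5, (50, 50), params, seed=3)
        se = np.sqrt(pp * (1 - pp) / params.n_permutations)
        assert abs(pa - pp) <= 3 * se

    def test_dims_smaller_than_ranks_rejected(self):
        aset = _aset([(5, 5), (6, 6), (7, 7), (8, 8)])
        block = chain_anchors(aset)[0]
        with pytest.raises(ValueError, match="dims"):
            block_pvalue(block, aset, dims=(4, 10))


class TestFilterBlocks:
    def _block(self, size, pvalue):
        anchors = [(i, i, 90.0, f"a{i}", f"b{i}") for i in range(1, size + 1)]
        return CollinearBlock("A", "c1", "B", "k1", anchors, "parallel",
                              block_id="b", pvalue=pvalue)

    def test_alpha_threshold_is_strict(self):
        kept = filter_blocks([self._block(6, 0.049), self._block(6, 0.05)])
        assert len(kept) == 1
        assert kept[0].pvalue == 0.049

    def test_min_size_enforced_regardless_of_p(self):
        assert filter_blocks([self._block(3, 1e-10)]) == []

    def test_empty_in_empty_out(self):
        assert filter_blocks([]) == []


class TestExportDotplot:
    def test_every_anchor_row_carries_block_or_dot(self, tmp_path):
        aset = _aset([(1, 1), (2, 2), (3, 3), (4, 4), (30, 90)])
        params = ChainParams()
        blocks = filter_blocks(score_blocks(aset, params), params)
        out = tmp_path / "dots.tsv"
        export_dotplot(aset, blocks, out)
        lines = [l for l in out.read_text().splitlines()
                 if not l.startswith("#")][1:]
        assert len(lines) == len(aset.anchors)
        ids = {l.split("\t")[-1] for l in lines}
        assert "." in ids
        assert {b.block_id for b in blocks} == ids - {"."}
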