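"""Anchor detection, collinear chaining, duplicate classification."""

import itertools

import numpy as np
import pytest

from genefam import simulate, synteny
from genefam.synteny import (
    AnchorPair, chain_anchors, classify_duplicates, find_homolog_pairs,
    summarize_duplication,
)
from genefam.types import CodingGene


def _gene(gid, chrom, rank, protein="MKVLSTAGRN" * 10):
    return CodingGene(id=gid, chromosome=chrom, start=1 + rank * 1000,
                      end=rank * 1000 + 300, cds="", protein=protein, rank=rank)


def _anchor(gid_a, chrom_a, rank_a, gid_b, chrom_b, rank_b):
    return AnchorPair(_gene(gid_a, chrom_a, rank_a),
                      _gene(gid_b, chrom_b, rank_b), 100.0, 0.9)


class TestHomologPairs:
    def test_identical_proteins_maximal_score(self):
        genes = [_gene("a", "chr1", 0), _gene("b", "chr2", 0)]
        pairs = find_homolog_pairs(genes)
        assert len(pairs) == 1
        assert pairs[0].norm_score == pytest.approx(1.0)

    def test_unrelated_proteins_no_pair(self):
        rng = np.random.default_rng(0)
        genes = [CodingGene(id=f"g{i}", cds=simulate.random_cds(rng, 200))
                 for i in range(8)]
        assert find_homolog_pairs(genes) == []

    def test_planted_paralog_set_all_pairs(self):
        prot = "MKVDESTRGH" * 12
        genes = [_gene(f"g{i}", "chr1", i, prot) for i in range(4)]
        assert len(find_homolog_pairs(genes)) == 6  # C(4,2)


class TestChaining:
    def test_perfect_block(self):
        anchors = [_anchor(f"a{i}", "chr1", i, f"b{i}", "chr2", i)
                   for i in range(6)]
        blocks = chain_anchors(anchors, min_anchors=5)
        assert len(blocks) == 1
        assert len(blocks[0].anchors) == 6
        assert blocks[0].orientation == "+"

    def test_inverted_block(self):
        anchors = [_anchor(f"a{i}", "chr1", i, f"b{i}", "chr2", 10 - i)
                   for i in range(6)]
        blocks = chain_anchors(anchors, min_anchors=5)
        assert len(blocks) == 1
        assert blocks[0].orientation == "-"

    def test_stray_anchor_unblocked(self):
        anchors = [_anchor(f"a{i}", "chr1", i, f"b{i}", "chr2", i)
                   for i in range(6)]
        anchors.append(_anchor("x", "chr1", 3, "y", "chr2", 20))
        blocks = chain_anchors(anchors, min_anchors=5)
        assert len(blocks) == 1
        ids = {a.gene_a.id for a in blocks[0].anchors}
        assert ids == {f"a{i}" for i in range(6)}

    def test_below_min_anchors_no_block(self):
        anchors = [_anchor(f"a{i}", "chr1", i, f"b{i}", "chr2", i)
                   for i in range(4)]
        assert chain_anchors(anchors, min_anchors=5) == []

    def test_max_gap_splits_chain(self):
        anchors = [_anchor(f"a{i}", "chr1", i, f"b{i}", "chr2", i)
                   for i in range(5)]
        anchors += [_anchor(f"c{i}", "chr1", 100 + i, f"d{i}", "chr2", 100 + i)
                    for i in range(5)]
        blocks = chain_anchors(anchors, min_anchors=5, max_gap=25)
        assert len(blocks) == 2

    def test_dp_matches_exhaustive_search(self):
        """DP chain equals the best monotone subset on small instances."""
        rng = np.random.default_rng(1)
        for rep in range(20):
            n = int(rng.integers(4, 11))
            pts = [(int(rng.integers(0, 15)), int(rng.integers(0, 15)))
                   for _ in range(n)]
            pts = list(dict.fromkeys(pts))
            max_gap = 6

            def chain_ok(sub, sign):
                for (a1, b1), (a2, b2) in zip(sub, sub[1:]):
                    if not (0 < a2 - a1 <= max_gap
                            and 0 < sign * (b2 - b1) <= max_gap):
                        return False
                return True

            best = 1
            ordered = sorted(pts)  # chains are increasing in the first rank
            for r in range(2, len(ordered) + 1):
                for sub in itertools.combinations(ordered, r):
                    if chain_ok(sub, +1) or chain_ok(sub, -1):
                        best = max(best, r)
            anchors = [_anchor(f"a{i}", "chr1", a, f"b{i}", "chr2", b)
                       for i, (a, b) in enumerate(pts)]
            blocks = chain_anchors(anchors, min_anchors=1, max_gap=max_gap)
            got = max((len(b.anchors) for b in blocks), default=0)
            assert got == best, (pts, got, best)


class TestClassification:
    def test_pair_in_block_segmental(self):
        anchors = [_anchor(f"a{i}", "chr1", i, f"b{i}", "chr2", i)
                   for i in range(6)]
        blocks = chain_anchors(anchors, min_anchors=5)
        calls = classify_duplicates(anchors, blocks)
        assert all(c.type == "segmental" for c in calls)
        assert all(c.support_id for c in calls)

    def test_adjacent_paralogs_tandem(self):
        pair = [_anchor("a", "chr1", 5, "b", "chr1", 6)]
        calls = classify_duplicates(pair, [])
        assert calls[0].type == "tandem"

    def test_distant_same_chromosome_dispersed(self):
        pair = [_anchor("a", "chr1", 5, "b", "chr1", 205)]
        calls = classify_duplicates(pair, [])
        assert calls[0].type == "dispersed"

    def test_partition_property(self, planted_genome):
        _, fx = planted_genome
        anchors = find_homolog_pairs(fx.genes)
        blocks = chain_anchors(anchors)
        calls = classify_duplicates(anchors, blocks)
        assert len(calls) == len(anchors)
        assert all(c.type in {"segmental", "tandem", "dispersed"} for c in calls)

    def test_missing_rank_rejected(self):
        a = _gene("a", "chr1", 0)
        b = _gene("b", "chr1", 1)
        b.rank = None
        with pytest.raises(ValueError):
            classify_duplicates([AnchorPair(a, b, 1.0, 0.9)], [])


class TestSummary:
    def _calls(self, pairs):
        return [synteny.DuplicationCall(a, b, "segmental", "blk") for a, b in pairs]

    def test_maize_style_percentage(self):
        # 18 pairs covering 24 distinct genes out of a 31-gene family
        pairs = [(f"g{i}", f"g{i + 12}") for i in range(12)]
        pairs += [(f"g{i}", f"g{i + 6}") for i in range(6)]
        calls = self._calls(pairs)
        genes = {g for p in pairs for g in p}
        assert len(calls) == 18 and len(genes) == 24
        summary = summarize_duplication(calls, [f"g{i}" for i in range(31)])
        assert summary.pct_segmental == 77.4

    def test_half_of_family(self):
        calls = self._calls([("a1", "a2"), ("a3", "a4"), ("a5", "a6"),
                             ("a7", "a8"), ("a1", "a9")])
        summary = summarize_duplication(calls, [f"a{i}" for i in range(1, 19)])
        assert summary.n_segmental_genes == 9
        assert summary.pct_segmental == 50.0

    def test_no_pairs(self):
        summary = summarize_duplication([], ["a", "b", "c"])
        assert summary.pct_segmental == 0.0

    def test_empty_family_rejected(self):
        with pytest.raises(ValueError):
            summarize_duplication([], [])


class TestPlantedRecovery:
    def test_blocks_and_tandem_recovered(self, planted_genome):
        _, fx = planted_genome
        anchors = find_homolog_pairs(fx.genes)
        blocks = chain_anchors(anchors)
        truth = set(map(tuple, fx.truth_anchors[["gene_a", "gene_b"]]
                        .apply(sorted, axis=1)))
        found = set().union(*[b.pairs for b in blocks]) if blocks else set()
        assert found == truth
        calls = classify_duplicates(anchors, blocks)
        tandem_genes = set(fx.truth_tandem["gene_id"])
        for c in calls:
            if {c.gene_a, c.gene_b} <= tandem_genes:
                assert c.type == "tandem"

    def test_shuffled_genome_no_blocks(self):
        fx = simulate.simulate_genomes(simulate.GenomeFixtureParams(seed=11))
        anchors = find_homolog_pairs(fx.genes)
        assert chain_anchors(anchors) == []
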