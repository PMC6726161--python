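"""Collinear-block detection and duplicate-pair classification.

Homologous anchor pairs (normalized protein-alignment score above a
cutoff) are chained per chromosome pair and orientation by a
longest-increasing-subsequence style dynamic program over gene-rank
coordinates, MCScan-fashion.  Family duplicate pairs are then labeled
segmental (inside a collinear block), tandem (near-adjacent on one
chromosome), or dispersed, and the classic duplication summary
(distinct duplicated genes as a percentage of the family) is computed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from genefam.kaks import protein_score
from genefam.types import CodingGene


@dataclass
class AnchorPair:
    gene_a: CodingGene
    gene_b: CodingGene
    score: float
    norm_score: float  # score / min(self-scores): bitscore-like significance proxy


@dataclass
class CollinearBlock:
    block_id: str
    chrom_a: str
    chrom_b: str
    orientation: str  # '+' (both increasing) or '-' (second decreasing)
    anchors: list[AnchorPair]

    @property
    def pairs(self) -> set[tuple[str, str]]:
        return {tuple(sorted((a.gene_a.id, a.gene_b.id))) for a in self.anchors}


@dataclass
class DuplicationCall:
    gene_a: str
    gene_b: str
    type: str  # segmental | tandem | dispersed
    support_id: str | None = None


def find_homolog_pairs(
    genes: list[CodingGene],
    score_cutoff: float = 0.5,
) -> list[AnchorPair]:
    """All unordered gene pairs whose normalized alignment score passes.

    The significance proxy is the global BLOSUM62 alignment score
    divided by the smaller of the two self-scores, so identical
    proteins score 1 and unrelated ones near or below 0.  Pairs are
    reported once with gene ids in sorted order.
    """
    ordered = sorted(genes, key=lambda g: g.id)
    self_scores = {g.id: protein_score(g.protein, g.protein) for g in ordered}
    out = []
    for i, ga in enumerate(ordered):
        for gb in ordered[i + 1:]:
            score = protein_score(ga.protein, gb.protein)
            norm = score / min(self_scores[ga.id], self_scores[gb.id])
            if norm >= score_cutoff:
                out.append(AnchorPair(ga, gb, score, norm))
    return out


def _chain_dp(points: list[tuple[int, int, int]], max_gap: int,
              sign: int) -> list[int]:
    """Best monotone chain over (rank_a, rank_b, anchor_index) points.

    rank_a strictly increases; rank_b strictly increases (sign=+1) or
    decreases (sign=-1); consecutive gaps on both axes at most max_gap.
    Returns anchor indices of the heaviest chain (by count), with
    deterministic leftmost tie-breaking.
    """
    pts = sorted(points, key=lambda p: (p[0], sign * p[1], p[2]))
    n = len(pts)
    best = [1] * n
    prev = [-1] * n
    for i in range(n):
        for j in range(i):
            da = pts[i][0] - pts[j][0]
            db = sign * (pts[i][1] - pts[j][1])
            if 0 < da <= max_gap and 0 < db <= max_gap:
                if best[j] + 1 > best[i]:
                    best[i] = best[j] + 1
                    prev[i] = j
    top = max(range(n), key=lambda i: (best[i], -i), default=-1)
    chain = []
    while top != -1:
        chain.append(pts[top][2])
        top = prev[top]
    return chain[::-1]


def chain_anchors(
    anchors: list[AnchorPair],
    min_anchors: int = 5,
    max_gap: int = 25,
) -> list[CollinearBlock]:
    """Chain anchors into collinear blocks per chromosome pair.

    Within each chromosome pair the heaviest monotone chain (either
    orientation) is extracted, its anchors are removed, and the search
    repeats; chains shorter than min_anchors are dropped.  Each anchor
    belongs to at most one block.
    """
    groups: dict[tuple[str, str], list[AnchorPair]] = {}
    for anc in anchors:
        ga, gb = anc.gene_a, anc.gene_b
        if ga.rank is None or gb.rank is None:
            raise ValueError(f"anchor {ga.id}-{gb.id} lacks gene ranks")
        if (gb.chromosome, gb.rank) < (ga.chromosome, ga.rank):
            anc = AnchorPair(gb, ga, anc.score, anc.norm_score)
        groups.setdefault((anc.gene_a.chromosome, anc.gene_b.chromosome),
                          []).append(anc)

    blocks: list[CollinearBlock] = []
    counter = 0
    for (ca, cb), group in sorted(groups.items()):
        remaining = list(group)
        while True:
            points = [(a.gene_a.rank, a.gene_b.rank, i)
                      for i, a in enumerate(remaining)]
            if not points:
                break
            fwd = _chain_dp(points, max_gap, +1)
            rev = _chain_dp(points, max_gap, -1)
            chain, orient = (fwd, "+") if len(fwd) >= len(rev) else (rev, "-")
            if len(chain) < min_anchors:
                break
            counter += 1
            blocks.append(CollinearBlock(
                block_id=f"block{counter}", chrom_a=ca, chrom_b=cb,
                orientation=orient,
                anchors=[remaining[i] for i in chain]))
            used = set(chain)
            remaining = [a for i, a in enumerate(remaining) if i not in used]
    return blocks


def classify_duplicates(
    family_pairs: list[AnchorPair],
    blocks: list[CollinearBlock],
    tandem_max_rank_gap: int = 10,
) -> list[DuplicationCall]:
    """Label each family duplicate pair segmental, tandem, or dispersed.

    A pair inside a collinear block is segmental; a same-chromosome pair
    within tandem_max_rank_gap gene ranks and not in a block is tandem;
    everything else is dispersed.  The labels partition the pairs.
    """
    in_block: dict[tuple[str, str], str] = {}
    for blk in blocks:
        for pair in blk.pairs:
            in_block.setdefault(pair, blk.block_id)
    calls = []
    for anc in family_pairs:
        ga, gb = anc.gene_a, anc.gene_b
        if ga.rank is None or gb.rank is None:
            raise ValueError(f"pair {ga.id}-{gb.id} lacks gene ranks")
        key = tuple(sorted((ga.id, gb.id)))
        if key in in_block:
            calls.append(DuplicationCall(*key, "segmental", in_block[key]))
        elif (ga.chromosome == gb.chromosome
              and abs(ga.rank - gb.rank) <= tandem_max_rank_gap):
            calls.append(DuplicationCall(*key, "tandem"))
        else:
            calls.append(DuplicationCall(*key, "dispersed"))
    return calls


@dataclass
class DuplicationSummary:
    n_segmental_pairs: int
    n_tandem_pairs: int
    n_dispersed_pairs: int
    n_segmental_genes: int
    family_size: int
    pct_segmental: float  # percentage of the family, 1 decimal


def summarize_duplication(
    calls: list[DuplicationCall],
    family_genes: list[str],
) -> DuplicationSummary:
    """Duplication census: distinct segmental genes over family size."""
    if not family_genes:
        raise ValueError("empty family")
    seg_genes = {g for c in calls if c.type == "segmental"
                 for g in (c.gene_a, c.gene_b)}
    by_type = {"segmental": 0, "tandem": 0, "dispersed": 0}
    for c in calls:
        by_type[c.type] += 1
    return DuplicationSummary(
        n_segmental_pairs=by_type["segmental"],
        n_tandem_pairs=by_type["tandem"],
        n_dispersed_pairs=by_type["dispersed"],
        n_segmental_genes=len(seg_genes),
        family_size=len(set(family_genes)),
        pct_segmental=round(100.0 * len(seg_genes) / len(set(family_genes)), 1),
    )


def blocks_table(blocks: list[CollinearBlock]) -> pd.DataFrame:
    rows = []
    for blk in blocks:
        for anc in blk.anchors:
            rows.append({
                "block_id": blk.block_id, "chrom_a": blk.chrom_a,
                "chrom_b": blk.chrom_b, "orientation": blk.orientation,
                "gene_a": anc.gene_a.id, "gene_b": anc.gene_b.id,
                "rank_a": anc.gene_a.rank, "rank_b": anc.gene_b.rank,
                "norm_score": round(anc.norm_score, 3),
            })
    return pd.DataFrame(rows, columns=[
        "block_id", "chrom_a", "chrom_b", "orientation",
        "gene_a", "gene_b", "rank_a", "rank_b", "norm_score"])


def calls_table(calls: list[DuplicationCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"gene_a": c.gene_a, "gene_b": c.gene_b, "type": c.type,
          "support_id": c.support_id or ""} for c in calls],
        columns=["gene_a", "gene_b", "type", "support_id"])
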