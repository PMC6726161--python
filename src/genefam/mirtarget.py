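"""miRNA target-site scanning with an expectation (penalty) score.

Transcripts (CDS + 3' UTR) are scanned ungapped for windows
complementary to the mature miRNA.  Per position, a Watson-Crick pair
costs 0, a G:U wobble 0.5, and a mismatch 1; penalties are doubled in
the seed region (miRNA positions 2-13 from the 5' end).  Lower
expectation means better complementarity; sites at or below the cutoff
(default 3) are reported, the best-scoring site winning overlaps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd

from genefam.types import CodingGene

RNA_ALPHABET = set("ACGU")

#: Watson-Crick partners on the DNA target strand, keyed by miRNA base.
WC_PARTNER = {"A": "T", "U": "A", "G": "C", "C": "G"}
#: G:U wobble partners on the target strand.
WOBBLE_PARTNER = {"G": "T", "U": "G"}


@dataclass
class MirQuery:
    """A mature miRNA, 5'->3', RNA alphabet, 20-24 nt."""

    sequence: str
    seed_start: int = 2
    seed_end: int = 13

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper().replace("T", "U")
        if not 20 <= len(self.sequence) <= 24:
            raise ValueError("mature miRNA must be 20-24 nt")
        bad = set(self.sequence) - RNA_ALPHABET
        if bad:
            raise ValueError(f"non-RNA characters in miRNA: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class ScoreScheme:
    mismatch: float = 1.0
    wobble: float = 0.5
    seed_factor: float = 2.0


@dataclass
class TargetSite:
    gene_id: str
    region: str  # "CDS" or "3UTR"
    start: int   # 1-based on the transcript (CDS + 3' UTR)
    end: int     # inclusive
    expectation: float
    alignment: str  # three-line rendering


def _pair_symbol(mir_base: str, target_base: str) -> str:
    t = "T" if target_base == "U" else target_base
    if WC_PARTNER[mir_base] == t:
        return "|"
    if WOBBLE_PARTNER.get(mir_base) == t:
        return "o"
    return " "


def pair_symbols(mirna: MirQuery, window: str) -> str:
    """Pairing string in target orientation: '|' WC, 'o' wobble, ' ' mismatch."""
    window = window.upper()
    L = len(mirna)
    if len(window) != L:
        raise ValueError("window length must equal miRNA length")
    bad = set(window) - set("ACGTU")
    if bad:
        raise ValueError(f"non-nucleotide characters in target: {sorted(bad)}")
    # miRNA position p (1-based, 5'->3') faces target window index L - p
    return "".join(
        _pair_symbol(mirna.sequence[p - 1], window[L - p]) for p in range(L, 0, -1)
    )


def score_site(mirna: MirQuery, window: str, scheme: ScoreScheme | None = None) -> float:
    """Expectation penalty of one ungapped miRNA/target window."""
    scheme = scheme or ScoreScheme()
    symbols = pair_symbols(mirna, window)
    L = len(mirna)
    total = 0.0
    for idx, sym in enumerate(symbols):
        p = L - idx  # miRNA position facing this target column
        if sym == "|":
            continue
        penalty = scheme.wobble if sym == "o" else scheme.mismatch
        if mirna.seed_start <= p <= mirna.seed_end:
            penalty *= scheme.seed_factor
        total += penalty
    return total


def render_alignment(mirna: MirQuery, window: str,
                     scheme: ScoreScheme | None = None) -> str:
    """Three-line target/pairing/miRNA rendering of a scored site."""
    window = window.upper()
    symbols = pair_symbols(mirna, window)
    target_line = f"target 5' {window} 3'"
    pair_line = f"          {symbols}   "
    mir_line = f"miRNA  3' {mirna.sequence[::-1]} 5'"
    return "\n".join([target_line, pair_line, mir_line])


def expectation_from_alignment(rendered: str, mirna: MirQuery,
                               scheme: ScoreScheme | None = None) -> float:
    """Recompute the expectation from a rendered pairing string."""
    scheme = scheme or ScoreScheme()
    symbols = rendered.splitlines()[1][10:10 + len(mirna)]
    L = len(mirna)
    total = 0.0
    for idx, sym in enumerate(symbols):
        p = L - idx
        if sym == "|":
            continue
        penalty = scheme.wobble if sym == "o" else scheme.mismatch
        if mirna.seed_start <= p <= mirna.seed_end:
            penalty *= scheme.seed_factor
        total += penalty
    return total


def scan_targets(
    mirna: MirQuery,
    genes: list[CodingGene],
    max_expectation: float = 3.0,
    scheme: ScoreScheme | None = None,
) -> list[TargetSite]:
    """Scan CDS and 3' UTR of each gene for miRNA-complementary sites.

    Every window of miRNA length on the transcript is scored; windows at
    or below max_expectation are kept, overlaps resolved to the
    best-scoring site (ties to the leftmost).  The region label comes
    from the window midpoint.  Transcripts shorter than the miRNA are
    skipped with a warning.
    """
    scheme = scheme or ScoreScheme()
    L = len(mirna)
    sites: list[TargetSite] = []
    for g in genes:
        tx = g.transcript.upper()
        if len(tx) < L:
            warnings.warn(f"transcript of {g.id} shorter than the miRNA; skipped")
            continue
        candidates = []
        for start in range(len(tx) - L + 1):
            window = tx[start:start + L]
            exp = score_site(mirna, window, scheme)
            if exp <= max_expectation:
                candidates.append((exp, start, window))
        chosen: list[tuple[float, int, str]] = []
        for cand in sorted(candidates, key=lambda c: (c[0], c[1])):
            if all(abs(cand[1] - c[1]) >= L for c in chosen):
                chosen.append(cand)
        for exp, start, window in sorted(chosen, key=lambda c: c[1]):
            mid = start + L // 2
            region = "CDS" if mid < len(g.cds) else "3UTR"
            sites.append(TargetSite(
                gene_id=g.id, region=region, start=start + 1, end=start + L,
                expectation=exp,
                alignment=render_alignment(mirna, window, scheme)))
    return sites


def sites_table(sites: list[TargetSite]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"gene_id": s.gene_id, "region": s.region, "start": s.start,
          "end": s.end, "expectation": s.expectation} for s in sites],
        columns=["gene_id", "region", "start", "end", "expectation"])
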