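"""Gene-family identification and per-protein descriptive statistics.

Family members are recognized by a deterministic two-signature scan for
the SBP-domain zinc fingers (Cys-Cys-Cys-His followed by
Cys-Cys-His-Cys, in order, within a ~76-aa window), standing in for a
profile-HMM search.  Candidates are deduplicated (longest isoform per
gene, identical sequences collapsed), ordered along the chromosomes and
renamed ``<prefix>1..N``.  Descriptive statistics follow the usual
proteomics conventions: average-mass molecular weight, isoelectric
point solved by bisection on the Henderson–Hasselbalch net charge with
a Bjellqvist-style pKa table.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import pandas as pd

from genefam.types import CodingGene

AA20 = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class ScanConfig:
    """Spacing and span bounds of the two zinc-finger signatures.

    The domain (Zn-1 start through Zn-2 end) must span min_span..max_span
    residues, bracketing the ~76-aa SBP consensus.
    """

    min_span: int = 60
    max_span: int = 90
    zn1_pattern: str = r"C.{2,4}?C.{10,20}?C.{2,4}?H"
    zn2_pattern: str = r"C.{2,4}?C.{10,20}?H.{2,4}?C"


@dataclass
class DomainHit:
    """1-based inclusive positions of one domain hit on the protein."""

    start: int
    end: int
    zf1_span: tuple[int, int]
    zf2_span: tuple[int, int]


def _overlapping_matches(pattern: str, seq: str) -> list[tuple[int, int]]:
    """All (0-based start, end-exclusive) minimal matches, overlapping allowed."""
    rx = re.compile(f"(?=({pattern}))")
    return [(m.start(), m.start() + len(m.group(1))) for m in rx.finditer(seq)]


def scan_sbp_domain(protein: str, config: ScanConfig | None = None) -> list[DomainHit]:
    """Scan a protein for SBP-type domains.

    A hit pairs a Zn-1 signature with the earliest Zn-2 signature that
    starts after it and keeps the combined span within the configured
    bounds.  Overlapping candidates resolve to the leftmost.
    """
    config = config or ScanConfig()
    seq = protein.upper()
    if not seq:
        raise ValueError("empty protein sequence")
    zn1 = _overlapping_matches(config.zn1_pattern, seq)
    zn2 = _overlapping_matches(config.zn2_pattern, seq)
    candidates = []
    for s1, e1 in zn1:
        for s2, e2 in zn2:
            if s2 < e1:
                continue
            span = e2 - s1
            if span > config.max_span:
                break
            if span >= config.min_span:
                candidates.append(DomainHit(
                    start=s1 + 1, end=e2,
                    zf1_span=(s1 + 1, e1), zf2_span=(s2 + 1, e2)))
                break
    hits: list[DomainHit] = []
    for hit in sorted(candidates, key=lambda h: (h.start, h.end)):
        if not hits or hit.start > hits[-1].end:
            hits.append(hit)
    return hits


def dedupe_family(
    candidates: list[CodingGene],
    prefix: str = "FAM",
    rename: bool = True,
) -> list[CodingGene]:
    """Collapse redundant candidates and name the family along chromosomes.

    Records with identical protein sequences, or isoforms of one source
    gene, collapse to the longest representative.  Survivors are sorted
    by chromosome then start coordinate and renamed ``<prefix>1..N``.
    The operation is idempotent.
    """
    by_gene: dict[str, CodingGene] = {}
    for cand in candidates:
        key = cand.source_id or cand.id
        prev = by_gene.get(key)
        if prev is None or len(cand.protein) > len(prev.protein):
            by_gene[key] = cand
    by_seq: dict[str, CodingGene] = {}
    for cand in by_gene.values():
        by_seq.setdefault(cand.protein, cand)
    survivors = list(by_seq.values())
    if rename:
        for g in survivors:
            if g.chromosome is None or g.start is None:
                raise ValueError(f"candidate {g.id} lacks coordinates; cannot order")

        def chrom_key(chrom: str):
            m = re.search(r"(\d+)$", chrom)
            return (int(m.group(1)), chrom) if m else (10**9, chrom)

        survivors.sort(key=lambda g: (chrom_key(g.chromosome), g.start))
        survivors = [g.renamed(f"{prefix}{i + 1}") for i, g in enumerate(survivors)]
    return survivors


# Expasy-style average residue masses (Da) and the mass of water.
RESIDUE_MASS = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886, "C": 103.1388,
    "E": 129.1155, "Q": 128.1307, "G": 57.0519, "H": 137.1411, "I": 113.1594,
    "L": 113.1594, "K": 128.1741, "M": 131.1926, "F": 147.1766, "P": 97.1167,
    "S": 87.0782, "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
    "X": 110.0,  # ambiguous residue: average mass, no charge contribution
}
WATER_MASS = 18.01524

# Bjellqvist-style pKa values; termini plus charged side chains.
PKA_POSITIVE = {"nterm": 7.5, "K": 10.0, "R": 12.0, "H": 5.98}
PKA_NEGATIVE = {"cterm": 3.55, "D": 4.05, "E": 4.45, "C": 9.0, "Y": 10.0}


@dataclass
class ProteinStats:
    orf_length_bp: int
    exon_count: int
    molecular_weight_kda: float
    isoelectric_point: float


def molecular_weight_kda(protein: str) -> float:
    """Average-mass MW (residue masses + one water), in kDa."""
    seq = protein.upper().rstrip("*")
    try:
        mass = sum(RESIDUE_MASS[a] for a in seq) + WATER_MASS
    except KeyError as exc:
        raise ValueError(f"unknown residue {exc.args[0]!r}") from None
    return mass / 1000.0


def net_charge(protein: str, ph: float) -> float:
    """Henderson–Hasselbalch net charge at a given pH."""
    seq = protein.upper().rstrip("*")
    charge = 1.0 / (1.0 + 10.0 ** (ph - PKA_POSITIVE["nterm"]))
    charge -= 1.0 / (1.0 + 10.0 ** (PKA_NEGATIVE["cterm"] - ph))
    for aa in seq:
        if aa in PKA_POSITIVE:
            charge += 1.0 / (1.0 + 10.0 ** (ph - PKA_POSITIVE[aa]))
        elif aa in PKA_NEGATIVE:
            charge -= 1.0 / (1.0 + 10.0 ** (PKA_NEGATIVE[aa] - ph))
    return charge


def isoelectric_point(protein: str, tol: float = 1e-4) -> float:
    """pI solved by bisection on the net-charge function over pH 0..14."""
    lo, hi = 0.0, 14.0
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if net_charge(protein, mid) > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def compute_protein_stats(gene: CodingGene) -> ProteinStats:
    """ORF length, exon count, MW (kDa), and pI for one family gene."""
    if len(gene.cds) % 3 != 0:
        raise ValueError(f"CDS of {gene.id} not divisible by 3")
    return ProteinStats(
        orf_length_bp=len(gene.cds),
        exon_count=gene.exon_count,
        molecular_weight_kda=molecular_weight_kda(gene.protein),
        isoelectric_point=isoelectric_point(gene.protein),
    )


def identify_family(
    genes: list[CodingGene],
    config: ScanConfig | None = None,
    prefix: str = "FAM",
    rename: bool = True,
) -> list[CodingGene]:
    """Scan, filter, and deduplicate a protein set into the named family."""
    hits = [g for g in genes if scan_sbp_domain(g.protein, config)]
    return dedupe_family(hits, prefix=prefix, rename=rename)


def family_stats_table(genes: list[CodingGene]) -> pd.DataFrame:
    rows = []
    for g in genes:
        st = compute_protein_stats(g)
        rows.append({
            "gene_id": g.id, "chromosome": g.chromosome, "start": g.start,
            "orf_length_bp": st.orf_length_bp, "exon_count": st.exon_count,
            "molecular_weight_kda": round(st.molecular_weight_kda, 2),
            "isoelectric_point": round(st.isoelectric_point, 2),
        })
    return pd.DataFrame(rows)
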