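"""Pairwise molecular-evolution analysis of duplicated coding sequences.

Implements the Nei–Gojobori (1986) counting method: synonymous and
nonsynonymous site fractions per codon, mutational-pathway-averaged
difference counts, Jukes–Cantor multiple-hit correction, a sliding-window
Ka/Ks track, Ks-based duplication dating (T = Ks / 2λ), and the standard
selection classification (Ka/Ks < 1 purifying, ≈ 1 neutral, > 1 positive).

Codon alignments are built by globally aligning the two translations
(BLOSUM62, affine gaps) and expanding each protein gap to a codon gap, so
gap runs always respect codon boundaries.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from functools import lru_cache

import pandas as pd
from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Data import CodonTable

from genefam.types import translate_cds

BASES = "ACGT"

_STANDARD = CodonTable.unambiguous_dna_by_id[1]
CODON_TO_AA: dict[str, str] = dict(_STANDARD.forward_table)
STOP_CODONS = frozenset(_STANDARD.stop_codons)
SENSE_CODONS: tuple[str, ...] = tuple(sorted(CODON_TO_AA))

#: synonymous-substitution rate per site per year used for dating
#: (the grass-lineage molecular-clock convention).
GRASS_LAMBDA = 6.5e-9

#: half-width of the Ka/Ks band treated as neutral selection.  Published
#: duplication tables call 0.997 purifying and only an exact 1.000
#: neutral, so the band is kept narrow.
NEUTRAL_TOLERANCE = 1e-3


class SaturationError(ValueError):
    """Raised when a proportion of differences exceeds the Jukes–Cantor limit."""


def _check_sense(codon: str) -> str:
    codon = codon.upper()
    if len(codon) != 3 or any(b not in BASES for b in codon):
        raise ValueError(f"not an unambiguous codon: {codon!r}")
    if codon in STOP_CODONS:
        raise ValueError(f"stop codon not allowed: {codon}")
    return codon


@lru_cache(maxsize=None)
def ng86_site_counts(codon: str) -> tuple[float, float]:
    """Synonymous and nonsynonymous site fractions of a sense codon.

    Each of the nine single-nucleotide mutants contributes 1/3 of a site
    at its position; mutations to stop codons count as nonsynonymous.
    The two fractions always sum to exactly 3.
    """
    codon = _check_sense(codon)
    aa = CODON_TO_AA[codon]
    s = 0.0
    for pos in range(3):
        syn = 0
        for alt in BASES:
            if alt == codon[pos]:
                continue
            mut = codon[:pos] + alt + codon[pos + 1:]
            if mut not in STOP_CODONS and CODON_TO_AA[mut] == aa:
                syn += 1
        s += syn / 3.0
    return s, 3.0 - s


def _step_is_synonymous(before: str, after: str) -> bool:
    """Classify one single-nucleotide step; steps touching a stop are nonsynonymous."""
    if before in STOP_CODONS or after in STOP_CODONS:
        return False
    return CODON_TO_AA[before] == CODON_TO_AA[after]


@lru_cache(maxsize=None)
def ng86_diff_counts(codon_a: str, codon_b: str) -> tuple[float, float]:
    """Pathway-averaged synonymous/nonsynonymous difference counts.

    For k differing positions the k! mutational orderings are averaged
    with equal weight.  Pathways that pass through a stop codon at an
    intermediate state are excluded; if every pathway does, all are kept
    (the standard fallback).  sd + nd equals k exactly.
    """
    codon_a, codon_b = _check_sense(codon_a), _check_sense(codon_b)
    diffs = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diffs:
        return 0.0, 0.0
    paths = []
    for order in itertools.permutations(diffs):
        current = codon_a
        sd = nd = 0
        through_stop = False
        for pos in order:
            nxt = current[:pos] + codon_b[pos] + current[pos + 1:]
            if _step_is_synonymous(current, nxt):
                sd += 1
            else:
                nd += 1
            if nxt in STOP_CODONS and nxt != codon_b:
                through_stop = True
            current = nxt
        paths.append((sd, nd, through_stop))
    kept = [(sd, nd) for sd, nd, bad in paths if not bad]
    if not kept:
        kept = [(sd, nd) for sd, nd, _ in paths]
    sd = sum(p[0] for p in kept) / len(kept)
    nd = sum(p[1] for p in kept) / len(kept)
    return sd, nd


@dataclass
class CodonAlignment:
    """A pairwise codon alignment (gap runs on codon boundaries)."""

    id_a: str
    id_b: str
    seq_a: str
    seq_b: str

    def __post_init__(self) -> None:
        if len(self.seq_a) != len(self.seq_b):
            raise ValueError("aligned sequences differ in length")
        if len(self.seq_a) % 3 != 0:
            raise ValueError("alignment length not divisible by 3")

    def __len__(self) -> int:
        return len(self.seq_a)

    def codon_columns(self) -> list[tuple[int, str, str]]:
        """(0-based bp offset, codon_a, codon_b) for comparable columns.

        Columns with a gap or an ambiguous base in either sequence are
        excluded (complete deletion within the pair).
        """
        out = []
        for off in range(0, len(self.seq_a), 3):
            ca = self.seq_a[off:off + 3].upper()
            cb = self.seq_b[off:off + 3].upper()
            if all(b in BASES for b in ca + cb) and ca not in STOP_CODONS and cb not in STOP_CODONS:
                out.append((off, ca, cb))
        return out

    def slice_bp(self, start: int, end: int) -> "CodonAlignment":
        """Sub-alignment over 0-based half-open [start, end) bp coordinates."""
        return CodonAlignment(self.id_a, self.id_b, self.seq_a[start:end], self.seq_b[start:end])


@dataclass
class KaKsEstimate:
    ka: float
    ks: float
    ratio: float | None
    sites_s: float
    sites_n: float
    diffs_sd: float
    diffs_nd: float
    n_codons: int
    selection_class: str
    date_mya: float


def _protein_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    return aligner


def protein_score(seq_a: str, seq_b: str) -> float:
    """Global protein alignment score (BLOSUM62, affine gaps)."""
    return _protein_aligner().score(seq_a, seq_b)


def _strip_terminal_stop(cds: str) -> str:
    if len(cds) % 3 == 0 and cds[-3:].upper() in STOP_CODONS:
        return cds[:-3]
    return cds


def protein_guided_codon_align(
    cds_a: str, cds_b: str, id_a: str = "a", id_b: str = "b"
) -> CodonAlignment:
    """Align two CDS at the codon level via their translations.

    The translations are globally aligned (BLOSUM62, affine gaps) and
    every protein gap is expanded to one codon gap, so removing gaps
    recovers the input CDS exactly.  A terminal stop codon, if present,
    is stripped before alignment.
    """
    cds_a, cds_b = _strip_terminal_stop(cds_a.upper()), _strip_terminal_stop(cds_b.upper())
    prot_a, prot_b = translate_cds(cds_a), translate_cds(cds_b)
    aln = _protein_aligner().align(prot_a, prot_b)[0]
    row_a, row_b = str(aln[0]), str(aln[1])
    out_a, out_b = [], []
    ia = ib = 0
    for pa, pb in zip(row_a, row_b):
        if pa == "-":
            out_a.append("---")
        else:
            out_a.append(cds_a[3 * ia:3 * ia + 3])
            ia += 1
        if pb == "-":
            out_b.append("---")
        else:
            out_b.append(cds_b[3 * ib:3 * ib + 3])
            ib += 1
    return CodonAlignment(id_a, id_b, "".join(out_a), "".join(out_b))


def jukes_cantor(p: float) -> float:
    """JC-corrected distance d = -(3/4) ln(1 - 4p/3); raises at saturation."""
    if p < 0:
        raise ValueError("proportion must be nonnegative")
    if p >= 0.75:
        raise SaturationError(f"proportion {p:.3f} at or beyond the JC limit 3/4")
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def date_duplication(ks: float, lam: float = GRASS_LAMBDA) -> float:
    """Duplication time in Mya from synonymous divergence: T = Ks / (2 λ) · 10⁻⁶."""
    if ks < 0:
        raise ValueError("Ks must be nonnegative")
    return ks / (2.0 * lam) * 1e-6


def classify_selection(ratio: float | None, neutral_tol: float = NEUTRAL_TOLERANCE) -> str:
    """Selection regime from Ka/Ks: purifying (<1), neutral (≈1), positive (>1)."""
    if ratio is None or (isinstance(ratio, float) and math.isnan(ratio)):
        return "undetermined"
    if abs(ratio - 1.0) <= neutral_tol:
        return "neutral"
    return "purifying" if ratio < 1.0 else "positive"


def estimate_kaks(
    aln: CodonAlignment,
    lam: float = GRASS_LAMBDA,
    neutral_tol: float = NEUTRAL_TOLERANCE,
) -> KaKsEstimate:
    """NG86 Ka/Ks estimate on comparable (gap-free, sense) codon columns.

    Site counts are averaged over the two sequences; proportions are
    Jukes–Cantor corrected.  Ks = 0 leaves the ratio undefined (None)
    rather than raising; saturated proportions raise SaturationError.
    """
    cols = aln.codon_columns()
    if not cols:
        raise ValueError("no comparable codon columns")
    s_a = s_b = sd = nd = 0.0
    for _, ca, cb in cols:
        s_a += ng86_site_counts(ca)[0]
        s_b += ng86_site_counts(cb)[0]
        d = ng86_diff_counts(ca, cb)
        sd += d[0]
        nd += d[1]
    n_codons = len(cols)
    sites_s = 0.5 * (s_a + s_b)
    sites_n = 3.0 * n_codons - sites_s
    ps = sd / sites_s if sites_s > 0 else 0.0
    pn = nd / sites_n if sites_n > 0 else 0.0
    ks = jukes_cantor(ps)
    ka = jukes_cantor(pn)
    ratio = ka / ks if ks > 0 else None
    return KaKsEstimate(
        ka=ka, ks=ks, ratio=ratio, sites_s=sites_s, sites_n=sites_n,
        diffs_sd=sd, diffs_nd=nd, n_codons=n_codons,
        selection_class=classify_selection(ratio, neutral_tol),
        date_mya=date_duplication(ks, lam),
    )


@dataclass
class Window:
    start_bp: int  # 1-based on alignment coordinates
    end_bp: int    # inclusive
    ka: float | None
    ks: float | None
    ratio: float | None


def sliding_window_kaks(
    aln: CodonAlignment, window_size: int = 150, step_size: int = 9
) -> list[Window]:
    """Ka/Ks in sliding windows over alignment coordinates.

    Both window and step must be divisible by 3 so windows stay
    codon-aligned; a length-L alignment yields floor((L-W)/step)+1
    windows starting at 1, 1+step, ....  Windows with Ks = 0, saturated
    proportions, or no comparable codons carry an undefined ratio.
    """
    if window_size % 3 or step_size % 3:
        raise ValueError("window_size and step_size must be divisible by 3")
    length = len(aln)
    if length < window_size:
        raise ValueError("alignment shorter than the window")
    windows = []
    for start in range(0, length - window_size + 1, step_size):
        sub = aln.slice_bp(start, start + window_size)
        ka = ks = ratio = None
        try:
            est = estimate_kaks(sub)
            ka, ks, ratio = est.ka, est.ks, est.ratio
        except (ValueError, SaturationError):
            pass
        windows.append(Window(start + 1, start + window_size, ka, ks, ratio))
    return windows


def derive_table_columns(
    table: pd.DataFrame, lam: float = GRASS_LAMBDA, neutral_tol: float = NEUTRAL_TOLERANCE
) -> pd.DataFrame:
    """Derive ratio / selection / date columns from printed Ka and Ks values.

    Input needs columns ``pair``, ``ka``, ``ks``; output adds ``ratio``
    (3 dp), ``purifying`` (Yes/No), ``selection`` and ``date_mya`` (2 dp),
    matching the print conventions of published duplication tables.
    """
    out = table.copy()
    ratios = out["ka"] / out["ks"]
    out["ratio"] = ratios.round(3)
    out["selection"] = [classify_selection(r, neutral_tol) for r in ratios]
    out["purifying"] = ["Yes" if r < 1.0 else "No" for r in ratios]
    out["date_mya"] = (out["ks"].map(lambda k: date_duplication(k, lam))).round(2)
    return out
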