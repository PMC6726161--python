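"""Synthetic-data generators with recorded ground truth.

Every input the pipeline consumes can be generated here with known
structure: codon-sequence pairs diverged under a chosen dN/dS (ω) and
synonymous divergence, multi-chromosome gene orders with planted
collinear blocks and tandem arrays, transcripts with planted
miRNA-complementary sites, FPKM expression matrices, and qPCR Ct tables
with a stable reference gene.  All generators are deterministic given
their seed, and each writes TSV truth tables alongside the fixtures.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from genefam import io
from genefam.kaks import (
    BASES, CODON_TO_AA, SENSE_CODONS, STOP_CODONS, ng86_site_counts,
)
from genefam.types import CodingGene, translate_cds

# ---------------------------------------------------------------------------
# codon-pair evolution


@dataclass
class EvolSimParams:
    """Controls for the two-lineage codon substitution simulator.

    omega is the true dN/dS the estimator must recover; target_ks the
    expected synonymous substitutions per synonymous site between the
    two descendants.
    """

    omega: float = 0.3
    target_ks: float = 0.4
    n_codons: int = 500
    seed: int = 0

    def validate(self) -> None:
        if not self.omega > 0:
            raise ValueError("omega must be > 0")
        if self.target_ks < 0:
            raise ValueError("target_ks must be >= 0")
        if self.n_codons < 10:
            raise ValueError("n_codons must be >= 10")


@dataclass
class CodonPair:
    """Two descendant CDS plus the realized per-site truth."""

    seq_a: str
    seq_b: str
    n_syn_events: int
    n_nonsyn_events: int
    ka_true: float
    ks_true: float


# codon -> list of (position, alternative base, kind) for all 9 mutants;
# kind is "syn", "nonsyn", or "stop"
_MUTANTS: dict[str, list[tuple[int, str, str]]] = {}
for _codon in SENSE_CODONS:
    entries = []
    for _pos in range(3):
        for _alt in BASES:
            if _alt == _codon[_pos]:
                continue
            _mut = _codon[:_pos] + _alt + _codon[_pos + 1:]
            if _mut in STOP_CODONS:
                kind = "stop"
            elif CODON_TO_AA[_mut] == CODON_TO_AA[_codon]:
                kind = "syn"
            else:
                kind = "nonsyn"
            entries.append((_pos, _alt, kind))
    _MUTANTS[_codon] = entries


def random_cds(rng: np.random.Generator, n_codons: int) -> str:
    """Uniform sense-codon CDS (no internal stops, no terminal stop)."""
    idx = rng.integers(0, len(SENSE_CODONS), size=n_codons)
    return "".join(SENSE_CODONS[i] for i in idx)


def _codon_weights(codons: list[str], omega: float) -> np.ndarray:
    w = np.empty(len(codons))
    for j, c in enumerate(codons):
        syn = sum(1 for _, _, k in _MUTANTS[c] if k == "syn")
        non = sum(1 for _, _, k in _MUTANTS[c] if k == "nonsyn")
        w[j] = syn + omega * non
    return w


def simulate_codon_pair(params: EvolSimParams) -> CodonPair:
    """Diverge two copies of a random ancestor under dN/dS = omega.

    Substitution events are placed one at a time: every non-stop
    single-nucleotide mutation of the current sequence is a candidate,
    synonymous candidates carry weight 1 and nonsynonymous candidates
    weight omega, so per-site rates stand in the ratio 1 : omega.  The
    expected number of events is calibrated so that synonymous events
    per synonymous site equal target_ks.  Mutations creating stop codons
    are never placed.  The realized truth (event counts per NG86 sites
    of the final pair) is returned alongside the sequences.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    ancestor = random_cds(rng, params.n_codons)
    codons = [ancestor[i:i + 3] for i in range(0, len(ancestor), 3)]
    s_anc = sum(ng86_site_counts(c)[0] for c in codons)
    n_anc = 3 * params.n_codons - s_anc

    lineages = [list(codons), list(codons)]
    weights = [_codon_weights(codons, params.omega) for _ in range(2)]

    lam = params.target_ks * (s_anc + params.omega * n_anc)
    n_events = int(rng.poisson(lam)) if lam > 0 else 0

    n_syn = n_nonsyn = 0
    for _ in range(n_events):
        li = int(rng.integers(0, 2))
        w = weights[li]
        total = w.sum()
        j = int(rng.choice(len(w), p=w / total))
        codon = lineages[li][j]
        cands = [(p, a, k) for p, a, k in _MUTANTS[codon] if k != "stop"]
        cw = np.array([1.0 if k == "syn" else params.omega for _, _, k in cands])
        pick = int(rng.choice(len(cands), p=cw / cw.sum()))
        pos, alt, kind = cands[pick]
        new = codon[:pos] + alt + codon[pos + 1:]
        lineages[li][j] = new
        syn = sum(1 for _, _, k in _MUTANTS[new] if k == "syn")
        non = sum(1 for _, _, k in _MUTANTS[new] if k == "nonsyn")
        weights[li][j] = syn + params.omega * non
        if kind == "syn":
            n_syn += 1
        else:
            n_nonsyn += 1

    seq_a, seq_b = "".join(lineages[0]), "".join(lineages[1])
    s_final = 0.5 * sum(
        ng86_site_counts(c)[0] for seq in lineages for c in seq
    )
    n_final = 3 * params.n_codons - s_final
    return CodonPair(
        seq_a=seq_a, seq_b=seq_b,
        n_syn_events=n_syn, n_nonsyn_events=n_nonsyn,
        ks_true=n_syn / s_final if s_final else 0.0,
        ka_true=n_nonsyn / n_final if n_final else 0.0,
    )


# ---------------------------------------------------------------------------
# genome fixtures


@dataclass
class GenomeFixtureParams:
    """Layout of a synthetic multi-chromosome genome.

    planted_blocks: list of ((chrom_a, chrom_b), n_anchors, orientation)
    planted_tandem_arrays: list of (chromosome, array_size, spacing_in_genes)
    """

    n_chromosomes: int = 3
    genes_per_chromosome: int = 30
    planted_blocks: list = field(default_factory=list)
    planted_tandem_arrays: list = field(default_factory=list)
    gene_codons: int = 100
    n_pair_substitutions: int = 5
    family_signature: bool = True
    seed: int = 0

    def chromosome(self, i: int) -> str:
        return f"chr{i + 1}"


@dataclass
class GenomeFixture:
    genes: list[CodingGene]
    truth_anchors: pd.DataFrame   # block_id, gene_a, gene_b, orientation
    truth_tandem: pd.DataFrame    # array_id, chromosome, gene_id
    family_ids: list[str]

    def write(self, out_dir: str | os.PathLike) -> None:
        os.makedirs(out_dir, exist_ok=True)
        io.write_fasta({g.id: g.cds for g in self.genes}, os.path.join(out_dir, "cds.fa"))
        io.write_fasta({g.id: g.protein for g in self.genes}, os.path.join(out_dir, "protein.fa"))
        io.write_gff3(self.genes, os.path.join(out_dir, "genes.gff3"))
        io.write_tsv(self.truth_anchors, os.path.join(out_dir, "truth_blocks.tsv"))
        io.write_tsv(self.truth_tandem, os.path.join(out_dir, "truth_tandem.tsv"))
        io.write_tsv(pd.DataFrame({"gene_id": self.family_ids}),
                     os.path.join(out_dir, "truth_family.tsv"))


def _signature_protein(rng: np.random.Generator, total_len: int) -> str:
    """Random protein containing one planted SBP-type domain.

    Only the zinc-binding architecture is conserved (Zn-1 =
    C-x(2,4)-C-x(10,20)-C-x(2,4)-H, then Zn-2 =
    C-x(2,4)-C-x(10,20)-H-x(2,4)-C, total span 60-90 aa); all spacer and
    flank residues are random and avoid C/H, so unrelated family genes
    share the motif but not the sequence — as in real domain families.
    """
    aa = "ADEFGIKLMNPQRSTVWY"

    def bg(n: int) -> str:
        return "".join(aa[i] for i in rng.integers(0, len(aa), int(n)))

    zn1 = ("C" + bg(rng.integers(2, 5)) + "C" + bg(rng.integers(10, 21))
           + "C" + bg(rng.integers(2, 5)) + "H")
    zn2 = ("C" + bg(rng.integers(2, 5)) + "C" + bg(rng.integers(10, 21))
           + "H" + bg(rng.integers(2, 5)) + "C")
    lo = max(0, 60 - len(zn1) - len(zn2))
    hi = 90 - len(zn1) - len(zn2)
    core = zn1 + bg(rng.integers(lo, hi + 1)) + zn2
    flank = total_len - len(core)
    if flank < 10:
        raise ValueError("protein too short to host the domain signature")
    left = int(rng.integers(5, flank - 4))
    return bg(left) + core + bg(flank - left)


def back_translate(protein: str, rng: np.random.Generator) -> str:
    """Choose a uniform codon for each residue."""
    by_aa: dict[str, list[str]] = {}
    for c, a in CODON_TO_AA.items():
        by_aa.setdefault(a, []).append(c)
    return "".join(
        by_aa[a][int(rng.integers(0, len(by_aa[a])))] for a in protein
    )


def _mutated_copy(cds: str, n_subs: int, rng: np.random.Generator,
                  keep_signature: bool) -> str:
    """Copy with point substitutions; never introduces a stop, and keeps
    the planted domain signature intact if asked (bounded retries)."""
    from genefam.family import ScanConfig, scan_sbp_domain  # local: avoid cycle

    for _ in range(50):
        seq = list(cds)
        for _ in range(n_subs):
            for _ in range(50):
                i = int(rng.integers(0, len(seq)))
                alt = BASES[int(rng.integers(0, 4))]
                if alt == seq[i]:
                    continue
                old = seq[i]
                seq[i] = alt
                codon_start = 3 * (i // 3)
                if "".join(seq[codon_start:codon_start + 3]) in STOP_CODONS:
                    seq[i] = old
                    continue
                break
        out = "".join(seq)
        if not keep_signature:
            return out
        if scan_sbp_domain(translate_cds(out), ScanConfig()):
            return out
    raise RuntimeError("failed to mutate copy while preserving the domain signature")


def simulate_genomes(params: GenomeFixtureParams) -> GenomeFixture:
    """Build gene orders with planted collinear blocks and tandem arrays.

    Planted family genes (block anchors and tandem-array members) carry
    the SBP-type domain signature so the fixture exercises the
    identification stage too; background genes are random signature-free
    CDS.  Anchor/array partners are near-identical copies (a few point
    substitutions), so homology detection recovers exactly the planted
    pairs.  Truth tables record every planted anchor pair and array.
    """
    rng = np.random.default_rng(params.seed)
    n_chrom, per_chrom = params.n_chromosomes, params.genes_per_chromosome

    # slot occupancy per chromosome
    used: dict[str, set[int]] = {params.chromosome(i): set() for i in range(n_chrom)}
    planted: dict[tuple[str, int], CodingGene] = {}
    anchors_rows, tandem_rows, family = [], [], []

    def place(chrom: str, slot: int, gene: CodingGene) -> None:
        if slot < 0 or slot >= per_chrom:
            raise ValueError(f"slot {slot} outside chromosome {chrom}")
        if slot in used[chrom]:
            raise ValueError(f"placement collision at {chrom} slot {slot}")
        used[chrom].add(slot)
        planted[(chrom, slot)] = gene

    def make_family_cds() -> str:
        if params.family_signature:
            return back_translate(_signature_protein(rng, params.gene_codons), rng)
        return random_cds(rng, params.gene_codons)

    gene_counter = 0

    def new_id() -> str:
        nonlocal gene_counter
        gene_counter += 1
        return f"G{gene_counter:04d}"

    for b, (chrom_pair, n_anchors, orientation) in enumerate(params.planted_blocks):
        ca, cb = chrom_pair
        if orientation not in "+-":
            raise ValueError("orientation must be '+' or '-'")
        span = 2 * n_anchors
        if span > per_chrom:
            raise ValueError("block exceeds chromosome capacity")
        for _ in range(200):
            start_a = int(rng.integers(0, per_chrom - span + 1))
            start_b = int(rng.integers(0, per_chrom - span + 1))
            slots_a = [start_a + 2 * k for k in range(n_anchors)]
            slots_b = [start_b + 2 * k for k in range(n_anchors)]
            taken_a = used[ca].intersection(slots_a)
            taken_b = used[cb].intersection(slots_b + (slots_a if ca == cb else []))
            if not taken_a and not taken_b:
                break
        else:
            raise ValueError(f"no room for block {b + 1} on {ca}/{cb}")
        if orientation == "-":
            slots_b = slots_b[::-1]
        for k in range(n_anchors):
            cds = make_family_cds()
            ga = CodingGene(id=new_id(), cds=cds)
            gb = CodingGene(id=new_id(), cds=_mutated_copy(
                cds, params.n_pair_substitutions, rng, params.family_signature))
            place(ca, slots_a[k], ga)
            place(cb, slots_b[k], gb)
            anchors_rows.append({
                "block_id": f"B{b + 1}", "gene_a": ga.id, "gene_b": gb.id,
                "chrom_a": ca, "chrom_b": cb, "orientation": orientation,
            })
            family += [ga.id, gb.id]

    for t, (chrom, size, spacing) in enumerate(params.planted_tandem_arrays):
        if size < 2:
            raise ValueError("tandem array needs >= 2 genes")
        span = spacing * (size - 1) + 1
        free = [s for s in range(per_chrom - span + 1)
                if all(s + k * spacing not in used[chrom] for k in range(size))]
        if not free:
            raise ValueError(f"no room for tandem array on {chrom}")
        start = free[int(rng.integers(0, len(free)))]
        base = make_family_cds()
        for k in range(size):
            cds = base if k == 0 else _mutated_copy(
                base, params.n_pair_substitutions, rng, params.family_signature)
            g = CodingGene(id=new_id(), cds=cds)
            place(chrom, start + k * spacing, g)
            tandem_rows.append({"array_id": f"T{t + 1}", "chromosome": chrom,
                                "gene_id": g.id})
            family.append(g.id)

    # background fill
    genes: list[CodingGene] = []
    for i in range(n_chrom):
        chrom = params.chromosome(i)
        for slot in range(per_chrom):
            g = planted.get((chrom, slot))
            if g is None:
                g = CodingGene(id=new_id(), cds=random_cds(rng, params.gene_codons))
            g.chromosome = chrom
            g.start = 1 + slot * 5000
            g.end = g.start + len(g.cds) - 1
            g.strand = "+"
            g.exon_count = int(rng.integers(1, 6))
            genes.append(g)
    io.assign_ranks(genes)

    return GenomeFixture(
        genes=genes,
        truth_anchors=pd.DataFrame(
            anchors_rows, columns=["block_id", "gene_a", "gene_b",
                                   "chrom_a", "chrom_b", "orientation"]),
        truth_tandem=pd.DataFrame(tandem_rows,
                                  columns=["array_id", "chromosome", "gene_id"]),
        family_ids=family,
    )


# ---------------------------------------------------------------------------
# planted miRNA target sites


@dataclass
class PlantedSite:
    """Specification of one site to plant: mismatch/wobble counts split
    between the seed region (miRNA positions 2-13) and the rest."""

    gene_id: str
    region: str  # "CDS" or "3UTR"
    n_mismatches: int = 0
    n_wobbles: int = 0
    seed_mismatches: int = 0
    seed_wobbles: int = 0

    def expectation(self, mismatch=1.0, wobble=0.5, seed_factor=2.0) -> float:
        return (self.n_mismatches * mismatch + self.n_wobbles * wobble
                + seed_factor * (self.seed_mismatches * mismatch
                                 + self.seed_wobbles * wobble))


_WC = {"A": "T", "U": "A", "G": "C", "C": "G"}
_WOBBLE = {"G": "T", "U": "G"}


def _perfect_target(mirna: str) -> str:
    """DNA reverse complement of the miRNA (the perfect site, 5'->3')."""
    return "".join(_WC[b] for b in reversed(mirna))


def _degrade_site(mirna: str, spec: PlantedSite, rng: np.random.Generator,
                  seed_range: tuple[int, int] = (2, 13)) -> str:
    """Apply the requested mismatches/wobbles to a perfect site."""
    site = list(_perfect_target(mirna))
    L = len(mirna)
    lo, hi = seed_range
    seed_pos = [p for p in range(1, L + 1) if lo <= p <= hi]
    other_pos = [p for p in range(1, L + 1) if p not in seed_pos]

    def apply(positions, n, kind):
        pool = list(positions)
        if kind == "wobble":
            pool = [p for p in pool if mirna[p - 1] in _WOBBLE]
        if n > len(pool):
            raise ValueError(f"not enough positions for {n} {kind}(s)")
        chosen = rng.choice(len(pool), size=n, replace=False)
        for ci in chosen:
            p = pool[int(ci)]
            ti = L - p  # 0-based index into the target window
            mb = mirna[p - 1]
            if kind == "wobble":
                site[ti] = _WOBBLE[mb]
            else:
                banned = {_WC[mb], _WOBBLE.get(mb, "")}
                choices = [b for b in "ACGT" if b not in banned]
                site[ti] = choices[int(rng.integers(0, len(choices)))]
            positions.remove(p)

    apply(seed_pos, spec.seed_mismatches, "mismatch")
    apply(seed_pos, spec.seed_wobbles, "wobble")
    apply(other_pos, spec.n_mismatches, "mismatch")
    apply(other_pos, spec.n_wobbles, "wobble")
    return "".join(site)


def plant_mir_sites(
    genes: list[CodingGene],
    mirna: str,
    sites: list[PlantedSite],
    seed: int = 0,
    max_attempts: int = 200,
    preserve=None,
) -> tuple[list[CodingGene], pd.DataFrame]:
    """Write miRNA-complementary sites into CDS or 3' UTRs.

    CDS insertions are retried at new positions until the edited CDS
    still translates without internal stops; overlapping two planted
    sites in one gene is an error.  An optional ``preserve`` predicate
    on the edited gene gates placements (e.g. to keep a domain
    signature intact).  Returns the edited genes and a truth table with
    the expectation score each site must earn under the scanner's
    scheme.
    """
    rng = np.random.default_rng(seed)
    mirna = mirna.upper().replace("T", "U")
    L = len(mirna)
    by_id = {g.id: g for g in genes}
    occupied: dict[str, list[tuple[int, int]]] = {}
    rows = []
    for spec in sites:
        g = by_id[spec.gene_id]
        if spec.region not in ("CDS", "3UTR"):
            raise ValueError(f"unknown region {spec.region}")
        target = _degrade_site(mirna, spec, rng)
        placed = None
        for _ in range(max_attempts):
            if spec.region == "CDS":
                if len(g.cds) < L:
                    raise ValueError(f"CDS of {g.id} shorter than the miRNA")
                pos = int(rng.integers(0, len(g.cds) - L + 1))
                tx_start = pos  # transcript coords == CDS coords here
            else:
                if len(g.utr3) < L:
                    raise ValueError(f"3' UTR of {g.id} shorter than the miRNA")
                pos = int(rng.integers(0, len(g.utr3) - L + 1))
                tx_start = len(g.cds) + pos
            span = (tx_start, tx_start + L)
            if any(span[0] < e and s < span[1] for s, e in occupied.get(g.id, [])):
                raise ValueError(f"site collision on {g.id}")
            if spec.region == "CDS":
                new_cds = g.cds[:pos] + target + g.cds[pos + L:]
                try:
                    prot = translate_cds(new_cds)
                except ValueError:
                    continue
                old_cds, old_prot = g.cds, g.protein
                g.cds, g.protein = new_cds, prot
                if preserve is not None and not preserve(g):
                    g.cds, g.protein = old_cds, old_prot
                    continue
            else:
                old_utr = g.utr3
                g.utr3 = g.utr3[:pos] + target + g.utr3[pos + L:]
                if preserve is not None and not preserve(g):
                    g.utr3 = old_utr
                    continue
            placed = span
            break
        if placed is None:
            raise RuntimeError(
                f"could not place site in {g.id} without creating stops")
        occupied.setdefault(g.id, []).append(placed)
        rows.append({
            "gene_id": g.id, "region": spec.region,
            "start": placed[0] + 1, "end": placed[1],
            "n_mismatches": spec.n_mismatches, "n_wobbles": spec.n_wobbles,
            "seed_mismatches": spec.seed_mismatches,
            "seed_wobbles": spec.seed_wobbles,
            "expectation": spec.expectation(),
        })
    truth = pd.DataFrame(rows, columns=[
        "gene_id", "region", "start", "end", "n_mismatches", "n_wobbles",
        "seed_mismatches", "seed_wobbles", "expectation"])
    return genes, truth


# ---------------------------------------------------------------------------
# expression fixtures


@dataclass
class ExpressionFixtureParams:
    """FPKM matrix generator: mixture of constitutive, tissue-specific
    (expressed in 1-3 tissues) and silent genes, with multiplicative
    lognormal noise of scale noise_sd."""

    n_genes: int = 30
    n_tissues: int = 18
    p_constitutive: float = 0.6
    p_specific: float = 0.3
    p_silent: float = 0.1
    noise_sd: float = 0.3
    seed: int = 0

    def validate(self) -> None:
        total = self.p_constitutive + self.p_specific + self.p_silent
        if abs(total - 1.0) > 1e-9:
            raise ValueError("profile-class proportions must sum to 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def simulate_expression(
    params: ExpressionFixtureParams,
    gene_ids: list[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """FPKM matrix (genes x tissues) plus a per-gene truth-class table."""
    params.validate()
    rng = np.random.default_rng(params.seed)
    n = params.n_genes
    genes = gene_ids if gene_ids is not None else [f"gene{i + 1}" for i in range(n)]
    if len(genes) != n:
        raise ValueError("gene_ids length mismatch")
    tissues = [f"tissue{j + 1}" for j in range(params.n_tissues)]

    n_const = int(round(params.p_constitutive * n))
    n_spec = int(round(params.p_specific * n))
    classes = (["constitutive"] * n_const + ["tissue_specific"] * n_spec
               + ["silent"] * (n - n_const - n_spec))
    rng.shuffle(classes)

    mat = np.zeros((n, params.n_tissues))
    for i, cls in enumerate(classes):
        if cls == "silent":
            continue
        base = float(rng.lognormal(mean=3.0, sigma=0.8))
        noise = (np.exp(rng.normal(0.0, params.noise_sd, params.n_tissues))
                 if params.noise_sd > 0 else np.ones(params.n_tissues))
        if cls == "constitutive":
            mat[i] = base * noise
        else:
            k = int(rng.integers(1, 4))
            on = rng.choice(params.n_tissues, size=k, replace=False)
            mat[i, on] = base * noise[on]
    fpkm = pd.DataFrame(mat, index=genes, columns=tissues)
    fpkm.index.name = "gene_id"
    truth = pd.DataFrame({"gene_id": genes, "profile_class": classes})
    return fpkm, truth


@dataclass
class CtSimParams:
    """qPCR Ct-table generator.

    fold_changes maps (gene, sample) -> true expression fold relative to
    the calibrator sample; unlisted combinations are fold 1.  The
    reference gene holds a constant Ct (up to noise) in every sample.
    """

    genes: list[str] = field(default_factory=lambda: ["geneA", "geneB"])
    samples: list[str] = field(default_factory=lambda: ["control", "treated"])
    calibrator: str = "control"
    ref_gene: str = "RefActin"
    n_replicates: int = 3
    fold_changes: dict = field(default_factory=dict)
    ref_ct: float = 20.0
    base_delta_ct: float = 5.0
    noise_sd: float = 0.0
    seed: int = 0


def simulate_ct_table(params: CtSimParams) -> pd.DataFrame:
    """Long-format Ct table: columns gene, sample, replicate, ct.

    With noise_sd = 0 the ΔΔCt method recovers every planted fold
    change exactly.
    """
    if params.calibrator not in params.samples:
        raise ValueError("calibrator must be one of the samples")
    rng = np.random.default_rng(params.seed)
    rows = []

    def noise() -> float:
        return float(rng.normal(0.0, params.noise_sd)) if params.noise_sd > 0 else 0.0

    for sample in params.samples:
        for rep in range(1, params.n_replicates + 1):
            rows.append({"gene": params.ref_gene, "sample": sample,
                         "replicate": rep, "ct": params.ref_ct + noise()})
        for gene in params.genes:
            fold = float(params.fold_changes.get((gene, sample), 1.0))
            if fold <= 0:
                raise ValueError("fold changes must be positive")
            ct = params.ref_ct + params.base_delta_ct - np.log2(fold)
            for rep in range(1, params.n_replicates + 1):
                rows.append({"gene": gene, "sample": sample,
                             "replicate": rep, "ct": ct + noise()})
    return pd.DataFrame(rows, columns=["gene", "sample", "replicate", "ct"])
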