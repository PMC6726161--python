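"""FASTA / GFF3 / TSV input-output helpers.

FASTA goes through Biopython's SeqIO; GFF3 is written and read as the
9-column tab layout with ``ID=`` attributes (1-based inclusive
coordinates).  TSV tables are pandas round-trips.
"""

from __future__ import annotations

import os
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from genefam.types import CodingGene

GFF_COLUMNS = [
    "seqid", "source", "type", "start", "end",
    "score", "strand", "phase", "attributes",
]


def write_fasta(records: Mapping[str, str], path: str | os.PathLike) -> None:
    seqs = [SeqRecord(Seq(s), id=name, description="") for name, s in records.items()]
    SeqIO.write(seqs, str(path), "fasta")


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_gff3(genes: Iterable[CodingGene], path: str | os.PathLike) -> None:
    """Write gene/mRNA/exon features.  Exons split the gene span evenly."""
    lines = ["##gff-version 3"]
    for g in genes:
        if g.chromosome is None or g.start is None:
            raise ValueError(f"gene {g.id} lacks coordinates")
        attrs = f"ID={g.id}"
        lines.append("\t".join(map(str, [
            g.chromosome, "genefam", "gene", g.start, g.end, ".", g.strand, ".", attrs,
        ])))
        lines.append("\t".join(map(str, [
            g.chromosome, "genefam", "mRNA", g.start, g.end, ".", g.strand, ".",
            f"ID={g.id}.t1;Parent={g.id}",
        ])))
        span = g.end - g.start + 1
        n = max(1, g.exon_count)
        bounds = [g.start + round(i * span / n) for i in range(n)] + [g.end + 1]
        for i in range(n):
            lines.append("\t".join(map(str, [
                g.chromosome, "genefam", "exon", bounds[i], bounds[i + 1] - 1,
                ".", g.strand, ".", f"ID={g.id}.exon{i + 1};Parent={g.id}.t1",
            ])))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_gff3(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", header=None, names=GFF_COLUMNS)
    df["feature_id"] = df["attributes"].str.extract(r"ID=([^;]+)")
    df["parent"] = df["attributes"].str.extract(r"Parent=([^;]+)")
    return df


def genes_from_files(
    cds_fasta: str | os.PathLike,
    gff3: str | os.PathLike | None = None,
    utr3_fasta: str | os.PathLike | None = None,
) -> list[CodingGene]:
    """Assemble CodingGene objects from on-disk fixtures.

    Ranks (gene ordinals along each chromosome) are recomputed from the
    GFF3 start coordinates.
    """
    cds = read_fasta(cds_fasta)
    utr3 = read_fasta(utr3_fasta) if utr3_fasta else {}
    coords: dict[str, tuple] = {}
    exons: dict[str, int] = {}
    if gff3 is not None:
        df = read_gff3(gff3)
        for _, row in df[df["type"] == "gene"].iterrows():
            coords[row["feature_id"]] = (row["seqid"], row["strand"], int(row["start"]), int(row["end"]))
        ex = df[df["type"] == "exon"].copy()
        ex["gene"] = ex["parent"].str.replace(r"\.t\d+$", "", regex=True)
        exons = ex.groupby("gene").size().to_dict()
    genes = []
    for gid, seq in cds.items():
        chrom, strand, start, end = coords.get(gid, (None, "+", None, None))
        genes.append(CodingGene(
            id=gid, chromosome=chrom, strand=strand, start=start, end=end,
            cds=seq, exon_count=exons.get(gid, 1), utr3=utr3.get(gid, ""),
        ))
    assign_ranks(genes)
    return genes


def assign_ranks(genes: list[CodingGene]) -> None:
    """Set each gene's ordinal position along its chromosome, in place."""
    by_chrom: dict[str, list[CodingGene]] = {}
    for g in genes:
        if g.chromosome is not None and g.start is not None:
            by_chrom.setdefault(g.chromosome, []).append(g)
    for members in by_chrom.values():
        members.sort(key=lambda g: g.start)
        for i, g in enumerate(members):
            g.rank = i


def write_tsv(df: pd.DataFrame, path: str | os.PathLike, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


def read_tsv(path: str | os.PathLike, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kwargs)
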