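"""Shared domain types."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from Bio.Seq import Seq


@dataclass
class CodingGene:
    """A protein-coding gene: the atom shared by all pipeline stages.

    Coordinates are 1-based inclusive on the chromosome.  ``rank`` is the
    ordinal position of the gene along its chromosome (0-based), the
    coordinate system used for collinearity chaining and tandem calls.
    ``utr3`` holds the 3' UTR sequence (DNA, transcript orientation);
    the scanned transcript is ``cds + utr3``.
    """

    id: str
    chromosome: str | None = None
    strand: str = "+"
    start: int | None = None
    end: int | None = None
    cds: str = ""
    protein: str = ""
    exon_count: int = 1
    utr3: str = ""
    rank: int | None = None
    source_id: str | None = None

    def __post_init__(self) -> None:
        if self.cds and not self.protein:
            self.protein = translate_cds(self.cds)

    @property
    def transcript(self) -> str:
        return self.cds + self.utr3

    def renamed(self, new_id: str) -> "CodingGene":
        return replace(self, id=new_id, source_id=self.source_id or self.id)


def translate_cds(cds: str, strip_terminal_stop: bool = True) -> str:
    """Translate a CDS; raises on length or internal-stop violations."""
    if len(cds) % 3 != 0:
        raise ValueError(f"CDS length {len(cds)} not divisible by 3")
    prot = str(Seq(cds).translate())
    if strip_terminal_stop and prot.endswith("*"):
        prot = prot[:-1]
    if "*" in prot:
        raise ValueError("CDS contains an internal stop codon")
    return prot
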