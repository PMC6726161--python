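import numpy as np
import pytest

from genefam import simulate
from genefam.types import CodingGene


@pytest.fixture(scope="session")
def planted_genome():
    """Genome fixture with two collinear blocks and one tandem array."""
    params = simulate.GenomeFixtureParams(
        n_chromosomes=3, genes_per_chromosome=30,
        planted_blocks=[(("chr1", "chr2"), 6, "+"), (("chr2", "chr3"), 5, "-")],
        planted_tandem_arrays=[("chr1", 3, 1)],
        seed=7,
    )
    return params, simulate.simulate_genomes(params)


@pytest.fixture(scope="session")
def mir156():
    from genefam.pipeline import bundled_mirna

    return bundled_mirna()


@pytest.fixture()
def random_genes():
    """Factory for random unrelated coding genes."""

    def make(n, n_codons=120, utr_codons=0, seed=0):
        rng = np.random.default_rng(seed)
        return [
            CodingGene(
                id=f"g{i}",
                cds=simulate.random_cds(rng, n_codons),
                utr3=simulate.random_cds(rng, utr_codons) if utr_codons else "",
            )
            for i in range(n)
        ]

    return make
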