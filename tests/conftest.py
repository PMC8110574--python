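import numpy as np
import pytest

from syntevo.genome import GeneModel, GenomeAnnotation
from syntevo.simulate import SimulationConfig, simulate_genomes, simulate_hit_table
from syntevo.synteny import SyntenyParams


def make_annotation(genome_id: str, chrom_genes: dict[str, int], prefix: str | None = None,
                    gene_bp: int = 900, spacing: int = 1000, ploidy: int = 1) -> GenomeAnnotation:
    """A regular annotation: ``chrom_genes`` maps chromosome -> gene count."""
    prefix = prefix if prefix is not None else genome_id
    genes = []
    for chrom, n in chrom_genes.items():
        for i in range(n):
            start = i * spacing
            genes.append(GeneModel(f"{prefix}_{chrom}_{i:04d}", chrom, start, start + gene_bp))
    return GenomeAnnotation(genome_id, genes, ploidy=ploidy)


@pytest.fixture
def params():
    return SyntenyParams()


@pytest.fixture(scope="session")
def small_sim():
    """A small two-genome simulation with WGD, sequences, and planted events."""
    config = SimulationConfig(
        seed=11, n_chromosomes=3, genes_per_chromosome=100,
        gene_length_codons=(300, 450), tandem_family_count=15, expansion_count=4,
        inversion_count=1, translocation_count=1, inversion_size=(20, 40),
    )
    result = simulate_genomes(config)
    return result, simulate_hit_table(result)


@pytest.fixture(scope="session")
def clean_sim():
    """No WGD, no rearrangements, no duplications, no noise: two genomes that
    differ only by sequence divergence."""
    config = SimulationConfig(
        seed=7, n_chromosomes=2, genes_per_chromosome=60, wgd=False,
        gene_length_codons=(300, 400), inversion_count=0, translocation_count=0,
        tandem_family_count=0, expansion_count=0, noise_hit_fraction=0.0,
    )
    result = simulate_genomes(config)
    return result, simulate_hit_table(result)
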