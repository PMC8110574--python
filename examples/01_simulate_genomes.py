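"""Simulate a two-genome comparison with planted truth.

Builds a pair of genomes descended from a shared whole-genome duplication
(dS ~0.4) that speciated at dS ~0.1585, with one inversion, tandem arrays,
and species-specific expansions, then prints what was planted.
"""

from syntevo.simulate import SimulationConfig, simulate_genomes, simulate_hit_table

config = SimulationConfig(
    seed=1, n_chromosomes=3, genes_per_chromosome=100,
    gene_length_codons=(300, 450), inversion_count=1, inversion_size=(20, 40),
)
result = simulate_genomes(config)
hits = simulate_hit_table(result)

truth = result.truth
print(f"genome A: {len(result.annotations['A'])} genes on "
      f"{len(result.annotations['A'].chromosomes)} chromosomes")
print(f"genome B: {len(result.annotations['B'])} genes")
print(f"planted 1:1 orthologs : {len(truth.orthologs)}")
print(f"planted WGD paralog pairs (A): {len(truth.wgd_paralogs['A'])}")
print(f"planted tandem arrays (A): {len(truth.tandem_arrays['A'])}")
print(f"planted species-specific expansions: {len(truth.expansions)}")
print(f"planted inversions: {len(truth.inversions)}")
print(f"hit table rows (incl. {config.noise_hit_fraction:.0%} noise): {len(hits)}")
# Each ortholog pair should later be recovered by the synteny pipeline; the
# WGD pairs should surface as an intra-genome Ks peak near 0.4.
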