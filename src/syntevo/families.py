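"""Gene-family expansion classification, tandem-array detection, and
hypergeometric pathway enrichment.

Expansion rules follow two conventions: *lineage-shared* expansions need
strictly more than ``min_genes`` members with strictly more than
``min_fraction`` contributed jointly by the two focal genomes (each
contributing at least one gene); *species-specific* expansions use non-strict
thresholds (at least ``min_genes`` members, at least ``min_fraction`` from the
single focal genome).
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.stats import hypergeom

from .genome import GenomeAnnotation, ValidationError
from .ksdating import KsDistribution, ks_for_cds_pair, ks_peak
from .synteny import Orthogroup


@dataclass
class ExpansionCall:
    og_id: str
    label: str  # "lineage_shared" | "species_specific:<genome>" | "none"
    gene_count: int
    focal_fraction: float


@dataclass
class TandemArray:
    array_id: str
    chromosome: str
    member_genes: list[str]  # ordered by rank
    family: str

    @property
    def size(self) -> int:
        return len(self.member_genes)


@dataclass
class EnrichmentResult:
    pathway_id: str
    overlap: int
    set_size: int
    pathway_size: int
    universe_size: int
    p_value: float
    enriched: bool


@dataclass
class OverlapReport:
    n_expansion_genes: int
    n_overlap: int
    fraction: float


# ---------------------------------------------------------------------------
# Expansion classification
# ---------------------------------------------------------------------------

def classify_expansion(
    og: Orthogroup,
    focal_genomes: Sequence[str],
    mode: str,
    min_genes: int = 5,
    min_fraction: float | None = None,
) -> ExpansionCall:
    """Classify one orthogroup under the lineage or species expansion rule.

    ``lineage_shared``: total > min_genes (strict) and the combined focal-pair
    fraction > min_fraction (strict, default 0.70), with both focal genomes
    contributing. ``species_specific``: total >= min_genes and single-genome
    fraction >= min_fraction (both non-strict, default 0.50).
    """
    total = og.size
    if mode == "lineage_shared":
        frac_threshold = 0.70 if min_fraction is None else min_fraction
        focal = sum(len(og.members.get(g, ())) for g in focal_genomes)
        frac = focal / total if total else 0.0
        ok = (
            total > min_genes
            and frac > frac_threshold
            and all(len(og.members.get(g, ())) >= 1 for g in focal_genomes)
        )
        label = "lineage_shared" if ok else "none"
    elif mode == "species_specific":
        frac_threshold = 0.50 if min_fraction is None else min_fraction
        (genome,) = focal_genomes
        focal = len(og.members.get(genome, ()))
        frac = focal / total if total else 0.0
        ok = total >= min_genes and frac >= frac_threshold
        label = f"species_specific:{genome}" if ok else "none"
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return ExpansionCall(og.og_id, label, total, frac)


def classify_expansions(
    orthogroups: Iterable[Orthogroup],
    focal_genomes: Sequence[str],
    mode: str,
    min_genes: int = 5,
    min_fraction: float | None = None,
) -> list[ExpansionCall]:
    return [
        classify_expansion(og, focal_genomes, mode, min_genes, min_fraction)
        for og in orthogroups
    ]


# ---------------------------------------------------------------------------
# Tandem arrays
# ---------------------------------------------------------------------------

def detect_tandem_arrays(
    annotation: GenomeAnnotation,
    family_map: Mapping[str, str],
    max_rank_gap: int = 1,
) -> list[TandemArray]:
    """Maximal runs of same-family genes along a chromosome.

    Consecutive members may be at most ``max_rank_gap`` ranks apart
    (default 1: strictly adjacent, the conservative convention); runs of
    at least two genes are emitted.
    """
    arrays: list[TandemArray] = []
    serial = 0
    for chrom in annotation.chromosomes:
        members_by_family: dict[str, list] = defaultdict(list)
        for g in annotation.genes_on(chrom):
            fam = family_map.get(g.gene_id)
            if fam is not None:
                members_by_family[fam].append(g)
        for fam in sorted(members_by_family):
            genes = members_by_family[fam]  # already rank-ordered
            run = [genes[0]]
            for g in genes[1:]:
                if g.rank - run[-1].rank <= max_rank_gap:
                    run.append(g)
                else:
                    if len(run) >= 2:
                        arrays.append(
                            TandemArray(f"TA{serial:05d}", chrom,
                                        [x.gene_id for x in run], fam)
                        )
                        serial += 1
                    run = [g]
            if len(run) >= 2:
                arrays.append(
                    TandemArray(f"TA{serial:05d}", chrom, [x.gene_id for x in run], fam)
                )
                serial += 1
    return arrays


def expansion_tandem_overlap(
    expansions: Iterable[ExpansionCall],
    orthogroups: Mapping[str, Orthogroup],
    arrays: Iterable[TandemArray],
    genome_id: str,
) -> OverlapReport:
    """Fraction of species-specific expansion genes that sit in tandem arrays.

    Counting is gene-level: the focal genome's genes of expanded orthogroups
    intersected with tandem-array membership.
    """
    expansion_genes: set[str] = set()
    for call in expansions:
        if call.label == f"species_specific:{genome_id}":
            expansion_genes |= orthogroups[call.og_id].members.get(genome_id, set())
    array_genes = {g for arr in arrays for g in arr.member_genes}
    overlap = expansion_genes & array_genes
    frac = len(overlap) / len(expansion_genes) if expansion_genes else 0.0
    return OverlapReport(len(expansion_genes), len(overlap), frac)


# ---------------------------------------------------------------------------
# Relative-age Ks profiling
# ---------------------------------------------------------------------------

def expansion_age_profile(
    expanded_groups: Mapping[str, Sequence[Orthogroup]],
    cds: Mapping[str, str],
    reference_pairs: Sequence[tuple[str, str]] = (),
    **peak_kwargs,
) -> dict[str, KsDistribution]:
    """Pooled within-orthogroup Ks distributions per expansion class.

    For each class, Ks is computed for every intra-orthogroup gene pair with
    available CDS; orthogroups lacking two sequenced members are skipped.
    A ``reference`` distribution from supplied 1:1 ortholog pairs overlays
    the divergence peak.
    """
    import warnings

    out: dict[str, KsDistribution] = {}
    for label, groups in expanded_groups.items():
        values: list[float] = []
        for og in groups:
            genes = sorted(g for g in og.genes() if g in cds)
            if len(genes) < 2:
                warnings.warn(f"orthogroup {og.og_id} lacks two sequenced members")
                continue
            for i in range(len(genes)):
                for j in range(i + 1, len(genes)):
                    est = ks_for_cds_pair(genes[i], genes[j], cds[genes[i]], cds[genes[j]])
                    if not est.saturated:
                        values.append(est.ks)
        out[label] = ks_peak(values, **peak_kwargs)
    if reference_pairs:
        ref = [
            ks_for_cds_pair(a, b, cds[a], cds[b]).ks
            for a, b in reference_pairs
            if a in cds and b in cds
        ]
        out["reference"] = ks_peak(ref, **peak_kwargs)
    return out


# ---------------------------------------------------------------------------
# Hypergeometric pathway enrichment
# ---------------------------------------------------------------------------

def hypergeometric_enrichment(
    gene_set: Iterable[str],
    pathway_map: Mapping[str, Iterable[str]],
    universe: Iterable[str],
    alpha: float = 0.05,
) -> list[EnrichmentResult]:
    """Upper-tail hypergeometric enrichment of a gene set against pathways.

    For each pathway (intersected with the universe), p = P[X >= overlap]
    with population = universe size, successes = pathway size, draws = set
    size; pathways with p < alpha are flagged enriched. Results sorted by
    ascending p.
    """
    uni = set(universe)
    if not uni:
        raise ValidationError("empty universe")
    genes = set(gene_set) & uni
    results = []
    for pid in sorted(pathway_map):
        path = set(pathway_map[pid]) & uni
        k = len(genes & path)
        p = float(hypergeom.sf(k - 1, len(uni), len(path), len(genes)))
        p = min(p, 1.0)
        results.append(
            EnrichmentResult(pid, k, len(genes), len(path), len(uni), p, p < alpha)
        )
    results.sort(key=lambda r: (r.p_value, r.pathway_id))
    return results


def read_pathway_map(path) -> dict[str, set[str]]:
    """Pathway map TSV: pathway_id <tab> gene_id per line."""
    out: dict[str, set[str]] = defaultdict(set)
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            pid, gid = line.split("\t")[:2]
            out[pid].add(gid)
    return dict(out)
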