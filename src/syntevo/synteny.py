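"""Synteny-constrained orthology: cull -> pairwise orthogroups -> collinear
block chaining -> DBSCAN density pruning -> orthogroup completion -> block
extension -> syntenic homolog classification, plus per-chromosome summaries.

All collinearity is computed in *gene-rank* space: a block is a run of anchor
pairs strictly monotone in the ranks of both chromosomes, collinear
(rank_b increasing with rank_a) or inverted (rank_b decreasing).
"""

from __future__ import annotations

import warnings
from bisect import bisect_left
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.cluster import DBSCAN

from .genome import GenomeAnnotation, HomologyHit, ValidationError


@dataclass
class SyntenyParams:
    """Tunable parameters of the synteny pipeline.

    ``mbs`` is the minimum block size in anchors; the maximum allowed
    inter-anchor rank gap during chaining is
    ``gap_allowance_factor * 0.5 * mbs`` (25 at defaults) applied on both
    chromosomes independently. Density pruning uses DBSCAN with
    ``eps = dbscan_radius_factor * mbs`` gene ranks (Chebyshev metric by
    default) and ``min_pts = mbs`` (the point itself counts).
    """

    mbs: int = 10
    gap_allowance_factor: float = 5.0
    dbscan_radius_factor: float = 5.0
    dbscan_min_pts: int | None = None
    extension_radius: int = 100
    orthology_cull_radius: int = 50
    min_bit_score: float = 50.0
    top_hits_per_haplotype: int = 2
    best_score_fraction: float = 0.5
    tandem_exclusion_radius: int = 5
    dbscan_metric: str = "chebyshev"
    # alternative reading of the gap rule: cap the number of gapped steps per
    # block instead of the per-step rank gap (see docs/methods.md)
    gap_rule: str = "per_step"

    def __post_init__(self) -> None:
        if self.mbs < 1 or self.min_bit_score < 0:
            raise ValidationError("invalid synteny parameters")
        if not (0 < self.best_score_fraction <= 1):
            raise ValidationError("best_score_fraction must be in (0, 1]")

    @property
    def max_gap(self) -> int:
        return int(round(self.gap_allowance_factor * 0.5 * self.mbs))

    @property
    def eps(self) -> float:
        return self.dbscan_radius_factor * self.mbs

    @property
    def min_pts(self) -> int:
        return self.dbscan_min_pts if self.dbscan_min_pts is not None else self.mbs


@dataclass(frozen=True)
class AnchorPair:
    """One homologous gene pair placed in rank space on a chromosome pair."""

    gene_a: str
    gene_b: str
    rank_a: int
    rank_b: int
    bit_score: float = 0.0


@dataclass
class SyntenyBlock:
    """An ordered run of anchors on one chromosome pair."""

    block_id: str
    genome_a: str
    genome_b: str
    chrom_a: str
    chrom_b: str
    anchors: list[AnchorPair]
    orientation: str  # "collinear" | "inverted"

    @property
    def anchor_count(self) -> int:
        return len(self.anchors)

    def rank_bounds(self) -> tuple[int, int, int, int]:
        ra = [a.rank_a for a in self.anchors]
        rb = [a.rank_b for a in self.anchors]
        return min(ra), max(ra), min(rb), max(rb)


@dataclass
class Orthogroup:
    """Genes across >=1 genomes descended from a single ancestral gene."""

    og_id: str
    members: dict[str, set[str]] = field(default_factory=dict)

    @property
    def size(self) -> int:
        return sum(len(v) for v in self.members.values())

    def genes(self) -> set[str]:
        return set().union(*self.members.values()) if self.members else set()


@dataclass(frozen=True)
class SyntenicHomologClass:
    gene_a: str
    gene_b: str
    label: str  # ortholog | paralog | unclustered_homolog | dropped


# ---------------------------------------------------------------------------
# Stage 0: hit culling
# ---------------------------------------------------------------------------

def cull_hits(
    hits: Iterable[HomologyHit],
    annotations: Mapping[str, GenomeAnnotation],
    params: SyntenyParams | None = None,
) -> list[HomologyHit]:
    """Drop self-hits and weak hits; keep the top hits per target haplotype.

    Per query gene and target genome, the ``top_hits_per_haplotype x ploidy``
    highest-scoring hits survive (a haploid gene set standing for a diploid
    assembly keeps 2 x ploidy per genome), and every survivor must reach
    ``min_bit_score``. Output is a subset of input; the operation is
    idempotent.
    """
    params = params or SyntenyParams()
    genome_of = gene_to_genome(annotations)
    per_slot: dict[tuple[str, str], list[HomologyHit]] = defaultdict(list)
    for h in hits:
        if h.is_self or h.bit_score < params.min_bit_score:
            continue
        if h.query_gene not in genome_of or h.target_gene not in genome_of:
            raise ValidationError(
                f"hit references unknown gene: {h.query_gene} -> {h.target_gene}"
            )
        per_slot[(h.query_gene, genome_of[h.target_gene])].append(h)

    kept: list[HomologyHit] = []
    for (_, tgenome), slot in per_slot.items():
        cap = params.top_hits_per_haplotype * annotations[tgenome].ploidy
        slot.sort(key=lambda h: (-h.bit_score, h.target_gene))
        kept.extend(slot[:cap])
    kept.sort(key=lambda h: (h.query_gene, h.target_gene, -h.bit_score))
    return kept


def gene_to_genome(annotations: Mapping[str, GenomeAnnotation]) -> dict[str, str]:
    out: dict[str, str] = {}
    for gid, ann in annotations.items():
        for g in ann.genes:
            out[g.gene_id] = gid
    return out


# ---------------------------------------------------------------------------
# Stage 1: pairwise orthogroup inference
# ---------------------------------------------------------------------------

def infer_pairwise_orthogroups(
    culled_hits: Iterable[HomologyHit],
    genome_of: Mapping[str, str],
    genome_pair: tuple[str, str],
    params: SyntenyParams | None = None,
    og_prefix: str = "OG",
) -> list[Orthogroup]:
    """Cluster the inter-genome hit graph of one genome pair into orthogroups.

    Deterministic stand-in for a delegated clustering tool: hits below
    ``best_score_fraction`` of each gene's best inter-genome score are
    dropped, then connected components of the remaining undirected graph
    become orthogroups (singletons are not emitted).
    """
    params = params or SyntenyParams()
    ga, gb = genome_pair
    edges: list[tuple[str, str, float]] = []
    best: dict[str, float] = defaultdict(float)
    for h in culled_hits:
        qg, tg = genome_of[h.query_gene], genome_of[h.target_gene]
        if {qg, tg} != {ga, gb} or qg == tg:
            continue
        best[h.query_gene] = max(best[h.query_gene], h.bit_score)
        best[h.target_gene] = max(best[h.target_gene], h.bit_score)
        edges.append((h.query_gene, h.target_gene, h.bit_score))

    graph = nx.Graph()
    for u, v, s in edges:
        if s >= params.best_score_fraction * min(best[u], best[v]):
            graph.add_edge(u, v)

    groups: list[Orthogroup] = []
    comps = sorted(nx.connected_components(graph), key=lambda c: sorted(c)[0])
    for i, comp in enumerate(comps):
        og = Orthogroup(f"{og_prefix}_{ga}_{gb}_{i:05d}")
        for gene in comp:
            og.members.setdefault(genome_of[gene], set()).add(gene)
        groups.append(og)
    return groups


def gene_to_orthogroup(groups: Iterable[Orthogroup]) -> dict[str, str]:
    out: dict[str, str] = {}
    for og in groups:
        for gene in og.genes():
            out[gene] = og.og_id
    return out


def hits_within_orthogroups(
    hits: Iterable[HomologyHit], groups: Iterable[Orthogroup]
) -> list[HomologyHit]:
    """Retain only hits whose two endpoints fall in the same orthogroup."""
    og_of = gene_to_orthogroup(groups)
    return [
        h
        for h in hits
        if og_of.get(h.query_gene) is not None
        and og_of.get(h.query_gene) == og_of.get(h.target_gene)
    ]


# ---------------------------------------------------------------------------
# Stage 2: collinear block chaining
# ---------------------------------------------------------------------------

def anchors_from_hits(
    hits: Iterable[HomologyHit],
    ann_a: GenomeAnnotation,
    ann_b: GenomeAnnotation,
    params: SyntenyParams | None = None,
) -> dict[tuple[str, str], list[AnchorPair]]:
    """Place hits in rank space, grouped by (chrom_a, chrom_b).

    In intra-genome (paralog) mode — ``ann_a is ann_b`` — self-hits and
    tandem neighbours within ``tandem_exclusion_radius`` ranks are excluded
    and unordered pairs deduplicated, so tandem arrays do not masquerade as
    duplicated segments.
    """
    params = params or SyntenyParams()
    intra = ann_a.genome_id == ann_b.genome_id
    seen: set[tuple[str, str]] = set()
    out: dict[tuple[str, str], list[AnchorPair]] = defaultdict(list)
    for h in hits:
        if h.query_gene not in ann_a or h.target_gene not in ann_b:
            continue
        a, b = ann_a.gene(h.query_gene), ann_b.gene(h.target_gene)
        if intra:
            if a.gene_id == b.gene_id:
                continue
            if (
                a.chromosome == b.chromosome
                and abs(a.rank - b.rank) <= params.tandem_exclusion_radius
            ):
                continue
            key = (min(a.gene_id, b.gene_id), max(a.gene_id, b.gene_id))
            if key in seen:
                continue
            seen.add(key)
            if (a.chromosome, a.rank) > (b.chromosome, b.rank):
                a, b = b, a
        out[(a.chromosome, b.chromosome)].append(
            AnchorPair(a.gene_id, b.gene_id, a.rank, b.rank, h.bit_score)
        )
    return dict(out)


def _best_chain(
    ra: np.ndarray,
    rb: np.ndarray,
    order: np.ndarray,
    sign: int,
    max_gap: int,
    total_budget: int | None = None,
) -> tuple[list[int], int]:
    """Best monotone chain (indices into the original arrays) for one
    orientation; score = (length, -total excess gap, -start rank_a).

    ``total_budget``, when set, additionally caps the summed excess gap
    (ranks skipped beyond adjacency, both axes) over the whole chain.
    """
    n = len(order)
    length = np.ones(n, dtype=np.int64)
    gapsum = np.zeros(n, dtype=np.int64)
    prev = np.full(n, -1, dtype=np.int64)
    ras = ra[order]
    rbs = rb[order]
    for i in range(n):
        lo = bisect_left(ras, ras[i] - max_gap, 0, i)
        best = (0, 0)
        bj = -1
        for j in range(lo, i):
            da = ras[i] - ras[j]
            db = sign * (rbs[i] - rbs[j])
            if da < 1 or db < 1 or db > max_gap:
                continue
            excess = (da - 1) + (db - 1)
            if total_budget is not None and gapsum[j] + excess > total_budget:
                continue
            cand = (length[j], -(gapsum[j] + excess))
            if cand > best:
                best = cand
                bj = j
        if bj >= 0:
            length[i] = length[bj] + 1
            gapsum[i] = -best[1]
            prev[i] = bj
    # pick chain end: longest, then smallest gap sum, then smallest start rank
    starts = np.empty(n, dtype=np.int64)
    for i in range(n):
        j = i
        while prev[j] >= 0:
            j = prev[j]
        starts[i] = ras[j]
    best_i = min(range(n), key=lambda i: (-length[i], gapsum[i], starts[i]))
    chain = []
    j = best_i
    while j >= 0:
        chain.append(order[j])
        j = prev[j]
    chain.reverse()
    return chain, int(length[best_i])


def chain_collinear_blocks(
    anchors: Sequence[AnchorPair],
    params: SyntenyParams | None = None,
    genome_a: str = "A",
    genome_b: str = "B",
    chrom_a: str = "",
    chrom_b: str = "",
    block_prefix: str = "blk",
) -> list[SyntenyBlock]:
    """Chain anchors of one chromosome pair into maximal collinear blocks.

    Iterated dynamic programming in rank space: repeatedly extract the best
    chain strictly monotone in both ranks (either orientation) whose
    consecutive anchors are separated by at most ``max_gap`` ranks on both
    chromosomes; chains shorter than ``mbs`` are discarded, and each anchor
    joins at most one block. Chain score is anchor count; ties prefer the
    smaller total rank gap, then the smaller starting rank_a, then collinear
    orientation.
    """
    params = params or SyntenyParams()
    uniq: dict[tuple[int, int], AnchorPair] = {}
    dup = 0
    for a in anchors:
        key = (a.rank_a, a.rank_b)
        if key in uniq:
            dup += 1
            if a.bit_score > uniq[key].bit_score:
                uniq[key] = a
        else:
            uniq[key] = a
    if dup:
        warnings.warn(f"deduplicated {dup} anchors with identical rank coordinates")

    budget = params.max_gap if params.gap_rule == "total_gaps" else None
    pool = sorted(uniq.values(), key=lambda a: (a.rank_a, a.rank_b))
    blocks: list[SyntenyBlock] = []
    serial = 0
    while len(pool) >= params.mbs:
        ra = np.array([a.rank_a for a in pool])
        rb = np.array([a.rank_b for a in pool])
        idx = np.arange(len(pool))
        chain_f, len_f = _best_chain(ra, rb, idx, +1, params.max_gap, budget)
        chain_r, len_r = _best_chain(ra, rb, idx, -1, params.max_gap, budget)
        if (len_f, -_chain_gap(pool, chain_f)) >= (len_r, -_chain_gap(pool, chain_r)):
            chain, orientation = chain_f, "collinear"
        else:
            chain, orientation = chain_r, "inverted"
        if len(chain) < params.mbs:
            break
        members = [pool[i] for i in chain]
        blocks.append(
            SyntenyBlock(
                block_id=f"{block_prefix}{serial:04d}",
                genome_a=genome_a,
                genome_b=genome_b,
                chrom_a=chrom_a,
                chrom_b=chrom_b,
                anchors=members,
                orientation=orientation,
            )
        )
        serial += 1
        used = set(chain)
        pool = [a for i, a in enumerate(pool) if i not in used]
    return blocks


def _chain_gap(pool: Sequence[AnchorPair], chain: Sequence[int]) -> int:
    g = 0
    for u, v in zip(chain, chain[1:]):
        g += abs(pool[v].rank_a - pool[u].rank_a) + abs(pool[v].rank_b - pool[u].rank_b)
    return g


# ---------------------------------------------------------------------------
# Stage 3: density pruning (DBSCAN in rank space)
# ---------------------------------------------------------------------------

def prune_blocks_density(
    blocks: Iterable[SyntenyBlock], params: SyntenyParams | None = None
) -> list[SyntenyBlock]:
    """Prune each block to its dense cores.

    Anchors are clustered by DBSCAN in 2-D rank space (``eps = 5 x mbs``
    gene ranks, Chebyshev metric, ``min_pts = mbs`` counting the point
    itself); noise anchors and clusters below ``mbs`` anchors are removed,
    surviving clusters re-emitted as blocks.
    """
    params = params or SyntenyParams()
    out: list[SyntenyBlock] = []
    for blk in blocks:
        if blk.anchor_count < params.min_pts:
            continue
        pts = np.array([[a.rank_a, a.rank_b] for a in blk.anchors], dtype=float)
        db = DBSCAN(
            eps=params.eps, min_samples=params.min_pts, metric=params.dbscan_metric
        ).fit(pts)
        labels = db.labels_.copy()
        # DBSCAN border-point assignment depends on visit order; pin it down
        # by re-assigning each border point to its nearest core point.
        core = np.zeros(len(pts), dtype=bool)
        core[db.core_sample_indices_] = True
        if core.any():
            border = (labels >= 0) & ~core
            if border.any():
                dists = cdist(pts[border], pts[core], metric=params.dbscan_metric)
                labels[border] = labels[core][np.argmin(dists, axis=1)]
        for sub, label in enumerate(sorted(set(labels) - {-1})):
            members = [a for a, l in zip(blk.anchors, labels) if l == label]
            if len(members) < params.mbs:
                continue
            members.sort(key=lambda a: a.rank_a)
            out.append(
                SyntenyBlock(
                    block_id=f"{blk.block_id}.{sub}" if len(set(labels) - {-1}) > 1 else blk.block_id,
                    genome_a=blk.genome_a,
                    genome_b=blk.genome_b,
                    chrom_a=blk.chrom_a,
                    chrom_b=blk.chrom_b,
                    anchors=members,
                    orientation=_orientation_of(members),
                )
            )
    return out


def _orientation_of(anchors: Sequence[AnchorPair]) -> str:
    if len(anchors) < 2:
        return "collinear"
    up = sum(b.rank_b > a.rank_b for a, b in zip(anchors, anchors[1:]))
    return "collinear" if up * 2 >= len(anchors) - 1 else "inverted"


# ---------------------------------------------------------------------------
# Stage 4: orthogroup completion
# ---------------------------------------------------------------------------

def complete_orthogroups(
    pairwise_groups: Iterable[Orthogroup],
    genome_of: Mapping[str, str],
    og_prefix: str = "COG",
) -> list[Orthogroup]:
    """Merge pairwise orthogroups into multi-genome groups by transitive
    closure over shared genes. Idempotent: completing twice equals once."""
    graph = nx.Graph()
    for og in pairwise_groups:
        genes = sorted(og.genes())
        graph.add_nodes_from(genes)
        graph.add_edges_from(zip(genes, genes[1:]))
    merged: list[Orthogroup] = []
    comps = sorted(nx.connected_components(graph), key=lambda c: sorted(c)[0])
    for i, comp in enumerate(comps):
        og = Orthogroup(f"{og_prefix}{i:05d}")
        for gene in comp:
            og.members.setdefault(genome_of[gene], set()).add(gene)
        merged.append(og)
    return merged


# ---------------------------------------------------------------------------
# Stage 5: block extension with orthogroup-agnostic hits
# ---------------------------------------------------------------------------

def extend_blocks(
    blocks: Sequence[SyntenyBlock],
    score_passing_hits: Iterable[HomologyHit],
    ann_a: GenomeAnnotation,
    ann_b: GenomeAnnotation,
    params: SyntenyParams | None = None,
) -> list[SyntenyBlock]:
    """Re-form blocks after pulling in score-passing hits near existing
    blocks, orthogroup identity notwithstanding.

    Hits whose endpoints both lie within ``extension_radius`` gene ranks of a
    block on the same chromosome pair join the anchor pool; chaining and
    density pruning are re-run on the enlarged pools.
    """
    params = params or SyntenyParams()
    boxes: dict[tuple[str, str], list[tuple[int, int, int, int]]] = defaultdict(list)
    existing: dict[tuple[str, str], dict[tuple[int, int], AnchorPair]] = defaultdict(dict)
    for blk in blocks:
        key = (blk.chrom_a, blk.chrom_b)
        boxes[key].append(blk.rank_bounds())
        for a in blk.anchors:
            existing[key][(a.rank_a, a.rank_b)] = a

    r = params.extension_radius
    candidate = anchors_from_hits(
        [h for h in score_passing_hits if h.bit_score >= params.min_bit_score],
        ann_a,
        ann_b,
        params,
    )
    pools: dict[tuple[str, str], dict[tuple[int, int], AnchorPair]] = {
        key: dict(v) for key, v in existing.items()
    }
    for key, anchors in candidate.items():
        if key not in boxes:
            continue
        for a in anchors:
            if any(
                lo_a - r <= a.rank_a <= hi_a + r and lo_b - r <= a.rank_b <= hi_b + r
                for lo_a, hi_a, lo_b, hi_b in boxes[key]
            ):
                pools[key].setdefault((a.rank_a, a.rank_b), a)

    out: list[SyntenyBlock] = []
    for i, key in enumerate(sorted(pools)):
        chained = chain_collinear_blocks(
            list(pools[key].values()),
            params,
            genome_a=ann_a.genome_id,
            genome_b=ann_b.genome_id,
            chrom_a=key[0],
            chrom_b=key[1],
            block_prefix=f"ext{i:02d}_",
        )
        out.extend(prune_blocks_density(chained, params))
    return out


# ---------------------------------------------------------------------------
# Stage 6: syntenic homolog classification
# ---------------------------------------------------------------------------

def classify_syntenic_homologs(
    blocks: Sequence[SyntenyBlock],
    hits: Iterable[HomologyHit],
    completed_groups: Iterable[Orthogroup],
    annotations: Mapping[str, GenomeAnnotation],
    params: SyntenyParams | None = None,
) -> list[SyntenicHomologClass]:
    """Label hits near syntenic blocks as ortholog / paralog /
    unclustered_homolog / dropped.

    Hits are first culled to within ``orthology_cull_radius`` gene ranks of a
    block on the same chromosome pair. A surviving pair in a shared orthogroup
    is an ortholog (inter-genome) or paralog (intra-genome); an unclustered
    pair survives only with ``bit_score >= min_bit_score`` and at least
    ``best_score_fraction`` of the best score for that gene-by-genome
    combination.
    """
    params = params or SyntenyParams()
    genome_of = gene_to_genome(annotations)
    og_of = gene_to_orthogroup(completed_groups)

    # rank intervals covered by blocks, per (genome, chromosome), both sides
    intervals: dict[tuple[str, str], list[tuple[int, int]]] = defaultdict(list)
    for blk in blocks:
        lo_a, hi_a, lo_b, hi_b = blk.rank_bounds()
        intervals[(blk.genome_a, blk.chrom_a)].append((lo_a, hi_a))
        intervals[(blk.genome_b, blk.chrom_b)].append((lo_b, hi_b))

    def near_block(h: HomologyHit) -> bool:
        r = params.orthology_cull_radius
        for gene in (h.query_gene, h.target_gene):
            genome = genome_of[gene]
            g = annotations[genome].gene(gene)
            if not any(
                lo - r <= g.rank <= hi + r
                for lo, hi in intervals.get((genome, g.chromosome), ())
            ):
                return False
        return True

    best: dict[tuple[str, str], float] = defaultdict(float)
    pairs: dict[tuple[str, str], float] = {}
    for h in hits:
        if h.is_self:
            continue
        key = (min(h.query_gene, h.target_gene), max(h.query_gene, h.target_gene))
        if key not in pairs or h.bit_score > pairs[key]:
            pairs[key] = h.bit_score
        best[(h.query_gene, genome_of[h.target_gene])] = max(
            best[(h.query_gene, genome_of[h.target_gene])], h.bit_score
        )
        best[(h.target_gene, genome_of[h.query_gene])] = max(
            best[(h.target_gene, genome_of[h.query_gene])], h.bit_score
        )

    out: list[SyntenicHomologClass] = []
    for (a, b), score in sorted(pairs.items()):
        h = HomologyHit(a, b, score)
        if not near_block(h):
            continue
        ga, gb = genome_of[a], genome_of[b]
        oa, ob = og_of.get(a), og_of.get(b)
        if oa is not None and oa == ob:
            label = "paralog" if ga == gb else "ortholog"
        else:
            frac_ok = score >= params.best_score_fraction * max(
                best[(a, gb)], best[(b, ga)]
            )
            label = (
                "unclustered_homolog"
                if score >= params.min_bit_score and frac_ok
                else "dropped"
            )
        out.append(SyntenicHomologClass(a, b, label))
    return out


# ---------------------------------------------------------------------------
# Reporting
# ---------------------------------------------------------------------------

def pct(numerator: float, denominator: float) -> float:
    """Percentage rounded to one decimal, the convention of the summary table."""
    return round(100.0 * numerator / denominator, 1) if denominator else 0.0


def summarize_synteny(
    blocks: Sequence[SyntenyBlock],
    annotation: GenomeAnnotation,
    min_block_genes: int = 25,
) -> pd.DataFrame:
    """Per-chromosome synteny summary for the focal (A-side) genome.

    Blocks are re-filtered to ``min_block_genes`` anchors for reporting.
    Columns: total genes, genes in syntenic blocks, percent in blocks, number
    of blocks, genes in the largest block, percent captured by the largest
    block; a final TOTAL row carries genome-wide counts and percentage.
    """
    big = [b for b in blocks if b.anchor_count >= min_block_genes]
    per_chrom_genes: dict[str, set[str]] = defaultdict(set)
    per_chrom_blocks: dict[str, list[set[str]]] = defaultdict(list)
    for blk in big:
        genes = {a.gene_a for a in blk.anchors}
        per_chrom_genes[blk.chrom_a] |= genes
        per_chrom_blocks[blk.chrom_a].append(genes)

    rows = []
    for chrom in annotation.chromosomes:
        total = len(annotation.genes_on(chrom))
        in_blocks = len(per_chrom_genes.get(chrom, set()))
        largest = max((len(g) for g in per_chrom_blocks.get(chrom, [])), default=0)
        rows.append(
            {
                "chromosome": chrom,
                "total_genes": total,
                "genes_in_blocks": in_blocks,
                "pct_in_blocks": pct(in_blocks, total),
                "n_blocks": len(per_chrom_blocks.get(chrom, [])),
                "largest_block_genes": largest,
                "pct_largest_block": pct(largest, total),
            }
        )
    total_genes = sum(r["total_genes"] for r in rows)
    total_in = sum(r["genes_in_blocks"] for r in rows)
    rows.append(
        {
            "chromosome": "TOTAL",
            "total_genes": total_genes,
            "genes_in_blocks": total_in,
            "pct_in_blocks": pct(total_in, total_genes),
            "n_blocks": sum(r["n_blocks"] for r in rows),
            "largest_block_genes": max((r["largest_block_genes"] for r in rows), default=0),
            "pct_largest_block": float("nan"),
        }
    )
    return pd.DataFrame(rows)


def summary_from_counts(
    counts: Sequence[tuple[str, int, int, int]]
) -> pd.DataFrame:
    """Summary-table arithmetic from per-chromosome counts.

    ``counts`` rows are (chromosome, total_genes, genes_in_blocks,
    largest_block_genes); used when block gene counts come from an external
    table rather than from block objects.
    """
    rows = [
        {
            "chromosome": chrom,
            "total_genes": total,
            "genes_in_blocks": in_blocks,
            "pct_in_blocks": pct(in_blocks, total),
            "largest_block_genes": largest,
            "pct_largest_block": pct(largest, total),
        }
        for chrom, total, in_blocks, largest in counts
    ]
    total_genes = sum(r["total_genes"] for r in rows)
    total_in = sum(r["genes_in_blocks"] for r in rows)
    rows.append(
        {
            "chromosome": "TOTAL",
            "total_genes": total_genes,
            "genes_in_blocks": total_in,
            "pct_in_blocks": pct(total_in, total_genes),
            "largest_block_genes": max(r["largest_block_genes"] for r in rows),
            "pct_largest_block": float("nan"),
        }
    )
    return pd.DataFrame(rows)


def write_blocks(blocks: Iterable[SyntenyBlock], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "block_id\tgenome_a\tchrom_a\tgenome_b\tchrom_b\torientation"
            "\tanchor_count\tanchors\n"
        )
        for b in blocks:
            pairs = ",".join(f"{a.gene_a}|{a.gene_b}" for a in b.anchors)
            fh.write(
                f"{b.block_id}\t{b.genome_a}\t{b.chrom_a}\t{b.genome_b}\t{b.chrom_b}"
                f"\t{b.orientation}\t{b.anchor_count}\t{pairs}\n"
            )


def write_orthogroups(groups: Iterable[Orthogroup], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("og_id\tgenome_id\tgene_id\n")
        for og in groups:
            for genome in sorted(og.members):
                for gene in sorted(og.members[genome]):
                    fh.write(f"{og.og_id}\t{genome}\t{gene}\n")
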