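"""Synthetic genome-evolution simulator with planted truth.

Generates two descendant genomes related by an optional shared whole-genome
duplication (WGD), lineage-specific inversions and reciprocal translocations,
tandem duplications and species-specific family expansions, codon sequences
evolved to target synonymous divergences, an all-vs-all hit table, and diploid
read profiles at a target heterozygosity — together with truth tables for
every planted feature.

Every gene carries a lineage *path* from its family root (family ->
WGD copy -> species -> duplication events), each step with an expected
synonymous branch length; the true pairwise dS of any two copies is the sum
of branch lengths below their last shared node, and codon sequences are
evolved along exactly those branches.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

from . import _codons as ct
from .genome import GeneModel, GenomeAnnotation, HomologyHit
from .popgen import ProfileSet


@dataclass
class SimulationConfig:
    """Study conditions of a simulated two-genome comparison.

    Defaults mirror the structure of a eucalypt-style comparison: 11
    chromosomes, a shared paleotetraploidy at dS ~0.4, a speciation
    divergence at dS ~0.1585, diploid heterozygosity ~0.8% at 20x coverage
    with 1% sequencing error.
    """

    seed: int = 0
    n_chromosomes: int = 11
    genes_per_chromosome: int = 200
    gene_length_codons: tuple[int, int] = (300, 1500)
    wgd: bool = True
    wgd_ks: float = 0.4
    speciation_ks: float = 0.1585
    loss_fraction: float = 0.3
    inversion_count: int = 3
    inversion_size: tuple[int, int] = (30, 100)
    translocation_count: int = 1
    tandem_family_count: int = 40
    tandem_sizes: tuple[int, ...] = (2, 3)
    tandem_ks: float = 0.02
    expansion_count: int = 8
    expansion_size: int = 6
    expansion_ks: float = 0.05
    noise_hit_fraction: float = 0.1
    omega: float = 0.2
    emit_sequences: bool = True
    heterozygosity: float = 0.008
    coverage: float = 20.0
    error_rate: float = 0.01
    profile_sites: int = 100_000
    intergenic_bp: int = 500

    def __post_init__(self) -> None:
        for frac in (self.loss_fraction, self.noise_hit_fraction):
            if not (0.0 <= frac <= 1.0):
                raise ValueError("fractions must be in [0, 1]")
        if self.wgd and self.wgd_ks < self.speciation_ks:
            raise ValueError("wgd_ks must be >= speciation_ks (WGD predates speciation)")
        if self.inversion_count and self.inversion_size[0] >= self.genes_per_chromosome:
            raise ValueError("inversion longer than a chromosome")


@dataclass
class TruthTables:
    """Planted ground truth, keyed by emitted gene ids."""

    orthologs: list[tuple[str, str]] = field(default_factory=list)
    wgd_paralogs: dict[str, list[tuple[str, str]]] = field(default_factory=dict)
    block_extents: list[dict] = field(default_factory=list)
    tandem_arrays: dict[str, list[list[str]]] = field(default_factory=dict)
    expansions: dict[str, list[str]] = field(default_factory=dict)
    inversions: list[dict] = field(default_factory=list)
    translocations: list[dict] = field(default_factory=list)
    family_map: dict[str, dict[str, str]] = field(default_factory=dict)
    theta: float = 0.0


class _SimGene:
    __slots__ = ("origin", "family", "path", "seq", "length", "strand")

    def __init__(self, origin, family, path, seq, length, strand="+"):
        self.origin = origin
        self.family = family
        self.path = path  # tuple of (node label, branch dS)
        self.seq = seq  # codon-index array or None
        self.length = length  # codons
        self.strand = strand

    def child(self, label: str, branch_ds: float, rng, omega: float) -> "_SimGene":
        seq = (
            evolve_codon_array(self.seq, branch_ds, omega, rng)
            if self.seq is not None
            else None
        )
        return _SimGene(
            origin=f"{self.origin}.{label}" if label[0] in "de" else self.origin,
            family=self.family,
            path=self.path + ((label, branch_ds),),
            seq=seq,
            length=self.length,
            strand=self.strand,
        )


def pair_divergence(path_a, path_b) -> float:
    """True expected pairwise dS: branch lengths below the last shared node."""
    i = 0
    while i < min(len(path_a), len(path_b)) and path_a[i][0] == path_b[i][0]:
        i += 1
    return sum(l for _, l in path_a[i:]) + sum(l for _, l in path_b[i:])


# ---------------------------------------------------------------------------
# Codon evolution
# ---------------------------------------------------------------------------

def evolve_codon_array(
    codons: np.ndarray, target_ds: float, omega: float, rng: np.random.Generator
) -> np.ndarray:
    """Evolve a codon sequence to an expected synonymous divergence.

    Single-base proposals are applied at random positions: changes creating a
    stop codon are rejected, synonymous changes always accepted, and
    nonsynonymous changes accepted with probability ``omega``. The number of
    synonymous substitutions is Poisson with mean ``target_ds`` times the
    sequence's synonymous site count, so the realised dS is the target in
    expectation.
    """
    arr = [int(c) for c in codons]
    if target_ds <= 0:
        return np.array(arr, dtype=np.int64)
    syn_sites = float(ct.SYN_SITES[np.asarray(arr)].sum())
    n_syn_target = int(rng.poisson(target_ds * syn_sites))
    if n_syn_target == 0:
        return np.array(arr, dtype=np.int64)

    neighbor = ct.NEIGHBOR.tolist()
    aa = ct.AA.tolist()
    is_stop = ct.IS_STOP.tolist()
    n_pos = 3 * len(arr)
    syn_done = 0
    while syn_done < n_syn_target:
        pos = rng.integers(0, n_pos, size=2048)
        offs = rng.integers(1, 4, size=2048)
        us = rng.random(2048)
        for i in range(2048):
            p = int(pos[i])
            ci, cp = divmod(p, 3)
            cur = arr[ci]
            base = (cur >> ((2 - cp) * 2)) & 3
            nxt = neighbor[cur][cp][(base + int(offs[i])) % 4]
            if is_stop[nxt]:
                continue
            if aa[nxt] == aa[cur]:
                arr[ci] = nxt
                syn_done += 1
                if syn_done >= n_syn_target:
                    break
            elif us[i] < omega:
                arr[ci] = nxt
    return np.array(arr, dtype=np.int64)


def evolve_codons(cds: str, target_ds: float, omega: float = 0.2, seed: int = 0) -> str:
    """String-level convenience wrapper around :func:`evolve_codon_array`."""
    rng = np.random.default_rng(seed)
    return ct.decode(evolve_codon_array(ct.encode(cds), target_ds, omega, rng))


# ---------------------------------------------------------------------------
# Genome simulation
# ---------------------------------------------------------------------------

@dataclass
class SimulationResult:
    config: SimulationConfig
    annotations: dict[str, GenomeAnnotation]
    cds: dict[str, dict[str, str]]
    truth: TruthTables
    #: per genome: chromosome -> ordered list of (_SimGene, gene_id)
    _layout: dict = field(default_factory=dict, repr=False)

    def proteins(self, genome: str) -> dict[str, str]:
        return {
            gid: ct.translate_codons(ct.encode(seq))
            for gid, seq in self.cds[genome].items()
        }


def simulate_genomes(config: SimulationConfig) -> SimulationResult:
    """Simulate two genomes with planted WGD, rearrangements, and duplications.

    Pipeline: ancestral gene order with random CDS -> optional WGD (duplicate
    all chromosomes, diverge the copies, apply gene loss in the pre-speciation
    ancestor) -> speciation into genomes A and B -> inversions and reciprocal
    translocations in genome B (lineage-specific) -> tandem arrays in both
    genomes and species-specific expansions in genome A -> coordinate/rank
    assignment. Truth tables record every event.
    """
    rng = np.random.default_rng(config.seed)
    lo, hi = config.gene_length_codons

    # 1. ancestral genome
    ancestor: list[list[_SimGene]] = []
    for c in range(config.n_chromosomes):
        chrom = []
        for j in range(config.genes_per_chromosome):
            fam = f"F{c:02d}{j:04d}"
            length = int(rng.integers(lo, hi + 1))
            seq = (
                np.array(rng.choice(ct.SENSE_CODONS, size=length), dtype=np.int64)
                if config.emit_sequences
                else None
            )
            strand = "+" if rng.random() < 0.5 else "-"
            chrom.append(_SimGene(fam, fam, ((fam, 0.0),), seq, length, strand))
        ancestor.append(chrom)

    truth = TruthTables(theta=config.heterozygosity)

    # 2. WGD: duplicate every chromosome, diverge the two copies so that at
    # speciation they sit at pairwise dS = wgd_ks - speciation_ks, then lose
    # copies in the shared ancestor.
    if config.wgd:
        half_branch = (config.wgd_ks - config.speciation_ks) / 2.0
        copy0, copy1 = [], []
        for chrom in ancestor:
            c0, c1 = [], []
            for g in chrom:
                g0 = g.child("w0", half_branch, rng, config.omega)
                g1 = g.child("w1", half_branch, rng, config.omega)
                g0.origin, g1.origin = f"{g.family}.w0", f"{g.family}.w1"
                if rng.random() >= config.loss_fraction:
                    c0.append(g0)
                if rng.random() >= config.loss_fraction:
                    c1.append(g1)
            copy0.append(c0)
            copy1.append(c1)
        chromosomes = copy0 + copy1
    else:
        chromosomes = ancestor

    # 3. speciation
    genomes: dict[str, list[list[_SimGene]]] = {}
    for gname in ("A", "B"):
        genomes[gname] = [
            [g.child(gname, config.speciation_ks / 2.0, rng, config.omega) for g in chrom]
            for chrom in chromosomes
        ]

    # 4. lineage-specific rearrangements (genome B)
    inv_members: list[dict] = []
    n_chroms = len(genomes["B"])
    for _ in range(config.inversion_count):
        ci = int(rng.integers(0, n_chroms))
        chrom = genomes["B"][ci]
        hi_sz = min(config.inversion_size[1], len(chrom) - 1)
        lo_sz = min(config.inversion_size[0], hi_sz)
        size = int(rng.integers(lo_sz, hi_sz + 1))
        start = int(rng.integers(0, len(chrom) - size + 1))
        seg = chrom[start : start + size][::-1]
        for g in seg:
            g.strand = "-" if g.strand == "+" else "+"
        chrom[start : start + size] = seg
        inv_members.append(
            {"genome": "B", "chrom_index": ci, "origins": [g.origin for g in seg]}
        )
    for _ in range(config.translocation_count):
        if n_chroms < 2:
            break
        ci, cj = rng.choice(n_chroms, size=2, replace=False)
        a, b = genomes["B"][int(ci)], genomes["B"][int(cj)]
        cut_a = int(rng.integers(int(0.3 * len(a)), int(0.8 * len(a))))
        cut_b = int(rng.integers(int(0.3 * len(b)), int(0.8 * len(b))))
        genomes["B"][int(ci)], genomes["B"][int(cj)] = (
            a[:cut_a] + b[cut_b:],
            b[:cut_b] + a[cut_a:],
        )
        truth.translocations.append(
            {"genome": "B", "chrom_a": int(ci), "chrom_b": int(cj),
             "cut_a": cut_a, "cut_b": cut_b}
        )

    # 5. tandem arrays (both genomes) and species-specific expansions (A)
    planted_arrays: dict[str, list[list[str]]] = {"A": [], "B": []}
    expansion_origins: dict[str, list[str]] = {}
    for gname in ("A", "B"):
        chroms = genomes[gname]
        flat = [(ci, gi) for ci, chrom in enumerate(chroms) for gi in range(len(chrom))]
        n_tandem = min(config.tandem_family_count, len(flat))
        sel = rng.choice(len(flat), size=n_tandem, replace=False)
        sizes = [int(rng.choice(config.tandem_sizes)) for _ in range(n_tandem)]
        # insert from the highest index down so earlier picks keep their indices
        for (s, size) in sorted(zip(sel.tolist(), sizes), reverse=True):
            ci, gi = flat[s]
            parent = chroms[ci][gi]
            copies = [
                parent.child(f"d{d + 1}", config.tandem_ks, rng, config.omega)
                for d in range(size - 1)
            ]
            chroms[ci][gi + 1 : gi + 1] = copies
            planted_arrays[gname].append([parent.origin] + [c.origin for c in copies])
        planted_arrays[gname].sort()
        if gname == "A" and config.expansion_count:
            used_fams = {arr[0].split(".")[0] for arrs in planted_arrays.values() for arr in arrs}
            candidates = [
                (ci, gi)
                for ci, chrom in enumerate(chroms)
                for gi, g in enumerate(chrom)
                if g.family not in used_fams and "." not in g.origin.replace(".w", "")
            ]
            sel = rng.permutation(len(candidates))[: config.expansion_count]
            for s in sorted(sel, reverse=True):  # insert from the back: stable indices
                ci, gi = candidates[int(s)]
                parent = chroms[ci][gi]
                n_new = max(config.expansion_size - 1, 1)
                copies = [
                    parent.child(f"e{d + 1}", config.expansion_ks, rng, config.omega)
                    for d in range(n_new)
                ]
                chroms[ci][gi + 1 : gi + 1] = copies
                expansion_origins[parent.family] = [parent.origin] + [
                    c.origin for c in copies
                ]

    # 6. assemble annotations, ids, coordinates, truth
    annotations: dict[str, GenomeAnnotation] = {}
    cds: dict[str, dict[str, str]] = {}
    layout: dict[str, dict[str, list]] = {}
    origin_to_id: dict[str, dict[str, str]] = {"A": {}, "B": {}}
    origin_pos: dict[str, dict[str, tuple[str, int]]] = {"A": {}, "B": {}}
    for gname in ("A", "B"):
        genes, seqs = [], {}
        layout[gname] = {}
        fam_map: dict[str, str] = {}
        for ci, chrom in enumerate(genomes[gname]):
            cname = f"chr{ci + 1:02d}"
            pos = 0
            layout[gname][cname] = []
            for rank, g in enumerate(chrom):
                gid = f"g{gname}.{g.origin}"
                start = pos + config.intergenic_bp
                end = start + 3 * g.length
                pos = end
                genes.append(GeneModel(gid, cname, start, end, g.strand))
                if g.seq is not None:
                    seqs[gid] = ct.decode(g.seq)
                fam_map[gid] = g.family
                layout[gname][cname].append((g, gid))
                origin_to_id[gname][g.origin] = gid
                origin_pos[gname][g.origin] = (cname, rank)
        annotations[gname] = GenomeAnnotation(gname, genes)
        cds[gname] = seqs
        truth.family_map[gname] = fam_map

    # orthologs: shared origins (1:1 by construction)
    shared = sorted(set(origin_to_id["A"]) & set(origin_to_id["B"]))
    truth.orthologs = [(origin_to_id["A"][o], origin_to_id["B"][o]) for o in shared]

    # WGD paralog pairs per genome
    if config.wgd:
        for gname in ("A", "B"):
            pairs = []
            ids = origin_to_id[gname]
            for o in ids:
                if o.endswith(".w0"):
                    twin = o[:-3] + ".w1"
                    if twin in ids:
                        pairs.append((ids[o], ids[twin]))
            truth.wgd_paralogs[gname] = sorted(pairs)

    # planted tandem arrays / expansions, as emitted gene ids
    for gname in ("A", "B"):
        truth.tandem_arrays[gname] = [
            [origin_to_id[gname][o] for o in arr] for arr in planted_arrays[gname]
        ]
    truth.expansions = {
        fam: [origin_to_id["A"][o] for o in origins]
        for fam, origins in expansion_origins.items()
    }

    # inversion extents in final rank space
    for inv in inv_members:
        ranks = [origin_pos["B"][o][1] for o in inv["origins"] if o in origin_pos["B"]]
        chroms_now = {origin_pos["B"][o][0] for o in inv["origins"] if o in origin_pos["B"]}
        for cname in sorted(chroms_now):
            rs = [
                origin_pos["B"][o][1]
                for o in inv["origins"]
                if o in origin_pos["B"] and origin_pos["B"][o][0] == cname
            ]
            if len(rs) >= 2:
                truth.inversions.append(
                    {"genome": "B", "chromosome": cname,
                     "lo_rank": min(rs), "hi_rank": max(rs), "n_genes": len(rs)}
                )

    truth.block_extents = _true_block_extents(origin_pos, shared)
    return SimulationResult(config, annotations, cds, truth, _layout=layout)


def _true_block_extents(origin_pos, shared_origins, gap_tol: int = 10):
    """Maximal monotone runs of true ortholog pairs in A-B rank space."""
    by_chrom: dict[str, list[tuple[int, str, int]]] = {}
    for o in shared_origins:
        ca, ra = origin_pos["A"][o]
        cb, rb = origin_pos["B"][o]
        by_chrom.setdefault(ca, []).append((ra, cb, rb))
    extents = []
    for ca in sorted(by_chrom):
        pts = sorted(by_chrom[ca])
        run: list[tuple[int, str, int]] = []
        direction = 0
        for pt in pts:
            if run:
                pra, pcb, prb = run[-1]
                ra, cb, rb = pt
                step = rb - prb
                ok = (
                    cb == pcb
                    and ra - pra <= gap_tol
                    and 0 < abs(step) <= gap_tol
                    and (direction == 0 or np.sign(step) == direction)
                )
                if ok:
                    direction = int(np.sign(step)) if direction == 0 else direction
                    run.append(pt)
                    continue
                if len(run) >= 2:
                    extents.append(_extent_record(ca, run, direction))
                run, direction = [], 0
            run.append(pt)
        if len(run) >= 2:
            extents.append(_extent_record(ca, run, direction))
    return extents


def _extent_record(chrom_a, run, direction):
    ras = [r[0] for r in run]
    rbs = [r[2] for r in run]
    return {
        "chrom_a": chrom_a,
        "chrom_b": run[0][1],
        "ra_lo": min(ras),
        "ra_hi": max(ras),
        "rb_lo": min(rbs),
        "rb_hi": max(rbs),
        "orientation": "inverted" if direction < 0 else "collinear",
        "n_pairs": len(run),
    }


# ---------------------------------------------------------------------------
# Hit-table synthesis
# ---------------------------------------------------------------------------

def _bit_score(d: float, length_aa: int) -> float:
    """Deterministic identity->score map, strictly decreasing in divergence."""
    return round(2.0 * length_aa * math.exp(-1.3 * d), 2)


def simulate_hit_table(
    result: SimulationResult, config: SimulationConfig | None = None
) -> list[HomologyHit]:
    """Synthesize an all-vs-all hit table from the planted homology.

    Every within-family pair of gene copies (inter- and intra-genome) yields
    a directed hit in both directions with a deterministic bit score strictly
    decreasing in true divergence; ``noise_hit_fraction`` spurious random
    pairs are added with low, seeded-random scores (40-80).
    """
    config = config or result.config
    rng = np.random.default_rng(config.seed + 1)

    fam_members: dict[str, list[tuple[str, _SimGene]]] = {}
    all_ids: list[str] = []
    for gname, per_chrom in result._layout.items():
        for cname in sorted(per_chrom):
            for g, gid in per_chrom[cname]:
                fam_members.setdefault(g.family, []).append((gid, g))
                all_ids.append(gid)

    hits: list[HomologyHit] = []
    for fam in sorted(fam_members):
        members = fam_members[fam]
        for i in range(len(members)):
            for j in range(len(members)):
                if i == j:
                    continue
                gid_i, gi = members[i]
                gid_j, gj = members[j]
                d = pair_divergence(gi.path, gj.path)
                length = min(gi.length, gj.length)
                score = _bit_score(d, length)
                pid = round(100.0 * math.exp(-0.45 * d), 1)
                hits.append(
                    HomologyHit(gid_i, gid_j, bit_score=score,
                                percent_identity=pid,
                                evalue=float(2.0 ** (-min(score, 900.0))),
                                length=length)
                )

    n_noise = int(round(config.noise_hit_fraction * len(hits)))
    if n_noise:
        qi = rng.integers(0, len(all_ids), size=n_noise)
        ti = rng.integers(0, len(all_ids), size=n_noise)
        scores = rng.uniform(40.0, 80.0, size=n_noise)
        pids = rng.uniform(30.0, 60.0, size=n_noise)
        for q, t, s, p in zip(qi, ti, scores, pids):
            if q == t:
                t = (t + 1) % len(all_ids)
            hits.append(
                HomologyHit(all_ids[int(q)], all_ids[int(t)],
                            bit_score=round(float(s), 2),
                            percent_identity=round(float(p), 1),
                            evalue=1e-5, length=100)
            )
    return hits


# ---------------------------------------------------------------------------
# Read-profile simulation
# ---------------------------------------------------------------------------

def simulate_profiles(
    config: SimulationConfig, n_sites: int | None = None, seed: int | None = None
) -> tuple[ProfileSet, float]:
    """Simulate diploid read profiles at the configured heterozygosity.

    Per site: heterozygous with probability theta/(1+theta); depth is
    Poisson(coverage); reads split evenly between the two alleles of a het
    site; each read errs with probability ``error_rate`` to a uniformly
    chosen other base. Returns the profiles and the true theta.
    """
    rng = np.random.default_rng(config.seed + 2 if seed is None else seed)
    n = config.profile_sites if n_sites is None else n_sites
    theta = config.heterozygosity
    eps = config.error_rate

    depth = rng.poisson(config.coverage, size=n)
    het = rng.random(n) < theta / (1.0 + theta)
    base1 = rng.integers(0, 4, size=n)
    base2 = (base1 + rng.integers(1, 4, size=n)) % 4

    counts = np.zeros((n, 4), dtype=np.int64)
    from_b1 = np.where(het, rng.binomial(depth, 0.5), depth)
    from_b2 = depth - from_b1

    for source, nreads in ((base1, from_b1), (base2, from_b2)):
        active = nreads > 0
        err = rng.binomial(nreads, eps) if eps > 0 else np.zeros(n, dtype=np.int64)
        correct = nreads - err
        np.add.at(counts, (np.arange(n)[active], source[active]), correct[active])
        has_err = err > 0
        if has_err.any():
            split = rng.multinomial(err[has_err], [1 / 3.0] * 3)
            rows = np.arange(n)[has_err]
            src = source[has_err]
            for k in range(3):
                dest = (src + 1 + k) % 4
                np.add.at(counts, (rows, dest), split[:, k])

    chroms = np.array(["sim"] * n, dtype=object)
    return ProfileSet(counts, chroms, np.arange(1, n + 1)), theta


# ---------------------------------------------------------------------------
# Output writing
# ---------------------------------------------------------------------------

def write_simulation(result: SimulationResult, outdir: str | Path) -> None:
    """Emit GFF3 + FASTA (CDS, protein) per genome, hit TSV, and truth JSON."""
    from .genome import write_annotation, write_hit_table

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    for gname, ann in result.annotations.items():
        write_annotation(ann, out / f"genome{gname}.gff3")
        if result.cds[gname]:
            with open(out / f"genome{gname}.cds.fasta", "w") as fh:
                for gid in sorted(result.cds[gname]):
                    fh.write(f">{gid}\n{result.cds[gname][gid]}\n")
            with open(out / f"genome{gname}.protein.fasta", "w") as fh:
                for gid, prot in sorted(result.proteins(gname).items()):
                    fh.write(f">{gid}\n{prot}\n")
    write_hit_table(simulate_hit_table(result), out / "hits.tsv")
    with open(out / "truth.json", "w") as fh:
        json.dump(asdict(result.truth), fh, indent=1, default=list)
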