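"""End-to-end orchestration: synteny -> orthology -> Ks -> families
(+ optional popgen), with a machine-readable run manifest.

The pipeline is a thin composition of the library modules; every number in
its reports is reproducible by calling the corresponding module operation
directly on the same inputs.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any

import yaml

from . import families as fam
from . import ksdating as ks
from . import popgen as pg
from . import synteny as syn
from .genome import read_annotation, read_hit_table, write_annotation


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Paths and parameters of a full run; YAML round-trippable."""

    gff: dict[str, str]  # genome_id -> GFF3 path
    hits: str
    outdir: str
    cds: dict[str, str] = field(default_factory=dict)  # genome_id -> CDS FASTA
    profiles: str | None = None
    pathways: str | None = None
    focal_genome: str | None = None
    synteny: dict[str, Any] = field(default_factory=dict)
    divergence_times: list[float] = field(default_factory=lambda: [57.2e6, 64.6e6])
    ne: int = 112_421
    generation_time: float = 15.0
    min_block_genes: int = 25
    wgd_window: tuple[float, float] = (0.33, 0.45)
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if "wgd_window" in data:
            data["wgd_window"] = tuple(data["wgd_window"])
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["wgd_window"] = list(self.wgd_window)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _read_fasta(path: str | Path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def run_full_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Execute all configured stages and write a report bundle.

    Outputs under ``config.outdir``: blocks.tsv, orthogroups.tsv,
    synteny_summary.tsv, homolog_classes.tsv, ks_pairs.tsv / ks_peaks.tsv
    (when CDS supplied), families_*.tsv, popgen.json (when profiles
    supplied), and manifest.json echoing every parameter and input checksum.
    Any stage failure raises :class:`StageError` naming the stage.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    params = syn.SyntenyParams(**config.synteny)
    stages_done: list[str] = []
    results: dict[str, Any] = {}

    # ---- load ----------------------------------------------------------
    try:
        annotations = {
            gid: read_annotation(path, gid) for gid, path in sorted(config.gff.items())
        }
        hits = read_hit_table(config.hits)
        genome_of = syn.gene_to_genome(annotations)
    except Exception as exc:
        raise StageError("load", exc) from exc
    stages_done.append("load")

    genome_ids = sorted(annotations)
    focal = config.focal_genome or genome_ids[0]
    other = [g for g in genome_ids if g != focal]

    # ---- synteny -------------------------------------------------------
    try:
        culled = syn.cull_hits(hits, annotations, params)
        pairwise_groups: list[syn.Orthogroup] = []
        all_blocks: list[syn.SyntenyBlock] = []
        for i, ga in enumerate(genome_ids):
            for gb in genome_ids[i + 1 :]:
                groups = syn.infer_pairwise_orthogroups(
                    culled, genome_of, (ga, gb), params
                )
                pairwise_groups.extend(groups)
                constrained = syn.hits_within_orthogroups(culled, groups)
                anchors = syn.anchors_from_hits(
                    constrained, annotations[ga], annotations[gb], params
                )
                chained = []
                for (ca, cb) in sorted(anchors):
                    chained.extend(
                        syn.chain_collinear_blocks(
                            anchors[(ca, cb)], params, genome_a=ga, genome_b=gb,
                            chrom_a=ca, chrom_b=cb,
                            block_prefix=f"{ga}{gb}_{ca}_{cb}_",
                        )
                    )
                pruned = syn.prune_blocks_density(chained, params)
                extended = syn.extend_blocks(
                    pruned,
                    [h for h in hits if h.bit_score >= params.min_bit_score],
                    annotations[ga],
                    annotations[gb],
                    params,
                )
                all_blocks.extend(extended)
        completed = syn.complete_orthogroups(pairwise_groups, genome_of)
        classes = syn.classify_syntenic_homologs(
            all_blocks, hits, completed, annotations, params
        )
        summary = syn.summarize_synteny(
            all_blocks, annotations[focal], config.min_block_genes
        )
        syn.write_blocks(all_blocks, out / "blocks.tsv")
        syn.write_orthogroups(completed, out / "orthogroups.tsv")
        summary.to_csv(out / "synteny_summary.tsv", sep="\t", index=False)
        with open(out / "homolog_classes.tsv", "w") as fh:
            fh.write("gene_a\tgene_b\tlabel\n")
            for c in classes:
                fh.write(f"{c.gene_a}\t{c.gene_b}\t{c.label}\n")
        results["n_blocks"] = len(all_blocks)
        results["n_orthogroups"] = len(completed)
        results["synteny_summary"] = summary
        results["blocks"] = all_blocks
        results["orthogroups"] = completed
    except Exception as exc:
        raise StageError("synteny", exc) from exc
    stages_done.append("synteny")

    # ---- ks dating -----------------------------------------------------
    if config.cds:
        try:
            cds: dict[str, str] = {}
            for gid in genome_ids:
                if gid not in config.cds:
                    raise FileNotFoundError(f"no CDS FASTA configured for {gid}")
                cds.update(_read_fasta(config.cds[gid]))
            single = ks.single_copy_orthologs(completed, genome_ids)
            estimates = []
            for og in single:
                genes = sorted(og.genes())
                for i in range(len(genes)):
                    for j in range(i + 1, len(genes)):
                        a, b = genes[i], genes[j]
                        if a in cds and b in cds:
                            estimates.append(ks.ks_for_cds_pair(a, b, cds[a], cds[b]))
            ks.write_ks_table(estimates, out / "ks_pairs.tsv")
            values = [e.ks for e in estimates if not e.saturated]
            peak_rows = []
            if len(values) >= 20:
                dist = ks.ks_peak(values)
                for (loc, dens), med in zip(dist.peaks, dist.peak_medians):
                    rates = {
                        f"rate_T{t:g}": ks.rate_per_site_year(med, t).rate
                        for t in config.divergence_times
                    }
                    peak_rows.append({"mode": loc, "median": med, "density": dens, **rates})
                results["ks_peaks"] = peak_rows
            with open(out / "ks_peaks.tsv", "w") as fh:
                fh.write("mode\tmedian\tdensity\trates\n")
                for r in peak_rows:
                    fh.write(f"{r['mode']:.4f}\t{r['median']:.4f}\t{r['density']:.4f}\t"
                             + ",".join(f"{k}={v:.4g}" for k, v in r.items()
                                        if k.startswith("rate_")) + "\n")
            results["n_single_copy"] = len(single)
        except Exception as exc:
            raise StageError("ks_dating", exc) from exc
        stages_done.append("ks_dating")

    # ---- gene families -------------------------------------------------
    try:
        family_map = {
            gene: og.og_id for og in completed for gene in og.genes()
        }
        arrays = {
            gid: fam.detect_tandem_arrays(annotations[gid], family_map)
            for gid in genome_ids
        }
        og_by_id = {og.og_id: og for og in completed}
        species_calls = fam.classify_expansions(
            completed, [focal], "species_specific"
        )
        overlap = fam.expansion_tandem_overlap(
            species_calls, og_by_id, arrays[focal], focal
        )
        with open(out / "families_tandem.tsv", "w") as fh:
            fh.write("genome\tarray_id\tchromosome\tfamily\tgenes\n")
            for gid in genome_ids:
                for arr in arrays[gid]:
                    fh.write(f"{gid}\t{arr.array_id}\t{arr.chromosome}\t{arr.family}\t"
                             + ",".join(arr.member_genes) + "\n")
        with open(out / "families_expansions.tsv", "w") as fh:
            fh.write("og_id\tlabel\tgene_count\tfocal_fraction\n")
            for c in species_calls:
                if c.label != "none":
                    fh.write(f"{c.og_id}\t{c.label}\t{c.gene_count}\t{c.focal_fraction:.3f}\n")
        if config.pathways:
            pathway_map = fam.read_pathway_map(config.pathways)
            universe = {g.gene_id for g in annotations[focal].genes}
            exp_genes = {
                g
                for c in species_calls
                if c.label != "none"
                for g in og_by_id[c.og_id].members.get(focal, set())
            }
            enr = fam.hypergeometric_enrichment(exp_genes, pathway_map, universe)
            with open(out / "families_enrichment.tsv", "w") as fh:
                fh.write("pathway\toverlap\tset_size\tpathway_size\tuniverse\tp\tenriched\n")
                for r in enr:
                    fh.write(f"{r.pathway_id}\t{r.overlap}\t{r.set_size}\t{r.pathway_size}"
                             f"\t{r.universe_size}\t{r.p_value:.4g}\t{int(r.enriched)}\n")
        results["n_tandem_arrays"] = {g: len(a) for g, a in arrays.items()}
        results["expansion_tandem_overlap"] = overlap
    except Exception as exc:
        raise StageError("gene_families", exc) from exc
    stages_done.append("gene_families")

    # ---- popgen --------------------------------------------------------
    if config.profiles:
        try:
            profiles = pg.load_profiles(config.profiles)
            est = pg.estimate_theta_ml(profiles)
            rates = pg.mutation_rates(est.theta, config.ne, config.generation_time)
            report = {
                "theta": est.theta, "ci_low": est.ci_low, "ci_high": est.ci_high,
                "error_rate": est.error_rate, "sites_used": est.sites_used,
                "mu_per_generation": rates.mu_per_generation,
                "mu_per_year": rates.mu_per_year,
            }
            with open(out / "popgen.json", "w") as fh:
                json.dump(report, fh, indent=1)
            results["popgen"] = report
        except Exception as exc:
            raise StageError("popgen", exc) from exc
        stages_done.append("popgen")

    # ---- manifest ------------------------------------------------------
    inputs = dict(config.gff)
    inputs["hits"] = config.hits
    inputs.update({f"cds_{k}": v for k, v in config.cds.items()})
    for key in ("profiles", "pathways"):
        if getattr(config, key):
            inputs[key] = getattr(config, key)
    manifest = {
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "stages_completed": stages_done,
        "parameters": {**asdict(config), "synteny_resolved": asdict(params)},
        "input_checksums": {k: _sha256(v) for k, v in sorted(inputs.items())},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    results["manifest"] = manifest
    return results
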