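"""Core genome data model: gene annotations, homology hits, windowed tracks.

Coordinates are 0-based half-open internally; GFF3 I/O converts to/from the
format's native 1-based inclusive convention. Every gene carries a per
chromosome *rank* — its ordinal position along the chromosome ordered by
start — which is the coordinate system used by all collinearity and radius
rules downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd


class ParseError(ValueError):
    """A malformed input file (names the offending line where possible)."""


class ValidationError(ValueError):
    """An input that parses but violates a data-model invariant."""


@dataclass(frozen=True)
class GeneModel:
    """A gene locus: one gene = one primary model.

    ``rank`` is the gene's index along its chromosome ordered by ascending
    start (ties: ascending end, then gene_id); it is assigned by
    :class:`GenomeAnnotation` and is -1 until then.
    """

    gene_id: str
    chromosome: str
    start: int  # 0-based, half-open
    end: int
    strand: str = "+"
    rank: int = -1

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"gene {self.gene_id}: invalid interval [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ValidationError(f"gene {self.gene_id}: bad strand {self.strand!r}")


@dataclass(frozen=True)
class HomologyHit:
    """A scored directed gene-pair similarity record (one aligner hit)."""

    query_gene: str
    target_gene: str
    bit_score: float
    percent_identity: float = 100.0
    evalue: float = 0.0
    length: int = 0

    def __post_init__(self) -> None:
        if self.bit_score < 0:
            raise ValidationError("bit_score must be >= 0")
        if not (0.0 <= self.percent_identity <= 100.0):
            raise ValidationError("percent_identity must be in [0, 100]")

    @property
    def is_self(self) -> bool:
        return self.query_gene == self.target_gene


@dataclass
class WindowedTrack:
    """Per-window values (counts or means) along one chromosome."""

    chromosome: str
    window_size: int
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)


class GenomeAnnotation:
    """All gene models of one genome plus chromosome lengths and ploidy.

    Ranks are (re)assigned on construction: per chromosome, genes are sorted
    by (start, end, gene_id) and numbered 0..n-1.
    """

    def __init__(
        self,
        genome_id: str,
        genes: Iterable[GeneModel],
        chromosome_lengths: Mapping[str, int] | None = None,
        ploidy: int = 1,
    ):
        self.genome_id = genome_id
        self.ploidy = int(ploidy)
        if self.ploidy < 1:
            raise ValidationError("ploidy must be >= 1")

        by_chrom: dict[str, list[GeneModel]] = {}
        for g in genes:
            by_chrom.setdefault(g.chromosome, []).append(g)

        self._genes_by_chrom: dict[str, list[GeneModel]] = {}
        self._by_id: dict[str, GeneModel] = {}
        for chrom in sorted(by_chrom):
            ordered = sorted(by_chrom[chrom], key=lambda g: (g.start, g.end, g.gene_id))
            ranked = [replace(g, rank=i) for i, g in enumerate(ordered)]
            self._genes_by_chrom[chrom] = ranked
            for g in ranked:
                if g.gene_id in self._by_id:
                    raise ValidationError(f"duplicate gene_id {g.gene_id!r}")
                self._by_id[g.gene_id] = g

        if chromosome_lengths is None:
            chromosome_lengths = {
                c: max(g.end for g in gs) for c, gs in self._genes_by_chrom.items()
            }
        self.chromosome_lengths = dict(chromosome_lengths)
        for chrom, gs in self._genes_by_chrom.items():
            if chrom not in self.chromosome_lengths:
                raise ValidationError(f"chromosome {chrom!r} missing a length")
            clen = self.chromosome_lengths[chrom]
            bad = [g for g in gs if g.end > clen]
            if bad:
                raise ValidationError(
                    f"gene {bad[0].gene_id} ends past chromosome {chrom} ({clen} bp)"
                )

    # -- access -----------------------------------------------------------
    @property
    def genes(self) -> list[GeneModel]:
        return [g for c in sorted(self._genes_by_chrom) for g in self._genes_by_chrom[c]]

    @property
    def chromosomes(self) -> list[str]:
        return sorted(self._genes_by_chrom)

    def genes_on(self, chromosome: str) -> list[GeneModel]:
        return list(self._genes_by_chrom.get(chromosome, []))

    def gene(self, gene_id: str) -> GeneModel:
        return self._by_id[gene_id]

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._by_id

    def __len__(self) -> int:
        return len(self._by_id)


# ---------------------------------------------------------------------------
# GFF3 I/O (gene features only)
# ---------------------------------------------------------------------------

def _parse_attr_id(attrs: str, lineno: int) -> str:
    for part in attrs.strip().rstrip(";").split(";"):
        key, _, value = part.strip().partition("=")
        if key == "ID":
            return value
    raise ParseError(f"line {lineno}: gene feature without an ID attribute")


def read_annotation(
    path: str | Path, genome_id: str, ploidy: int = 1, feature_type: str = "gene"
) -> GenomeAnnotation:
    """Read gene features from a GFF3 file (1-based inclusive coordinates).

    Returns a :class:`GenomeAnnotation` with 0-based half-open coordinates and
    per-chromosome ranks assigned. ``##sequence-region`` pragmas, when present,
    provide chromosome lengths.
    """
    genes: list[GeneModel] = []
    seq_regions: dict[str, int] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line:
                continue
            if line.startswith("##sequence-region"):
                parts = line.split()
                if len(parts) >= 4:
                    seq_regions[parts[1]] = int(parts[3])
                continue
            if line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ParseError(f"line {lineno}: expected 9 columns, got {len(cols)}")
            if cols[2] != feature_type:
                continue
            try:
                start1, end1 = int(cols[3]), int(cols[4])
            except ValueError:
                raise ParseError(f"line {lineno}: non-integer coordinates") from None
            gid = _parse_attr_id(cols[8], lineno)
            genes.append(
                GeneModel(
                    gene_id=gid,
                    chromosome=cols[0],
                    start=start1 - 1,  # to 0-based half-open
                    end=end1,
                    strand=cols[6] if cols[6] in "+-" else "+",
                )
            )
    return GenomeAnnotation(
        genome_id, genes, chromosome_lengths=seq_regions or None, ploidy=ploidy
    )


def write_annotation(annotation: GenomeAnnotation, path: str | Path) -> None:
    """Write gene features as GFF3 (round-trips with :func:`read_annotation`)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for chrom in annotation.chromosomes:
            fh.write(
                f"##sequence-region {chrom} 1 {annotation.chromosome_lengths[chrom]}\n"
            )
        for chrom in annotation.chromosomes:
            for g in annotation.genes_on(chrom):
                fh.write(
                    "\t".join(
                        [
                            chrom,
                            "syntevo",
                            "gene",
                            str(g.start + 1),
                            str(g.end),
                            ".",
                            g.strand,
                            ".",
                            f"ID={g.gene_id}",
                        ]
                    )
                    + "\n"
                )


# ---------------------------------------------------------------------------
# Hit tables (12-column tabular, BLAST outfmt-6 style)
# ---------------------------------------------------------------------------

_HIT_COLUMNS = [
    "query", "target", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "tstart", "tend", "evalue", "bitscore",
]


def read_hit_table(path: str | Path) -> list[HomologyHit]:
    """Read a 12-column tab-separated all-vs-all hit table.

    Self-hits (query == target) are retained; they are flagged via
    :attr:`HomologyHit.is_self` and removed later by the synteny cull.
    """
    try:
        df = pd.read_csv(
            path, sep="\t", names=_HIT_COLUMNS, header=None, comment="#",
            dtype={"query": str, "target": str},
        )
    except pd.errors.EmptyDataError:
        return []
    if df.shape[1] != 12:
        raise ParseError(f"{path}: expected 12 columns, got {df.shape[1]}")
    if df[["pident", "evalue", "bitscore"]].isna().any().any():
        bad = int(df[["pident", "evalue", "bitscore"]].isna().any(axis=1).idxmax()) + 1
        raise ParseError(f"{path}: malformed row {bad} (wrong column count?)")
    return [
        HomologyHit(
            query_gene=r.query,
            target_gene=r.target,
            bit_score=float(r.bitscore),
            percent_identity=float(r.pident),
            evalue=float(r.evalue),
            length=int(r.length),
        )
        for r in df.itertuples(index=False)
    ]


def write_hit_table(hits: Iterable[HomologyHit], path: str | Path) -> None:
    with open(path, "w") as fh:
        for h in hits:
            n = max(h.length, 1)
            fh.write(
                f"{h.query_gene}\t{h.target_gene}\t{h.percent_identity:.1f}\t{n}"
                f"\t0\t0\t1\t{n}\t1\t{n}\t{h.evalue:.3g}\t{h.bit_score:.1f}\n"
            )


# ---------------------------------------------------------------------------
# Windowed tracks (per-megabase genome features)
# ---------------------------------------------------------------------------

def compute_windowed_tracks(
    annotation: GenomeAnnotation | Mapping[str, int],
    features: Sequence,
    window_size: int = 1_000_000,
) -> dict[str, WindowedTrack]:
    """Count positioned features per fixed-size window on each chromosome.

    ``features`` are (chromosome, position) pairs or objects with
    ``chromosome``/``start`` attributes (e.g. :class:`GeneModel`). A feature is
    assigned to exactly one window by its start position, so window counts on a
    chromosome always sum to its feature count.
    """
    if window_size <= 0:
        raise ValidationError("window_size must be positive")
    lengths = (
        annotation.chromosome_lengths
        if isinstance(annotation, GenomeAnnotation)
        else dict(annotation)
    )
    tracks = {
        chrom: np.zeros(max(1, math.ceil(length / window_size)))
        for chrom, length in lengths.items()
    }
    for f in features:
        if hasattr(f, "chromosome"):
            chrom, pos = f.chromosome, f.start
        else:
            chrom, pos = f
        if chrom not in tracks:
            raise ValidationError(f"feature on unknown chromosome {chrom!r}")
        tracks[chrom][int(pos) // window_size] += 1
    return {
        chrom: WindowedTrack(chrom, window_size, vals) for chrom, vals in tracks.items()
    }


def write_tracks(tracks: Mapping[str, WindowedTrack], path: str | Path) -> None:
    """TSV track output: chromosome, window_start, value."""
    with open(path, "w") as fh:
        fh.write("chromosome\twindow_start\tvalue\n")
        for chrom in sorted(tracks):
            t = tracks[chrom]
            for i, v in enumerate(t.values):
                fh.write(f"{chrom}\t{i * t.window_size}\t{v:g}\n")
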