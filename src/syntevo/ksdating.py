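"""Pairwise synonymous/nonsynonymous divergence (Ks/Ka) and molecular-clock
arithmetic.

The estimator is Nei & Gojobori (1986) counting with a Jukes-Cantor multiple
hit correction: per codon, the expected synonymous site count is the fraction
of single-base changes that preserve the amino acid (changes creating a stop
count as nonsynonymous, so S + N = 3 per codon); observed differences are
averaged over all mutational pathways between the two codons, excluding
pathways that pass through a stop codon. Proportions beyond the correction
domain flag the pair as saturated.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import Align
from scipy.signal import find_peaks
from scipy.stats import gaussian_kde

from . import _codons as ct
from .synteny import Orthogroup

#: Jukes-Cantor domain guard on the raw difference proportion
SATURATION_PD = 0.74
#: Ks value reported for saturated pairs
KS_CAP = 3.0


@dataclass
class CodonAlignment:
    """A pair of gapped CDS strings aligned codon-by-codon."""

    id_a: str
    id_b: str
    seq_a: str
    seq_b: str

    def __post_init__(self) -> None:
        if len(self.seq_a) != len(self.seq_b):
            raise ValueError("aligned CDS lengths differ")
        if len(self.seq_a) % 3:
            raise ValueError("aligned CDS length is not a multiple of 3")

    @property
    def n_codons(self) -> int:
        return len(self.seq_a) // 3


@dataclass
class KsEstimate:
    gene_a: str
    gene_b: str
    ks: float
    ka: float
    s_sites: float
    n_sites: float
    saturated: bool = False


@dataclass
class KsDistribution:
    """A collection of Ks values with detected density peaks.

    ``peaks`` are (mode location, density) ordered by location;
    ``peak_medians`` is the median of values within one bandwidth of each
    peak (the 'median Ks peak' convention).
    """

    values: np.ndarray
    peaks: list[tuple[float, float]]
    peak_medians: list[float]
    bandwidth: float


@dataclass
class RateEstimate:
    """Substitution rate per site per year from a Ks peak and a fossil age."""

    rate: float
    ks_input: float
    divergence_time: float


# ---------------------------------------------------------------------------
# Codon back-translation (protein alignment -> codon alignment)
# ---------------------------------------------------------------------------

def _strip_stop(cds: str) -> str:
    if len(cds) >= 3 and str(ct.AA[ct.encode(cds[-3:])[0]]) == "*":
        return cds[:-3]
    return cds


def backtranslate_alignment(
    id_a: str,
    id_b: str,
    prot_a_aligned: str,
    prot_b_aligned: str,
    cds_a: str,
    cds_b: str,
) -> CodonAlignment:
    """Thread ungapped CDS through a gapped protein alignment.

    Each amino acid is replaced by its source codon and each protein gap by
    ``---``. The ungapped protein must equal the standard-code translation of
    its CDS (terminal stop stripped); a mismatch raises an error naming the
    first discordant residue.
    """
    out = []
    for name, prot, cds in ((id_a, prot_a_aligned, cds_a), (id_b, prot_b_aligned, cds_b)):
        cds = _strip_stop(cds.upper())
        ungapped = prot.replace("-", "")
        if len(cds) != 3 * len(ungapped):
            raise ValueError(
                f"{name}: CDS length {len(cds)} != 3 x protein length {len(ungapped)}"
            )
        codons = ct.encode(cds)
        trans = ct.translate_codons(codons)
        for i, (x, y) in enumerate(zip(trans, ungapped)):
            if x != y:
                raise ValueError(
                    f"{name}: translation mismatch at residue {i + 1}: "
                    f"CDS gives {x!r}, protein has {y!r}"
                )
        pieces, k = [], 0
        for aa in prot:
            if aa == "-":
                pieces.append("---")
            else:
                pieces.append(ct.CODONS[int(codons[k])])
                k += 1
        out.append("".join(pieces))
    return CodonAlignment(id_a, id_b, out[0], out[1])


def align_cds_pair(id_a: str, id_b: str, cds_a: str, cds_b: str) -> CodonAlignment:
    """Globally align the two translations, then back-translate.

    Convenience wrapper for sequence pairs arriving without a precomputed
    protein alignment.
    """
    pa = ct.translate_codons(ct.encode(_strip_stop(cds_a.upper())))
    pb = ct.translate_codons(ct.encode(_strip_stop(cds_b.upper())))
    aligner = Align.PairwiseAligner(
        mode="global",
        match_score=2,
        mismatch_score=-1,
        open_gap_score=-5,
        extend_gap_score=-0.5,
    )
    aln = aligner.align(pa, pb)[0]
    ga, gb = str(aln[0]), str(aln[1])
    return backtranslate_alignment(id_a, id_b, ga, gb, cds_a, cds_b)


# ---------------------------------------------------------------------------
# NG86 pairwise Ks/Ka
# ---------------------------------------------------------------------------

def _codon_differences(c1: int, c2: int) -> tuple[float, float]:
    """Pathway-averaged (synonymous, nonsynonymous) difference counts between
    two sense codons, excluding pathways through stop codons."""
    diff_pos = [p for p in range(3)
                if ((c1 >> ((2 - p) * 2)) & 3) != ((c2 >> ((2 - p) * 2)) & 3)]
    k = len(diff_pos)
    if k == 0:
        return 0.0, 0.0
    results = []
    for order in itertools.permutations(diff_pos):
        cur = c1
        syn = nsyn = 0
        blocked = False
        for p in order:
            b = (c2 >> ((2 - p) * 2)) & 3
            nxt = int(ct.NEIGHBOR[cur, p, b])
            if ct.IS_STOP[nxt]:
                blocked = True
                break
            if ct.AA[nxt] == ct.AA[cur]:
                syn += 1
            else:
                nsyn += 1
            cur = nxt
        if not blocked:
            results.append((syn, nsyn))
    if not results:
        # every ordering passes through a stop; fall back to counting all
        for order in itertools.permutations(diff_pos):
            cur = c1
            syn = nsyn = 0
            for p in order:
                b = (c2 >> ((2 - p) * 2)) & 3
                nxt = int(ct.NEIGHBOR[cur, p, b])
                if ct.AA[nxt] == ct.AA[cur] and not ct.IS_STOP[nxt]:
                    syn += 1
                else:
                    nsyn += 1
                cur = nxt
            results.append((syn, nsyn))
    s = sum(r[0] for r in results) / len(results)
    n = sum(r[1] for r in results) / len(results)
    return s, n


# memoised per-pair difference table, filled lazily
_DIFF_CACHE: dict[tuple[int, int], tuple[float, float]] = {}


def _jc_correct(p: float) -> float:
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


def estimate_pairwise_ks(alignment: CodonAlignment) -> KsEstimate:
    """NG86 Ks/Ka with Jukes-Cantor correction for one codon alignment.

    Columns containing gaps or ambiguous bases are skipped. An internal stop
    codon in a compared column raises an error. If the raw proportion of
    differences exceeds the correction domain (pd > 0.74) in either class the
    pair is flagged saturated and Ks reported at the cap.
    """
    s_sites = n_sites = 0.0
    sd = nd = 0.0
    compared = 0
    for i in range(alignment.n_codons):
        ca = alignment.seq_a[3 * i : 3 * i + 3].upper()
        cb = alignment.seq_b[3 * i : 3 * i + 3].upper()
        if any(b not in "ACGT" for b in ca + cb):
            continue
        c1, c2 = int(ct.encode(ca)[0]), int(ct.encode(cb)[0])
        if ct.IS_STOP[c1] or ct.IS_STOP[c2]:
            raise ValueError(f"internal stop codon at codon {i + 1}")
        compared += 1
        s_sites += 0.5 * (ct.SYN_SITES[c1] + ct.SYN_SITES[c2])
        n_sites += 3.0 - 0.5 * (ct.SYN_SITES[c1] + ct.SYN_SITES[c2])
        if c1 != c2:
            key = (min(c1, c2), max(c1, c2))
            if key not in _DIFF_CACHE:
                _DIFF_CACHE[key] = _codon_differences(key[0], key[1])
            s, n = _DIFF_CACHE[key]
            sd += s
            nd += n
    if compared == 0:
        raise ValueError("no comparable codon columns")

    ps = sd / s_sites if s_sites > 0 else 0.0
    pn = nd / n_sites if n_sites > 0 else 0.0
    saturated = ps > SATURATION_PD or pn > SATURATION_PD
    ks = KS_CAP if ps > SATURATION_PD else _jc_correct(ps)
    ka = KS_CAP if pn > SATURATION_PD else _jc_correct(pn)
    return KsEstimate(
        alignment.id_a, alignment.id_b, ks=ks, ka=ka,
        s_sites=s_sites, n_sites=n_sites, saturated=saturated,
    )


def ks_for_cds_pair(id_a: str, id_b: str, cds_a: str, cds_b: str) -> KsEstimate:
    """Align (via translated global alignment) and estimate Ks for two CDS."""
    return estimate_pairwise_ks(align_cds_pair(id_a, id_b, cds_a, cds_b))


# ---------------------------------------------------------------------------
# Orthogroup filtering and peak detection
# ---------------------------------------------------------------------------

def single_copy_orthologs(
    orthogroups: Iterable[Orthogroup], genomes: Iterable[str]
) -> list[Orthogroup]:
    """Orthogroups with exactly one member in each requested genome."""
    wanted = set(genomes)
    return [
        og
        for og in orthogroups
        if set(og.members) == wanted and all(len(og.members[g]) == 1 for g in wanted)
    ]


def ks_peak(
    values: Sequence[float] | np.ndarray,
    bandwidth: float | None = None,
    cap: float = 2.0,
    min_values: int = 20,
    prominence_fraction: float = 0.05,
) -> KsDistribution:
    """Detect modes of a Ks distribution by Gaussian kernel density.

    The KDE (Silverman bandwidth by default, fit to values <= ``cap``) is
    evaluated on a fine grid over [0, cap]; local maxima above a prominence
    floor (``prominence_fraction`` of the highest density) become peaks,
    ordered by location. For each peak the median of values within one
    bandwidth is also reported.
    """
    vals = np.asarray(values, dtype=float)
    vals = vals[np.isfinite(vals)]
    vals = vals[(vals >= 0) & (vals <= cap)]
    if len(vals) < min_values:
        raise ValueError(f"need >= {min_values} finite Ks values, got {len(vals)}")

    if np.ptp(vals) == 0:
        v = float(vals[0])
        return KsDistribution(vals, [(v, float("inf"))], [v], bandwidth or 0.0)

    if bandwidth is None:
        kde = gaussian_kde(vals, bw_method="silverman")
    else:
        kde = gaussian_kde(vals, bw_method=bandwidth / vals.std(ddof=1))
    bw = float(kde.factor * vals.std(ddof=1))

    grid = np.linspace(0.0, min(cap, vals.max() + 3 * bw), 1024)
    dens = kde(grid)
    idx, _ = find_peaks(dens, prominence=prominence_fraction * dens.max())
    # an interior-grid maximum at the left edge (mode at/near 0) is a peak too
    if dens[0] > dens[1]:
        idx = np.concatenate([[0], idx])
    peaks = [(float(grid[i]), float(dens[i])) for i in idx]
    medians = [
        float(np.median(vals[(vals >= loc - bw) & (vals <= loc + bw)]))
        if np.any((vals >= loc - bw) & (vals <= loc + bw))
        else loc
        for loc, _ in peaks
    ]
    return KsDistribution(vals, peaks, medians, bw)


def rate_per_site_year(ks: float, divergence_time: float) -> RateEstimate:
    """Substitution rate per site per year: R = Ks / (2 T)."""
    if divergence_time <= 0:
        raise ValueError("divergence_time must be positive")
    if ks < 0:
        raise ValueError("ks must be >= 0")
    return RateEstimate(rate=ks / (2.0 * divergence_time), ks_input=ks,
                        divergence_time=divergence_time)


def extract_wgd_paralogs(
    estimates: Iterable[KsEstimate], window: tuple[float, float] = (0.33, 0.45)
) -> list[KsEstimate]:
    """Paralog pairs whose Ks falls inside the WGD peak window (inclusive)."""
    low, high = window
    if low > high:
        raise ValueError("window low > high")
    return [e for e in estimates if not e.saturated and low <= e.ks <= high]


def write_ks_table(estimates: Iterable[KsEstimate], path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_a\tgene_b\tka\tks\ts_sites\tn_sites\tsaturated\n")
        for e in estimates:
            fh.write(
                f"{e.gene_a}\t{e.gene_b}\t{e.ka:.6f}\t{e.ks:.6f}"
                f"\t{e.s_sites:.2f}\t{e.n_sites:.2f}\t{int(e.saturated)}\n"
            )
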