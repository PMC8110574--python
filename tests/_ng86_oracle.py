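"""Brute-force Nei-Gojobori (1986) oracle, written independently of the
package implementation: string-based codons, Biopython translation calls,
explicit enumeration of site fractions and mutational pathways."""

import math
from functools import lru_cache
from itertools import permutations

from Bio.Seq import Seq

BASES = "ACGT"


@lru_cache(maxsize=None)
def _aa(codon: str) -> str:
    return str(Seq(codon).translate())


@lru_cache(maxsize=None)
def syn_sites(codon: str) -> float:
    """Expected synonymous sites: per position, the fraction of the three
    single-base changes that are synonymous (stop-creating changes count as
    nonsynonymous)."""
    total = 0.0
    for p in range(3):
        for b in BASES:
            if b == codon[p]:
                continue
            alt = codon[:p] + b + codon[p + 1 :]
            if _aa(alt) != "*" and _aa(alt) == _aa(codon):
                total += 1.0 / 3.0
    return total


@lru_cache(maxsize=None)
def pathway_counts(c1: str, c2: str) -> tuple[float, float]:
    """Pathway-averaged (syn, nonsyn) differences; stop-passing pathways
    excluded, falling back to all pathways if every ordering is blocked."""
    pos = [p for p in range(3) if c1[p] != c2[p]]
    if not pos:
        return 0.0, 0.0

    def walk(order, allow_stops):
        cur, sd, nd = c1, 0, 0
        for p in order:
            nxt = cur[:p] + c2[p] + cur[p + 1 :]
            if _aa(nxt) == "*":
                if not allow_stops:
                    return None
                nd += 1
            elif _aa(nxt) == _aa(cur):
                sd += 1
            else:
                nd += 1
            cur = nxt
        return sd, nd

    paths = [r for order in permutations(pos) if (r := walk(order, False)) is not None]
    if not paths:
        paths = [walk(order, True) for order in permutations(pos)]
    return (
        sum(p[0] for p in paths) / len(paths),
        sum(p[1] for p in paths) / len(paths),
    )


def ng86(seq1: str, seq2: str, saturation_pd: float = 0.74, cap: float = 3.0):
    """(ks, ka, s_sites, n_sites, saturated) for two equal-length ungapped CDS."""
    assert len(seq1) == len(seq2) and len(seq1) % 3 == 0
    s_sites = n_sites = sd = nd = 0.0
    for i in range(0, len(seq1), 3):
        c1, c2 = seq1[i : i + 3].upper(), seq2[i : i + 3].upper()
        s = 0.5 * (syn_sites(c1) + syn_sites(c2))
        s_sites += s
        n_sites += 3.0 - s
        dsd, dnd = pathway_counts(c1, c2)
        sd += dsd
        nd += dnd
    ps = sd / s_sites if s_sites else 0.0
    pn = nd / n_sites if n_sites else 0.0
    saturated = ps > saturation_pd or pn > saturation_pd
    ks = cap if ps > saturation_pd else -0.75 * math.log(1.0 - 4.0 * ps / 3.0)
    ka = cap if pn > saturation_pd else -0.75 * math.log(1.0 - 4.0 * pn / 3.0)
    return ks, ka, s_sites, n_sites, saturated
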