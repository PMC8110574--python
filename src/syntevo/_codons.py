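"""Standard-genetic-code codon tables shared by the Ks estimator and the
codon-evolution simulator.

Codons are encoded as integers 0..63 with base order A,C,G,T and the first
codon position in the high bits: ``index = 16*b0 + 4*b1 + b2``.
"""

from __future__ import annotations

import itertools

import numpy as np
from Bio.Seq import Seq

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}

#: all 64 codons in index order
CODONS = ["".join(c) for c in itertools.product(BASES, repeat=3)]
CODON_INDEX = {c: i for i, c in enumerate(CODONS)}

#: amino acid per codon ("*" for stop), standard code
AA = np.array([str(Seq(c).translate()) for c in CODONS])
IS_STOP = AA == "*"

# neighbour[c, p, b] = codon obtained from c by setting position p to base b
NEIGHBOR = np.empty((64, 3, 4), dtype=np.int64)
for c in range(64):
    for p in range(3):
        shift = (2 - p) * 2
        cleared = c & ~(3 << shift)
        for b in range(4):
            NEIGHBOR[c, p, b] = cleared | (b << shift)

# Per-codon synonymous site fractions, NG86 convention: at each position the
# fraction of the three single-base changes that preserve the amino acid.
# Changes creating a stop codon count as nonsynonymous, so syn + nonsyn
# fractions sum to exactly 1 per position (and S + N = 3 per codon).
SYN_FRACTION = np.zeros((64, 3))
for c in range(64):
    if IS_STOP[c]:
        continue
    for p in range(3):
        syn = 0
        for b in range(4):
            n = NEIGHBOR[c, p, b]
            if n == c:
                continue
            if not IS_STOP[n] and AA[n] == AA[c]:
                syn += 1
        SYN_FRACTION[c, p] = syn / 3.0

#: total synonymous sites per codon (0..3)
SYN_SITES = SYN_FRACTION.sum(axis=1)

SENSE_CODONS = [c for c in range(64) if not IS_STOP[c]]


def encode(cds: str) -> np.ndarray:
    """Encode an ungapped CDS string as an array of codon indices."""
    s = cds.upper()
    if len(s) % 3:
        raise ValueError(f"CDS length {len(s)} is not a multiple of 3")
    try:
        flat = np.array([BASE_INDEX[b] for b in s], dtype=np.int64)
    except KeyError as exc:  # pragma: no cover - message detail only
        raise ValueError(f"non-ACGT base in CDS: {exc}") from None
    return 16 * flat[0::3] + 4 * flat[1::3] + flat[2::3]


def decode(codons: np.ndarray) -> str:
    """Inverse of :func:`encode`."""
    return "".join(CODONS[int(c)] for c in codons)


def translate_codons(codons: np.ndarray) -> str:
    return "".join(AA[int(c)] for c in codons)
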