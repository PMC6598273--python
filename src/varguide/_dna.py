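"""Shared DNA alphabet helpers: encoding, complementing, IUPAC matching.

Internal module. The integer encoding is fixed package-wide:
A=0, C=1, G=2, T=3, N=4, and 5 is the inter-sequence separator used by
the search index (it never matches anything).
"""

from __future__ import annotations

import numpy as np

BASES = "ACGT"
A, C, G, T, N, SEP = 0, 1, 2, 3, 4, 5

_ENCODE = np.full(256, N, dtype=np.uint8)
for _i, _b in enumerate("ACGTN#"):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i

_DECODE = np.frombuffer(b"ACGTN#", dtype=np.uint8)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

# IUPAC code -> set of concrete bases it stands for. N additionally matches a
# genomic N; no other code does (the meaning of N in a target is undefined, so
# only an explicit wildcard accepts it).
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGTN",
}

IUPAC_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")

PURINES = frozenset("AG")


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string to the package's uint8 alphabet."""
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(arr: np.ndarray) -> str:
    return _DECODE[arr].tobytes().decode("ascii")


def revcomp(seq: str) -> str:
    """Reverse complement; N maps to N."""
    return seq.translate(_COMPLEMENT)[::-1]


def revcomp_motif(motif: str) -> str:
    """Reverse complement of an IUPAC motif (R<->Y etc.)."""
    return motif.translate(IUPAC_COMPLEMENT)[::-1]


def iupac_match(motif: str, seq: str) -> bool:
    """True if ``seq`` (concrete bases, possibly N) satisfies ``motif``."""
    if len(motif) != len(seq):
        return False
    return all(s in IUPAC[m] for m, s in zip(motif, seq))


def motif_mask(motif: str) -> np.ndarray:
    """Boolean table (len(motif), 6): entry [i, code] says whether the
    encoded base ``code`` satisfies motif position ``i``.  The separator
    code never matches."""
    mask = np.zeros((len(motif), 6), dtype=bool)
    for i, m in enumerate(motif):
        for b in IUPAC[m]:
            mask[i, "ACGTN".index(b)] = True
    return mask


def is_transition(b1: str, b2: str) -> bool:
    """Purine<->purine or pyrimidine<->pyrimidine substitution."""
    return b1 != b2 and (b1 in PURINES) == (b2 in PURINES)
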