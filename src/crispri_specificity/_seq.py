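"""Nucleotide encoding, reverse complement and IUPAC pattern matching.

Sequences are handled internally as uint8 code arrays (A=0, C=1, G=2, T=3,
N=4). A genomic ``N`` never matches anything: not a spacer base and not any
IUPAC pattern position, so an unknown base always counts against a site.
"""

from __future__ import annotations

import numpy as np

CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
BASES = "ACGTN"

# complement on codes: A<->T, C<->G, N->N
_COMP_CODE = np.array([3, 2, 1, 0, 4], dtype=np.uint8)

_ENC = np.full(256, 255, dtype=np.uint8)
for _b, _c in CODE.items():
    _ENC[ord(_b)] = _c
    _ENC[ord(_b.lower())] = _c

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T", "U": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMP_CHAR = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N",
              "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
              "B": "V", "V": "B", "D": "H", "H": "D", "U": "A"}


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string to uint8 codes; raises on non-ACGTN characters."""
    arr = _ENC[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if (arr == 255).any():
        bad = sorted({c for c in seq.upper() if c not in CODE})
        raise ValueError(f"sequence contains non-ACGTN characters: {bad}")
    return arr


def decode(codes: np.ndarray) -> str:
    return "".join(BASES[c] for c in codes)


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    return _COMP_CODE[codes][::-1]


def revcomp(seq: str) -> str:
    return decode(revcomp_codes(encode(seq)))


def revcomp_pattern(pattern: str) -> str:
    """Reverse complement of an IUPAC pattern string."""
    return "".join(_COMP_CHAR[c] for c in reversed(pattern.upper()))


def validate_pattern(pattern: str) -> str:
    pat = pattern.upper()
    bad = sorted({c for c in pat if c not in IUPAC})
    if bad:
        raise ValueError(f"invalid IUPAC characters in pattern: {bad}")
    return pat


def pattern_tables(pattern: str) -> np.ndarray:
    """Boolean table (len(pattern), 5): does genome code match pattern position.

    Code 4 (N in the genome) matches nothing.
    """
    pat = validate_pattern(pattern)
    tab = np.zeros((len(pat), 5), dtype=bool)
    for j, ch in enumerate(pat):
        for b in IUPAC[ch]:
            tab[j, CODE[b]] = True
    return tab


def iupac_match(seq: str, pattern: str) -> bool:
    """Exact (zero-flaw) match of a genomic string against an IUPAC pattern."""
    if len(seq) != len(pattern):
        return False
    tab = pattern_tables(pattern)
    try:
        codes = encode(seq)
    except ValueError:
        return False
    return bool(tab[np.arange(len(pattern)), codes].all())
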