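"""Shared low-level helpers: alphabets, complements, IUPAC matching."""

from __future__ import annotations

import numpy as np

BASES = "ACGT"

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

# IUPAC nucleotide codes -> the set of concrete bases they match.
# N deliberately matches only A/C/G/T, never a genomic N.
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


def seq_to_codes(seq: str) -> np.ndarray:
    """Encode a DNA string as a uint8 array of ASCII codes."""
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def iupac_match_positions(codes: np.ndarray, pattern: str) -> np.ndarray:
    """Start positions where `pattern` (IUPAC) matches the encoded sequence.

    N in the pattern matches A/C/G/T only; any non-ACGT genomic base fails
    every pattern position.
    """
    k = len(pattern)
    n = codes.size
    if n < k:
        return np.empty(0, dtype=np.intp)
    mask = np.ones(n - k + 1, dtype=bool)
    for offset, sym in enumerate(pattern.upper()):
        allowed = IUPAC[sym]
        window = codes[offset : n - k + 1 + offset]
        ok = np.zeros(window.size, dtype=bool)
        for base in allowed:
            ok |= window == ord(base)
        mask &= ok
    return np.nonzero(mask)[0]


def acgt_run_mask(codes: np.ndarray, width: int) -> np.ndarray:
    """Boolean array: True at start positions whose `width`-window is pure ACGT."""
    n = codes.size
    if n < width:
        return np.empty(0, dtype=bool)
    valid = np.zeros(n, dtype=bool)
    for base in BASES:
        valid |= codes == ord(base)
    # prefix sums -> window is clean iff it contains `width` valid bases
    csum = np.concatenate([[0], np.cumsum(valid)])
    return (csum[width:] - csum[:-width]) == width
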