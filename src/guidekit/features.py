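"""Deterministic tokenisation of guide sequences into numeric feature vectors.

Feature families (all on by default):

* ``global_mono`` — counts of A, C, G, T over the whole sequence;
* ``global_di`` — counts of the 16 dinucleotides (lexicographic order);
* ``positional_mono`` — one-hot indicator of the base at each position;
* ``positional_di`` — one-hot indicator of the dinucleotide starting at each
  position;
* ``gc`` — GC fraction of the sequence.

Schema order is fixed: global mono (A,C,G,T), global di (AA..TT), positional
mono (position-major, base-minor), positional di (position-major,
pair-minor), gc last. For a length-L sequence with every family on the vector
has 4 + 16 + 4L + 16(L-1) + 1 entries (685 for the canonical 34-nt Cas12a
context).

The canonical 34-nt Cas12a context is
``[4-nt 5' flank][4-nt TTTN PAM][20-nt protospacer][6-nt 3' flank]``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from ._util import BASES

DINUCS = tuple(a + b for a in BASES for b in BASES)

ALL_FAMILIES = ("global_mono", "global_di", "positional_mono", "positional_di", "gc")

SCHEMA_VERSION = "guidekit-features-1"

CAS12A_CONTEXT_LENGTH = 34  # 4 flank + 4 PAM + 20 protospacer + 6 flank
SNV_WINDOW_LENGTH = 39  # 10 5' flank + 20 protospacer + 9 3' flank


@dataclass(frozen=True)
class FeatureVector:
    values: np.ndarray
    schema: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.values) != len(self.schema):
            raise ValueError("values and schema lengths differ")

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.schema, self.values.tolist()))


def _validate(seq: str) -> str:
    seq = seq.upper()
    for i, ch in enumerate(seq):
        if ch not in BASES:
            raise ValueError(f"non-ACGT character {ch!r} at position {i}")
    return seq


def tokenize(
    seq: str, families: Sequence[str] = ALL_FAMILIES, prefix: str = ""
) -> FeatureVector:
    """Encode one DNA sequence as an ordered numeric feature vector."""
    seq = _validate(seq)
    L = len(seq)
    unknown = set(families) - set(ALL_FAMILIES)
    if unknown:
        raise ValueError(f"unknown feature families: {sorted(unknown)}")
    if L < 2 and ("global_di" in families or "positional_di" in families):
        raise ValueError("dinucleotide families need sequence length >= 2")
    names: list[str] = []
    values: list[float] = []
    if "global_mono" in families:
        for b in BASES:
            names.append(f"{prefix}glob_{b}")
            values.append(seq.count(b))
    if "global_di" in families:
        for d in DINUCS:
            names.append(f"{prefix}glob_{d}")
            values.append(sum(seq[i : i + 2] == d for i in range(L - 1)))
    if "positional_mono" in families:
        for i in range(L):
            for b in BASES:
                names.append(f"{prefix}pos{i}_{b}")
                values.append(1.0 if seq[i] == b else 0.0)
    if "positional_di" in families:
        for i in range(L - 1):
            pair = seq[i : i + 2]
            for d in DINUCS:
                names.append(f"{prefix}pos{i}_{d}")
                values.append(1.0 if pair == d else 0.0)
    if "gc" in families:
        names.append(f"{prefix}gc")
        values.append((seq.count("G") + seq.count("C")) / L)
    return FeatureVector(np.asarray(values, dtype=float), tuple(names))


def tokenize_components(
    components: Mapping[str, str], families: Sequence[str] = ALL_FAMILIES
) -> FeatureVector:
    """Tokenise named sequence components separately and concatenate.

    Keeps each component's features independent (no cross-component
    dinucleotides); schema names are prefixed with the component name.
    """
    names = list(components)
    if len(set(names)) != len(names):
        raise ValueError("duplicate component names")
    parts = [tokenize(seq, families, prefix=f"{name}_") for name, seq in components.items()]
    return FeatureVector(
        np.concatenate([p.values for p in parts]),
        tuple(n for p in parts for n in p.schema),
    )


def window_features(
    seq: str, width: int, step: int = 1, families: Sequence[str] = ALL_FAMILIES
) -> FeatureVector:
    """Tokenise sliding windows of `seq`; blocks prefixed win{start}_."""
    seq = _validate(seq)
    if not 1 <= width <= len(seq):
        raise ValueError(f"width must be in [1, {len(seq)}]")
    if step < 1:
        raise ValueError("step must be >= 1")
    parts = [
        tokenize(seq[start : start + width], families, prefix=f"win{start}_")
        for start in range(0, len(seq) - width + 1, step)
    ]
    return FeatureVector(
        np.concatenate([p.values for p in parts]),
        tuple(n for p in parts for n in p.schema),
    )


def expected_length(L: int, families: Sequence[str] = ALL_FAMILIES) -> int:
    """Closed-form vector length for a single length-L sequence."""
    total = 0
    if "global_mono" in families:
        total += 4
    if "global_di" in families:
        total += 16
    if "positional_mono" in families:
        total += 4 * L
    if "positional_di" in families:
        total += 16 * (L - 1)
    if "gc" in families:
        total += 1
    return total


def tokenize_many(
    seqs: Iterable[str], families: Sequence[str] = ALL_FAMILIES
) -> tuple[np.ndarray, tuple[str, ...]]:
    """Feature matrix for equal-length sequences plus the shared schema."""
    vectors = [tokenize(s, families) for s in seqs]
    if not vectors:
        raise ValueError("no sequences given")
    schema = vectors[0].schema
    for v in vectors[1:]:
        if v.schema != schema:
            raise ValueError("sequences produce differing schemas (unequal lengths?)")
    return np.vstack([v.values for v in vectors]), schema


def read_sequence_file(path: str | Path) -> list[tuple[int, str]]:
    """Read sequences from a plain-text (one per line) or FASTA file.

    Returns (line_number, sequence) pairs; blank lines are skipped. FASTA is
    detected by a leading '>'.
    """
    text = Path(path).read_text()
    lines = text.splitlines()
    out: list[tuple[int, str]] = []
    if any(ln.startswith(">") for ln in lines):
        current: list[str] = []
        start_line = 0
        for i, ln in enumerate(lines, start=1):
            if ln.startswith(">"):
                if current:
                    out.append((start_line, "".join(current)))
                current, start_line = [], i
            elif ln.strip():
                current.append(ln.strip())
        if current:
            out.append((start_line, "".join(current)))
    else:
        for i, ln in enumerate(lines, start=1):
            if ln.strip():
                out.append((i, ln.strip()))
    return out
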