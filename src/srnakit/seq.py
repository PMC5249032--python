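"""Small sequence helpers shared across the package.

All internal sequence handling is DNA-alphabet, uppercase, U→T normalized;
reads and references are converted on load and never re-checked downstream.
"""

from __future__ import annotations

import numpy as np

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

ALPHABET = "ACGT"


def normalize(seq: str) -> str:
    """Uppercase and convert RNA (U) to DNA (T)."""
    return seq.upper().replace("U", "T")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA sequence (N self-complements)."""
    return seq.translate(_COMPLEMENT)[::-1]


def random_seq(rng: np.random.Generator, length: int) -> str:
    """Uniform random DNA string."""
    return "".join(np.array(list(ALPHABET))[rng.integers(0, 4, size=length)])


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal lengths")
    return sum(x != y for x, y in zip(a, b))


def find_all(text: str, pattern: str) -> list[int]:
    """All (possibly overlapping) start offsets of pattern in text."""
    hits = []
    i = text.find(pattern)
    while i != -1:
        hits.append(i)
        i = text.find(pattern, i + 1)
    return hits
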