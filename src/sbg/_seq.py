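"""Small nucleotide-string helpers shared across modules."""

from __future__ import annotations

import numpy as np

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")

BASES = "ACGT"


def complement(base: str) -> str:
    return base.translate(_COMP)


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def encode(seqs: list[str]) -> np.ndarray:
    """Encode equal-length sequences as a 2-D uint8 array of ASCII codes."""
    if not seqs:
        return np.empty((0, 0), dtype=np.uint8)
    arr = np.frombuffer("".join(seqs).encode("ascii"), dtype=np.uint8)
    return arr.reshape(len(seqs), -1)


def find_all(haystack: str, needle: str) -> list[int]:
    """All (possibly overlapping) start positions of ``needle``."""
    out = []
    i = haystack.find(needle)
    while i != -1:
        out.append(i)
        i = haystack.find(needle, i + 1)
    return out
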