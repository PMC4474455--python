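"""Low-level DNA sequence helpers shared across modules."""

from __future__ import annotations

import numpy as np

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")

A, C, G, T = (ord(b) for b in "ACGT")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string."""
    return seq.translate(_COMP)[::-1]


def complement(seq: str) -> str:
    return seq.translate(_COMP)


def c2t(seq: str) -> str:
    """Bisulfite-style full conversion of the forward alphabet (C -> T)."""
    return seq.replace("C", "T").replace("c", "t")


def g2a(seq: str) -> str:
    """Complementary-strand conversion alphabet (G -> A)."""
    return seq.replace("G", "A").replace("g", "a")


def to_array(seq: str) -> np.ndarray:
    """Encode a DNA string as a uint8 array of ASCII codes."""
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def from_array(arr: np.ndarray) -> str:
    return arr.tobytes().decode("ascii")


def revcomp_array(arr: np.ndarray) -> np.ndarray:
    table = np.zeros(256, dtype=np.uint8)
    for x, y in zip(b"ACGTN", b"TGCAN"):
        table[x] = y
    return table[arr][::-1]


def cg_start_positions(seq: str) -> np.ndarray:
    """0-based positions p with seq[p:p+2] == 'CG' (the plus-strand C)."""
    arr = to_array(seq)
    if arr.size < 2:
        return np.empty(0, dtype=np.int64)
    mask = (arr[:-1] == C) & (arr[1:] == G)
    return np.nonzero(mask)[0].astype(np.int64)


def phred_to_q(qual: str, offset: int = 33) -> np.ndarray:
    """Phred+33 quality string to integer scores."""
    return np.frombuffer(qual.encode("ascii"), dtype=np.uint8).astype(np.int64) - offset
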