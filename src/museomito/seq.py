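"""Low-level sequence helpers shared across modules."""

from __future__ import annotations

import numpy as np

BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def seq_to_array(seq: str) -> np.ndarray:
    """Byte view of an (uppercase) sequence for vectorised comparison."""
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def hamming(a: str, b: str) -> int:
    """Number of differing positions between two equal-length strings."""
    if len(a) != len(b):
        raise ValueError("hamming requires equal-length sequences")
    if not a:
        return 0
    return int((seq_to_array(a) != seq_to_array(b)).sum())


def match_count(a: str, b: str) -> int:
    """Number of identical positions between two equal-length strings."""
    return len(a) - hamming(a, b)


def circular_slice(genome: str, start0: int, length: int) -> str:
    """Substring of a circular sequence, 0-based start, wrapping the origin."""
    n = len(genome)
    if length > n:
        raise ValueError("slice longer than genome")
    start0 %= n
    end = start0 + length
    if end <= n:
        return genome[start0:end]
    return genome[start0:] + genome[: end - n]
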