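"""Minimal k-mer seeded ungapped read mapper for circular references.

SAM import (see :mod:`museomito.samio`) is the fidelity path for
externally mapped data; this mapper exists so the pipeline runs
end-to-end without external aligners.  Placement is by exact k-mer
seeding followed by ungapped scoring on both strands; mapping quality
reflects the gap between the best and second-best placement, so a read
that fits two places equally well gets MQ 0.
"""

from __future__ import annotations

from collections import Counter, defaultdict

import numpy as np

from museomito.seq import reverse_complement, seq_to_array
from museomito.types import MappedRead, SequencingRead

DEFAULT_K = 13
MAX_MAPQ = 60
# Placements with more than this fraction of mismatching bases are
# rejected, emulating the mismatch tolerance of short-read mappers on
# degraded reads; reads from genome regions locally more diverged than
# this relative to the reference therefore drop out of the pileup.
DEFAULT_MAX_MISMATCH_FRACTION = 0.08
# Per-base score gap -> MQ scaling; a gap of MAX_MAPQ/_MQ_SCALE matching
# bases between best and runner-up saturates the quality.
_MQ_SCALE = 3


class ReferenceIndex:
    """Exact k-mer index over a circular reference sequence."""

    def __init__(self, reference: str, k: int = DEFAULT_K):
        if len(reference) < k:
            raise ValueError("reference shorter than k")
        self.reference = reference.upper()
        self.k = k
        self.length = len(reference)
        # extend past the origin so wrapping k-mers and extensions resolve
        self._extended = self.reference + self.reference[: max(k, 400)]
        self._ext_arr = seq_to_array(self._extended)
        self.kmers: dict[str, list[int]] = defaultdict(list)
        for i in range(self.length):
            self.kmers[self._extended[i : i + k]].append(i)

    def score(self, read_arr: np.ndarray, start0: int) -> int:
        """Matching bases of an ungapped placement at 0-based start."""
        seg = self._ext_arr[start0 : start0 + len(read_arr)]
        if len(seg) < len(read_arr):
            return 0
        return int((seg == read_arr).sum())


def _candidate_starts(index: ReferenceIndex, seq: str) -> Counter:
    votes: Counter = Counter()
    k = index.k
    for off in range(0, len(seq) - k + 1, 4):
        for pos in index.kmers.get(seq[off : off + k], ()):
            votes[(pos - off) % index.length] += 1
    return votes


def map_read(
    read: SequencingRead,
    index: ReferenceIndex,
    reference_id: str = "ref",
    max_mismatch_frac: float = DEFAULT_MAX_MISMATCH_FRACTION,
) -> list[MappedRead]:
    """Place one read on the reference; [] if no adequate placement.

    Returns one record, or two when the placement wraps the circular
    origin (the read is split into two mapped segments sharing the
    read id and mapping quality).
    """
    if len(read) < index.k:
        return []
    scored: dict[tuple[int, str], int] = {}
    for strand, seq in (("+", read.bases), ("-", reverse_complement(read.bases))):
        arr = seq_to_array(seq.upper())
        votes = _candidate_starts(index, seq.upper())
        for start0, _ in votes.most_common(8):
            scored[(start0, strand)] = index.score(arr, start0)
    if not scored:
        return []
    ranked = sorted(scored.items(), key=lambda kv: (-kv[1], kv[0][0], kv[0][1]))
    (start0, strand), best_score = ranked[0]
    if len(read) - best_score > max_mismatch_frac * len(read):
        return []
    second_score = ranked[1][1] if len(ranked) > 1 else 0
    if second_score == best_score:
        mapq = 0
    else:
        mapq = min(MAX_MAPQ, _MQ_SCALE * (best_score - second_score))
    seq = read.bases if strand == "+" else reverse_complement(read.bases)
    quals = read.qualities if strand == "+" else list(reversed(read.qualities))
    n = index.length
    end0 = start0 + len(seq)  # exclusive
    if end0 <= n:
        return [
            MappedRead(
                read.read_id, reference_id, start0 + 1, strand, seq, mapq,
                base_qualities=quals,
            )
        ]
    # wraps the origin: split into two segments
    head_len = n - start0
    return [
        MappedRead(
            read.read_id, reference_id, start0 + 1, strand, seq[:head_len], mapq,
            base_qualities=quals[:head_len],
        ),
        MappedRead(
            read.read_id, reference_id, 1, strand, seq[head_len:], mapq,
            base_qualities=quals[head_len:],
        ),
    ]


def map_reads(
    reads: list[SequencingRead],
    reference: str,
    reference_id: str = "ref",
    k: int = DEFAULT_K,
    max_mismatch_frac: float = DEFAULT_MAX_MISMATCH_FRACTION,
) -> list[MappedRead]:
    """Map a read set to one circular reference; unplaced reads omitted."""
    index = ReferenceIndex(reference, k=k)
    out: list[MappedRead] = []
    for read in reads:
        out.extend(map_read(read, index, reference_id, max_mismatch_frac))
    return out
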