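"""Pileup construction and threshold-based consensus calling.

The caller reproduces a conservative archival-DNA consensus rule: a
reference position receives a base only when covered by at least
``min_depth`` filtered reads whose modal base reaches at least
``min_agreement`` of the filtered depth, counting only non-duplicate
reads with mapping quality of at least ``min_mapq`` (defaults 5x, 80%,
MQ 25; all thresholds inclusive).  Everything else is N, so consensus
completeness directly measures how much of the genome the data and the
chosen reference can support.

Consensus sequences are reference-projected (same length as the
reference; indels are not called) — output headers carry this caveat.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from museomito.seq import match_count, seq_to_array
from museomito.types import ConsensusParams, ConsensusSequence, MappedRead

logger = logging.getLogger(__name__)

_BASE_INDEX = {ord(b): i for i, b in enumerate("ACGT")}


@dataclass
class PileupColumn:
    """Filtered base counts at one 1-based reference position."""

    position: int
    base_counts: dict[str, int]

    @property
    def depth(self) -> int:
        return sum(self.base_counts.values())


class Pileup:
    """Per-position filtered base counts over a whole reference.

    ``counts`` is an (L, 4) integer array in A,C,G,T order built from
    non-duplicate reads passing the mapping-quality filter.
    """

    def __init__(self, counts: np.ndarray):
        self.counts = counts

    @property
    def depth(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def column(self, position: int) -> PileupColumn:
        """1-based accessor."""
        row = self.counts[position - 1]
        return PileupColumn(position, {b: int(row[i]) for i, b in enumerate("ACGT")})

    def columns(self) -> list[PileupColumn]:
        return [self.column(p + 1) for p in np.flatnonzero(self.depth > 0)]


def build_pileup(
    mapped: list[MappedRead], params: ConsensusParams, reference_length: int
) -> Pileup:
    """Count bases per reference position from MQ-passing, non-duplicate reads.

    Non-ACGT read characters (including deletion placeholders) add no
    count.  Reads must all be on one reference.
    """
    refs = {r.reference_id for r in mapped}
    if len(refs) > 1:
        raise ValueError(f"reads on mixed references: {sorted(refs)}")
    counts = np.zeros((reference_length, 4), dtype=np.int32)
    for r in mapped:
        if r.duplicate or r.mapping_quality < params.min_mapq:
            continue
        if r.end > reference_length:
            raise ValueError(
                f"read {r.read_id} extends past reference end "
                f"({r.end} > {reference_length})"
            )
        arr = seq_to_array(r.aligned.upper())
        for code, col in _BASE_INDEX.items():
            pos = np.flatnonzero(arr == code)
            np.add.at(counts[:, col], r.start - 1 + pos, 1)
    return Pileup(counts)


def call_consensus(
    pileup: Pileup, params: ConsensusParams, sample_id: str = "sample",
    reference_id: str = "ref",
) -> ConsensusSequence:
    """Apply the depth/agreement thresholds to a filtered pileup.

    A site is called with its modal base iff depth >= min_depth, the
    modal count is at least min_agreement of the depth, and the mode is
    unique; otherwise N.  Positions never covered are N.
    """
    counts = pileup.counts
    depth = counts.sum(axis=1)
    modal = counts.max(axis=1)
    modal_idx = counts.argmax(axis=1)
    unique_mode = (counts == modal[:, None]).sum(axis=1) == 1
    with np.errstate(invalid="ignore", divide="ignore"):
        agreement = np.where(depth > 0, modal / np.maximum(depth, 1), 0.0)
    callable_ = (
        (depth >= params.min_depth)
        & (agreement >= params.min_agreement)
        & unique_mode
    )
    bases = np.full(len(counts), "N", dtype="U1")
    lut = np.array(list("ACGT"))
    bases[callable_] = lut[modal_idx[callable_]]
    return ConsensusSequence(sample_id, reference_id, "".join(bases))


def select_reference(consensuses: list[ConsensusSequence]) -> ConsensusSequence:
    """Pick the candidate reference yielding the most complete consensus.

    Ties are broken by input order and logged.
    """
    if not consensuses:
        raise ValueError("no candidate consensuses")
    best = max(consensuses, key=lambda c: c.completeness)
    ties = [c for c in consensuses if c.completeness == best.completeness]
    winner = ties[0]
    if len(ties) > 1:
        logger.info(
            "completeness tie (%.4f) among references %s; keeping %s",
            winner.completeness,
            [c.reference_id for c in ties],
            winner.reference_id,
        )
    return winner


def collapse_concatemer(contig: str, min_identity: float = 0.98) -> str:
    """Collapse a tandem two-copy (concatemeric) assembly to one copy.

    Circular genomes assembled de novo sometimes emerge as two
    concatenated copies.  Candidate copy lengths within +-10% of half
    the contig length are scanned; if splitting there aligns the two
    copies ungapped at identity >= ``min_identity``, the first copy is
    returned (disagreements between the two copies are 1-vs-1 ties and
    resolve to the first copy).  Otherwise the contig is unchanged.
    """
    if not contig:
        raise ValueError("empty contig")
    n = len(contig)
    half = n // 2
    margin = max(1, int(round(0.1 * half)))
    best_m, best_identity = None, -1.0
    for m in range(max(1, half - margin), min(n - 1, half + margin) + 1):
        a, b = contig[:m], contig[m:]
        span = min(len(a), len(b))
        if span < 0.8 * m:
            continue
        identity = match_count(a[:span], b[:span]) / span
        if identity > best_identity:
            best_m, best_identity = m, identity
    if best_m is None or best_identity < min_identity:
        return contig
    return contig[:best_m]
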