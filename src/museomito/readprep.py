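"""Read preparation: demultiplexing, pair merging, deduplication.

Demultiplexing assigns a read pair to a sample only on an exact match
of the inline barcode at the 5' end of read 1 (degraded-specimen
libraries are demultiplexed strictly; a single mismatch leaves the
pair unassigned).  Overlapping pairs are merged into consensus reads;
mapped reads sharing coordinates and strand are collapsed to one
representative.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from museomito.seq import match_count, reverse_complement
from museomito.types import MappedRead, SampleManifest, SequencingRead

DEFAULT_MIN_OVERLAP = 11
DEFAULT_MAX_MISMATCH_FRACTION = 0.1

ReadPair = tuple[SequencingRead, SequencingRead]


@dataclass
class DemuxResult:
    assigned: dict[str, list[ReadPair]] = field(default_factory=dict)
    unassigned: list[ReadPair] = field(default_factory=list)

    @property
    def n_assigned(self) -> int:
        return sum(len(v) for v in self.assigned.values())


def demultiplex(pairs: list[ReadPair] | list[SequencingRead], manifest: SampleManifest) -> DemuxResult:
    """Bin read pairs by exact inline-barcode match on read 1.

    The barcode is trimmed from assigned reads; qualities are trimmed in
    step.  Assignment is a partition: every input pair lands in exactly
    one sample bin or in ``unassigned``.
    """
    lookup = manifest.as_dict()
    length = manifest.barcode_length
    result = DemuxResult(assigned={sid: [] for sid, _ in manifest.entries})
    for item in pairs:
        pair: ReadPair = item if isinstance(item, tuple) else (item, item)
        r1 = pair[0]
        if len(r1) < length:
            result.unassigned.append(pair)
            continue
        sample = lookup.get(r1.bases[:length])
        if sample is None:
            result.unassigned.append(pair)
            continue
        trimmed = SequencingRead(
            r1.read_id, r1.bases[length:], r1.qualities[length:], mate=r1.mate
        )
        if isinstance(item, tuple):
            result.assigned[sample].append((trimmed, pair[1]))
        else:
            result.assigned[sample].append((trimmed, trimmed))
    return result


def _overlap_candidates(
    r1: SequencingRead, rc2_bases: str, min_overlap: int
) -> list[tuple[int, int]]:
    """(overlap_length, match_count) for every overlap >= min_overlap.

    Overlap o aligns the last o bases of read 1 with the first o bases
    of the reverse-complemented read 2 (standard innie geometry).
    """
    out = []
    for o in range(min_overlap, min(len(r1.bases), len(rc2_bases)) + 1):
        m = match_count(r1.bases[-o:], rc2_bases[:o])
        out.append((o, m))
    return out


def merge_pairs(
    pair: ReadPair,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    max_mismatch_fraction: float = DEFAULT_MAX_MISMATCH_FRACTION,
) -> SequencingRead | ReadPair:
    """Merge an overlapping pair into one consensus read, if possible.

    Read 2 is reverse-complemented; among overlap offsets of length at
    least ``min_overlap`` whose mismatch fraction is at most
    ``max_mismatch_fraction``, the one with the most matching bases is
    chosen (ties go to the longer overlap).  Disagreeing overlap
    positions take the higher-quality base; the merged quality is the
    max of the two.  If no offset qualifies the pair is returned as is.
    """
    r1, r2 = pair
    if not r1.bases or not r2.bases:
        raise ValueError("cannot merge an empty read")
    rc2_bases = reverse_complement(r2.bases)
    rc2_quals = list(reversed(r2.qualities))

    best: tuple[int, int] | None = None  # (match_count, overlap)
    for o, m in _overlap_candidates(r1, rc2_bases, min_overlap):
        if (o - m) / o > max_mismatch_fraction:
            continue
        if best is None or (m, o) > best:
            best = (m, o)
    if best is None:
        return pair
    o = best[1]

    head = r1.bases[:-o] if o < len(r1.bases) else ""
    head_q = r1.qualities[:-o] if o < len(r1.bases) else []
    tail = rc2_bases[o:]
    tail_q = rc2_quals[o:]
    mid = []
    mid_q = []
    for b1, q1, b2, q2 in zip(
        r1.bases[-o:], r1.qualities[-o:], rc2_bases[:o], rc2_quals[:o]
    ):
        if b1 == b2 or q1 >= q2:
            mid.append(b1)
        else:
            mid.append(b2)
        mid_q.append(max(q1, q2))
    return SequencingRead(
        r1.read_id, head + "".join(mid) + tail, head_q + mid_q + tail_q, mate="merged"
    )


def deduplicate(mapped: list[MappedRead]) -> list[MappedRead]:
    """Keep one representative per (reference, start, end, strand).

    The representative is the read with the highest base-quality sum
    (ties, or reads without qualities: the first encountered).  Output
    preserves the input order of the surviving reads.
    """
    best: dict[tuple[str, int, int, str], tuple[int, float]] = {}
    for i, r in enumerate(mapped):
        key = (r.reference_id, r.start, r.end, r.strand)
        score = float(sum(r.base_qualities)) if r.base_qualities else 0.0
        if key not in best or score > best[key][1]:
            best[key] = (i, score)
    keep = {i for i, _ in best.values()}
    return [r for i, r in enumerate(mapped) if i in keep]
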