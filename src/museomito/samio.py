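"""SAM import/export for the minimal dialect the pipeline consumes.

SAM is the fidelity path for externally mapped reads.  Parsing goes
through pysam; only the fields the pileup needs are retained.  CIGAR
handling: M/=/X consume reference and read, I is ignored for the
pileup, D (and N) advance the reference contributing no base, soft
clips are trimmed, hard clips and padding are skipped.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pysam

from museomito.types import MappedRead

logger = logging.getLogger(__name__)

# CIGAR operation codes (pysam numeric encoding)
_OP_M, _OP_I, _OP_D, _OP_N, _OP_S, _OP_H, _OP_P, _OP_EQ, _OP_X = range(9)


def _aligned_from_cigar(seq: str, quals: list[int] | None, cigartuples) -> tuple[str, list[int] | None]:
    """Project the read onto the reference: one char per reference
    position covered, '-' at deletions; soft-clipped bases dropped."""
    out: list[str] = []
    out_q: list[int] | None = [] if quals is not None else None
    qpos = 0
    for op, length in cigartuples:
        if op in (_OP_M, _OP_EQ, _OP_X):
            out.append(seq[qpos : qpos + length])
            if out_q is not None:
                out_q.extend(quals[qpos : qpos + length])
            qpos += length
        elif op == _OP_I:
            qpos += length
        elif op in (_OP_D, _OP_N):
            out.append("-" * length)
            if out_q is not None:
                out_q.extend([0] * length)
        elif op == _OP_S:
            qpos += length
        elif op in (_OP_H, _OP_P):
            continue
        else:
            raise ValueError(f"unsupported CIGAR operation code {op}")
    return "".join(out), out_q


def read_sam(path: str | Path) -> list[MappedRead]:
    """Parse a SAM file into mapped reads.

    Unmapped records are omitted; malformed records are skipped with a
    logged warning rather than aborting the run.
    """
    out: list[MappedRead] = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for rec in fh:
            try:
                if rec.is_unmapped or rec.cigartuples is None:
                    continue
                quals = list(rec.query_qualities) if rec.query_qualities is not None else None
                aligned, aligned_q = _aligned_from_cigar(
                    rec.query_sequence or "", quals, rec.cigartuples
                )
                if not aligned:
                    continue
                out.append(
                    MappedRead(
                        read_id=rec.query_name or "",
                        reference_id=rec.reference_name or "",
                        start=rec.reference_start + 1,
                        strand="-" if rec.is_reverse else "+",
                        aligned=aligned,
                        mapping_quality=rec.mapping_quality,
                        duplicate=rec.is_duplicate,
                        base_qualities=aligned_q,
                    )
                )
            except (ValueError, TypeError) as exc:
                logger.warning("skipping malformed SAM record %s: %s", rec.query_name, exc)
    return out


def write_sam(
    mapped: list[MappedRead],
    path: str | Path,
    reference_lengths: dict[str, int],
) -> None:
    """Write mapped reads as SAM (header built from reference lengths)."""
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": name, "LN": length} for name, length in reference_lengths.items()],
    }
    ref_ids = {name: i for i, name in enumerate(reference_lengths)}
    with pysam.AlignmentFile(str(path), "w", header=header) as fh:
        for r in mapped:
            rec = pysam.AlignedSegment(fh.header)
            rec.query_name = r.read_id
            rec.reference_id = ref_ids[r.reference_id]
            rec.reference_start = r.start - 1
            rec.mapping_quality = r.mapping_quality
            flag = 0
            if r.strand == "-":
                flag |= 0x10
            if r.duplicate:
                flag |= 0x400
            rec.flag = flag
            rec.query_sequence = r.aligned_bases
            if r.base_qualities is not None:
                rec.query_qualities = pysam.qualitystring_to_array(
                    "".join(
                        chr(q + 33)
                        for q, c in zip(r.base_qualities, r.aligned)
                        if c != "-"
                    )
                )
            rec.cigartuples = _cigar_from_aligned(r.aligned)
            fh.write(rec)


def _cigar_from_aligned(aligned: str) -> list[tuple[int, int]]:
    """Run-length encode an aligned string into M/D CIGAR tuples."""
    tuples: list[tuple[int, int]] = []
    for ch in aligned:
        op = _OP_D if ch == "-" else _OP_M
        if tuples and tuples[-1][0] == op:
            tuples[-1] = (op, tuples[-1][1] + 1)
        else:
            tuples.append((op, 1))
    return tuples
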