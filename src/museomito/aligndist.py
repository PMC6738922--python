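"""Alignment masking and uncorrected pairwise divergence.

Divergence between two aligned mitogenomes is reported as an
uncorrected p-distance under pairwise deletion: an alignment column
counts only when both rows hold an unambiguous base (A, C, G or T);
gaps, N, ? and IUPAC ambiguity codes are treated as missing.  The
number of retained columns — the valid positions — is reported
alongside every divergence, since partial archival genomes make that
denominator vary strongly across pairs.

Alignment regions of ambiguous homology (e.g. the D-loop) are masked
by coordinates on a named anchor sequence: a region is given as
1-based inclusive positions in the anchor's ungapped sequence and
translated to alignment columns before removal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import AlignIO
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from museomito.types import DistanceResult, MaskRegion

logger = logging.getLogger(__name__)

_VALID = np.frombuffer(b"ACGT", dtype=np.uint8)
GAP_CHARS = set("-")


@dataclass
class MultipleAlignment:
    """Equal-length rows over uniquely labelled taxa.

    Rows are stored uppercase with U normalised to T; '?' and 'N' are
    preserved as written (both count as missing in distances).
    """

    taxa: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.taxa) != len(self.rows):
            raise ValueError("taxa/rows length mismatch")
        if len(set(self.taxa)) != len(self.taxa):
            raise ValueError("duplicate taxon labels")
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise ValueError("ragged alignment rows")
        self.rows = [r.upper().replace("U", "T") for r in self.rows]

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def row(self, taxon: str) -> str:
        try:
            return self.rows[self.taxa.index(taxon)]
        except ValueError:
            raise KeyError(f"taxon {taxon!r} not in alignment") from None


def read_alignment(path: str | Path, fmt: str | None = None) -> MultipleAlignment:
    """Read a NEXUS or FASTA alignment (interleaved NEXUS supported)."""
    path = Path(path)
    if fmt is None:
        fmt = "nexus" if path.suffix.lower() in (".nex", ".nexus", ".nxs") else "fasta"
    if fmt not in ("nexus", "fasta"):
        raise ValueError(f"unknown alignment format {fmt!r}")
    aln = AlignIO.read(str(path), fmt)
    return MultipleAlignment(
        taxa=[rec.id for rec in aln], rows=[str(rec.seq) for rec in aln]
    )


def write_alignment(alignment: MultipleAlignment, path: str | Path, fmt: str = "fasta") -> None:
    records = [
        SeqRecord(Seq(row), id=taxon, description="")
        for taxon, row in zip(alignment.taxa, alignment.rows)
    ]
    msa = MultipleSeqAlignment(records)
    if fmt == "nexus":
        for rec in msa:
            rec.annotations["molecule_type"] = "DNA"
    AlignIO.write(msa, str(path), fmt)


def ungapped_length(row: str) -> int:
    """Count of unambiguous bases (A/C/G/T) in an alignment row."""
    arr = np.frombuffer(row.upper().encode("ascii"), dtype=np.uint8)
    return int(np.isin(arr, _VALID).sum())


def map_anchor_to_columns(alignment: MultipleAlignment, region: MaskRegion) -> set[int]:
    """Translate anchor-sequence coordinates to alignment columns (1-based).

    Returns the columns holding the anchor row's start-th through end-th
    non-gap characters inclusive, plus any gap-only columns interior to
    that span.
    """
    row = alignment.row(region.anchor_taxon)
    nongap = [i for i, ch in enumerate(row) if ch not in GAP_CHARS]
    if region.end > len(nongap):
        raise ValueError(
            f"region {region.start}-{region.end} exceeds ungapped length "
            f"{len(nongap)} of anchor {region.anchor_taxon!r}"
        )
    first = nongap[region.start - 1]
    last = nongap[region.end - 1]
    return set(range(first + 1, last + 2))  # 1-based inclusive span


@dataclass
class MaskReport:
    per_region: list[tuple[MaskRegion, int]] = field(default_factory=list)
    columns_removed: int = 0


def mask_columns(
    alignment: MultipleAlignment, regions: list[MaskRegion]
) -> tuple[MultipleAlignment, MaskReport]:
    """Remove the union of the mapped region columns (order preserved)."""
    report = MaskReport()
    union: set[int] = set()
    for region in regions:
        cols = map_anchor_to_columns(alignment, region)
        report.per_region.append((region, len(cols)))
        union |= cols
    report.columns_removed = len(union)
    keep = [i for i in range(alignment.n_columns) if (i + 1) not in union]
    masked = MultipleAlignment(
        taxa=list(alignment.taxa),
        rows=["".join(row[i] for i in keep) for row in alignment.rows],
    )
    return masked, report


def p_distance(row_a: str, row_b: str, taxon_a: str = "a", taxon_b: str = "b") -> DistanceResult:
    """Uncorrected divergence with pairwise deletion.

    Columns where either row holds anything but A/C/G/T are excluded;
    mismatches are counted over the remaining valid positions.
    """
    if len(row_a) != len(row_b):
        raise ValueError("rows must have equal length")
    a = np.frombuffer(row_a.upper().replace("U", "T").encode("ascii"), dtype=np.uint8)
    b = np.frombuffer(row_b.upper().replace("U", "T").encode("ascii"), dtype=np.uint8)
    valid = np.isin(a, _VALID) & np.isin(b, _VALID)
    n_valid = int(valid.sum())
    if n_valid == 0:
        raise ZeroDivisionError(f"no valid positions between {taxon_a} and {taxon_b}")
    mismatches = int((a[valid] != b[valid]).sum())
    return DistanceResult(taxon_a, taxon_b, mismatches, n_valid)


@dataclass
class DistanceMatrix:
    """All pairwise divergences with valid-position accounting."""

    taxa: list[str]
    results: dict[frozenset[str], DistanceResult]
    failed_pairs: list[tuple[str, str]] = field(default_factory=list)

    def get(self, a: str, b: str) -> DistanceResult:
        return self.results[frozenset((a, b))]

    def divergence_array(self) -> np.ndarray:
        n = len(self.taxa)
        mat = np.zeros((n, n))
        for i, a in enumerate(self.taxa):
            for j in range(i + 1, n):
                b = self.taxa[j]
                key = frozenset((a, b))
                if key not in self.results:
                    mat[i, j] = mat[j, i] = np.nan
                else:
                    mat[i, j] = mat[j, i] = self.results[key].divergence
        return mat

    def to_long_table(self):
        """Long-format pair table as a pandas DataFrame."""
        import pandas as pd

        rows = []
        for i, a in enumerate(self.taxa):
            for b in self.taxa[i + 1 :]:
                key = frozenset((a, b))
                if key not in self.results:
                    continue
                r = self.results[key]
                rows.append(
                    {
                        "taxon_a": a,
                        "taxon_b": b,
                        "mismatches": r.mismatches,
                        "valid_positions": r.valid_positions,
                        "divergence": r.divergence,
                    }
                )
        return pd.DataFrame(rows)


def distance_matrix(alignment: MultipleAlignment) -> DistanceMatrix:
    """Pairwise-deletion p-distances for all unordered taxon pairs.

    Pairs sharing no valid positions are flagged in ``failed_pairs``
    rather than aborting the whole matrix.
    """
    if len(alignment.taxa) < 2:
        raise ValueError("need at least 2 taxa")
    out = DistanceMatrix(taxa=list(alignment.taxa), results={})
    for i, a in enumerate(alignment.taxa):
        for b in alignment.taxa[i + 1 :]:
            try:
                out.results[frozenset((a, b))] = p_distance(
                    alignment.row(a), alignment.row(b), a, b
                )
            except ZeroDivisionError:
                logger.warning("no valid positions between %s and %s", a, b)
                out.failed_pairs.append((a, b))
    return out


def nj_tree(matrix: DistanceMatrix) -> str:
    """Neighbor-joining tree (newick, branch lengths) from a full matrix.

    A sanity-check tree only; distances must be available for every pair.
    """
    if len(matrix.taxa) < 3:
        raise ValueError("need at least 3 taxa for a tree")
    if matrix.failed_pairs:
        raise ValueError(f"missing distances for pairs: {matrix.failed_pairs}")
    from skbio import DistanceMatrix as SkbioDM
    from skbio.tree import nj

    dm = SkbioDM(matrix.divergence_array(), ids=matrix.taxa)
    tree = nj(dm)
    return str(tree).strip()
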