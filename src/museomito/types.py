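"""Domain types shared across the pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass
class SequencingRead:
    """A sequencing read with Phred-scale base qualities.

    ``mate`` is 1 or 2 for the members of a pair and "merged" for a
    consensus read built from an overlapping pair.
    """

    read_id: str
    bases: str
    qualities: list[int]
    mate: str = "1"

    def __post_init__(self) -> None:
        if len(self.bases) != len(self.qualities):
            raise ValueError(
                f"read {self.read_id}: {len(self.bases)} bases but "
                f"{len(self.qualities)} qualities"
            )
        if any(q < 0 or q > 60 for q in self.qualities):
            raise ValueError(f"read {self.read_id}: Phred quality outside [0, 60]")

    def __len__(self) -> int:
        return len(self.bases)


@dataclass
class MappedRead:
    """A read placed on a reference.

    ``aligned`` is the read projected onto the reference: one character
    per reference position covered, with "-" at positions deleted from
    the read (these consume reference but contribute no pileup count).
    ``start`` is 1-based inclusive.
    """

    read_id: str
    reference_id: str
    start: int
    strand: str  # "+" or "-"
    aligned: str
    mapping_quality: int
    duplicate: bool = False
    base_qualities: list[int] | None = None

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(f"read {self.read_id}: start must be >= 1")
        if self.strand not in ("+", "-"):
            raise ValueError(f"read {self.read_id}: strand must be + or -")
        if self.mapping_quality < 0:
            raise ValueError(f"read {self.read_id}: negative mapping quality")

    @property
    def end(self) -> int:
        """1-based inclusive last reference position covered."""
        return self.start + len(self.aligned) - 1

    @property
    def aligned_bases(self) -> str:
        """Read bases only (deletion placeholders stripped)."""
        return self.aligned.replace("-", "")


@dataclass
class ConsensusParams:
    """Thresholds for consensus calling on a pileup.

    A site is called only with depth >= ``min_depth``, modal-base
    agreement >= ``min_agreement``, and from reads with mapping quality
    >= ``min_mapq``; all thresholds are inclusive.
    """

    min_depth: int = 5
    min_agreement: float = 0.8
    min_mapq: int = 25

    def __post_init__(self) -> None:
        if self.min_depth < 1:
            raise ValueError("min_depth must be >= 1")
        if not 0 < self.min_agreement <= 1:
            raise ValueError("min_agreement must be in (0, 1]")
        if self.min_mapq < 0:
            raise ValueError("min_mapq must be >= 0")


@dataclass
class ConsensusSequence:
    """Reference-length consensus with N at uncalled sites."""

    sample_id: str
    reference_id: str
    bases: str

    def __post_init__(self) -> None:
        bad = set(self.bases) - set("ACGTN")
        if bad:
            raise ValueError(f"consensus contains non-ACGTN characters: {sorted(bad)}")

    @property
    def completeness(self) -> float:
        """Fraction of positions with a called (non-N) base."""
        if not self.bases:
            return 0.0
        return 1.0 - self.bases.count("N") / len(self.bases)

    def __len__(self) -> int:
        return len(self.bases)


@dataclass
class SampleManifest:
    """sample_id -> inline barcode table used for demultiplexing."""

    entries: list[tuple[str, str]]

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValueError("manifest is empty")
        barcodes = [bc for _, bc in self.entries]
        if len(set(barcodes)) != len(barcodes):
            raise ValueError("duplicate barcodes in manifest")
        lengths = {len(bc) for bc in barcodes}
        if len(lengths) != 1:
            raise ValueError("barcodes must all have the same length")
        for _, bc in self.entries:
            if set(bc) - set("ACGT"):
                raise ValueError(f"barcode {bc} contains non-ACGT characters")

    @property
    def barcode_length(self) -> int:
        return len(self.entries[0][1])

    def as_dict(self) -> dict[str, str]:
        """barcode -> sample_id lookup."""
        return {bc: sid for sid, bc in self.entries}


@dataclass
class MaskRegion:
    """A 1-based inclusive interval in ungapped coordinates of an anchor taxon."""

    anchor_taxon: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not 1 <= self.start <= self.end:
            raise ValueError(f"invalid mask region {self.start}-{self.end}")

    def __len__(self) -> int:
        return self.end - self.start + 1


@dataclass
class DistanceResult:
    """Uncorrected pairwise divergence for one taxon pair.

    ``valid_positions`` counts alignment columns where both rows hold an
    unambiguous base (pairwise deletion of gaps, missing and ambiguity
    codes); ``divergence`` = mismatches / valid_positions.
    """

    taxon_a: str
    taxon_b: str
    mismatches: int
    valid_positions: int

    def __post_init__(self) -> None:
        if not 0 <= self.mismatches <= self.valid_positions:
            raise ValueError("mismatches must lie in [0, valid_positions]")

    @property
    def divergence(self) -> float:
        if self.valid_positions == 0:
            raise ZeroDivisionError(
                f"no valid positions between {self.taxon_a} and {self.taxon_b}"
            )
        return self.mismatches / self.valid_positions


@dataclass
class SimulationConfig:
    """Parameters of the degraded-specimen read simulator.

    Defaults describe the study conditions the generator emulates:
    a ~17.2 kb circular mitogenome, short fragments (mean 90 bp),
    elevated per-base error, 20x coverage and a 20% duplicate fraction.
    """

    genome_length: int = 17200
    divergence_targets: list[float] = field(default_factory=lambda: [0.04])
    fragment_length_mean: float = 90.0
    fragment_length_sd: float = 20.0
    read_length: int = 75
    per_base_error_rate: float = 0.005
    mean_depth: float = 20.0
    duplicate_rate: float = 0.2
    dropout_regions: list[tuple[int, int]] = field(default_factory=list)
    barcode_length: int = 6
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.genome_length <= 0:
            raise ValueError("genome_length must be positive")
        for name in ("per_base_error_rate", "duplicate_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        for p in self.divergence_targets:
            if not 0 <= p < 0.75:
                raise ValueError("divergence targets must be in [0, 0.75)")
        if self.fragment_length_mean <= 0 or self.fragment_length_sd < 0:
            raise ValueError("invalid fragment length parameters")
        if self.read_length <= 0:
            raise ValueError("read_length must be positive")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")
        if self.barcode_length < 0:
            raise ValueError("barcode_length must be >= 0")
        for start, end in self.dropout_regions:
            if not 1 <= start <= end <= self.genome_length:
                raise ValueError(
                    f"dropout region ({start}, {end}) outside [1, {self.genome_length}]"
                )
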