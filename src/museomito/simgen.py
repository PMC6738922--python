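"""Synthetic data generator for degraded-specimen capture sequencing.

Emulates the statistical structure of sequencing data from old,
degraded museum specimens: a circular mitogenome of ~17.2 kb, taxon
pairs diverged by a chosen per-site substitution probability, short
fragments with elevated per-base error, inline sample barcodes, PCR
duplicates, and missing-region dropout that yields partial genomes.
Every emitted read carries a truth record (taxon, origin coordinates,
strand, duplicate flag) so downstream stages can be scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from museomito.seq import BASES, circular_slice, hamming, reverse_complement
from museomito.types import SequencingRead, SimulationConfig

# Phred range assigned to simulated bases; errors are applied at the
# configured rate independently of these values.
_QUAL_LOW, _QUAL_HIGH = 30, 41

_MIN_FRAGMENT = 30  # shortest fragment the simulator emits, bp


@dataclass
class ReadOrigin:
    """Truth record for one read pair (one sequenced fragment)."""

    read_id: str
    taxon: str
    start: int  # 1-based inclusive on the taxon genome
    end: int  # may exceed genome length when the fragment wraps the origin
    strand: str
    is_duplicate: bool


@dataclass
class TruthSet:
    """Ground truth accompanying a simulated read set."""

    ancestral_genome: str
    taxon_genomes: dict[str, str] = field(default_factory=dict)
    origins: list[ReadOrigin] = field(default_factory=list)
    realized_divergence: dict[str, float] = field(default_factory=dict)

    def n_distinct_fragments(self, taxon: str | None = None) -> int:
        return sum(
            1
            for o in self.origins
            if not o.is_duplicate and (taxon is None or o.taxon == taxon)
        )

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("read_id\ttaxon\tstart\tend\tstrand\tis_duplicate\n")
            for o in self.origins:
                fh.write(
                    f"{o.read_id}\t{o.taxon}\t{o.start}\t{o.end}\t"
                    f"{o.strand}\t{int(o.is_duplicate)}\n"
                )


def simulate_genome(length: int, seed: int) -> str:
    """Uniform-composition random circular genome over ACGT."""
    if length <= 0:
        raise ValueError("genome length must be positive")
    rng = np.random.default_rng(seed)
    return "".join(np.array(list(BASES))[rng.integers(0, 4, size=length)])


def evolve(genome: str, p_target: float, seed: int) -> str:
    """Derive a taxon genome by independent-site uniform substitution.

    Each site is substituted with probability ``p_target``; the new base
    is uniform among the three alternatives (a Jukes-Cantor-like move).
    """
    if not 0 <= p_target < 0.75:
        raise ValueError("p_target must be in [0, 0.75)")
    if p_target == 0:
        return genome
    rng = np.random.default_rng(seed)
    arr = np.frombuffer(genome.encode("ascii"), dtype=np.uint8).copy()
    hit = rng.random(len(arr)) < p_target
    idx = np.flatnonzero(hit)
    base_bytes = np.frombuffer(BASES.encode("ascii"), dtype=np.uint8)
    for i in idx:
        alternatives = base_bytes[base_bytes != arr[i]]
        arr[i] = rng.choice(alternatives)
    return arr.tobytes().decode("ascii")


def _allowed_intervals(
    genome_length: int, dropout: list[tuple[int, int]]
) -> list[tuple[int, int]]:
    """Complement of the dropout regions as 1-based inclusive intervals."""
    if not dropout:
        return [(1, genome_length)]
    merged: list[list[int]] = []
    for s, e in sorted(dropout):
        if merged and s <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    allowed = []
    prev_end = 0
    for s, e in merged:
        if s > prev_end + 1:
            allowed.append((prev_end + 1, s - 1))
        prev_end = e
    if prev_end < genome_length:
        allowed.append((prev_end + 1, genome_length))
    if not allowed:
        raise ValueError("dropout regions cover the whole genome")
    return allowed


def _apply_errors(bases: str, rate: float, rng: np.random.Generator) -> str:
    if rate == 0 or not bases:
        return bases
    arr = np.frombuffer(bases.encode("ascii"), dtype=np.uint8).copy()
    hit = np.flatnonzero(rng.random(len(arr)) < rate)
    base_bytes = np.frombuffer(BASES.encode("ascii"), dtype=np.uint8)
    for i in hit:
        arr[i] = rng.choice(base_bytes[base_bytes != arr[i]])
    return arr.tobytes().decode("ascii")


def generate_reads(
    taxon_genome: str,
    config: SimulationConfig,
    barcode: str,
    taxon: str = "taxon",
    seed: int | None = None,
    truth: TruthSet | None = None,
) -> tuple[list[tuple[SequencingRead, SequencingRead]], TruthSet]:
    """Draw paired reads from circular fragments of ``taxon_genome``.

    Fragments are placed only where they fit entirely outside dropout
    regions (wrapping the origin is allowed when no dropout blocks it).
    Read 1 carries the inline barcode at its 5' end; read 2 is the
    reverse complement of the fragment's other end.  PCR duplicates
    re-emit the same fragment with independent sequencing errors.
    """
    if set(barcode) - set("ACGT"):
        raise ValueError("barcode must be over ACGT")
    if len(barcode) != config.barcode_length:
        raise ValueError(
            f"barcode length {len(barcode)} != configured {config.barcode_length}"
        )
    n = len(taxon_genome)
    if n != config.genome_length:
        raise ValueError("taxon genome length differs from config.genome_length")
    rng = np.random.default_rng(config.rng_seed if seed is None else seed)
    if truth is None:
        truth = TruthSet(ancestral_genome="")
    truth.taxon_genomes.setdefault(taxon, taxon_genome)

    allowed = _allowed_intervals(n, config.dropout_regions)
    # Allow origin wrap only when position n and position 1 are both allowed.
    wrap_ok = allowed[0][0] == 1 and allowed[-1][1] == n and len(allowed) >= 1

    eff_len = sum(e - s + 1 for s, e in allowed)
    n_fragments = int(round(config.mean_depth * eff_len / config.fragment_length_mean))

    pairs: list[tuple[SequencingRead, SequencingRead]] = []
    frag_no = 0
    attempts = 0
    max_attempts = 50 * n_fragments + 1000
    while frag_no < n_fragments and attempts < max_attempts:
        attempts += 1
        flen = int(round(rng.normal(config.fragment_length_mean, config.fragment_length_sd)))
        flen = max(_MIN_FRAGMENT, min(flen, n))
        # choose an interval weighted by the number of fits, then a start
        weights = []
        for s, e in allowed:
            ilen = e - s + 1
            if s == allowed[-1][0] and wrap_ok and len(allowed) == 1:
                weights.append(ilen)  # fully circular: every start fits
            else:
                weights.append(max(0, ilen - flen + 1))
        total = sum(weights)
        if total == 0:
            continue
        r = rng.integers(0, total)
        for (s, e), w in zip(allowed, weights):
            if r < w:
                start = s + int(r)
                break
            r -= w
        end = start + flen - 1
        if end > n and not (wrap_ok and len(allowed) == 1):
            continue
        frag_no += 1
        strand = "+" if rng.random() < 0.5 else "-"
        n_copies = 1 + (1 if rng.random() < config.duplicate_rate else 0)
        fragment = circular_slice(taxon_genome, start - 1, flen)
        if strand == "-":
            fragment_seq = reverse_complement(fragment)
        else:
            fragment_seq = fragment
        for copy in range(n_copies):
            is_dup = copy > 0
            rid = f"frag{frag_no:06d}" + (f".dup{copy}" if is_dup else "")
            rlen = min(config.read_length, flen)
            r1_genomic = _apply_errors(
                fragment_seq[:rlen], config.per_base_error_rate, rng
            )
            r2_genomic = _apply_errors(
                reverse_complement(fragment_seq[-rlen:]),
                config.per_base_error_rate,
                rng,
            )
            r1_bases = barcode + r1_genomic
            q1 = rng.integers(_QUAL_LOW, _QUAL_HIGH, size=len(r1_bases)).tolist()
            q2 = rng.integers(_QUAL_LOW, _QUAL_HIGH, size=len(r2_genomic)).tolist()
            pairs.append(
                (
                    SequencingRead(rid, r1_bases, q1, mate="1"),
                    SequencingRead(rid, r2_genomic, q2, mate="2"),
                )
            )
            truth.origins.append(
                ReadOrigin(rid, taxon, start, end, strand, is_dup)
            )
    if frag_no < n_fragments:
        raise RuntimeError("could not place the requested number of fragments")
    return pairs, truth


def simulate_taxon_pairs(config: SimulationConfig, seed: int) -> TruthSet:
    """Ancestral genome plus one derived genome per divergence target.

    Taxa are named ``taxon_<percent>`` after their target divergence;
    realized Hamming fractions are recorded exactly in the truth set.
    """
    ancestral = simulate_genome(config.genome_length, seed)
    truth = TruthSet(ancestral_genome=ancestral)
    truth.taxon_genomes["ancestral"] = ancestral
    for i, p in enumerate(config.divergence_targets):
        name = f"taxon_{100 * p:g}pct"
        derived = evolve(ancestral, p, seed + 1000 + i)
        truth.taxon_genomes[name] = derived
        truth.realized_divergence[name] = hamming(ancestral, derived) / len(ancestral)
    return truth


def write_fastq(
    pairs: list[tuple[SequencingRead, SequencingRead]],
    r1_path: str | Path,
    r2_path: str | Path,
) -> None:
    """Write a paired read set as two Phred+33 FASTQ files."""
    with open(r1_path, "w") as f1, open(r2_path, "w") as f2:
        for r1, r2 in pairs:
            for fh, r in ((f1, r1), (f2, r2)):
                qual = "".join(chr(q + 33) for q in r.qualities)
                fh.write(f"@{r.read_id}/{r.mate}\n{r.bases}\n+\n{qual}\n")
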