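# Methods

## Scope and model

`museomito` reconstructs a circular mitochondrial genome from short,
degraded, barcoded sequencing reads by mapping to candidate reference
mitogenomes and calling a thresholded consensus, then quantifies
between-genome divergence as an uncorrected p-distance with explicit
valid-position accounting. The package treats substitutions only:
consensus sequences are reference-projected (one output base per
reference position; insertions and deletions relative to the
reference are not called), and output FASTA headers carry that
caveat. De novo assembly is out of scope; the only assembly-side
operation provided is the collapse of tandem two-copy (concatemeric)
contigs, an artifact of assembling circular molecules.

## Synthetic-data generator

The generator emulates capture sequencing of archival specimens.
Defaults (all overridable in `SimulationConfig`):

| parameter | default | rationale |
|---|---|---|
| genome_length | 17,200 bp | typical frog mitogenome length |
| fragment_length_mean / sd | 90 / 20 bp | degraded-template fragment sizes |
| read_length | 75 bp | short paired-end reads; pairs from a ~90 bp fragment overlap heavily and merge |
| per_base_error_rate | 0.005 | elevated uniform error standing in for base damage |
| mean_depth | 20× | coverage giving a mostly callable genome at a 5× floor |
| duplicate_rate | 0.2 | PCR re-amplification fraction in low-input libraries |
| barcode_length | 6 bp | inline sample barcode at the 5' end of read 1 |

Taxon genomes derive from a common sequence by independent-site
uniform substitution (each site substituted with probability
`p_target`, new base uniform over the three alternatives — a
Jukes–Cantor-style move). Realized Hamming fractions are recorded in
the truth set, so calibration checks compare against the realized
value, not just the target. Fragments are drawn uniformly over the
circular genome (wrapping the origin when no missing region blocks
it) but only where they fit entirely outside configured dropout
intervals; dropout therefore produces genuinely uncoverable regions
and partial genomes. PCR duplicates re-emit a fragment with the same
coordinates but independent sequencing errors. Every read pair
carries a truth record `(taxon, start, end, strand, is_duplicate)`
with unwrapped 1-based coordinates.

Deliberately not modeled: ancient-DNA cytosine-deamination damage
profiles (no published profile for this material; the uniform error
rate stands in), capture-probe efficiency variation, indels, chimeric
fragments, and quality-score/error correlation. Passing tests
therefore show that the pipeline's logic and thresholds behave as
specified under realistic coverage, error, duplication and
missing-data structure — not that it is robust to damage-pattern or
indel pathologies of real archival libraries.

## Read preparation

Demultiplexing assigns a pair to a sample only on an exact match of
the inline barcode (the first L bases of read 1); one mismatch leaves
the pair unassigned, and the barcode is trimmed on assignment.
Pair merging reverse-complements read 2 and scans every overlap
length from `min_overlap` (default 11) upward; among overlaps with
mismatch fraction ≤ 0.1 it keeps the one with the most matching bases
(ties to the longer overlap). Disagreeing overlap positions take the
higher-quality base and the merged quality is the positionwise
maximum. The merge parameters are exposed because no authoritative
values exist for this protocol; 11/0.1 are conventional for
read-pair merging tools.
Deduplication keeps one read per `(reference, start, end, strand)`
key — the standard coordinate definition of a PCR duplicate for
merged single-end-like reads — preferring the highest base-quality
sum, ties to the first encountered, with stable output order.

## Mapping

SAM import is the fidelity path for externally mapped data (header
with @SQ; M/=/X consume reference and read, I is ignored for the
pileup, D/N advance the reference without adding a base, soft clips
trimmed; malformed records are skipped with a warning; unmapped
records omitted). The built-in mapper exists so the pipeline runs
without external aligners: exact 13-mer seeding on both strands,
ungapped scoring of candidate placements, best placement by match
count. Mapping quality is the score gap to the runner-up placement
(3 points per base of gap, capped at 60, 0 on a tie), so repeated
sequence yields MQ 0 and is removed by the MQ ≥ 25 filter.
Placements with more than 8% mismatching bases are rejected,
emulating the mismatch tolerance of short-read mappers on ~60–150 bp
reads. This cap is what produces reference bias in the synthetic
scenario: substitutions between sample and reference are spatially
i.i.d., so reads from windows that are locally more diverged than the
cap fail to map, coverage falls below the calling floor there, and
completeness decreases with reference divergence — while sites that
are called remain essentially unbiased, since the consensus base
comes from the reads, not the reference. The same mechanism makes
consensus-based divergence estimates slight underestimates: the
uncallable windows are the most diverged ones. Reads that wrap the
circular origin are split into two mapped segments sharing the read
id and mapping quality.

## Consensus calling

Pileups count one base per aligned reference position from
non-duplicate reads with MQ ≥ `min_mapq`; non-ACGT read characters
contribute nothing. A site is called with its modal base iff
filtered depth ≥ `min_depth` (default 5), the modal count is at least
`min_agreement` (default 0.8) of the filtered depth, and the mode is
unique; all thresholds are inclusive ("at least"). Everything else,
including never-covered sites, is N. Tied modes give N rather than
an IUPAC ambiguity code because the divergence stage treats ambiguity
as missing anyway. The agreement denominator is the filtered,
deduplicated depth: the quality filters are applied before the
consensus rule, matching the order in which the procedure is stated.
Overlapping unmerged mates double-count a site; merging first makes
this rare, and it is accepted rather than corrected. Completeness is
the fraction of reference positions with a non-N call; among
candidate references the one yielding the most complete consensus is
selected, ties broken by input order and logged.

## Concatemer collapse

For a contig suspected to contain two tandem copies of a circular
genome, candidate copy lengths within ±10% of half the contig length
are scanned; if splitting at the best candidate aligns the two copies
ungapped at ≥ 98% identity the first copy is returned (disagreements
between two copies are 1-vs-1 ties and resolve to the first copy),
otherwise the contig is unchanged.

## Divergence accounting

A column is valid for a pair iff both rows hold A, C, G or T
(case-insensitive, U≡T); gaps, N, ?, and IUPAC ambiguity codes are
missing. This strict validity set matches the consensus caller's
N-only output; treating ambiguity codes as half-matches is the first
toggle to try if reproduction of externally computed tables is off by
a few positions. Divergence is mismatches over valid positions, and
both counts are always reported, because partial genomes make the
denominator vary by orders of magnitude across pairs. Masking takes
regions in 1-based inclusive ungapped coordinates of a named anchor
row, maps them to alignment columns (interior gap columns included),
and removes the union. The neighbor-joining tree (via scikit-bio) is
a sanity check on distance structure, not an inference method;
likelihood or Bayesian phylogenetics is out of scope.

## Problem sizes and determinism

The test suite and the acceptance script run the full scenario at
study scale — 17.2 kb genomes, 20× coverage (~3,800 fragments),
three candidate references — which completes in seconds; unit tests
use 2–6 kb genomes. All randomness flows through explicit integer
seeds (numpy `default_rng`), so identical configuration and seed give
byte-identical FASTQ output and identical reports. One reproduction
check requires the deposited mitogenome alignment
(`data/s1_mitogenome_alignment.nex`, not distributable with the
package); it fails with instructions when the file is absent.

## Known limitations

- Uniform error and substitution models: no damage profiles, rate
  heterogeneity among sites, or indels.
- The built-in mapper is ungapped and exact-seeded; heavily diverged
  or indel-rich references need external mapping plus SAM import.
- The strict-ACGT validity rule can differ from tools that count
  compatible ambiguity overlaps as matches.
- Completeness differences between closely spaced reference
  divergences (e.g. 0.5% vs 4%) are small at 20×; at some seeds the
  two can tie to machine precision.
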