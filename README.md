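# museomito

Reference-guided mitochondrial genome reconstruction and uncorrected
divergence accounting for degraded (museum-specimen) sequencing data.

## The problem

Archival specimens — fluid-preserved frogs collected more than a
century ago, for instance — yield DNA that is short (fragment means
near 60–120 bp), error-prone, and incomplete. De novo assembly of a
mitogenome typically fails on such material, so the standard approach
is to map reads to candidate reference mitogenomes from related
species and call a conservative consensus. Two methodological
questions then dominate downstream taxonomy:

1. **Reference bias.** How much does the choice of reference genome
   shape the consensus? A distant reference loses reads wherever the
   sample diverges locally from it, so completeness drops — and the
   portions recovered are biased toward conserved regions.
2. **Divergence accounting.** Comparisons among partial genomes must
   state their denominator. The uncorrected pairwise divergence
   (p-distance) under pairwise deletion is

   p = m / v,

   where *v* counts alignment columns in which **both** sequences hold
   an unambiguous base (A/C/G/T; gaps, N, ? and IUPAC ambiguity codes
   are excluded) and *m* counts the mismatching columns among them.
   `museomito` always reports *m* and *v* alongside *p*.

The package implements the full chain: exact-barcode demultiplexing,
overlap merging of read pairs, mapping (built-in k-mer mapper or SAM
import), coordinate-based deduplication, pileup consensus calling
under inclusive thresholds (depth ≥ 5, modal-base agreement ≥ 80%,
mapping quality ≥ 25), reference selection by consensus completeness,
tandem-concatemer collapse for circular assemblies, alignment masking
by anchor-sequence coordinates, pairwise-deletion p-distances, and a
neighbor-joining sanity tree. A synthetic-data generator with exact
truth files makes every stage testable without external data.

## Worked example

Simulate a degraded museum sample (17.2 kb circular mitogenome, 20×
coverage, 0.5% per-base error, 20% PCR duplicates, a 1 kb dropout
region) whose true genome is 4% diverged from a second taxon, then
reconstruct it against candidate references at 0.5%, 4% and 8%
divergence:

```bash
museomito run --out runs/demo --seed 2
```

Key fields of the printed JSON report (seed 2):

```
"completeness": {"ref_0.5pct": 0.9341, "ref_4pct": 0.9298, "ref_8pct": 0.6405}
"selected_reference": "ref_0.5pct"
"consensus_accuracy": 1.0
"estimated_divergence": {"ref_4pct": 0.03845, ...}
"true_divergence_from_ancestor": 0.03901
```

Reading this: consensus completeness falls as the reference diverges
from the sample (93.4% → 93.0% → 64.0%) — the reference-bias effect —
and the closest reference is selected. At called sites the consensus
matches the true sample genome (accuracy 1.0), and the pairwise
divergence estimated from the consensus against the 4% reference
(3.85%) recovers the realized truth (3.90%) well within one binomial
standard error. The divergence is a slight underestimate: reads from
the most locally diverged windows are the ones that fail to map, so
the called portion of the genome is biased toward conserved regions.

Alignment-side tools work on NEXUS or FASTA alignments:

```bash
museomito pdist --aln alignment.nex --mask regions.tsv --out pairs.tsv
museomito njtree --aln alignment.nex
```

where `regions.tsv` lists ambiguous-homology regions as
`anchor<TAB>start<TAB>end` in 1-based ungapped coordinates of the
anchor sequence.

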