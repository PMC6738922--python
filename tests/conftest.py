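"""Shared fixtures: small deterministic genomes and one full-scale
simulated degraded-specimen dataset reused by the end-to-end tests."""

from __future__ import annotations

import pytest

from museomito.readprep import demultiplex, merge_pairs
from museomito.simgen import evolve, generate_reads, simulate_genome
from museomito.types import SampleManifest, SequencingRead, SimulationConfig

BARCODE = "ACGTAC"


@pytest.fixture(scope="session")
def small_genome() -> str:
    return simulate_genome(2000, seed=11)


@pytest.fixture(scope="session")
def study_scale_dataset():
    """Full study-scale scenario: two 17.2 kb taxa at 4% divergence,
    20x coverage, 0.5% per-base error, 20% duplicates, one 1 kb
    dropout region; plus candidate references at 0.5%/4%/8% divergence
    from the sample's true genome (the 4% candidate is the second taxon)."""
    cfg = SimulationConfig(
        genome_length=17200,
        divergence_targets=[0.04],
        mean_depth=20.0,
        per_base_error_rate=0.005,
        duplicate_rate=0.2,
        dropout_regions=[(3000, 3999)],
        rng_seed=101,
    )
    other_taxon = simulate_genome(cfg.genome_length, seed=101)
    sample_genome = evolve(other_taxon, 0.04, seed=201)
    pairs, truth = generate_reads(
        sample_genome, cfg, BARCODE, taxon="museum_sample", seed=118
    )
    references = {
        "ref_near": evolve(sample_genome, 0.005, seed=301),
        "ref_mid": other_taxon,  # the second taxon, ~4% diverged
        "ref_far": evolve(sample_genome, 0.08, seed=303),
    }
    return {
        "config": cfg,
        "sample_genome": sample_genome,
        "other_taxon": other_taxon,
        "pairs": pairs,
        "truth": truth,
        "references": references,
    }


@pytest.fixture(scope="session")
def merged_study_reads(study_scale_dataset) -> list[SequencingRead]:
    manifest = SampleManifest([("museum_sample", BARCODE)])
    demux = demultiplex(study_scale_dataset["pairs"], manifest)
    merged: list[SequencingRead] = []
    for pair in demux.assigned["museum_sample"]:
        m = merge_pairs(pair)
        if isinstance(m, SequencingRead):
            merged.append(m)
        else:
            merged.extend(m)
    return merged
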