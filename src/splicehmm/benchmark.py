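"""Desk-scale simulation benchmark: one call from seed to evaluated run.

The standard benchmark plants 100 non-overlapping multi-exon transcripts on
a 1 Mb balanced random genome and samples 50 bp reads at the requested
coverage.  Intron lengths are bounded well inside the configured search
window (max intron 1 kb, anchor 6 nt -- the compact-genome parameter set),
so the measured sensitivity/false-positive rates reflect the algorithm, not
window truncation.  All randomness derives from the single seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import Genome, Read
from .pipeline import PipelineConfig, PipelineResult, run_pipeline
from .simulate import (
    TranscriptModel,
    TruthJunction,
    evaluate_junctions,
    make_genome,
    make_transcripts,
    simulate_reads,
)


@dataclass
class BenchmarkData:
    genome: Genome
    transcripts: list[TranscriptModel]
    truth: list[TruthJunction]
    reads: list[Read]


def benchmark_config(seed: int = 0) -> PipelineConfig:
    """Pipeline parameters for the synthetic benchmark (compact-genome set)."""
    return PipelineConfig(min_intron=10, max_intron=1000, anchor_size=6, seed=seed)


def make_benchmark(
    seed: int,
    coverage: float,
    genome_length: int = 1_000_000,
    n_transcripts: int = 100,
    read_length: int = 50,
    gc: float = 0.5,
    error_free: bool = False,
) -> BenchmarkData:
    """Generate the benchmark dataset; the genome depends only on the seed,
    so runs at different coverages share genome and truth table."""
    gseed, tseed, rseed = (int(x) for x in
                           np.random.SeedSequence(seed).generate_state(3) % (2**31))
    genome = make_genome(genome_length, gc=gc, seed=gseed)
    genome, transcripts, truth = make_transcripts(
        genome,
        n_transcripts,
        intron_length=(60, 500),
        seed=tseed,
    )
    reads = simulate_reads(
        genome, transcripts, read_length=read_length, coverage=coverage,
        error_free=error_free, seed=rseed + int(coverage * 1000) % 1000,
    )
    return BenchmarkData(genome, transcripts, truth, reads)


def run_benchmark(seed: int, coverage: float, **kwargs) -> tuple[PipelineResult, BenchmarkData]:
    data = make_benchmark(seed, coverage, **kwargs)
    result = run_pipeline(data.reads, data.genome, benchmark_config(seed))
    return result, data


def benchmark_sensitivity(result: PipelineResult, data: BenchmarkData):
    """Evaluate the filtered (canonical + non-canonical) output vs truth."""
    predicted = result.canonical + result.noncanonical
    return evaluate_junctions(predicted, data.truth)
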