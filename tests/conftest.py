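"""Shared fixtures: seed-pinned simulated runs reused across test modules."""

from __future__ import annotations

from dataclasses import dataclass

import pytest

from bsvalid.methylation import build_report
from bsvalid.pipeline import PipelineConfig, run_pipeline
from bsvalid.simulate import (
    SimConfig,
    assign_methylation,
    evaluate_mapping,
    simulate_genome,
    simulate_reads,
)


@dataclass
class SimRun:
    config: SimConfig
    genome: object
    states: dict
    reads: list
    truths: list
    results: list  # list of (ReadRecord, FinalVerdict)

    @property
    def verdicts(self):
        return [v for _, v in self.results]

    def stats(self, tolerance: int = 0):
        return evaluate_mapping(self.verdicts, self.truths, tolerance)


def _run(sim_cfg: SimConfig, pipe_cfg: PipelineConfig) -> SimRun:
    genome = simulate_genome(sim_cfg.genome_length, sim_cfg.gc_fraction, sim_cfg.seed)
    states = assign_methylation(
        genome, sim_cfg.level_cpg, sim_cfg.level_chg, sim_cfg.level_chh, sim_cfg.seed + 1
    )
    reads, truths = simulate_reads(genome, states, sim_cfg)
    results = run_pipeline(reads, genome, config=pipe_cfg)
    return SimRun(sim_cfg, genome, states, reads, truths, results)


@pytest.fixture(scope="session")
def clean_run() -> SimRun:
    """2,000 directional 75 bp reads from a 50 kb genome, no conversion
    failure, no sequencing error."""
    cfg = SimConfig(seed=11, conversion_failure=0.0, error_rate_start=0.0,
                    error_rate_end=0.0)
    return _run(cfg, PipelineConfig(mode="directional"))


@pytest.fixture(scope="session")
def noisy_run() -> SimRun:
    """Same genome with 1% conversion failure and 0.1%->0.6% per-cycle error."""
    cfg = SimConfig(seed=11)
    return _run(cfg, PipelineConfig(mode="directional"))


@pytest.fixture(scope="session")
def noisy_run_tier1_only(noisy_run) -> SimRun:
    """The noisy read set realigned with the permissive tier disabled."""
    cfg = noisy_run.config
    results = run_pipeline(
        noisy_run.reads,
        noisy_run.genome,
        config=PipelineConfig(mode="directional", permissive=None),
    )
    return SimRun(cfg, noisy_run.genome, noisy_run.states, noisy_run.reads,
                  noisy_run.truths, results)


@pytest.fixture(scope="session")
def meth_run():
    """20x coverage of a 40 kb genome at planted CpG level 0.7, conversion
    failure 1%, no sequencing error; returns (SimRun, MethylationReport)."""
    glen = 40_000
    cfg = SimConfig(
        genome_length=glen,
        n_reads=int(round(20 * glen / 75)),
        seed=5,
        conversion_failure=0.01,
        error_rate_start=0.0,
        error_rate_end=0.0,
    )
    run = _run(cfg, PipelineConfig(mode="directional"))
    report = build_report(run.verdicts, run.genome)
    return run, report
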