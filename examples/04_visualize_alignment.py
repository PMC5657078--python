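"""Render a color-coded alignment view in the terminal.

Maps one simulated read and prints the stacked reference / match-bar /
read block.  In the default alignment view, mismatches and gaps are blue
and methylated bases red; the plain markup used here wraps each styled
base in brackets with its column code (e.g. ``[CM]`` is a methylated C),
which is what the ANSI and HTML markups color.
"""

from bsvalid import PipelineConfig, SimConfig, run_pipeline
from bsvalid.simulate import assign_methylation, simulate_genome, simulate_reads
from bsvalid.visualize import ALIGNMENT_VIEW, render_read_report, strip_markup

cfg = SimConfig(genome_length=5_000, n_reads=3, seed=2, conversion_failure=0.0,
                error_rate_start=0.01, error_rate_end=0.01)
genome = simulate_genome(cfg.genome_length, cfg.gc_fraction, cfg.seed)
states = assign_methylation(genome, 0.7, 0.02, 0.02, cfg.seed + 1)
reads, _ = simulate_reads(genome, states, cfg)
results = run_pipeline(reads, genome, config=PipelineConfig(mode="directional"))

read, verdict = results[0]
print(render_read_report(verdict, read, genome, ALIGNMENT_VIEW, width=60,
                         markup="plain"))
print("stripped to plain text:")
print(strip_markup(render_read_report(verdict, read, genome, ALIGNMENT_VIEW,
                                      width=60, markup="plain")))
# '|' bars mark exact non-cytosine matches; unmarked columns are
# methylation calls (M/U), excused SNPs or styled mismatches/gaps.
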