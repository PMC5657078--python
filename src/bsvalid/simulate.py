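"""Bisulfite read simulation and mapping evaluation.

The simulator emulates an Illumina-like whole-genome bisulfite
experiment: a random genome, per-cytosine methylation states drawn
independently with per-context probabilities (both strands), fragments
sampled uniformly, bisulfite conversion of unmethylated cytosines with a
configurable failure probability (a failed conversion retains the C but
is recorded as *unmethylated* in the truth — it is a chemistry artifact,
not biology), and per-cycle substitution errors whose rate interpolates
linearly from the first to the last cycle.

Mapping results are scored with two headline statistics: mappability
(fraction of reads uniquely mapped) and correct mappability (fraction of
reads whose unique mapping is at the true locus, on the same original
strand, within a start-position tolerance).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np

from .conversion import ORIGINAL_STRAND, revcomp
from .methylation import cytosine_context
from .postprocess import FinalVerdict
from .seqio import Genome, ReadRecord

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass
class SimConfig:
    """Study conditions for one simulated run.

    Defaults describe a directional 75 bp single-end Illumina-like run at
    1% bisulfite conversion failure with per-cycle error rising linearly
    from 0.1% to 0.6%, on a 50 kb uniform-GC genome; methylation levels
    default to 0.7 (CpG) and 0.02 (CHG/CHH), typical of mammalian somatic
    tissue.
    """

    genome_length: int = 50_000
    gc_fraction: float = 0.5
    n_reads: int = 2_000
    read_length: int = 75
    paired: bool = False
    insert_mean: float = 250.0
    insert_sd: float = 30.0
    level_cpg: float = 0.7
    level_chg: float = 0.02
    level_chh: float = 0.02
    conversion_failure: float = 0.01
    error_rate_start: float = 0.001
    error_rate_end: float = 0.006
    directional: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "gc_fraction",
            "level_cpg",
            "level_chg",
            "level_chh",
            "conversion_failure",
            "error_rate_start",
            "error_rate_end",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.read_length > self.genome_length:
            raise ValueError("read_length exceeds genome_length")


@dataclass
class TruthRecord:
    """Ground truth for one simulated read."""

    read_id: str
    contig: str
    start: int
    strand_task: str
    methylated_positions: set[int] = field(default_factory=set)


@dataclass
class MappingStats:
    n_reads: int
    n_unique: int
    n_unique_correct: int

    @property
    def mappability(self) -> float:
        return self.n_unique / self.n_reads if self.n_reads else 0.0

    @property
    def correct_mappability(self) -> float:
        return self.n_unique_correct / self.n_reads if self.n_reads else 0.0

    @property
    def precision(self) -> float:
        """Fraction of unique mappings that are correct."""
        return self.n_unique_correct / self.n_unique if self.n_unique else 0.0

    def summary(self) -> str:
        return (
            f"reads\t{self.n_reads}\n"
            f"unique\t{self.n_unique}\n"
            f"unique_correct\t{self.n_unique_correct}\n"
            f"mappability\t{100 * self.mappability:.2f}%\n"
            f"correct_mappability\t{100 * self.correct_mappability:.2f}%\n"
        )


def simulate_genome(
    length: int, gc_fraction: float = 0.5, seed: int = 0, name: str = "sim1"
) -> Genome:
    """I.i.d. random genome with P(G)=P(C)=gc/2 and P(A)=P(T)=(1-gc)/2."""
    if length < 1:
        raise ValueError("genome length must be >= 1")
    rng = np.random.default_rng(seed)
    p_at = (1.0 - gc_fraction) / 2.0
    p_gc = gc_fraction / 2.0
    draws = rng.choice(_BASES, size=length, p=[p_at, p_gc, p_gc, p_at])
    return Genome({name: draws.tobytes().decode("ascii")})


MethylationStates = dict[tuple[str, int, str], bool]


def assign_methylation(
    genome: Genome,
    level_cpg: float = 0.7,
    level_chg: float = 0.02,
    level_chh: float = 0.02,
    seed: int = 0,
) -> MethylationStates:
    """Independently methylate every cytosine on both strands with its
    context's probability.  Keys are (contig, position, strand); only
    methylated cytosines are stored (missing means unmethylated)."""
    rng = np.random.default_rng(seed)
    levels = {"CpG": level_cpg, "CHG": level_chg, "CHH": level_chh}
    states: MethylationStates = {}
    for name, seq in genome.contigs.items():
        for pos, base in enumerate(seq):
            if base == "C":
                if rng.random() < levels[cytosine_context(seq, pos, "+")]:
                    states[(name, pos, "+")] = True
            elif base == "G":
                if rng.random() < levels[cytosine_context(seq, pos, "-")]:
                    states[(name, pos, "-")] = True
    return states


def _bisulfite_convert(
    fragment: str,
    contig: str,
    start: int,
    strand: str,
    states: MethylationStates,
    failure: float,
    rng: np.random.Generator,
) -> tuple[str, set[int]]:
    """Convert one physical-strand fragment; returns (sequence, offsets of
    methylated cytosines).  ``fragment`` is the strand's 5'->3' sequence;
    for the - strand, offset j corresponds to reference position
    ``start + len - 1 - j``."""
    L = len(fragment)
    out = list(fragment)
    methylated: set[int] = set()
    for j, base in enumerate(fragment):
        if base != "C":
            continue
        ref_pos = start + j if strand == "+" else start + L - 1 - j
        if states.get((contig, ref_pos, strand), False):
            methylated.add(j)  # methylated C survives bisulfite
        elif failure > 0.0 and rng.random() < failure:
            pass  # conversion failure: C retained but NOT methylated
        else:
            out[j] = "T"
    return "".join(out), methylated


def _apply_cycle_errors(
    seq: str, rate_start: float, rate_end: float, rng: np.random.Generator
) -> str:
    if rate_start == 0.0 and rate_end == 0.0:
        return seq
    L = len(seq)
    rates = np.linspace(rate_start, rate_end, L)
    hits = np.nonzero(rng.random(L) < rates)[0]
    if hits.size == 0:
        return seq
    out = list(seq)
    for j in hits:
        choices = [b for b in "ACGT" if b != out[j]]
        out[j] = choices[rng.integers(0, 3)]
    return "".join(out)


def _make_read(
    genome: Genome,
    states: MethylationStates,
    config: SimConfig,
    contig: str,
    start: int,
    task: str,
    rng: np.random.Generator,
) -> tuple[str, set[int]]:
    """Generate one read of ``config.read_length`` for a fragment whose
    leftmost reference coordinate is ``start``.  Returns (sequence,
    methylated read offsets in final read orientation)."""
    L = config.read_length
    watson = genome.contigs[contig][start : start + L]
    strand = ORIGINAL_STRAND[task]
    physical = watson if strand == "+" else revcomp(watson)
    bs, meth = _bisulfite_convert(
        physical, contig, start, strand, states, config.conversion_failure, rng
    )
    if task in ("CTOT", "CTOB"):  # PCR complement of the bisulfite strand
        bs = revcomp(bs)
        meth = {L - 1 - j for j in meth}
    seq = _apply_cycle_errors(bs, config.error_rate_start, config.error_rate_end, rng)
    return seq, meth


def simulate_reads(
    genome: Genome, states: MethylationStates, config: SimConfig
) -> tuple[list[ReadRecord], list[TruthRecord]]:
    """Simulate a read set with its ground truth.

    Single-end mode draws a uniform locus and strand task per read
    (OT/OB only when directional).  Paired mode draws an insert length
    from a truncated normal and emits mate 0 from the fragment's left,
    forward-aligning task and mate 1 from the right, reverse-aligning
    task ({OT,OB} fragments in directional mode, plus {CTOB,CTOT} in
    non-directional mode).  Output is fully determined by ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    contigs = list(genome.contigs)
    lengths = np.array([len(genome.contigs[c]) for c in contigs], dtype=float)
    weights = lengths / lengths.sum()
    L = config.read_length
    reads: list[ReadRecord] = []
    truths: list[TruthRecord] = []

    for i in range(config.n_reads):
        contig = contigs[rng.choice(len(contigs), p=weights)]
        clen = len(genome.contigs[contig])
        if not config.paired:
            task = ("OT", "OB")[rng.integers(0, 2)] if config.directional else (
                "OT",
                "OB",
                "CTOT",
                "CTOB",
            )[rng.integers(0, 4)]
            start = int(rng.integers(0, clen - L + 1))
            seq, meth = _make_read(genome, states, config, contig, start, task, rng)
            rid = f"r{i}"
            reads.append(ReadRecord(rid, seq, "I" * L))
            truths.append(TruthRecord(rid, contig, start, task, meth))
            continue
        # paired: fragment [p, p+insert); mate0 left/forward, mate1 right/reverse
        insert = 0
        for _ in range(100):
            insert = int(round(rng.normal(config.insert_mean, config.insert_sd)))
            if L <= insert <= clen:
                break
        else:
            raise RuntimeError("could not sample a feasible insert length")
        p = int(rng.integers(0, clen - insert + 1))
        combo = ("OT", "OB") if config.directional or rng.integers(0, 2) == 0 else (
            "CTOB",
            "CTOT",
        )
        fwd_task, rev_task = combo
        rid = f"r{i}"
        s0, m0 = _make_read(genome, states, config, contig, p, fwd_task, rng)
        s1, m1 = _make_read(
            genome, states, config, contig, p + insert - L, rev_task, rng
        )
        reads.append(ReadRecord(rid, s0, "I" * L, mate=0))
        reads.append(ReadRecord(rid, s1, "I" * L, mate=1))
        truths.append(TruthRecord(f"{rid}/1", contig, p, fwd_task, m0))
        truths.append(TruthRecord(f"{rid}/2", contig, p + insert - L, rev_task, m1))
    return reads, truths


def write_truth_tsv(truths: Iterable[TruthRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\tcontig\tstart\ttask\tmethylated_offsets\n")
        for t in truths:
            offs = ",".join(str(o) for o in sorted(t.methylated_positions))
            fh.write(f"{t.read_id}\t{t.contig}\t{t.start}\t{t.strand_task}\t{offs}\n")


def read_truth_tsv(path) -> list[TruthRecord]:
    truths = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("read_id\t"):
            raise ValueError(f"{path}: not a truth TSV")
        for line in fh:
            rid, contig, start, task, offs = line.rstrip("\n").split("\t")
            meth = {int(o) for o in offs.split(",")} if offs else set()
            truths.append(TruthRecord(rid, contig, int(start), task, meth))
    return truths


def evaluate_mapping(
    verdicts: Iterable[FinalVerdict],
    truths: Iterable[TruthRecord],
    tolerance: int = 0,
) -> MappingStats:
    """Score verdicts against ground truth.

    A unique verdict is correct when the contig matches, the reported
    start is within ``tolerance`` bases of the true start, and the
    reported original strand equals the truth task's strand.
    """
    truth_by_id = {t.read_id: t for t in truths}
    n_unique = n_correct = 0
    for v in verdicts:
        truth = truth_by_id.get(v.read_id)
        if truth is None:
            raise ValueError(f"verdict for unknown read {v.read_id!r}")
        if v.status != "unique" or v.alignment is None:
            continue
        n_unique += 1
        cand = v.alignment.candidate
        if (
            cand.contig == truth.contig
            and abs(cand.start - truth.start) <= tolerance
            and ORIGINAL_STRAND[cand.task] == ORIGINAL_STRAND[truth.strand_task]
        ):
            n_correct += 1
    return MappingStats(
        n_reads=len(truth_by_id), n_unique=n_unique, n_unique_correct=n_correct
    )
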