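"""Chemistry validation, SNP-tolerant filtering and per-read resolution.

Three-letter alignment is deliberately blind to C/T (or G/A) differences,
so it accepts placements the bisulfite chemistry forbids: conversion only
ever turns C into T, never T into C.  Every candidate is therefore
re-walked over the *original* read and reference, each column classified,
impossible matches flagged, and the surviving candidates merged and
deduplicated into one verdict per read.

Column codes:

* ``.`` — non-cytosine match
* ``M`` — methylated call (reference C, read C, in the task's space)
* ``U`` — unmethylated call (reference C, read T)
* ``x`` — ordinary mismatch (also used for inserted read bases)
* ``X`` — bisulfite-invalid match (reference T under a read C)
* ``S`` — mismatch excused by a known SNP whose alt allele explains the
  observed base

For tasks aligned against the G->A reference copy the mirrored rules
apply (reference G/read G is methylated, reference A under read G is
invalid).  Codes are stored in read orientation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

from .aligner import CandidateAlignment
from .conversion import ORIGINAL_STRAND, STRAND_TASKS, revcomp
from .seqio import Genome, ReadRecord, SNPSet, cigar_ops

#: Per-column contributions to the validated score, plus gap penalties
#: taken from the CIGAR (open 5, extend 3, matching the aligner).  The
#: bisulfite-invalid penalty is deliberately much heavier than an
#: ordinary mismatch so chemistry-violating placements lose ties even
#: when they are tolerated by a relaxed filter.
CODE_SCORES = {".": 1, "M": 1, "U": 1, "S": 1, "x": -2, "X": -8}
GAP_OPEN = 5
GAP_EXTEND = 3


@dataclass
class ClassifiedAlignment:
    """A candidate re-evaluated on the original sequences."""

    candidate: CandidateAlignment
    codes: str
    n_invalid: int
    n_mismatch: int
    n_snp_excused: int
    valid_score: int


@dataclass
class FinalVerdict:
    """The per-read outcome after filtering, merging and deduplication."""

    read_id: str
    status: str  # "unique" | "ambiguous" | "unmapped"
    alignment: Optional[ClassifiedAlignment] = None
    alternates: list[ClassifiedAlignment] = field(default_factory=list)
    reason: Optional[str] = None


def _classify_column(ref_base: str, read_base: str, space: str) -> str:
    if space == "CT":
        if ref_base == "C":
            if read_base == "C":
                return "M"
            if read_base == "T":
                return "U"
            return "x"
        if ref_base == "T" and read_base == "C":
            return "X"
    else:  # GA space
        if ref_base == "G":
            if read_base == "G":
                return "M"
            if read_base == "A":
                return "U"
            return "x"
        if ref_base == "A" and read_base == "G":
            return "X"
    if ref_base == read_base and ref_base != "N":
        return "."
    return "x"


def classify_alignment(
    cand: CandidateAlignment,
    read: ReadRecord,
    genome: Genome,
    snps: Optional[SNPSet] = None,
) -> ClassifiedAlignment:
    """Walk a candidate's edit path over the original read and reference.

    For reverse-orientation tasks the read is placed in reference
    orientation before walking; the resulting code string is flipped back
    so ``codes[i]`` always describes ``read.seq[i]``.  Mismatches (and
    invalid matches) are downgraded to ``S`` when the SNP set contains an
    entry whose alt allele equals the observed reference-oriented base.
    """
    task = STRAND_TASKS[cand.task]
    oriented = revcomp(read.seq) if task.orientation == "reverse" else read.seq
    ref = genome.contigs[cand.contig]
    space = task.ref_space

    codes: list[str] = []
    score = 0
    i, p = 0, cand.start
    for length, op in cigar_ops(cand.cigar):
        if op == "M":
            for _ in range(length):
                code = _classify_column(ref[p], oriented[i], space)
                if code in "xX" and snps is not None and oriented[i] in "ACGT":
                    if (cand.contig, p, ref[p], oriented[i]) in snps:
                        code = "S"
                codes.append(code)
                i += 1
                p += 1
        elif op == "I":
            codes.extend("x" * length)
            i += length
            score -= GAP_OPEN + GAP_EXTEND * (length - 1)
        elif op == "D":
            p += length
            score -= GAP_OPEN + GAP_EXTEND * (length - 1)
        else:
            raise ValueError(f"unsupported CIGAR op {op!r} in {cand.cigar!r}")
    if i != len(oriented) or p != cand.start + cand.ref_span():
        raise RuntimeError(
            f"edit path {cand.cigar!r} inconsistent with read/reference lengths"
        )
    score += sum(CODE_SCORES[c] for c in codes)
    if task.orientation == "reverse":
        codes.reverse()
    code_str = "".join(codes)
    return ClassifiedAlignment(
        candidate=cand,
        codes=code_str,
        n_invalid=code_str.count("X"),
        n_mismatch=code_str.count("x"),
        n_snp_excused=code_str.count("S"),
        valid_score=score,
    )


def filter_alignment(
    ca: ClassifiedAlignment, max_invalid: int = 0, max_mismatch: int = 3
) -> tuple[bool, Optional[str]]:
    """Apply the bisulfite-invalid and mismatch budgets.

    Returns ``(kept, reason)`` where ``reason`` is ``None`` when kept,
    else ``"bisulfite-invalid"`` or ``"mismatch-budget"``.
    """
    if ca.n_invalid > max_invalid:
        return False, "bisulfite-invalid"
    if ca.n_mismatch > max_mismatch:
        return False, "mismatch-budget"
    return True, None


def resolve_read(
    cands: list[ClassifiedAlignment], min_score_gap: int = 0
) -> FinalVerdict:
    """Merge tiers and deduplicate the surviving candidates of one read.

    Candidates at the same ``(contig, start, original strand)`` are
    duplicates; the highest-scoring one is kept.  The verdict is unique
    iff a single deduplicated candidate attains the maximal validated
    score (by at least ``min_score_gap`` over the runner-up); equal-best
    candidates at distinct loci make the read ambiguous.
    """
    if not cands:
        return FinalVerdict(read_id="", status="unmapped", reason="no-candidate")
    read_ids = {c.candidate.read_id for c in cands}
    if len(read_ids) != 1:
        raise RuntimeError(f"resolve_read got candidates from several reads: {read_ids}")
    read_id = read_ids.pop()

    best_at: dict[tuple[str, int, str], ClassifiedAlignment] = {}
    for ca in cands:
        key = (
            ca.candidate.contig,
            ca.candidate.start,
            ORIGINAL_STRAND[ca.candidate.task],
        )
        prev = best_at.get(key)
        if prev is None or (ca.valid_score, -ca.candidate.tier, ca.candidate.task) > (
            prev.valid_score,
            -prev.candidate.tier,
            prev.candidate.task,
        ):
            best_at[key] = ca
    survivors = sorted(
        best_at.values(),
        key=lambda c: (
            -c.valid_score,
            c.candidate.contig,
            c.candidate.start,
            c.candidate.task,
        ),
    )
    best = survivors[0].valid_score
    winners = [c for c in survivors if c.valid_score == best]
    if len(winners) == 1 and (
        len(survivors) == 1 or best - survivors[1].valid_score >= min_score_gap
    ):
        return FinalVerdict(read_id=read_id, status="unique", alignment=winners[0])
    return FinalVerdict(
        read_id=read_id,
        status="ambiguous",
        alignment=winners[0],
        alternates=winners,
        reason="tied-best-loci",
    )


def write_audit_tsv(rows: Iterable[tuple], path) -> None:
    """Write the per-read audit log: read_id, status, reason, n_invalid,
    n_mismatch, n_snp_excused."""
    with open(path, "w") as fh:
        fh.write("read_id\tstatus\treason\tn_invalid\tn_mismatch\tn_snp_excused\n")
        for row in rows:
            fh.write("\t".join("" if v is None else str(v) for v in row) + "\n")
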