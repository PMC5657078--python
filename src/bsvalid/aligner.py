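"""Seed-and-extend read mapping in converted (three-letter) space.

Two parameter tiers mirror the strict-then-permissive strategy: a strict
end-to-end tier maps the bulk of reads with long seeds and a tight
mismatch budget, and a permissive tier with shorter seeds and gapped
extension is applied only to the reads the strict tier leaves unmapped.

Scoring in converted space: match +1, mismatch -2, gap open -5, gap
extend -3 (a gap of length g costs ``open + extend*(g-1)``).  A candidate
is kept when its score is at least the floor implied by the tier's
mismatch budget, i.e. the score of an ungapped placement with exactly
``max_mismatches_converted`` mismatches.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional

from .conversion import (
    ALL_TASKS,
    DIRECTIONAL_TASKS,
    ConvertedReference,
    STRAND_TASKS,
    convert_read,
    revcomp,
)
from .seqio import ReadRecord, cigar_ref_span

log = logging.getLogger("bsvalid")


@dataclass(frozen=True)
class AlignParams:
    k: int = 20
    max_mismatches_converted: int = 2
    allow_gaps: bool = False
    gap_open: int = 5
    gap_extend: int = 3
    mismatch_penalty: int = 2
    match_reward: int = 1
    band: int = 8
    max_candidates_per_read: int = 10

    def __post_init__(self) -> None:
        if self.k < 8:
            raise ValueError("seed length k must be >= 8")
        if min(self.gap_open, self.gap_extend, self.mismatch_penalty) < 0:
            raise ValueError("penalties must be non-negative")

    def score_floor(self, read_len: int) -> int:
        mm = self.max_mismatches_converted
        return (read_len - mm) * self.match_reward - mm * self.mismatch_penalty


#: Strict tier: long seeds, end-to-end, small mismatch budget.
STRICT = AlignParams(k=20, max_mismatches_converted=2, allow_gaps=False)
#: Permissive tier: short seeds, gapped extension, larger budget.
PERMISSIVE = AlignParams(k=12, max_mismatches_converted=5, allow_gaps=True)


@dataclass
class KmerIndex:
    """Exact k-mer lookup table over one converted reference copy.

    k-mers containing N are never stored, so N positions can seed nothing.
    """

    k: int
    table: dict[str, list[tuple[str, int]]] = field(default_factory=dict)


@dataclass
class CandidateAlignment:
    """A hit in converted space, in original (forward) reference coordinates."""

    read_id: str
    task: str
    contig: str
    start: int
    cigar: str
    conv_score: int
    tier: int = 1

    def ref_span(self) -> int:
        return cigar_ref_span(self.cigar)


def build_index(conv_ref: ConvertedReference, k: int) -> None:
    """Fill ``conv_ref.indexes[(space, k)]`` for both converted copies."""
    if not conv_ref.original.contigs:
        raise ValueError("cannot index an empty genome")
    shortest = min(len(s) for s in conv_ref.original.contigs.values())
    if k > shortest:
        raise ValueError(f"k={k} exceeds shortest contig length {shortest}")
    for space in ("CT", "GA"):
        if (space, k) in conv_ref.indexes:
            continue
        table: dict[str, list[tuple[str, int]]] = {}
        for name, seq in conv_ref.space(space).contigs.items():
            for off in range(len(seq) - k + 1):
                kmer = seq[off : off + k]
                if "N" in kmer:
                    continue
                table.setdefault(kmer, []).append((name, off))
        conv_ref.indexes[(space, k)] = KmerIndex(k=k, table=table)


def seed_offsets(read_len: int, k: int) -> list[int]:
    """Non-overlapping seeds at stride k from offset 0, plus one flush
    with the read end.  Guarantees a clean seed whenever the mismatch
    count is below ``floor(read_len / k)``."""
    offs = list(range(0, read_len - k + 1, k))
    last = read_len - k
    if last >= 0 and last not in offs:
        offs.append(last)
    return offs


def _count_mismatches(read: str, ref: str, limit: int) -> int:
    mm = 0
    for a, b in zip(read, ref):
        if a != b or a == "N":
            mm += 1
            if mm > limit:
                return mm
    return mm


def seed_and_extend(
    conv_read: str,
    space: str,
    orientation: str,
    conv_ref: ConvertedReference,
    params: AlignParams,
) -> list[CandidateAlignment]:
    """Map one converted read string against one converted reference copy.

    ``orientation="reverse"`` reverse-complements the read before seeding;
    coordinates are always reported against the forward reference.  Returns
    candidates sorted by (score desc, contig, start), capped at
    ``params.max_candidates_per_read``.
    """
    s = revcomp(conv_read) if orientation == "reverse" else conv_read
    L = len(s)
    if L < params.k:
        log.warning("read of length %d shorter than seed length %d", L, params.k)
        return []
    index = conv_ref.indexes.get((space, params.k))
    if index is None:
        raise RuntimeError(f"index for space {space} k={params.k} not built")
    ref_genome = conv_ref.space(space)

    diagonals: set[tuple[str, int]] = set()
    for off in seed_offsets(L, params.k):
        kmer = s[off : off + params.k]
        if "N" in kmer:
            continue
        for contig, hit in index.table.get(kmer, ()):
            diagonals.add((contig, hit - off))

    floor = params.score_floor(L)
    seen: set[tuple[str, int, str]] = set()
    cands: list[CandidateAlignment] = []
    for contig, start in sorted(diagonals):
        ref = ref_genome.contigs[contig]
        if not params.allow_gaps:
            if start < 0 or start + L > len(ref):
                continue
            mm = _count_mismatches(s, ref[start : start + L], params.max_mismatches_converted)
            if mm > params.max_mismatches_converted:
                continue
            score = (L - mm) * params.match_reward - mm * params.mismatch_penalty
            key = (contig, start, f"{L}M")
            if key in seen:
                continue
            seen.add(key)
            cands.append(
                CandidateAlignment("", "", contig, start, f"{L}M", score)
            )
        else:
            win_start = max(0, start - params.band)
            win_end = min(len(ref), start + L + params.band)
            if win_end - win_start < L:
                continue
            score, cigar, ref_begin = _fit_align(s, ref[win_start:win_end], params)
            if score < floor:
                continue
            key = (contig, win_start + ref_begin, cigar)
            if key in seen:
                continue
            seen.add(key)
            cands.append(
                CandidateAlignment("", "", contig, win_start + ref_begin, cigar, score)
            )
    cands.sort(key=lambda c: (-c.conv_score, c.contig, c.start))
    return cands[: params.max_candidates_per_read]


def _fit_align(read: str, window: str, params: AlignParams) -> tuple[int, str, int]:
    """Glocal alignment: the read is consumed end-to-end, the reference
    window is free at both ends.  Affine gaps (open + extend*(g-1)).
    Returns (score, cigar over {M,I,D}, 0-based window offset of the
    leftmost aligned reference base)."""
    L, W = len(read), len(window)
    NEG = -(10**9)
    match, mis = params.match_reward, params.mismatch_penalty
    g1 = params.gap_open  # cost of a length-1 gap
    ge = params.gap_extend

    # M[i][j]: best score aligning read[:i] ending in match/mismatch at window j-1
    # I[i][j]: ... ending in read insertion; D[i][j]: ... ending in deletion
    M = [[NEG] * (W + 1) for _ in range(L + 1)]
    I = [[NEG] * (W + 1) for _ in range(L + 1)]
    D = [[NEG] * (W + 1) for _ in range(L + 1)]
    M[0] = [0] * (W + 1)  # free leading reference
    for i in range(1, L + 1):
        I[i][0] = -(g1 + ge * (i - 1))
    for i in range(1, L + 1):
        a = read[i - 1]
        Mi, Ii, Di = M[i], I[i], D[i]
        Mp, Ip, Dp = M[i - 1], I[i - 1], D[i - 1]
        for j in range(1, W + 1):
            s = match if (a == window[j - 1] and a != "N") else -mis
            best_prev = max(Mp[j - 1], Ip[j - 1], Dp[j - 1])
            Mi[j] = best_prev + s if best_prev > NEG else NEG
            Ii[j] = max(Mp[j] - g1, Ip[j] - ge, Dp[j] - g1)
            Di[j] = max(Mi[j - 1] - g1, Di[j - 1] - ge)
    # free trailing reference: best over final row
    best_j, best_state, best = 0, "M", NEG
    for j in range(W + 1):
        for state, mat in (("M", M), ("I", I), ("D", D)):
            if mat[L][j] > best:
                best, best_j, best_state = mat[L][j], j, state
    # traceback
    ops: list[str] = []
    i, j, state = L, best_j, best_state
    while i > 0:
        if state == "M":
            a = read[i - 1]
            s = match if (a == window[j - 1] and a != "N") else -mis
            prev = M[i][j] - s
            ops.append("M")
            i, j = i - 1, j - 1
            state = (
                "M" if M[i][j] == prev else "I" if I[i][j] == prev else "D"
            )
        elif state == "I":
            ops.append("I")
            cur = I[i][j]
            if M[i - 1][j] - g1 == cur:
                state = "M"
            elif I[i - 1][j] - ge == cur:
                state = "I"
            else:
                state = "D"
            i -= 1
        else:  # D
            ops.append("D")
            cur = D[i][j]
            if M[i][j - 1] - g1 == cur:
                state = "M"
            else:
                state = "D"
            j -= 1
    # trailing deletions before the first read base are free reference, drop them
    while ops and ops[-1] == "D":
        ops.pop()
        j += 1
    ref_begin = j
    ops.reverse()
    # leading deletions after the last read base are also free reference
    while ops and ops[-1] == "D":
        ops.pop()
    cigar = _compress(ops)
    return best, cigar, ref_begin


def _compress(ops: list[str]) -> str:
    out = []
    i = 0
    while i < len(ops):
        j = i
        while j < len(ops) and ops[j] == ops[i]:
            j += 1
        out.append(f"{j - i}{ops[i]}")
        i = j
    return "".join(out)


def align_read_all_tasks(
    read: ReadRecord,
    conv_ref: ConvertedReference,
    params: AlignParams,
    mode: str = "non-directional",
    tier: int = 1,
) -> list[CandidateAlignment]:
    """Run seed-and-extend once per enabled strand task.

    Directional mode searches OT and OB only; non-directional searches all
    four tasks.  Candidates are labelled with their task and sorted by
    (score desc, contig, start, task) for determinism.
    """
    labels = DIRECTIONAL_TASKS if mode == "directional" else ALL_TASKS
    out: list[CandidateAlignment] = []
    for label in labels:
        task = STRAND_TASKS[label]
        conv = convert_read(read.seq, task)
        for cand in seed_and_extend(conv, task.ref_space, task.orientation, conv_ref, params):
            out.append(
                replace(cand, read_id=read.read_id, task=label, tier=tier)
            )
    out.sort(key=lambda c: (-c.conv_score, c.contig, c.start, c.task))
    return out


def two_tier_align(
    reads: Iterable[ReadRecord],
    conv_ref: ConvertedReference,
    strict: AlignParams = STRICT,
    permissive: Optional[AlignParams] = PERMISSIVE,
    mode: str = "non-directional",
) -> dict[str, list[CandidateAlignment]]:
    """Strict tier on all reads; permissive tier only on reads the strict
    tier left without candidates.  A read's list never mixes tiers.

    Pass ``permissive=None`` to disable the second tier.
    """
    if permissive is not None:
        if permissive.max_mismatches_converted < strict.max_mismatches_converted:
            raise ValueError("permissive tier must not be stricter than tier 1")
        build_index(conv_ref, permissive.k)
    build_index(conv_ref, strict.k)
    result: dict[str, list[CandidateAlignment]] = {}
    for read in reads:
        key = read.read_id if read.mate is None else f"{read.read_id}/{read.mate + 1}"
        cands = align_read_all_tasks(read, conv_ref, strict, mode, tier=1)
        if not cands and permissive is not None:
            cands = align_read_all_tasks(read, conv_ref, permissive, mode, tier=2)
        result[key] = cands
    return result


#: Task pairs that constitute a proper pair: the two mates' tasks must
#: imply opposite original strands.  The forward-oriented task's mate is
#: the leftmost on the reference.
PROPER_PAIR_TASKS = (frozenset({"OT", "OB"}), frozenset({"CTOT", "CTOB"}))


def pair_mates(
    cands1: list[CandidateAlignment],
    cands2: list[CandidateAlignment],
    insert_min: int,
    insert_max: int,
) -> list[tuple[CandidateAlignment, CandidateAlignment]]:
    """Select proper pairs from two mates' candidate lists.

    A pair is proper when both candidates share a contig, their tasks form
    an opposite-strand combination, the forward-oriented candidate is
    leftmost, and the outer span lies within ``[insert_min, insert_max]``.
    Pairs are sorted by combined converted-space score, descending.
    """
    pairs = []
    for a in cands1:
        for b in cands2:
            if a.contig != b.contig:
                continue
            if frozenset({a.task, b.task}) not in PROPER_PAIR_TASKS:
                continue
            fa = STRAND_TASKS[a.task].orientation == "forward"
            fwd, rev = (a, b) if fa else (b, a)
            if STRAND_TASKS[rev.task].orientation != "reverse":
                continue
            if fwd.start > rev.start:
                continue
            span = (rev.start + rev.ref_span()) - fwd.start
            if insert_min <= span <= insert_max:
                pairs.append((a, b))
    pairs.sort(
        key=lambda p: (
            -(p[0].conv_score + p[1].conv_score),
            p[0].contig,
            p[0].start,
            p[1].start,
        )
    )
    return pairs
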