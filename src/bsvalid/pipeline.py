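"""End-to-end orchestration: align, validate, filter, resolve.

This is the library face of the ``align`` CLI subcommand: reads go in,
one :class:`~bsvalid.postprocess.FinalVerdict` per read (per mate for
paired data) comes out, ready for SAM output, methylation reporting and
evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

from .aligner import (
    AlignParams,
    PERMISSIVE,
    STRICT,
    align_read_all_tasks,
    build_index,
    pair_mates,
)
from .conversion import ConvertedReference, prepare_reference
from .postprocess import (
    ClassifiedAlignment,
    FinalVerdict,
    classify_alignment,
    filter_alignment,
    resolve_read,
)
from .seqio import Genome, ReadRecord, SNPSet


@dataclass
class PipelineConfig:
    mode: str = "non-directional"  # "directional" | "non-directional"
    strict: AlignParams = STRICT
    permissive: Optional[AlignParams] = PERMISSIVE  # None disables tier 2
    max_invalid: int = 0
    max_mismatch: int = 3
    min_score_gap: int = 0
    insert_min: int = 0
    insert_max: int = 1000


def _tiered_candidates(read, conv_ref, cfg: PipelineConfig):
    cands = align_read_all_tasks(read, conv_ref, cfg.strict, cfg.mode, tier=1)
    if not cands and cfg.permissive is not None:
        cands = align_read_all_tasks(read, conv_ref, cfg.permissive, cfg.mode, tier=2)
    return cands


def _classify_and_resolve(
    read: ReadRecord,
    cands,
    genome: Genome,
    snps: Optional[SNPSet],
    cfg: PipelineConfig,
    verdict_id: str,
) -> FinalVerdict:
    kept: list[ClassifiedAlignment] = []
    reasons: list[str] = []
    for cand in cands:
        ca = classify_alignment(cand, read, genome, snps)
        ok, reason = filter_alignment(ca, cfg.max_invalid, cfg.max_mismatch)
        if ok:
            kept.append(ca)
        else:
            reasons.append(reason)
    verdict = resolve_read(kept, cfg.min_score_gap)
    verdict.read_id = verdict_id
    if verdict.status == "unmapped" and reasons:
        # every candidate was rejected; report the dominant reason
        verdict.reason = max(set(reasons), key=reasons.count)
    return verdict


def run_pipeline(
    reads: Iterable[ReadRecord],
    reference: Genome | ConvertedReference,
    snps: Optional[SNPSet] = None,
    config: Optional[PipelineConfig] = None,
) -> list[tuple[ReadRecord, FinalVerdict]]:
    """Align a read stream and return ``(read, verdict)`` pairs.

    Paired reads (``mate`` set, arriving mate 0 then mate 1) are paired
    through the proper-pair table first; when at least one proper pair
    exists, each mate's candidates are restricted to the best-scoring
    pairs before validation, otherwise both mates fall back to
    independent single-end resolution.  Verdicts for paired reads carry
    ``/1`` and ``/2`` id suffixes.
    """
    cfg = config or PipelineConfig()
    conv_ref = (
        reference
        if isinstance(reference, ConvertedReference)
        else prepare_reference(reference)
    )
    build_index(conv_ref, cfg.strict.k)
    if cfg.permissive is not None:
        build_index(conv_ref, cfg.permissive.k)
    genome = conv_ref.original

    out: list[tuple[ReadRecord, FinalVerdict]] = []
    pending: Optional[ReadRecord] = None
    for read in reads:
        if read.mate is None:
            cands = _tiered_candidates(read, conv_ref, cfg)
            out.append(
                (read, _classify_and_resolve(read, cands, genome, snps, cfg, read.read_id))
            )
            continue
        if read.mate == 0:
            pending = read
            continue
        if pending is None or pending.read_id != read.read_id:
            raise ValueError(f"unpaired mate-1 read {read.read_id!r}")
        r1, r2 = pending, read
        pending = None
        c1 = _tiered_candidates(r1, conv_ref, cfg)
        c2 = _tiered_candidates(r2, conv_ref, cfg)
        pairs = pair_mates(c1, c2, cfg.insert_min, cfg.insert_max)
        if pairs:
            best = pairs[0][0].conv_score + pairs[0][1].conv_score
            top = [p for p in pairs if p[0].conv_score + p[1].conv_score == best]
            c1 = [p[0] for p in top]
            c2 = [p[1] for p in top]
        out.append(
            (r1, _classify_and_resolve(r1, c1, genome, snps, cfg, f"{r1.read_id}/1"))
        )
        out.append(
            (r2, _classify_and_resolve(r2, c2, genome, snps, cfg, f"{r2.read_id}/2"))
        )
    if pending is not None:
        raise ValueError(f"mate-0 read {pending.read_id!r} has no mate-1 partner")
    return out


def audit_rows(results: Iterable[tuple[ReadRecord, FinalVerdict]]):
    """Yield audit-log rows (read_id, status, reason, n_invalid,
    n_mismatch, n_snp_excused) from pipeline results."""
    for _read, v in results:
        ca = v.alignment
        yield (
            v.read_id,
            v.status,
            v.reason,
            ca.n_invalid if ca else "",
            ca.n_mismatch if ca else "",
            ca.n_snp_excused if ca else "",
        )
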