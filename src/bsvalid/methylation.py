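"""Per-read methylation strings and per-position methylation aggregation.

Every retained reference cytosine observed in a uniquely mapped read is
either methylated (``M``, the C survived bisulfite) or unmethylated
(``U``, converted to T).  Tasks aligned against the C->T reference copy
observe cytosines on the + strand; tasks aligned against the G->A copy
observe the - strand (reference G positions).  Context is taken from the
original reference trinucleotide: CpG when the next base (strand-wise) is
G, CHG when the base after next is G, otherwise CHH.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

from .conversion import STRAND_TASKS
from .postprocess import ClassifiedAlignment, FinalVerdict
from .seqio import Genome, cigar_ops

CONTEXTS = ("CpG", "CHG", "CHH")


def cytosine_context(ref: str, pos: int, strand: str) -> str:
    """Trinucleotide context of the cytosine at ``pos`` on ``strand``.

    On the - strand the cytosine sits opposite a reference G and its
    downstream neighbours run leftwards (complemented).  Positions whose
    context runs off the contig end are called CHH.
    """
    if strand == "+":
        nxt = ref[pos + 1] if pos + 1 < len(ref) else ""
        nxt2 = ref[pos + 2] if pos + 2 < len(ref) else ""
        if nxt == "G":
            return "CpG"
        if nxt2 == "G":
            return "CHG"
        return "CHH"
    nxt = ref[pos - 1] if pos - 1 >= 0 else ""
    nxt2 = ref[pos - 2] if pos - 2 >= 0 else ""
    if nxt == "C":
        return "CpG"
    if nxt2 == "C":
        return "CHG"
    return "CHH"


@dataclass
class MethylationReport:
    """Rows of (contig, 0-based position, strand, context, n_meth, n_unmeth,
    level) at reference cytosine positions, sorted by (contig, position)."""

    rows: list[tuple[str, int, str, str, int, int, float]]

    def total_calls(self) -> int:
        return sum(r[4] + r[5] for r in self.rows)

    def weighted_level(self, context: Optional[str] = None) -> float:
        """Coverage-weighted mean methylation level, optionally per context."""
        m = u = 0
        for row in self.rows:
            if context is not None and row[3] != context:
                continue
            m += row[4]
            u += row[5]
        return m / (m + u) if m + u else float("nan")


def methylation_string(ca: ClassifiedAlignment) -> str:
    """The per-read code string emitted as the XM tag.

    Only filtered alignments may be stringified: a surviving ``X`` code
    means the chemistry filter was bypassed and is an error.
    """
    if "X" in ca.codes:
        raise ValueError("alignment with bisulfite-invalid columns was not filtered")
    return ca.codes


def build_report(
    verdicts: Iterable[FinalVerdict], genome: Genome
) -> MethylationReport:
    """Aggregate M/U observations from uniquely mapped reads.

    Ambiguous and unmapped reads contribute nothing.  Each ``M``/``U``
    code is assigned to its reference cytosine via the candidate's edit
    path; insertions consume read positions without a reference column.
    """
    counts: dict[tuple[str, int, str], list[int]] = {}
    for verdict in verdicts:
        if verdict.status != "unique" or verdict.alignment is None:
            continue
        ca = verdict.alignment
        cand = ca.candidate
        task = STRAND_TASKS[cand.task]
        strand = "+" if task.ref_space == "CT" else "-"
        codes = ca.codes[::-1] if task.orientation == "reverse" else ca.codes
        i, p = 0, cand.start
        for length, op in cigar_ops(cand.cigar):
            if op == "M":
                for _ in range(length):
                    c = codes[i]
                    if c in "MU":
                        cell = counts.setdefault((cand.contig, p, strand), [0, 0])
                        cell[0 if c == "M" else 1] += 1
                    i += 1
                    p += 1
            elif op == "I":
                i += length
            elif op == "D":
                p += length
    rows = []
    for (contig, pos, strand), (n_m, n_u) in sorted(counts.items()):
        ctx = cytosine_context(genome.contigs[contig], pos, strand)
        rows.append((contig, pos, strand, ctx, n_m, n_u, n_m / (n_m + n_u)))
    return MethylationReport(rows=rows)


def write_report_tsv(
    report: MethylationReport,
    path,
    one_based: bool = False,
    contexts: Optional[set[str]] = None,
    min_coverage: int = 0,
) -> None:
    """Write the report as a bedGraph-like TSV with a header line."""
    shift = 1 if one_based else 0
    with open(path, "w") as fh:
        fh.write("contig\tposition\tstrand\tcontext\tn_methylated\tn_unmethylated\tlevel\n")
        for contig, pos, strand, ctx, n_m, n_u, level in report.rows:
            if contexts is not None and ctx not in contexts:
                continue
            if n_m + n_u < min_coverage:
                continue
            fh.write(
                f"{contig}\t{pos + shift}\t{strand}\t{ctx}\t{n_m}\t{n_u}\t{level:.6g}\n"
            )
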