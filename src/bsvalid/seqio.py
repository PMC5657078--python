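"""Sequence and variant file I/O.

All genomic coordinates inside the package are 0-based, half-open.  The
only places where 1-based coordinates appear are the SAM POS column and
VCF position column, each converted exactly once at the I/O boundary.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional

log = logging.getLogger("bsvalid")

VALID_BASES = frozenset("ACGTN")


class FormatError(ValueError):
    """Raised for malformed input files; carries the offending line number."""

    def __init__(self, path, line_no: int, message: str):
        super().__init__(f"{path}:{line_no}: {message}")
        self.path = str(path)
        self.line_no = line_no


@dataclass
class Genome:
    """A reference genome: ordered mapping of contig name to uppercase sequence.

    Sequences are strings over ``{A,C,G,T,N}``; anything else is rejected
    at construction time.
    """

    contigs: dict[str, str]

    def __post_init__(self) -> None:
        for name, seq in self.contigs.items():
            if not name:
                raise ValueError("empty contig name")
            bad = set(seq) - VALID_BASES
            if bad:
                raise ValueError(
                    f"contig {name!r} contains illegal characters: {sorted(bad)}"
                )

    def __len__(self) -> int:
        return len(self.contigs)

    def total_length(self) -> int:
        return sum(len(s) for s in self.contigs.values())


@dataclass
class ReadRecord:
    """One sequencing read.

    ``mate`` is 0 or 1 for paired data, ``None`` for single-end.
    """

    read_id: str
    seq: str
    quals: Optional[str] = None
    mate: Optional[int] = None

    def __post_init__(self) -> None:
        if len(self.seq) < 1:
            raise ValueError(f"read {self.read_id!r} has empty sequence")
        if self.quals is not None and len(self.quals) != len(self.seq):
            raise ValueError(
                f"read {self.read_id!r}: quality length {len(self.quals)} "
                f"!= sequence length {len(self.seq)}"
            )


@dataclass
class SNPSet:
    """Known single-nucleotide variants used to excuse mismatches.

    Entries are ``(contig, 0-based position, ref allele, alt allele)``.
    Tolerance requires the alt allele to *explain* the observed read base,
    not merely mark the position as variable.
    """

    entries: set[tuple[str, int, str, str]] = field(default_factory=set)

    def __post_init__(self) -> None:
        for contig, pos, ref, alt in self.entries:
            if ref not in "ACGT" or alt not in "ACGT" or ref == alt:
                raise ValueError(f"bad SNP entry {(contig, pos, ref, alt)}")

    def __contains__(self, item: tuple[str, int, str, str]) -> bool:
        return item in self.entries

    def __len__(self) -> int:
        return len(self.entries)

    def validate_against(self, genome: Genome) -> None:
        for contig, pos, _ref, _alt in self.entries:
            if contig not in genome.contigs:
                raise ValueError(f"SNP contig {contig!r} not in genome")
            if not 0 <= pos < len(genome.contigs[contig]):
                raise ValueError(f"SNP position {contig}:{pos} out of bounds")


# ---------------------------------------------------------------------------
# FASTA / FASTQ
# ---------------------------------------------------------------------------

def read_fasta(path) -> Genome:
    """Load a FASTA file into a :class:`Genome`.

    Lowercase input is accepted and uppercased; multi-line records are
    joined.  Malformed headers, duplicate or empty records and illegal
    characters raise :class:`FormatError` naming the line.
    """
    contigs: dict[str, str] = {}
    name: Optional[str] = None
    chunks: list[str] = []
    name_line = 0

    def flush(line_no: int) -> None:
        if name is None:
            return
        seq = "".join(chunks)
        if not seq:
            raise FormatError(path, name_line, f"record {name!r} has no sequence")
        contigs[name] = seq

    with open(path) as fh:
        line_no = 0
        for line_no, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush(line_no)
                name = line[1:].split()[0] if len(line) > 1 else ""
                if not name:
                    raise FormatError(path, line_no, "empty FASTA header")
                if name in contigs:
                    raise FormatError(path, line_no, f"duplicate contig name {name!r}")
                name_line = line_no
                chunks = []
            else:
                if name is None:
                    raise FormatError(path, line_no, "sequence before any header")
                seq = line.upper()
                bad = set(seq) - VALID_BASES
                if bad:
                    raise FormatError(
                        path, line_no, f"illegal character(s) {sorted(bad)} in sequence"
                    )
                chunks.append(seq)
        flush(line_no + 1)
    if not contigs:
        raise FormatError(path, 0, "no FASTA records found")
    return Genome(contigs)


_MATE_SUFFIX = re.compile(r"(?:/[12]|[ _][12])$")


def _strip_mate_suffix(read_id: str) -> str:
    return _MATE_SUFFIX.sub("", read_id)


def _read_single(path) -> Iterator[ReadRecord]:
    """Parse one FASTQ or FASTA read file (autodetected by first character)."""
    with open(path) as fh:
        first = fh.read(1)
        fh.seek(0)
        if first == "@":
            yield from _parse_fastq(path, fh)
        elif first == ">":
            for rec in _parse_read_fasta(path, fh):
                yield rec
        elif first == "":
            return
        else:
            raise FormatError(path, 1, f"cannot autodetect format from {first!r}")


def _parse_fastq(path, fh) -> Iterator[ReadRecord]:
    line_no = 0
    while True:
        header = fh.readline()
        if not header:
            return
        line_no += 1
        header = header.rstrip("\n")
        if not header:
            continue
        if not header.startswith("@"):
            raise FormatError(path, line_no, "expected '@' header line")
        seq = fh.readline().rstrip("\n").upper()
        plus = fh.readline().rstrip("\n")
        quals = fh.readline().rstrip("\n")
        if not quals and not plus:
            raise FormatError(path, line_no, "truncated FASTQ record")
        line_no += 3
        if not plus.startswith("+"):
            raise FormatError(path, line_no - 1, "expected '+' separator line")
        if len(quals) != len(seq):
            raise FormatError(
                path, line_no, f"quality length {len(quals)} != sequence length {len(seq)}"
            )
        bad = set(seq) - VALID_BASES
        if bad:
            raise FormatError(path, line_no - 2, f"illegal character(s) {sorted(bad)}")
        yield ReadRecord(header[1:].split()[0], seq, quals)


def _parse_read_fasta(path, fh) -> Iterator[ReadRecord]:
    name = None
    chunks: list[str] = []
    line_no = 0
    for line_no, raw in enumerate(fh, start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith(">"):
            if name is not None:
                yield ReadRecord(name, "".join(chunks))
            name = line[1:].split()[0] if len(line) > 1 else ""
            if not name:
                raise FormatError(path, line_no, "empty FASTA header")
            chunks = []
        else:
            seq = line.upper()
            bad = set(seq) - VALID_BASES
            if bad:
                raise FormatError(path, line_no, f"illegal character(s) {sorted(bad)}")
            chunks.append(seq)
    if name is not None:
        yield ReadRecord(name, "".join(chunks))


def read_reads(path1, path2=None) -> Iterator[ReadRecord]:
    """Stream reads from FASTQ/FASTA; paired when two files are given.

    Paired mode yields mate 0 then mate 1 for each fragment, with trailing
    ``/1``-style suffixes stripped so both mates share one id.
    """
    if path2 is None:
        yield from _read_single(path1)
        return
    it1, it2 = _read_single(path1), _read_single(path2)
    for r1 in it1:
        try:
            r2 = next(it2)
        except StopIteration:
            raise FormatError(path2, 0, "fewer reads in mate-2 file than mate-1 file")
        id1, id2 = _strip_mate_suffix(r1.read_id), _strip_mate_suffix(r2.read_id)
        if id1 != id2:
            raise FormatError(path2, 0, f"mate id mismatch: {r1.read_id!r} vs {r2.read_id!r}")
        r1.read_id, r1.mate = id1, 0
        r2.read_id, r2.mate = id2, 1
        yield r1
        yield r2
    try:
        next(it2)
    except StopIteration:
        pass
    else:
        raise FormatError(path2, 0, "more reads in mate-2 file than mate-1 file")


def write_fastq(records: Iterable[ReadRecord], path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            quals = rec.quals if rec.quals is not None else "I" * len(rec.seq)
            fh.write(f"@{rec.read_id}\n{rec.seq}\n+\n{quals}\n")


# ---------------------------------------------------------------------------
# SNP files (VCF SNV subset, or 4-column TSV)
# ---------------------------------------------------------------------------

def read_snp_file(path, genome: Optional[Genome] = None) -> SNPSet:
    """Load known SNVs from a VCF (SNV subset) or a 4-column TSV.

    TSV columns: contig, 1-based position, ref, alt.  Non-SNV VCF records
    (indels, multi-allelic with no SNV allele) are skipped and counted.
    """
    entries: set[tuple[str, int, str, str]] = set()
    skipped = 0
    with open(path) as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            try:
                if len(fields) >= 5:
                    # VCF body line: CHROM POS ID REF ALT ...
                    contig, pos_s, _id, ref, alts = fields[:5]
                    pos = int(pos_s) - 1
                    if len(ref) != 1 or ref not in "ACGT":
                        skipped += 1
                        continue
                    any_snv = False
                    for alt in alts.split(","):
                        if len(alt) == 1 and alt in "ACGT" and alt != ref:
                            entries.add((contig, pos, ref, alt))
                            any_snv = True
                    if not any_snv:
                        skipped += 1
                elif len(fields) == 4:
                    contig, pos_s, ref, alt = fields
                    pos = int(pos_s) - 1
                    entries.add((contig, pos, ref.upper(), alt.upper()))
                else:
                    raise ValueError("expected VCF record or 4-column TSV line")
            except (ValueError, IndexError) as exc:
                raise FormatError(path, line_no, f"unparseable SNP line: {exc}") from exc
    if skipped:
        log.info("read_snp_file: skipped %d non-SNV record(s)", skipped)
    snps = SNPSet(entries)
    if genome is not None:
        snps.validate_against(genome)
    return snps


# ---------------------------------------------------------------------------
# SAM output
# ---------------------------------------------------------------------------

def write_sam(pairs, genome: Genome, path) -> None:
    """Write final per-read verdicts as a SAM file.

    ``pairs`` is an iterable of ``(ReadRecord, FinalVerdict)``.  Uniquely
    mapped reads produce one aligned line; ambiguous and unmapped reads are
    emitted with FLAG 0x4.  Reads mapped to the reverse original strand are
    stored reverse-complemented with FLAG 0x10, per the SAM convention, and
    the XM methylation string is reversed alongside so it stays aligned
    with SEQ.  Custom tags: XM:Z methylation string, XG:Z strand task,
    NM:i substitution mismatches plus inserted and deleted bases.
    """
    from .conversion import STRAND_TASKS, revcomp

    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        for name, seq in genome.contigs.items():
            fh.write(f"@SQ\tSN:{name}\tLN:{len(seq)}\n")
        fh.write("@PG\tID:bsvalid\tPN:bsvalid\n")
        for read, verdict in pairs:
            quals = read.quals if read.quals is not None else "*"
            if verdict.status != "unique":
                fh.write(
                    f"{read.read_id}\t4\t*\t0\t0\t*\t*\t0\t0\t{read.seq}\t{quals}\t"
                    f"XS:Z:{verdict.status}\n"
                )
                continue
            ca = verdict.alignment
            cand = ca.candidate
            if cand.contig not in genome.contigs:
                raise ValueError(f"alignment references unknown contig {cand.contig!r}")
            task = STRAND_TASKS[cand.task]
            reverse = task.orientation == "reverse"
            flag = 0x10 if reverse else 0
            seq = revcomp(read.seq) if reverse else read.seq
            q = quals if quals == "*" or not reverse else quals[::-1]
            xm = ca.codes[::-1] if reverse else ca.codes
            inserted = sum(n for n, op in _cigar_ops(cand.cigar) if op == "I")
            deleted = sum(n for n, op in _cigar_ops(cand.cigar) if op == "D")
            subs = ca.n_mismatch - inserted + ca.n_invalid
            nm = subs + inserted + deleted
            fh.write(
                f"{read.read_id}\t{flag}\t{cand.contig}\t{cand.start + 1}\t42\t"
                f"{cand.cigar}\t*\t0\t0\t{seq}\t{q}\t"
                f"NM:i:{nm}\tXM:Z:{xm}\tXG:Z:{cand.task}\n"
            )


_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")


def _cigar_ops(cigar: str) -> list[tuple[int, str]]:
    ops = [(int(n), op) for n, op in _CIGAR_RE.findall(cigar)]
    if "".join(f"{n}{op}" for n, op in ops) != cigar:
        raise ValueError(f"malformed CIGAR {cigar!r}")
    return ops


def cigar_ops(cigar: str) -> list[tuple[int, str]]:
    """Parse a CIGAR string into ``(length, op)`` runs."""
    return _cigar_ops(cigar)


def cigar_ref_span(cigar: str) -> int:
    return sum(n for n, op in _cigar_ops(cigar) if op in "MD")


def cigar_read_span(cigar: str) -> int:
    return sum(n for n, op in _cigar_ops(cigar) if op in "MI")
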