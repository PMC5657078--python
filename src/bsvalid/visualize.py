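"""Color-coded alignment rendering as styled terminal text or static HTML.

Each alignment is shown as stacked three-line blocks (reference slice,
match bar, read) wrapped at a fixed width.  Two named schemes exist:

* ``alignment-view`` (default) — mismatches, insertions and deletions in
  blue, methylated bases in red.
* ``methylation-view`` — methylated in blue, unmethylated in green,
  bisulfite-invalid columns in red (useful when auditing candidates
  before filtering).

Three markups are supported: ``plain`` wraps a styled base in brackets
together with its code letter (``[CM]`` is a C carrying code M), so
output is byte-exactly testable; ``ansi`` uses terminal color escapes;
``html`` emits inline-styled spans.
"""

from __future__ import annotations

import html as _html
import re
from dataclasses import dataclass, field
from typing import Optional

from .conversion import STRAND_TASKS, revcomp
from .postprocess import ClassifiedAlignment, FinalVerdict
from .seqio import Genome, ReadRecord, cigar_ops


@dataclass(frozen=True)
class RenderScheme:
    name: str
    #: map column code -> color name; codes absent from the palette are
    #: rendered unstyled.  "I"/"D" are the synthetic codes given to
    #: inserted read bases and deletion dashes.
    palette: dict[str, str] = field(default_factory=dict)


ALIGNMENT_VIEW = RenderScheme(
    "alignment-view",
    {"x": "blue", "X": "blue", "I": "blue", "D": "blue", "M": "red"},
)
METHYLATION_VIEW = RenderScheme(
    "methylation-view",
    {"M": "blue", "U": "green", "X": "red"},
)
SCHEMES = {"alignment": ALIGNMENT_VIEW, "methylation": METHYLATION_VIEW}

_ANSI = {"blue": "\x1b[34m", "red": "\x1b[31m", "green": "\x1b[32m"}
_RESET = "\x1b[0m"

_PLAIN_TOKEN = re.compile(r"\[(.)(.)\]")
_ANSI_TOKEN = re.compile(r"\x1b\[\d+m")


def _style(char: str, code: str, color: Optional[str], markup: str) -> str:
    if color is None:
        return char
    if markup == "plain":
        return f"[{char}{code}]"
    if markup == "ansi":
        return f"{_ANSI[color]}{char}{_RESET}"
    if markup == "html":
        return f'<span style="color:{color}">{_html.escape(char)}</span>'
    raise ValueError(f"unknown markup {markup!r}")


def strip_markup(text: str) -> str:
    """Remove styling tokens, leaving the raw three-line columns."""
    text = _PLAIN_TOKEN.sub(r"\1", text)
    text = _ANSI_TOKEN.sub("", text)
    text = re.sub(r"<span[^>]*>(.*?)</span>", r"\1", text)
    return text


def _columns(
    ca: ClassifiedAlignment, genome: Genome, read: ReadRecord
) -> list[tuple[str, str, str, str]]:
    """Expand the edit path into (ref_char, bar_char, read_char, code)."""
    cand = ca.candidate
    task = STRAND_TASKS[cand.task]
    oriented = revcomp(read.seq) if task.orientation == "reverse" else read.seq
    codes = ca.codes[::-1] if task.orientation == "reverse" else ca.codes
    ref = genome.contigs[cand.contig]
    cols = []
    i, p = 0, cand.start
    for length, op in cigar_ops(cand.cigar):
        if op == "M":
            for _ in range(length):
                code = codes[i]
                bar = "|" if code == "." else " "
                cols.append((ref[p], bar, oriented[i], code))
                i += 1
                p += 1
        elif op == "I":
            for _ in range(length):
                cols.append(("-", " ", oriented[i], "I"))
                i += 1
        elif op == "D":
            for _ in range(length):
                cols.append((ref[p], " ", "-", "D"))
                p += 1
    return cols


def render_alignment(
    ca: ClassifiedAlignment,
    read: ReadRecord,
    genome: Genome,
    scheme: RenderScheme = ALIGNMENT_VIEW,
    width: int = 60,
    markup: str = "plain",
) -> str:
    """Render one classified alignment as stacked three-line blocks.

    Deleted reference bases appear as ``-`` in the read line, inserted
    read bases as ``-`` in the reference line; styling follows the
    scheme's palette.
    """
    cols = _columns(ca, genome, read)
    blocks = []
    for off in range(0, len(cols), width):
        chunk = cols[off : off + width]
        ref_line = "".join(c[0] for c in chunk)
        bar_line = "".join(c[1] for c in chunk)
        read_line = "".join(
            _style(c[2], c[3], scheme.palette.get(c[3]), markup) for c in chunk
        )
        blocks.append(f"{ref_line}\n{bar_line}\n{read_line}")
    return "\n\n".join(blocks)


def render_read_report(
    verdict: FinalVerdict,
    read: ReadRecord,
    genome: Genome,
    scheme: RenderScheme = ALIGNMENT_VIEW,
    width: int = 60,
    markup: str = "plain",
) -> str:
    """Render all of a read's surviving placements.

    Unique reads get one block, ambiguous reads one block per equal-best
    locus, unmapped reads a one-line notice.
    """
    if verdict.status == "unmapped":
        return f"{verdict.read_id or read.read_id}: unmapped\n"
    targets = verdict.alternates if verdict.status == "ambiguous" else [verdict.alignment]
    parts = []
    for ca in targets:
        cand = ca.candidate
        header = (
            f"{read.read_id} {verdict.status} {cand.contig}:{cand.start}"
            f" task={cand.task} tier={cand.tier} score={ca.valid_score}"
        )
        parts.append(header + "\n" + render_alignment(ca, read, genome, scheme, width, markup))
    return "\n\n".join(parts) + "\n"


def render_html_document(body_blocks: list[str], title: str = "bsvalid alignment view") -> str:
    """Wrap pre-rendered HTML blocks in a minimal static page."""
    joined = "\n\n".join(body_blocks)
    return (
        "<!DOCTYPE html>\n<html>\n<head>\n"
        f"<meta charset=\"utf-8\"/>\n<title>{_html.escape(title)}</title>\n"
        "</head>\n<body>\n"
        f"<pre style=\"font-family:monospace\">\n{joined}\n</pre>\n"
        "</body>\n</html>\n"
    )
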