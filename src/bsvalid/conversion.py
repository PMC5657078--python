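"""Three-letter base conversions and the four-strand bisulfite model.

Bisulfite treatment converts unmethylated cytosine to uracil, read as T
after PCR.  Collapsing C to T in both reads and reference (and G to A for
the complementary strand) makes conversion invisible to the aligner; the
chemistry is re-checked later against the original sequences.

A sequenced fragment can originate from four strands:

* ``OT``   — original top (bisulfite Watson): read C->T, aligned forward
             against the C->T reference copy.
* ``OB``   — original bottom (bisulfite Crick): read C->T, reverse
             complemented, aligned against the G->A reference copy.
* ``CTOT`` — PCR complement of OT: read G->A, reverse complemented,
             aligned against the C->T copy.
* ``CTOB`` — PCR complement of OB: read G->A, aligned forward against
             the G->A copy.

The low-level aligner never searches reverse complements on its own;
orientation is handled only through this table, which is what restricts
each converted read copy to its matching converted reference strand.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .seqio import Genome

_C2T = str.maketrans("C", "T")
_G2A = str.maketrans("G", "A")
_COMP = str.maketrans("ACGTN", "TGCAN")


def convert_c2t(seq: str) -> str:
    """Replace every C by T; everything else unchanged."""
    return seq.translate(_C2T)


def convert_g2a(seq: str) -> str:
    """Replace every G by A; everything else unchanged."""
    return seq.translate(_G2A)


def revcomp(seq: str) -> str:
    """Reverse Watson-Crick complement; N maps to N."""
    return seq.translate(_COMP)[::-1]


@dataclass(frozen=True)
class StrandTask:
    label: str
    read_conversion: str  # "CT" | "GA"
    ref_space: str        # "CT" | "GA"
    orientation: str      # "forward" | "reverse"


STRAND_TASKS: dict[str, StrandTask] = {
    "OT": StrandTask("OT", "CT", "CT", "forward"),
    "OB": StrandTask("OB", "CT", "GA", "reverse"),
    "CTOT": StrandTask("CTOT", "GA", "CT", "reverse"),
    "CTOB": StrandTask("CTOB", "GA", "GA", "forward"),
}

DIRECTIONAL_TASKS = ("OT", "OB")
ALL_TASKS = ("OT", "OB", "CTOT", "CTOB")

#: Original genomic strand each task's fragment derives from; used for
#: candidate deduplication and for scoring mapping correctness.
ORIGINAL_STRAND = {"OT": "+", "CTOT": "+", "OB": "-", "CTOB": "-"}


def convert_read(seq: str, task: StrandTask) -> str:
    """Apply the task's read-side conversion (not its orientation)."""
    return convert_c2t(seq) if task.read_conversion == "CT" else convert_g2a(seq)


@dataclass
class ConvertedReference:
    """Original genome plus its two converted copies and seed indexes.

    ``indexes`` maps ``(ref_space, k)`` to a :class:`~bsvalid.aligner.KmerIndex`
    and is populated by :func:`bsvalid.aligner.build_index`.
    """

    original: Genome
    ct_copy: Genome
    ga_copy: Genome
    indexes: dict = field(default_factory=dict)

    def space(self, ref_space: str) -> Genome:
        return self.ct_copy if ref_space == "CT" else self.ga_copy


def prepare_reference(genome: Genome) -> ConvertedReference:
    """Build the C->T and G->A copies of a genome, keeping the original."""
    ct = Genome({name: convert_c2t(seq) for name, seq in genome.contigs.items()})
    ga = Genome({name: convert_g2a(seq) for name, seq in genome.contigs.items()})
    return ConvertedReference(original=genome, ct_copy=ct, ga_copy=ga)
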