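# Methods

## Strand model and three-letter conversion

A bisulfite fragment can reach the sequencer from four strands. Each is
handled as an explicit *strand task* that fixes which converted read
copy is searched against which converted reference copy, and in which
orientation:

| task | read conversion | reference copy | orientation | original strand |
|------|-----------------|----------------|-------------|-----------------|
| OT (bisulfite Watson) | C→T | C→T | forward | + |
| OB (bisulfite Crick) | C→T | G→A | reverse | − |
| CTOT (PCR complement of OT) | G→A | C→T | reverse | + |
| CTOB (PCR complement of OB) | G→A | G→A | forward | − |

The table is consistent because `c2t(revcomp(s)) == revcomp(g2a(s))`
for every sequence `s` (a property test asserts this). The low-level
aligner never searches reverse complements itself; orientation enters
only through this table, which is what restricts each converted read to
the same-strand converted reference. Non-directional search (all four
tasks) is the default for the library pipeline; the simulator defaults
to directional (OT/OB), matching the most common protocol, and the
evaluation runs use directional mode end to end.

## Seed-and-extend alignment

The converted reference copies are indexed with an exact k-mer table
(k-mers containing N are omitted, so N can seed nothing). Seeds are
non-overlapping at stride k from offset 0 plus one seed flush with the
read end; this guarantees a clean seed whenever the read has fewer than
`floor(L/k)` mismatches at its true diagonal. Each distinct seed
diagonal is extended:

* **ungapped tiers** count mismatches directly (N scores as mismatch)
  and keep placements within the tier's mismatch budget;
* **gapped tiers** run a read-global/reference-local ("fit") alignment
  over the diagonal's window (±`band` = 8 bp flanks) with affine gaps.

Converted-space scoring is match +1, mismatch −2, gap open −5, gap
extend −3 (a length-g gap costs `open + extend·(g−1)`); these values are
a fixed design choice of the package and all tests are defined against
them. A candidate is kept when its score reaches the floor implied by
the tier's mismatch budget, i.e. the score of an ungapped placement
with exactly that many mismatches. Candidates are sorted by (score,
contig, start) and capped (default 10 per read per task); identical
inputs always give byte-identical candidate lists.

Two tiers mirror a strict-then-rescue strategy: the strict tier
(k=20, ≤2 mismatches, no gaps) runs on every read; only reads it leaves
with *zero candidates* are re-run with the permissive tier (k=12, ≤5
mismatches, gaps allowed). A read's candidate list never mixes tiers,
so enabling the second tier can only add mappings, never change a
strict-tier verdict. Candidates that survive post-processing are never
overridden by the permissive tier either — rescue is for unmapped reads
only. The permissive tier is end-to-end in the read: soft-clipping was
deliberately left out so that every reported column is classified under
the chemistry rules and the validated score has no unscored positions.

Paired-end reads are paired before validation: a proper pair requires
one forward-task and one reverse-task mate on the same contig whose
tasks imply opposite original strands ({OT,OB} or {CTOT,CTOB}), the
forward mate leftmost, and an outer span inside the insert window. When
proper pairs exist, each mate's candidates are restricted to the
best-scoring pairs; otherwise both mates fall back to single-end
resolution. The simulator emits pairs with the same geometry, so the
contract is testable by round trip.

## Chemistry validation and filtering

Every candidate is re-walked over the original read and reference.
Tasks aligned through the C→T reference copy use the C/T rules (ref C &
read C → `M`; ref C & read T → `U`; ref T & read C → `X`); tasks
aligned through the G→A copy use the mirrored G/A rules. The rule set
is keyed by the task's *reference space* because that is the alphabet
in which the masking happened once the read is placed in reference
orientation. Codes are stored per read position in read orientation; in
SAM output the `XM` string is reversed for reverse-strand records so it
stays column-aligned with `SEQ`.

The validated score is +1 per `.`, `M`, `U`, `S`, −2 per `x`, −8 per
`X`, plus the CIGAR gap penalties (inserted read bases are coded `x`
and also pay the gap penalty — the scheme deliberately overweights
indels so gapped placements only win when nothing cleaner exists). The
−8 invalid penalty is much heavier than an ordinary mismatch so that
even under a relaxed invalid budget, chemistry-violating placements
lose ties. Filtering rejects alignments with more than `max_invalid`
(default 0) invalid columns or more than `max_mismatch` (default 3)
mismatches. The default `max_invalid=0` is the strict reading of
one-directional chemistry; it is exposed because sequencing errors can
create rare read-C artifacts, and the noisy-data evaluation shows the
cost: such reads become unmapped rather than misplaced.

SNP tolerance downgrades `x` or `X` to `S` only when a supplied variant
at that exact position has an alt allele equal to the observed
reference-oriented base — excusing genuine genotype differences rather
than blanket-masking variable sites. Enlarging the SNP set can
therefore only raise scores and never flips a kept alignment to
rejected (property-tested). Ref-C/read-T columns are always called `U`
even where a C→T SNP exists; the two cases are indistinguishable in a
bisulfite read.

Per read, surviving candidates at the same (contig, start, original
strand) are duplicates — e.g. the same locus reached through OT and
CTOT, or through both tiers — and only the best-scoring one is kept. A
read is *unique* iff a single deduplicated candidate attains the
maximal validated score (an optional `min_score_gap` demands a margin;
default 0 so only exact ties are ambiguous), *ambiguous* when several
tie, *unmapped* when nothing survives.

## Methylation calling

`M`/`U` codes from uniquely mapped reads are assigned to reference
cytosines through the edit path: + strand positions for CT-space tasks,
− strand (reference G) positions for GA-space tasks. Context comes from
the original reference trinucleotide — CpG when the strand-wise next
base is G, CHG when the base after next is G, else CHH; positions whose
context runs off the contig end are called CHH. Ambiguous reads
contribute nothing (avoiding double counting), and the report conserves
counts: total M+U codes across unique reads equals the report's total.

## The simulator as study condition

Defaults emulate an Illumina-like directional WGBS run: 50 kb uniform
genome at GC 0.5, 2,000 single-end 75 bp reads, CpG/CHG/CHH methylation
levels 0.7/0.02/0.02 (typical mammalian somatic values), bisulfite
conversion failure 1%, per-cycle substitution error linear from 0.1% to
0.6%, constant Phred-40 qualities (scoring ignores qualities — the
mapping method is not quality-aware, so the simulator does not model
quality profiles either). Methylation states are drawn independently
per cytosine on both strands; conversion failure retains the C but is
recorded as *unmethylated* in the truth, since it is a chemistry
artifact, which makes the expected observed level
`level + (1 − level)·failure`. Insert lengths for paired mode are
normal (mean 250, sd 30) truncated below at the read length.

What the simulator does **not** model — and what passing tests
therefore cannot show about real data: genomic repeats and low-
complexity regions (uniform random genomes make uniqueness easy),
CpG-island clustering and region-level methylation correlation, indel
sequencing errors, M-bias, adapter read-through, PCR duplicates, and
RRBS fragment selection. Mappability figures on real genomes will be
lower than on these conditions; the *relative* guarantees (chemistry
safety, tier monotonicity, exact-locus precision) are the point.

Correctness tolerance for "correct mappability" is 0 bases (exact
start) by default — the strictest testable choice — with a `--tolerance`
flag for gapped runs where the reported leftmost position can shift.

## Evaluation problem sizes

The standard evaluation runs use the 50 kb / 2,000-read conditions
above for the clean-data, noisy-data and tier-comparison checks, and a
40 kb genome at 20× coverage (10,667 reads) for methylation recovery;
the recovery run disables sequencing error so the measured level is
compared against the exact conversion-failure formula, and the larger
genome keeps the planted-level binomial noise (~2,500 CpG sites per
strand) well inside the ±0.03 comparison band. All runs are seeded and
fully deterministic; the whole suite plus the acceptance script
completes in well under a minute on one CPU.

## Numerical and degenerate-input choices

* Coordinates are 0-based half-open internally; SAM POS and VCF
  positions are converted exactly once at I/O.
* N never matches: it seeds nothing, scores as mismatch in extension,
  and classifies as `x`.
* Ties everywhere are broken deterministically (score desc, contig,
  start, task lexicographic); tier 1 beats tier 2 at equal score in
  deduplication.
* Reads shorter than the seed length warn and return no candidates; no
  hard minimum or maximum read length is enforced.
* Empty genomes and k-mer sizes exceeding the shortest contig are
  rejected at index build.
* Ambiguous reads are written to SAM as unmapped (FLAG 0x4) with an
  `XS:Z` status note; their placements remain available through the
  library API.

## Known limitations

Single-threaded (`--threads` is accepted as a stub); exact k-mer tables
trade memory for simplicity and are not suited to mammalian-scale
genomes; no FM-index, no soft-clipping, no splicing, no color space, no
BAM/CRAM, no quality-aware scoring, no PCR-duplicate marking, no
differential-methylation statistics. External-aligner integration
behind the candidate-list contract is possible by construction but not
shipped.
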