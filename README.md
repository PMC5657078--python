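# bsvalid

Bisulfite read alignment with chemistry validation: three-letter mapping,
post-hoc rejection of chemically impossible placements, SNP-tolerant
filtering, methylation calling, SAM output and color-coded alignment
views — plus a bisulfite read simulator so the whole pipeline can be
exercised and scored without any external data.

## The problem

Bisulfite sequencing measures DNA methylation: treatment converts every
*unmethylated* cytosine to uracil (read as T after PCR) while methylated
cytosines stay C. A bisulfite read therefore differs from the genome at
every converted position, and ordinary aligners reject it. The standard
fix is **three-letter alignment**: convert C→T in the reads and in one
reference copy (and G→A in a second copy, for fragments that derive from
the complementary strand) so conversion no longer counts as mismatch.

The masking is one-sided, though. Conversion only ever turns C into T —
never T into C — yet in converted space a read **C** lands happily on a
reference **T**. For example the read `AGACCCATG` converts to
`AGATTTATG` and matches a reference window `AGATTTATG` perfectly, but
the placement is chemically impossible at three columns. `bsvalid`
re-walks every candidate over the *original* read and reference and
classifies each column:

| code | meaning |
|------|---------|
| `.`  | non-cytosine match |
| `M`  | methylated call (ref C, read C) |
| `U`  | unmethylated call (ref C, read T) |
| `x`  | ordinary mismatch (insertions included) |
| `X`  | bisulfite-invalid match (ref T under read C) |
| `S`  | mismatch excused by a known SNP whose alt allele explains the base |

Alignments exceeding the invalid budget (default 0) or the mismatch
budget (default 3) are rejected; mirrored G/A rules apply to fragments
aligned through the G→A reference copy. A read can originate from four
strands (OT, OB and their PCR complements CTOT/CTOB); each is searched as
an explicit task against its matching converted reference copy, never by
letting the low-level aligner flip strands on its own.

Mapping itself is two-tiered: a strict end-to-end tier (seed length 20,
≤2 converted-space mismatches, no gaps) handles the bulk, and a
permissive gapped tier (seed 12, ≤5 mismatches) is applied only to reads
the strict tier leaves unmapped. Surviving candidates are deduplicated
per read; a read is **uniquely mapped** when a single candidate attains
the best validated score, and per-position methylation
(CpG / CHG / CHH context) is aggregated from unique reads only.

The simulator generates the matching evaluation data — random genome,
per-context methylation states on both strands, directional or
non-directional reads, bisulfite conversion with a configurable failure
rate, per-cycle substitution errors — and the evaluator scores
**mappability** (unique reads / all reads) and **correct mappability**
(unique reads at the exact true locus and strand / all reads).

## Worked example

```bash
python examples/02_simulate_align_evaluate.py
```

simulates 500 directional 75 bp reads from a 20 kb genome with 1%
conversion failure and 0.1%→0.6% per-cycle sequencing error, maps them
and prints:

```
reads	500
unique	496
unique_correct	496
mappability	99.20%
correct_mappability	99.20%

tier-2 rescues	1
```

496 of 500 reads map uniquely and *every* unique mapping is at the exact
simulated locus; the four losses are reads whose sequencing errors
created a bisulfite-invalid column (the chemistry filter rejects them
rather than risk a wrong placement), and one read needed the permissive
second tier. `examples/01_conversion_and_validation.py`,
`examples/03_methylation_report.py` and
`examples/04_visualize_alignment.py` walk the false-mapping example, the
methylation report and the terminal alignment view the same way.

The same operations are available as a CLI:

```bash
bsvalid --seed 7 simulate --out-prefix sim --genome-length 8000 --n-reads 150
bsvalid index sim.fa --out sim.idx
bsvalid align --reads sim.fastq --index sim.idx --out out.sam --mode directional
bsvalid evaluate --sam out.sam --truth sim.truth.tsv
bsvalid report --sam out.sam --genome sim.fa --out meth.tsv
bsvalid view --sam out.sam --genome sim.fa --read r0
```

SAM output carries `XM:Z` (methylation string), `XG:Z` (strand task) and
`NM:i` tags.

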