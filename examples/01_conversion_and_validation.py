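"""Three-letter conversion and why it needs chemistry validation.

Bisulfite treatment converts unmethylated C to T, so aligners mask the
C/T difference by converting reads and reference to a three-letter
alphabet.  The masking is deliberately too permissive: a read C can land
on a reference T, which the chemistry forbids (conversion never goes
T -> C).  This script shows the masking, the resulting false mapping,
and the validation step that catches it.
"""

from bsvalid import (
    CandidateAlignment,
    Genome,
    ReadRecord,
    classify_alignment,
    convert_c2t,
    filter_alignment,
)

read = "AGACCCATG"
ref_window = "AGATTTATG"

print(f"read           : {read}")
print(f"reference      : {ref_window}")
print(f"converted read : {convert_c2t(read)}   <- identical to the reference")
print()

# In converted space the read matches the window perfectly, so any
# three-letter aligner will report this placement.  Validation walks the
# ORIGINAL sequences:
genome = Genome({"chr_demo": ref_window})
candidate = CandidateAlignment("demo_read", "OT", "chr_demo", 0, "9M", 9)
ca = classify_alignment(candidate, ReadRecord("demo_read", read), genome)

print(f"column codes   : {ca.codes}")
print(f"invalid columns: {ca.n_invalid}")
kept, reason = filter_alignment(ca, max_invalid=0)
print(f"verdict        : {'kept' if kept else 'rejected'} ({reason})")
# The three X codes are read Cs over reference Ts -- impossible under
# bisulfite chemistry -- so the placement is rejected as a false mapping.
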