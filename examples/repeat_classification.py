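"""Classify indel repeat context against a toy reference sequence.

Runs the HR/TR classifier on four hand-built indels: an A insertion in an
A-homopolymer, a G insertion in the same run, and AC-unit deletions in
dinucleotide arrays of 9 and 8 copies.
"""

from denovorate.repeats import classify_indel_context, extract_context

reference = {
    "toy": "GGTC" + "A" * 8 + "TCGG" + "AC" * 9 + "TTGG" + "AC" * 8 + "GGTT",
}

cases = [
    ("A insertion in A8 run", 5, "A", "AA"),
    ("G insertion in A8 run", 5, "A", "AG"),
    ("AC deletion in (AC)x9", 17, "CAC", "C"),
    ("AC deletion in (AC)x8", 39, "CAC", "C"),
]

for label, pos, ref, alt in cases:
    window, offset = extract_context(reference, "toy", pos, ref, flank=20)
    ann = classify_indel_context(window, offset, ref, alt)
    print(f"{label:26s} -> {ann.klass:5s} unit={ann.unit} copies={ann.copies}")

print()
print("HR needs a run of >= 6 identical bases matching the indel sequence;")
print("a mismatching base demotes to HR_NC.  A tandem unit of u bp is")
print("canonical (TR) at >= 2u+5 copies - 9 for dinucleotides - else TR_NC.")
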