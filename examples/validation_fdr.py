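"""Tally Sanger-validation outcomes into per-class false discovery rates.

Builds a small synthetic validation table (one row per assayed variant) and
summarises it: FDR = invalidated / conclusively assayed, with failed assays
excluded from the denominator.
"""

from denovorate.validation import ValidationRecord, tally_all

spec = {
    # class: (validated, invalidated, failed_assay)
    "de novo SNV": (23, 1, 26),
    "de novo indel": (17, 2, 31),
}
records = []
i = 0
for cls, (v, inv, fail) in spec.items():
    for outcome, count in (("validated", v), ("invalidated", inv), ("failed_assay", fail)):
        for _ in range(count):
            i += 1
            records.append(ValidationRecord("chr1", i, "A", "C", cls, outcome))

print(tally_all(records).to_string(index=False))
print()
print("'assayed' counts only conclusive outcomes; e.g. 1 invalidated of 24")
print("assayed de novo SNVs gives an FDR of 0.042 even though 50 were picked.")
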