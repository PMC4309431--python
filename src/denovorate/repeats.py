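"""Homopolymer-run / tandem-repeat context classification of indels.

Indels in repetitive DNA are both enriched and error-prone, so each indel is
annotated by the repeat structure of its flanking sequence:

* ``HR``   — canonical homopolymer run: the indel lies within a run of six or
  more identical bases and the inserted/deleted sequence consists of that
  base only.
* ``HR_NC`` — the run criterion holds but the indel sequence contains other
  bases.
* ``TR``   — canonical tandem repeat: the indel lies within an exact tandem
  array with unit length > 1 repeated at least ``unit_length * 2 + 5`` times
  (2 bp units: >= 9 copies, 3 bp units: >= 11 copies, ...).
* ``TR_NC`` — a tandem array (>= 2 copies) below the canonical threshold.
* ``NONE`` — no qualifying repeat context.

Precedence when several arrays overlap the indel: HR > TR > HR_NC > TR_NC.
Detection is exact-match (no mismatches within an array), with units
canonicalised to their lexicographically minimal rotation and restricted to
primitive units (a unit that is itself a repetition of a shorter string is
reported under the shorter unit instead).
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "RepeatAnnotation",
    "extract_context",
    "find_tandem_repeats",
    "canonical_tr_threshold",
    "classify_indel_context",
    "HR",
    "TR",
    "HR_NC",
    "TR_NC",
    "NONE",
]

HR = "HR"
TR = "TR"
HR_NC = "HR_NC"
TR_NC = "TR_NC"
NONE = "NONE"

MIN_HR_RUN = 6  # canonical homopolymer: run of six or more identical bases
MAX_UNIT = 50


def canonical_tr_threshold(unit_length: int) -> int:
    """Minimum copy number for a canonical tandem repeat: unit_length * 2 + 5."""
    if unit_length < 2:
        raise ValueError("tandem-repeat units are > 1 bp; unit length 1 is the HR domain")
    return unit_length * 2 + 5


@dataclass(frozen=True)
class RepeatAnnotation:
    """Repeat context of an indel within its extracted window."""

    klass: str
    unit: str | None = None
    copies: int = 0
    span: tuple[int, int] | None = None  # [start, end) in window coordinates


def extract_context(reference, chrom: str, pos: int, ref_allele: str, flank: int = 100):
    """Extract the window of ``flank`` bp around an indel's reference span.

    ``reference`` is a mapping of contig name to sequence (e.g. a
    ``pyfaidx.Fasta``).  ``pos`` is the 1-based position of the VCF record.
    Returns ``(window, offset)`` where ``offset`` is the 0-based index of the
    record's anchor base inside the window; the window is clipped at contig
    ends.
    """
    seq = str(reference[chrom][:])
    start0 = pos - 1
    if start0 < 0 or start0 >= len(seq):
        raise ValueError(f"{chrom}:{pos} outside contig (length {len(seq)})")
    lo = max(0, start0 - flank)
    hi = min(len(seq), start0 + len(ref_allele) + flank)
    return seq[lo:hi].upper(), start0 - lo


def _is_primitive(unit: str) -> bool:
    n = len(unit)
    for p in range(1, n):
        if n % p == 0 and unit == unit[:p] * (n // p):
            return False
    return True


def _min_rotation(unit: str) -> str:
    return min(unit[i:] + unit[:i] for i in range(len(unit)))


def find_tandem_repeats(window: str) -> list[tuple[str, int, tuple[int, int]]]:
    """All maximal exact tandem arrays in a window.

    Returns ``(unit, copies, (start, end))`` triples where ``unit`` is the
    minimal rotation of the primitive repeat unit, ``copies`` the whole-copy
    count and the span covers the full matched region (including a trailing
    partial copy).  Unit lengths run 1..50; mononucleotide arrays are
    reported only at six or more copies, longer units at two or more.
    Arrays contained in the span of a reported array with a shorter unit are
    suppressed.
    """
    window = window.upper()
    n = len(window)
    raw: list[tuple[int, str, int, tuple[int, int]]] = []  # (unit_len, unit, copies, span)
    for u in range(1, min(MAX_UNIT, n // 2) + 1):
        i = 0
        limit = n - u
        while i < limit:
            if window[i] != window[i + u]:
                i += 1
                continue
            j = i
            while j < limit and window[j] == window[j + u]:
                j += 1
            # matched run i..j-1 => repeated region [i, j + u)
            span = (i, j + u)
            length = span[1] - span[0]
            copies = length // u
            unit = window[i : i + u]
            min_copies = MIN_HR_RUN if u == 1 else 2
            if copies >= min_copies and _is_primitive(unit):
                raw.append((u, _min_rotation(unit), copies, span))
            i = j + 1
    raw.sort(key=lambda r: (r[0], r[3][0]))
    kept: list[tuple[str, int, tuple[int, int]]] = []
    kept_spans: list[tuple[int, int, int]] = []  # (unit_len, start, end)
    for u, unit, copies, span in raw:
        contained = any(
            ku < u and ks <= span[0] and span[1] <= ke for ku, ks, ke in kept_spans
        )
        if contained:
            continue
        kept.append((unit, copies, span))
        kept_spans.append((u, span[0], span[1]))
    return kept


def _indel_interval(offset: int, ref: str, alt: str) -> tuple[int, int, str]:
    """Window-coordinate interval intersected with repeat spans, plus indel seq.

    Deletions occupy the deleted reference bases; insertions are a point
    between the anchor base and the next, represented as the two flanking
    bases so that touching arrays count as overlapping.
    """
    if len(ref) == len(alt):
        raise ValueError("not an indel")
    if len(ref) > len(alt):  # deletion; VCF anchor base is shared
        seq = ref[len(alt):] if ref.startswith(alt) else ref[1:]
        start = offset + len(ref) - len(seq)
        return start, start + len(seq), seq.upper()
    seq = alt[len(ref):] if alt.startswith(ref) else alt[1:]
    return offset, offset + 2, seq.upper()


def classify_indel_context(
    window: str,
    offset: int,
    ref: str,
    alt: str,
    repeats: list[tuple[str, int, tuple[int, int]]] | None = None,
) -> RepeatAnnotation:
    """Classify an indel's repeat context from its flanking window.

    ``offset`` is the window index of the VCF anchor base.  ``repeats`` may
    carry externally produced (unit, copies, span) annotations (e.g. parsed
    from a Tandem Repeat Finder run) to substitute for the internal detector.
    """
    window = window.upper()
    if repeats is None:
        repeats = find_tandem_repeats(window)
    a, b, seq = _indel_interval(offset, ref, alt)
    overlapping = [r for r in repeats if r[2][0] < b and a < r[2][1]]

    def best(cands):
        return max(cands, key=lambda r: (r[2][1] - r[2][0], -len(r[0]), -r[2][0]))

    hr_hits = [r for r in overlapping if len(r[0]) == 1 and r[1] >= MIN_HR_RUN]
    hr_canon = [r for r in hr_hits if set(seq) == {r[0]}]
    if hr_canon:
        unit, copies, span = best(hr_canon)
        return RepeatAnnotation(HR, unit, copies, span)
    tr_hits = [r for r in overlapping if len(r[0]) > 1]
    tr_canon = [r for r in tr_hits if r[1] >= canonical_tr_threshold(len(r[0]))]
    if tr_canon:
        unit, copies, span = best(tr_canon)
        return RepeatAnnotation(TR, unit, copies, span)
    if hr_hits:
        unit, copies, span = best(hr_hits)
        return RepeatAnnotation(HR_NC, unit, copies, span)
    if tr_hits:
        unit, copies, span = best(tr_hits)
        return RepeatAnnotation(TR_NC, unit, copies, span)
    return RepeatAnnotation(NONE)


def annotate_vcf(vcf_path, fasta, out_path, flank: int = 100) -> int:
    """Annotate indels in a VCF with HR/TR context INFO keys; returns count."""
    import pysam

    with pysam.VariantFile(str(vcf_path)) as vf:
        header = vf.header.copy()
        for key in (HR, TR, HR_NC, TR_NC):
            if key not in header.info:
                header.info.add(key, 0, "Flag", f"Indel in {key} repeat context")
        if "RUNIT" not in header.info:
            header.info.add("RUNIT", 1, "String", "Repeat unit")
        if "RCOPIES" not in header.info:
            header.info.add("RCOPIES", 1, "Integer", "Repeat copy number")
        n_annotated = 0
        with pysam.VariantFile(str(out_path), "w", header=header) as out:
            for rec in vf:
                alts = rec.alts or ()
                if len(alts) == 1 and rec.ref and len(rec.ref) != len(alts[0]):
                    window, offset = extract_context(fasta, rec.chrom, rec.pos, rec.ref, flank)
                    ann = classify_indel_context(window, offset, rec.ref, alts[0])
                    new = out.header.new_record(
                        contig=rec.chrom, start=rec.start, alleles=rec.alleles
                    )
                    for s in rec.samples:
                        for k, v in rec.samples[s].items():
                            new.samples[s][k] = v
                    if ann.klass != NONE:
                        new.info[ann.klass] = True
                        new.info["RUNIT"] = ann.unit
                        new.info["RCOPIES"] = ann.copies
                        n_annotated += 1
                    out.write(new)
                else:
                    out.write(rec)
    return n_annotated
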