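"""Tallying Sanger-validation outcomes into per-class false discovery rates.

The FDR of a variant class is the number of invalidated calls over the
number of conclusively assayed calls (validated + invalidated); assays that
failed (no amplification, unreadable chromatogram) are excluded from the
denominator.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

__all__ = [
    "ValidationRecord",
    "VALIDATED",
    "INVALIDATED",
    "FAILED_ASSAY",
    "read_validation_table",
    "tally_fdr",
    "tally_all",
]

VALIDATED = "validated"
INVALIDATED = "invalidated"
FAILED_ASSAY = "failed_assay"
_OUTCOMES = {VALIDATED, INVALIDATED, FAILED_ASSAY}


@dataclass(frozen=True)
class ValidationRecord:
    """One assayed variant: its class label and the assay outcome."""

    chrom: str
    pos: int
    ref: str
    alt: str
    variant_class: str
    outcome: str

    def __post_init__(self) -> None:
        if self.outcome not in _OUTCOMES:
            raise ValueError(f"outcome must be one of {sorted(_OUTCOMES)}")


DEFAULT_COLUMNS = {
    "chrom": "chrom",
    "pos": "pos",
    "ref": "ref",
    "alt": "alt",
    "variant_class": "variant_class",
    "outcome": "outcome",
}


def read_validation_table(
    path: str | Path,
    column_map: dict[str, str] | None = None,
    outcome_map: dict[str, str] | None = None,
) -> tuple[list[ValidationRecord], int]:
    """Read a validation TSV into records.

    ``column_map`` maps the canonical field names to the table's column
    headers (a shim for externally produced spreadsheets); ``outcome_map``
    translates the table's outcome vocabulary onto
    validated/invalidated/failed_assay.  Returns ``(records, n_unmapped)``
    where unmapped rows (missing fields or untranslatable outcomes) are
    counted rather than raised.
    """
    columns = {**DEFAULT_COLUMNS, **(column_map or {})}
    df = pd.read_csv(path, sep="\t", dtype=str)
    records: list[ValidationRecord] = []
    unmapped = 0
    for _, row in df.iterrows():
        try:
            outcome = str(row[columns["outcome"]]).strip().lower()
            if outcome_map:
                outcome = outcome_map.get(outcome, outcome)
            rec = ValidationRecord(
                chrom=str(row[columns["chrom"]]),
                pos=int(row[columns["pos"]]),
                ref=str(row[columns["ref"]]),
                alt=str(row[columns["alt"]]),
                variant_class=str(row[columns["variant_class"]]).strip(),
                outcome=outcome,
            )
        except (KeyError, ValueError, TypeError):
            unmapped += 1
            continue
        records.append(rec)
    return records, unmapped


def tally_fdr(records, variant_class: str) -> tuple[int, int, float]:
    """FDR of one class: (assayed, invalidated, invalidated/assayed).

    Only conclusive assays count; raises if no record in the class has a
    conclusive outcome.
    """
    validated = invalidated = 0
    for rec in records:
        if rec.variant_class != variant_class:
            continue
        if rec.outcome == VALIDATED:
            validated += 1
        elif rec.outcome == INVALIDATED:
            invalidated += 1
    assayed = validated + invalidated
    if assayed == 0:
        raise ValueError(f"class {variant_class!r} has no conclusively assayed records")
    return assayed, invalidated, invalidated / assayed


def tally_all(records) -> pd.DataFrame:
    """Per-class tallies for every class present with a conclusive assay."""
    classes = sorted({r.variant_class for r in records})
    rows = []
    for cls in classes:
        try:
            assayed, invalidated, fdr = tally_fdr(records, cls)
        except ValueError:
            continue
        rows.append(
            {
                "variant_class": cls,
                "assayed": assayed,
                "invalidated": invalidated,
                "fdr": fdr,
                "fdr_display": round(fdr, 2),
            }
        )
    return pd.DataFrame(rows, columns=["variant_class", "assayed", "invalidated", "fdr", "fdr_display"])
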