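"""Mendelian-violation candidate calling and the quality-filter stack.

A candidate de novo mutation is a child heterozygote whose parents are both
confidently homozygous reference and whose variant is absent from every other
family in the cohort.  Candidates must additionally survive:

* a cohort-level *site filter* (strand-bias and read-position tests with
  known null distributions, thresholded on p-value), and
* per-individual *heterozygote* / *homozygote* filters on GQ, DP and the
  alt-supporting read count.

Surviving candidates are partitioned by allele balance into germline calls
(AB within the configured closed interval, default [0.3, 0.7]) and putative
somatic/mosaic candidates (outside it).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _stats
from .io import Cohort, Genotype, GenotypeObservation, SiteRecord, INDEL

__all__ = [
    "FilterConfig",
    "DeNovoCall",
    "SiteFilterResult",
    "site_filter",
    "site_filter_batch",
    "heterozygote_filter",
    "homozygote_filter",
    "mendelian_violation_candidate",
    "classify_allele_balance",
    "call_denovo",
    "GERMLINE",
    "SOMATIC",
]

GERMLINE = "germline"
SOMATIC = "somatic_candidate"


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds of the individual and site filters.

    Defaults are the published operating point: GQ>=50 for both individual
    filters, DP in the closed interval [10, 120], zero alt-supporting reads
    for the homozygote filter, allele balance in the closed interval
    [0.3, 0.7], and indels restricted to < 40 bp.
    """

    gq_min: int = 50
    dp_min: int = 10
    dp_max: int = 120
    hom_alt_reads_max: int = 0
    ab_lo: float = 0.3
    ab_hi: float = 0.7
    max_indel_len: int = 40
    site_test_alphas: dict = field(
        default_factory=lambda: {"strand_bias": 0.01, "read_position": 0.01}
    )

    def __post_init__(self) -> None:
        if not (0.0 <= self.ab_lo < self.ab_hi <= 1.0):
            raise ValueError("require 0 <= ab_lo < ab_hi <= 1")
        if self.dp_min > self.dp_max:
            raise ValueError("require dp_min <= dp_max")
        for name, alpha in self.site_test_alphas.items():
            if not (0.0 <= alpha < 1.0):
                raise ValueError(f"site test alpha {name} outside [0, 1)")


@dataclass(frozen=True)
class SiteFilterResult:
    passed: bool
    pvalues: dict


@dataclass(frozen=True)
class DeNovoCall:
    """A de novo call in one family, classified by allele balance."""

    family_id: str
    site_index: int
    chrom: str
    pos: int
    ref: str
    alt: str
    variant_type: str
    ab: float
    classification: str


# ---- individual filters --------------------------------------------------------


def heterozygote_filter(obs: GenotypeObservation, config: FilterConfig) -> bool:
    """True iff the call is a heterozygote passing GQ and DP bounds (inclusive)."""
    return (
        obs.gt == Genotype.HET
        and obs.gq >= config.gq_min
        and config.dp_min <= obs.dp <= config.dp_max
    )


def homozygote_filter(obs: GenotypeObservation, config: FilterConfig) -> bool:
    """True iff a confident hom-ref call: GQ/DP bounds plus AD2 <= hom_alt_reads_max."""
    return (
        obs.gt == Genotype.HOM_REF
        and obs.gq >= config.gq_min
        and config.dp_min <= obs.dp <= config.dp_max
        and obs.ad_alt <= config.hom_alt_reads_max
    )


def classify_allele_balance(ab: float | None, config: FilterConfig) -> str:
    """Partition a candidate by allele balance: germline inside [ab_lo, ab_hi]."""
    if ab is None:
        raise ValueError("allele balance undefined: no informative reads (uncallable)")
    return GERMLINE if config.ab_lo <= ab <= config.ab_hi else SOMATIC


# ---- site filter ---------------------------------------------------------------


def site_filter(site: SiteRecord, config: FilterConfig, cohort: Cohort | None = None) -> SiteFilterResult:
    """Apply the cohort-level tests to one site.

    Pass iff every configured test's p-value is >= its alpha.  Sites lacking
    the read-level inputs for a test pass that test with p = 1 (degenerate
    inputs are uninformative, not evidence against the site).
    """
    pvals: dict = {}
    stats = site.site_stats
    if "strand_bias" in config.site_test_alphas:
        if all(k in stats for k in ("srf", "srr", "saf", "sar")):
            p = _stats.strand_bias_pvalues(
                np.array([stats["srf"]]),
                np.array([stats["srr"]]),
                np.array([stats["saf"]]),
                np.array([stats["sar"]]),
            )[0]
        else:
            p = 1.0
        pvals["strand_bias"] = float(p)
    if "read_position" in config.site_test_alphas:
        av = stats.get("alt_pos")
        rv = stats.get("ref_pos")
        if av is not None and rv is not None and len(av) and len(rv):
            p = _stats.mann_whitney_pvalue(av, rv)
        else:
            p = 1.0
        pvals["read_position"] = float(p)
    passed = all(pvals[name] >= alpha for name, alpha in config.site_test_alphas.items())
    site.site_stats.update({f"{k}_p": v for k, v in pvals.items()})
    return SiteFilterResult(passed=passed, pvalues=pvals)


def site_filter_batch(
    cohort: Cohort, config: FilterConfig, indices: np.ndarray | None = None
) -> tuple[np.ndarray, dict]:
    """Vectorised site filter over (a subset of) a cohort's sites.

    Returns ``(pass_mask, pvalues)`` where ``pvalues`` maps test name to an
    array aligned with ``indices`` (default: all sites).
    """
    if indices is None:
        indices = np.arange(cohort.n_sites)
    indices = np.asarray(indices)
    n = len(indices)
    pvals: dict = {}
    if "strand_bias" in config.site_test_alphas:
        if "srf" in cohort.site_stats:
            pvals["strand_bias"] = _stats.strand_bias_pvalues(
                cohort.site_stats["srf"][indices],
                cohort.site_stats["srr"][indices],
                cohort.site_stats["saf"][indices],
                cohort.site_stats["sar"][indices],
            )
        else:
            pvals["strand_bias"] = np.ones(n)
    if "read_position" in config.site_test_alphas:
        if "alt_pos" in cohort.site_stats:
            alt_lists = [cohort.site_stats["alt_pos"][i] for i in indices]
            ref_lists = [cohort.site_stats["ref_pos"][i] for i in indices]
            pvals["read_position"] = _stats.mann_whitney_pvalues_batch(alt_lists, ref_lists)
        else:
            pvals["read_position"] = np.ones(n)
    mask = np.ones(n, dtype=bool)
    for name, alpha in config.site_test_alphas.items():
        mask &= pvals[name] >= alpha
    return mask, pvals


# ---- Mendelian violations ------------------------------------------------------


def mendelian_violation_candidate(
    site: SiteRecord, family, cohort: Cohort, config: FilterConfig | None = None
) -> bool:
    """True iff the site is a de novo candidate in this family.

    Requires: child called het and passing the heterozygote filter, both
    parents called hom-ref and passing the homozygote filter, and no sample
    outside the family carrying a non-hom-ref call at the site.  (Child
    hom-alt violations from two hom-ref parents are excluded: the
    callability model calibrates het calling only.)
    """
    config = config or FilterConfig()
    child = site.observation(family.child_id)
    father = site.observation(family.father_id)
    mother = site.observation(family.mother_id)
    if not heterozygote_filter(child, config):
        return False
    if not (homozygote_filter(father, config) and homozygote_filter(mother, config)):
        return False
    family_members = set(family.members)
    for obs in site.observations:
        if obs.sample_id in family_members:
            continue
        if obs.gt in (Genotype.HET, Genotype.HOM_ALT):
            return False
    return True


def call_denovo(cohort: Cohort, config: FilterConfig | None = None) -> list[DeNovoCall]:
    """Call and classify de novo SNVs and short indels across the cohort.

    Sites are screened with vectorised genotype masks; the (expensive) site
    tests run only on Mendelian-violation candidates, which cannot change the
    result since both screens must pass.  Indels with length >= 40 bp are
    excluded.  Returns one call per (family, site), classified as germline or
    somatic_candidate by the child's allele balance.
    """
    config = config or FilterConfig()
    if cohort.n_sites == 0:
        return []
    gt, gq, dp = cohort.gt, cohort.gq, cohort.dp
    ad_ref, ad_alt = cohort.ad_ref, cohort.ad_alt
    non_homref = (gt == int(Genotype.HET)) | (gt == int(Genotype.HOM_ALT))
    carriers_total = non_homref.sum(axis=1)

    lengths = (
        cohort.variants["ref"].str.len() - cohort.variants["alt"].str.len()
    ).abs().to_numpy()
    is_indel = (
        (cohort.variants["ref"].str.len() > 1) | (cohort.variants["alt"].str.len() > 1)
    ).to_numpy()
    length_ok = ~is_indel | (lengths < config.max_indel_len)

    het_ok = (
        (gt == int(Genotype.HET))
        & (gq >= config.gq_min)
        & (dp >= config.dp_min)
        & (dp <= config.dp_max)
    )
    hom_ok = (
        (gt == int(Genotype.HOM_REF))
        & (gq >= config.gq_min)
        & (dp >= config.dp_min)
        & (dp <= config.dp_max)
        & (ad_alt <= config.hom_alt_reads_max)
    )

    calls: list[DeNovoCall] = []
    candidate_rows: list[tuple[int, str]] = []
    for ped in cohort.pedigrees:
        ci, fi, mi = cohort.family_columns(ped)
        in_family = non_homref[:, ci] | non_homref[:, fi] | non_homref[:, mi]
        outside = carriers_total - (
            non_homref[:, ci].astype(np.int64)
            + non_homref[:, fi]
            + non_homref[:, mi]
        )
        mask = (
            het_ok[:, ci]
            & hom_ok[:, fi]
            & hom_ok[:, mi]
            & (outside == 0)
            & length_ok
        )
        for i in np.nonzero(mask)[0]:
            candidate_rows.append((int(i), ped.family_id))

    if not candidate_rows:
        return []
    cand_idx = np.array(sorted({i for i, _ in candidate_rows}))
    site_pass, _ = site_filter_batch(cohort, config, cand_idx)
    passed = {int(i) for i, ok in zip(cand_idx, site_pass) if ok}

    for i, family_id in candidate_rows:
        if i not in passed:
            continue
        ped = cohort.family(family_id)
        ci = cohort.sample_index[ped.child_id]
        total = int(ad_ref[i, ci] + ad_alt[i, ci])
        if total <= 0:
            continue  # uncallable allele balance despite a passing call
        ab = float(ad_alt[i, ci]) / total
        row = cohort.variants.iloc[i]
        vtype = INDEL if is_indel[i] else "SNV"
        calls.append(
            DeNovoCall(
                family_id=family_id,
                site_index=i,
                chrom=row["chrom"],
                pos=int(row["pos"]),
                ref=row["ref"],
                alt=row["alt"],
                variant_type=vtype,
                ab=ab,
                classification=classify_allele_balance(ab, config),
            )
        )
    return calls
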