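"""Depth-stratified callability calibration and mutation-rate estimation.

The rate denominator is probabilistic rather than a hard callable/uncallable
mask: for each family f and position x, the *callability* C_f(x) is the
probability that a true de novo mutation there would be called and survive
every filter.  Assuming the three family members are called independently,

    C_f(x) = C_het(d_child(x)) * C_hom(d_father(x)) * C_hom(d_mother(x)),

where the two conditional call probabilities are functions of depth,
estimated empirically from genotype classes whose truth is known from
Mendelian logic:

* ``C_het(d)``: at sites where one parent is confidently hom-ref and the
  other confidently hom-alt, the child must be heterozygous; the fraction of
  such children at depth d called het and passing the heterozygote filter.
* ``C_hom(d)``: at sites where both parents of a family are confidently
  hom-ref, the variant is carried by another family and (for SNVs) is a
  known polymorphism, the children must be hom-ref; the fraction called
  hom-ref and passing the homozygote filter.

The family rate is N_f / (2 * (1 - alpha_site) * sum_x C_f(x)) — diploid
site-generations, discounted by the site filter's expected false-rejection
fraction alpha_site — with exact (Garwood) Poisson confidence intervals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import chi2

from .filters import FilterConfig, site_filter_batch
from .io import Cohort, DepthHistogram, Genotype

__all__ = [
    "CallabilityTable",
    "SiteFilterLoss",
    "RateEstimate",
    "PaternalAgeModel",
    "calibrate_het_callability",
    "calibrate_homref_callability",
    "family_site_callability",
    "expected_callable_sites",
    "alpha_site_from_config",
    "poisson_rate_ci",
    "estimate_rate",
    "paternal_age_fit",
    "estimate_denovo_rate",
]

HET_CHILD = "het_child"
HOMREF_PARENT = "homref_parent"


class CallabilityTable:
    """Per-depth P(correct, retained call | true genotype) with raw counts.

    Depth bins with fewer than ``min_trials`` observations are pooled with
    their nearest neighbours outward (ties broken toward lower depth) until
    the threshold is met; queries outside the calibrated range clamp to the
    nearest observed depth and pool from there.
    """

    def __init__(
        self,
        role: str,
        successes: dict[int, int],
        trials: dict[int, int],
        min_trials: int = 100,
    ) -> None:
        if role not in (HET_CHILD, HOMREF_PARENT):
            raise ValueError(f"unknown role {role!r}")
        if not trials or sum(trials.values()) == 0:
            raise ValueError("no calibration observations: calibration impossible")
        self.role = role
        self.min_trials = int(min_trials)
        depths = np.array(sorted(trials), dtype=np.int64)
        self._depths = depths
        self._succ = np.array([successes.get(int(d), 0) for d in depths], dtype=np.int64)
        self._tri = np.array([trials[int(d)] for d in depths], dtype=np.int64)
        if np.any(self._succ > self._tri):
            raise ValueError("successes exceed trials")
        self._cache: dict[int, float] = {}

    @property
    def successes(self) -> dict[int, int]:
        return dict(zip(self._depths.tolist(), self._succ.tolist()))

    @property
    def trials(self) -> dict[int, int]:
        return dict(zip(self._depths.tolist(), self._tri.tolist()))

    def estimate(self, depth: int) -> float:
        """Pooled callability estimate at a depth (always in [0, 1])."""
        depth = int(depth)
        if depth in self._cache:
            return self._cache[depth]
        d = self._depths
        # clamp to the calibrated range
        target = min(max(depth, int(d[0])), int(d[-1]))
        # start from the nearest observed depth
        j = int(np.searchsorted(d, target))
        if j == len(d) or (j > 0 and target - d[j - 1] <= d[j] - target):
            j -= 1
        lo = hi = j
        succ = int(self._succ[j])
        tri = int(self._tri[j])
        while tri < self.min_trials and (lo > 0 or hi < len(d) - 1):
            left_gap = target - d[lo - 1] if lo > 0 else math.inf
            right_gap = d[hi + 1] - target if hi < len(d) - 1 else math.inf
            if left_gap <= right_gap:
                lo -= 1
                succ += int(self._succ[lo])
                tri += int(self._tri[lo])
            else:
                hi += 1
                succ += int(self._succ[hi])
                tri += int(self._tri[hi])
        est = succ / tri
        self._cache[depth] = est
        return est

    def estimates(self, depths: np.ndarray) -> np.ndarray:
        """Vectorised pooled estimates for an array of depths."""
        depths = np.asarray(depths, dtype=np.int64)
        if depths.size == 0:
            return np.zeros(depths.shape)
        lo = min(int(depths.min()), int(self._depths[0]))
        hi = max(int(depths.max()), int(self._depths[-1]))
        table = np.array([self.estimate(d) for d in range(lo, hi + 1)])
        return table[depths - lo]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "role": self.role,
                "depth": self._depths,
                "successes": self._succ,
                "trials": self._tri,
                "estimate": self._succ / np.maximum(self._tri, 1),
            }
        )


@dataclass(frozen=True)
class SiteFilterLoss:
    """Expected fraction of good sites rejected by the site filter."""

    alpha_site: float
    per_test_alphas: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.alpha_site < 1.0):
            raise ValueError("alpha_site must be in [0, 1)")


def alpha_site_from_config(site_test_alphas: dict | FilterConfig) -> SiteFilterLoss:
    """Combine per-test alphas assuming independent tests: 1 - prod(1 - a_k)."""
    if isinstance(site_test_alphas, FilterConfig):
        site_test_alphas = site_test_alphas.site_test_alphas
    alpha = 1.0
    for a in site_test_alphas.values():
        if not (0.0 <= a < 1.0):
            raise ValueError("per-test alphas must be in [0, 1)")
        alpha *= 1.0 - a
    return SiteFilterLoss(alpha_site=1.0 - alpha, per_test_alphas=dict(site_test_alphas))


# ---- calibration ---------------------------------------------------------------


def _variant_type_mask(cohort: Cohort, variant_type: str | None) -> np.ndarray:
    is_indel = (
        (cohort.variants["ref"].str.len() > 1) | (cohort.variants["alt"].str.len() > 1)
    ).to_numpy()
    if variant_type is None:
        return np.ones(cohort.n_sites, dtype=bool)
    if variant_type == "SNV":
        return ~is_indel
    if variant_type == "indel":
        return is_indel
    raise ValueError(f"unknown variant type {variant_type!r}")


def calibrate_het_callability(
    cohort: Cohort,
    config: FilterConfig | None = None,
    variant_type: str | None = "SNV",
    min_trials: int = 100,
    site_pass: np.ndarray | None = None,
) -> CallabilityTable:
    """Estimate C_het(d) from opposite-homozygote parent pairs.

    At site-filter-passing sites where one parent is hom-ref and the other
    hom-alt (both with GQ >= gq_min), the child is truly heterozygous; the
    per-depth estimate is the fraction of such children called het and
    passing the heterozygote filter.
    """
    config = config or FilterConfig()
    if site_pass is None:
        site_pass, _ = site_filter_batch(cohort, config)
    keep = site_pass & _variant_type_mask(cohort, variant_type)

    gt, gq, dp = cohort.gt, cohort.gq, cohort.dp
    successes: dict[int, int] = {}
    trials: dict[int, int] = {}
    for ped in cohort.pedigrees:
        ci, fi, mi = cohort.family_columns(ped)
        conf = gq >= config.gq_min
        f_hr = (gt[:, fi] == 0) & conf[:, fi]
        f_ha = (gt[:, fi] == 2) & conf[:, fi]
        m_hr = (gt[:, mi] == 0) & conf[:, mi]
        m_ha = (gt[:, mi] == 2) & conf[:, mi]
        qualifying = keep & ((f_hr & m_ha) | (f_ha & m_hr))
        if not qualifying.any():
            continue
        d = dp[qualifying, ci]
        ok = (
            (gt[qualifying, ci] == 1)
            & (gq[qualifying, ci] >= config.gq_min)
            & (dp[qualifying, ci] >= config.dp_min)
            & (dp[qualifying, ci] <= config.dp_max)
        )
        for depth, success in zip(d.tolist(), ok.tolist()):
            trials[depth] = trials.get(depth, 0) + 1
            if success:
                successes[depth] = successes.get(depth, 0) + 1
    return CallabilityTable(HET_CHILD, successes, trials, min_trials=min_trials)


def calibrate_homref_callability(
    cohort: Cohort,
    config: FilterConfig | None = None,
    variant_type: str | None = "SNV",
    min_trials: int = 100,
    children_only: bool = True,
    site_pass: np.ndarray | None = None,
) -> CallabilityTable:
    """Estimate C_hom(d) from families whose parents are both hom-ref.

    Qualifying observations: individuals (children by default) in families
    where both parents are confidently hom-ref, at site-filter-passing sites
    carried by at least one other family; SNV sites must additionally be in
    the known-variants list.  The per-depth estimate is the fraction called
    hom-ref and passing the homozygote filter.
    """
    config = config or FilterConfig()
    if site_pass is None:
        site_pass, _ = site_filter_batch(cohort, config)
    keep = site_pass & _variant_type_mask(cohort, variant_type)
    known = cohort.variants["known"].to_numpy(dtype=bool)
    is_snv = _variant_type_mask(cohort, "SNV")
    keep = keep & (~is_snv | known)  # dbSNP requirement applies to SNVs only

    gt, gq, dp = cohort.gt, cohort.gq, cohort.dp
    ad_alt = cohort.ad_alt
    non_homref = (gt == 1) | (gt == 2)
    carriers_total = non_homref.sum(axis=1)

    successes: dict[int, int] = {}
    trials: dict[int, int] = {}
    for ped in cohort.pedigrees:
        ci, fi, mi = cohort.family_columns(ped)
        conf = gq >= config.gq_min
        parents_hr = (gt[:, fi] == 0) & conf[:, fi] & (gt[:, mi] == 0) & conf[:, mi]
        in_family = (
            non_homref[:, ci].astype(np.int64) + non_homref[:, fi] + non_homref[:, mi]
        )
        carried_elsewhere = (carriers_total - in_family) > 0
        qualifying = keep & parents_hr & carried_elsewhere
        if not qualifying.any():
            continue
        columns = [ci] if children_only else [ci, fi, mi]
        for col in columns:
            if col != ci and not children_only:
                # parents qualify only as truly hom-ref, which they are by
                # construction here (both confidently hom-ref).
                pass
            d = dp[qualifying, col]
            ok = (
                (gt[qualifying, col] == 0)
                & (gq[qualifying, col] >= config.gq_min)
                & (dp[qualifying, col] >= config.dp_min)
                & (dp[qualifying, col] <= config.dp_max)
                & (ad_alt[qualifying, col] <= config.hom_alt_reads_max)
            )
            for depth, success in zip(d.tolist(), ok.tolist()):
                trials[depth] = trials.get(depth, 0) + 1
                if success:
                    successes[depth] = successes.get(depth, 0) + 1
    return CallabilityTable(HOMREF_PARENT, successes, trials, min_trials=min_trials)


def family_site_callability(c_het_child: float, c_hom_father: float, c_hom_mother: float) -> float:
    """C_f(x) as the product of the three per-member call probabilities."""
    for p in (c_het_child, c_hom_father, c_hom_mother):
        if not (0.0 <= p <= 1.0):
            raise ValueError("callability factors must lie in [0, 1]")
    return c_het_child * c_hom_father * c_hom_mother


def expected_callable_sites(
    depth_histogram: DepthHistogram,
    het_table: CallabilityTable,
    homref_table: CallabilityTable,
) -> float:
    """Sum of C_f(x) over all positions, computed from the joint depth histogram."""
    if depth_histogram.total_positions == 0:
        return 0.0
    c_het = het_table.estimates(depth_histogram.d_child)
    c_f = homref_table.estimates(depth_histogram.d_father)
    c_m = homref_table.estimates(depth_histogram.d_mother)
    return float(np.sum(depth_histogram.counts * c_het * c_f * c_m))


# ---- rate estimation -----------------------------------------------------------


def poisson_rate_ci(n: int, denominator: float, level: float = 0.95) -> tuple[float, float]:
    """Exact (Garwood) chi-square confidence interval for a Poisson rate.

    lo = qchisq((1-level)/2, 2n)/2 / denominator (0 when n = 0);
    hi = qchisq(1-(1-level)/2, 2n+2)/2 / denominator.
    """
    if n < 0:
        raise ValueError("count must be non-negative")
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    a = 1.0 - level
    lo = 0.0 if n == 0 else chi2.ppf(a / 2.0, 2 * n) / 2.0 / denominator
    hi = chi2.ppf(1.0 - a / 2.0, 2 * n + 2) / 2.0 / denominator
    return float(lo), float(hi)


@dataclass(frozen=True)
class RateEstimate:
    """A Poisson rate with its effective diploid denominator and exact CI."""

    scope: str
    n_mutations: int
    effective_denominator: float
    rate: float
    ci_lo: float
    ci_hi: float
    alpha_site: float
    per_family: pd.DataFrame | None = None


def estimate_rate(
    n_mutations_per_family: dict[str, int],
    callable_per_family: dict[str, float],
    alpha_site: float | SiteFilterLoss = 0.0,
    level: float = 0.95,
) -> RateEstimate:
    """Pooled mutation rate with per-family breakdown.

    Each family's effective denominator is 2 * (1 - alpha_site) * sum_x C_f(x)
    diploid site-generations; the pooled rate is the total count over the
    total denominator (not the mean of family rates).
    """
    if isinstance(alpha_site, SiteFilterLoss):
        alpha_site = alpha_site.alpha_site
    rows = []
    total_n = 0
    total_denom = 0.0
    for fam, callable_sites in callable_per_family.items():
        if callable_sites <= 0:
            raise ValueError(f"family {fam}: callable site sum must be positive")
        n = int(n_mutations_per_family.get(fam, 0))
        denom = 2.0 * (1.0 - alpha_site) * callable_sites
        lo, hi = poisson_rate_ci(n, denom, level)
        rows.append(
            {
                "family_id": fam,
                "n_mutations": n,
                "denominator": denom,
                "rate": n / denom,
                "ci_lo": lo,
                "ci_hi": hi,
            }
        )
        total_n += n
        total_denom += denom
    per_family = pd.DataFrame(rows)
    lo, hi = poisson_rate_ci(total_n, total_denom, level)
    return RateEstimate(
        scope="pooled",
        n_mutations=total_n,
        effective_denominator=total_denom,
        rate=total_n / total_denom,
        ci_lo=lo,
        ci_hi=hi,
        alpha_site=float(alpha_site),
        per_family=per_family,
    )


@dataclass(frozen=True)
class PaternalAgeModel:
    """OLS fit of per-family mutation rate on the father's age at birth."""

    slope: float  # extra mutations per nucleotide per year
    intercept: float
    slope_se: float
    intercept_se: float
    p_value: float
    n_families: int


def paternal_age_fit(
    per_family_rates,
    father_ages,
    weights=None,
) -> PaternalAgeModel:
    """Fit rate = intercept + slope * age by (optionally weighted) least squares.

    Requires >= 2 families and non-constant ages; a slope p-value is reported
    only with >= 3 families.
    """
    rates = np.asarray(per_family_rates, dtype=float)
    ages = np.asarray(father_ages, dtype=float)
    if len(rates) != len(ages) or len(rates) < 2:
        raise ValueError("need matched rates and ages for at least 2 families")
    if np.allclose(ages, ages[0]):
        raise ValueError("all father ages identical: slope unidentifiable")
    X = sm.add_constant(ages)
    if weights is None:
        fit = sm.OLS(rates, X).fit()
    else:
        fit = sm.WLS(rates, X, weights=np.asarray(weights, dtype=float)).fit()
    n = len(rates)
    p_value = float(fit.pvalues[1]) if n >= 3 else float("nan")
    slope_se = float(fit.bse[1]) if n >= 3 else float("nan")
    intercept_se = float(fit.bse[0]) if n >= 3 else float("nan")
    return PaternalAgeModel(
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        slope_se=slope_se,
        intercept_se=intercept_se,
        p_value=p_value,
        n_families=n,
    )


# ---- end-to-end convenience ----------------------------------------------------


def estimate_denovo_rate(
    cohort: Cohort,
    depth_histograms: dict[str, DepthHistogram],
    config: FilterConfig | None = None,
    variant_type: str = "SNV",
    min_trials: int = 100,
    calls=None,
    with_age_model: bool = True,
) -> tuple[RateEstimate, PaternalAgeModel | None]:
    """Run the full pipeline: call, calibrate, sum callability, estimate.

    ``depth_histograms`` maps family_id to that family's joint depth
    histogram.  The numerator counts germline-classified calls of the
    requested variant type.  Indel callability is calibrated on indel sites
    without the known-variants requirement applied to SNVs.
    """
    from .filters import GERMLINE, call_denovo

    config = config or FilterConfig()
    if calls is None:
        calls = call_denovo(cohort, config)
    counts: dict[str, int] = {ped.family_id: 0 for ped in cohort.pedigrees}
    for call in calls:
        if call.classification == GERMLINE and call.variant_type == variant_type:
            counts[call.family_id] += 1

    site_pass, _ = site_filter_batch(cohort, config)
    het_tab = calibrate_het_callability(
        cohort, config, variant_type=variant_type, min_trials=min_trials, site_pass=site_pass
    )
    hom_tab = calibrate_homref_callability(
        cohort, config, variant_type=variant_type, min_trials=min_trials, site_pass=site_pass
    )
    callable_per_family = {
        ped.family_id: expected_callable_sites(
            depth_histograms[ped.family_id], het_tab, hom_tab
        )
        for ped in cohort.pedigrees
    }
    loss = alpha_site_from_config(config)
    estimate = estimate_rate(counts, callable_per_family, loss)

    age_model = None
    if with_age_model:
        ages = [ped.father_age_at_birth for ped in cohort.pedigrees]
        if all(a is not None for a in ages) and len(set(ages)) > 1:
            fam_rates = (
                estimate.per_family.set_index("family_id")["rate"]
                .reindex([p.family_id for p in cohort.pedigrees])
                .to_numpy()
            )
            age_model = paternal_age_fit(fam_rates, np.asarray(ages, dtype=float))
    return estimate, age_model
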