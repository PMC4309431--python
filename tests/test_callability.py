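"""Callability calibration, the rate denominator and Poisson-rate inference."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import poisson

from denovorate.callability import (
    HET_CHILD,
    HOMREF_PARENT,
    CallabilityTable,
    alpha_site_from_config,
    calibrate_het_callability,
    calibrate_homref_callability,
    estimate_rate,
    expected_callable_sites,
    family_site_callability,
    paternal_age_fit,
    poisson_rate_ci,
)
from denovorate.filters import FilterConfig
from denovorate.io import DepthHistogram

CFG = FilterConfig(site_test_alphas={})


# ---- het-callability calibration -----------------------------------------------


def _het_calibration_cohort(cohort_factory, child_states, dp_child=30, gq_child=99):
    """One family per qualifying observation: father hom-ref, mother hom-alt."""
    n = len(child_states)
    gt = np.zeros((n, 3), dtype=np.int8)
    gt[:, 1] = 0
    gt[:, 2] = 2
    gt[:, 0] = child_states
    dp = np.full((n, 3), 40)
    dp[:, 0] = dp_child
    gq = np.full((n, 3), 99)
    gq[:, 0] = gq_child
    return cohort_factory(gt, dp=dp, gq=gq)


def test_het_calibration_all_pass(cohort_factory):
    cohort = _het_calibration_cohort(cohort_factory, [1, 1, 1, 1])
    table = calibrate_het_callability(cohort, CFG, min_trials=1)
    assert table.estimate(30) == 1.0


def test_het_calibration_half_pass(cohort_factory):
    # two children called het, one miscalled hom-ref, one missing
    cohort = _het_calibration_cohort(cohort_factory, [1, 1, 0, -1])
    table = calibrate_het_callability(cohort, CFG, min_trials=1)
    assert table.estimate(30) == 0.5


def test_het_calibration_requires_confident_parents(cohort_factory):
    gt = np.array([[1, 0, 2]], dtype=np.int8)
    gq = np.array([[99, 40, 99]])  # father below the conservative GQ cut
    cohort = cohort_factory(gt, gq=gq)
    with pytest.raises(ValueError, match="calibration impossible"):
        calibrate_het_callability(cohort, CFG, min_trials=1)


def test_pooling_merges_sparse_bins_to_weighted_mean():
    successes = {10: 5, 11: 0, 12: 10}
    trials = {10: 10, 11: 10, 12: 10}
    table = CallabilityTable(HET_CHILD, successes, trials, min_trials=25)
    # every query pools all three bins: (5+0+10)/30
    for d in (5, 10, 11, 12, 40):
        assert table.estimate(d) == pytest.approx(15 / 30)
    # with min_trials=10 each bin stands alone and out-of-range clamps
    solo = CallabilityTable(HET_CHILD, successes, trials, min_trials=10)
    assert solo.estimate(11) == 0.0
    assert solo.estimate(5) == 0.5  # clamped to depth 10
    assert solo.estimate(40) == 1.0  # clamped to depth 12


def test_pooling_expands_outward_nearest_first():
    successes = {10: 0, 20: 10, 21: 2}
    trials = {10: 10, 20: 10, 21: 10}
    table = CallabilityTable(HET_CHILD, successes, trials, min_trials=20)
    # at depth 21, the nearest extra bin is 20 (gap 1) not 10 (gap 11)
    assert table.estimate(21) == pytest.approx(12 / 20)


# ---- hom-ref calibration -------------------------------------------------------


def _homref_cohort(cohort_factory, child_ad_alt=0, known=True, carrier_family=True):
    # F0: parents hom-ref + child hom-ref (the measured obs);
    # F1: carrier family (child het) making the variant "present elsewhere".
    gt = np.array([[0, 0, 0, 1 if carrier_family else 0, 0, 0]], dtype=np.int8)
    ad_alt = np.array([[child_ad_alt, 0, 0, 15, 0, 0]])
    return cohort_factory(gt, ad_alt=ad_alt, known=known)


def test_homref_calibration_counts_clean_children(cohort_factory):
    table = calibrate_homref_callability(
        _homref_cohort(cohort_factory), CFG, min_trials=1
    )
    assert table.estimate(30) == 1.0


def test_homref_calibration_single_alt_read_fails_ad2(cohort_factory):
    table = calibrate_homref_callability(
        _homref_cohort(cohort_factory, child_ad_alt=1), CFG, min_trials=1
    )
    assert table.estimate(30) == 0.0  # 1 trial, failing AD2=0


def test_homref_calibration_requires_known_snv_and_other_carrier(cohort_factory):
    with pytest.raises(ValueError, match="calibration impossible"):
        calibrate_homref_callability(
            _homref_cohort(cohort_factory, known=False), CFG, min_trials=1
        )
    with pytest.raises(ValueError, match="calibration impossible"):
        calibrate_homref_callability(
            _homref_cohort(cohort_factory, carrier_family=False), CFG, min_trials=1
        )


def test_homref_indel_calibration_skips_dbsnp_requirement(cohort_factory):
    variants = pd.DataFrame(
        {"chrom": "chr1", "pos": [100], "ref": ["AT"], "alt": ["A"], "known": False}
    )
    gt = np.array([[0, 0, 0, 1, 0, 0]], dtype=np.int8)
    cohort = cohort_factory(gt, variants=variants)
    table = calibrate_homref_callability(cohort, CFG, variant_type="indel", min_trials=1)
    assert table.estimate(30) == 1.0


# ---- callability product and denominator ---------------------------------------


def test_family_site_callability_is_product():
    assert family_site_callability(0.9, 0.8, 0.7) == pytest.approx(0.504)
    assert family_site_callability(0.9, 0.0, 0.7) == 0.0
    assert family_site_callability(1, 1, 1) == 1.0
    with pytest.raises(ValueError):
        family_site_callability(1.2, 0.5, 0.5)


def _uniform_table(role, value, depth=30):
    n = 1000
    return CallabilityTable(role, {depth: int(value * n)}, {depth: n}, min_trials=1)


def test_expected_callable_sites_uniform_depth():
    het = _uniform_table(HET_CHILD, 0.9)
    hom = _uniform_table(HOMREF_PARENT, 0.8)
    hist = DepthHistogram(np.array([30]), np.array([30]), np.array([30]), np.array([1000]))
    assert expected_callable_sites(hist, het, hom) == pytest.approx(1000 * 0.9 * 0.8 * 0.8)


def test_expected_callable_sites_empty_histogram():
    het = _uniform_table(HET_CHILD, 0.9)
    hom = _uniform_table(HOMREF_PARENT, 0.8)
    empty = DepthHistogram(*[np.empty(0, dtype=int)] * 4)
    assert expected_callable_sites(empty, het, hom) == 0.0


def test_expected_callable_sites_matches_per_position_brute_force():
    rng = np.random.default_rng(7)
    succ_h = {d: int(v) for d, v in zip(range(10, 40), rng.integers(100, 200, 30))}
    tri_h = {d: 200 for d in range(10, 40)}
    het = CallabilityTable(HET_CHILD, succ_h, tri_h, min_trials=1)
    succ_o = {d: int(v) for d, v in zip(range(10, 40), rng.integers(150, 200, 30))}
    hom = CallabilityTable(HOMREF_PARENT, succ_o, tri_h, min_trials=1)
    positions = rng.integers(10, 40, size=(500, 3))
    hist = DepthHistogram.from_positions(positions[:, 0], positions[:, 1], positions[:, 2])
    brute = sum(
        het.estimate(c) * hom.estimate(f) * hom.estimate(m) for c, f, m in positions
    )
    assert expected_callable_sites(hist, het, hom) == pytest.approx(brute, rel=1e-9)


def test_all_estimates_lie_in_unit_interval():
    rng = np.random.default_rng(13)
    trials = {d: int(t) for d, t in zip(range(50), rng.integers(1, 50, 50))}
    succ = {d: int(rng.integers(0, trials[d] + 1)) for d in trials}
    table = CallabilityTable(HET_CHILD, succ, trials, min_trials=30)
    for d in range(-5, 60):
        assert 0.0 <= table.estimate(d) <= 1.0


# ---- alpha_site ----------------------------------------------------------------


def test_alpha_site_independence_product():
    assert alpha_site_from_config({"a": 0.0, "b": 0.0}).alpha_site == 0.0
    assert alpha_site_from_config({"a": 0.01, "b": 0.01}).alpha_site == pytest.approx(
        0.0199
    )
    assert alpha_site_from_config({"a": 0.05}).alpha_site == pytest.approx(0.05)


# ---- rate estimation -----------------------------------------------------------


def test_estimate_rate_basic_identity():
    est = estimate_rate({"F0": 2}, {"F0": 1e8}, alpha_site=0.0)
    assert est.rate == pytest.approx(2 / (2 * 1e8))
    assert est.ci_lo <= est.rate <= est.ci_hi


def test_doubling_denominators_halves_pooled_rate():
    n = {"F0": 3, "F1": 5}
    call = {"F0": 1e7, "F1": 2e7}
    est1 = estimate_rate(n, call)
    est2 = estimate_rate(n, {f: 2 * v for f, v in call.items()})
    assert est2.rate == pytest.approx(est1.rate / 2)


def test_alpha_site_inflates_rate():
    est0 = estimate_rate({"F0": 10}, {"F0": 1e8}, alpha_site=0.0)
    est = estimate_rate({"F0": 10}, {"F0": 1e8}, alpha_site=0.02)
    assert est.rate == pytest.approx(est0.rate / 0.98)


def test_zero_callable_sites_is_fatal():
    with pytest.raises(ValueError, match="positive"):
        estimate_rate({"F0": 1}, {"F0": 0.0})


def test_poisson_ci_zero_count_lower_bound():
    lo, hi = poisson_rate_ci(0, 1e6)
    assert lo == 0.0 and hi > 0


def test_poisson_ci_matches_cdf_inversion():
    """Garwood bounds equal brute-force inversion of the Poisson tails."""

    def invert(n):
        # lo: largest mu with P(X >= n | mu) = 0.025 ; hi: P(X <= n) = 0.025
        def bisect(f, lo, hi):
            for _ in range(200):
                mid = 0.5 * (lo + hi)
                if f(mid) > 0:
                    hi = mid
                else:
                    lo = mid
            return 0.5 * (lo + hi)

        lo_mu = 0.0 if n == 0 else bisect(lambda mu: poisson.sf(n - 1, mu) - 0.025, 0, 100)
        hi_mu = bisect(lambda mu: -(poisson.cdf(n, mu) - 0.025), max(n, 1e-9), 200)
        return lo_mu, hi_mu

    for n in (0, 1, 10):
        lo, hi = poisson_rate_ci(n, 1.0)
        exp_lo, exp_hi = invert(n)
        assert lo == pytest.approx(exp_lo, abs=1e-6)
        assert hi == pytest.approx(exp_hi, abs=1e-6)


# ---- paternal age --------------------------------------------------------------


def test_age_fit_flat_rates_give_zero_slope():
    model = paternal_age_fit([2e-8, 2e-8, 2e-8, 2e-8], [20, 25, 30, 35])
    assert model.slope == pytest.approx(0.0, abs=1e-24)


def test_age_fit_two_point_line():
    model = paternal_age_fit([1e-8, 2e-8], [20, 40])
    assert model.slope == pytest.approx(5e-10)
    assert np.isnan(model.p_value)  # inference needs >= 3 families


def test_age_fit_identical_ages_fatal():
    with pytest.raises(ValueError, match="unidentifiable"):
        paternal_age_fit([1e-8, 2e-8], [30, 30])


def test_age_fit_recovers_planted_slope():
    rng = np.random.default_rng(41)
    ages = np.linspace(20, 40, 12)
    slope = 4e-10
    recovered = []
    for _ in range(20):
        rates = 1e-8 + slope * (ages - 28) + rng.normal(0, 1e-9, size=len(ages))
        model = paternal_age_fit(rates, ages)
        recovered.append(model.slope)
        assert abs(model.slope - slope) < 3 * model.slope_se
    assert np.mean(recovered) == pytest.approx(slope, rel=0.25)
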