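"""Individual/site filters, Mendelian-violation candidates and classification."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from denovorate import _stats
from denovorate.filters import (
    GERMLINE,
    SOMATIC,
    FilterConfig,
    call_denovo,
    classify_allele_balance,
    heterozygote_filter,
    homozygote_filter,
    mendelian_violation_candidate,
    site_filter,
)
from denovorate.io import Genotype, GenotypeObservation


def obs(gt, gq=99, dp=30, ad=(15, 15), sample="s"):
    return GenotypeObservation(sample, Genotype(gt), gq, dp, ad[0], ad[1])


# ---- individual filters --------------------------------------------------------


@pytest.mark.parametrize(
    "o,expected",
    [
        (obs(1, gq=50, dp=10), True),  # thresholds are inclusive
        (obs(1, gq=50, dp=120), True),
        (obs(1, gq=49, dp=30), False),
        (obs(1, gq=99, dp=121), False),
        (obs(1, gq=99, dp=9), False),
        (obs(0, gq=99, dp=30), False),  # not a het call
        (obs(-1, gq=0, dp=0, ad=(0, 0)), False),  # missing is uncallable
    ],
)
def test_heterozygote_filter_boundaries(o, expected):
    assert heterozygote_filter(o, FilterConfig()) is expected


@pytest.mark.parametrize(
    "o,expected",
    [
        (obs(0, gq=60, dp=30, ad=(30, 0)), True),
        (obs(0, gq=60, dp=30, ad=(29, 1)), False),  # any alt-supporting read fails
        (obs(0, gq=60, dp=9, ad=(9, 0)), False),
        (obs(0, gq=49, dp=30, ad=(30, 0)), False),
        (obs(1, gq=99, dp=30), False),
        (obs(-1, gq=0, dp=0, ad=(0, 0)), False),
    ],
)
def test_homozygote_filter_boundaries(o, expected):
    assert homozygote_filter(o, FilterConfig()) is expected


@pytest.mark.parametrize(
    "ab,expected",
    [
        (0.50, GERMLINE),
        (0.18, SOMATIC),
        (0.30, GERMLINE),  # closed interval endpoints
        (0.70, GERMLINE),
        (0.299, SOMATIC),
        (0.85, SOMATIC),
    ],
)
def test_allele_balance_classification(ab, expected):
    assert classify_allele_balance(ab, FilterConfig()) == expected


def test_undefined_allele_balance_is_uncallable():
    with pytest.raises(ValueError, match="uncallable"):
        classify_allele_balance(None, FilterConfig())


def test_filter_config_validation():
    with pytest.raises(ValueError):
        FilterConfig(ab_lo=0.7, ab_hi=0.3)
    with pytest.raises(ValueError):
        FilterConfig(dp_min=50, dp_max=10)


# ---- site filter and its exact nulls -------------------------------------------


def fisher_oracle(srf, srr, saf, sar):
    """Two-sided conditional test by direct enumeration of 2x2 tables."""
    N = srf + srr + saf + sar
    K = saf + sar  # alt reads
    n = srf + saf  # forward reads

    def prob(a):
        return (
            math.comb(K, a) * math.comb(N - K, n - a) / math.comb(N, n)
        )

    p_obs = prob(saf)
    total = 0.0
    for a in range(max(0, K + n - N), min(K, n) + 1):
        p = prob(a)
        if p <= p_obs * (1 + 1e-7):
            total += p
    return min(1.0, total)


def test_site_filter_all_alt_reads_on_one_strand_fails():
    # 20/20 ref reads by strand but all 10 alt reads forward: strand bias.
    stats = {"srf": 20, "srr": 20, "saf": 10, "sar": 0}
    from denovorate.io import SiteRecord

    site = SiteRecord("chr1", 100, "A", "C", site_stats=dict(stats))
    cfg = FilterConfig(site_test_alphas={"strand_bias": 0.05})
    result = site_filter(site, cfg)
    expected_p = fisher_oracle(**stats)
    assert expected_p < 0.05
    assert result.pvalues["strand_bias"] == pytest.approx(expected_p, rel=1e-9)
    assert not result.passed


def test_site_filter_balanced_site_passes():
    from denovorate.io import SiteRecord

    rng = np.random.default_rng(5)
    site = SiteRecord(
        "chr1",
        100,
        "A",
        "C",
        site_stats={
            "srf": 20,
            "srr": 20,
            "saf": 10,
            "sar": 10,
            "alt_pos": rng.integers(40, 61, size=10),
            "ref_pos": rng.integers(40, 61, size=16),
        },
    )
    cfg = FilterConfig(site_test_alphas={"strand_bias": 0.05, "read_position": 0.05})
    result = site_filter(site, cfg)
    assert result.passed
    assert result.pvalues["strand_bias"] == pytest.approx(
        fisher_oracle(20, 20, 10, 10), rel=1e-9
    )


def test_zero_alphas_pass_every_site(cohort_factory):
    from denovorate.io import SiteRecord

    site = SiteRecord("chr1", 100, "A", "C", site_stats={"srf": 0, "srr": 50, "saf": 30, "sar": 0})
    cfg = FilterConfig(site_test_alphas={"strand_bias": 0.0, "read_position": 0.0})
    assert site_filter(site, cfg).passed  # rejection region is empty


def test_degenerate_sites_pass_with_p_one():
    from denovorate.io import SiteRecord

    site = SiteRecord("chr1", 100, "A", "C", site_stats={})
    result = site_filter(site, FilterConfig())
    assert result.passed and all(p == 1.0 for p in result.pvalues.values())


@given(
    st.integers(0, 40), st.integers(0, 40), st.integers(0, 40), st.integers(0, 40)
)
def test_strand_bias_matches_scipy_fisher(srf, srr, saf, sar):
    """The batched hypergeometric enumeration agrees with an independent route."""
    from scipy.stats import fisher_exact

    p = _stats.strand_bias_pvalues(
        np.array([srf]), np.array([srr]), np.array([saf]), np.array([sar])
    )[0]
    expected = fisher_exact([[saf, sar], [srf, srr]], alternative="two-sided")[1]
    assert p == pytest.approx(expected, rel=1e-6, abs=1e-12)


def test_rank_test_matches_permutation_enumeration():
    """Exact Mann-Whitney p equals brute-force enumeration over assignments."""
    alt = np.array([7.1, 9.3, 2.2])
    ref = np.array([1.5, 3.4, 5.9, 8.8])
    pooled = np.concatenate([alt, ref])
    n, m = len(alt), len(ref)
    u_obs = _stats.mann_whitney_u(alt, ref)
    stats = []
    for picks in itertools.combinations(range(n + m), n):
        a = pooled[list(picks)]
        r = np.delete(pooled, list(picks))
        stats.append(_stats.mann_whitney_u(a, r))
    u_low = min(u_obs, n * m - u_obs)
    expected = sum(1 for u in stats if u <= u_low or u >= n * m - u_low) / len(stats)
    assert _stats.mann_whitney_pvalue(alt, ref) == pytest.approx(expected, rel=1e-12)


@given(
    st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=8, unique=True),
    st.lists(st.floats(2, 3, allow_nan=False), min_size=1, max_size=8, unique=True),
)
def test_rank_test_matches_scipy_exact_without_ties(alt, ref):
    from scipy.stats import mannwhitneyu

    expected = mannwhitneyu(alt, ref, alternative="two-sided", method="exact").pvalue
    assert _stats.mann_whitney_pvalue(np.array(alt), np.array(ref)) == pytest.approx(
        expected, rel=1e-9
    )


def test_rank_test_batch_agrees_with_scalar():
    rng = np.random.default_rng(3)
    alt_lists = [rng.integers(1, 101, size=rng.integers(0, 17)) for _ in range(50)]
    ref_lists = [rng.integers(1, 101, size=rng.integers(0, 17)) for _ in range(50)]
    batch = _stats.mann_whitney_pvalues_batch(alt_lists, ref_lists)
    for i in range(50):
        if len(alt_lists[i]) and len(ref_lists[i]):
            expected = _stats.mann_whitney_pvalue(alt_lists[i], ref_lists[i])
        else:
            expected = 1.0
        assert batch[i] == pytest.approx(expected, rel=1e-12)


# ---- Mendelian-violation candidates --------------------------------------------


def test_candidate_requires_confident_trio_and_no_outside_carriers(cohort_factory):
    # two families; site 0: F0 child het, parents hom-ref, F1 all hom-ref
    gt = [[1, 0, 0, 0, 0, 0]]
    cohort = cohort_factory(gt)
    site = cohort.site(0)
    assert mendelian_violation_candidate(site, cohort.pedigrees[0], cohort)
    assert not mendelian_violation_candidate(site, cohort.pedigrees[1], cohort)

    # one parent het: not a violation
    cohort2 = cohort_factory([[1, 1, 0, 0, 0, 0]])
    assert not mendelian_violation_candidate(
        cohort2.site(0), cohort2.pedigrees[0], cohort2
    )

    # carrier in the other family: excluded
    cohort3 = cohort_factory([[1, 0, 0, 1, 0, 0]])
    assert not mendelian_violation_candidate(
        cohort3.site(0), cohort3.pedigrees[0], cohort3
    )


def test_call_denovo_empty_without_violations(cohort_factory):
    gt = [[0, 0, 0, 0, 0, 0], [1, 1, 0, 0, 0, 0], [2, 1, 1, 0, 0, 0]]
    assert call_denovo(cohort_factory(gt)) == []


def test_call_denovo_classifies_by_allele_balance(cohort_factory):
    gt = [[1, 0, 0, 0, 0, 0], [1, 0, 0, 0, 0, 0]]
    ad_alt = np.zeros((2, 6), dtype=int)
    ad_alt[0, 0] = 15  # ab 0.5 -> germline
    ad_alt[1, 0] = 4   # ab ~0.13 -> somatic candidate
    cohort = cohort_factory(gt, ad_alt=ad_alt)
    calls = call_denovo(cohort)
    assert len(calls) == 2
    by_pos = {c.pos: c.classification for c in calls}
    assert by_pos[100] == GERMLINE and by_pos[101] == SOMATIC


def test_call_denovo_excludes_long_indels(cohort_factory):
    import pandas as pd

    variants = pd.DataFrame(
        {
            "chrom": "chr1",
            "pos": [100, 200],
            "ref": ["A" + "T" * 45, "A" + "T" * 5],
            "alt": ["A", "A"],
            "known": False,
        }
    )
    cohort = cohort_factory([[1, 0, 0, 0, 0, 0]] * 2, variants=variants)
    calls = call_denovo(cohort)
    assert [c.pos for c in calls] == [200]
    assert calls[0].variant_type == "indel"


def test_homalt_children_are_not_candidates(cohort_factory):
    cohort = cohort_factory([[2, 0, 0, 0, 0, 0]])
    assert call_denovo(cohort) == []


def test_vectorised_calls_match_scalar_loop(cohort_factory):
    """call_denovo agrees with a per-site loop over the scalar operations."""
    rng = np.random.default_rng(17)
    cfg = FilterConfig(site_test_alphas={})
    for _ in range(20):
        gt = rng.integers(-1, 3, size=(12, 6)).astype(np.int8)
        dp = rng.integers(0, 140, size=(12, 6))
        gq = rng.integers(0, 100, size=(12, 6))
        cohort = cohort_factory(gt, dp=dp, gq=gq)
        expected = []
        for i in range(cohort.n_sites):
            site = cohort.site(i)
            for ped in cohort.pedigrees:
                if mendelian_violation_candidate(site, ped, cohort, cfg):
                    expected.append((i, ped.family_id))
        got = [(c.site_index, c.family_id) for c in call_denovo(cohort, cfg)]
        # the vectorised caller also drops candidates with no informative reads
        expected = [
            (i, f)
            for (i, f) in expected
            if (
                cohort.ad_ref[i, cohort.sample_index[cohort.family(f).child_id]]
                + cohort.ad_alt[i, cohort.sample_index[cohort.family(f).child_id]]
            )
            > 0
        ]
        assert sorted(got) == sorted(expected)


def test_call_counts_monotone_in_thresholds(cohort_factory):
    """Raising GQ or narrowing the depth window never yields more calls."""
    rng = np.random.default_rng(23)
    gt = rng.integers(0, 2, size=(40, 9)).astype(np.int8)
    dp = rng.integers(5, 130, size=(40, 9))
    gq = rng.integers(30, 100, size=(40, 9))
    cohort = cohort_factory(gt, dp=dp, gq=gq)
    base = FilterConfig(site_test_alphas={})
    n_base = len(call_denovo(cohort, base))
    for cfg in (
        FilterConfig(gq_min=70, site_test_alphas={}),
        FilterConfig(dp_min=20, dp_max=100, site_test_alphas={}),
        FilterConfig(gq_min=90, dp_min=25, dp_max=60, site_test_alphas={}),
    ):
        assert len(call_denovo(cohort, cfg)) <= n_base


def test_partition_invariant(cohort_factory):
    rng = np.random.default_rng(29)
    gt = np.zeros((30, 6), dtype=np.int8)
    gt[:, 0] = 1  # every site a violation in F0
    ad_alt = np.column_stack(
        [rng.integers(0, 31, size=30), np.zeros((30, 5), dtype=int).T.reshape(5, 30).T]
    )
    cohort = cohort_factory(gt, ad_alt=ad_alt)
    calls = call_denovo(cohort)
    n_germ = sum(1 for c in calls if c.classification == GERMLINE)
    n_som = sum(1 for c in calls if c.classification == SOMATIC)
    assert n_germ + n_som == len(calls)
    assert len({(c.site_index, c.family_id) for c in calls}) == len(calls)
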