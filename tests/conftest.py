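import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from denovorate.io import Cohort, TrioPedigree

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


def make_cohort(
    gt,
    gq=99,
    dp=30,
    ad_alt=None,
    variants=None,
    known=False,
    site_stats=None,
    ages=None,
):
    """Build a small Cohort from a genotype matrix (n_sites x 3*n_families).

    Defaults give confident, filter-passing observations: GQ 99, DP 30 and
    allelic depths consistent with the genotype (het 15/15, hom-ref 30/0,
    hom-alt 0/30).
    """
    gt = np.atleast_2d(np.asarray(gt, dtype=np.int8))
    n_sites, n_samples = gt.shape
    assert n_samples % 3 == 0
    n_fam = n_samples // 3
    peds = [
        TrioPedigree(
            f"F{k}",
            f"F{k}-C",
            f"F{k}-F",
            f"F{k}-M",
            father_age_at_birth=None if ages is None else ages[k],
        )
        for k in range(n_fam)
    ]
    samples = [s for p in peds for s in p.members]
    gq_m = np.broadcast_to(np.asarray(gq, dtype=np.int32), gt.shape).copy()
    dp_m = np.broadcast_to(np.asarray(dp, dtype=np.int32), gt.shape).copy()
    if ad_alt is None:
        ad_alt_m = np.where(gt == 1, dp_m // 2, np.where(gt == 2, dp_m, 0)).astype(np.int32)
    else:
        ad_alt_m = np.broadcast_to(np.asarray(ad_alt, dtype=np.int32), gt.shape).copy()
    ad_ref_m = (dp_m - ad_alt_m).astype(np.int32)
    ad_ref_m[gt == -1] = 0
    ad_alt_m[gt == -1] = 0
    if variants is None:
        variants = pd.DataFrame(
            {
                "chrom": "chr1",
                "pos": np.arange(100, 100 + n_sites),
                "ref": "A",
                "alt": "C",
                "known": known,
            }
        )
    return Cohort(
        pedigrees=peds,
        samples=samples,
        variants=variants,
        gt=gt,
        gq=gq_m,
        dp=dp_m,
        ad_ref=ad_ref_m,
        ad_alt=ad_alt_m,
        site_stats=site_stats or {},
        contigs={"chr1": 100000},
    )


@pytest.fixture
def cohort_factory():
    return make_cohort
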