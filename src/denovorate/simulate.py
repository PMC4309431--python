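"""Synthetic trio-cohort generator with known truth.

Emulates the data a joint genotyper would emit for a cohort of high-depth
father-mother-child trios: a polymorphic background (Hardy-Weinberg
genotypes at configurable site density), seeded de novo SNVs and short
indels at a per-nucleotide rate with a linear paternal-age effect, bimodal
child allele balance (a germline mode at 0.5 and a somatic/mosaic mode near
0.18), depth-dependent genotype-call success, and per-site read-level
summaries (strand counts and read-offset subsamples) that drive the
cohort-level site tests at their configured null rejection rates.

Everything is drawn from one seeded generator stream; the same seed
reproduces the cohort byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import nbinom

from .io import Cohort, DepthHistogram, Genotype, TrioPedigree

__all__ = [
    "CallCurve",
    "SimConfig",
    "SimulatedCohort",
    "simulate_cohort",
    "inject_genotype_errors",
    "synthesize_gq",
    "write_cohort_files",
]

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class CallCurve:
    """Logistic call-success curve in depth: cmax / (1 + exp(-(d-d_mid)/steepness))."""

    cmax: float = 0.98
    d_mid: float = 12.0
    steepness: float = 2.5

    def __call__(self, depth) -> np.ndarray:
        d = np.asarray(depth, dtype=float)
        if self.steepness <= 0:  # degenerate: hard step at d_mid
            return np.where(d >= self.d_mid, self.cmax, 0.0)
        return self.cmax / (1.0 + np.exp(-(d - self.d_mid) / self.steepness))

    @classmethod
    def constant(cls, value: float) -> "CallCurve":
        """A depth-independent curve (the logistic term underflows to 0)."""
        return cls(cmax=value, d_mid=-1e9, steepness=1.0)


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic cohort.

    Defaults mirror the cohort the method was developed on: 10 trios at ~50x
    depth, fathers averaging 28.4 years at the child's birth, a germline SNV
    rate of 1.27e-8 per nucleotide per generation with 3.88e-10 extra
    mutations per year of paternal age, an indel rate of 1.5e-9, and
    somatic-candidate rates scaled by the observed somatic:germline ratios
    (222:508 for SNVs, 54:70 for indels).  The germline allele-balance
    component Beta(60, 60) puts ~98% of observed balances inside [0.3, 0.7]
    at 50x; the somatic component Beta(10, 42) has its mode at 0.18.
    """

    seed: int = 0
    n_families: int = 10
    genome_length: int = 10_000_000
    chrom: str = "chr1"
    # mutation model
    mu: float = 1.27e-8
    mu_indel: float = 1.5e-9
    somatic_mu: float | None = None  # default: mu * 222 / 508
    somatic_mu_indel: float | None = None  # default: mu_indel * 54 / 70
    age_slope: float = 3.88e-10
    age_ref: float = 28.4
    age_min: float = 20.4
    age_max: float = 36.4
    # sequencing model
    depth_mean: float = 50.0
    depth_shape: float = 25.0  # negative-binomial size; var = m + m^2/shape
    depth_tail_mass: float = 1e-6
    read_error: float = 1e-3
    read_len: int = 100
    pos_subsample: int = 16
    # genotype-call model
    het_curve: CallCurve = field(default_factory=lambda: CallCurve(0.98, 12.0, 2.5))
    hom_curve: CallCurve = field(default_factory=lambda: CallCurve(0.995, 10.0, 2.0))
    miscall_fraction: float = 0.3  # failed calls that miscall rather than go missing
    # allele-balance mixture
    germline_ab: tuple[float, float] = (60.0, 60.0)
    somatic_ab: tuple[float, float] = (10.0, 42.0)
    # polymorphic background
    background_density: float = 2e-3  # sites per bp
    background_maf: tuple[float, float] = (0.05, 0.95)
    background_indel_fraction: float = 0.13
    known_prob: float = 0.9
    dnm_known_prob: float = 0.035
    materialize_depths: bool = False  # per-position depth tracks (small genomes)

    def resolved(self) -> "SimConfig":
        som = self.mu * 222.0 / 508.0 if self.somatic_mu is None else self.somatic_mu
        som_i = (
            self.mu_indel * 54.0 / 70.0
            if self.somatic_mu_indel is None
            else self.somatic_mu_indel
        )
        return replace(self, somatic_mu=som, somatic_mu_indel=som_i)


@dataclass
class SimulatedCohort:
    """A simulated cohort with its truth tables and per-family depth histograms."""

    cohort: Cohort
    depth_histograms: dict[str, DepthHistogram]
    truth: pd.DataFrame
    config: SimConfig
    depth_tracks: dict[str, np.ndarray] | None = None  # per-sample per-position depths


def _depth_support(config: SimConfig) -> tuple[np.ndarray, np.ndarray]:
    """Clipped negative-binomial depth pmf covering 1 - 2*tail_mass of mass."""
    r = config.depth_shape
    p = r / (r + config.depth_mean)
    lo = int(nbinom.ppf(config.depth_tail_mass, r, p))
    hi = int(nbinom.ppf(1.0 - config.depth_tail_mass, r, p))
    support = np.arange(lo, hi + 1)
    pmf = nbinom.pmf(support, r, p)
    return support, pmf / pmf.sum()


def synthesize_gq(gt: np.ndarray, dp: np.ndarray, ad_ref: np.ndarray, ad_alt: np.ndarray) -> np.ndarray:
    """Deterministic phred-like genotype quality from depth and allele counts.

    Heterozygote confidence shrinks with the allele-balance margin
    |AB - 0.5|; homozygote confidence shrinks with reads supporting the
    other allele.  Chosen so the GQ >= 50 threshold is comfortably met at
    ~50x for clean calls and exercised at low depth / skewed balance.
    """
    dp_f = dp.astype(float)
    total = np.maximum(ad_ref + ad_alt, 1)
    ab = ad_alt / total
    gq_het = 3.0 * dp_f * (1.0 - 2.0 * np.abs(ab - 0.5))
    gq_hr = 2.5 * np.maximum(0.0, dp_f - 6.0 * ad_alt)
    gq_ha = 2.5 * np.maximum(0.0, dp_f - 6.0 * ad_ref)
    gq = np.select(
        [gt == 1, gt == 0, gt == 2], [gq_het, gq_hr, gq_ha], default=0.0
    )
    gq = np.clip(np.floor(gq), 0, 99).astype(np.int32)
    gq[gt == int(Genotype.MISSING)] = 0
    return gq


def inject_genotype_errors(
    cohort: Cohort,
    het_curve: CallCurve,
    hom_curve: CallCurve,
    seed: int,
    miscall_fraction: float = 0.3,
) -> Cohort:
    """Degrade perfect genotype calls with depth-dependent call success.

    Each true heterozygote is retained with probability ``het_curve(dp)``,
    each homozygote with ``hom_curve(dp)``; failures become miscalls (het ->
    hom-ref, hom -> het) with probability ``miscall_fraction`` and missing
    calls otherwise.  GQ is re-synthesised for the resulting calls.
    """
    rng = np.random.default_rng(seed)
    gt = cohort.gt.astype(np.int8).copy()
    success_p = np.where(gt == 1, het_curve(cohort.dp), hom_curve(cohort.dp))
    ok = rng.random(gt.shape) < success_p
    miscall = rng.random(gt.shape) < miscall_fraction
    callable_gt = gt != int(Genotype.MISSING)
    failed = ~ok & callable_gt
    new_gt = gt.copy()
    new_gt[failed & miscall & (gt == 1)] = 0
    new_gt[failed & miscall & (gt != 1)] = 1
    new_gt[failed & ~miscall] = int(Genotype.MISSING)
    gq = synthesize_gq(new_gt, cohort.dp, cohort.ad_ref, cohort.ad_alt)
    return Cohort(
        pedigrees=cohort.pedigrees,
        samples=cohort.samples,
        variants=cohort.variants,
        gt=new_gt,
        gq=gq,
        dp=cohort.dp,
        ad_ref=cohort.ad_ref,
        ad_alt=cohort.ad_alt,
        site_stats=cohort.site_stats,
        contigs=cohort.contigs,
    )


def _random_alleles(rng, n: int, indel_mask: np.ndarray, max_unit: int = 3):
    base_idx = rng.integers(0, 4, size=n)
    other = rng.integers(1, 4, size=n)
    refs = _BASES[base_idx].astype(object)
    alts = _BASES[(base_idx + other) % 4].astype(object)
    for i in np.nonzero(indel_mask)[0]:
        b = str(_BASES[base_idx[i]])
        unit = "".join(rng.choice(_BASES, size=rng.integers(1, max_unit + 1)))
        if rng.random() < 0.5:
            refs[i], alts[i] = b, b + unit  # insertion
        else:
            refs[i], alts[i] = b + unit, b  # deletion
    return refs, alts


def simulate_cohort(config: SimConfig) -> SimulatedCohort:
    """Generate a full cohort (genotypes, qualities, site stats, truth).

    The expected number of seeded germline events per family is
    ``2 * L * mu_f`` where ``mu_f = mu + age_slope * (father_age - age_ref)``
    for SNVs (no age effect on indels or somatic candidates).
    """
    config = config.resolved()
    rng = np.random.default_rng(config.seed)
    L = int(config.genome_length)

    fam_ids = [f"F{k + 1:02d}" for k in range(config.n_families)]
    ages = rng.uniform(config.age_min, config.age_max, size=config.n_families)
    pedigrees = [
        TrioPedigree(
            family_id=f,
            child_id=f"{f}-C",
            father_id=f"{f}-F",
            mother_id=f"{f}-M",
            father_age_at_birth=float(round(a, 1)),
        )
        for f, a in zip(fam_ids, ages)
    ]
    samples = [s for ped in pedigrees for s in ped.members]
    n_fam = config.n_families
    n_samples = 3 * n_fam

    # ---- site layout -----------------------------------------------------------
    n_bg = int(round(config.background_density * L))
    n_bg = min(n_bg, L)
    bg_pos = np.sort(rng.choice(L, size=n_bg, replace=False)) + 1
    taken = set(bg_pos.tolist())

    def draw_positions(count: int) -> np.ndarray:
        out: list[int] = []
        while len(out) < count:
            cand = int(rng.integers(1, L + 1))
            if cand not in taken:
                taken.add(cand)
                out.append(cand)
        return np.array(out, dtype=np.int64)

    mu_f = np.clip(
        config.mu + config.age_slope * (np.array([p.father_age_at_birth for p in pedigrees]) - config.age_ref),
        0.0,
        None,
    )
    dnm_rows = []  # (pos, ref, alt, family_index, label, is_indel)
    for k in range(n_fam):
        spec = [
            (rng.poisson(2.0 * L * mu_f[k]), "germline", False),
            (rng.poisson(2.0 * L * config.somatic_mu), "somatic", False),
            (rng.poisson(2.0 * L * config.mu_indel), "germline", True),
            (rng.poisson(2.0 * L * config.somatic_mu_indel), "somatic", True),
        ]
        for count, label, is_indel in spec:
            if count == 0:
                continue
            pos = draw_positions(count)
            refs, alts = _random_alleles(rng, count, np.full(count, is_indel))
            for p, r, a in zip(pos, refs, alts):
                dnm_rows.append((int(p), r, a, k, label, is_indel))

    bg_indel = rng.random(n_bg) < config.background_indel_fraction
    bg_ref, bg_alt = _random_alleles(rng, n_bg, bg_indel)
    bg_freq = rng.uniform(*config.background_maf, size=n_bg)
    bg_known = rng.random(n_bg) < config.known_prob

    pos_all = np.concatenate([bg_pos, np.array([r[0] for r in dnm_rows], dtype=np.int64)])
    ref_all = np.concatenate([bg_ref, np.array([r[1] for r in dnm_rows], dtype=object)])
    alt_all = np.concatenate([bg_alt, np.array([r[2] for r in dnm_rows], dtype=object)])
    n_dnm = len(dnm_rows)
    known_all = np.concatenate(
        [bg_known, rng.random(n_dnm) < config.dnm_known_prob]
    )
    order = np.argsort(pos_all, kind="stable")
    n_sites = len(pos_all)

    # ---- true genotypes --------------------------------------------------------
    gt_true = np.zeros((n_sites, n_samples), dtype=np.int8)
    # background: HWE parents, Mendelian child
    for k in range(n_fam):
        ci, fi, mi = 3 * k, 3 * k + 1, 3 * k + 2
        f_gt = rng.binomial(2, bg_freq)
        m_gt = rng.binomial(2, bg_freq)
        child = rng.binomial(1, f_gt / 2.0) + rng.binomial(1, m_gt / 2.0)
        gt_true[:n_bg, fi] = f_gt
        gt_true[:n_bg, mi] = m_gt
        gt_true[:n_bg, ci] = child
    # de novo events: everyone hom-ref except the target child (het)
    dnm_true_ab = np.zeros(n_dnm)
    ga, gb = config.germline_ab
    sa, sb = config.somatic_ab
    for j, (pos, r, a, k, label, is_indel) in enumerate(dnm_rows):
        gt_true[n_bg + j, 3 * k] = 1
        dnm_true_ab[j] = rng.beta(ga, gb) if label == "germline" else rng.beta(sa, sb)

    # ---- depths ----------------------------------------------------------------
    support, pmf = _depth_support(config)
    depth_tracks = None
    if config.materialize_depths:
        if L > 2_000_000:
            raise ValueError("materialize_depths supported only for genomes <= 2 Mb")
        depth_tracks = {
            s: rng.choice(support, size=L, p=pmf).astype(np.int16) for s in samples
        }
        dp = np.stack([depth_tracks[s][pos_all - 1] for s in samples], axis=1).astype(np.int32)
    else:
        dp = rng.choice(support, size=(n_sites, n_samples), p=pmf).astype(np.int32)

    # ---- reads -----------------------------------------------------------------
    p_alt = np.full((n_sites, n_samples), config.read_error)
    p_alt[gt_true == 2] = 1.0 - config.read_error
    het_mask = gt_true == 1
    p_alt[het_mask] = rng.beta(ga, gb, size=int(het_mask.sum()))
    for j, (pos, r, a, k, label, is_indel) in enumerate(dnm_rows):
        p_alt[n_bg + j, 3 * k] = dnm_true_ab[j]
    ad_alt = rng.binomial(dp, p_alt).astype(np.int32)
    ad_ref = (dp - ad_alt).astype(np.int32)

    # ---- site-level read summaries ---------------------------------------------
    alt_total = ad_alt.sum(axis=1)
    ref_total = ad_ref.sum(axis=1)
    saf = rng.binomial(alt_total, 0.5)
    srf = rng.binomial(ref_total, 0.5)
    sar = alt_total - saf
    srr = ref_total - srf
    n_a = np.minimum(alt_total, config.pos_subsample)
    n_r = np.minimum(ref_total, config.pos_subsample)
    alt_pos = np.split(
        rng.integers(1, config.read_len + 1, size=int(n_a.sum())), np.cumsum(n_a)[:-1]
    )
    ref_pos = np.split(
        rng.integers(1, config.read_len + 1, size=int(n_r.sum())), np.cumsum(n_r)[:-1]
    )

    variants = pd.DataFrame(
        {
            "chrom": config.chrom,
            "pos": pos_all,
            "ref": ref_all,
            "alt": alt_all,
            "known": known_all,
        }
    )

    perfect = Cohort(
        pedigrees=pedigrees,
        samples=samples,
        variants=variants.iloc[order].reset_index(drop=True),
        gt=gt_true[order],
        gq=synthesize_gq(gt_true, dp, ad_ref, ad_alt)[order],
        dp=dp[order],
        ad_ref=ad_ref[order],
        ad_alt=ad_alt[order],
        site_stats={
            "srf": srf[order],
            "srr": srr[order],
            "saf": saf[order],
            "sar": sar[order],
            "ref_pos": [ref_pos[i] for i in order],
            "alt_pos": [alt_pos[i] for i in order],
        },
        contigs={config.chrom: L},
    )
    error_seed = int(rng.integers(0, 2**31 - 1))
    cohort = inject_genotype_errors(
        perfect,
        config.het_curve,
        config.hom_curve,
        seed=error_seed,
        miscall_fraction=config.miscall_fraction,
    )

    # ---- truth table -----------------------------------------------------------
    truth_rows = []
    for j, (pos, r, a, k, label, is_indel) in enumerate(dnm_rows):
        i = n_bg + j
        ci = 3 * k
        total = int(ad_ref[i, ci] + ad_alt[i, ci])
        truth_rows.append(
            {
                "family_id": fam_ids[k],
                "chrom": config.chrom,
                "pos": int(pos),
                "ref": r,
                "alt": a,
                "variant_type": "indel" if is_indel else "SNV",
                "label": label,
                "true_ab": float(dnm_true_ab[j]),
                "ab_obs": (ad_alt[i, ci] / total) if total else np.nan,
                "d_child": int(dp[i, ci]),
                "d_father": int(dp[i, ci + 1]),
                "d_mother": int(dp[i, ci + 2]),
            }
        )
    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "family_id", "chrom", "pos", "ref", "alt", "variant_type",
            "label", "true_ab", "ab_obs", "d_child", "d_father", "d_mother",
        ],
    ).sort_values(["family_id", "pos"]).reset_index(drop=True)

    # ---- per-family joint depth histograms --------------------------------------
    histograms: dict[str, DepthHistogram] = {}
    if depth_tracks is not None:
        for ped in pedigrees:
            histograms[ped.family_id] = DepthHistogram.from_positions(
                depth_tracks[ped.child_id],
                depth_tracks[ped.father_id],
                depth_tracks[ped.mother_id],
            )
    else:
        d = len(support)
        joint_pmf = (pmf[:, None, None] * pmf[None, :, None] * pmf[None, None, :]).ravel()
        joint_pmf = joint_pmf / joint_pmf.sum()
        cells_c, cells_f, cells_m = np.meshgrid(support, support, support, indexing="ij")
        cells_c, cells_f, cells_m = cells_c.ravel(), cells_f.ravel(), cells_m.ravel()
        for ped in pedigrees:
            counts = rng.multinomial(L, joint_pmf)
            nz = counts > 0
            histograms[ped.family_id] = DepthHistogram(
                cells_c[nz], cells_f[nz], cells_m[nz], counts[nz]
            )

    return SimulatedCohort(
        cohort=cohort,
        depth_histograms=histograms,
        truth=truth,
        config=config,
        depth_tracks=depth_tracks,
    )


# ---- file emission -------------------------------------------------------------


def write_cohort_files(sim: SimulatedCohort, out_dir) -> dict[str, str]:
    """Write the simulated cohort in the formats the readers consume.

    Emits cohort.vcf, cohort.ped, ages.tsv, known_sites.tsv, truth.tsv and
    either per-sample BED depth tracks (when per-position depths were
    materialised) or per-family joint depth-histogram TSVs.
    """
    from pathlib import Path

    from .io import write_vcf

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}

    vcf_path = out / "cohort.vcf"
    write_vcf(sim.cohort, vcf_path)
    paths["vcf"] = str(vcf_path)

    ped_path = out / "cohort.ped"
    with open(ped_path, "w") as fh:
        for ped in sim.cohort.pedigrees:
            fh.write(f"{ped.family_id}\t{ped.father_id}\t0\t0\t1\t-9\n")
            fh.write(f"{ped.family_id}\t{ped.mother_id}\t0\t0\t2\t-9\n")
            fh.write(
                f"{ped.family_id}\t{ped.child_id}\t{ped.father_id}\t{ped.mother_id}\t0\t-9\n"
            )
    paths["ped"] = str(ped_path)

    ages_path = out / "ages.tsv"
    with open(ages_path, "w") as fh:
        fh.write("family_id\tfather_age\n")
        for ped in sim.cohort.pedigrees:
            fh.write(f"{ped.family_id}\t{ped.father_age_at_birth}\n")
    paths["ages"] = str(ages_path)

    known_path = out / "known_sites.tsv"
    known = sim.cohort.variants[sim.cohort.variants["known"]]
    with open(known_path, "w") as fh:
        fh.write("chrom\tpos\tref\talt\n")
        for _, row in known.iterrows():
            fh.write(f"{row['chrom']}\t{row['pos']}\t{row['ref']}\t{row['alt']}\n")
    paths["known_sites"] = str(known_path)

    truth_path = out / "truth.tsv"
    sim.truth.to_csv(truth_path, sep="\t", index=False)
    paths["truth"] = str(truth_path)

    if sim.depth_tracks is not None:
        track_dir = out / "depth_tracks"
        track_dir.mkdir(exist_ok=True)
        for s, depths in sim.depth_tracks.items():
            path = track_dir / f"{s}.bed"
            _write_rle_bed(path, sim.config.chrom, depths)
            paths[f"track:{s}"] = str(path)
    else:
        hist_path = out / "depth_hist.tsv"
        frames = []
        for fam, hist in sim.depth_histograms.items():
            df = hist.to_frame()
            df.insert(0, "family_id", fam)
            frames.append(df)
        pd.concat(frames).to_csv(hist_path, sep="\t", index=False)
        paths["depth_hist"] = str(hist_path)
    return paths


def _write_rle_bed(path, chrom: str, depths: np.ndarray) -> None:
    """Run-length encode a per-position depth array as BED (0-based half-open)."""
    change = np.nonzero(np.diff(depths))[0] + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [len(depths)]])
    with open(path, "w") as fh:
        for s, e in zip(starts, ends):
            fh.write(f"{chrom}\t{s}\t{e}\t{int(depths[s])}\n")
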