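# Methods

## The estimation problem

A de novo mutation (DNM) rate estimate is a ratio: germline DNM calls over
the opportunity to have observed them. Both halves are biased by filtering —
stringent filters are required to keep false positives out of the numerator,
but every filter also removes true events. Instead of compensating by
loosening filters, the package keeps the filters stringent and measures
their cost: every position contributes its *callability* — the probability
that a true DNM there would have been called and retained — to the
denominator. A position where a DNM would be found 60% of the time counts
as 0.6 of a site.

## Calling model

A candidate at site *x* in family *f* requires:

1. *Site filter.* Two cohort-level tests on read summaries, each with a
   known null distribution and thresholded on p-value at a configurable
   alpha (default 0.01 each):
   * strand bias: the 2×2 allele × strand table, tested by the exact
     conditional (hypergeometric) distribution of the forward-alt count
     given the margins; two-sided by summing tables at most as probable as
     the observed one. When the conditional support exceeds 256 states the
     discrete null is effectively continuous and a continuity-corrected
     normal approximation to the hypergeometric is used instead.
   * read position: Mann–Whitney rank test of alt-read offsets against
     ref-read offsets, using the exact no-ties null distribution (computed
     by the standard counting recurrence and cached per (n, m)); ties take
     midranks against that null, a slightly conservative convention.
   Sites lacking the read-level inputs pass with p = 1: absent evidence is
   not evidence against a site.
2. *Trio genotypes.* Child called heterozygous with GQ ≥ 50 and
   DP ∈ [10, 120] (closed bounds); both parents called homozygous reference
   with the same GQ/DP bounds and zero alt-supporting reads (AD2 = 0).
3. *Cohort privacy.* No sample outside the family carries a non-hom-ref
   call at the site, regardless of that call's quality (conservative:
   a low-quality het elsewhere still vetoes). Child hom-alt violations from
   two hom-ref parents are excluded throughout — the callability model
   calibrates het calling only, and a double-hit DNM is vanishingly rare.

Candidates are partitioned by the child's allele balance: AB ∈ [0.3, 0.7]
(closed) is germline; outside is a somatic/mosaic candidate. Indels use the
same machinery, restricted to length < 40 bp.

## Callability and the denominator

Assuming members are genotyped independently given their depths,
`C_f(x) = C_het(d_child) · C_hom(d_father) · C_hom(d_mother)`.

* `C_het(d)` is calibrated at sites where one parent is confidently hom-ref
  and the other confidently hom-alt (both GQ ≥ 50): the child is then
  heterozygous by Mendelian necessity, and the estimate at depth *d* is the
  fraction of such children called het *and* passing the heterozygote
  filter.
* `C_hom(d)` is calibrated at sites where both parents of a family are
  confidently hom-ref, the variant is carried by at least one other family,
  and (for SNVs) is in the known-variants list — conditions that make the
  variant real while the measured children are truly hom-ref. By default
  only children are measured (an option widens to parents).

Both calibrations condition on the site filter passing, so the site
filter's own loss is not double counted; it enters once, as
`alpha_site = 1 − Π(1 − alpha_k)` under the assumption of independent
tests. Per-depth bins with fewer than `min_trials` (default 100)
observations are pooled with their nearest neighbour bins outward (ties
toward lower depth) until the threshold is met; depths outside the
calibrated range clamp to the nearest bin and pool from there. The family
denominator is `2 · (1 − alpha_site) · Σ_x C_f(x)` — the factor 2 counts the
two transmitted haploid genomes, putting the rate on the per-nucleotide,
per-generation scale.

## Inference

Counts are treated as Poisson. Intervals are exact Garwood bounds,
`[χ²(α/2, 2n)/2, χ²(1−α/2, 2n+2)/2] / denominator`, which behave correctly
at the small indel counts where normal approximations fail. The pooled rate
is total count over total denominator; per-family rates exist for the
paternal-age regression, an unweighted OLS of family rate on father's age
(a weighted variant, weights = family denominators, is available). A slope
p-value is only reported with ≥ 3 families; identical ages are rejected as
unidentifiable.

## Repeat-context classification

Windows of ±100 bp (configurable) around the indel are scanned for maximal
exact tandem arrays of primitive units (lengths 1–50), units canonicalised
to their minimal rotation; arrays contained in a reported array with a
shorter unit are suppressed, and a trailing partial copy extends the span
but not the copy count. Classification precedence is HR > TR > HR_NC >
TR_NC: HR requires a mononucleotide run ≥ 6 whose base composes the entire
inserted/deleted sequence; HR_NC drops the composition requirement; TR
requires a unit of u bp at ≥ 2u+5 copies; TR_NC is any overlapping array
below that. Ties among arrays of the winning class resolve to (longest
span, then shortest unit). Exact matching is deliberate — unlike
mismatch-tolerant repeat finders it has a precisely checkable definition —
and externally produced annotations (e.g. a Tandem Repeat Finder run) can
be passed in as a drop-in substitute. TR classes do not require the unit to
match the indel sequence; only HR carries a composition requirement.

## Synthetic cohorts

The simulator generates what a joint genotyper would emit, with truth
retained. Defaults are the study conditions of the cohort the method
targets:

| parameter | default | note |
| --- | --- | --- |
| families | 10 | trios, child/father/mother |
| depth | NB(mean 50, size 25) | ~50× coverage, clipped to the central 1−2e-6 of mass |
| father ages | U(20.4, 36.4) years | mean 28.4 |
| germline SNV rate | 1.27e-8 /nt/gen | at the reference age 28.4 |
| paternal-age slope | 3.88e-10 /nt/yr | applied to germline SNVs only |
| indel rate | 1.5e-9 /nt/gen | |
| somatic rates | × 222/508 (SNV), × 54/70 (indel) | the observed somatic:germline ratios |
| germline AB | Beta(60, 60) | ~98% of observed AB in [0.3, 0.7] at 50× |
| somatic AB | Beta(10, 42) | mode 0.18 |
| background sites | 2e-3 /bp, MAF U(0.05, 0.95), 90% known | populates both calibration classes |
| read error | 1e-3 /read | drives AD2 failures in hom-ref parents |

Genotype-call success is a logistic curve in depth (separately for het and
hom calls, defaults cmax 0.98/0.995, midpoints 12/10); failures miscall
with probability 0.3 and go missing otherwise. GQ is a deterministic
function of depth and the allele-balance margin (het: 3·DP·(1−2|AB−0.5|);
hom: 2.5·(DP − 6·AD_other)), so the GQ ≥ 50 threshold is genuinely
exercised at low depth and skewed balance. Per-site strand counts split
total reads binomially and read offsets are uniform subsamples (≤ 16 per
allele), so the site tests reject good sites at their nominal alphas.
Joint family depth histograms are drawn as one multinomial over the product
pmf (members are depth-independent); per-position depth tracks are
materialised only for genomes ≤ 2 Mb when files are emitted, in which case
variant-site depths come from the tracks themselves.

What the simulator does *not* emulate: linkage disequilibrium, alignment
artefacts correlated along the genome, per-sample coverage differences,
mutational sequence context (alleles are random), and read-level data.
Passing tests therefore demonstrate the estimator's statistical behaviour
under the stated generative model, not robustness to alignment pathology on
real data.

## Numerical and design choices

* Multi-allelic records are skipped with a counter, not split — splitting
  would change AD semantics. Analysis is restricted to autosomes by default.
* Missing FORMAT fields (./., absent GQ) yield a Missing observation that
  fails every individual filter.
* Known-site membership is exact on (chrom, pos, ref, alt).
* Problem sizes in the heavier tests — 100 replicates of 10 trios × 10 Mb
  for rate recovery, 200 cohorts of 1 Mb for interval coverage — were
  chosen as the smallest sizes at which the binomial/Poisson noise floor is
  well below the tolerances being asserted.
* The recovery tolerance (relative bias < 10%) absorbs the small real
  biases the estimator shares with its design: germline events whose
  observed AB leaves [0.3, 0.7] (~2% at 50×), candidates vetoed by a
  miscalled carrier in another family (a few percent), and the conservatism
  of discrete exact tests relative to their nominal alphas.

## Known limitations

* The callability model conditions on depth only; residual dependence of
  call success on mapping quality or context is averaged over.
* `C_hom` is calibrated at known polymorphic sites, which may be easier to
  genotype than a random genomic position of equal depth.
* Somatic candidates are partitioned, not modelled: no attempt is made to
  estimate the true mosaic fraction.
* The pooled rate assumes the per-family Poisson counts are independent
  given their denominators; family-level overdispersion would widen the
  true interval relative to the reported one.
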