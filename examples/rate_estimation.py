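"""Estimate a de novo mutation rate end to end on simulated data.

Simulates 10 trios over a 10 Mb genome with a planted rate of 1e-7 per
nucleotide per generation, calibrates depth-stratified callability from the
cohort itself, sums per-family callability over the joint depth histograms
and reports the pooled rate with its exact Poisson interval plus the
paternal-age regression.
"""

from denovorate.callability import estimate_denovo_rate
from denovorate.simulate import SimConfig, simulate_cohort

mu = 1e-7
cfg = SimConfig(seed=8, genome_length=10_000_000, mu=mu, age_slope=2e-9)
sim = simulate_cohort(cfg)
est, age_model = estimate_denovo_rate(sim.cohort, sim.depth_histograms)

print(f"planted rate:      {mu:.3e} /nt/generation")
print(f"pooled estimate:   {est.rate:.3e}  (95% CI {est.ci_lo:.3e} .. {est.ci_hi:.3e})")
print(f"germline calls:    {est.n_mutations}")
print(f"denominator:       {est.effective_denominator:.3e} diploid site-generations")
print(f"alpha_site:        {est.alpha_site:.4f}")
if age_model is not None:
    print(
        f"paternal age:      slope {age_model.slope:.2e} /nt/yr "
        f"(planted 2e-09), p = {age_model.p_value:.3f}"
    )
print()
print("The denominator is 2 * (1 - alpha_site) * sum_x C_f(x) summed over")
print("families: the number of diploid site-generations in which a de novo")
print("mutation would have been called, so the interval should cover the")
print("planted rate in ~95% of seeds.")
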