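"""The paired statistical battery on its own: routing, effect sizes, FDR.

The same machinery the pipeline applies to metric AUCs: Shapiro-Wilk
decides between the paired t test (effect size dz = t/sqrt(n)) and the
Wilcoxon signed-rank test (r = z/sqrt(n)); families of parallel tests are
Benjamini-Hochberg adjusted.
"""

import numpy as np

import netshift as ns

rng = np.random.default_rng(42)
n = 36

# a paired sample with a moderate shift
before = rng.normal(50, 8, n)
after = before + rng.normal(2.0, 4.0, n)
sample = ns.PairedSample(x_A=before, x_B=after)

route = ns.shapiro_route(sample)
res = ns.compare_paired(sample)
print(f"routed to: {route}")
print(f"statistic = {res.statistic:.3f}, p = {res.p_raw:.4f}, "
      f"effect = {res.effect_size:.2f} "
      f"[{res.effect_ci[0]:.2f}, {res.effect_ci[1]:.2f}]")

# effect sizes from printed statistics: dz = t/sqrt(n), r = z/sqrt(n)
print(f"dz for t = 4.182, n = 36: {ns.cohens_d_from_t(4.182, 36):.2f}")
print(f"r  for z = -2.35, n = 36: {abs(ns.r_from_z(-2.35, 36)):.2f}")

# BH-FDR over a family of 90 node-level p-values, three real effects
p = np.concatenate([[1e-4, 5e-4, 2e-3], rng.uniform(0.01, 1, 87)])
adjusted, significant = ns.bh_fdr(p, q=0.05)
print(f"FDR at q = 0.05: {significant.sum()} of {len(p)} significant; "
      f"smallest adjusted p = {adjusted.min():.4f}")
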