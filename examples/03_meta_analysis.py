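"""Genotype-count meta-analysis of simulated studies.

Pools 12 simulated case-control studies of varying size around a true
allelic OR of 1.8 with mild between-study variance, then prints the
pooled estimate, heterogeneity statistics, and publication-bias tests.
"""

import numpy as np

import ecrisk

sizes = [(int(n), int(n)) for n in np.random.default_rng(5).integers(150, 1500, 12)]
studies = ecrisk.generate_study_collection(
    k=12, true_or=1.8, tau2=0.02, sizes=sizes, seed=5
)
res = ecrisk.meta_analyze(studies, genetic_model="allelic")

print(f"k = {res.k} studies, model used: {res.model_used}")
print(f"pooled OR = {res.pooled_or:.3f} (95% CI {res.ci95[0]:.3f}-{res.ci95[1]:.3f})")
print(f"Q = {res.Q:.2f} (df {res.df}, p = {res.p_Q:.3f}), I2 = {res.I2:.1f}%, tau2 = {res.tau2:.4f}")
print(f"Begg p = {res.begg_p:.3f}, Egger p = {res.egger_p:.3f}")
print(
    "\nThe pooled OR should sit near the generating 1.8; the fixed/random"
    "\nchoice follows the p_Q >= 0.10 or I2 <= 50% rule, and with no"
    "\nsimulated bias both funnel tests stay non-significant."
)
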