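"""Per-SNP case-control association under the five genetic contrasts.

Computes crude odds ratios, control HWE, FPRP at priors 0.25/0.1/0.01,
and attributable-risk fractions for each SNP of the default panel on a
simulated cohort.
"""

import ecrisk

spec = ecrisk.PopulationSpec(n_cases=500, n_controls=500, seed=17)
subjects = ecrisk.generate_case_control(spec)

report = ecrisk.association_report(subjects, ecrisk.default_panel())
best = report[report["model"] == report["rsid"].map(
    {s.rsid: s.genetic_model for s in ecrisk.default_panel()}
)]
cols = ["rsid", "model", "or", "ci_lo", "ci_hi", "p_value", "hwe_p", "fprp_0.25"]
print(best[cols].round(4).to_string(index=False))
print(
    "\nEach SNP is tested under its best-fitting genetic model; the OR"
    "\nshould track the generating value, HWE p stays non-significant in"
    "\ncontrols, and FPRP < 0.5 marks the association as noteworthy."
)
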