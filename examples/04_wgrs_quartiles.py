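"""Weighted genetic risk score and its quartile association.

Scores every subject with the multiplicative wGRS (per-SNP genotype
scores normalized to unit HWE mean), then estimates adjusted
per-quartile odds ratios against the lowest control quartile.
"""

import ecrisk

panel = ecrisk.default_panel()
spec = ecrisk.PopulationSpec(snps=panel, n_cases=500, n_controls=500, seed=17)
subjects = ecrisk.generate_case_control(spec)
subjects["wgrs"] = ecrisk.add_wgrs(subjects, panel)

for table in (ecrisk.score_snp(s) for s in panel[:2]):
    print(
        f"{table.rsid}: W = {table.W:.4f}, scores "
        f"AA {table.score_AA:.3f} / AB {table.score_AB:.3f} / BB {table.score_BB:.3f}"
    )

res = ecrisk.quartile_association(subjects, subjects["wgrs"])
print(f"\ncontrol quartile cutpoints: {[round(c, 3) for c in res.cutpoints]}")
for q, (odds, ci, n) in enumerate(zip(res.odds_ratios, res.ci95, res.counts), start=1):
    label = "reference" if q == 1 else f"OR {odds:.2f} ({ci[0]:.2f}-{ci[1]:.2f})"
    print(f"  Q{q}: {n[0]} cases / {n[1]} controls, {label}")
print(f"p for trend = {res.trend_p:.2e}")
print(
    "\nRising quartile ORs with a small trend p reproduce the pattern of"
    "\na genuine multiplicative genetic effect; the top-vs-bottom OR is"
    "\nthe headline genetic risk gradient."
)
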