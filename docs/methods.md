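# Methods

This note documents the statistical machinery in `ecrisk`, the design
of the synthetic-data generator, and the numerical and design choices
made where more than one defensible option existed.

## Study design being modelled

The package targets hospital-based case-control studies of esophageal
cancer with a candidate-SNP design: a literature meta-analysis screens
SNPs, a case-control sample validates them, the validated SNPs are
combined into a multiplicative weighted genetic risk score (wGRS), and
logistic risk models with and without the wGRS are compared on a 60/40
train/validation split.

## Synthetic-data generator

`generate_case_control` rejection-samples a source population:
genotypes are drawn independently per SNP under Hardy–Weinberg
equilibrium (HWE) at the panel's risk-allele frequency; smoking,
drinking and family history are Bernoulli at configurable source
prevalences (defaults 34.6%, 29.6%, 2.0% — the study's control
prevalences); disease status is Bernoulli with logit

    baseline_logit + Σ_snp log(OR_snp)·contrast_snp + exposure terms,

where `contrast_snp` is the indicator (dominant/recessive) or dosage
(allelic) that defines each SNP's genetic model. Sampling continues
until the requested numbers of cases and controls are collected.

Defaults and their rationale:

- **SNP effects.** The five validated susceptibility SNPs with their
  published best-fitting models and odds ratios: rs1042522 recessive
  0.69, rs1229984 recessive 1.78, rs1801133 dominant 0.41, rs2274223
  dominant 1.93, rs671 dominant 2.42.
- **Risk-allele frequencies** are *illustrative placeholders* (0.55,
  0.60, 0.35, 0.30, 0.20): the study's reference (CHB) frequencies are
  not published. Substitute reference-panel values for substantive use.
- **Exposure effects** come from the published combined-model equation:
  smoking β = −0.558, family history β = 1.976, smoking×drinking
  β = 1.393, no drinking main effect. Using the study's own fitted
  coefficients makes the downstream logistic fits well-specified.
- **baseline_logit = −3** keeps the source-population disease risk low
  (≈5% at covariate baseline) so that control exposure and genotype
  frequencies converge to the source values (rare-disease logic) while
  rejection sampling stays cheap. A much lower intercept fails loudly
  with guidance rather than looping forever.
- **Age** is drawn per arm (cases Normal(63.00, 8.33), controls
  Normal(46.80, 11.55), years) rather than through the disease model,
  since the published model equations contain no age term.
- **Sex** enters no equation; controls' sex is drawn at the cases'
  empirical male fraction (frequency matching, default 72.6% male).
- **Missingness** is injectable at a configurable rate (default 0) to
  exercise the missing-genotype-scores-as-1 rule.

What the generator does *not* emulate: linkage disequilibrium between
SNPs, population stratification, genotyping error, and exposure
confounding with genotype. Tests passing on these synthetic cohorts
therefore show correctness of the statistical machinery under the
model's own assumptions, not robustness to those real-data features.

`generate_study_collection` simulates a meta-analysis corpus: per-study
true log ORs are Normal(log OR, τ²), controls follow HWE, and case
genotype probabilities are derived from the study OR under the chosen
contrast. τ² = 0 yields homogeneous studies. One caveat: with all
studies the same size, the funnel plot degenerates (no precision
spread) and small-sample correlation between the OR estimate and its SE
dominates the Begg/Egger statistics; funnel-behaviour tests therefore
vary study sizes.

## Association statistics

Odds ratios use Woolf log-SE confidence intervals; the
Haldane–Anscombe +0.5 correction is applied to all four cells only when
a zero cell occurs (configurable off, in which case an infinite OR is
signalled explicitly). The baseline-characteristics chi-square uses no
continuity correction — this reproduces the published statistics
(10.047, 9.403, 57.616) exactly from the printed counts. The HWE test
estimates the allele frequency from the control counts and uses a
1-df Pearson statistic.

FPRP follows the standard posterior formula
`α(1−π) / (α(1−π) + power·π)` with power computed against a threshold
OR under the normal approximation, direction-matched to the observed
effect (the reciprocal threshold is used for protective ORs). The
threshold OR defaults to 1.5 — the conventional moderate effect — and
is configurable; priors default to 0.25/0.1/0.01 with noteworthiness at
FPRP < 0.5. ARP = 100(OR−1)/OR is reported as 0 for protective ORs
(relabel the allele to get an attributable fraction); PARP uses the
control prevalence of the risk contrast.

## Meta-analysis engine

Per-study effects are Woolf log ORs on the collapsed 2×2. Cochran's Q
and I² = max(0, 100(Q−df)/Q) are computed from inverse-variance
weights; DerSimonian–Laird τ² is the usual moment estimator truncated
at 0. The fixed-effect pooled OR is Mantel–Haenszel with the
Robins–Breslow–Greenland variance (the standard pairing in the major
meta-analysis packages); the random-effects estimate re-weights by
1/(se² + τ²). Model choice follows the disjunctive rule: fixed iff
p(Q) ≥ 0.10 **or** I² ≤ 50%. Begg's test uses Kendall's S between
variance-standardized deviations and variances with a
normal-approximation p and no continuity correction; Egger's test
regresses the standardized effect on precision by OLS with a t-test on
the intercept at k−2 df. Both report not-evaluable (NaN) below k = 3.
Optional inclusion rules exclude studies with an arm under 10 subjects
or HWE-failing controls (p < 0.05), with an audit log.

## wGRS

Each SNP's genotype scores 1/W, OR/W, OR²/W are normalized by
W = (1−p)² + 2p(1−p)OR + p²OR², making the HWE-expected score exactly
1 — hence the population-mean wGRS of independent SNPs is 1 and the
score multiplies cleanly across SNPs. Missing genotypes contribute a
factor 1. The per-risk-allele OR is used as the weight so that
BB = OR² matches the multiplicative allele structure; the wGRS enters
regressions as the raw product (not logged or standardized).

Quartile cutpoints come from the *training-set controls* and are frozen
for the validation set (this prevents leakage where the convention is
ambiguous); ties at a cutpoint fall to the lower quartile (left-closed
intervals). Per-quartile ORs and the trend test come from logistic
models adjusted for age, smoking, drinking and family history; the
trend p is the Wald p of an ordinal 1–4 quartile term. These adjusted
fits use IRLS (binomial GLM): with a 2% family-history prevalence,
small cohorts regularly produce quasi-separated cells that would crash
a Newton fit, while IRLS returns the (divergent-coefficient,
huge-SE) fit the other quartile estimates are unaffected by.

## Risk models

The three models replicate the published term sets exactly: genetic =
{wGRS}; non-genetic = {smoking, family history, smoking×drinking} —
deliberately non-hierarchical (no drinking main effect), replicated
verbatim with a logged warning; combined = union. Age is excluded
because the published equations contain no age term despite the
case-control age gap; covariates can be added via `fit_logistic`
directly. The split is simple (unstratified) randomization. The
published coefficient vectors are available as frozen models
(`load_printed_model`) for regression tests and demonstrations.
Complete or quasi-complete separation and singular designs raise
explicit diagnostics rather than returning garbage.

## Evaluation

AUC is the Mann–Whitney concordance probability with half credit for
ties, computed via midranks; its CI and the paired AUC comparison use
DeLong structural components. Operating points scan thresholds at
midpoints between adjacent distinct scores; Youden ties break toward
the higher-specificity threshold; LR+ is reported as infinite at
perfect specificity; accuracy is computed at the Youden-optimal
threshold. NRI defaults to the category-free (continuous) form — any
increase/decrease in predicted risk counts — because no category
cutoffs are published; categorical NRI with user thresholds is
available and yields different numbers. The NRI z uses the standard
two-proportion asymptotic variance. AIC = −2logL + 2k and
BIC = −2logL + k·ln n with k counting all coefficients including the
intercept.

## Determinism and problem sizes

All randomness flows through `numpy.random.default_rng`; the pipeline
derives per-stage substreams from one run seed via `SeedSequence`, so
adding a stage never perturbs earlier stages' draws and a fixed
configuration reproduces byte-identical outputs.

Problem sizes used by the test suite and acceptance script are the
package's own choices: parameter-recovery checks run five single-SNP
cohorts of 5000/5000 (single-SNP because crude collapsed ORs on the
joint cohort are attenuated by odds-ratio non-collapsibility — a
property of the marginal estimand, not an estimator defect); the
model-comparison demonstration runs at the study's 500/500 scale; the
null-calibration check runs 500 replicates of 150/150 cohorts with all
generating ORs at 1 while scoring with the panel's nominal weights
(scoring with null weights would make the wGRS constant and quartiles
undefined).

## Known limitations

- The wGRS weighting assumes independent SNPs; correlated SNPs
  double-count shared signal.
- Crude ORs, FPRP and ARP/PARP are computed from collapsed 2×2 tables;
  covariate-adjusted per-SNP ORs require a custom `fit_logistic` call.
- The Begg/Egger tests have low power at small k and misbehave when all
  studies share one size; results below k ≈ 10 are descriptive.
- No calibration modelling, IDI, or decision-curve analysis; no
  VCF/PLINK ingestion (panels here are ≤ 14 SNPs; a dosage TSV
  suffices).
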