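"""Synthetic case-control cohorts and multi-study genotype counts.

The generator emulates a hospital case-control study of esophageal
cancer: genotypes drawn under Hardy-Weinberg equilibrium, binary
exposures (smoking, drinking, family history) at stated source
prevalences, and disease status from a logistic model whose log-odds sum
per-SNP genetic-model contrasts and exposure effects.  Cases and
controls are accumulated by rejection sampling until the requested arm
sizes are reached, so downstream logistic fits are well-specified by
construction.

Default effect sizes are the study's own: per-SNP odds ratios under each
SNP's best-fitting genetic model, and exposure effects from the fitted
combined risk equation (smoking, family history, and a smoking x
drinking interaction).  The default risk-allele frequencies are
illustrative values, not estimates from any reference panel.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grs import SnpSpec
from .meta import StudyCounts

#: Control exposure prevalences observed in the study population.
DEFAULT_EXPOSURE_PREVALENCES = {"smoking": 0.346, "drinking": 0.296, "family_history": 0.02}

#: Exposure odds ratios from the fitted combined model (no drinking main effect).
DEFAULT_EXPOSURE_ORS = {
    "smoking": math.exp(-0.558),
    "drinking": 1.0,
    "family_history": math.exp(1.976),
}
DEFAULT_INTERACTION_OR = math.exp(1.393)

#: Case/control age distributions (mean, SD) in years.
CASE_AGE = (63.00, 8.33)
CONTROL_AGE = (46.80, 11.55)
MALE_FRACTION = 0.726


def default_panel() -> list[SnpSpec]:
    """The five validated susceptibility SNPs with their best-fitting
    genetic models and odds ratios.

    Risk-allele frequencies are illustrative placeholders (the study's
    reference frequencies are not published); replace them with real
    reference-panel values for any substantive use.
    """
    return [
        SnpSpec("rs1042522", "C", p=0.55, or_allele=0.69, genetic_model="recessive"),
        SnpSpec("rs1229984", "C", p=0.60, or_allele=1.78, genetic_model="recessive"),
        SnpSpec("rs1801133", "T", p=0.35, or_allele=0.41, genetic_model="dominant"),
        SnpSpec("rs2274223", "G", p=0.30, or_allele=1.93, genetic_model="dominant"),
        SnpSpec("rs671", "A", p=0.20, or_allele=2.42, genetic_model="dominant"),
    ]


@dataclass
class PopulationSpec:
    """Data-generating conditions for one synthetic cohort."""

    snps: list[SnpSpec] = field(default_factory=default_panel)
    exposure_prevalences: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_EXPOSURE_PREVALENCES)
    )
    exposure_ors: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_EXPOSURE_ORS))
    interaction_or: float = DEFAULT_INTERACTION_OR
    baseline_logit: float = -3.0
    n_cases: int = 500
    n_controls: int = 500
    male_fraction: float = MALE_FRACTION
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name, p in self.exposure_prevalences.items():
            if not 0 <= p <= 1:
                raise ValueError(f"prevalence of {name} must lie in [0, 1]")
        for name, o in self.exposure_ors.items():
            if o <= 0:
                raise ValueError(f"odds ratio of {name} must be positive")
        if self.interaction_or <= 0:
            raise ValueError("interaction odds ratio must be positive")
        if self.n_cases < 1 or self.n_controls < 1:
            raise ValueError("need at least one case and one control")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must lie in [0, 1)")


def generate_genotypes(p: float, n: int, rng: np.random.Generator | int) -> np.ndarray:
    """Risk-allele dosages 0/1/2 drawn under HWE at allele frequency ``p``."""
    if not 0 <= p <= 1:
        raise ValueError("allele frequency must lie in [0, 1]")
    if n < 1:
        raise ValueError("n must be at least 1")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    probs = np.array([(1 - p) ** 2, 2 * p * (1 - p), p**2])
    return rng.choice(3, size=n, p=probs)


def _model_contrast(dosages: np.ndarray, genetic_model: str) -> np.ndarray:
    """Indicator/count of the model-defining risk contrast per subject."""
    if genetic_model == "allelic":
        return dosages.astype(float)
    if genetic_model == "dominant":
        return (dosages >= 1).astype(float)
    if genetic_model == "recessive":
        return (dosages == 2).astype(float)
    raise ValueError(f"unsupported generating model {genetic_model!r}")


def generate_case_control(spec: PopulationSpec) -> pd.DataFrame:
    """Rejection-sample a case-control cohort from the source population.

    Returns a subject table with columns id, status (1=case), age, sex,
    smoking, drinking, family_history and one dosage column per rsID
    (NaN = missing).  Reproducible for a fixed seed.
    """
    rng = np.random.default_rng(spec.seed)
    need = spec.n_cases + spec.n_controls
    batch = max(4096, 2 * need)
    max_draws = 4000 * need

    cases: list[pd.DataFrame] = []
    controls: list[pd.DataFrame] = []
    got_cases = got_controls = 0
    drawn = 0
    while got_cases < spec.n_cases or got_controls < spec.n_controls:
        if drawn >= max_draws:
            raise RuntimeError(
                f"could not reach {spec.n_cases} cases / {spec.n_controls} controls after "
                f"{drawn} draws; raise baseline_logit (disease too rare) or lower it "
                "(disease too common)"
            )
        drawn += batch
        cols = {
            name: (rng.random(batch) < prev).astype(int)
            for name, prev in spec.exposure_prevalences.items()
        }
        logit = np.full(batch, spec.baseline_logit)
        for name, odds in spec.exposure_ors.items():
            logit += cols[name] * math.log(odds)
        logit += cols["smoking"] * cols["drinking"] * math.log(spec.interaction_or)
        for snp in spec.snps:
            d = generate_genotypes(snp.p, batch, rng)
            cols[snp.rsid] = d
            logit += _model_contrast(d, snp.genetic_model) * math.log(snp.or_allele)
        prob = 1.0 / (1.0 + np.exp(-logit))
        status = (rng.random(batch) < prob).astype(int)
        df = pd.DataFrame(cols)
        df.insert(0, "status", status)
        new_cases = df[df["status"] == 1].iloc[: spec.n_cases - got_cases]
        new_controls = df[df["status"] == 0].iloc[: spec.n_controls - got_controls]
        cases.append(new_cases)
        controls.append(new_controls)
        got_cases += len(new_cases)
        got_controls += len(new_controls)

    case_df = pd.concat(cases, ignore_index=True)
    ctrl_df = pd.concat(controls, ignore_index=True)

    # sex is frequency-matched: controls drawn at the cases' empirical male fraction
    case_male = rng.random(len(case_df)) < spec.male_fraction
    ctrl_male = rng.random(len(ctrl_df)) < case_male.mean()
    case_df["sex"] = np.where(case_male, "male", "female")
    ctrl_df["sex"] = np.where(ctrl_male, "male", "female")
    case_df["age"] = rng.normal(CASE_AGE[0], CASE_AGE[1], len(case_df))
    ctrl_df["age"] = rng.normal(CONTROL_AGE[0], CONTROL_AGE[1], len(ctrl_df))

    out = pd.concat([case_df, ctrl_df], ignore_index=True)
    out.insert(0, "id", [f"S{i + 1:05d}" for i in range(len(out))])
    snp_cols = [s.rsid for s in spec.snps]
    out[snp_cols] = out[snp_cols].astype(float)
    if spec.missing_rate > 0:
        mask = rng.random((len(out), len(snp_cols))) < spec.missing_rate
        vals = out[snp_cols].to_numpy()
        vals[mask] = np.nan
        out[snp_cols] = vals
    order = ["id", "status", "age", "sex", "smoking", "drinking", "family_history"] + snp_cols
    return out[order]


def _case_genotype_probs(p: float, odds: float, genetic_model: str) -> np.ndarray:
    """Case genotype distribution implied by an OR on the model contrast,
    given HWE controls at risk-allele frequency ``p``."""
    ctrl = np.array([(1 - p) ** 2, 2 * p * (1 - p), p**2])
    if genetic_model == "allelic":
        odds0 = p / (1 - p)
        p_case = odds * odds0 / (1 + odds * odds0)
        return np.array([(1 - p_case) ** 2, 2 * p_case * (1 - p_case), p_case**2])
    if genetic_model == "dominant":
        exposed = ctrl[1] + ctrl[2]
        split = ctrl[1:] / exposed
    elif genetic_model == "recessive":
        exposed = ctrl[2]
        split = np.array([1.0])
    else:
        raise ValueError(f"unsupported generating model {genetic_model!r}")
    odds1 = odds * exposed / (1 - exposed)
    e1 = odds1 / (1 + odds1)
    if genetic_model == "dominant":
        return np.array([1 - e1, e1 * split[0], e1 * split[1]])
    unexposed_split = ctrl[:2] / ctrl[:2].sum()
    return np.array([(1 - e1) * unexposed_split[0], (1 - e1) * unexposed_split[1], e1])


def generate_study_collection(
    k: int,
    true_or: float,
    tau2: float,
    sizes: int | tuple[int, int] | list[tuple[int, int]],
    seed: int,
    p: float = 0.3,
    genetic_model: str = "allelic",
) -> list[StudyCounts]:
    """Simulate ``k`` studies' genotype counts around a common odds ratio.

    Each study's true log OR is drawn Normal(log true_or, tau2); controls
    follow HWE at frequency ``p`` and cases follow the genotype
    distribution implied by that study's OR under ``genetic_model``.
    tau2 = 0 yields homogeneous studies.
    """
    if k < 1:
        raise ValueError("k must be at least 1")
    if true_or <= 0:
        raise ValueError("true_or must be positive")
    if tau2 < 0:
        raise ValueError("tau2 must be non-negative")
    if isinstance(sizes, int):
        sizes = [(sizes, sizes)] * k
    elif isinstance(sizes, tuple) and len(sizes) == 2 and isinstance(sizes[0], int):
        sizes = [sizes] * k
    if len(sizes) != k:
        raise ValueError("sizes must match the number of studies")

    rng = np.random.default_rng(seed)
    ctrl_probs = np.array([(1 - p) ** 2, 2 * p * (1 - p), p**2])
    out = []
    for i, (n_case, n_ctrl) in enumerate(sizes):
        theta = rng.normal(math.log(true_or), math.sqrt(tau2))
        case_probs = _case_genotype_probs(p, math.exp(theta), genetic_model)
        out.append(
            StudyCounts(
                study_id=f"study{i + 1:03d}",
                case_counts=tuple(rng.multinomial(n_case, case_probs)),
                control_counts=tuple(rng.multinomial(n_ctrl, ctrl_probs)),
            )
        )
    return out
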