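"""Per-SNP case-control association statistics.

Hardy-Weinberg goodness of fit in controls, crude odds ratios under the
five classical genetic contrasts, false-positive report probability
(FPRP), and attributable-risk fractions.  Genotype counts are always
ordered (AA, AB, BB) with B the risk allele.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

GENETIC_MODELS = ("allelic", "heterozygous", "homozygous", "dominant", "recessive")

#: Conventional moderate threshold effect used for FPRP power when none is given.
DEFAULT_FPRP_THRESHOLD_OR = 1.5
DEFAULT_FPRP_PRIORS = (0.25, 0.1, 0.01)


@dataclass(frozen=True)
class GenotypeCounts:
    """Genotype counts (AA, AB, BB) in cases and controls; B is the risk allele."""

    case_counts: tuple[int, int, int]
    control_counts: tuple[int, int, int]

    def __post_init__(self) -> None:
        for arm in (self.case_counts, self.control_counts):
            if len(arm) != 3 or any(c < 0 for c in arm):
                raise ValueError("genotype counts must be three non-negative numbers")
            if sum(arm) < 1:
                raise ValueError("each arm must contain at least one subject")


@dataclass(frozen=True)
class AssocResult:
    """Odds ratio for one genetic contrast with Woolf 95% CI and Wald p."""

    model: str
    or_estimate: float
    ci95: tuple[float, float]
    p_value: float
    table2x2: tuple[float, float, float, float]
    log_or: float = field(repr=False, default=float("nan"))
    se_log_or: float = field(repr=False, default=float("nan"))


@dataclass(frozen=True)
class FprpResult:
    """False-positive report probability at one prior.

    ``power`` is the probability that a two-sided test at the observed
    significance level rejects when the true odds ratio equals the
    threshold effect (normal approximation, matched to the direction of
    the observed effect).
    """

    prior: float
    alpha_obs: float
    power: float
    fprp: float
    noteworthy: bool


def hwe_test(control_counts: tuple[int, int, int]) -> tuple[float, float]:
    """Chi-square goodness-of-fit of control genotypes to Hardy-Weinberg.

    The allele frequency is estimated from the counts themselves and the
    Pearson statistic carries a single degree of freedom.
    """
    n_aa, n_ab, n_bb = (float(c) for c in control_counts)
    n = n_aa + n_ab + n_bb
    if n <= 0:
        raise ValueError("control genotype counts sum to zero")
    q = (n_ab + 2.0 * n_bb) / (2.0 * n)  # risk-allele frequency
    expected = np.array([n * (1 - q) ** 2, 2 * n * q * (1 - q), n * q**2])
    observed = np.array([n_aa, n_ab, n_bb])
    # monomorphic sample: expectation degenerate, fits HWE exactly
    mask = expected > 0
    chi2 = float(((observed[mask] - expected[mask]) ** 2 / expected[mask]).sum())
    p = float(stats.chi2.sf(chi2, df=1))
    return chi2, p


def collapse_genetic_model(
    counts: GenotypeCounts, model: str
) -> tuple[float, float, float, float]:
    """Collapse genotype counts into a 2x2 contrast for one genetic model.

    Returns ``(case_exposed, case_unexposed, control_exposed,
    control_unexposed)`` where "exposed" is the risk side of the contrast:
    risk alleles (allelic), AB+BB (dominant), BB (recessive), BB vs AA
    (homozygous) or AB vs AA (heterozygous).
    """
    if model not in GENETIC_MODELS:
        raise ValueError(f"unknown genetic model {model!r}; choose from {GENETIC_MODELS}")

    def arm(c: tuple[int, int, int]) -> tuple[float, float]:
        aa, ab, bb = c
        if model == "allelic":
            return ab + 2 * bb, 2 * aa + ab
        if model == "dominant":
            return ab + bb, aa
        if model == "recessive":
            return bb, aa + ab
        if model == "homozygous":
            return bb, aa
        return ab, aa  # heterozygous

    a, b = arm(counts.case_counts)
    c, d = arm(counts.control_counts)
    return a, b, c, d


def or_2x2(
    a: float,
    b: float,
    c: float,
    d: float,
    correction: bool = True,
    model: str = "custom",
) -> AssocResult:
    """Odds ratio ``ad/bc`` with Woolf log-SE 95% CI and Wald p-value.

    ``(a, b, c, d)`` = (case exposed, case unexposed, control exposed,
    control unexposed).  When any cell is zero and ``correction`` is on,
    the Haldane-Anscombe +0.5 is added to every cell; with correction off
    a zero ``b`` or ``c`` cell raises, since the OR is infinite.
    """
    cells = [float(a), float(b), float(c), float(d)]
    if any(x < 0 for x in cells):
        raise ValueError("2x2 cells must be non-negative")
    if any(x == 0 for x in cells):
        if not correction:
            raise ZeroDivisionError(
                "zero cell yields an infinite or undefined OR; "
                "enable the Haldane-Anscombe correction"
            )
        cells = [x + 0.5 for x in cells]
    a_, b_, c_, d_ = cells
    log_or = math.log(a_ * d_ / (b_ * c_))
    se = math.sqrt(1 / a_ + 1 / b_ + 1 / c_ + 1 / d_)
    z = log_or / se
    p = 2 * float(stats.norm.sf(abs(z)))
    lo, hi = math.exp(log_or - 1.959963984540054 * se), math.exp(log_or + 1.959963984540054 * se)
    return AssocResult(
        model=model,
        or_estimate=math.exp(log_or),
        ci95=(lo, hi),
        p_value=p,
        table2x2=(a, b, c, d),
        log_or=log_or,
        se_log_or=se,
    )


def snp_association(
    counts: GenotypeCounts, models: tuple[str, ...] = GENETIC_MODELS, correction: bool = True
) -> dict[str, AssocResult]:
    """Crude ORs for one SNP under each requested genetic contrast."""
    out = {}
    for m in models:
        a, b, c, d = collapse_genetic_model(counts, m)
        out[m] = or_2x2(a, b, c, d, correction=correction, model=m)
    return out


def baseline_table(subjects: pd.DataFrame) -> pd.DataFrame:
    """Case-control comparison of baseline characteristics.

    Pearson chi-square (no continuity correction) for each binary
    variable; pooled-variance two-sample t for age.  Expects the subject
    table produced by :mod:`ecrisk.simulate` / :mod:`ecrisk.io`.
    """
    cases = subjects[subjects["status"] == 1]
    controls = subjects[subjects["status"] == 0]
    if cases.empty or controls.empty:
        raise ValueError("both arms must be non-empty")
    rows = []

    t, p = stats.ttest_ind(cases["age"], controls["age"], equal_var=True)
    rows.append(
        {
            "variable": "age",
            "test": "t",
            "statistic": float(t),
            "p_value": float(p),
            "cases": float(cases["age"].mean()),
            "controls": float(controls["age"].mean()),
        }
    )

    binaries = ["smoking", "drinking", "family_history"]
    if "sex" in subjects.columns:
        binaries = ["sex"] + binaries
    for var in binaries:
        x = (subjects[var] == "male").astype(int) if var == "sex" else subjects[var]
        tab = np.array(
            [
                [int(x[cases.index].sum()), int((1 - x[cases.index]).sum())],
                [int(x[controls.index].sum()), int((1 - x[controls.index]).sum())],
            ],
            dtype=float,
        )
        if tab[:, 0].sum() == 0 or tab[:, 1].sum() == 0:
            rows.append(
                {
                    "variable": var,
                    "test": "chi2",
                    "statistic": float("nan"),
                    "p_value": float("nan"),
                    "cases": tab[0, 0] / tab[0].sum(),
                    "controls": tab[1, 0] / tab[1].sum(),
                }
            )
            continue
        chi2, p, _, _ = stats.chi2_contingency(tab, correction=False)
        rows.append(
            {
                "variable": var,
                "test": "chi2",
                "statistic": float(chi2),
                "p_value": float(p),
                "cases": tab[0, 0] / tab[0].sum(),
                "controls": tab[1, 0] / tab[1].sum(),
            }
        )
    return pd.DataFrame(rows)


def fprp_from_power(alpha_obs: float, power: float, prior: float) -> float:
    """FPRP = alpha(1-pi) / (alpha(1-pi) + power*pi)."""
    if not 0 < prior < 1:
        raise ValueError("prior must lie strictly between 0 and 1")
    if not 0 <= alpha_obs <= 1 or not 0 <= power <= 1:
        raise ValueError("alpha and power must lie in [0, 1]")
    num = alpha_obs * (1 - prior)
    denom = num + power * prior
    return num / denom if denom > 0 else 1.0


def fprp(
    alpha_obs: float,
    or_hat: float,
    se_log_or: float,
    threshold_or: float = DEFAULT_FPRP_THRESHOLD_OR,
    prior: float = 0.25,
    cutoff: float = 0.5,
) -> FprpResult:
    """False-positive report probability for one observed association.

    Power is computed against a threshold odds ratio on the same side as
    the observed effect (the reciprocal is used for protective ORs), with
    the usual normal approximation for the log OR.
    """
    if se_log_or <= 0:
        raise ValueError("se_log_or must be positive")
    if threshold_or <= 0:
        raise ValueError("threshold_or must be positive")
    if not 0 < prior < 1:
        raise ValueError("prior must lie strictly between 0 and 1")
    theta = abs(math.log(threshold_or))
    if or_hat < 1:
        theta = -theta
    z_crit = stats.norm.isf(alpha_obs / 2)
    shift = theta / se_log_or
    power = float(stats.norm.sf(z_crit - shift) + stats.norm.cdf(-z_crit - shift))
    value = fprp_from_power(alpha_obs, power, prior)
    return FprpResult(
        prior=prior, alpha_obs=alpha_obs, power=power, fprp=value, noteworthy=value < cutoff
    )


def arp(odds_ratio: float) -> float:
    """Attributable risk percent among the exposed: 100*(OR-1)/OR.

    Defined for risk effects; a protective OR (<= 1) returns 0 — report
    such SNPs with the allele relabelled if an attributable fraction is
    wanted.
    """
    if odds_ratio <= 0:
        raise ValueError("odds ratio must be positive")
    if odds_ratio <= 1:
        return 0.0
    return 100.0 * (odds_ratio - 1.0) / odds_ratio


def parp(odds_ratio: float, exposure_prev: float) -> float:
    """Population attributable risk percent: 100*p(OR-1)/(p(OR-1)+1)."""
    if odds_ratio <= 0:
        raise ValueError("odds ratio must be positive")
    if not 0 <= exposure_prev <= 1:
        raise ValueError("exposure prevalence must lie in [0, 1]")
    if odds_ratio <= 1:
        return 0.0
    x = exposure_prev * (odds_ratio - 1.0)
    return 100.0 * x / (x + 1.0)
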