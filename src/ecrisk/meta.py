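"""Genotype-count meta-analysis: MH fixed and DL random pooling.

Pools per-study odds ratios for a chosen genetic contrast across
case-control studies, quantifies heterogeneity (Cochran Q, I2, tau2),
selects fixed vs random effects by the p_Q >= 0.10 or I2 <= 50% rule,
and tests funnel-plot asymmetry (Begg rank correlation, Egger
regression).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .assoc import GenotypeCounts, collapse_genetic_model, hwe_test, or_2x2

Z95 = 1.959963984540054


@dataclass(frozen=True)
class StudyCounts:
    """Genotype counts (AA, AB, BB) for one study's cases and controls."""

    study_id: str
    case_counts: tuple[int, int, int]
    control_counts: tuple[int, int, int]

    def genotype_counts(self) -> GenotypeCounts:
        return GenotypeCounts(self.case_counts, self.control_counts)


@dataclass(frozen=True)
class MetaResult:
    model_used: str  # "fixed" | "random"
    pooled_or: float
    ci95: tuple[float, float]
    z: float
    p_value: float
    Q: float
    df: int
    p_Q: float
    I2: float
    tau2: float
    k: int
    begg_p: float
    egger_intercept: float
    egger_p: float
    excluded: tuple[str, ...] = ()


def study_or(counts: StudyCounts, model: str) -> tuple[float, float]:
    """Woolf log OR and SE on the study's collapsed 2x2 table."""
    a, b, c, d = collapse_genetic_model(counts.genotype_counts(), model)
    if (a + b) == 0 or (c + d) == 0:
        raise ValueError(f"study {counts.study_id}: empty arm after collapse")
    res = or_2x2(a, b, c, d, model=model)
    return res.log_or, res.se_log_or


def apply_inclusion_rules(
    studies: list[StudyCounts], min_arm: int = 10, hwe_alpha: float = 0.05
) -> tuple[list[StudyCounts], list[tuple[str, str]]]:
    """Drop studies with an arm below ``min_arm`` or HWE-failing controls.

    Returns the retained studies and an audit log of (study_id, reason).
    """
    kept, audit = [], []
    for s in studies:
        if sum(s.case_counts) < min_arm or sum(s.control_counts) < min_arm:
            audit.append((s.study_id, f"arm smaller than {min_arm} subjects"))
            continue
        _, p_hwe = hwe_test(s.control_counts)
        if p_hwe < hwe_alpha:
            audit.append((s.study_id, f"controls deviate from HWE (p={p_hwe:.4g})"))
            continue
        kept.append(s)
    return kept, audit


def pool_fixed_mh(
    tables: list[tuple[float, float, float, float]],
) -> tuple[float, tuple[float, float], float, float]:
    """Mantel-Haenszel pooled OR with Robins-Breslow-Greenland variance.

    Tables are (a, b, c, d) = (case exposed, case unexposed, control
    exposed, control unexposed).  Returns (pooled OR, 95% CI, z, p).
    """
    if not tables:
        raise ValueError("no tables to pool")
    arr = np.array(tables, dtype=float)
    if np.any(arr.sum(axis=1) == 0):
        raise ValueError("degenerate (all-zero) table")
    # Haldane correction per table only where the MH terms would vanish entirely
    a, b, c, d = arr.T
    n = a + b + c + d
    r = a * d / n
    s = b * c / n
    if s.sum() == 0 or r.sum() == 0:
        arr = arr + 0.5
        a, b, c, d = arr.T
        n = a + b + c + d
        r = a * d / n
        s = b * c / n
    or_mh = r.sum() / s.sum()

    p = (a + d) / n
    q = (b + c) / n
    var_log = (
        (p * r).sum() / (2 * r.sum() ** 2)
        + ((p * s + q * r).sum()) / (2 * r.sum() * s.sum())
        + (q * s).sum() / (2 * s.sum() ** 2)
    )
    se = math.sqrt(var_log)
    log_or = math.log(or_mh)
    z = log_or / se if se > 0 else float("inf")
    p_val = 2 * float(stats.norm.sf(abs(z)))
    ci = (math.exp(log_or - Z95 * se), math.exp(log_or + Z95 * se))
    return or_mh, ci, z, p_val


def pool_random_dl(
    log_ors: np.ndarray, ses: np.ndarray
) -> tuple[float, tuple[float, float], float, float, float, float]:
    """DerSimonian-Laird random-effects pooling.

    Returns (pooled OR, 95% CI, z, p, Q, tau2).  With a single study the
    study's own estimate is returned and tau2 is NaN.
    """
    y = np.asarray(log_ors, dtype=float)
    v = np.asarray(ses, dtype=float) ** 2
    k = len(y)
    if k == 0:
        raise ValueError("no studies")
    w = 1.0 / v
    ybar = (w * y).sum() / w.sum()
    q = float((w * (y - ybar) ** 2).sum())
    if k == 1:
        se = math.sqrt(v[0])
        z = y[0] / se
        return (
            math.exp(y[0]),
            (math.exp(y[0] - Z95 * se), math.exp(y[0] + Z95 * se)),
            z,
            2 * float(stats.norm.sf(abs(z))),
            0.0,
            float("nan"),
        )
    df = k - 1
    c = w.sum() - (w**2).sum() / w.sum()
    tau2 = max(0.0, (q - df) / c) if c > 0 else 0.0
    w_star = 1.0 / (v + tau2)
    mu = (w_star * y).sum() / w_star.sum()
    se = math.sqrt(1.0 / w_star.sum())
    z = mu / se
    p = 2 * float(stats.norm.sf(abs(z)))
    return math.exp(mu), (math.exp(mu - Z95 * se), math.exp(mu + Z95 * se)), z, p, q, tau2


def heterogeneity(Q: float, df: int) -> tuple[float, float]:
    """Cochran-Q p-value and I2 = max(0, 100*(Q-df)/Q)."""
    if Q < 0:
        raise ValueError("Q must be non-negative")
    if df < 1:
        raise ValueError("df must be at least 1")
    p = float(stats.chi2.sf(Q, df))
    i2 = 0.0 if Q <= 0 else max(0.0, 100.0 * (Q - df) / Q)
    return p, i2


def select_model(p_Q: float, I2: float) -> str:
    """Fixed effects iff p_Q >= 0.10 or I2 <= 50% (disjunction); else random."""
    return "fixed" if (p_Q >= 0.10 or I2 <= 50.0) else "random"


def begg_test(log_ors: np.ndarray, ses: np.ndarray) -> float:
    """Begg-Mazumdar rank correlation test for funnel asymmetry.

    Kendall tau between the variance-standardized deviations from the
    inverse-variance pooled estimate and the study variances; p from the
    normal approximation to Kendall's S without continuity correction.
    Requires k >= 3; otherwise NaN (not evaluable).
    """
    y = np.asarray(log_ors, dtype=float)
    v = np.asarray(ses, dtype=float) ** 2
    k = len(y)
    if k < 3:
        return float("nan")
    w = 1.0 / v
    ybar = (w * y).sum() / w.sum()
    v_star = v - 1.0 / w.sum()
    v_star = np.maximum(v_star, 1e-12)
    t = (y - ybar) / np.sqrt(v_star)
    s_stat = 0
    for i in range(k):
        for j in range(i + 1, k):
            s_stat += int(np.sign((t[j] - t[i]) * (v[j] - v[i])))
    var_s = k * (k - 1) * (2 * k + 5) / 18.0
    z = s_stat / math.sqrt(var_s)
    return 2 * float(stats.norm.sf(abs(z)))


def egger_test(log_ors: np.ndarray, ses: np.ndarray) -> tuple[float, float]:
    """Egger regression test: standardized effect on precision.

    OLS of y_i/se_i on 1/se_i; the intercept estimates asymmetry and its
    t-test (k-2 df) gives the p-value.  Requires k >= 3; otherwise NaN.
    """
    y = np.asarray(log_ors, dtype=float)
    se = np.asarray(ses, dtype=float)
    k = len(y)
    if k < 3:
        return float("nan"), float("nan")
    t_i = y / se
    prec = 1.0 / se
    fit = sm.OLS(t_i, sm.add_constant(prec)).fit()
    return float(fit.params[0]), float(fit.pvalues[0])


def meta_analyze(
    studies: list[StudyCounts],
    genetic_model: str = "allelic",
    enforce_inclusion: bool = False,
) -> MetaResult:
    """Full pooling of one SNP's studies under one genetic contrast.

    Heterogeneity (Q, I2, tau2) is computed from the inverse-variance
    Woolf log ORs; the fixed-effect pooled OR uses Mantel-Haenszel with
    the RBG variance, the random-effects pooled OR uses DL re-weighting.
    """
    excluded: tuple[str, ...] = ()
    if enforce_inclusion:
        studies, audit = apply_inclusion_rules(studies)
        excluded = tuple(sid for sid, _ in audit)
    if not studies:
        raise ValueError("no studies remain after applying inclusion rules")

    tables, log_ors, ses = [], [], []
    for s in studies:
        a, b, c, d = collapse_genetic_model(s.genotype_counts(), genetic_model)
        res = or_2x2(a, b, c, d, model=genetic_model)
        tables.append((a, b, c, d))
        log_ors.append(res.log_or)
        ses.append(res.se_log_or)
    y = np.array(log_ors)
    se = np.array(ses)
    k = len(y)

    _, _, _, _, q, tau2 = pool_random_dl(y, se) if k >= 2 else (None, None, None, None, 0.0, 0.0)
    if k >= 2:
        p_q, i2 = heterogeneity(q, k - 1)
    else:
        q, p_q, i2, tau2 = 0.0, 1.0, 0.0, float("nan")

    chosen = select_model(p_q, i2)
    if chosen == "fixed":
        pooled, ci, z, p = pool_fixed_mh(tables)
    else:
        pooled, ci, z, p, _, _ = pool_random_dl(y, se)

    return MetaResult(
        model_used=chosen,
        pooled_or=pooled,
        ci95=ci,
        z=z,
        p_value=p,
        Q=float(q),
        df=max(k - 1, 0),
        p_Q=p_q,
        I2=i2,
        tau2=tau2,
        k=k,
        begg_p=begg_test(y, se),
        egger_intercept=egger_test(y, se)[0],
        egger_p=egger_test(y, se)[1],
        excluded=excluded,
    )
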