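"""Multiplicative weighted genetic risk score (wGRS).

Each SNP contributes a genotype score normalized by

    W = (1-p)^2 + 2p(1-p)*OR + p^2*OR^2

so that the expected score under Hardy-Weinberg equilibrium at the
reference risk-allele frequency ``p`` is exactly 1.  Genotype scores are
AA = 1/W, AB = OR/W, BB = OR^2/W (B = risk allele), and the subject-level
wGRS is the product over SNPs, with missing genotypes contributing a
factor of 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

ADJUSTMENT_COVARIATES = ("age", "smoking", "drinking", "family_history")


@dataclass(frozen=True)
class SnpSpec:
    """One SNP of the score panel.

    ``p`` is the risk-allele frequency in the reference population and
    ``or_allele`` the per-risk-allele odds ratio used as the weight.
    ``genetic_model`` records the best-fitting contrast for the SNP; it
    drives simulation and association testing, not the score itself.
    """

    rsid: str
    risk_allele: str
    p: float
    or_allele: float
    genetic_model: str = "allelic"

    def __post_init__(self) -> None:
        if not 0 <= self.p <= 1:
            raise ValueError(f"{self.rsid}: risk-allele frequency must lie in [0, 1]")
        if self.or_allele <= 0:
            raise ValueError(f"{self.rsid}: odds ratio must be positive")


@dataclass(frozen=True)
class SnpScoreTable:
    rsid: str
    W: float
    score_AA: float
    score_AB: float
    score_BB: float

    def score(self, dosage: float) -> float:
        """Score for a risk-allele dosage; missing (NaN) scores as 1."""
        if dosage is None or (isinstance(dosage, float) and math.isnan(dosage)):
            return 1.0
        if dosage == 0:
            return self.score_AA
        if dosage == 1:
            return self.score_AB
        if dosage == 2:
            return self.score_BB
        raise ValueError(f"{self.rsid}: dosage must be 0, 1, 2 or missing, got {dosage!r}")


@dataclass(frozen=True)
class WgrsQuartiles:
    """Adjusted quartile association of the wGRS with disease."""

    cutpoints: tuple[float, float, float]
    odds_ratios: tuple[float, ...]  # Q1 (reference, 1.0) .. Q4
    ci95: tuple[tuple[float, float], ...]
    p_values: tuple[float, ...]
    trend_p: float
    counts: tuple[tuple[int, int], ...]  # (cases, controls) per quartile


def score_snp(spec: SnpSpec) -> SnpScoreTable:
    """Genotype score table for one SNP: W and the three genotype scores."""
    p, odds = spec.p, spec.or_allele
    w = (1 - p) ** 2 + 2 * p * (1 - p) * odds + p**2 * odds**2
    return SnpScoreTable(
        rsid=spec.rsid, W=w, score_AA=1.0 / w, score_AB=odds / w, score_BB=odds**2 / w
    )


def compute_wgrs(dosages: dict[str, float], tables: list[SnpScoreTable]) -> float:
    """wGRS for one subject: product of per-SNP genotype scores.

    Missing genotypes contribute a factor of 1.  A dosage for an rsID
    without a score table is an error; a table without a dosage column is
    treated as missing.
    """
    known = {t.rsid for t in tables}
    extra = [r for r in dosages if r not in known]
    if extra:
        raise KeyError(f"no score table for SNP(s): {', '.join(sorted(extra))}")
    value = 1.0
    for table in tables:
        value *= table.score(dosages.get(table.rsid, float("nan")))
    return value


def add_wgrs(subjects: pd.DataFrame, panel: list[SnpSpec]) -> pd.Series:
    """Vectorized wGRS over a subject table (one dosage column per rsID)."""
    tables = [score_snp(s) for s in panel]
    value = np.ones(len(subjects))
    for t in tables:
        if t.rsid not in subjects.columns:
            continue
        d = subjects[t.rsid].to_numpy(dtype=float)
        scores = np.ones_like(d)
        for dosage, s in ((0, t.score_AA), (1, t.score_AB), (2, t.score_BB)):
            scores[d == dosage] = s
        value *= scores
    return pd.Series(value, index=subjects.index, name="wgrs")


def assign_quartiles(values: pd.Series, cutpoints: tuple[float, float, float]) -> pd.Series:
    """Quartile labels 1-4 with left-closed intervals (ties to the lower quartile)."""
    cuts = np.asarray(cutpoints, dtype=float)
    if np.any(np.diff(cuts) < 0):
        raise ValueError("cutpoints must be non-decreasing")
    q = np.searchsorted(cuts, values.to_numpy(dtype=float), side="left") + 1
    return pd.Series(q, index=values.index, name="wgrs_quartile")


def control_cutpoints(subjects: pd.DataFrame, wgrs: pd.Series) -> tuple[float, float, float]:
    """Quartile cutpoints of the control wGRS distribution."""
    ctrl = wgrs[subjects["status"] == 0]
    if ctrl.nunique() < 4:
        raise ValueError("need at least 4 distinct control wGRS values for quartiles")
    q1, q2, q3 = np.quantile(ctrl.to_numpy(), [0.25, 0.5, 0.75])
    return float(q1), float(q2), float(q3)


def quartile_association(
    subjects: pd.DataFrame,
    wgrs: pd.Series,
    cutpoints: tuple[float, float, float] | None = None,
    covariates: tuple[str, ...] = ADJUSTMENT_COVARIATES,
) -> WgrsQuartiles:
    """Quartile-based wGRS association, adjusted by logistic regression.

    Cutpoints default to the quartiles of the control distribution in the
    supplied data; pass frozen training-set cutpoints when scoring a
    validation set.  Per-quartile ORs (lowest quartile reference) come
    from a multivariable logistic model adjusted for age, smoking,
    drinking and family history; the trend p is the Wald p of an ordinal
    1-4 quartile term in the same adjusted model.
    """
    if cutpoints is None:
        cutpoints = control_cutpoints(subjects, wgrs)
    quart = assign_quartiles(wgrs, cutpoints)
    y = subjects["status"].to_numpy(dtype=float)

    counts = []
    for q in (1, 2, 3, 4):
        in_q = quart == q
        counts.append((int(y[in_q].sum()), int((1 - y[in_q]).sum())))

    dummies = pd.get_dummies(quart, prefix="Q", dtype=float).reindex(
        columns=["Q_1", "Q_2", "Q_3", "Q_4"], fill_value=0.0
    )
    covs = subjects[list(covariates)].astype(float)
    x = pd.concat([dummies[["Q_2", "Q_3", "Q_4"]], covs], axis=1)
    # IRLS-based GLM: robust to quasi-separated covariates (e.g. a rare
    # family-history cell), which would break a Newton Logit fit
    fit = sm.GLM(
        y, sm.add_constant(x, has_constant="add"), family=sm.families.Binomial()
    ).fit(maxiter=200)

    odds_ratios: list[float] = [1.0]
    cis: list[tuple[float, float]] = [(float("nan"), float("nan"))]
    pvals: list[float] = [float("nan")]
    conf = fit.conf_int()
    for name in ("Q_2", "Q_3", "Q_4"):
        if counts[int(name[-1]) - 1] == (0, 0):
            odds_ratios.append(float("nan"))
            cis.append((float("nan"), float("nan")))
            pvals.append(float("nan"))
            continue
        odds_ratios.append(float(np.exp(fit.params[name])))
        cis.append((float(np.exp(conf.loc[name, 0])), float(np.exp(conf.loc[name, 1]))))
        pvals.append(float(fit.pvalues[name]))

    x_trend = pd.concat([quart.astype(float).rename("quartile"), covs], axis=1)
    fit_trend = sm.GLM(
        y, sm.add_constant(x_trend, has_constant="add"), family=sm.families.Binomial()
    ).fit(maxiter=200)
    trend_p = float(fit_trend.pvalues["quartile"])

    return WgrsQuartiles(
        cutpoints=cutpoints,
        odds_ratios=tuple(odds_ratios),
        ci95=tuple(cis),
        p_values=tuple(pvals),
        trend_p=trend_p,
        counts=tuple(counts),
    )
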