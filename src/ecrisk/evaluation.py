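"""Discrimination and fit metrics for competing risk models.

AUC as the Mann-Whitney concordance probability (half credit for ties)
with a DeLong variance; operating-point statistics at the Youden-optimal
threshold; the DeLong test for paired AUCs via structural components;
continuous and categorical net reclassification improvement (NRI); and
AIC/BIC.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

Z95 = 1.959963984540054


@dataclass(frozen=True)
class ModelEval:
    """Table-3-style evaluation of one model's scores."""

    auc: float
    auc_ci95: tuple[float, float]
    youden: float
    threshold: float
    sensitivity: float  # percent
    specificity: float  # percent
    accuracy: float  # percent
    lr_pos: float
    lr_neg: float
    aic: float | None = None
    bic: float | None = None


@dataclass(frozen=True)
class ModelComparison:
    """Table-4-style head-to-head comparison of two models."""

    delta_auc: float
    delta_auc_ci95: tuple[float, float]
    delong_z: float
    delong_p: float
    nri: float
    nri_z: float
    nri_p: float


def _split_scores(scores: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    cases = scores[labels == 1]
    controls = scores[labels == 0]
    if len(cases) == 0 or len(controls) == 0:
        raise ValueError("both classes must be present")
    return cases, controls


def _structural_components(
    cases: np.ndarray, controls: np.ndarray
) -> tuple[float, np.ndarray, np.ndarray]:
    """AUC and DeLong structural components via midranks.

    V10[i] is the mean of the Mann-Whitney kernel over controls for case
    i, V01[j] the mean over cases for control j.
    """
    m, n = len(cases), len(controls)
    combined = np.concatenate([cases, controls])
    tz = stats.rankdata(combined)  # midranks
    tx = stats.rankdata(cases)
    ty = stats.rankdata(controls)
    v10 = (tz[:m] - tx) / n
    v01 = 1.0 - (tz[m:] - ty) / m
    auc = float(v10.mean())
    return auc, v10, v01


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> tuple[float, tuple[float, float]]:
    """AUC with a 95% CI from the DeLong variance."""
    cases, controls = _split_scores(np.asarray(scores), np.asarray(labels))
    auc, v10, v01 = _structural_components(cases, controls)
    var = _delong_var(v10, v01)
    se = math.sqrt(var)
    lo, hi = max(0.0, auc - Z95 * se), min(1.0, auc + Z95 * se)
    return auc, (lo, hi)


def _delong_var(v10: np.ndarray, v01: np.ndarray) -> float:
    s10 = float(np.var(v10, ddof=1)) if len(v10) > 1 else 0.0
    s01 = float(np.var(v01, ddof=1)) if len(v01) > 1 else 0.0
    return s10 / len(v10) + s01 / len(v01)


def operating_point(scores: np.ndarray, labels: np.ndarray) -> ModelEval:
    """Operating-point statistics at the Youden-optimal threshold.

    Thresholds are scanned at midpoints between adjacent distinct scores
    (plus sentinels beyond the extremes); a subject is called positive
    when its score is at or above the threshold.  Youden ties are broken
    toward the higher-specificity threshold.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    cases, controls = _split_scores(scores, labels)
    auc, ci = roc_auc(scores, labels)

    uniq = np.unique(scores)
    candidates = np.concatenate(
        [[uniq[0] - 1.0], (uniq[:-1] + uniq[1:]) / 2.0, [uniq[-1] + 1.0]]
    )
    best = None
    for thr in candidates:
        sens = float((cases >= thr).mean())
        spec = float((controls < thr).mean())
        youden = sens + spec - 1.0
        # strictly-better Youden wins; on ties keep the higher specificity
        if best is None or youden > best[0] + 1e-12 or (
            abs(youden - best[0]) <= 1e-12 and spec > best[2]
        ):
            best = (youden, sens, spec, thr)
    youden, sens, spec, thr = best
    tp = float((cases >= thr).sum())
    tn = float((controls < thr).sum())
    accuracy = (tp + tn) / (len(cases) + len(controls))
    lr_pos = sens / (1 - spec) if spec < 1 else float("inf")
    lr_neg = (1 - sens) / spec if spec > 0 else float("inf")
    return ModelEval(
        auc=auc,
        auc_ci95=ci,
        youden=youden,
        threshold=float(thr),
        sensitivity=100.0 * sens,
        specificity=100.0 * spec,
        accuracy=100.0 * accuracy,
        lr_pos=lr_pos,
        lr_neg=lr_neg,
    )


def delong_compare(
    scores_a: np.ndarray, scores_b: np.ndarray, labels: np.ndarray
) -> tuple[float, tuple[float, float], float, float]:
    """DeLong test for the difference of two paired AUCs.

    Returns (delta_auc, 95% CI, z, p).  Scores must be paired: both
    models evaluated on the same subjects in the same order.
    """
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    labels = np.asarray(labels)
    if scores_a.shape != scores_b.shape:
        raise ValueError("paired score vectors must have equal length")
    ca, na = _split_scores(scores_a, labels)
    cb, nb = _split_scores(scores_b, labels)
    auc_a, v10_a, v01_a = _structural_components(ca, na)
    auc_b, v10_b, v01_b = _structural_components(cb, nb)
    m, n = len(ca), len(na)
    s10 = np.cov(np.vstack([v10_a, v10_b]), ddof=1) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(np.vstack([v01_a, v01_b]), ddof=1) if n > 1 else np.zeros((2, 2))
    cov = s10 / m + s01 / n
    delta = auc_a - auc_b
    var = cov[0, 0] + cov[1, 1] - 2 * cov[0, 1]
    if var <= 0:
        return delta, (delta, delta), 0.0, 1.0
    se = math.sqrt(var)
    z = delta / se
    p = 2 * float(stats.norm.sf(abs(z)))
    return delta, (delta - Z95 * se, delta + Z95 * se), z, p


def nri(
    old_scores: np.ndarray,
    new_scores: np.ndarray,
    labels: np.ndarray,
    mode: str = "continuous",
    thresholds: tuple[float, ...] | None = None,
) -> tuple[float, float, float]:
    """Net reclassification improvement of new over old predictions.

    Continuous (category-free) mode counts any increase/decrease in
    predicted risk; categorical mode reclassifies across the supplied
    risk-category thresholds.  Returns (NRI, z, p) with the standard
    two-proportion asymptotic variance.
    """
    old = np.asarray(old_scores, dtype=float)
    new = np.asarray(new_scores, dtype=float)
    labels = np.asarray(labels)
    if old.shape != new.shape or old.shape != labels.shape:
        raise ValueError("old, new and labels must have equal length")
    if mode == "categorical":
        if thresholds is None:
            raise ValueError("categorical NRI requires risk-category thresholds")
        cuts = np.asarray(thresholds, dtype=float)
        old = np.searchsorted(cuts, old, side="right").astype(float)
        new = np.searchsorted(cuts, new, side="right").astype(float)
    elif mode != "continuous":
        raise ValueError(f"unknown NRI mode {mode!r}")

    is_case = labels == 1
    up = new > old
    down = new < old
    n_e = int(is_case.sum())
    n_c = int((~is_case).sum())
    if n_e == 0 or n_c == 0:
        raise ValueError("both classes must be present")
    pu_e = float(up[is_case].mean())
    pd_e = float(down[is_case].mean())
    pu_c = float(up[~is_case].mean())
    pd_c = float(down[~is_case].mean())
    value = (pu_e - pd_e) + (pd_c - pu_c)
    var = (pu_e + pd_e - (pu_e - pd_e) ** 2) / n_e + (pu_c + pd_c - (pd_c - pu_c) ** 2) / n_c
    if var <= 0:
        return value, 0.0, 1.0
    z = value / math.sqrt(var)
    return value, z, 2 * float(stats.norm.sf(abs(z)))


def aic_bic(log_likelihood: float, k: int, n: int) -> tuple[float, float]:
    """AIC = -2logL + 2k; BIC = -2logL + k ln n."""
    if k < 1 or n < 1:
        raise ValueError("k and n must be at least 1")
    return -2.0 * log_likelihood + 2.0 * k, -2.0 * log_likelihood + k * math.log(n)


def evaluate_model(
    scores: np.ndarray,
    labels: np.ndarray,
    log_likelihood: float | None = None,
    k: int | None = None,
) -> ModelEval:
    """Full Table-3-style evaluation; AIC/BIC when a fit is supplied."""
    ev = operating_point(scores, labels)
    if log_likelihood is not None and k is not None:
        aic, bic = aic_bic(log_likelihood, k, len(np.asarray(labels)))
        ev = ModelEval(**{**ev.__dict__, "aic": aic, "bic": bic})
    return ev


def compare_models(
    scores_a: np.ndarray,
    scores_b: np.ndarray,
    labels: np.ndarray,
    nri_mode: str = "continuous",
    nri_thresholds: tuple[float, ...] | None = None,
) -> ModelComparison:
    """DeLong AUC difference plus NRI for model b over model a."""
    delta, ci, z, p = delong_compare(scores_b, scores_a, labels)
    nri_val, nri_z, nri_p = nri(scores_a, scores_b, labels, nri_mode, nri_thresholds)
    return ModelComparison(
        delta_auc=delta,
        delta_auc_ci95=ci,
        delong_z=z,
        delong_p=p,
        nri=nri_val,
        nri_z=nri_z,
        nri_p=nri_p,
    )
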