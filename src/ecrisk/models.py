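"""Logistic risk models: genetic (wGRS), non-genetic, and combined.

The genetic model regresses disease on the wGRS alone; the non-genetic
model on smoking, family history and the smoking x drinking interaction
(no drinking main effect — the published model is deliberately
non-hierarchical); the combined model on the union.  Data are split
60/40 into training and validation by simple (unstratified)
randomization.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

logger = logging.getLogger(__name__)

MODEL_TERMS: dict[str, tuple[str, ...]] = {
    "genetic": ("wgrs",),
    "non_genetic": ("smoking", "family_history", "smoking_x_drinking"),
    "combined": ("wgrs", "smoking", "family_history", "smoking_x_drinking"),
}

#: Published coefficient vectors, frozen for regression tests and demos.
_PRINTED_MODELS = {
    "non_genetic_paper": {
        "intercept": -0.236,
        "smoking": -0.584,
        "family_history": 2.038,
        "smoking_x_drinking": 1.392,
    },
    "combined_paper": {
        "intercept": -1.110,
        "wgrs": 0.908,
        "smoking": -0.558,
        "family_history": 1.976,
        "smoking_x_drinking": 1.393,
    },
}


@dataclass(frozen=True)
class FittedModel:
    """A fitted (or frozen) logistic risk model."""

    name: str
    terms: tuple[str, ...]
    coefficients: dict[str, float]  # includes "intercept"
    log_likelihood: float | None = None
    n: int | None = None
    k: int = field(default=0)

    def __post_init__(self) -> None:
        object.__setattr__(self, "k", len(self.coefficients))
        if any(not math.isfinite(v) for v in self.coefficients.values()):
            raise ValueError(f"model {self.name}: non-finite coefficients")


def split_data(
    subjects: pd.DataFrame, fraction: float = 0.6, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simple random train/validation split, reproducible by seed."""
    if subjects.empty:
        raise ValueError("cannot split an empty table")
    if not 0 < fraction <= 1:
        raise ValueError("fraction must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(subjects))
    n_train = round(fraction * len(subjects))
    train = subjects.iloc[perm[:n_train]].reset_index(drop=True)
    valid = subjects.iloc[perm[n_train:]].reset_index(drop=True)
    if valid.empty:
        logger.warning("validation set is empty (fraction=%.3f)", fraction)
    return train, valid


def build_design(subjects: pd.DataFrame, terms: tuple[str, ...]) -> pd.DataFrame:
    """Design matrix for the given terms; derives the interaction column."""
    df = subjects.copy()
    if "smoking_x_drinking" in terms and "smoking_x_drinking" not in df.columns:
        df["smoking_x_drinking"] = df["smoking"] * df["drinking"]
    missing = [t for t in terms if t not in df.columns]
    if missing:
        raise KeyError(f"missing model terms: {', '.join(missing)}")
    return df[list(terms)].astype(float)


def fit_logistic(
    design: pd.DataFrame, outcome: np.ndarray | pd.Series, name: str = "model"
) -> FittedModel:
    """Maximum-likelihood logistic fit with separation/collinearity checks."""
    y = np.asarray(outcome, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("outcome must be binary 0/1")
    if len(set(np.unique(y))) < 2:
        raise ValueError("outcome must contain both classes")
    x = sm.add_constant(design.astype(float), has_constant="add")
    if len(y) <= x.shape[1]:
        raise ValueError("more parameters than observations")
    rank = np.linalg.matrix_rank(x.to_numpy())
    if rank < x.shape[1]:
        raise ValueError(f"singular design matrix; check collinearity among {list(design.columns)}")
    import warnings

    from statsmodels.tools.sm_exceptions import PerfectSeparationWarning

    with warnings.catch_warnings():
        warnings.simplefilter("error", PerfectSeparationWarning)
        try:
            fit = sm.Logit(y, x).fit(disp=0, maxiter=200)
        except (PerfectSeparationWarning, np.linalg.LinAlgError) as err:
            raise RuntimeError(
                f"model {name}: complete or quasi-complete separation detected; "
                "coefficients diverge"
            ) from err
    params = np.asarray(fit.params)
    if not fit.mle_retvals.get("converged", False) or np.abs(params).max() > 30:
        raise RuntimeError(
            f"model {name}: fit did not converge or coefficients diverged "
            "(possible complete separation)"
        )
    coefs = {"intercept": float(fit.params["const"])}
    coefs.update({t: float(fit.params[t]) for t in design.columns})
    return FittedModel(
        name=name,
        terms=tuple(design.columns),
        coefficients=coefs,
        log_likelihood=float(fit.llf),
        n=int(len(y)),
    )


def fit_model(subjects: pd.DataFrame, name: str) -> FittedModel:
    """Fit one of the three named risk models on a subject table with a
    ``wgrs`` column (for genetic/combined)."""
    if name not in MODEL_TERMS:
        raise KeyError(f"unknown model {name!r}; choose from {sorted(MODEL_TERMS)}")
    if name == "non_genetic":
        logger.warning(
            "non_genetic model includes smoking x drinking without a drinking "
            "main effect (replicating the published, non-hierarchical form)"
        )
    design = build_design(subjects, MODEL_TERMS[name])
    return fit_logistic(design, subjects["status"], name=name)


def predict(model: FittedModel, subjects: pd.DataFrame) -> pd.Series:
    """Predicted disease probability: inverse logit of the linear predictor."""
    design = build_design(subjects, model.terms)
    eta = np.full(len(design), model.coefficients["intercept"])
    for term in model.terms:
        eta += design[term].to_numpy() * model.coefficients[term]
    return pd.Series(1.0 / (1.0 + np.exp(-eta)), index=subjects.index, name=model.name)


def load_printed_model(name: str) -> FittedModel:
    """The published coefficient vectors as frozen models.

    ``non_genetic_paper``: smoking, family history, smoking x drinking.
    ``combined_paper``: wGRS plus the same non-genetic terms.
    """
    if name not in _PRINTED_MODELS:
        raise KeyError(f"unknown printed model {name!r}; choose from {sorted(_PRINTED_MODELS)}")
    coefs = dict(_PRINTED_MODELS[name])
    terms = tuple(t for t in coefs if t != "intercept")
    return FittedModel(name=name, terms=terms, coefficients=coefs)
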