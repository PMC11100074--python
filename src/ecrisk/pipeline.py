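"""End-to-end orchestration: simulate/ingest -> association -> wGRS ->
split -> fit -> evaluate -> compare, with all intermediates written.

Every stage draws its randomness from substreams derived from one run
seed, so a fixed configuration reproduces byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as eio
from .assoc import (
    DEFAULT_FPRP_PRIORS,
    GenotypeCounts,
    arp,
    baseline_table,
    fprp,
    hwe_test,
    parp,
    snp_association,
)
from .evaluation import compare_models, evaluate_model
from .grs import SnpSpec, add_wgrs, control_cutpoints, quartile_association
from .models import MODEL_TERMS, fit_model, predict, split_data
from .simulate import PopulationSpec, generate_case_control

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Configuration of a full pipeline run."""

    panel: list[SnpSpec]
    subjects_path: str | None = None  # None -> simulate
    n_cases: int = 500
    n_controls: int = 500
    split_fraction: float = 0.6
    seed: int = 17
    fprp_priors: tuple[float, ...] = DEFAULT_FPRP_PRIORS
    fprp_threshold_or: float = 1.5
    nri_mode: str = "continuous"
    outdir: str = "ecrisk_run"

    def __post_init__(self) -> None:
        if not 0 < self.split_fraction < 1:
            raise ValueError("split_fraction must lie in (0, 1)")
        for prior in self.fprp_priors:
            if not 0 < prior < 1:
                raise ValueError("FPRP priors must lie in (0, 1)")


@dataclass
class RunReport:
    seed: int
    config: dict
    baseline: pd.DataFrame
    association: pd.DataFrame
    quartiles_training: object
    quartiles_validation: object
    evaluation: pd.DataFrame
    comparison: pd.DataFrame
    outdir: Path = field(repr=False, default=Path("."))


def _substream(seed: int, stage: int) -> int:
    """Deterministic per-stage seed; adding stages never shifts earlier draws."""
    return int(np.random.SeedSequence([seed, stage]).generate_state(1)[0] % (2**31))


def genotype_counts_from_subjects(subjects: pd.DataFrame, rsid: str) -> GenotypeCounts:
    """Observed genotype counts for one SNP (missing dosages dropped)."""
    d = subjects[[rsid, "status"]].dropna()
    case = d[d["status"] == 1][rsid]
    ctrl = d[d["status"] == 0][rsid]
    return GenotypeCounts(
        tuple(int((case == g).sum()) for g in (0, 1, 2)),
        tuple(int((ctrl == g).sum()) for g in (0, 1, 2)),
    )


def association_report(
    subjects: pd.DataFrame,
    panel: list[SnpSpec],
    priors: tuple[float, ...] = DEFAULT_FPRP_PRIORS,
    threshold_or: float = 1.5,
) -> pd.DataFrame:
    """Per-SNP crude association across the five genetic contrasts, with
    control HWE, FPRP at each prior (for the SNP's own model), and
    ARP/PARP at the control exposure prevalence of the risk contrast."""
    rows = []
    for snp in panel:
        counts = genotype_counts_from_subjects(subjects, snp.rsid)
        chi2_hwe, p_hwe = hwe_test(counts.control_counts)
        results = snp_association(counts)
        for model, res in results.items():
            row = {
                "rsid": snp.rsid,
                "model": model,
                "or": res.or_estimate,
                "ci_lo": res.ci95[0],
                "ci_hi": res.ci95[1],
                "p_value": res.p_value,
                "hwe_chi2": chi2_hwe,
                "hwe_p": p_hwe,
            }
            if model == snp.genetic_model:
                for prior in priors:
                    fr = fprp(
                        max(res.p_value, 1e-300),
                        res.or_estimate,
                        res.se_log_or,
                        threshold_or=threshold_or,
                        prior=prior,
                    )
                    row[f"fprp_{prior}"] = fr.fprp
                # prevalence of the risk contrast among controls
                _, _, c, d = res.table2x2
                prev = c / (c + d) if (c + d) > 0 else float("nan")
                row["arp"] = arp(res.or_estimate)
                row["parp"] = parp(res.or_estimate, prev) if res.or_estimate > 1 else 0.0
            rows.append(row)
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute the full analysis and write per-stage reports."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    if config.subjects_path is None:
        spec = PopulationSpec(
            snps=config.panel,
            n_cases=config.n_cases,
            n_controls=config.n_controls,
            seed=_substream(config.seed, 0),
        )
        subjects = generate_case_control(spec)
        eio.write_subject_table(subjects, outdir / "subjects.tsv")
    else:
        subjects = eio.read_subject_table(config.subjects_path)

    base = baseline_table(subjects)
    base.to_csv(outdir / "baseline.tsv", sep="\t", index=False)

    assoc_df = association_report(
        subjects, config.panel, config.fprp_priors, config.fprp_threshold_or
    )
    assoc_df.to_csv(outdir / "association.tsv", sep="\t", index=False)

    subjects = subjects.copy()
    subjects["wgrs"] = add_wgrs(subjects, config.panel)
    subjects[["id", "wgrs"]].to_csv(outdir / "wgrs.tsv", sep="\t", index=False)

    train, valid = split_data(subjects, config.split_fraction, _substream(config.seed, 1))

    cuts = control_cutpoints(train, train["wgrs"])
    quart_train = quartile_association(train, train["wgrs"], cuts)
    quart_valid = quartile_association(valid, valid["wgrs"], cuts)

    fits = {name: fit_model(train, name) for name in MODEL_TERMS}
    for name, model in fits.items():
        eio.write_model(model, outdir / f"model_{name}.json")

    eval_rows, preds = [], {}
    for dataset, df in (("training", train), ("validation", valid)):
        for name, model in fits.items():
            scores = predict(model, df)
            preds[(dataset, name)] = scores
            ev = evaluate_model(
                scores.to_numpy(), df["status"].to_numpy(), model.log_likelihood, model.k
            )
            # AIC/BIC belong to the training fit; recompute only there
            eval_rows.append(
                {
                    "dataset": dataset,
                    "model": name,
                    "auc": ev.auc,
                    "auc_lo": ev.auc_ci95[0],
                    "auc_hi": ev.auc_ci95[1],
                    "youden": ev.youden,
                    "sensitivity_pct": ev.sensitivity,
                    "specificity_pct": ev.specificity,
                    "accuracy_pct": ev.accuracy,
                    "lr_pos": ev.lr_pos,
                    "lr_neg": ev.lr_neg,
                    "aic": ev.aic if dataset == "training" else float("nan"),
                    "bic": ev.bic if dataset == "training" else float("nan"),
                }
            )
    eval_df = pd.DataFrame(eval_rows)
    eval_df.to_csv(outdir / "evaluation.tsv", sep="\t", index=False)

    comp_rows = []
    pairs = [("genetic", "non_genetic"), ("genetic", "combined"), ("non_genetic", "combined")]
    for dataset, df in (("training", train), ("validation", valid)):
        y = df["status"].to_numpy()
        for old, new in pairs:
            comp = compare_models(
                preds[(dataset, old)].to_numpy(),
                preds[(dataset, new)].to_numpy(),
                y,
                nri_mode=config.nri_mode,
            )
            comp_rows.append(
                {
                    "dataset": dataset,
                    "comparison": f"{old} vs {new}",
                    "delta_auc": comp.delta_auc,
                    "delta_lo": comp.delta_auc_ci95[0],
                    "delta_hi": comp.delta_auc_ci95[1],
                    "delong_z": comp.delong_z,
                    "delong_p": comp.delong_p,
                    "nri": comp.nri,
                    "nri_z": comp.nri_z,
                    "nri_p": comp.nri_p,
                }
            )
    comp_df = pd.DataFrame(comp_rows)
    comp_df.to_csv(outdir / "comparison.tsv", sep="\t", index=False)

    report = RunReport(
        seed=config.seed,
        config={
            **{
                k: v
                for k, v in dataclasses.asdict(config).items()
                if k not in ("panel",)
            },
            "panel": [s.rsid for s in config.panel],
        },
        baseline=base,
        association=assoc_df,
        quartiles_training=quart_train,
        quartiles_validation=quart_valid,
        evaluation=eval_df,
        comparison=comp_df,
        outdir=outdir,
    )
    summary = {
        "seed": config.seed,
        "config": report.config,
        "quartiles": {
            ds: {
                "cutpoints": list(q.cutpoints),
                "odds_ratios": list(q.odds_ratios),
                "trend_p": q.trend_p,
            }
            for ds, q in (("training", quart_train), ("validation", quart_valid))
        },
    }
    (outdir / "run_report.json").write_text(json.dumps(summary, indent=2) + "\n")
    return report
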