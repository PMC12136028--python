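"""End-to-end orchestration: prep -> cutpoints -> score building -> survival
evaluation (+ optional taxonomy), with a reproducibility manifest.

Train/validation hygiene: all model decisions (sparsity filter, imputation,
cutpoints, ridge ordering, selection, thresholds) are made on the training
cohort only; the validation cohort is imputed separately and only ever
scored with the frozen model.
"""

from __future__ import annotations

import hashlib
import json
import time
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from statsmodels.stats.proportion import proportion_confint

from . import __version__
from .cutpoints import binarize, cutpoint_table, fit_cutpoints, mann_whitney_auc
from .datatypes import MetaboliteMatrix, validate_cohort
from .errors import DegenerateDataError, PipelineError
from .prep import filter_sparse_metabolites, impute_pmm, stratified_split
from .score import (
    MDSModel,
    apply_score,
    build_iterations,
    iteration_table,
    ridge_importance,
    select_model,
)
from .survival import cox_fit, kaplan_meier, log_rank, schoenfeld_ph_test


@dataclass
class RunConfig:
    """Pipeline configuration; every random decision has a named seed."""

    cohort_path: str | None = None
    metabolites_path: str | None = None
    taxa_path: str | None = None
    out_dir: str = "mds_run"
    train_fraction: float = 0.75
    split_seed: int = 0
    imputation_seed: int = 0
    ridge_seed: int = 0
    bootstrap_seed: int = 0
    simulation_seed: int = 0
    n_boot: int = 10
    donors: int = 5
    max_missing_frac: float = 0.20
    exclusions: list[str] = field(default_factory=list)
    impute_exempt: list[str] = field(default_factory=list)
    cv_folds: int = 5
    ridge_family: str = "logistic"
    selection_tolerance: float = 0.01
    selection_objective: str = "accuracy"
    rmst_tau: float = 30.0
    covariates: list[str] = field(default_factory=lambda: ["cci", "sofa"])

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:12]


def performance_table(scores, labels, threshold: float) -> dict:
    """Accuracy / sensitivity / specificity with Wilson 95% CIs plus AUC.

    Nonsurvivors (label 1) are the positive class; prediction is
    score > threshold.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise DegenerateDataError("labels contain a single class")
    pred = scores > threshold
    pos = labels == 1

    def wilson(count, nobs):
        if nobs == 0:
            return (float("nan"), float("nan"))
        lo, hi = proportion_confint(count, nobs, alpha=0.05, method="wilson")
        return (float(lo), float(hi))

    n = len(labels)
    n_correct = int((pred == pos).sum())
    tp = int((pred & pos).sum())
    tn = int((~pred & ~pos).sum())
    n_pos = int(pos.sum())
    n_neg = n - n_pos
    return {
        "auc": float(mann_whitney_auc(scores, labels)),
        "accuracy": n_correct / n,
        "accuracy_ci": wilson(n_correct, n),
        "sensitivity": tp / n_pos,
        "sensitivity_ci": wilson(tp, n_pos),
        "specificity": tn / n_neg,
        "specificity_ci": wilson(tn, n_neg),
        "n": n,
    }


def _cox_table(fit) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "covariate": fit.names,
            "coef": fit.coef,
            "hazard_ratio": fit.hr,
            "ci95_low": [c[0] for c in fit.ci95],
            "ci95_high": [c[1] for c in fit.ci95],
            "p_lrt": fit.p_lrt,
            "ph_test_p": fit.ph_test_p["per_covariate"] if fit.ph_test_p else np.nan,
        }
    )


def _km_table(times, events, group) -> pd.DataFrame:
    rows = []
    for g in sorted(set(group)):
        sel = np.asarray(group) == g
        curve = kaplan_meier(np.asarray(times)[sel], np.asarray(events)[sel])
        for t, n, d, s in zip(
            curve.event_times, curve.n_at_risk, curve.n_events, curve.survival
        ):
            rows.append(
                {"group": g, "time": t, "n_at_risk": n, "n_events": d, "survival": s}
            )
    return pd.DataFrame(rows)


def _fit_cox_with_ph(X, names, times, events):
    fit = cox_fit(X, times, events, names=names)
    per_cov, global_p = schoenfeld_ph_test(fit, X, times, events)
    fit.ph_test_p = {"per_covariate": list(per_cov), "global": global_p}
    return fit


def run_pipeline(
    config: RunConfig,
    cohort: pd.DataFrame | None = None,
    metabolites: MetaboliteMatrix | None = None,
) -> dict:
    """Execute the full analysis and write the report bundle to out_dir.

    Inputs may be passed in memory or read from the configured paths.
    Returns a dict with the fitted model, per-stage tables, and file paths.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": __version__,
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "stages": {},
    }
    report: dict = {"manifest": manifest}
    t_start = time.time()

    def stage(name):
        class _Stage:
            def __enter__(self):
                self.t0 = time.time()
                return self

            def __exit__(self, exc_type, exc, tb):
                manifest["stages"][name] = {"seconds": round(time.time() - self.t0, 3)}
                (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
                if exc is not None and not isinstance(exc, PipelineError):
                    raise PipelineError(name, str(exc)) from exc

        return _Stage()

    with stage("load"):
        if cohort is None:
            if config.cohort_path is None:
                raise ValueError("no cohort provided (cohort_path unset)")
            cohort = pd.read_csv(config.cohort_path, sep="\t")
        validate_cohort(cohort)
        if metabolites is None:
            if config.metabolites_path is None:
                raise ValueError("no metabolites provided (metabolites_path unset)")
            mdf = pd.read_csv(config.metabolites_path, sep="\t", index_col=0)
            metabolites = MetaboliteMatrix(mdf)
        metabolites = metabolites.align_to(cohort)

    with stage("split"):
        split = stratified_split(cohort, config.train_fraction, config.split_seed)
        train_ids = split.ids("train")
        val_ids = split.ids("validation")
        cohort_idx = cohort.set_index("patient_id", drop=False)
        train_cohort = cohort_idx.loc[train_ids].reset_index(drop=True)
        val_cohort = cohort_idx.loc[val_ids].reset_index(drop=True)
        split.assignment.rename("split").to_csv(out / "split.tsv", sep="\t")

    with stage("prep"):
        train_m = metabolites.subset_patients(train_ids)
        train_m, dropped = filter_sparse_metabolites(
            train_m, config.max_missing_frac, config.exclusions
        )
        train_m = impute_pmm(
            train_m, donors=config.donors, seed=config.imputation_seed,
            exempt=config.impute_exempt,
        )
        # validation imputed separately with the same rules; never touches
        # any training decision
        val_m = metabolites.subset_patients(val_ids).subset_metabolites(
            train_m.metabolites
        )
        val_m = impute_pmm(
            val_m, donors=config.donors, seed=config.imputation_seed + 1,
            exempt=config.impute_exempt,
        )
        manifest["dropped_metabolites"] = dropped

    train_labels = train_cohort["mortality_label"].to_numpy(dtype=int)
    with stage("cutpoints"):
        cuts = fit_cutpoints(
            train_m, train_labels, n_boot=config.n_boot, seed=config.bootstrap_seed
        )
        cutpoint_table(cuts).to_csv(out / "cutpoints.tsv", sep="\t", index=False)
        points = binarize(train_m, cuts)

    with stage("score"):
        ranking = ridge_importance(
            points,
            train_labels,
            cv_folds=config.cv_folds,
            seed=config.ridge_seed,
            family=config.ridge_family,
        )
        ranked_points = type(points)(
            data=points.data[[r.metabolite for r in sorted(ranking, key=lambda r: r.rank)]],
            cutpoints=points.cutpoints,
        )
        iterations = build_iterations(
            ranked_points, ranking, train_cohort, tau=config.rmst_tau
        )
        iteration_table(iterations).to_csv(out / "iterations.tsv", sep="\t", index=False)
        model = select_model(
            iterations,
            tolerance=config.selection_tolerance,
            cutpoints=cuts,
            ranking=ranking,
            objective=config.selection_objective,
        )
        model.to_json(out / "model.json")

    with stage("evaluate"):
        train_scores, train_dys = apply_score(model, train_m)
        val_scores, val_dys = apply_score(model, val_m)
        perf = {
            "train": performance_table(train_scores, train_labels, model.score_threshold),
            "validation": performance_table(
                val_scores, val_cohort["mortality_label"].to_numpy(dtype=int),
                model.score_threshold,
            ),
        }
        (out / "performance.json").write_text(json.dumps(perf, indent=2))

    with stage("survival"):
        surv_tables = {}
        cox_results = {}
        for name, coh, scores, dys in (
            ("train", train_cohort, train_scores, train_dys),
            ("validation", val_cohort, val_scores, val_dys),
        ):
            times = coh["survival_days"].to_numpy(dtype=float)
            events = coh["event"].to_numpy(dtype=int)
            km = _km_table(times, events, dys)
            km.to_csv(out / f"km_{name}.tsv", sep="\t", index=False)
            surv_tables[name] = km
            if len(set(dys.tolist())) == 2:
                _, lr_p = log_rank(times, events, dys)
            else:
                lr_p = float("nan")
            covs = coh[config.covariates].to_numpy(dtype=float)
            try:
                cont = _fit_cox_with_ph(
                    np.column_stack([covs, scores]),
                    config.covariates + ["mds"], times, events,
                )
                dich = _fit_cox_with_ph(
                    np.column_stack([covs, dys]),
                    config.covariates + ["mds_high"], times, events,
                )
                tbl = pd.concat(
                    [_cox_table(cont).assign(model="continuous"),
                     _cox_table(dich).assign(model="dichotomous")]
                )
                tbl.to_csv(out / f"cox_{name}.tsv", sep="\t", index=False)
                cox_results[name] = {"continuous": cont, "dichotomous": dich,
                                     "logrank_p": lr_p}
            except DegenerateDataError as exc:
                warnings.warn(f"{name}: Cox model skipped ({exc})")
                cox_results[name] = {"logrank_p": lr_p, "skipped": str(exc)}

    manifest["total_seconds"] = round(time.time() - t_start, 3)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    report.update(
        split=split,
        model=model,
        cutpoints=cuts,
        ranking=ranking,
        iterations=iterations,
        performance=perf,
        cox=cox_results,
        km=surv_tables,
        train_cohort=train_cohort,
        validation_cohort=val_cohort,
        train_scores=train_scores,
        validation_scores=val_scores,
    )
    return report
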