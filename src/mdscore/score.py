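"""Score assembly: ridge-based metabolite importance, iterative score
building with per-iteration classification and survival metrics, parsimony
model selection, and application of fitted or predefined scores.

The score of a patient is the number of metabolites whose concentration lies
on the nonsurvivor side of that metabolite's cutpoint; the dysbiosis flag
compares the integer score against a half-integer Youden threshold.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression, Ridge
from sklearn.model_selection import StratifiedKFold, KFold

from .cutpoints import (
    HIGH,
    LOW,
    Cutpoint,
    PointMatrix,
    binarize,
    mann_whitney_auc,
    youden_cutpoint,
)
from .datatypes import MetaboliteMatrix, validate_cohort
from .errors import ConfigurationError, DegenerateDataError
from .survival import log_rank, rmst_diff


@dataclass
class ImportanceRanking:
    metabolite: str
    beta: float
    abs_beta: float
    rank: int  # 1 = largest |beta|


@dataclass
class ScoreIteration:
    k: int
    included: list[str]
    scores: np.ndarray
    score_threshold: float
    accuracy: float
    auc: float
    sens: float
    spec: float
    rmst_diff_days: float
    logrank_p: float
    degenerate: bool = False


@dataclass
class MDSModel:
    cutpoints: list[Cutpoint]
    order: list[ImportanceRanking]
    n_metabolites: int
    score_threshold: float
    dysbiosis_rule: str = "score > threshold"

    @property
    def metabolites(self) -> list[str]:
        return [c.metabolite for c in self.cutpoints]

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "n_metabolites": self.n_metabolites,
            "score_threshold": self.score_threshold,
            "dysbiosis_rule": self.dysbiosis_rule,
            "cutpoints": [asdict(c) for c in self.cutpoints],
            "order": [asdict(r) for r in self.order],
        }
        text = json.dumps(payload, indent=2, default=float)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, text_or_path: str | Path) -> "MDSModel":
        p = Path(str(text_or_path))
        text = p.read_text() if p.exists() else str(text_or_path)
        payload = json.loads(text)
        return cls(
            cutpoints=[Cutpoint(**c) for c in payload["cutpoints"]],
            order=[ImportanceRanking(**r) for r in payload["order"]],
            n_metabolites=payload["n_metabolites"],
            score_threshold=payload["score_threshold"],
            dysbiosis_rule=payload.get("dysbiosis_rule", "score > threshold"),
        )


def ridge_importance(
    points: PointMatrix,
    labels,
    cv_folds: int = 5,
    seed: int = 0,
    family: str = "logistic",
    n_penalties: int = 25,
    fixed_penalty: float | None = None,
) -> list[ImportanceRanking]:
    """Rank point-matrix columns by |beta| from an L2-penalized fit.

    Binary columns are standardized before fitting; the penalty strength is
    chosen by ``cv_folds``-fold cross-validated deviance (log loss) over a
    logarithmic grid with seed-deterministic fold assignment (or fixed via
    ``fixed_penalty``: C for logistic, alpha for linear).  Coefficients
    are reported on the standardized scale.  Constant columns are dropped
    with a warning; ties in |beta| break lexicographically by metabolite id.
    """
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise DegenerateDataError("labels contain a single class")
    if min((labels == 0).sum(), (labels == 1).sum()) < 2:
        raise DegenerateDataError("need >= 2 patients per class")
    cols = list(points.data.columns)
    X = points.data.to_numpy(dtype=float)
    sds = X.std(axis=0)
    keep = sds > 0
    if not keep.all():
        dropped = [c for c, k in zip(cols, keep) if not k]
        warnings.warn(f"constant point columns dropped before ridge: {dropped}")
        cols = [c for c, k in zip(cols, keep) if k]
        X = X[:, keep]
        sds = sds[keep]
    if not cols:
        raise DegenerateDataError("no non-constant columns to rank")
    Xs = (X - X.mean(axis=0)) / sds

    if family == "logistic":
        if fixed_penalty is not None:
            best_c = fixed_penalty
        else:
            cs = np.logspace(-4, 4, n_penalties)
            folds = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
            best_c, best_dev = None, np.inf
            eps = 1e-12
            for c in cs:
                dev = 0.0
                for tr, te in folds.split(Xs, labels):
                    clf = LogisticRegression(
                        C=c, solver="lbfgs", max_iter=5000, tol=1e-10
                    ).fit(Xs[tr], labels[tr])
                    prob = clf.predict_proba(Xs[te])[:, 1].clip(eps, 1 - eps)
                    dev += -np.sum(
                        labels[te] * np.log(prob) + (1 - labels[te]) * np.log(1 - prob)
                    )
                if dev < best_dev - 1e-12:
                    best_dev, best_c = dev, c
        model = LogisticRegression(
            C=best_c, solver="lbfgs", max_iter=20000, tol=1e-12
        ).fit(Xs, labels)
        betas = model.coef_.ravel()
    elif family == "linear":
        if fixed_penalty is not None:
            best_a = fixed_penalty
        else:
            alphas = np.logspace(-4, 4, n_penalties)
            folds = KFold(n_splits=cv_folds, shuffle=True, random_state=seed)
            best_a, best_mse = None, np.inf
            for a in alphas:
                mse = 0.0
                for tr, te in folds.split(Xs):
                    reg = Ridge(alpha=a).fit(Xs[tr], labels[tr])
                    mse += float(np.sum((reg.predict(Xs[te]) - labels[te]) ** 2))
                if mse < best_mse - 1e-12:
                    best_mse, best_a = mse, a
        betas = Ridge(alpha=best_a).fit(Xs, labels).coef_
    else:
        raise ConfigurationError("family must be 'logistic' or 'linear'")

    order = sorted(zip(cols, betas), key=lambda cb: (-abs(cb[1]), cb[0]))
    return [
        ImportanceRanking(metabolite=c, beta=float(b), abs_beta=float(abs(b)), rank=i + 1)
        for i, (c, b) in enumerate(order)
    ]


def _score_metrics(scores: np.ndarray, labels: np.ndarray, threshold: float):
    pred = scores > threshold
    pos = labels == 1
    accuracy = float((pred == pos).mean())
    sens = float(pred[pos].mean()) if pos.any() else math.nan
    spec = float((~pred[~pos]).mean()) if (~pos).any() else math.nan
    return pred, accuracy, sens, spec


def build_iterations(
    points: PointMatrix,
    ranking: list[ImportanceRanking],
    cohort: pd.DataFrame,
    tau: float = 30.0,
) -> list[ScoreIteration]:
    """For k = 1..K, score patients on the top-k ranked metabolites and
    re-optimize the score threshold (Youden, nonsurvivor = positive class);
    survival metrics compare the low- vs high-score strata at horizon tau."""
    validate_cohort(cohort)
    order = [r.metabolite for r in sorted(ranking, key=lambda r: r.rank)]
    missing = [c for c in points.metabolites if c not in order]
    if missing:
        raise ConfigurationError(f"ranking does not cover point columns: {missing}")
    labels = cohort["mortality_label"].to_numpy(dtype=int)
    times = cohort["survival_days"].to_numpy(dtype=float)
    events = cohort["event"].to_numpy(dtype=int)
    X = points.data[order].to_numpy(dtype=float)

    iterations = []
    scores = np.zeros(len(cohort))
    for k in range(1, len(order) + 1):
        scores = scores + X[:, k - 1]
        cp = youden_cutpoint(scores, labels, n_boot=0, direction=HIGH)
        thr = cp.threshold
        pred, accuracy, sens, spec = _score_metrics(scores, labels, thr)
        auc = mann_whitney_auc(scores, labels)
        if pred.any() and not pred.all():
            res = rmst_diff(times, events, pred.astype(int), tau=tau)
            # low-score minus high-score restricted mean (days)
            rm_diff = res.rmst_per_group[0] - res.rmst_per_group[1]
            _, lr_p = log_rank(times, events, pred.astype(int))
            degenerate = cp.degenerate
        else:
            warnings.warn(f"iteration k={k}: all patients on one side; survival skipped")
            rm_diff, lr_p, degenerate = math.nan, math.nan, True
        iterations.append(
            ScoreIteration(
                k=k,
                included=order[:k],
                scores=scores.astype(int).copy(),
                score_threshold=thr,
                accuracy=accuracy,
                auc=float(auc),
                sens=sens,
                spec=spec,
                rmst_diff_days=rm_diff,
                logrank_p=lr_p,
                degenerate=degenerate,
            )
        )
    return iterations


def select_model(
    iterations: list[ScoreIteration],
    tolerance: float = 0.01,
    cutpoints: dict[str, Cutpoint] | None = None,
    ranking: list[ImportanceRanking] | None = None,
    objective: str = "accuracy",
) -> MDSModel:
    """Pick the smallest k whose objective is within ``tolerance`` of the best.

    ``cutpoints``/``ranking`` provenance (e.g. from the fitted PointMatrix)
    populates the returned model; without them the model carries only the
    metabolite order and threshold via empty cutpoints.
    """
    if not iterations:
        raise DegenerateDataError("no iterations to select from")
    if objective not in ("accuracy", "auc"):
        raise ConfigurationError("objective must be 'accuracy' or 'auc'")
    vals = [getattr(it, objective) for it in iterations]
    best = max(vals)
    chosen = next(it for it, v in zip(iterations, vals) if v >= best - tolerance)
    cuts = []
    if cutpoints is not None:
        missing = [mname for mname in chosen.included if mname not in cutpoints]
        if missing:
            raise ConfigurationError(f"cutpoints missing for: {missing}")
        cuts = [cutpoints[mname] for mname in chosen.included]
    order = []
    if ranking is not None:
        by_name = {r.metabolite: r for r in ranking}
        order = [by_name[mname] for mname in chosen.included]
    return MDSModel(
        cutpoints=cuts,
        order=order,
        n_metabolites=chosen.k,
        score_threshold=chosen.score_threshold,
    )


def apply_score(model: MDSModel, m: MetaboliteMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Score a metabolite matrix with a fitted model.

    Returns (integer scores in [0, n_metabolites], dysbiosis flags where
    score > score_threshold).
    """
    if not model.cutpoints:
        raise ConfigurationError("model carries no cutpoints")
    absent = [c.metabolite for c in model.cutpoints if c.metabolite not in m.data.columns]
    if absent:
        raise ConfigurationError(f"matrix lacks model metabolites: {absent}")
    sub = m.subset_metabolites(model.metabolites)
    pm = binarize(sub, {c.metabolite: c for c in model.cutpoints})
    scores = pm.data.to_numpy().sum(axis=1)
    dysbiosis = (scores > model.score_threshold).astype(int)
    return scores.astype(int), dysbiosis


@dataclass
class PredefinedScore:
    """A user-supplied fixed score: metabolite thresholds/directions plus a
    flag rule (comparison operator and cut, e.g. score >= 2)."""

    metabolites: list[str]
    thresholds: dict[str, float]
    directions: dict[str, str]
    score_cut: float
    operator: str = ">="  # ">=" or ">"

    def __post_init__(self):
        if not self.metabolites:
            raise ConfigurationError("predefined score needs >= 1 metabolite")
        for mname in self.metabolites:
            if mname not in self.thresholds or mname not in self.directions:
                raise ConfigurationError(f"missing threshold/direction for {mname!r}")
            if self.directions[mname] not in (HIGH, LOW):
                raise ConfigurationError(f"bad direction for {mname!r}")
        if self.operator not in (">=", ">"):
            raise ConfigurationError("operator must be '>=' or '>'")


def apply_predefined_score(
    spec: PredefinedScore, m: MetaboliteMatrix
) -> tuple[np.ndarray, np.ndarray]:
    """Score with user-specified cutpoints and flag rule (>= allowed)."""
    cuts = {
        mname: Cutpoint(
            metabolite=mname,
            threshold=spec.thresholds[mname],
            direction=spec.directions[mname],
            youden_j=math.nan,
            sens=math.nan,
            spec=math.nan,
            auc=math.nan,
        )
        for mname in spec.metabolites
    }
    absent = [mname for mname in spec.metabolites if mname not in m.data.columns]
    if absent:
        raise ConfigurationError(f"matrix lacks metabolites: {absent}")
    pm = binarize(m.subset_metabolites(spec.metabolites), cuts)
    scores = pm.data.to_numpy().sum(axis=1).astype(int)
    if spec.operator == ">=":
        flags = (scores >= spec.score_cut).astype(int)
    else:
        flags = (scores > spec.score_cut).astype(int)
    return scores, flags


def iteration_table(iterations: list[ScoreIteration]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "k": it.k,
                "added": it.included[-1],
                "score_threshold": it.score_threshold,
                "accuracy": it.accuracy,
                "auc": it.auc,
                "sens": it.sens,
                "spec": it.spec,
                "rmst_diff_days": it.rmst_diff_days,
                "logrank_p": it.logrank_p,
                "degenerate": it.degenerate,
            }
            for it in iterations
        ]
    )
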