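"""Per-metabolite ROC analysis and Youden-optimal cutpoints.

A cutpoint carries a concentration threshold plus the *direction* in which
nonsurvivors are enriched; the point matrix assigns one point to each
patient/metabolite cell whose concentration lies on the nonsurvivor side.

Candidate thresholds are midpoints between consecutive distinct observed
values, with +/-inf sentinels, so thresholds on integer-valued scores come
out as half-integers.  Ties in the Youden index are broken toward higher
specificity, then toward the lower threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .datatypes import MetaboliteMatrix
from .errors import ConfigurationError, DegenerateDataError

HIGH = "high_in_nonsurvivors"
LOW = "low_in_nonsurvivors"


@dataclass
class RocCurve:
    thresholds: np.ndarray  # ascending, midpoints plus sentinels
    sens: np.ndarray  # P(value > t | label 1)
    spec: np.ndarray  # P(value <= t | label 0)
    auc: float


@dataclass
class Cutpoint:
    metabolite: str
    threshold: float
    direction: str  # HIGH or LOW
    youden_j: float
    sens: float
    spec: float
    auc: float
    bootstrap_mean_threshold: float = math.nan
    bootstrap_sd_threshold: float = math.nan
    n_boot: int = 0
    degenerate: bool = False


@dataclass
class PointMatrix:
    """Binary patients x metabolites matrix with its cutpoint provenance."""

    data: pd.DataFrame
    cutpoints: dict[str, Cutpoint] = field(default_factory=dict)

    @property
    def metabolites(self) -> list[str]:
        return list(self.data.columns)


def _check_two_classes(labels: np.ndarray) -> None:
    if set(np.unique(labels)) != {0, 1}:
        raise DegenerateDataError("both classes (0 and 1) must be present")


def mann_whitney_auc(values, labels) -> float:
    """AUC with higher-value-predicts-positive orientation; tied pairs count 1/2.

    Equals the Mann-Whitney U statistic divided by n1*n0.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=int)
    _check_two_classes(labels)
    ranks = rankdata(values)
    n1 = int(labels.sum())
    n0 = len(labels) - n1
    u = ranks[labels == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def candidate_thresholds(values) -> np.ndarray:
    """Midpoints of consecutive distinct sorted values, with ±inf sentinels."""
    distinct = np.unique(np.asarray(values, dtype=float))
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    return np.concatenate([[-np.inf], mids, [np.inf]])


def roc_curve(values, labels) -> RocCurve:
    """Empirical ROC over midpoint thresholds (higher value predicts positive)."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if np.isnan(values).any():
        raise ConfigurationError("values contain missing entries; impute first")
    _check_two_classes(labels)
    thr = candidate_thresholds(values)
    pos = values[labels == 1]
    neg = values[labels == 0]
    sens = np.array([(pos > t).mean() for t in thr])
    spec = np.array([(neg <= t).mean() for t in thr])
    return RocCurve(thresholds=thr, sens=sens, spec=spec, auc=mann_whitney_auc(values, labels))


def _points(values: np.ndarray, threshold: float, direction: str) -> np.ndarray:
    # midpoint thresholds never coincide with data; ties (user-supplied
    # thresholds) fall on the nonsurvivor side
    if direction == HIGH:
        return values >= threshold
    if direction == LOW:
        return values <= threshold
    raise ConfigurationError(f"unknown direction {direction!r}")


def _best_threshold(
    values: np.ndarray, labels: np.ndarray, direction: str
) -> tuple[float, float, float, float]:
    """Maximize J over midpoint candidates; returns (threshold, J, sens, spec)."""
    best = None
    for t in candidate_thresholds(values):
        pts = _points(values, t, direction)
        sens = pts[labels == 1].mean()
        spec = 1.0 - pts[labels == 0].mean()
        j = sens + spec - 1.0
        key = (round(j, 12), round(spec, 12), -t if np.isfinite(t) else -np.inf)
        if best is None or key > best[0]:
            best = (key, t, j, sens, spec)
    _, t, j, sens, spec = best
    return float(t), float(j), float(sens), float(spec)


def youden_cutpoint(
    values,
    labels,
    n_boot: int = 10,
    seed: int = 0,
    metabolite: str = "",
    direction: str | None = None,
) -> Cutpoint:
    """Youden-index-optimal cutpoint with a stratified stability bootstrap.

    Direction (which side of the threshold is scored as nonsurvivor-like) is
    fixed from the full sample, unless supplied explicitly: the direction
    whose best threshold attains the larger Youden index wins, with the
    Mann-Whitney AUC orientation breaking ties.  The deployed threshold is
    the full-sample optimum; the ``n_boot`` within-class resamples only fill
    the stability summary.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if np.isnan(values).any():
        raise ConfigurationError("values contain missing entries; impute first")
    _check_two_classes(labels)
    if n_boot < 0:
        raise ConfigurationError("n_boot must be >= 0")
    auc_high = mann_whitney_auc(values, labels)
    if direction is None:
        best_high = _best_threshold(values, labels, HIGH)
        best_low = _best_threshold(values, labels, LOW)
        if abs(best_high[1] - best_low[1]) < 1e-12:
            direction = HIGH if auc_high >= 0.5 else LOW
        else:
            direction = HIGH if best_high[1] > best_low[1] else LOW
    elif direction not in (HIGH, LOW):
        raise ConfigurationError(f"unknown direction {direction!r}")
    auc = auc_high if direction == HIGH else 1.0 - auc_high

    t, j, sens, spec = _best_threshold(values, labels, direction)
    degenerate = len(np.unique(values)) < 2 or j <= 0.0

    boot_mean = boot_sd = math.nan
    if n_boot > 0 and not degenerate:
        rng = np.random.default_rng(seed)
        idx1 = np.flatnonzero(labels == 1)
        idx0 = np.flatnonzero(labels == 0)
        thresholds = []
        for _ in range(n_boot):
            take = np.concatenate(
                [rng.choice(idx1, size=len(idx1)), rng.choice(idx0, size=len(idx0))]
            )
            bt, *_rest = _best_threshold(values[take], labels[take], direction)
            thresholds.append(bt)
        finite = [t_ for t_ in thresholds if np.isfinite(t_)]
        if finite:
            boot_mean = float(np.mean(finite))
            boot_sd = float(np.std(finite, ddof=1)) if len(finite) > 1 else 0.0

    return Cutpoint(
        metabolite=metabolite,
        threshold=t,
        direction=direction,
        youden_j=max(j, 0.0),
        sens=sens,
        spec=spec,
        auc=auc,
        bootstrap_mean_threshold=boot_mean,
        bootstrap_sd_threshold=boot_sd,
        n_boot=n_boot,
        degenerate=degenerate,
    )


def fit_cutpoints(
    m: MetaboliteMatrix, labels, n_boot: int = 10, seed: int = 0
) -> dict[str, Cutpoint]:
    """Youden cutpoint per metabolite column (seed-deterministic per column)."""
    labels = np.asarray(labels, dtype=int)
    ss = np.random.SeedSequence(seed).spawn(len(m.metabolites))
    cuts = {}
    for child, met in zip(ss, m.metabolites):
        cuts[met] = youden_cutpoint(
            m.data[met].to_numpy(dtype=float),
            labels,
            n_boot=n_boot,
            seed=child.generate_state(1)[0],
            metabolite=met,
        )
    return cuts


def binarize(m: MetaboliteMatrix, cuts: dict[str, Cutpoint] | list[Cutpoint]) -> PointMatrix:
    """Binary point matrix: 1 iff the concentration lies on the nonsurvivor
    side of the metabolite's cutpoint."""
    if not isinstance(cuts, dict):
        cuts = {c.metabolite: c for c in cuts}
    missing_cuts = [c for c in m.metabolites if c not in cuts]
    if missing_cuts:
        raise ConfigurationError(f"metabolites without a cutpoint: {missing_cuts}")
    if m.data.isna().any().any():
        raise ConfigurationError("point matrix requires imputed (complete) data")
    out = {}
    for met in m.metabolites:
        cp = cuts[met]
        out[met] = _points(
            m.data[met].to_numpy(dtype=float), cp.threshold, cp.direction
        ).astype(int)
    data = pd.DataFrame(out, index=m.data.index)
    return PointMatrix(data=data, cutpoints={met: cuts[met] for met in m.metabolites})


def cutpoint_table(cuts: dict[str, Cutpoint]) -> pd.DataFrame:
    """Serializable per-metabolite cutpoint summary table."""
    return pd.DataFrame(
        [
            {
                "metabolite": c.metabolite,
                "threshold": c.threshold,
                "direction": c.direction,
                "youden_j": c.youden_j,
                "sens": c.sens,
                "spec": c.spec,
                "auc": c.auc,
                "bootstrap_mean_threshold": c.bootstrap_mean_threshold,
                "bootstrap_sd_threshold": c.bootstrap_sd_threshold,
                "n_boot": c.n_boot,
                "degenerate": c.degenerate,
            }
            for c in cuts.values()
        ]
    )
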