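"""Cohort preparation: stratified splitting, missingness handling, and the
univariate group-comparison statistics (contingency tests, rank-sum tests,
BH adjustment, volcano fold changes)."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import MetaboliteMatrix, validate_cohort
from .errors import ConfigurationError, DegenerateDataError

EXACT_RANKSUM_MAX_N = 50  # normal approximation at or above this group size


@dataclass
class SplitAssignment:
    """Patient -> {train, validation} assignment from a stratified split."""

    assignment: pd.Series  # index patient_id, values "train"/"validation"
    train_fraction: float
    seed: int

    def ids(self, which: str) -> list[str]:
        return list(self.assignment.index[self.assignment == which])


@dataclass
class GroupTestResult:
    feature: str
    statistic: float
    p: float
    test_name: str
    q: float | None = None
    log2fc: float | None = None
    extra: dict = field(default_factory=dict)


def stratified_split(
    cohort: pd.DataFrame, train_fraction: float, seed: int
) -> SplitAssignment:
    """Outcome-stratified random split with largest-remainder rounding.

    Per-stratum training quotas are ``train_fraction * n_stratum`` floored,
    with leftover seats (to reach ``round(train_fraction * n_total)``) handed
    out by descending fractional remainder (ties: larger stratum first).
    """
    if not 0.0 < train_fraction < 1.0:
        raise ConfigurationError("train_fraction must lie in (0, 1)")
    validate_cohort(cohort)
    labels = cohort["mortality_label"].to_numpy()
    for stratum in (0, 1):
        if (labels == stratum).sum() == 0:
            raise DegenerateDataError(f"outcome stratum {stratum} is empty")

    n_total = len(cohort)
    target_total = int(np.floor(train_fraction * n_total + 0.5))
    strata = sorted(np.unique(labels))
    quotas = {s: train_fraction * (labels == s).sum() for s in strata}
    base = {s: int(np.floor(quotas[s])) for s in strata}
    leftover = target_total - sum(base.values())
    order = sorted(
        strata,
        key=lambda s: (-(quotas[s] - base[s]), -(labels == s).sum(), s),
    )
    counts = dict(base)
    for s in order[: max(leftover, 0)]:
        counts[s] += 1

    rng = np.random.default_rng(seed)
    assignment = pd.Series(
        "validation", index=pd.Index(cohort["patient_id"], name="patient_id")
    )
    for s in strata:
        ids = cohort.loc[labels == s, "patient_id"].to_numpy()
        chosen = rng.choice(ids, size=counts[s], replace=False)
        assignment.loc[chosen] = "train"
    return SplitAssignment(assignment=assignment, train_fraction=train_fraction, seed=seed)


def filter_sparse_metabolites(
    m: MetaboliteMatrix,
    max_missing_frac: float = 0.20,
    exclusions: tuple[str, ...] | list[str] = (),
) -> tuple[MetaboliteMatrix, list[str]]:
    """Drop metabolites with missing fraction strictly above the threshold,
    plus explicit exclusions; returns (filtered matrix, dropped ids)."""
    if not 0.0 <= max_missing_frac < 1.0:
        raise ConfigurationError("max_missing_frac must lie in [0, 1)")
    frac = m.missing_fraction()
    dropped = [c for c in m.metabolites if frac[c] > max_missing_frac or c in set(exclusions)]
    kept = [c for c in m.metabolites if c not in dropped]
    if not kept:
        raise DegenerateDataError("all metabolites dropped by the sparsity filter")
    return m.subset_metabolites(kept), dropped


def impute_pmm(
    m: MetaboliteMatrix,
    donors: int = 5,
    seed: int = 0,
    exempt: tuple[str, ...] | list[str] = (),
) -> MetaboliteMatrix:
    """Single predictive-mean-matching imputation.

    For each metabolite with missing entries, a linear model of the target on
    the other (non-exempt) metabolites is fit on rows where the target is
    observed (predictors mean-filled); each missing cell is filled with the
    observed value of one of the ``donors`` patients nearest in predicted
    mean.  Exempt metabolites are neither imputed nor used as predictors.
    """
    if donors < 1:
        raise ConfigurationError("donors must be >= 1")
    rng = np.random.default_rng(seed)
    df = m.data.copy()
    exempt = set(exempt)
    usable = [c for c in df.columns if c not in exempt]
    targets = [c for c in usable if df[c].isna().any()]
    if not targets:
        return MetaboliteMatrix(df, dict(m.panel))

    # predictors mean-filled once, on observed values
    filled = df[usable].fillna(df[usable].mean())
    for target in targets:
        obs_mask = df[target].notna().to_numpy()
        n_obs = int(obs_mask.sum())
        if n_obs < donors:
            raise DegenerateDataError(
                f"metabolite {target!r} has {n_obs} observed values; needs >= {donors}"
            )
        predictors = [c for c in usable if c != target]
        X = np.column_stack([np.ones(len(df)), filled[predictors].to_numpy()])
        y = df[target].to_numpy(dtype=float)
        beta, *_ = np.linalg.lstsq(X[obs_mask], y[obs_mask], rcond=None)
        yhat = X @ beta
        obs_idx = np.flatnonzero(obs_mask)
        obs_pred = yhat[obs_idx]
        for i in np.flatnonzero(~obs_mask):
            dist = np.abs(obs_pred - yhat[i])
            pool = obs_idx[np.argsort(dist, kind="stable")[:donors]]
            donor = pool[rng.integers(len(pool))]
            df.iloc[i, df.columns.get_loc(target)] = y[donor]
    return MetaboliteMatrix(df, dict(m.panel))


def chi_square_2x2(a: int, b: int, c: int, d: int) -> GroupTestResult:
    """Yates-continuity-corrected chi-square test on a 2x2 table
    ``[[a, b], [c, d]]`` (1 df, two-sided)."""
    obs = np.array([[a, b], [c, d]], dtype=float)
    if (obs < 0).any() or not np.allclose(obs, np.round(obs)):
        raise ConfigurationError("counts must be nonnegative integers")
    n = obs.sum()
    rows = obs.sum(axis=1)
    cols = obs.sum(axis=0)
    if (rows == 0).any() or (cols == 0).any() or n == 0:
        raise DegenerateDataError("2x2 test undefined: a margin is zero")
    expected = np.outer(rows, cols) / n
    # continuity correction: shift observed toward expected by up to 0.5,
    # never past it
    shift = np.minimum(0.5, np.abs(expected - obs))
    adj = obs + shift * np.sign(expected - obs)
    stat = float(((adj - expected) ** 2 / expected).sum())
    p = float(stats.chi2.sf(stat, df=1))
    return GroupTestResult(
        feature="2x2", statistic=stat, p=p, test_name="chi-square (Yates)"
    )


def _exact_ranksum_feasible(x: np.ndarray, y: np.ndarray) -> bool:
    if max(len(x), len(y)) >= EXACT_RANKSUM_MAX_N:
        return False
    combined = np.concatenate([x, y])
    return len(np.unique(combined)) == len(combined)  # exact mode requires no ties


def rank_sum_test(x, y, feature: str = "") -> GroupTestResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Exact null distribution for small tie-free samples; tie-corrected normal
    approximation with continuity correction otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise DegenerateDataError("rank-sum test requires two nonempty samples")
    if np.unique(np.concatenate([x, y])).size == 1:  # zero variance under ties
        return GroupTestResult(
            feature=feature, statistic=len(x) * len(y) / 2.0, p=1.0,
            test_name="rank-sum (degenerate)",
        )
    method = "exact" if _exact_ranksum_feasible(x, y) else "asymptotic"
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=True
    )
    return GroupTestResult(
        feature=feature,
        statistic=float(res.statistic),
        p=float(min(res.pvalue, 1.0)),
        test_name=f"rank-sum ({method})",
    )


def t_test(x, y, feature: str = "") -> GroupTestResult:
    """Unpaired two-sample, two-tailed t test (continuous table variables)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise DegenerateDataError("t test requires >= 2 values per group")
    res = stats.ttest_ind(x, y)
    return GroupTestResult(
        feature=feature, statistic=float(res.statistic), p=float(res.pvalue),
        test_name="t-test",
    )


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone, capped at 1)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ConfigurationError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def volcano_stats(
    m: MetaboliteMatrix,
    cohort: pd.DataFrame,
    log2fc_cut: float = 0.75,
    q_cut: float = 0.1,
) -> pd.DataFrame:
    """Per-metabolite survivor-vs-nonsurvivor contrast.

    log2fc is the log2 ratio of the survivor-group median over the
    nonsurvivor-group median (with a half-minimum-positive pseudocount added
    to both medians when either is zero), p from the rank-sum test, q by BH.
    Rows are flagged when |log2fc| exceeds ``log2fc_cut`` and q < ``q_cut``.
    """
    validate_cohort(cohort)
    aligned = m.align_to(cohort)
    surv = cohort["mortality_label"].to_numpy() == 0
    rows = []
    for met in aligned.metabolites:
        vals = aligned.data[met].to_numpy(dtype=float)
        xs = vals[surv & ~np.isnan(vals)]
        xn = vals[~surv & ~np.isnan(vals)]
        if len(xs) == 0 or len(xn) == 0:
            warnings.warn(f"metabolite {met!r} all-missing in one group; skipped")
            continue
        med_s, med_n = float(np.median(xs)), float(np.median(xn))
        if med_s == 0.0 or med_n == 0.0:
            positives = vals[(vals > 0) & ~np.isnan(vals)]
            if len(positives) == 0:
                warnings.warn(f"metabolite {met!r} has no positive values; skipped")
                continue
            pc = float(positives.min()) / 2.0
            med_s, med_n = med_s + pc, med_n + pc
        log2fc = float(np.log2(med_s / med_n))
        test = rank_sum_test(xs, xn, feature=met)
        rows.append(
            {"metabolite": met, "log2fc": log2fc, "statistic": test.statistic,
             "p": test.p, "test_name": test.test_name}
        )
    if not rows:
        raise DegenerateDataError("no testable metabolites")
    out = pd.DataFrame(rows)
    out["q"] = bh_adjust(out["p"].to_numpy())
    out["flagged"] = (out["log2fc"].abs() > log2fc_cut) & (out["q"] < q_cut)
    return out
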