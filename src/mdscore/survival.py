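"""Survival statistics: Kaplan-Meier, log-rank, restricted mean survival
time, Cox proportional hazards, and Schoenfeld proportional-hazards
diagnostics.

All routines are implemented directly from the estimating equations (the
test suite cross-checks them against an independent survival library).
Conventions: at tied times events precede censorings (censored subjects
remain in the risk set at their own time); Efron tie handling is the Cox
default; per-covariate Cox p-values come from likelihood-ratio refits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import ConfigurationError, ConvergenceError, DegenerateDataError

__all__ = [
    "SurvivalCurve",
    "CoxFit",
    "RmstResult",
    "kaplan_meier",
    "log_rank",
    "rmst",
    "rmst_diff",
    "cox_fit",
    "schoenfeld_residuals",
    "schoenfeld_ph_test",
]


# ---------------------------------------------------------------------------
# Kaplan-Meier


@dataclass
class SurvivalCurve:
    event_times: np.ndarray  # sorted unique times with >= 1 event
    n_at_risk: np.ndarray
    n_events: np.ndarray
    survival: np.ndarray  # product-limit estimate at each event time
    greenwood_var: np.ndarray  # Greenwood variance of the estimate

    def at(self, t: float) -> float:
        """Step-function evaluation S(t) (right-continuous)."""
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def _check_surv_input(times, events):
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise DegenerateDataError("empty survival input")
    if (times < 0).any():
        raise ConfigurationError("times must be nonnegative")
    if not np.isin(events, [0, 1]).all():
        raise ConfigurationError("events must be binary")
    return times, events


def kaplan_meier(times, events) -> SurvivalCurve:
    """Product-limit estimator; censorings at a tied time stay at risk."""
    times, events = _check_surv_input(times, events)
    uniq = np.unique(times[events == 1])
    n_at_risk, n_events, surv, gvar = [], [], [], []
    s = 1.0
    gsum = 0.0
    for t in uniq:
        n = int((times >= t).sum())
        d = int(((times == t) & (events == 1)).sum())
        s *= (n - d) / n
        if n > d:
            gsum += d / (n * (n - d))
        else:
            gsum = math.inf
        n_at_risk.append(n)
        n_events.append(d)
        surv.append(s)
        gvar.append(s * s * gsum if s > 0 else 0.0)
    return SurvivalCurve(
        event_times=uniq,
        n_at_risk=np.array(n_at_risk),
        n_events=np.array(n_events),
        survival=np.array(surv),
        greenwood_var=np.array(gvar),
    )


# ---------------------------------------------------------------------------
# Log-rank


def log_rank(times, events, group) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square with 1 df, p)."""
    times, events = _check_surv_input(times, events)
    group = np.asarray(group, dtype=int)
    if len(set(group.tolist())) < 2:
        raise DegenerateDataError("log-rank requires two nonempty groups")
    o_minus_e = 0.0
    var = 0.0
    for t in np.unique(times[events == 1]):
        at_risk = times >= t
        n = int(at_risk.sum())
        n1 = int((at_risk & (group == 1)).sum())
        dead = (times == t) & (events == 1)
        d = int(dead.sum())
        d1 = int((dead & (group == 1)).sum())
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if var == 0:
        return 0.0, 1.0
    chi2 = o_minus_e**2 / var
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


# ---------------------------------------------------------------------------
# RMST


@dataclass
class RmstResult:
    tau: float
    rmst_per_group: list[float]
    diff: float  # group1 - group0
    diff_p: float
    se_per_group: list[float] = field(default_factory=list)


def rmst(times, events, tau: float) -> tuple[float, float]:
    """Area under the KM curve on [0, tau] and its Greenwood-based variance."""
    times, events = _check_surv_input(times, events)
    if tau <= 0:
        raise ConfigurationError("tau must be positive")
    curve = kaplan_meier(times, events)
    knots = np.concatenate([[0.0], curve.event_times[curve.event_times < tau], [tau]])
    heights = np.concatenate([[1.0], curve.survival[curve.event_times < tau]])
    area = float(np.sum(heights * np.diff(knots)))

    # var = sum over event times t_j <= tau of A_j^2 * d_j / (n_j (n_j - d_j))
    # where A_j is the curve area on [t_j, tau]
    var = 0.0
    for t, n, d in zip(curve.event_times, curve.n_at_risk, curve.n_events):
        if t >= tau or n == d:
            continue
        sub_knots = np.concatenate(
            [[t], curve.event_times[(curve.event_times > t) & (curve.event_times < tau)], [tau]]
        )
        sub_heights = np.concatenate(
            [[curve.at(t)], curve.survival[(curve.event_times > t) & (curve.event_times < tau)]]
        )
        a_j = float(np.sum(sub_heights * np.diff(sub_knots)))
        var += a_j**2 * d / (n * (n - d))
    return area, var


def rmst_diff(times, events, group, tau: float) -> RmstResult:
    """RMST difference (group1 - group0) with an asymptotic normal p-value."""
    times, events = _check_surv_input(times, events)
    group = np.asarray(group, dtype=int)
    per_group, variances = [], []
    for g in (0, 1):
        sel = group == g
        if not sel.any():
            raise DegenerateDataError(f"group {g} is empty")
        max_follow = times[sel].max()
        tau_g = tau
        if tau > max_follow:
            import warnings

            warnings.warn(
                f"tau={tau} exceeds group {g} max follow-up {max_follow}; truncating"
            )
            tau_g = max_follow
        a, v = rmst(times[sel], events[sel], tau_g)
        per_group.append(a)
        variances.append(v)
    diff = per_group[1] - per_group[0]
    se = math.sqrt(variances[0] + variances[1])
    p = 1.0 if se == 0 else float(2.0 * stats.norm.sf(abs(diff) / se))
    return RmstResult(
        tau=tau,
        rmst_per_group=per_group,
        diff=float(diff),
        diff_p=p,
        se_per_group=[math.sqrt(v) for v in variances],
    )


# ---------------------------------------------------------------------------
# Cox proportional hazards


@dataclass
class CoxFit:
    names: list[str]
    coef: np.ndarray
    hr: np.ndarray
    ci95: list[tuple[float, float]]
    se: np.ndarray
    p_lrt: np.ndarray  # per-covariate likelihood-ratio p
    global_lrt_p: float
    loglik: float
    loglik_null: float
    var: np.ndarray  # inverse observed information
    n_events: int
    ties: str
    separation_flag: bool = False
    ph_test_p: dict | None = None


def _cox_derivatives(beta, X, times, events, ties):
    """(loglik, gradient, hessian) of the partial likelihood."""
    eta = X @ beta
    eta = eta - eta.max()  # guard overflow; partial likelihood is shift-invariant
    w = np.exp(eta)
    wx = w[:, None] * X
    wxx = np.einsum("i,ij,ik->ijk", w, X, X)
    p = X.shape[1]
    ll = 0.0
    grad = np.zeros(p)
    hess = np.zeros((p, p))
    for t in np.unique(times[events == 1]):
        risk = times >= t
        dead = (times == t) & (events == 1)
        d = int(dead.sum())
        s0 = w[risk].sum()
        s1 = wx[risk].sum(axis=0)
        s2 = wxx[risk].sum(axis=0)
        s0d = w[dead].sum()
        s1d = wx[dead].sum(axis=0)
        s2d = wxx[dead].sum(axis=0)
        ll += eta[dead].sum()
        grad += X[dead].sum(axis=0)
        for ell in range(d):
            f = ell / d if ties == "efron" else 0.0
            denom = s0 - f * s0d
            zbar = (s1 - f * s1d) / denom
            ll -= math.log(denom)
            grad -= zbar
            hess -= (s2 - f * s2d) / denom - np.outer(zbar, zbar)
    return ll, grad, hess


def _cox_maximize(X, times, events, ties, max_iter=100, tol=1e-9):
    p = X.shape[1]
    beta = np.zeros(p)
    ll, grad, hess = _cox_derivatives(beta, X, times, events, ties)
    # gradient tolerance scaled by event count: the score is a sum over
    # events, so its floating-point noise floor grows with them
    grad_tol = tol * max(1.0, float(events.sum()))
    for _ in range(max_iter):
        if np.linalg.norm(grad) < grad_tol:
            return beta, ll, -hess
        try:
            step = np.linalg.solve(-hess, grad)
        except np.linalg.LinAlgError as exc:
            raise ConvergenceError(f"singular information matrix: {exc}") from exc
        if np.linalg.norm(step) < 1e-10 * (1.0 + np.linalg.norm(beta)):
            return beta, ll, -hess
        # step halving if the likelihood does not improve
        for _half in range(40):
            cand = beta + step
            ll_new, grad_new, hess_new = _cox_derivatives(cand, X, times, events, ties)
            if ll_new >= ll - 1e-12:
                break
            step = step / 2.0
        beta, ll, grad, hess = cand, ll_new, grad_new, hess_new
    if np.linalg.norm(grad) < max(1e-5, grad_tol):  # close enough
        return beta, ll, -hess
    raise ConvergenceError(
        f"Cox fit did not converge in {max_iter} iterations "
        f"(grad norm {np.linalg.norm(grad):.3g}, |beta|max {np.abs(beta).max():.3g})"
    )


def cox_fit(covariates, times, events, ties: str = "efron", names=None) -> CoxFit:
    """Cox PH fit by Newton-Raphson on the partial likelihood.

    Per-covariate p-values are likelihood-ratio tests (refit without the
    covariate); 95% CIs are Wald intervals from the observed information.
    """
    X = np.asarray(covariates, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    times, events = _check_surv_input(times, events)
    if events.sum() < 1:
        raise DegenerateDataError("Cox fit requires at least one event")
    if ties not in ("efron", "breslow"):
        raise ConfigurationError("ties must be 'efron' or 'breslow'")
    p = X.shape[1]
    if names is None:
        names = [f"x{j}" for j in range(p)]
    sds = X.std(axis=0)
    if (sds == 0).any():
        bad = [names[j] for j in range(p) if sds[j] == 0]
        raise DegenerateDataError(f"constant covariates: {bad}")

    beta, ll, info = _cox_maximize(X, times, events, ties)
    separation = bool(np.abs(beta).max() > 20)
    var = np.linalg.inv(info)
    se = np.sqrt(np.diag(var))
    ll_null, *_ = _cox_derivatives(np.zeros(p), X, times, events, ties)
    global_p = float(stats.chi2.sf(2.0 * (ll - ll_null), df=p))

    p_lrt = np.empty(p)
    for j in range(p):
        if p == 1:
            ll_red = ll_null
        else:
            keep = [k for k in range(p) if k != j]
            _, ll_red, _ = _cox_maximize(X[:, keep], times, events, ties)
        p_lrt[j] = stats.chi2.sf(2.0 * (ll - ll_red), df=1)

    z = stats.norm.ppf(0.975)
    # clip exponents so near-separated fits yield inf-free (if huge) bounds
    ci95 = [
        (float(np.exp(min(b - z * s, 700.0))), float(np.exp(min(b + z * s, 700.0))))
        for b, s in zip(beta, se)
    ]
    return CoxFit(
        names=list(names),
        coef=beta,
        hr=np.exp(beta),
        ci95=ci95,
        se=se,
        p_lrt=p_lrt,
        global_lrt_p=global_p,
        loglik=ll,
        loglik_null=ll_null,
        var=var,
        n_events=int(events.sum()),
        ties=ties,
        separation_flag=separation,
    )


# ---------------------------------------------------------------------------
# Schoenfeld residuals and the proportional-hazards test


def schoenfeld_residuals(fit: CoxFit, covariates, times, events):
    """Unscaled Schoenfeld residuals, one row per event (time-ordered).

    At tied event times the Efron-adjusted risk-set mean (averaged over the
    within-tie positions) is subtracted from each event's covariates.
    """
    X = np.asarray(covariates, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    times, events = _check_surv_input(times, events)
    eta = X @ fit.coef
    eta = eta - eta.max()
    w = np.exp(eta)
    wx = w[:, None] * X
    rows = []
    rtimes = []
    for t in np.unique(times[events == 1]):
        risk = times >= t
        dead = (times == t) & (events == 1)
        d = int(dead.sum())
        s0 = w[risk].sum()
        s1 = wx[risk].sum(axis=0)
        s0d = w[dead].sum()
        s1d = wx[dead].sum(axis=0)
        if fit.ties == "efron" and d > 1:
            means = [
                (s1 - (ell / d) * s1d) / (s0 - (ell / d) * s0d) for ell in range(d)
            ]
            mbar = np.mean(means, axis=0)
        else:
            mbar = s1 / s0
        for xi in X[dead]:
            rows.append(xi - mbar)
            rtimes.append(t)
    return np.array(rows), np.array(rtimes)


def schoenfeld_ph_test(
    fit: CoxFit, covariates, times, events, transform: str = "km"
) -> tuple[np.ndarray, float]:
    """Grambsch-Therneau score test for proportional hazards.

    Correlates Schoenfeld residuals with transformed event times (default:
    the KM transform, g(t) = 1 - S_KM(t)).  Returns (per-covariate p-values,
    global p-value); for a single covariate the two coincide.
    """
    times, events = _check_surv_input(times, events)
    d = int(events.sum())
    if d < 3:
        raise DegenerateDataError("PH test requires at least 3 events")
    resid, rtimes = schoenfeld_residuals(fit, covariates, times, events)
    if transform == "km":
        km = kaplan_meier(times, events)
        g = np.array([1.0 - km.at(t) for t in rtimes])
    elif transform == "rank":
        g = stats.rankdata(rtimes)
    elif transform == "identity":
        g = rtimes.astype(float)
    else:
        raise ConfigurationError(f"unknown time transform {transform!r}")
    g = g - g.mean()
    gg = float(g @ g)
    if gg == 0:
        raise DegenerateDataError("degenerate time transform (all events tied)")
    z = g @ resid  # p-vector
    V = fit.var
    zv = z @ V
    per_cov = np.array(
        [stats.chi2.sf(d * zv[j] ** 2 / (V[j, j] * gg), df=1) for j in range(len(zv))]
    )
    global_chi2 = d * float(z @ V @ z) / gg
    global_p = float(stats.chi2.sf(global_chi2, df=len(zv)))
    return per_cov, global_p
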