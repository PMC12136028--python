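"""Synthetic ICU cohorts with the statistical structure the analysis assumes.

The generator emulates a prospective cohort with ~30% 30-day mortality,
log-normal fecal metabolite concentrations where a planted subset is shifted
between outcome groups, right-censoring at the horizon, integer CCI/SOFA
confounders correlated with the outcome, and Dirichlet taxa profiles with
optional pathobiont domination.  Everything is driven by a single seed; the
outcome, metabolite, and taxa components each consume a deterministic
sub-stream so that, e.g., changing ``n_taxa`` does not perturb the cohort.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .datatypes import MetaboliteMatrix, validate_cohort
from .errors import ConfigurationError

PATHOBIONT_LINEAGE = (
    "k__Bacteria|p__Bacillota|c__Bacilli|o__Lactobacillales"
    "|f__Enterococcaceae|g__Enterococcus|s__Enterococcus_faecium"
)

# logistic weights tying CCI / SOFA to mortality (log-odds per unit)
_CCI_BETA = 0.25
_SOFA_BETA = 0.15


@dataclass(frozen=True)
class SimConfig:
    """Parameters of a synthetic cohort.

    ``event_time_dist`` selects how death days are drawn: ``"uniform"``
    (default, uniform over {1..horizon_days}) or ``"exponential"`` (piecewise
    memoryless times under a planted ``hazard_ratio`` on a fair-coin binary
    risk group, censored at the horizon).
    """

    n_patients: int = 200
    n_metabolites: int = 30
    n_informative: int = 5
    effect_log2fc: float = 2.0
    mortality_rate: float = 0.306
    missing_rate: float = 0.0
    horizon_days: int = 30
    n_taxa: int = 12
    domination_prob: float = 0.2
    seed: int = 0
    event_time_dist: str = "uniform"
    hazard_ratio: float = 2.0
    log_sd: float = 1.0
    equicorrelation: float = 0.0

    def validate(self) -> "SimConfig":
        if self.n_patients < 1:
            raise ConfigurationError("n_patients must be a positive integer")
        if self.n_metabolites < 1:
            raise ConfigurationError("n_metabolites must be a positive integer")
        if not 0 <= self.n_informative <= self.n_metabolites:
            raise ConfigurationError("n_informative must lie in [0, n_metabolites]")
        if not 0.0 < self.mortality_rate < 1.0:
            raise ConfigurationError("mortality_rate must lie in (0, 1)")
        if not 0.0 <= self.missing_rate < 0.3:
            raise ConfigurationError("missing_rate must lie in [0, 0.3)")
        if self.horizon_days < 1:
            raise ConfigurationError("horizon_days must be a positive integer")
        if self.n_taxa < 2:
            raise ConfigurationError("n_taxa must be >= 2")
        if not 0.0 <= self.domination_prob <= 1.0:
            raise ConfigurationError("domination_prob must lie in [0, 1]")
        if self.event_time_dist not in ("uniform", "exponential"):
            raise ConfigurationError("event_time_dist must be 'uniform' or 'exponential'")
        if self.hazard_ratio <= 0:
            raise ConfigurationError("hazard_ratio must be positive")
        if self.log_sd <= 0:
            raise ConfigurationError("log_sd must be positive")
        if not 0.0 <= self.equicorrelation < 1.0:
            raise ConfigurationError("equicorrelation must lie in [0, 1)")
        return self


@dataclass
class SyntheticCohort:
    cohort: pd.DataFrame
    metabolites: MetaboliteMatrix
    taxa: pd.DataFrame  # lineage rows x patient columns, percent
    truth: dict = field(default_factory=dict)


def _rngs(config: SimConfig, n_streams: int = 3):
    children = np.random.SeedSequence(config.seed).spawn(n_streams)
    return [np.random.default_rng(s) for s in children]


def _calibrate_intercept(lp: np.ndarray, rate: float) -> float:
    """Intercept b0 such that mean(expit(b0 + lp)) == rate."""

    def f(b0):
        return expit(b0 + lp).mean() - rate

    return brentq(f, -30.0, 30.0)


def _draw_outcome(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    n, horizon = config.n_patients, config.horizon_days
    cci = rng.poisson(4.0, n)
    sofa = rng.poisson(8.0, n)
    cohort = pd.DataFrame(
        {
            "patient_id": [f"P{i:04d}" for i in range(n)],
            "cci": cci,
            "sofa": sofa,
        }
    )

    if config.event_time_dist == "uniform":
        lp = _CCI_BETA * (cci - cci.mean()) + _SOFA_BETA * (sofa - sofa.mean())
        b0 = _calibrate_intercept(lp, config.mortality_rate)
        p = expit(b0 + lp)
        event = (rng.random(n) < p).astype(int)
        days = np.full(n, horizon, dtype=int)
        days[event == 1] = rng.integers(1, horizon + 1, size=int(event.sum()))
    else:
        group = rng.integers(0, 2, size=n)
        hr = config.hazard_ratio

        def mean_event_prob(lam0):
            lam = lam0 * np.where(group == 1, hr, 1.0)
            return (1.0 - np.exp(-lam * horizon)).mean() - config.mortality_rate

        lam0 = brentq(mean_event_prob, 1e-9, 10.0)
        lam = lam0 * np.where(group == 1, hr, 1.0)
        t = rng.exponential(1.0 / lam)
        event = (t <= horizon).astype(int)
        days = np.where(event == 1, np.ceil(t).astype(int).clip(1, horizon), horizon)
        cohort["risk_group"] = group

    cohort["survival_days"] = days
    cohort["event"] = event
    cohort["mortality_label"] = event
    return cohort[
        ["patient_id", "survival_days", "event", "mortality_label", "cci", "sofa"]
        + (["risk_group"] if "risk_group" in cohort else [])
    ]


def _draw_metabolites(
    config: SimConfig, event: np.ndarray, rng: np.random.Generator
) -> tuple[MetaboliteMatrix, dict]:
    n, k = config.n_patients, config.n_metabolites
    names = [f"met_{j + 1:02d}" for j in range(k)]
    informative = names[: config.n_informative]
    # alternate planted directions: +1 = higher in nonsurvivors
    signs = np.array([1 if j % 2 == 0 else -1 for j in range(config.n_informative)])

    mu = rng.normal(0.0, 1.0, size=k)  # log-scale medians for survivors
    shift = np.zeros(k)
    shift[: config.n_informative] = signs * config.effect_log2fc * math.log(2.0)

    rho = config.equicorrelation
    z = rng.normal(size=(n, 1))
    eps = rng.normal(size=(n, k))
    noise = math.sqrt(rho) * z + math.sqrt(1.0 - rho) * eps
    logx = mu[None, :] + shift[None, :] * event[:, None] + config.log_sd * noise
    values = np.exp(logx)

    if config.missing_rate > 0:
        mask = rng.random(size=(n, k)) < config.missing_rate
        values = np.where(mask, np.nan, values)

    data = pd.DataFrame(values, columns=names)
    data.index = pd.Index([f"P{i:04d}" for i in range(n)], name="patient_id")
    matrix = MetaboliteMatrix(data, {m: "absolute" for m in names})
    truth = {
        "informative": informative,
        "signs": {m: int(s) for m, s in zip(informative, signs)},
        # midpoint between group medians on the log scale
        "thresholds": {
            m: float(np.exp(mu[j] + shift[j] / 2.0))
            for j, m in enumerate(informative)
        },
        "effect_log2fc": config.effect_log2fc,
    }
    return matrix, truth


def generate_taxa(config: SimConfig, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Dirichlet relative-abundance profiles, percent scale, one column per patient.

    Rows are species-level pipe-delimited lineages.  With probability
    ``domination_prob`` a patient's profile is dominated (>50%) by the
    designated pathobiont (Enterococcus).
    """
    config.validate()
    if rng is None:
        rng = _rngs(config)[2]
    n, k = config.n_patients, config.n_taxa
    lineages = [PATHOBIONT_LINEAGE]
    for j in range(1, k):
        lineages.append(
            f"k__Bacteria|p__Phylum{j % 3}|c__Class{j % 3}|o__Order{j % 4}"
            f"|f__Family{j}|g__Genus{j}|s__Species{j}"
        )
    profiles = rng.dirichlet(np.ones(k), size=n) * 100.0
    dominate = rng.random(n) < config.domination_prob
    dom_level = rng.uniform(51.0, 95.0, size=n)
    for i in range(n):
        if dominate[i]:
            rest = profiles[i].sum() - profiles[i, 0]
            profiles[i, 0] = dom_level[i]
            scale = (100.0 - dom_level[i]) / rest if rest > 0 else 0.0
            profiles[i, 1:] *= scale
    cols = [f"P{i:04d}" for i in range(n)]
    return pd.DataFrame(profiles.T, index=pd.Index(lineages, name="clade_name"), columns=cols)


def generate_cohort(config: SimConfig) -> SyntheticCohort:
    """Draw a full synthetic cohort (outcomes, metabolites, taxa, truth record)."""
    config.validate()
    rng_outcome, rng_met, rng_taxa = _rngs(config)
    cohort = _draw_outcome(config, rng_outcome)
    validate_cohort(cohort, horizon=config.horizon_days)
    matrix, truth = _draw_metabolites(
        config, cohort["event"].to_numpy(), rng_met
    )
    taxa = generate_taxa(config, rng_taxa)
    truth["hazard_ratio"] = (
        config.hazard_ratio if config.event_time_dist == "exponential" else None
    )
    truth["config"] = asdict(config)
    return SyntheticCohort(cohort=cohort, metabolites=matrix, taxa=taxa, truth=truth)


def write_cohort(sc: SyntheticCohort, outdir: str | Path) -> dict[str, Path]:
    """Write cohort/metabolite/taxa TSVs plus a truth JSON; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "cohort": outdir / "cohort.tsv",
        "metabolites": outdir / "metabolites.tsv",
        "taxa": outdir / "taxa.tsv",
        "truth": outdir / "truth.json",
    }
    sc.cohort.to_csv(paths["cohort"], sep="\t", index=False)
    sc.metabolites.data.to_csv(paths["metabolites"], sep="\t")
    sc.taxa.to_csv(paths["taxa"], sep="\t")
    paths["truth"].write_text(json.dumps(sc.truth, indent=2))
    return paths
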