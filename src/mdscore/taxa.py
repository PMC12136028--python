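"""Taxonomic-side computations on MetaPhlAn-style relative-abundance profiles:
parsing, rank aggregation, Shannon diversity, Bray-Curtis dissimilarity,
pathobiont-domination flags, and Youden-threshold survival stratification."""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cutpoints import Cutpoint, youden_cutpoint
from .datatypes import validate_cohort
from .errors import ConfigurationError, DegenerateDataError, SchemaError
from .survival import log_rank

UNCLASSIFIED_KEY = "UNCLASSIFIED"

RANK_PREFIXES = {
    "kingdom": "k__",
    "phylum": "p__",
    "class": "c__",
    "order": "o__",
    "family": "f__",
    "genus": "g__",
    "species": "s__",
}
_PREFIX_ORDER = list(RANK_PREFIXES.values())


@dataclass
class TaxaProfile:
    """Per-patient lineage-keyed relative abundances (percent)."""

    patient_id: str
    abundances: dict[str, float] = field(default_factory=dict)


def _lineage_rank(lineage: str) -> str | None:
    """Prefix (e.g. 's__') of the terminal component; None for UNCLASSIFIED."""
    if lineage == UNCLASSIFIED_KEY:
        return None
    last = lineage.split("|")[-1]
    return last[:3]


def _validate_lineage(lineage: str, lineno: int) -> None:
    if lineage == UNCLASSIFIED_KEY:
        return
    parts = lineage.split("|")
    for depth, part in enumerate(parts):
        if depth >= len(_PREFIX_ORDER) or not part.startswith(_PREFIX_ORDER[depth]):
            raise SchemaError(f"malformed lineage at line {lineno}: {lineage!r}")


def read_profiles(path: str | Path) -> dict[str, TaxaProfile]:
    """Parse a merged abundance TSV (lineage rows, one column per sample)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    profiles = {s: TaxaProfile(patient_id=str(s)) for s in df.columns}
    for lineno, (lineage, row) in enumerate(df.iterrows(), start=2):
        _validate_lineage(str(lineage), lineno)
        for sample, value in row.items():
            v = float(value)
            if v < 0:
                raise SchemaError(f"negative abundance at line {lineno}")
            if v > 0:
                profiles[sample].abundances[str(lineage)] = v
    return profiles


def write_profiles(profiles: dict[str, TaxaProfile], path: str | Path) -> None:
    lineages = sorted({ln for p in profiles.values() for ln in p.abundances})
    df = pd.DataFrame(
        {pid: [p.abundances.get(ln, 0.0) for ln in lineages] for pid, p in profiles.items()},
        index=pd.Index(lineages, name="clade_name"),
    )
    df.to_csv(path, sep="\t")


def aggregate_level(profile: TaxaProfile, rank: str) -> dict[str, float]:
    """Abundance per taxon at a rank.

    Rows terminating exactly at the rank are used when present (MetaPhlAn
    tables carry every rank); otherwise deeper lineages are summed by their
    prefix at the rank.  Returns taxon name (prefix stripped) -> abundance.
    """
    if rank not in RANK_PREFIXES:
        raise ConfigurationError(f"unknown rank {rank!r}")
    prefix = RANK_PREFIXES[rank]
    depth = _PREFIX_ORDER.index(prefix)

    at_rank: dict[str, float] = {}
    deeper: dict[str, float] = {}
    for lineage, value in profile.abundances.items():
        if lineage == UNCLASSIFIED_KEY:
            continue
        parts = lineage.split("|")
        if len(parts) <= depth:
            continue
        name = parts[depth][3:]
        if len(parts) - 1 == depth:
            at_rank[name] = at_rank.get(name, 0.0) + value
        else:
            deeper[name] = deeper.get(name, 0.0) + value
    result = at_rank if at_rank else deeper
    if not result:
        raise DegenerateDataError(f"profile has no rows at or below rank {rank!r}")
    return result


def shannon_index(abundances, base: float | None = None) -> float:
    """Shannon entropy -sum(p ln p) over renormalized proportions.

    Natural log by default; pass ``base`` to change it.  Zero-abundance
    entries contribute nothing.
    """
    vals = np.asarray(
        list(abundances.values()) if isinstance(abundances, dict) else abundances,
        dtype=float,
    )
    if (vals < 0).any():
        raise ConfigurationError("abundances must be nonnegative")
    total = vals.sum()
    if total <= 0:
        raise DegenerateDataError("all-zero abundance vector")
    p = vals[vals > 0] / total
    h = float(-(p * np.log(p)).sum())
    if base is not None:
        h /= math.log(base)
    return h


def bray_curtis(a, b) -> float:
    """Bray-Curtis dissimilarity sum|a-b| / sum(a+b) over the key union."""
    if isinstance(a, dict) or isinstance(b, dict):
        keys = sorted(set(a) | set(b))
        av = np.array([a.get(k, 0.0) for k in keys], dtype=float)
        bv = np.array([b.get(k, 0.0) for k in keys], dtype=float)
    else:
        av = np.asarray(a, dtype=float)
        bv = np.asarray(b, dtype=float)
    if (av < 0).any() or (bv < 0).any():
        raise ConfigurationError("abundances must be nonnegative")
    denom = float((av + bv).sum())
    if denom == 0:
        raise DegenerateDataError("both profiles are all-zero")
    return float(np.abs(av - bv).sum() / denom)


def domination_flag(
    profile: TaxaProfile, taxon: str, rank: str, threshold_pct: float
) -> int:
    """1 iff the taxon's aggregated abundance strictly exceeds threshold_pct."""
    if not 0.0 < threshold_pct < 100.0:
        raise ConfigurationError("threshold_pct must lie in (0, 100)")
    try:
        agg = aggregate_level(profile, rank)
    except DegenerateDataError:
        return 0
    return int(agg.get(taxon, 0.0) > threshold_pct)


def profile_shannon(profiles: dict[str, TaxaProfile], rank: str = "species") -> pd.Series:
    """Per-patient Shannon index at a rank (proportions renormalized)."""
    return pd.Series(
        {pid: shannon_index(aggregate_level(p, rank)) for pid, p in profiles.items()},
        name="shannon",
    )


def stratify_by_youden(
    values, cohort: pd.DataFrame
) -> tuple[Cutpoint, np.ndarray, tuple[float, float]]:
    """Threshold a continuous per-patient variable at its Youden optimum
    against 30-day mortality and log-rank the two strata.

    Returns (cutpoint, binary point-side labels, (chi2, p)).
    """
    validate_cohort(cohort)
    values = np.asarray(values, dtype=float)
    labels = cohort["mortality_label"].to_numpy(dtype=int)
    cp = youden_cutpoint(values, labels, n_boot=0)
    if cp.degenerate:
        raise DegenerateDataError("no discriminating threshold exists")
    if cp.direction == "high_in_nonsurvivors":
        groups = (values >= cp.threshold).astype(int)
    else:
        groups = (values <= cp.threshold).astype(int)
    chi2, p = log_rank(
        cohort["survival_days"].to_numpy(dtype=float),
        cohort["event"].to_numpy(dtype=int),
        groups,
    )
    return cp, groups, (chi2, p)
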