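"""Shared tabular data structures and their schemas.

A *cohort table* is a :class:`pandas.DataFrame` with one row per patient and
the columns in :data:`COHORT_COLUMNS`:

``patient_id``
    unique string identifier.
``survival_days``
    integer follow-up in days, in ``[0, horizon]``.
``event``
    1 if the patient died within the horizon, else 0 (censored at horizon).
``mortality_label``
    binary 30-day nonsurvivor label; equals ``event`` under the fixed horizon.
``cci``, ``sofa``
    nonnegative integer comorbidity / organ-failure scores.

A :class:`MetaboliteMatrix` wraps a patients x metabolites concentration
frame (``NaN`` marks a missing measurement) together with a per-metabolite
panel tag (``"absolute"`` in mM or ``"relative"`` in arbitrary units).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import SchemaError

COHORT_COLUMNS = [
    "patient_id",
    "survival_days",
    "event",
    "mortality_label",
    "cci",
    "sofa",
]

PANELS = ("absolute", "relative")


def validate_cohort(cohort: pd.DataFrame, horizon: int = 30) -> pd.DataFrame:
    """Check a cohort table against the schema; returns the frame unchanged."""
    missing = [c for c in COHORT_COLUMNS if c not in cohort.columns]
    if missing:
        raise SchemaError(f"cohort table missing columns: {missing}")
    if cohort["patient_id"].duplicated().any():
        raise SchemaError("cohort table has duplicated patient_id values")
    ev = cohort["event"].to_numpy()
    if not np.isin(ev, [0, 1]).all():
        raise SchemaError("event must be binary")
    days = cohort["survival_days"].to_numpy()
    if (days < 0).any() or (days > horizon).any():
        raise SchemaError(f"survival_days must lie in [0, {horizon}]")
    if not (days[ev == 0] == horizon).all():
        raise SchemaError(f"censored patients must have survival_days == {horizon}")
    if not (cohort["mortality_label"].to_numpy() == ev).all():
        raise SchemaError("mortality_label must equal event under the fixed horizon")
    if (cohort["cci"].to_numpy() < 0).any() or (cohort["sofa"].to_numpy() < 0).any():
        raise SchemaError("cci and sofa must be nonnegative")
    return cohort


@dataclass
class MetaboliteMatrix:
    """Patients x metabolites concentrations with missingness and panel tags.

    Parameters
    ----------
    data : DataFrame indexed by patient_id, one column per metabolite.
        ``NaN`` entries are missing measurements; observed values must be
        nonnegative.
    panel : mapping metabolite -> {"absolute", "relative"}.
        Metabolites absent from the mapping default to "absolute".
    """

    data: pd.DataFrame
    panel: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        vals = self.data.to_numpy(dtype=float)
        if np.nanmin(vals, initial=0.0) < 0:
            raise SchemaError("metabolite concentrations must be nonnegative")
        for met, tag in self.panel.items():
            if tag not in PANELS:
                raise SchemaError(f"unknown panel tag {tag!r} for {met!r}")

    @property
    def metabolites(self) -> list[str]:
        return list(self.data.columns)

    @property
    def patients(self) -> list[str]:
        return list(self.data.index)

    def panel_of(self, metabolite: str) -> str:
        return self.panel.get(metabolite, "absolute")

    def missing_fraction(self) -> pd.Series:
        """Per-metabolite fraction of missing values."""
        return self.data.isna().mean(axis=0)

    def subset_patients(self, patient_ids) -> "MetaboliteMatrix":
        return MetaboliteMatrix(self.data.loc[list(patient_ids)], dict(self.panel))

    def subset_metabolites(self, metabolite_ids) -> "MetaboliteMatrix":
        ids = list(metabolite_ids)
        return MetaboliteMatrix(
            self.data[ids], {m: self.panel_of(m) for m in ids}
        )

    def align_to(self, cohort: pd.DataFrame) -> "MetaboliteMatrix":
        """Reorder rows to match a cohort table; errors on unmatched patients."""
        ids = cohort["patient_id"].tolist()
        absent = [p for p in ids if p not in self.data.index]
        if absent:
            raise SchemaError(f"patients without metabolite rows: {absent[:5]}")
        return self.subset_patients(ids)
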