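"""Inclusion/exclusion screening of a cohort manifest.

Each subject is assigned to exactly one category, tested in a fixed
priority order: abnormal screening labs (positive CRP or abnormal blood
cell counts — the age criterion, 18 years or older, also lands here), then
missing laboratory parameters, then insufficient material for flow
cytometry, else included.  The priority order makes multi-flag subjects
count once, so the category counts always partition the manifest.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .exceptions import ValidationError

__all__ = ["ScreeningReport", "screen_cohort", "AGE_LIMIT_DAYS"]

#: Upper age bound of the study population: strictly under 18 years,
#: counted as 365-day years (leap days ignored).
AGE_LIMIT_DAYS = 18 * 365


@dataclass(frozen=True)
class ScreeningReport:
    """Exclusion accounting for one screened manifest.

    Invariant: ``n_assessed`` equals ``n_included`` plus the three exclusion
    counts — every subject lands in exactly one category.
    """

    n_assessed: int
    n_excluded_abnormal: int
    n_excluded_missing_labs: int
    n_excluded_insufficient_material: int
    n_included: int
    included_ids: tuple[str, ...] = field(default=(), repr=False)

    def __post_init__(self) -> None:
        counts = (self.n_excluded_abnormal, self.n_excluded_missing_labs,
                  self.n_excluded_insufficient_material, self.n_included)
        if any(c < 0 for c in counts) or self.n_assessed != sum(counts):
            raise ValidationError("screening counts do not partition n_assessed")

    @property
    def n_excluded(self) -> int:
        return self.n_assessed - self.n_included

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "n_assessed": self.n_assessed,
            "n_excluded_abnormal": self.n_excluded_abnormal,
            "n_excluded_missing_labs": self.n_excluded_missing_labs,
            "n_excluded_insufficient_material": self.n_excluded_insufficient_material,
            "n_included": self.n_included,
        }])


def screen_cohort(cohort: pd.DataFrame) -> ScreeningReport:
    """Apply the inclusion criteria to a cohort table.

    Parameters
    ----------
    cohort : DataFrame
        Must carry ``subject_id``, ``age_days`` and the boolean screening
        columns ``crp_positive_or_abnormal_counts``, ``labs_missing``,
        ``material_insufficient`` (encoded 0/1 or bool).

    Returns
    -------
    ScreeningReport
        Counts per category plus the ids of the included subjects, in
        manifest order.

    Raises
    ------
    ValidationError
        If subject ids are duplicated (the duplicates are listed).
    """
    required = ["subject_id", "age_days", "crp_positive_or_abnormal_counts",
                "labs_missing", "material_insufficient"]
    missing_cols = [c for c in required if c not in cohort.columns]
    if missing_cols:
        raise ValidationError(f"cohort table lacks required columns: {missing_cols}")
    dupes = cohort["subject_id"][cohort["subject_id"].duplicated()].unique().tolist()
    if dupes:
        raise ValidationError(f"duplicate subject ids: {dupes}")

    if len(cohort) == 0:
        return ScreeningReport(0, 0, 0, 0, 0, ())

    abnormal = cohort["crp_positive_or_abnormal_counts"].astype(bool).to_numpy() \
        | (cohort["age_days"].to_numpy() >= AGE_LIMIT_DAYS)
    missing = cohort["labs_missing"].astype(bool).to_numpy() & ~abnormal
    insufficient = cohort["material_insufficient"].astype(bool).to_numpy() & ~abnormal & ~missing
    included = ~(abnormal | missing | insufficient)

    return ScreeningReport(
        n_assessed=len(cohort),
        n_excluded_abnormal=int(abnormal.sum()),
        n_excluded_missing_labs=int(missing.sum()),
        n_excluded_insufficient_material=int(insufficient.sum()),
        n_included=int(included.sum()),
        included_ids=tuple(cohort.loc[included, "subject_id"].astype(str)),
    )


def included_subset(cohort: pd.DataFrame) -> pd.DataFrame:
    """The rows of ``cohort`` that pass screening, in manifest order."""
    report = screen_cohort(cohort)
    return cohort[cohort["subject_id"].astype(str).isin(set(report.included_ids))].copy()
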