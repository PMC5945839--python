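"""Per-patient reference evaluation and CD19-vs-CD20 marker comparison.

``evaluate_patient`` is the reference-calculator use case: given one
child's subset panel and age, look up the continuous reference for every
measured (subset, measure), compute the predicted value and the 90%/95%
limits at that age, and flag the observation as below / within / above
each band.  Intervals are closed (a value exactly on a limit is within),
the clinical convention.  Patients aged over 18 years are rejected: the
model is fitted on children only.

``compare_markers`` summarises the agreement of CD19 and CD20 as the
denominator marker across a cohort: the co-expression fraction, the
per-subject absolute-count differences, and the systematic shifts of the
naïve and switched-memory fractions between the two denominators.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bands import ContinuousReference
from .exceptions import MissingReferenceError, RangeError, ValidationError

__all__ = ["SubsetPanel", "ReferenceEvaluation", "PatientReport",
           "evaluate_patient", "compare_markers", "MarkerComparison"]

PANEL_SUBSETS = ("totalB", "naive", "nonswitched", "switched", "memory")


@dataclass
class SubsetPanel:
    """One patient's B cell measurements under a single denominator marker.

    ``values`` maps ``(subset, measure)`` — e.g. ``("switched", "abs")`` —
    to the measured value: fractions in % of B cells (total B in % of
    lymphocytes), absolute counts in cells/μl.
    """

    values: dict[tuple[str, str], float]
    denominator_marker: str = "CD19"

    def __post_init__(self) -> None:
        if self.denominator_marker not in ("CD19", "CD20"):
            raise ValidationError(f"unknown denominator marker {self.denominator_marker!r}")
        for (subset, measure), v in self.values.items():
            if subset not in PANEL_SUBSETS or measure not in ("pct", "abs"):
                raise ValidationError(f"unknown panel entry {(subset, measure)!r}")
            if measure == "pct" and not 0 <= v <= 100:
                raise ValidationError(f"{subset} fraction {v} outside [0, 100]%")
            if measure == "abs" and v < 0:
                raise ValidationError(f"{subset} absolute count {v} negative")
        for measure in ("pct", "abs"):
            trio = [self.values.get(("memory", measure)),
                    self.values.get(("nonswitched", measure)),
                    self.values.get(("switched", measure))]
            if all(v is not None for v in trio) and abs(trio[0] - trio[1] - trio[2]) > 0.5:
                raise ValidationError(
                    f"memory {measure} is not the sum of non-switched + switched "
                    f"(|{trio[0]} - {trio[1]} - {trio[2]}| > 0.5)")

    @classmethod
    def from_row(cls, row: pd.Series, denominator: str = "cd19") -> "SubsetPanel":
        """Extract a panel from one cohort-table row."""
        values = {}
        for subset in PANEL_SUBSETS:
            for measure in ("pct", "abs"):
                col = f"{subset}_{measure}_{denominator}"
                if col in row.index and pd.notna(row[col]):
                    values[(subset, measure)] = float(row[col])
        return cls(values, denominator_marker=denominator.upper())

    @staticmethod
    def absolute_from_dual_platform(lymphocytes_per_ul: float,
                                    fraction_of_lymphocytes_pct: float) -> float:
        """Dual-platform absolute count: analyzer lymphocytes × flow fraction."""
        if lymphocytes_per_ul < 0 or not 0 <= fraction_of_lymphocytes_pct <= 100:
            raise ValidationError("invalid dual-platform inputs")
        return lymphocytes_per_ul * fraction_of_lymphocytes_pct / 100.0


@dataclass(frozen=True)
class ReferenceEvaluation:
    """One measurement judged against its continuous reference."""

    subset: str
    measure: str
    age_years: float
    observed: float
    predicted: float
    limits: dict[float, tuple[float, float]]   # confidence -> (lower, upper)
    flags: dict[float, str]                    # confidence -> below/within/above

    @property
    def abnormal(self) -> bool:
        """Highlight marker: outside the widest (most permissive) band."""
        widest = max(self.flags)
        return self.flags[widest] != "within"


@dataclass
class PatientReport:
    """All evaluations for one patient, plus per-subset lookup failures."""

    age_years: float
    evaluations: list[ReferenceEvaluation]
    errors: list[tuple[str, str, str]] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for ev in self.evaluations:
            row = {"subset": ev.subset, "measure": ev.measure,
                   "age_years": ev.age_years, "observed": ev.observed,
                   "predicted": ev.predicted, "abnormal": int(ev.abnormal)}
            for conf, (lo, hi) in sorted(ev.limits.items()):
                pct = int(round(conf * 100))
                row[f"lower{pct}"] = lo
                row[f"upper{pct}"] = hi
                row[f"flag{pct}"] = ev.flags[conf]
            rows.append(row)
        return pd.DataFrame(rows)


def _flag(observed: float, lo: float, hi: float) -> str:
    if observed < lo:
        return "below"
    if observed > hi:
        return "above"
    return "within"


def evaluate_patient(panel: SubsetPanel, age_years: float,
                     references) -> PatientReport:
    """Evaluate every measured (subset, measure) against its reference.

    ``references`` is an iterable of :class:`ContinuousReference`; matching
    is by (subset, measure) with the panel's denominator marker preferred
    when several denominators are available.  A missing reference is
    recorded as a per-subset error; the remaining subsets are still
    evaluated.
    """
    if not 0 <= age_years <= 18:
        raise RangeError(f"patient age {age_years} y outside the supported 0-18 y domain")
    by_key: dict[tuple[str, str], ContinuousReference] = {}
    marker = panel.denominator_marker.lower()
    for ref in references:
        key = (ref.subset, ref.measure)
        if key not in by_key or ref.denominator.lower() == marker:
            by_key[key] = ref

    evaluations, errors = [], []
    for (subset, measure), observed in sorted(panel.values.items()):
        ref = by_key.get((subset, measure))
        if ref is None:
            errors.append((subset, measure,
                           f"no reference for ({subset}, {measure})"))
            continue
        limits, flags = {}, {}
        for band in ref.bands:
            lo, hi = ref.limits(age_years, band.confidence)
            limits[band.confidence] = (lo, hi)
            flags[band.confidence] = _flag(observed, lo, hi)
        evaluations.append(ReferenceEvaluation(
            subset=subset, measure=measure, age_years=age_years,
            observed=observed, predicted=ref.predicted(age_years),
            limits=limits, flags=flags))
    if not evaluations and errors:
        raise MissingReferenceError(
            "no reference matched any measured subset: " + "; ".join(e[2] for e in errors))
    return PatientReport(age_years=age_years, evaluations=evaluations, errors=errors)


@dataclass(frozen=True)
class MarkerComparison:
    """Cohort-level CD19-vs-CD20 agreement summary."""

    n: int
    median_abs_count_diff: float       # median |CD19 - CD20| total count, cells/μl
    count_diff_range: tuple[float, float]
    coexpression_pct: float            # median % of CD19+ B cells that are CD20+
    median_naive_pct_diff: float       # median (CD19 - CD20) naïve fraction
    median_switched_pct_diff: float    # median (CD19 - CD20) switched fraction

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "n": self.n,
            "median_abs_count_diff": self.median_abs_count_diff,
            "count_diff_min": self.count_diff_range[0],
            "count_diff_max": self.count_diff_range[1],
            "coexpression_pct": self.coexpression_pct,
            "median_naive_pct_diff": self.median_naive_pct_diff,
            "median_switched_pct_diff": self.median_switched_pct_diff,
        }])


def compare_markers(cohort: pd.DataFrame) -> MarkerComparison:
    """Compare CD19- and CD20-denominated measurements across a cohort.

    Rows with an incomplete marker pair (e.g. no cytometry) are dropped;
    the cohort must carry both markers' total counts and the naïve and
    switched fractions under both denominators.
    """
    needed = ["totalB_abs_cd19", "totalB_abs_cd20", "naive_pct_cd19",
              "naive_pct_cd20", "switched_pct_cd19", "switched_pct_cd20"]
    missing = [c for c in needed if c not in cohort.columns]
    if missing:
        raise ValidationError(f"cohort lacks marker-comparison columns: {missing}")
    sub = cohort[needed + (["cd20_coexpr_pct"] if "cd20_coexpr_pct" in cohort.columns else [])].dropna()
    if len(sub) == 0:
        raise ValidationError("no rows with complete CD19/CD20 marker pairs")

    diff = (sub["totalB_abs_cd19"] - sub["totalB_abs_cd20"]).abs()
    if "cd20_coexpr_pct" in sub.columns:
        coexpr = float(sub["cd20_coexpr_pct"].median())
    else:
        # fall back to the count ratio: overlap cannot exceed either total
        ratio = (np.minimum(sub["totalB_abs_cd20"], sub["totalB_abs_cd19"])
                 / sub["totalB_abs_cd19"]) * 100.0
        coexpr = float(ratio.median())
    return MarkerComparison(
        n=len(sub),
        median_abs_count_diff=float(diff.median()),
        count_diff_range=(float(diff.min()), float(diff.max())),
        coexpression_pct=coexpr,
        median_naive_pct_diff=float((sub["naive_pct_cd19"] - sub["naive_pct_cd20"]).median()),
        median_switched_pct_diff=float((sub["switched_pct_cd19"] - sub["switched_pct_cd20"]).median()),
    )
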