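"""Conventional age-group percentile references and their discontinuities.

Binned references assign every child to an age group and publish per-group
percentiles; at each group boundary the reference value jumps, although
nothing biological happens overnight on a birthday.  This module builds
such step references (with the same interpolated-quantile rule as the
continuous bands, for comparability), ingests externally published grouped
tables, and quantifies the boundary jumps against the smooth predicted
curve, whose per-day increment is bounded in closed form by
``|b*c| * exp(max(0, 18c)) / 365``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bands import ContinuousReference
from .exceptions import ValidationError

__all__ = ["GroupedReference", "build_grouped_reference", "step_discontinuity",
           "overlay_report", "max_daily_increment", "DEFAULT_GROUP_EDGES"]

#: Default age-group boundaries in years (half-open bins, last closed at 18).
DEFAULT_GROUP_EDGES = (0.0, 1.0, 2.0, 5.0, 11.0, 18.0)

PERCENTILES = (5, 10, 50, 90, 95)


@dataclass
class GroupedReference:
    """Per-age-group percentile table for a set of measurement columns.

    ``table`` has one row per (group, column) with columns
    ``group, age_lo, age_hi, column, n, mean, p5, p10, p50, p90, p95``.
    """

    group_edges: tuple[float, ...]
    table: pd.DataFrame

    def __post_init__(self) -> None:
        edges = tuple(float(e) for e in self.group_edges)
        if len(edges) < 2 or any(b <= a for a, b in zip(edges, edges[1:])):
            raise ValidationError("group_edges must be strictly increasing, length >= 2")
        self.group_edges = edges

    @property
    def n_groups(self) -> int:
        return len(self.group_edges) - 1

    @property
    def columns(self) -> tuple[str, ...]:
        return tuple(self.table["column"].unique())

    def percentile(self, column: str, percentile: int) -> np.ndarray:
        """The given percentile per group, ordered by age."""
        key = f"p{percentile}"
        if key not in self.table.columns:
            raise ValidationError(
                f"unknown percentile {percentile}; have {PERCENTILES}")
        sub = self.table[self.table["column"] == column].sort_values("age_lo")
        if len(sub) == 0:
            raise ValidationError(f"no grouped data for column {column!r}")
        return sub[key].to_numpy(dtype=float)

    def step_value(self, column: str, percentile: int, age_years) -> np.ndarray:
        """The step-function reference evaluated at arbitrary ages."""
        vals = self.percentile(column, percentile)
        age = np.atleast_1d(np.asarray(age_years, dtype=float))
        idx = np.clip(np.searchsorted(self.group_edges, age, side="right") - 1,
                      0, self.n_groups - 1)
        return vals[idx]

    @classmethod
    def from_published(cls, group_edges, rows: pd.DataFrame) -> "GroupedReference":
        """Ingest an externally published grouped table without refitting.

        ``rows`` must carry ``column`` plus any subset of ``n``, ``mean``
        and ``p5..p95``; group boundaries must be supplied explicitly, one
        row per (group, column) ordered by group.
        """
        edges = tuple(float(e) for e in group_edges)
        n_groups = len(edges) - 1
        if "column" not in rows.columns:
            raise ValidationError("published table needs a 'column' field")
        out = rows.copy()
        per_col = out.groupby("column").size()
        if not (per_col == n_groups).all():
            bad = per_col[per_col != n_groups].index.tolist()
            raise ValidationError(
                f"columns {bad} do not have one row per group ({n_groups} groups)")
        out["group"] = out.groupby("column").cumcount()
        out["age_lo"] = out["group"].map(lambda g: edges[g])
        out["age_hi"] = out["group"].map(lambda g: edges[g + 1])
        return cls(edges, out)


def build_grouped_reference(cohort: pd.DataFrame, group_edges=DEFAULT_GROUP_EDGES,
                            columns=None, age_col: str = "age_days",
                            age_in_days: bool = True) -> GroupedReference:
    """Empirical per-group percentiles of the given measurement columns.

    Group assignment is half-open ``[low, high)`` with the last bin closed
    at its upper edge.  Every group must be non-empty for every column.
    """
    edges = tuple(float(e) for e in group_edges)
    ages = cohort[age_col].to_numpy(dtype=float)
    if age_in_days:
        ages = ages / 365.0
    if columns is None:
        columns = [c for c in cohort.columns
                   if cohort[c].dtype.kind == "f" and c != age_col]
    idx = np.searchsorted(edges, ages, side="right") - 1
    idx[np.isclose(ages, edges[-1])] = len(edges) - 2  # close the last bin
    in_range = (idx >= 0) & (idx <= len(edges) - 2)

    rows = []
    for g in range(len(edges) - 1):
        mask = in_range & (idx == g)
        for col in columns:
            vals = cohort.loc[mask, col].dropna().to_numpy(dtype=float)
            if vals.size == 0:
                raise ValidationError(
                    f"age group [{edges[g]}, {edges[g + 1]}) y is empty for {col!r}")
            row = {"group": g, "age_lo": edges[g], "age_hi": edges[g + 1],
                   "column": col, "n": vals.size, "mean": float(vals.mean())}
            qs = np.quantile(vals, [p / 100 for p in PERCENTILES], method="linear")
            row.update({f"p{p}": float(q) for p, q in zip(PERCENTILES, qs)})
            rows.append(row)
    return GroupedReference(edges, pd.DataFrame(rows))


def step_discontinuity(grouped: GroupedReference, column: str,
                       percentile: int = 50) -> pd.DataFrame:
    """Jump size of the step reference at every internal group boundary."""
    if grouped.n_groups < 2:
        raise ValidationError("need at least 2 groups to measure discontinuities")
    vals = grouped.percentile(column, percentile)
    edges = grouped.group_edges
    return pd.DataFrame({
        "boundary_age_years": list(edges[1:-1]),
        "jump": [abs(vals[i + 1] - vals[i]) for i in range(len(vals) - 1)],
    })


def max_daily_increment(reference: ContinuousReference) -> float:
    """Closed-form bound on the smooth curve's change over any single day."""
    b, c = reference.b, reference.c
    hi = reference.age_domain[1]
    return abs(b * c) * np.exp(max(0.0, c * hi)) / 365.0


def overlay_report(grouped: GroupedReference, continuous: ContinuousReference,
                   column: str | None = None, step_years: float = 0.1) -> pd.DataFrame:
    """Grouped 10th–90th percentile band vs continuous 90% limits per age.

    The grouped column must denominate the same subset/measure as the
    continuous reference (matched by column name unless given explicitly).
    Adds boolean flags where the step band pokes outside the smooth band.
    """
    expected = f"{continuous.subset}_{continuous.measure}_{continuous.denominator}".lower()
    if column is None:
        matches = [c for c in grouped.columns if c.lower() == expected]
        if not matches:
            raise ValidationError(
                f"grouped table has no column matching {expected!r}; "
                f"available: {list(grouped.columns)}")
        column = matches[0]
    elif expected and column.lower() != expected:
        raise ValidationError(
            f"column {column!r} does not match the continuous reference "
            f"({expected!r})")

    lo, hi = continuous.age_domain
    ages = np.arange(lo, hi + step_years / 2, step_years)
    g10 = grouped.step_value(column, 10, ages)
    g90 = grouped.step_value(column, 90, ages)
    c_lo, c_hi = continuous.limits(ages, 0.90, extrapolate=True)
    return pd.DataFrame({
        "age_years": ages,
        "grouped_p10": g10,
        "grouped_p90": g90,
        "continuous_lower90": c_lo,
        "continuous_upper90": c_hi,
        "grouped_below_continuous": g10 < c_lo,
        "grouped_above_continuous": g90 > c_hi,
    })
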