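"""Matplotlib views of references and patient evaluations.

`plot_reference` draws one continuous reference the way clinical reference
charts are drawn: predicted curve (solid), 90% limits (dashed), 95% limits
(dotted), optionally the raw cohort points.  `plot_patient` marks a
patient's observed values as 'x' on a panel of such charts.
"""

from __future__ import annotations

import numpy as np

from .bands import ContinuousReference
from .calculator import PatientReport

__all__ = ["plot_reference", "plot_patient"]

_STYLE = {0.90: "--", 0.95: ":"}


def plot_reference(reference: ContinuousReference, ax=None, cohort=None,
                   age_col: str = "age_days"):
    """Draw one reference chart; returns the axes."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ages = np.linspace(*reference.age_domain, 400)
    if cohort is not None:
        col = f"{reference.subset}_{reference.measure}_{reference.denominator}"
        if col in cohort.columns:
            ax.plot(cohort[age_col] / 365.0, cohort[col], "k.", ms=3, alpha=0.5)
    ax.plot(ages, reference.predicted(ages), "-", color="tab:green", lw=2)
    for band in reference.bands:
        style = _STYLE.get(band.confidence, "-.")
        lo, hi = reference.limits(ages, band.confidence)
        ax.plot(ages, lo, style, color="tab:green", lw=1)
        ax.plot(ages, hi, style, color="tab:green", lw=1)
    unit = "%" if reference.measure_kind == "fraction_percent" else "cells/μl"
    ax.set_xlabel("age (years)")
    ax.set_ylabel(f"{reference.subset} {reference.measure} ({unit})")
    return ax


def plot_patient(report: PatientReport, references):
    """Panel of reference charts with the patient's values marked 'x'."""
    import matplotlib.pyplot as plt

    refs = {(r.subset, r.measure): r for r in references}
    evals = report.evaluations
    n = len(evals)
    ncols = 2 if n > 1 else 1
    nrows = int(np.ceil(n / ncols))
    fig, axes = plt.subplots(nrows, ncols, figsize=(5 * ncols, 3.5 * nrows),
                             squeeze=False)
    for ev, ax in zip(evals, axes.ravel()):
        ref = refs.get((ev.subset, ev.measure))
        if ref is not None:
            plot_reference(ref, ax=ax)
        color = "tab:red" if ev.abnormal else "tab:blue"
        ax.plot([ev.age_years], [ev.observed], "x", color=color, ms=10, mew=2)
    for ax in axes.ravel()[n:]:
        ax.set_visible(False)
    fig.tight_layout()
    return fig
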