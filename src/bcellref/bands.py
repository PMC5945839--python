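"""Distribution-free continuous reference intervals.

The reference band at confidence probability ``p`` is built from the fit
residuals alone: the empirical ``(1-p)/2`` and ``1-(1-p)/2`` quantiles of
``observed - predicted`` (linear interpolation between order statistics,
no distributional assumption) are added to the predicted curve at every
age.  The band therefore has age-constant width and inherits whatever
asymmetry the residual distribution carries — exactly what plain Gaussian
±z·σ limits would miss on skewed laboratory data.

Limits are clamped to the observable range after construction: fraction
limits to [0, 100] % and count lower limits to 0 cells/μl.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .exceptions import ConvergenceError, RangeError, ValidationError

__all__ = ["ReferenceBand", "ContinuousReference", "residual_quantile_offsets",
           "build_reference", "empirical_coverage", "DEFAULT_CONFIDENCES"]

DEFAULT_CONFIDENCES = (0.90, 0.95)
MEASURE_KINDS = ("fraction_percent", "absolute_count")


@dataclass(frozen=True)
class ReferenceBand:
    """Residual-quantile offsets for one confidence probability."""

    confidence: float
    lower_offset: float
    upper_offset: float

    def __post_init__(self) -> None:
        if not 0 < self.confidence <= 1:
            raise ValidationError("confidence must lie in (0, 1]")
        if self.lower_offset > self.upper_offset:
            raise ValidationError("lower_offset exceeds upper_offset")

    @property
    def width(self) -> float:
        return self.upper_offset - self.lower_offset


def residual_quantile_offsets(residuals, confidence: float) -> ReferenceBand:
    """Empirical equal-tail quantile offsets of the residuals.

    ``lower_offset`` is the quantile at ``(1-confidence)/2`` and
    ``upper_offset`` at ``1-(1-confidence)/2``, with linear interpolation
    between order statistics.  ``confidence=1`` gives (min, max).

    A warning is emitted below 20 residuals — the tail quantiles are then
    poorly determined.
    """
    r = np.asarray(residuals, dtype=float)
    if r.size == 0:
        raise ValidationError("cannot build a reference band from zero residuals")
    if not 0 < confidence <= 1:
        raise ValidationError(f"confidence must lie in (0, 1], got {confidence}")
    if r.size < 20:
        warnings.warn(f"only {r.size} residuals: tail quantiles are unstable",
                      stacklevel=2)
    alpha = (1.0 - confidence) / 2.0
    lo, hi = np.quantile(r, [alpha, 1.0 - alpha], method="linear")
    return ReferenceBand(confidence, float(lo), float(hi))


@dataclass
class ContinuousReference:
    """A publishable continuous reference: fitted curve + offset bands.

    Self-contained (carries the curve parameters, not the fitting data) so
    it round-trips through the reference-table format.  ``b_scaled``/``x0``
    keep prediction overflow-free; ``b = b_scaled * exp(-c*x0)``.
    """

    subset: str
    measure: str
    denominator: str
    a: float
    b_scaled: float
    c: float
    x0: float
    n: int
    ssr: float
    measure_kind: str
    bands: tuple[ReferenceBand, ...]
    age_domain: tuple[float, float] = (0.0, 18.0)

    def __post_init__(self) -> None:
        if self.measure_kind not in MEASURE_KINDS:
            raise ValidationError(f"unknown measure_kind {self.measure_kind!r}")
        self.bands = tuple(sorted(self.bands, key=lambda b: b.confidence))

    @property
    def b(self) -> float:
        with np.errstate(over="ignore"):
            return float(self.b_scaled * np.exp(-self.c * self.x0))

    @property
    def clamp_low(self) -> float:
        return 0.0

    @property
    def clamp_high(self) -> float:
        return 100.0 if self.measure_kind == "fraction_percent" else np.inf

    @property
    def confidences(self) -> tuple[float, ...]:
        return tuple(b.confidence for b in self.bands)

    def band(self, confidence: float) -> ReferenceBand:
        for b in self.bands:
            if np.isclose(b.confidence, confidence):
                return b
        raise ValidationError(f"no band at confidence {confidence}")

    def _check_domain(self, age, extrapolate: bool):
        age = np.asarray(age, dtype=float)
        lo, hi = self.age_domain
        if not extrapolate and (np.any(age < lo) or np.any(age > hi)):
            raise RangeError(f"age outside reference domain [{lo}, {hi}] years")
        return age

    def predicted(self, age_years, extrapolate: bool = False):
        """The fitted curve (band center), clamped to the observable range."""
        age = self._check_domain(age_years, extrapolate)
        y = self.a + self.b_scaled * np.exp(self.c * (age - self.x0))
        y = np.clip(y, self.clamp_low, self.clamp_high)
        return float(y) if np.isscalar(age_years) else y

    def limits(self, age_years, confidence: float, extrapolate: bool = False):
        """Clamped (lower, upper) reference limits at the given ages."""
        band = self.band(confidence)
        age = self._check_domain(age_years, extrapolate)
        center = self.a + self.b_scaled * np.exp(self.c * (age - self.x0))
        lo = np.clip(center + band.lower_offset, self.clamp_low, self.clamp_high)
        hi = np.clip(center + band.upper_offset, self.clamp_low, self.clamp_high)
        if np.isscalar(age_years):
            return float(lo), float(hi)
        return lo, hi

    def age_grid_table(self, step_years: float = 0.1):
        """Dense (age, predicted, limits…) table for plotting or LIS upload."""
        import pandas as pd

        lo, hi = self.age_domain
        ages = np.arange(lo, hi + step_years / 2, step_years)
        out = {"age_years": ages, "predicted": self.predicted(ages)}
        for band in self.bands:
            lo_, hi_ = self.limits(ages, band.confidence)
            pct = int(round(band.confidence * 100))
            out[f"lower{pct}"] = lo_
            out[f"upper{pct}"] = hi_
        return pd.DataFrame(out)


def build_reference(fit_results, measure_kind: str,
                    confidences=DEFAULT_CONFIDENCES, subset: str = "",
                    measure: str = "", denominator: str = "") -> ContinuousReference:
    """Attach residual-quantile bands to a converged fit.

    Raises
    ------
    ConvergenceError
        If the fit did not converge — its residuals are not trustworthy.
    """
    if not fit_results.converged:
        raise ConvergenceError(
            "refusing to build a reference from a non-converged fit "
            f"(subset={fit_results.model.subset_label!r})")
    bands = tuple(residual_quantile_offsets(fit_results.resid, p) for p in confidences)
    return ContinuousReference(
        subset=subset or fit_results.model.subset_label,
        measure=measure or fit_results.model.measure_label,
        denominator=denominator,
        a=fit_results.a, b_scaled=fit_results.b_scaled, c=fit_results.c,
        x0=fit_results.x0, n=fit_results.nobs, ssr=fit_results.ssr,
        measure_kind=measure_kind, bands=bands)


def empirical_coverage(reference: ContinuousReference, ages_years, values) -> dict[float, float]:
    """Fraction of (age, value) pairs inside each band at their own age.

    Intervals are closed; the test subjects must be independent of the
    fitting cohort for the result to estimate true coverage.
    """
    ages = np.asarray(ages_years, dtype=float)
    vals = np.asarray(values, dtype=float)
    if ages.size == 0:
        raise ValidationError("empty test set")
    # absolute slack so a numerically-zero-residual fit counts its own
    # points as inside (closed intervals up to float round-off)
    tol = 1e-7 * (np.max(np.abs(vals)) + 1.0)
    out = {}
    for band in reference.bands:
        lo, hi = reference.limits(ages, band.confidence, extrapolate=True)
        inside = (vals >= lo - tol) & (vals <= hi + tol)
        out[band.confidence] = float(inside.mean())
    return out
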