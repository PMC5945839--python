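"""Parametric age trajectories and their noise models.

A trajectory describes the expected value of one measurement (a subset
fraction in % or an absolute count in cells/μl) as a function of age in
years.  Two functional forms are supported:

* ``exponential`` — ``a + b * exp(c * age)``, the three-parameter curve
  that the fitting side of the package estimates.  With ``c < 0`` the curve
  relaxes monotonically from ``a + b`` at birth toward the asymptote ``a``.
* ``biexponential`` — ``a + b * exp(c * age) + b2 * exp(c2 * age)``, a
  generator-only extension whose two components of opposite sign produce the
  peaked absolute-count curves seen for memory subsets in early childhood.
  It is never fitted.

Noise is additive, applied after the deterministic curve, and can be plain
Gaussian or a skewed shifted-gamma shape (long tail in the direction of the
sign of ``noise_skew``).  A proportional component makes the scatter grow
with the curve level, which is how real cell-count data behave.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import ConfigError

__all__ = ["TrajectorySpec", "evaluate_trajectory", "sample_noise"]


@dataclass(frozen=True)
class TrajectorySpec:
    """One measurement's generative curve plus its noise model.

    Parameters
    ----------
    kind : {"exponential", "biexponential"}
        Functional form; ``b2``/``c2`` are only allowed for biexponential.
    a, b : float
        Asymptote and amplitude, in response units (% or cells/μl).
    c : float
        Rate per year; negative values decay toward the asymptote.
    b2, c2 : float, optional
        Second-component amplitude and rate (biexponential only).
    noise_kind : {"gaussian", "skewed"}
    noise_scale : float
        Constant noise standard deviation, response units.
    noise_skew : float
        Skewness of the shifted-gamma noise; sign sets the long tail's
        direction.  Ignored for Gaussian noise.
    noise_scale_prop : float
        Proportional noise component: the total standard deviation at age x
        is ``noise_scale + noise_scale_prop * |curve(x)|``.
    clamp : (float, float)
        Observable range; applied after noise.  ``(0, 100)`` for fractions,
        ``(0, inf)`` for counts.
    """

    kind: str = "exponential"
    a: float = 0.0
    b: float = 0.0
    c: float = 0.0
    b2: float | None = None
    c2: float | None = None
    noise_kind: str = "gaussian"
    noise_scale: float = 0.0
    noise_skew: float = 1.0
    noise_scale_prop: float = 0.0
    clamp: tuple[float, float] = (0.0, float("inf"))

    def __post_init__(self) -> None:
        if self.kind not in ("exponential", "biexponential"):
            raise ConfigError(f"kind: unknown trajectory kind {self.kind!r}")
        if self.kind == "exponential" and (self.b2 is not None or self.c2 is not None):
            raise ConfigError("b2/c2: must be unset for kind='exponential'")
        if self.kind == "biexponential" and (self.b2 is None or self.c2 is None):
            raise ConfigError("b2/c2: required for kind='biexponential'")
        if self.noise_kind not in ("gaussian", "skewed"):
            raise ConfigError(f"noise_kind: unknown noise kind {self.noise_kind!r}")
        if self.noise_scale < 0:
            raise ConfigError("noise_scale: must be >= 0")
        if self.noise_scale_prop < 0:
            raise ConfigError("noise_scale_prop: must be >= 0")
        if self.noise_kind == "skewed" and self.noise_skew == 0:
            raise ConfigError("noise_skew: must be nonzero for skewed noise")
        if not self.clamp[0] <= self.clamp[1]:
            raise ConfigError("clamp: lower bound exceeds upper bound")


def evaluate_trajectory(spec: TrajectorySpec, age_years) -> np.ndarray | float:
    """Noise-free trajectory value(s) at ``age_years``, clamped to range.

    Raises
    ------
    ValueError
        If any age is negative.
    """
    age = np.asarray(age_years, dtype=float)
    if np.any(age < 0):
        raise ValueError("age_years must be non-negative")
    y = spec.a + spec.b * np.exp(spec.c * age)
    if spec.kind == "biexponential":
        y = y + spec.b2 * np.exp(spec.c2 * age)
    y = np.clip(y, spec.clamp[0], spec.clamp[1])
    return float(y) if np.isscalar(age_years) else y


def sample_noise(spec: TrajectorySpec, curve_values: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Draw one additive noise value per curve value.

    Skewed noise is a shifted gamma scaled to zero mean and unit variance
    before multiplication by the age-dependent scale: with shape
    ``k = 4 / skew**2`` the standardized gamma has skewness ``|skew|``; its
    sign flips the tail direction.
    """
    curve_values = np.asarray(curve_values, dtype=float)
    scale = spec.noise_scale + spec.noise_scale_prop * np.abs(curve_values)
    if np.all(scale == 0):
        return np.zeros_like(curve_values)
    if spec.noise_kind == "gaussian":
        z = rng.standard_normal(curve_values.shape)
    else:
        k = 4.0 / spec.noise_skew**2
        g = rng.gamma(shape=k, scale=1.0, size=curve_values.shape)
        z = (g - k) / np.sqrt(k)
        if spec.noise_skew < 0:
            z = -z
    return scale * z
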