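"""Synthetic pediatric cohort generator.

Emulates a cross-sectional immunophenotyping study of healthy children aged
2 days to 18 years: per subject an age, sex, screening outcome and a B cell
subset panel — relative frequencies (% of CD19+ or CD20+ B cells) and
dual-platform absolute counts (cells/μl) for total, naïve, non-switched
memory, switched memory and (summed) memory B cells.

The generative trajectories reproduce the qualitative picture of pediatric
B cell development: a naïve fraction near 98% at birth declining over the
first decade, memory fractions rising over the first five years then
stable, and total B cell counts falling from roughly 1,800 cells/μl at
birth.  Fractions are primary; subset absolute counts are derived as
``total × fraction / 100``, so the peaked memory-count curve of early
childhood emerges as the product of a falling total and a rising fraction.
Noise is skewed and partly proportional by default, because real count data
are heteroscedastic and non-Gaussian — which is exactly the regime the
distribution-free reference bands must handle.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .exceptions import ConfigError
from .trajectories import TrajectorySpec, evaluate_trajectory, sample_noise

__all__ = ["CohortConfig", "default_trajectories", "generate_cohort", "SUBSETS", "MEASUREMENT_COLUMNS"]

SUBSETS = ("totalB", "naive", "nonswitched", "switched", "memory")
DENOMINATORS = ("cd19", "cd20")

#: All per-subject measurement columns, in canonical table order.
MEASUREMENT_COLUMNS = (
    ["lymphocytes_abs"]
    + [f"{s}_{m}_{d}" for s in SUBSETS for m in ("pct", "abs") for d in DENOMINATORS]
    + ["cd20_coexpr_pct"]
)

SCREENING_REASONS = ("abnormal", "missing_labs", "insufficient_material")


def default_trajectories() -> dict[tuple[str, str], TrajectorySpec]:
    """Generative curves for the primary measurements.

    Anchors: naïve fraction 98% of B cells and total count 1,800 cells/μl at
    birth; memory fractions ~0.7–0.8% at birth saturating by age 5; adult-like
    levels by late adolescence.  Counts carry right-skewed, proportional
    noise; the naïve fraction carries left-skewed noise (its ceiling is
    biological, its tail points down).
    """
    return {
        ("lymphocytes", "abs"): TrajectorySpec(
            a=2300, b=3200, c=-0.35, noise_kind="skewed", noise_skew=1.0,
            noise_scale_prop=0.10, clamp=(0, np.inf)),
        ("totalB", "abs"): TrajectorySpec(
            a=250, b=1550, c=-0.45, noise_kind="skewed", noise_skew=1.0,
            noise_scale_prop=0.22, clamp=(0, np.inf)),
        ("naive", "pct"): TrajectorySpec(
            a=62, b=36, c=-0.30, noise_kind="skewed", noise_skew=-1.0,
            noise_scale=3.5, clamp=(0, 100)),
        ("nonswitched", "pct"): TrajectorySpec(
            a=6.5, b=-6.1, c=-0.50, noise_kind="skewed", noise_skew=1.0,
            noise_scale=1.0, noise_scale_prop=0.10, clamp=(0, 100)),
        ("switched", "pct"): TrajectorySpec(
            a=10.5, b=-10.2, c=-0.45, noise_kind="skewed", noise_skew=1.0,
            noise_scale=1.0, noise_scale_prop=0.10, clamp=(0, 100)),
    }


@dataclass(frozen=True)
class CohortConfig:
    """Everything needed to generate one cohort deterministically.

    ``screening_fail_rates`` default to the enrollment experience of a
    227-child single-center study: 16/227 abnormal counts or positive CRP,
    21/227 missing laboratory parameters, 6/227 insufficient material.
    ``cd20_coexpression_rate`` defaults to 0.99 (fraction of CD19+ B cells
    co-expressing CD20); per-subject rates scatter around it with standard
    deviation ``cd20_coexpression_sd``.
    """

    n_subjects: int = 184
    age_min_days: int = 2
    age_max_days: int = 6570  # 18 years at 365 d/y
    age_distribution: str = "log_uniform"
    seed: int = 1234
    trajectories: dict[tuple[str, str], TrajectorySpec] = field(default_factory=default_trajectories)
    cd20_coexpression_rate: float = 0.99
    cd20_coexpression_sd: float = 0.005
    marker_shift_naive: float = 2.0       # naïve % points higher under CD20
    marker_shift_switched: float = -2.0   # switched % points lower under CD20
    marker_jitter_sd: float = 0.5         # extra scatter on CD20-denominated fractions
    female_fraction: float = 64 / 174
    screening_fail_rates: dict[str, float] = field(
        default_factory=lambda: {"abnormal": 16 / 227, "missing_labs": 21 / 227,
                                 "insufficient_material": 6 / 227})

    def __post_init__(self) -> None:
        if self.n_subjects <= 0:
            raise ConfigError("n_subjects: must be a positive integer")
        if self.age_min_days < 0:
            raise ConfigError("age_min_days: must be >= 0")
        if self.age_min_days >= self.age_max_days:
            raise ConfigError("age_min_days: must be < age_max_days")
        if self.age_distribution not in ("uniform", "log_uniform"):
            raise ConfigError(f"age_distribution: unknown value {self.age_distribution!r}")
        if not 0 <= self.cd20_coexpression_rate <= 1:
            raise ConfigError("cd20_coexpression_rate: must lie in [0, 1]")
        if self.cd20_coexpression_sd < 0:
            raise ConfigError("cd20_coexpression_sd: must be >= 0")
        if not 0 <= self.female_fraction <= 1:
            raise ConfigError("female_fraction: must lie in [0, 1]")
        for reason, p in self.screening_fail_rates.items():
            if reason not in SCREENING_REASONS:
                raise ConfigError(f"screening_fail_rates: unknown reason {reason!r}")
            if not 0 <= p <= 1:
                raise ConfigError(f"screening_fail_rates[{reason!r}]: must lie in [0, 1]")
        for key in self.trajectories:
            if key not in {("lymphocytes", "abs"), ("totalB", "abs"),
                           ("naive", "pct"), ("nonswitched", "pct"), ("switched", "pct"),
                           ("nonswitched", "abs"), ("switched", "abs")}:
                raise ConfigError(f"trajectories: unsupported key {key!r}")

    def noiseless(self) -> "CohortConfig":
        """Copy with every stochastic spread set to zero (curves only)."""
        quiet = {k: replace(t, noise_scale=0.0, noise_scale_prop=0.0)
                 for k, t in self.trajectories.items()}
        return replace(self, trajectories=quiet, cd20_coexpression_sd=0.0,
                       marker_jitter_sd=0.0)


def _sample_ages(config: CohortConfig, rng: np.random.Generator) -> np.ndarray:
    lo, hi = config.age_min_days, config.age_max_days
    if config.age_distribution == "uniform":
        days = rng.integers(lo, hi + 1, size=config.n_subjects)
    else:
        # log-uniform over days: over-represents infancy, where the
        # trajectories bend fastest
        u = rng.uniform(np.log(max(lo, 1)), np.log(hi), size=config.n_subjects)
        days = np.clip(np.rint(np.exp(u)).astype(int), lo, hi)
    return days.astype(int)


def _beta_params(mean: float, sd: float) -> tuple[float, float]:
    """Shape parameters of a Beta distribution with given mean and sd."""
    v = sd**2
    nu = mean * (1 - mean) / v - 1
    if nu <= 0:
        raise ConfigError("cd20_coexpression_sd: too large for the given rate")
    return mean * nu, (1 - mean) * nu


def generate_cohort(config: CohortConfig) -> pd.DataFrame:
    """Generate one cohort as a table with one row per subject.

    Returns a DataFrame with screening fields and the full measurement panel
    (``MEASUREMENT_COLUMNS``); panels of subjects flagged
    ``material_insufficient`` are left empty (NaN), as no cytometry was run
    for them.  Identical config (including its seed) yields an identical
    table.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_subjects
    ndigits = max(4, len(str(n)))
    ids = [f"S{i:0{ndigits}d}" for i in range(1, n + 1)]
    age_days = _sample_ages(config, rng)
    age_years = age_days / 365.0
    sex = np.where(rng.uniform(size=n) < config.female_fraction, "female", "male")

    rates = config.screening_fail_rates
    abnormal = rng.uniform(size=n) < rates.get("abnormal", 0.0)
    missing = rng.uniform(size=n) < rates.get("missing_labs", 0.0)
    insufficient = rng.uniform(size=n) < rates.get("insufficient_material", 0.0)

    traj = config.trajectories

    def draw(key: tuple[str, str]) -> np.ndarray:
        spec = traj[key]
        curve = evaluate_trajectory(spec, age_years)
        y = curve + sample_noise(spec, curve, rng)
        return np.clip(y, spec.clamp[0], spec.clamp[1])

    lymph = draw(("lymphocytes", "abs"))
    totalB19 = draw(("totalB", "abs"))
    naive = draw(("naive", "pct"))
    nonsw = draw(("nonswitched", "pct"))
    switched = draw(("switched", "pct"))

    # Optional: a memory subset's absolute count may be generated directly
    # (e.g. a peaked biexponential curve); its fraction is then derived from
    # the total so the panel stays internally consistent.
    for name, arr in (("nonswitched", nonsw), ("switched", switched)):
        if (name, "abs") in traj:
            abs_primary = draw((name, "abs"))
            with np.errstate(divide="ignore", invalid="ignore"):
                frac = np.where(totalB19 > 0, abs_primary / totalB19 * 100.0, 0.0)
            arr[:] = np.clip(frac, 0.0, 100.0)

    # keep naive + non-switched + switched within 100% of B cells
    total_frac = naive + nonsw + switched
    over = total_frac > 100.0
    if np.any(over):
        shrink = 100.0 / total_frac[over]
        naive[over] *= shrink
        nonsw[over] *= shrink
        switched[over] *= shrink
    memory = nonsw + switched

    # CD20 side: co-expression of CD20 on CD19+ B cells, plus the small,
    # systematic denominator shifts seen between the two markers
    if config.cd20_coexpression_sd > 0:
        a_, b_ = _beta_params(config.cd20_coexpression_rate, config.cd20_coexpression_sd)
        coexpr = rng.beta(a_, b_, size=n)
    else:
        coexpr = np.full(n, config.cd20_coexpression_rate)
    cd20_only = totalB19 * rng.uniform(0.0, 0.01, size=n)
    totalB20 = totalB19 * coexpr + cd20_only

    jitter = config.marker_jitter_sd

    def shift(frac: np.ndarray, delta: float) -> np.ndarray:
        out = frac + delta + (rng.normal(0.0, jitter, size=n) if jitter > 0 else 0.0)
        return np.clip(out, 0.0, 100.0)

    naive20 = shift(naive, config.marker_shift_naive)
    nonsw20 = shift(nonsw, 0.0)
    switched20 = shift(switched, config.marker_shift_switched)
    memory20 = nonsw20 + switched20

    with np.errstate(invalid="ignore"):
        cols: dict[str, np.ndarray] = {
            "lymphocytes_abs": lymph,
            "totalB_pct_cd19": np.clip(totalB19 / lymph * 100.0, 0, 100),
            "totalB_abs_cd19": totalB19,
            "totalB_pct_cd20": np.clip(totalB20 / lymph * 100.0, 0, 100),
            "totalB_abs_cd20": totalB20,
        }
    for name, f19, f20 in (("naive", naive, naive20),
                           ("nonswitched", nonsw, nonsw20),
                           ("switched", switched, switched20),
                           ("memory", memory, memory20)):
        cols[f"{name}_pct_cd19"] = f19
        cols[f"{name}_abs_cd19"] = totalB19 * f19 / 100.0
        cols[f"{name}_pct_cd20"] = f20
        cols[f"{name}_abs_cd20"] = totalB20 * f20 / 100.0
    cols["cd20_coexpr_pct"] = coexpr * 100.0

    df = pd.DataFrame({
        "subject_id": ids,
        "age_days": age_days,
        "sex": sex,
        "crp_positive_or_abnormal_counts": abnormal.astype(int),
        "labs_missing": missing.astype(int),
        "material_insufficient": insufficient.astype(int),
    })
    for name in MEASUREMENT_COLUMNS:
        df[name] = cols[name]
    df.loc[insufficient, MEASUREMENT_COLUMNS] = np.nan
    return df
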