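import numpy as np
import pytest

from bcellref import CohortConfig, generate_cohort
from bcellref.trajectories import TrajectorySpec, evaluate_trajectory, sample_noise


@pytest.fixture(scope="session")
def default_cohort():
    """n=1000 default-configuration cohort, shared across tests."""
    return generate_cohort(CohortConfig(n_subjects=1000, seed=7))


@pytest.fixture(scope="session")
def included_cohort(default_cohort):
    df = default_cohort
    clean = ((df["crp_positive_or_abnormal_counts"] == 0)
             & (df["labs_missing"] == 0) & (df["material_insufficient"] == 0))
    return df[clean]


def sample_trajectory_cohort(spec: TrajectorySpec, n: int, seed: int):
    """(ages, values) drawn from one trajectory with log-uniform ages."""
    rng = np.random.default_rng(seed)
    ages = np.exp(rng.uniform(np.log(2), np.log(6570), n)) / 365.0
    curve = evaluate_trajectory(spec, ages)
    values = np.clip(curve + sample_noise(spec, curve, rng), *spec.clamp)
    return ages, values


@pytest.fixture(scope="session")
def skewed_band_setup():
    """Fitting cohort + independent test set from one skewed-noise process."""
    spec = TrajectorySpec(a=10, b=88, c=-0.5, noise_kind="skewed",
                          noise_scale=6, noise_skew=1.0, clamp=(0, 100))
    fit_xy = sample_trajectory_cohort(spec, 500, seed=11)
    test_xy = sample_trajectory_cohort(spec, 10_000, seed=12)
    return spec, fit_xy, test_xy
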