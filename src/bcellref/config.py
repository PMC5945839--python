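"""Structured configuration for the end-to-end pipeline.

A config is a YAML mapping with an optional ``cohort`` section (fields of
:class:`~bcellref.cohort.CohortConfig`, with trajectories keyed
``"<subset>.<measure>"``) and pipeline-level options.  Every field is
addressable by name; unknown fields raise a :class:`ConfigError` naming
them.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

from .cohort import CohortConfig, default_trajectories
from .exceptions import ConfigError
from .trajectories import TrajectorySpec

__all__ = ["PipelineConfig", "load_config"]


@dataclass(frozen=True)
class PipelineConfig:
    cohort: CohortConfig = field(default_factory=CohortConfig)
    confidences: tuple[float, ...] = (0.90, 0.95)
    denominators: tuple[str, ...] = ("cd19", "cd20")
    subsets: tuple[str, ...] = ("totalB", "naive", "nonswitched", "switched", "memory")
    measures: tuple[str, ...] = ("pct", "abs")
    coverage_test_n: int = 2000

    def __post_init__(self) -> None:
        for p in self.confidences:
            if not 0 < p <= 1:
                raise ConfigError(f"confidences: {p} outside (0, 1]")
        if self.coverage_test_n <= 0:
            raise ConfigError("coverage_test_n: must be positive")


def _parse_trajectories(raw: dict) -> dict[tuple[str, str], TrajectorySpec]:
    out = dict(default_trajectories())
    for key, spec in raw.items():
        try:
            subset, measure = key.split(".")
        except ValueError:
            raise ConfigError(
                f"trajectories: key {key!r} must look like '<subset>.<measure>'")
        if "clamp" in spec:
            spec = {**spec, "clamp": tuple(spec["clamp"])}
        out[(subset, measure)] = TrajectorySpec(**spec)
    return out


def load_config(path=None, overrides: dict | None = None) -> PipelineConfig:
    """Load a pipeline config from YAML, applying defaults for absent fields."""
    raw: dict = {}
    if path is not None:
        raw = yaml.safe_load(Path(path).read_text()) or {}
    if overrides:
        raw = {**raw, **overrides}

    cohort_raw = dict(raw.pop("cohort", {}))
    if "trajectories" in cohort_raw:
        cohort_raw["trajectories"] = _parse_trajectories(cohort_raw["trajectories"])
    cohort_fields = {f.name for f in fields(CohortConfig)}
    unknown = set(cohort_raw) - cohort_fields
    if unknown:
        raise ConfigError(f"cohort: unknown fields {sorted(unknown)}")
    try:
        cohort = CohortConfig(**cohort_raw)
    except TypeError as exc:
        raise ConfigError(f"cohort: {exc}") from exc

    pipe_fields = {f.name for f in fields(PipelineConfig)} - {"cohort"}
    unknown = set(raw) - pipe_fields
    if unknown:
        raise ConfigError(f"unknown config fields {sorted(unknown)}")
    for tup in ("confidences", "denominators", "subsets", "measures"):
        if tup in raw:
            raw[tup] = tuple(raw[tup])
    return PipelineConfig(cohort=cohort, **raw)
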