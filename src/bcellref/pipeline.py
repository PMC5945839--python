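"""End-to-end pipeline: simulate → screen → fit → reference → validate.

Every stage logs its input/output row counts and writes its artifact
before the next stage starts, so a failing stage aborts with its name
while all earlier artifacts persist on disk.  All randomness flows from
the single cohort seed, making reruns byte-identical.
"""

from __future__ import annotations

import logging
from dataclasses import replace
from pathlib import Path

import pandas as pd

from .bands import build_reference, empirical_coverage
from .calculator import compare_markers
from .cohort import generate_cohort
from .config import PipelineConfig
from .exceptions import BCellRefError, InsufficientDataError
from .io import write_cohort, write_reference
from .model import ExponentialAgeModel
from .screening import screen_cohort

logger = logging.getLogger("bcellref")

__all__ = ["run_pipeline", "fit_cohort_references"]


def _derived_seed(seed: int, stream: int) -> int:
    # distinct, reproducible sub-seed per pipeline stream, kept below 2^31
    return (seed * 2654435761 + stream) % (2**31 - 1)


def fit_cohort_references(cohort: pd.DataFrame, config: PipelineConfig):
    """Fit every requested (subset, measure, denominator) on a cohort.

    Returns ``(fit_rows, references)``: a fit-table row per target and the
    corresponding :class:`ContinuousReference` objects.  Targets that
    cannot be fitted (e.g. a column with too few values) are recorded in
    the fit table with ``converged`` empty and skipped in the references.
    """
    fit_rows, references = [], []
    for subset in config.subsets:
        for measure in config.measures:
            for denom in config.denominators:
                col = f"{subset}_{measure}_{denom}"
                if col not in cohort.columns:
                    continue
                try:
                    res = ExponentialAgeModel.from_dataframe(
                        cohort, col, subset_label=subset, measure_label=measure).fit()
                except InsufficientDataError as exc:
                    logger.warning("fit %s skipped: %s", col, exc)
                    fit_rows.append({"subset": subset, "measure": measure,
                                     "denominator": denom, "error": str(exc)})
                    continue
                fit_rows.append({
                    "subset": subset, "measure": measure, "denominator": denom,
                    "a": res.a, "b": res.b, "c": res.c, "ssr": res.ssr,
                    "n": res.nobs, "converged": res.converged})
                kind = "fraction_percent" if measure == "pct" else "absolute_count"
                references.append(build_reference(
                    res, kind, config.confidences, subset=subset,
                    measure=measure, denominator=denom))
    return pd.DataFrame(fit_rows), references


def run_pipeline(config: PipelineConfig, outdir) -> dict[str, Path]:
    """Run the full pipeline, writing all artifacts under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}

    def stage(name):
        logger.info("stage %s: starting", name)
        return name

    current = stage("simulate")
    try:
        cohort = generate_cohort(config.cohort)
        artifacts["cohort"] = outdir / "cohort.csv"
        write_cohort(artifacts["cohort"], cohort)
        logger.info("stage simulate: %d subjects", len(cohort))

        current = stage("screen")
        report = screen_cohort(cohort)
        artifacts["screening_report"] = outdir / "screening_report.csv"
        report.to_frame().to_csv(artifacts["screening_report"], index=False)
        included = cohort[cohort["subject_id"].isin(set(report.included_ids))]
        artifacts["included"] = outdir / "included.csv"
        write_cohort(artifacts["included"], included)
        logger.info("stage screen: %d assessed -> %d included",
                    report.n_assessed, report.n_included)

        current = stage("fit")
        fit_table, references = fit_cohort_references(included, config)
        artifacts["fits"] = outdir / "fits.csv"
        fit_table.to_csv(artifacts["fits"], index=False, float_format="%.12g")
        logger.info("stage fit: %d fits", len(fit_table))

        current = stage("reference")
        artifacts["reference"] = outdir / "reference.csv"
        write_reference(artifacts["reference"], references)
        grid = pd.concat(
            [r.age_grid_table().assign(subset=r.subset, measure=r.measure,
                                       denominator=r.denominator)
             for r in references], ignore_index=True)
        artifacts["age_grid"] = outdir / "reference_age_grid.csv"
        grid.to_csv(artifacts["age_grid"], index=False, float_format="%.12g")
        logger.info("stage reference: %d references", len(references))

        current = stage("compare")
        artifacts["marker_comparison"] = outdir / "marker_comparison.csv"
        compare_markers(included).to_frame().to_csv(
            artifacts["marker_comparison"], index=False, float_format="%.12g")

        current = stage("coverage")
        test_cfg = replace(config.cohort, n_subjects=config.coverage_test_n,
                           seed=_derived_seed(config.cohort.seed, 1))
        test = generate_cohort(test_cfg)
        test = test[test["material_insufficient"] == 0]
        rows = []
        for ref in references:
            col = f"{ref.subset}_{ref.measure}_{ref.denominator}"
            sub = test[["age_days", col]].dropna()
            cov = empirical_coverage(ref, sub["age_days"] / 365.0, sub[col])
            for conf, frac in sorted(cov.items()):
                rows.append({"subset": ref.subset, "measure": ref.measure,
                             "denominator": ref.denominator,
                             "confidence": conf, "coverage": frac,
                             "n_test": len(sub)})
        artifacts["coverage"] = outdir / "coverage.csv"
        pd.DataFrame(rows).to_csv(artifacts["coverage"], index=False,
                                  float_format="%.12g")
        logger.info("stage coverage: %d rows", len(rows))
    except BCellRefError as exc:
        raise BCellRefError(f"pipeline stage {current!r} failed: {exc}") from exc

    return artifacts
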