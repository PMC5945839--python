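"""Delimited-text table formats: cohort tables and reference tables.

Everything is plain delimited text (comma by default, tab accepted) so
reference tables can be audited line-by-line before laboratory sign-off.
Floats are written with 12 significant digits, which makes the
write→read→write cycle byte-identical.
"""

from __future__ import annotations

import math
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .bands import ContinuousReference, ReferenceBand
from .exceptions import ValidationError

__all__ = ["read_cohort", "write_cohort", "read_reference", "write_reference"]

REQUIRED_COHORT_COLUMNS = (
    "subject_id", "age_days", "sex", "crp_positive_or_abnormal_counts",
    "labs_missing", "material_insufficient")
BOOL_COLUMNS = ("crp_positive_or_abnormal_counts", "labs_missing",
                "material_insufficient")

_FLOAT_FMT = "%.12g"


def _detect_sep(path: Path) -> str:
    with open(path) as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


def _check_header(path: Path, sep: str) -> list[str]:
    with open(path) as fh:
        names = fh.readline().rstrip("\n").split(sep)
    dupes = sorted({n for n in names if names.count(n) > 1})
    if dupes:
        raise ValidationError(f"{path}: duplicate header columns {dupes}")
    return names


def read_cohort(path) -> pd.DataFrame:
    """Read and validate a cohort table.

    Raises :class:`ValidationError` naming the offending column, row or
    subject for missing required columns, unparseable rows, non-finite
    numerics, or negative ages.  Unknown columns are kept, with a warning.
    """
    path = Path(path)
    sep = _detect_sep(path)
    names = _check_header(path, sep)
    missing = [c for c in REQUIRED_COHORT_COLUMNS if c not in names]
    if missing:
        raise ValidationError(f"{path}: cohort table lacks required columns {missing}")
    try:
        df = pd.read_csv(path, sep=sep, dtype={"subject_id": str})
    except (pd.errors.ParserError, ValueError) as exc:
        raise ValidationError(f"{path}: malformed cohort table: {exc}") from exc

    known_extra = {"lymphocytes_abs", "cd20_coexpr_pct"}
    from .cohort import MEASUREMENT_COLUMNS
    known = set(REQUIRED_COHORT_COLUMNS) | set(MEASUREMENT_COLUMNS) | known_extra
    unknown = [c for c in df.columns if c not in known]
    if unknown:
        warnings.warn(f"{path}: unknown columns preserved: {unknown}", stacklevel=2)

    for col in ("age_days",) + tuple(BOOL_COLUMNS):
        bad = df[pd.to_numeric(df[col], errors="coerce").isna()]
        if len(bad):
            raise ValidationError(
                f"{path}: column {col!r} not numeric for subjects "
                f"{bad['subject_id'].tolist()[:5]}")
    neg = df[df["age_days"] < 0]
    if len(neg):
        raise ValidationError(
            f"{path}: negative age_days for subjects {neg['subject_id'].tolist()}")
    for col in BOOL_COLUMNS:
        if not df[col].isin([0, 1]).all():
            raise ValidationError(f"{path}: column {col!r} must be encoded 0/1")
    num = df.select_dtypes(include=[float, int])
    inf_cols = [c for c in num.columns if np.isinf(num[c]).any()]
    if inf_cols:
        raise ValidationError(f"{path}: non-finite values in columns {inf_cols}")
    return df


def write_cohort(path, cohort: pd.DataFrame, sep: str = ",") -> None:
    cohort.to_csv(path, sep=sep, index=False, float_format=_FLOAT_FMT)


def write_reference(path, references, sep: str = ",") -> None:
    """Serialize continuous references, one row per (subset, measure, denominator).

    Band offsets appear as ``lower<pct>``/``upper<pct>`` column pairs; the
    clamp policy and age domain are explicit so a reference table is fully
    self-describing.
    """
    references = list(references)
    confidences = sorted({b.confidence for r in references for b in r.bands})
    cols = ["subset", "measure", "denominator", "measure_kind",
            "a", "b_scaled", "c", "x0", "n", "ssr"]
    for p in confidences:
        pct = int(round(p * 100))
        cols += [f"lower{pct}", f"upper{pct}"]
    cols += ["clamp_low", "clamp_high", "age_min", "age_max"]

    lines = [sep.join(cols)]
    for r in references:
        row = {"subset": r.subset, "measure": r.measure,
               "denominator": r.denominator, "measure_kind": r.measure_kind,
               "a": r.a, "b_scaled": r.b_scaled, "c": r.c, "x0": r.x0,
               "n": r.n, "ssr": r.ssr,
               "clamp_low": r.clamp_low, "clamp_high": r.clamp_high,
               "age_min": r.age_domain[0], "age_max": r.age_domain[1]}
        for band in r.bands:
            pct = int(round(band.confidence * 100))
            row[f"lower{pct}"] = band.lower_offset
            row[f"upper{pct}"] = band.upper_offset
        cells = []
        for c in cols:
            v = row.get(c, "")
            if isinstance(v, float):
                cells.append(_FLOAT_FMT % v)
            else:
                cells.append(str(v))
        lines.append(sep.join(cells))
    Path(path).write_text("\n".join(lines) + "\n")


def read_reference(path) -> list[ContinuousReference]:
    """Read a reference table back into :class:`ContinuousReference` objects."""
    path = Path(path)
    sep = _detect_sep(path)
    names = _check_header(path, sep)
    for col in ("subset", "measure", "a", "b_scaled", "c", "n"):
        if col not in names:
            raise ValidationError(f"{path}: reference table lacks column {col!r}")
    df = pd.read_csv(path, sep=sep)
    band_pcts = sorted(int(c[len("lower"):]) for c in df.columns
                       if c.startswith("lower") and c[len("lower"):].isdigit())
    refs = []
    for i, row in df.iterrows():
        bands = []
        for pct in band_pcts:
            lo, hi = row[f"lower{pct}"], row[f"upper{pct}"]
            if math.isnan(lo) or math.isnan(hi):
                continue
            bands.append(ReferenceBand(pct / 100.0, float(lo), float(hi)))
        if not bands:
            raise ValidationError(f"{path}: row {i} has no reference bands")
        refs.append(ContinuousReference(
            subset=str(row["subset"]), measure=str(row["measure"]),
            denominator="" if pd.isna(row.get("denominator")) else str(row["denominator"]),
            a=float(row["a"]), b_scaled=float(row["b_scaled"]),
            c=float(row["c"]), x0=float(row.get("x0", 0.0)),
            n=int(row["n"]), ssr=float(row.get("ssr", float("nan"))),
            measure_kind=str(row["measure_kind"]), bands=tuple(bands),
            age_domain=(float(row.get("age_min", 0.0)), float(row.get("age_max", 18.0))),
        ))
    return refs
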