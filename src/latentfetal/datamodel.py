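"""Cohort data schema, I/O, validation and complete-case filtering.

The analysis table holds one row per live-born singleton.  Columns fall into
four groups:

* maternal determinants — ``age`` (years), ``height_m`` (metres),
  ``prepreg_weight_kg`` (kilograms) and the binary flags ``elevated_bp``,
  ``primiparity``, ``smoking``, ``malaria_pregnancy``, ``insufficient_gwg``;
* optional antenatal ultrasound biometry z-scores for gestational age —
  ``hc_z`` (head circumference), ``ac_z`` (abdominal circumference),
  ``fl_z`` (femur length), observed in a subsample only;
* birth-size indicators — ``bwz`` and ``blz``, weight and length z-scores
  for gestational age and sex;
* binary perinatal outcomes — ``preterm``, ``reanimation``, ``formula_rx``,
  ``stay_gt3d``.

Binary columns are coded 0/1 with 1 = condition present.  Heights are stored
in metres and converted to centimetres only when the model design matrix is
assembled (:func:`cohort_units`), so the per-unit coefficient scales of the
structural model are per-centimetre and per-kilogram.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

CONTINUOUS_COLUMNS = ("age", "height_m", "prepreg_weight_kg")
BINARY_DETERMINANTS = (
    "elevated_bp",
    "primiparity",
    "smoking",
    "malaria_pregnancy",
    "insufficient_gwg",
)
BIOMETRY_COLUMNS = ("hc_z", "ac_z", "fl_z")
INDICATOR_COLUMNS = ("bwz", "blz")
OUTCOME_COLUMNS = ("preterm", "reanimation", "formula_rx", "stay_gt3d")

MANDATORY_COLUMNS = (
    CONTINUOUS_COLUMNS + BINARY_DETERMINANTS + INDICATOR_COLUMNS + OUTCOME_COLUMNS
)
ALL_BINARY_COLUMNS = BINARY_DETERMINANTS + OUTCOME_COLUMNS
ZSCORE_COLUMNS = BIOMETRY_COLUMNS + INDICATOR_COLUMNS

#: validation bounds: (lower, upper), inclusive
VALIDATION_BOUNDS = {
    "age": (10.0, 55.0),
    "height_m": (1.2, 2.1),
    "prepreg_weight_kg": (30.0, 200.0),
    **{c: (-6.0, 6.0) for c in ZSCORE_COLUMNS},
}

#: values accepted as missing in CSV cells
NA_VALUES = ["", "NA", "na", "NaN", "nan"]


class SchemaError(ValueError):
    """A required column is absent or the header does not match the schema."""


class EmptyInputError(ValueError):
    """The input file contains no data rows."""


@dataclass
class FilterReport:
    """Bookkeeping for a complete-case filter pass."""

    n_input: int
    n_retained: int
    removed_per_column: dict[str, int]
    required: tuple[str, ...]

    @property
    def n_removed(self) -> int:
        return self.n_input - self.n_retained

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        lines = [
            f"complete-case filter on {len(self.required)} column(s)",
            f"  rows in:       {self.n_input}",
            f"  rows retained: {self.n_retained}",
            f"  rows removed:  {self.n_removed}",
        ]
        for col, k in self.removed_per_column.items():
            if k:
                lines.append(f"    missing {col}: {k}")
        return "\n".join(lines)


@dataclass
class AnalysisConfig:
    """Settings for one analysis run.

    ``model_variant`` selects the population model (maternal determinants
    only) or the subsample model (adds ultrasound biometry).  ``alpha`` is
    the two-sided significance level used throughout.
    """

    model_variant: str = "population"
    covariates: tuple[str, ...] = ()
    endogenous_paths: tuple[str, ...] = ("elevated_bp", "insufficient_gwg")
    alpha: float = 0.05
    tol: float = 1e-8
    max_iter: int = 500
    seed: int = 20150701
    paths: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must lie in (0, 1), got {self.alpha}")
        known = set(MANDATORY_COLUMNS) | set(BIOMETRY_COLUMNS)
        unknown = [c for c in self.covariates if c not in known]
        if unknown:
            raise SchemaError(f"unknown covariate name(s): {unknown}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("covariates", "endogenous_paths"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def read_cohort(path: str | Path, required: tuple[str, ...] = MANDATORY_COLUMNS) -> pd.DataFrame:
    """Read a cohort CSV into a typed table.

    Header matching is case-insensitive.  Cells that cannot be parsed as
    numbers become missing, with a logged warning.  Empty cells and ``NA``
    are both accepted as missing.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path, na_values=NA_VALUES, keep_default_na=True, dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise EmptyInputError(f"{path} contains no data") from exc
    df.columns = [c.strip().lower() for c in df.columns]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"mandatory column(s) absent from {path.name}: {missing}")
    if df.shape[0] == 0:
        raise EmptyInputError(f"{path} has a header but no rows")
    out = {}
    for col in df.columns:
        raw = df[col]
        parsed = pd.to_numeric(raw, errors="coerce")
        bad = parsed.isna() & raw.notna()
        if bad.any():
            logger.warning(
                "column %r: %d unparseable cell(s) set to missing (first value %r)",
                col, int(bad.sum()), raw[bad].iloc[0],
            )
        out[col] = parsed
    result = pd.DataFrame(out, index=df.index)
    return result.reset_index(drop=True)


def write_cohort(df: pd.DataFrame, path: str | Path) -> None:
    """Write a cohort table as UTF-8 CSV; missing cells become empty."""
    df.to_csv(path, index=False, na_rep="")


def validate_cohort(df: pd.DataFrame) -> list[str]:
    """Check schema invariants; return human-readable warnings (empty = clean).

    Violations are flagged, not repaired: binary columns must contain only
    {0, 1, missing}; z-scores must lie in [-6, 6]; continuous determinants
    must lie within plausible physical bounds.
    """
    problems: list[str] = []
    for col in ALL_BINARY_COLUMNS:
        if col not in df.columns:
            continue
        vals = df[col].dropna()
        bad = ~vals.isin([0, 1])
        if bad.any():
            problems.append(f"{col}: {int(bad.sum())} value(s) outside {{0,1}}")
    for col, (lo, hi) in VALIDATION_BOUNDS.items():
        if col not in df.columns:
            continue
        vals = df[col].dropna()
        bad = (vals < lo) | (vals > hi)
        if bad.any():
            problems.append(f"{col}: {int(bad.sum())} value(s) outside [{lo}, {hi}]")
    for msg in problems:
        logger.warning("validation: %s", msg)
    return problems


def complete_case_filter(
    df: pd.DataFrame, required: tuple[str, ...]
) -> tuple[pd.DataFrame, FilterReport]:
    """Keep rows with no missing value in any *required* column.

    The report counts, per column, how many dropped rows were missing that
    column (a row missing several columns is counted under each).
    """
    absent = [c for c in required if c not in df.columns]
    if absent:
        raise SchemaError(f"required column(s) not in table: {absent}")
    isna = df[list(required)].isna()
    keep = ~isna.any(axis=1)
    removed_per_column = {c: int(isna.loc[~keep, c].sum()) for c in required}
    out = df.loc[keep].reset_index(drop=True)
    report = FilterReport(
        n_input=len(df),
        n_retained=len(out),
        removed_per_column=removed_per_column,
        required=tuple(required),
    )
    if len(out) == 0:
        warnings.warn("complete-case filter removed every row", stacklevel=2)
    return out, report


def cohort_units(df: pd.DataFrame, columns: tuple[str, ...]) -> pd.DataFrame:
    """Assemble the model-ready design matrix.

    Height enters the structural model per centimetre, so ``height_m`` is
    converted to a ``height_cm`` column here and nowhere else (single point
    of conversion, no double scaling).  Weight stays in kilograms.  Any
    requested column named ``height_cm`` is derived from ``height_m``.
    """
    out = pd.DataFrame(index=df.index)
    for col in columns:
        if col == "height_cm":
            out[col] = df["height_m"] * 100.0
        else:
            out[col] = df[col]
    return out
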