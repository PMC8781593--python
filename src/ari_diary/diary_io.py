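"""Reading, validating and filtering symptom-diary and covariate tables.

A diary CSV has one row per observed child-day; a missing diary day is simply
an absent row.  Symptom columns are coded 0 (absent) or 1-3 (present, with an
optional ordinal severity that is carried through but never used in
classification).  Covariates live in a separate one-row-per-child CSV.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .datamodel import (
    COVARIATE_CSV_COLUMNS,
    COVARIATE_LEVELS,
    DIAGNOSIS_COLUMNS,
    DIARY_COLUMNS,
    ObservationWindow,
    SYMPTOM_COLUMNS,
)

logger = logging.getLogger(__name__)


class SchemaError(ValueError):
    """Input table does not have the expected columns or codings."""


class ValidationError(ValueError):
    """Input table violates a row-level invariant (duplicates, unknown ids...)."""


def read_covariates(path: str | Path) -> pd.DataFrame:
    """Read and validate the per-child covariate table.

    Returns a DataFrame indexed by ``child_id`` with a parsed ``birth_date``
    and categorical levels checked against the questionnaire vocabulary.
    Missing covariate values (empty cells) are kept as NaN; models apply
    complete-case handling downstream.
    """
    dtypes = {"child_id": str, "pets": str}
    dtypes.update({c: str for c in COVARIATE_LEVELS})
    cov = pd.read_csv(path, dtype=dtypes)
    return validate_covariates(cov)


def validate_covariates(cov: pd.DataFrame) -> pd.DataFrame:
    missing_cols = [c for c in COVARIATE_CSV_COLUMNS if c not in cov.columns]
    if missing_cols:
        raise SchemaError(f"covariate table lacks columns: {missing_cols}")
    cov = cov.copy()
    cov["child_id"] = cov["child_id"].astype(str)
    if cov["child_id"].duplicated().any():
        dups = cov.loc[cov["child_id"].duplicated(), "child_id"].tolist()
        raise ValidationError(f"duplicate child_id in covariates: {dups}")
    cov["birth_date"] = pd.to_datetime(cov["birth_date"], format="ISO8601")
    for name, levels in COVARIATE_LEVELS.items():
        observed = set(cov[name].dropna().unique())
        unknown = observed - set(levels)
        if unknown:
            raise SchemaError(f"unknown level(s) {sorted(unknown)} in covariate {name!r}")
    return cov.set_index("child_id", drop=False)


def read_diary(path: str | Path, covariates: pd.DataFrame,
               window: ObservationWindow | None = None) -> pd.DataFrame:
    """Read a diary CSV and validate it against the covariate table.

    Adds ``day_of_life`` (0 = birth date) computed from each child's birth
    date; rows outside the observation window are dropped with a logged
    count.  Duplicate (child_id, date) rows and children absent from the
    covariate table are errors.
    """
    window = window or ObservationWindow()
    diary = pd.read_csv(path, dtype={"child_id": str})
    return validate_diary(diary, covariates, window)


def validate_diary(diary: pd.DataFrame, covariates: pd.DataFrame,
                   window: ObservationWindow | None = None) -> pd.DataFrame:
    window = window or ObservationWindow()
    expected = set(DIARY_COLUMNS)
    unknown = set(diary.columns) - expected
    if unknown:
        raise SchemaError(f"unknown diary column(s): {sorted(unknown)}")
    missing = expected - set(diary.columns)
    if missing:
        raise SchemaError(f"diary lacks column(s): {sorted(missing)}")

    diary = diary.copy()
    diary["child_id"] = diary["child_id"].astype(str)
    diary["date"] = pd.to_datetime(diary["date"], format="ISO8601")

    for col in SYMPTOM_COLUMNS:
        vals = diary[col]
        if not np.isin(vals, [0, 1, 2, 3]).all():
            bad = sorted(set(vals) - {0, 1, 2, 3})
            raise SchemaError(f"symptom column {col!r} has values outside 0-3: {bad}")
    for col in DIAGNOSIS_COLUMNS:
        if not np.isin(diary[col], [0, 1]).all():
            raise SchemaError(f"diagnosis column {col!r} must be coded 0/1")

    dup_mask = diary.duplicated(subset=["child_id", "date"], keep=False)
    if dup_mask.any():
        keys = (diary.loc[dup_mask, ["child_id", "date"]]
                .drop_duplicates().astype(str).agg("/".join, axis=1).tolist())
        raise ValidationError(f"duplicate child-day rows: {keys[:20]}")

    unknown_children = set(diary["child_id"]) - set(covariates.index)
    if unknown_children:
        raise ValidationError(
            f"diary children absent from covariates: {sorted(unknown_children)[:20]}")

    birth = covariates["birth_date"].reindex(diary["child_id"]).to_numpy()
    diary["day_of_life"] = (diary["date"].to_numpy() - birth) // np.timedelta64(1, "D")
    diary["day_of_life"] = diary["day_of_life"].astype(int)

    in_window = diary["day_of_life"].between(window.start_day, window.end_day)
    n_dropped = int((~in_window).sum())
    if n_dropped:
        logger.info("dropped %d diary rows outside days %d-%d of life",
                    n_dropped, window.start_day, window.end_day)
    return diary.loc[in_window].reset_index(drop=True)


def write_diary(diary: pd.DataFrame, path: str | Path) -> None:
    """Write a validated diary back to CSV (derived columns excluded)."""
    out = diary.loc[:, list(DIARY_COLUMNS)].copy()
    out["date"] = pd.to_datetime(out["date"]).dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False)


def completeness(diary: pd.DataFrame, child_id: str,
                 window: ObservationWindow | None = None) -> float:
    """Fraction of window days on which the child has a diary entry."""
    window = window or ObservationWindow()
    days = diary.loc[diary["child_id"] == str(child_id), "day_of_life"]
    present = days.between(window.start_day, window.end_day).sum()
    return float(present) / window.n_days


def completeness_table(diary: pd.DataFrame, covariates: pd.DataFrame,
                       window: ObservationWindow | None = None) -> pd.Series:
    """Per-child completeness for every child in the covariate table."""
    window = window or ObservationWindow()
    in_win = diary["day_of_life"].between(window.start_day, window.end_day)
    counts = diary.loc[in_win].groupby("child_id").size()
    counts = counts.reindex(covariates.index, fill_value=0)
    return counts / window.n_days


def apply_inclusion(diary: pd.DataFrame, covariates: pd.DataFrame,
                    window: ObservationWindow | None = None,
                    ) -> tuple[set[str], dict[str, float]]:
    """Apply the diary-completeness inclusion rule.

    Returns the set of included child ids (completeness >= threshold) and an
    exclusion log mapping each excluded child to its completeness.  Raises if
    no child survives the filter.
    """
    window = window or ObservationWindow()
    comp = completeness_table(diary, covariates, window)
    included = set(comp.index[comp >= window.completeness_threshold])
    excluded = {cid: float(c) for cid, c in comp.items() if cid not in included}
    if not included:
        raise ValidationError(
            f"no children reach completeness {window.completeness_threshold:.2f}; "
            "review the threshold or the input data")
    logger.info("inclusion filter: %d included, %d excluded", len(included), len(excluded))
    return included, excluded
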