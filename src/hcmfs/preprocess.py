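"""Dataset-variant preprocessing.

Four named variants of a raw cohort are used throughout the benchmarks:

* ``IMV``       -- sparse rows dropped, missing values imputed
* ``IMV+SS``    -- IMV plus standardization of numeric columns
* ``IMV+OR``    -- IMV plus mean-substitution of |z|>3 outliers
* ``IMV+OR+SS`` -- all three, applied in that fixed order

The pipeline order is fixed: sparse-row drop, imputation, outlier handling,
standardization.  Note that whole-table standardization here is for
exploratory reports; model evaluation standardizes per CV training fold
(see :mod:`hcmfs.bench`) to avoid leaking test-fold statistics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import CATEGORICAL, NUMERIC, FeatureTable

log = logging.getLogger(__name__)

VARIANTS = ("IMV", "IMV+SS", "IMV+OR", "IMV+OR+SS")


@dataclass(frozen=True)
class PreprocessConfig:
    max_missing_per_row: int = 5
    impute_numeric: str = "mean"  # or "median"
    outlier_z: float = 3.0
    do_outliers: bool = False
    do_standardize: bool = False

    def __post_init__(self) -> None:
        if self.max_missing_per_row < 0:
            raise ValueError("max_missing_per_row must be >= 0")
        if self.outlier_z <= 0:
            raise ValueError("outlier_z must be > 0")
        if self.impute_numeric not in ("mean", "median"):
            raise ValueError(f"unknown impute strategy {self.impute_numeric!r}")


def drop_sparse_rows(table: FeatureTable, max_missing: int = 5) -> FeatureTable:
    """Remove samples with strictly more than ``max_missing`` missing feature
    cells, preserving the order of survivors."""
    n_missing = table.missing_mask.sum(axis=1)
    keep = n_missing <= max_missing
    if not keep.any():
        log.warning("drop_sparse_rows removed every sample")
    out = table.copy()
    out.values = out.values.loc[keep].reset_index(drop=True)
    out.labels = out.labels.loc[keep].reset_index(drop=True)
    return out


def impute_missing(table: FeatureTable, config: PreprocessConfig = PreprocessConfig()) -> FeatureTable:
    """Column-wise imputation: mean (or median) for numeric, mode for
    categorical/binary.  A fully missing column is an error."""
    out = table.copy()
    for name, meta in out.meta.items():
        col = out.values[name]
        if not col.isna().any():
            continue
        observed = col.dropna()
        if observed.empty:
            raise ValueError(f"column {name!r} has no observed values to impute from")
        if meta.kind == NUMERIC:
            fill = observed.mean() if config.impute_numeric == "mean" else observed.median()
        else:
            fill = observed.mode().min()  # smallest code on ties
        out.values[name] = col.fillna(fill)
    return out


def replace_outliers(table: FeatureTable, config: PreprocessConfig = PreprocessConfig()) -> FeatureTable:
    """Mean-substitute numeric cells with |z| above ``config.outlier_z``.

    z uses the column's mean and sample SD over all rows; flagged cells are
    replaced by the mean of the unflagged cells.  Zero-SD columns are skipped
    and categorical columns untouched.
    """
    out = table.copy()
    for name in out.numeric_features():
        col = out.values[name].to_numpy(dtype=float)
        obs = ~np.isnan(col)
        if obs.sum() < 2:
            continue
        sd = np.nanstd(col, ddof=1)
        if sd == 0:
            continue
        z = (col - np.nanmean(col)) / sd
        flagged = obs & (np.abs(z) > config.outlier_z)
        if not flagged.any():
            continue
        keep = obs & ~flagged
        if not keep.any():
            continue
        col[flagged] = col[keep].mean()
        out.values[name] = col
    return out


def standardize(table: FeatureTable) -> FeatureTable:
    """Transform each numeric column to mean 0, SD 1 (population SD).

    Zero-SD columns map to all zeros; categorical codes are untouched.
    Idempotent up to floating tolerance.
    """
    out = table.copy()
    for name in out.numeric_features():
        col = out.values[name].to_numpy(dtype=float)
        mu = np.nanmean(col)
        sd = np.nanstd(col)  # population SD
        out.values[name] = np.zeros_like(col) if sd == 0 else (col - mu) / sd
    return out


def make_variants(
    table: FeatureTable, config: PreprocessConfig = PreprocessConfig()
) -> dict[str, FeatureTable]:
    """Build the four canonical dataset variants from a raw table."""
    base = impute_missing(drop_sparse_rows(table, config.max_missing_per_row), config)
    imv_or = replace_outliers(base, config)
    return {
        "IMV": base,
        "IMV+SS": standardize(base),
        "IMV+OR": imv_or,
        "IMV+OR+SS": standardize(imv_or),
    }


VARIANT_SUFFIX = {
    "IMV": ".imv.csv",
    "IMV+SS": ".imv_ss.csv",
    "IMV+OR": ".imv_or.csv",
    "IMV+OR+SS": ".imv_or_ss.csv",
}
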