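"""Expression-matrix preprocessing: filtering, quantile normalization, log2.

The fixed stage order used by the pipeline driver is

    filter -> quantile normalize -> log2,

i.e. rows that are all zero, contain missing values, or are constant are
removed first, columns are then forced onto a common reference
distribution, and finally intensities move to log2 scale. Quantile
normalization follows the rank-mean convention: the reference distribution
is the across-sample mean of the within-sample order statistics, and tied
values within a sample receive the mean of the reference values at the
tied ranks (the convention of limma's normalizeQuantiles with tie
averaging).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import DataError, ExpressionMatrix

log = logging.getLogger(__name__)


@dataclass
class FilterReport:
    """Who was removed, and why."""

    removed_mirnas: list[tuple[str, str]] = field(default_factory=list)
    removed_samples: list[tuple[str, str]] = field(default_factory=list)
    kept_mirnas: int = 0
    kept_samples: int = 0

    @property
    def n_removed_mirnas(self) -> int:
        return len(self.removed_mirnas)

    def to_jsonable(self) -> dict:
        return {
            "removed_mirnas": [list(t) for t in self.removed_mirnas],
            "removed_samples": [list(t) for t in self.removed_samples],
            "kept_mirnas": self.kept_mirnas,
            "kept_samples": self.kept_samples,
        }


def filter_matrix(
    expr: ExpressionMatrix,
    drop_all_zero: bool = True,
    drop_missing: bool = True,
    drop_zero_variance: bool = True,
) -> tuple[ExpressionMatrix, FilterReport]:
    """Drop unusable miRNA rows, then samples that still carry missing data.

    A row is removed if it is all zero, contains any missing value, or has
    zero variance (each rule separately switchable). Should missing values
    survive row filtering (possible only with ``drop_missing=False``),
    the affected samples are dropped afterwards.
    """
    df = expr.values
    report = FilterReport()
    keep_rows: list[str] = []
    for mirna, row in df.iterrows():
        vals = row.to_numpy(dtype=float)
        if drop_missing and np.isnan(vals).any():
            report.removed_mirnas.append((mirna, "contains_missing"))
        elif drop_all_zero and np.nansum(np.abs(vals)) == 0.0:
            report.removed_mirnas.append((mirna, "all_zero"))
        elif drop_zero_variance and np.nanvar(vals) == 0.0:
            report.removed_mirnas.append((mirna, "zero_variance"))
        else:
            keep_rows.append(mirna)
    out = df.loc[keep_rows]
    if out.empty:
        raise DataError("empty matrix after filtering")
    keep_cols = []
    for sample in out.columns:
        if out[sample].isna().any():
            report.removed_samples.append((sample, "contains_missing"))
        else:
            keep_cols.append(sample)
    out = out[keep_cols]
    if out.shape[1] == 0:
        raise DataError("empty matrix after filtering")
    report.kept_mirnas = out.shape[0]
    report.kept_samples = out.shape[1]
    return ExpressionMatrix(out, expr.log_scale), report


def quantile_normalize(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample onto the common rank-mean reference distribution.

    After normalization all columns share one multiset of values, column
    means are identical, and within-column rank order is preserved. Ties
    within a column get the mean of the reference values spanning the tied
    ranks, so the operation is idempotent.
    """
    df = expr.values
    if df.isna().any().any():
        raise DataError("quantile normalization requires a matrix without missing values")
    if df.shape[1] < 2:
        log.warning("single-sample matrix: quantile normalization is a no-op")
        return expr.copy()
    X = df.to_numpy(dtype=float)
    order = np.argsort(X, axis=0, kind="stable")
    reference = np.take_along_axis(X, order, axis=0).mean(axis=1)

    out = np.empty_like(X)
    n = X.shape[0]
    for j in range(X.shape[1]):
        col_sorted_idx = order[:, j]
        col_ref = np.empty(n)
        col_ref[col_sorted_idx] = reference
        # average reference over runs of tied input values
        vals = X[col_sorted_idx, j]
        start = 0
        while start < n:
            stop = start
            while stop + 1 < n and vals[stop + 1] == vals[start]:
                stop += 1
            if stop > start:
                tied = col_sorted_idx[start : stop + 1]
                col_ref[tied] = reference[start : stop + 1].mean()
            start = stop + 1
        out[:, j] = col_ref
    return ExpressionMatrix(
        pd.DataFrame(out, index=df.index, columns=df.columns), expr.log_scale
    )


def log2_transform(expr: ExpressionMatrix, pseudocount: float = 1.0) -> ExpressionMatrix:
    """Elementwise ``log2(x + pseudocount)``; flips ``log_scale`` to True."""
    if expr.log_scale:
        raise DataError("matrix is already log2-scale; refusing a second transform")
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    df = expr.values
    shifted = df.to_numpy(dtype=float) + pseudocount
    bad = np.argwhere(shifted <= 0)
    if bad.size:
        i, j = bad[0]
        raise DataError(
            f"non-positive value at miRNA {df.index[i]!r}, sample {df.columns[j]!r} "
            f"cannot be log2-transformed with pseudocount {pseudocount}"
        )
    return ExpressionMatrix(
        pd.DataFrame(np.log2(shifted), index=df.index, columns=df.columns),
        log_scale=True,
    )


def preprocess(
    expr: ExpressionMatrix,
    pseudocount: float = 1.0,
    quantile: bool = True,
) -> tuple[ExpressionMatrix, FilterReport]:
    """The full fixed-order preprocessing chain on a raw matrix."""
    if expr.log_scale:
        raise DataError("preprocess expects a raw-scale matrix")
    filtered, report = filter_matrix(expr)
    normed = quantile_normalize(filtered) if quantile else filtered
    return log2_transform(normed, pseudocount=pseudocount), report
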