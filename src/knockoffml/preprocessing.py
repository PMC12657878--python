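"""Quality-control transforms for raw feature tables.

The canonical order, enforced by :func:`run_pipeline`, is
winsorize -> missingness filter -> impute -> standardize -> dummy-encode.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.experimental import enable_iterative_imputer  # noqa: F401
from sklearn.impute import IterativeImputer

__all__ = [
    "QCReport",
    "winsorize",
    "missingness_filter",
    "standardize",
    "mode_impute",
    "mice_impute",
    "dummy_encode",
    "run_pipeline",
]


@dataclass
class QCReport:
    dropped_columns: list[str] = field(default_factory=list)
    winsor_bounds: dict[str, tuple[float, float]] = field(default_factory=dict)
    imputed_columns: dict[str, str] = field(default_factory=dict)
    unscaled_columns: list[str] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "dropped_columns": self.dropped_columns,
                    "winsor_bounds": {
                        k: list(v) for k, v in self.winsor_bounds.items()
                    },
                    "imputed_columns": self.imputed_columns,
                    "unscaled_columns": self.unscaled_columns,
                },
                indent=1,
            )
        )


def winsorize(
    x: pd.Series, lower_q: float = 0.01, upper_q: float = 0.99
) -> pd.Series:
    """Clip a numeric column at its empirical ``lower_q``/``upper_q``
    quantiles; missing values pass through.

    Bounds are order statistics (the smallest value at or above the lower
    quantile position and the largest at or below the upper one), which
    makes the transform idempotent: re-winsorizing clipped data recovers
    the same bounds.
    """
    if not 0 <= lower_q < upper_q <= 1:
        raise ValueError("need 0 <= lower_q < upper_q <= 1")
    observed = x.dropna()
    if observed.empty:
        raise ValueError(f"column {x.name!r} is entirely missing")
    lo = observed.quantile(lower_q, interpolation="higher")
    hi = observed.quantile(upper_q, interpolation="lower")
    if lo > hi:  # only possible for tiny n with near-equal quantiles
        hi = lo
    return x.clip(lower=lo, upper=hi)


def missingness_filter(
    table: pd.DataFrame, max_missing: float = 0.30
) -> tuple[pd.DataFrame, QCReport]:
    """Drop columns whose missing fraction strictly exceeds ``max_missing``."""
    if not 0 <= max_missing <= 1:
        raise ValueError("max_missing must be in [0, 1]")
    frac = table.isna().mean()
    dropped = list(frac.index[frac > max_missing])
    return table.drop(columns=dropped), QCReport(dropped_columns=dropped)


def standardize(
    table: pd.DataFrame, binary: set[str] | frozenset[str] = frozenset()
) -> tuple[pd.DataFrame, QCReport]:
    """Scale continuous columns to sample mean 0 / SD 1 (ddof=1); binary and
    non-numeric columns are untouched. Zero-variance continuous columns are
    flagged and left unscaled."""
    out = table.copy()
    report = QCReport()
    for col in table.columns:
        if col in binary or not pd.api.types.is_numeric_dtype(table[col]):
            continue
        sd = table[col].std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            warnings.warn(f"column {col!r} has zero variance; left unscaled")
            report.unscaled_columns.append(col)
            continue
        out[col] = (table[col] - table[col].mean()) / sd
    return out, report


def mode_impute(x: pd.Series) -> pd.Series:
    """Fill missing entries with the most frequent observed level; ties go to
    the first level in sorted order."""
    observed = x.dropna()
    if observed.empty:
        raise ValueError(f"column {x.name!r} is entirely missing")
    counts = observed.value_counts()
    top = counts.max()
    mode = sorted(counts.index[counts == top])[0]
    return x.fillna(mode)


def mice_impute(
    table: pd.DataFrame, seed: int = 0, max_iter: int = 10
) -> pd.DataFrame:
    """Chained-equations imputation of continuous columns (delegated to an
    iterative round-robin regression imputer)."""
    imputer = IterativeImputer(max_iter=max_iter, random_state=seed)
    values = imputer.fit_transform(table.to_numpy(dtype=float))
    return pd.DataFrame(values, columns=table.columns, index=table.index)


def dummy_encode(table: pd.DataFrame) -> pd.DataFrame:
    """Reference-code categorical columns: a k-level column becomes k-1
    indicators named ``<var>__<level>`` (reference = first-sorted level).
    Single-level columns are dropped with a warning."""
    out: list[pd.Series] = []
    for col in table.columns:
        x = table[col]
        if pd.api.types.is_numeric_dtype(x):
            out.append(x)
            continue
        levels = sorted(x.dropna().unique())
        if len(levels) < 2:
            warnings.warn(f"categorical column {col!r} has a single level; dropped")
            continue
        for level in levels[1:]:
            out.append(pd.Series((x == level).astype(float), name=f"{col}__{level}"))
    return pd.concat(out, axis=1) if out else pd.DataFrame(index=table.index)


def run_pipeline(
    table: pd.DataFrame,
    binary: set[str] | frozenset[str] = frozenset(),
    lower_q: float = 0.01,
    upper_q: float = 0.99,
    max_missing: float = 0.30,
    seed: int = 0,
) -> tuple[pd.DataFrame, QCReport]:
    """Winsorize -> filter -> impute -> standardize -> encode, returning the
    model-ready table and a combined QC report."""
    report = QCReport()
    work = table.copy()
    for col in work.columns:
        if col in binary or not pd.api.types.is_numeric_dtype(work[col]):
            continue
        if work[col].dropna().empty:
            continue  # handled by the missingness filter
        work[col] = winsorize(work[col], lower_q, upper_q)
        lo, hi = work[col].min(), work[col].max()
        report.winsor_bounds[col] = (float(lo), float(hi))

    work, filt = missingness_filter(work, max_missing)
    report.dropped_columns = filt.dropped_columns

    continuous = [
        c
        for c in work.columns
        if c not in binary and pd.api.types.is_numeric_dtype(work[c])
    ]
    if continuous and work[continuous].isna().any().any():
        work[continuous] = mice_impute(work[continuous], seed=seed)
        for c in continuous:
            report.imputed_columns[c] = "mice"
    for col in work.columns:
        if col in continuous:
            continue
        if work[col].isna().any():
            work[col] = mode_impute(work[col])
            report.imputed_columns[col] = "mode"

    work, scale_report = standardize(work, binary=binary)
    report.unscaled_columns = scale_report.unscaled_columns
    work = dummy_encode(work)
    return work, report
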