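"""Correlation and regression of quality indexes against morphometry.

Physicochemical indexes (hardness, flexibility, moisture) and the
3D morphological parameters (mean pore volume, area, length, width,
porosity) are related by a Pearson correlation matrix, and moisture is
regressed on porosity by ordinary least squares with R² reported.

By default each storage day contributes one row of per-day means, so the
correlations are over n = days rows; per-sample rows work identically.
Rows with missing values are dropped (complete-case) and logged.  p-values
are available but unadjusted — with n = 5 daily means they describe the
strength of a trend, not a hypothesis test.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
from scipy import stats as sps

log = logging.getLogger(__name__)


@dataclasses.dataclass
class LinearFit:
    slope: float
    intercept: float
    r_squared: float
    n: int


def _as_array(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional")
    return arr


def pearson(x, y) -> float:
    """Product-moment correlation coefficient.

    Raises on unequal lengths, fewer than 3 points, or a constant input
    (r is undefined there; silently returning 0 would hide a degenerate
    design).
    """
    xa, ya = _as_array(x, "x"), _as_array(y, "y")
    if len(xa) != len(ya):
        raise ValueError(f"length mismatch: {len(xa)} vs {len(ya)}")
    if len(xa) < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        raise ValueError("Pearson r is undefined for a constant input")
    r = float(sps.pearsonr(xa, ya).statistic)
    return max(-1.0, min(1.0, r))


def pearson_pvalue(x, y) -> float:
    """Two-sided, unadjusted p-value of the Pearson correlation."""
    return float(sps.pearsonr(_as_array(x, "x"), _as_array(y, "y")).pvalue)


def correlation_matrix(table: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Pearson matrix over the numeric columns of a feature table.

    Complete-case: rows with any missing value are dropped (and logged).
    A constant column is an error naming the column.  The result is
    symmetric with a unit diagonal.
    """
    if table.columns.duplicated().any():
        raise ValueError("column names must be unique")
    numeric = table.select_dtypes(include=[np.number])
    complete = numeric.dropna()
    dropped = len(numeric) - len(complete)
    if dropped:
        log.warning("correlation_matrix: dropped %d incomplete rows", dropped)
    if len(complete) < 3:
        raise ValueError(f"need >= 3 complete rows, have {len(complete)}")
    for col in complete.columns:
        if complete[col].nunique() <= 1:
            raise ValueError(f"column {col!r} is constant; Pearson r is undefined")
    cols = list(complete.columns)
    n = len(cols)
    mat = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            r = pearson(complete[cols[i]].to_numpy(), complete[cols[j]].to_numpy())
            mat[i, j] = mat[j, i] = r
    return pd.DataFrame(mat, index=cols, columns=cols)


def linear_fit(x, y) -> LinearFit:
    """Ordinary least squares of y on x; R² = 1 − SS_res/SS_tot.

    For simple regression R² equals the squared Pearson r of x and y.
    """
    xa, ya = _as_array(x, "x"), _as_array(y, "y")
    if len(xa) != len(ya):
        raise ValueError(f"length mismatch: {len(xa)} vs {len(ya)}")
    if len(xa) < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(xa) == 0:
        raise ValueError("x is constant; the fit is undefined")
    res = sps.linregress(xa, ya)
    if np.ptp(ya) == 0:
        r2 = 1.0  # exact horizontal line: residuals are zero
    else:
        r2 = float(res.rvalue**2)
    return LinearFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=min(max(r2, 0.0), 1.0),
        n=len(xa),
    )
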