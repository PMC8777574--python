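"""Bound-water-content reference analytics.

BWC (%) is the gravimetric moisture fraction after drying at 105 degC,
measured twice per (lot, subsample) sample.  This module provides the
descriptive statistics over sample means, Tukey-fence outlier screening
with the conservative k = 3.0 widening, per-lot ranges, and the scalar
nested ANOVA over the lot -> subsample -> lab-duplicate hierarchy.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from woodvar.anova import VarianceDecomposition, nested_decomposition
from woodvar.dataset import BWCTable
from woodvar.errors import DegenerateDataError


def bwc_descriptives(table: BWCTable) -> dict:
    """Mean, sd (n-1), min, max and range of the per-sample mean BWC (%)."""
    m = table.means.to_numpy(float)
    if m.size < 2:
        raise DegenerateDataError("need at least two samples for descriptives")
    return {
        "mean": float(m.mean()),
        "sd": float(m.std(ddof=1)),
        "min": float(m.min()),
        "max": float(m.max()),
        "range": float(m.max() - m.min()),
    }


def tukey_outliers(values, k: float = 3.0) -> tuple[np.ndarray, tuple[float, float]]:
    """Tukey-fence outlier flags with widened fences (default k = 3.0).

    Quartiles use linear interpolation between the closest order
    statistics (numpy's default).  A value is flagged when it falls below
    Q1 - k*IQR or above Q3 + k*IQR; with zero IQR the fences collapse to
    the quartile, so any distinct value outside is still flagged.

    Returns (boolean flags, (lower fence, upper fence)).
    """
    v = np.asarray(values, dtype=float)
    if v.size < 4:
        raise ValueError("need at least four values for quartile fences")
    if k <= 0:
        raise ValueError(f"fence multiplier k must be > 0, got {k}")
    q1, q3 = np.percentile(v, [25, 75], method="linear")
    iqr = q3 - q1
    lower, upper = q1 - k * iqr, q3 + k * iqr
    return (v < lower) | (v > upper), (float(lower), float(upper))


def lot_ranges(table: BWCTable) -> tuple[pd.Series, float]:
    """Per-lot range (max - min of sample means, %) and the unweighted average.

    A singleton lot has no range; it is reported as NaN.
    """
    df = pd.DataFrame({"lot": table.data["lot"], "mean": table.means})
    g = df.groupby("lot", sort=True)["mean"]
    ranges = g.max() - g.min()
    counts = g.count()
    ranges[counts < 2] = np.nan
    avg = float(ranges.dropna().mean())
    return ranges, avg


def bwc_nested_anova(table: BWCTable, weighted: bool = True) -> VarianceDecomposition:
    """Scalar nested ANOVA of BWC: lot -> subsample -> lab duplicate.

    The two duplicates per sample form the replicate level.  The default
    uses the count-weighted (classical) convention, which is the one the
    study-scale MSQ triple (lot >> subsample >> duplicate) arises from;
    pass ``weighted=False`` for the literal unweighted formulas.
    """
    d = table.data
    values = np.concatenate([d["dup1"].to_numpy(float), d["dup2"].to_numpy(float)])
    labels = pd.DataFrame(
        {
            "lot": np.concatenate([d["lot"], d["lot"]]),
            "subsample": np.concatenate([d["subsample"], d["subsample"]]),
        }
    )
    return nested_decomposition(values, labels, weighted=weighted, leaf_name="replicate")
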