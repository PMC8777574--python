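"""Independent reference implementations used only to check the package.

These deliberately use plain loops and dictionaries — no shared code with
woodvar — so they can serve as literal oracles for the nested SSQ/MSQ
formulas, the per-scan OLS behind MSC, and quartile fences.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def brute_nested(values, labels: pd.DataFrame, weighted: bool = False,
                 leaf_name: str = "scan"):
    """Literal nested decomposition: materialise every unit mean, sum squares.

    SSQ_lvl = sum_n (x_{n,lvl} - xbar_{lvl-1})^2 with x_{n,lvl} the mean of
    unit n's rows and xbar_{lvl-1} the unweighted mean of the parent's
    child-unit means (grand mean of top-unit means at the top).  With
    ``weighted=True`` each squared deviation is multiplied by the unit's
    row count and parent references are parent row means.
    """
    V = np.asarray(values, dtype=float)
    scalar = V.ndim == 1
    if scalar:
        V = V[:, None]
    labels = pd.DataFrame(labels).reset_index(drop=True)
    cols = list(labels.columns)
    nlev = len(cols)

    unit_rows = [dict() for _ in range(nlev)]
    for r in range(len(V)):
        for i in range(nlev):
            key = tuple(labels.iloc[r, : i + 1])
            unit_rows[i].setdefault(key, []).append(r)
    means = [{k: V[rows].mean(axis=0) for k, rows in u.items()} for u in unit_rows]

    ssq, dof = {}, {}
    prev_n = 1
    for i, name in enumerate(cols):
        m = means[i]
        if i == 0:
            if weighted:
                ref = {k: V.mean(axis=0) for k in m}
            else:
                grand = np.mean(list(m.values()), axis=0)
                ref = {k: grand for k in m}
        else:
            ref = {}
            by_parent: dict = {}
            for k in m:
                by_parent.setdefault(k[:-1], []).append(k)
            for pk, kids in by_parent.items():
                pref = means[i - 1][pk] if weighted else np.mean([m[k] for k in kids], axis=0)
                for k in kids:
                    ref[k] = pref
        s = np.zeros(V.shape[1])
        for k in m:
            w = len(unit_rows[i][k]) if weighted else 1
            s = s + w * (m[k] - ref[k]) ** 2
        ssq[name] = s
        dof[name] = len(m) - prev_n
        prev_n = len(m)

    s = np.zeros(V.shape[1])
    for r in range(len(V)):
        key = tuple(labels.iloc[r, :nlev])
        s = s + (V[r] - means[-1][key]) ** 2
    ssq[leaf_name] = s
    dof[leaf_name] = len(V) - prev_n

    msq = {
        k: (ssq[k] / dof[k] if dof[k] > 0 else np.full(V.shape[1], np.nan)) for k in ssq
    }
    if scalar:
        ssq = {k: float(v[0]) for k, v in ssq.items()}
        msq = {k: float(np.asarray(v)[0]) for k, v in msq.items()}
    return ssq, msq, dof


def ols_line(y: np.ndarray, x: np.ndarray) -> tuple[float, float]:
    """Closed-form simple OLS of y on x: returns (intercept, slope)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    slope = float(np.sum((x - x.mean()) * (y - y.mean())) / np.sum((x - x.mean()) ** 2))
    return float(y.mean() - slope * x.mean()), slope


def tukey_fences(values, k: float) -> tuple[float, float]:
    """Quartile fences under linear interpolation between order statistics."""
    v = np.sort(np.asarray(values, float))
    n = v.size

    def quantile(q):
        h = (n - 1) * q
        lo = int(np.floor(h))
        hi = min(lo + 1, n - 1)
        return v[lo] + (h - lo) * (v[hi] - v[lo])

    q1, q3 = quantile(0.25), quantile(0.75)
    iqr = q3 - q1
    return q1 - k * iqr, q3 + k * iqr


def random_hierarchy(rng: np.random.Generator, max_lots=3, max_subs=3, max_reps=2,
                     max_scans=5, n_cols=1):
    """A random (possibly unbalanced) nested design with random values."""
    rows = []
    for l in range(rng.integers(2, max_lots + 1)):
        for s in range(rng.integers(1, max_subs + 1)):
            for r in range(rng.integers(1, max_reps + 1)):
                for k in range(rng.integers(1, max_scans + 1)):
                    rows.append((f"l{l}", f"l{l}s{s}", f"l{l}s{s}r{r}"))
    labels = pd.DataFrame(rows, columns=["lot", "subsample", "replicate"])
    values = rng.standard_normal((len(labels), n_cols))
    return values, labels
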