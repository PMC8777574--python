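"""Nested analysis of variance over a sampling hierarchy.

For a hierarchy lot -> subsample -> replicate -> scan, the contribution of
each level is measured by a sum of squares

    SSQ_lvl = sum_{n=1..N_lvl} (x_{n,lvl} - xbar_{lvl-1})^2

where x_{n,lvl} is the mean of unit n's deepest-level rows and
xbar_{lvl-1} is the mean over the parent's child-unit means (the grand
mean of the top-level unit means at the top).  The mean square is

    MSQ_lvl = SSQ_lvl / (N_lvl - N_{lvl-1})

with N_lvl the number of distinct units at the level (N_0 = 1), so the
divisor is the level's degrees of freedom.  For spectral data the
decomposition runs independently at every wavenumber.

Two conventions are available.  The default follows the formulas above
literally: unit deviations enter unweighted and parent references are
unweighted means of child-unit means.  ``weighted=True`` gives the
classical nested ANOVA, where every squared deviation is multiplied by
the unit's descendant (row) count and parent references are row means;
in that convention the level SSQs sum exactly to the total sum of
squares about the grand mean.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from woodvar.dataset import SpectralDataset
from woodvar.errors import DesignError


@dataclass
class HierarchyDesign:
    """Level names and distinct-unit counts of a nested design.

    Counts need not be balanced; they are whatever the labels contain
    (e.g. 126 replicate tubes instead of 128 after data loss).
    """

    levels: tuple
    counts: dict

    @classmethod
    def from_labels(cls, labels: pd.DataFrame, leaf_name: str = "scan") -> "HierarchyDesign":
        """Derive the design from hierarchy label columns (rows = leaf units)."""
        labels = pd.DataFrame(labels)
        cols = list(labels.columns)
        counts = {}
        for i, name in enumerate(cols):
            counts[name] = labels.groupby(cols[: i + 1], sort=False).ngroup().nunique()
        counts[leaf_name] = len(labels)
        return cls(levels=tuple(cols) + (leaf_name,), counts=counts)

    def dof(self) -> tuple[dict, int]:
        return compute_dof(self)


def compute_dof(design) -> tuple[dict, int]:
    """Degrees of freedom per level: D_lvl = N_lvl - N_{lvl-1}, N_0 = 1.

    ``design`` is a :class:`HierarchyDesign` or a sequence of unit counts
    ordered from the top level down.  The total is N_deepest - 1.  A level
    with D <= 0 (no replication at that level) raises :class:`DesignError`
    naming the level.
    """
    if isinstance(design, HierarchyDesign):
        names = list(design.levels)
        counts = [design.counts[n] for n in names]
    else:
        counts = [int(c) for c in design]
        names = [f"level{i + 1}" for i in range(len(counts))]
    dof = {}
    prev = 1
    for name, n in zip(names, counts):
        d = int(n) - prev
        if d <= 0:
            raise DesignError(
                f"level {name!r} has {n} unit(s) under {prev} parent unit(s): "
                "zero degrees of freedom"
            )
        dof[name] = d
        prev = int(n)
    return dof, counts[-1] - 1


@dataclass
class VarianceDecomposition:
    """Per-level SSQ/MSQ with degrees of freedom.

    ``ssq``/``msq`` map level name to a per-wavenumber vector (spectral
    input) or a scalar (1-D input).  Levels without replication (zero
    degrees of freedom) are kept with MSQ = NaN and listed in
    ``undefined``.  ``total_ssq`` is the plain sum of squares about the
    grand (row) mean with ``total_dof = n_rows - 1``.
    """

    levels: tuple
    ssq: dict
    msq: dict
    dof: dict
    n_units: dict
    total_ssq: object
    total_dof: int
    weighted: bool = False
    undefined: set = field(default_factory=set)

    def msq_mean(self, level: str) -> float:
        """Mean of the level's MSQ over wavenumbers (the scalar itself for 1-D)."""
        return float(np.mean(self.msq[level]))

    def total_msq(self):
        """Total mean square about the grand mean (variance with n-1)."""
        if self.total_dof <= 0:
            return np.full_like(np.asarray(self.total_ssq, dtype=float), np.nan)
        return np.asarray(self.total_ssq, dtype=float) / self.total_dof

    def to_frame(self, axis: np.ndarray | None = None) -> pd.DataFrame:
        """Long-format table (level, wavenumber, ssq, msq, dof)."""
        rows = []
        for lvl in self.levels:
            s = np.atleast_1d(self.ssq[lvl])
            m = np.atleast_1d(self.msq[lvl])
            w = np.arange(s.size) if axis is None else np.asarray(axis)
            rows.append(
                pd.DataFrame(
                    {"level": lvl, "wavenumber": w, "ssq": s, "msq": m, "dof": self.dof[lvl]}
                )
            )
        return pd.concat(rows, ignore_index=True)


def _group_codes(labels: pd.DataFrame, depth: int) -> np.ndarray:
    cols = list(labels.columns[:depth])
    return labels.groupby(cols, sort=True).ngroup().to_numpy()


def _group_means(V: np.ndarray, codes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    means = pd.DataFrame(V).groupby(codes, sort=True).mean().to_numpy()
    return means, np.bincount(codes)


def nested_decomposition(
    values,
    labels,
    weighted: bool = False,
    leaf_name: str = "scan",
) -> VarianceDecomposition:
    """Nested SSQ/MSQ decomposition of ``values`` over ``labels``.

    Parameters
    ----------
    values
        (n_rows,) scalar response or (n_rows, n_wavenumbers) spectra; one
        row per deepest-level unit.
    labels
        DataFrame whose columns, outermost first, identify the grouping
        levels above the rows (e.g. ``lot, subsample, replicate`` when the
        rows are scans).  The rows themselves form the deepest level,
        named ``leaf_name``.
    weighted
        False (default): the literal unweighted formulas.  True: classical
        count-weighted nested ANOVA (additive decomposition of the total
        sum of squares in any design).

    Rows containing non-finite values are dropped with a warning before
    decomposition.
    """
    V = np.asarray(values, dtype=float)
    scalar = V.ndim == 1
    if scalar:
        V = V[:, None]
    if V.ndim != 2:
        raise ValueError("values must be 1-D or 2-D")
    labels = pd.DataFrame(labels).reset_index(drop=True)
    if len(labels) != V.shape[0]:
        raise ValueError(
            f"labels ({len(labels)} rows) do not cover the values ({V.shape[0]} rows)"
        )
    if len(labels.columns) == 0:
        raise ValueError("labels must have at least one grouping column")
    finite = np.isfinite(V).all(axis=1)
    if not finite.all():
        warnings.warn(
            f"dropping {int((~finite).sum())} row(s) with non-finite values",
            stacklevel=2,
        )
        V = V[finite]
        labels = labels.loc[finite].reset_index(drop=True)
    n = V.shape[0]
    if n == 0:
        raise ValueError("no finite rows left to decompose")

    group_cols = list(labels.columns)
    level_names = tuple(group_cols) + (leaf_name,)

    codes = [_group_codes(labels, i + 1) for i in range(len(group_cols))]
    stats = [_group_means(V, c) for c in codes]

    ssq: dict = {}
    msq: dict = {}
    dof: dict = {}
    n_units: dict = {}
    undefined: set = set()
    prev_n = 1

    for i, name in enumerate(group_cols):
        m, cnt = stats[i]
        n_i = m.shape[0]
        if i == 0:
            if weighted:
                ref_per_unit = np.broadcast_to(V.mean(axis=0)[None, :], m.shape)
            else:
                ref_per_unit = np.broadcast_to(m.mean(axis=0)[None, :], m.shape)
        else:
            pmap = (
                pd.DataFrame({"u": codes[i], "p": codes[i - 1]})
                .drop_duplicates("u")
                .sort_values("u")["p"]
                .to_numpy()
            )
            if weighted:
                ref_per_unit = stats[i - 1][0][pmap]
            else:
                parent_ref = pd.DataFrame(m).groupby(pmap, sort=True).mean().to_numpy()
                ref_per_unit = parent_ref[pmap]
        dev2 = (m - ref_per_unit) ** 2
        s = (dev2 * cnt[:, None]).sum(axis=0) if weighted else dev2.sum(axis=0)
        _store(name, s, n_i, prev_n, ssq, msq, dof, n_units, undefined)
        prev_n = n_i

    # deepest level: the rows themselves, deviations about their group mean
    leaf_ref = stats[-1][0][codes[-1]]
    s = ((V - leaf_ref) ** 2).sum(axis=0)
    _store(leaf_name, s, n, prev_n, ssq, msq, dof, n_units, undefined)

    grand = V.mean(axis=0)
    total_ssq = ((V - grand[None, :]) ** 2).sum(axis=0)

    if undefined:
        warnings.warn(
            f"levels {sorted(undefined)} have zero degrees of freedom; MSQ undefined",
            stacklevel=2,
        )

    if scalar:
        ssq = {k: float(v[0]) for k, v in ssq.items()}
        msq = {k: float(v[0]) for k, v in msq.items()}
        total_ssq = float(total_ssq[0])

    return VarianceDecomposition(
        levels=level_names,
        ssq=ssq,
        msq=msq,
        dof=dof,
        n_units=n_units,
        total_ssq=total_ssq,
        total_dof=n - 1,
        weighted=weighted,
        undefined=undefined,
    )


def _store(name, s, n_i, prev_n, ssq, msq, dof, n_units, undefined) -> None:
    d = n_i - prev_n
    ssq[name] = s
    dof[name] = d
    n_units[name] = n_i
    if d > 0:
        msq[name] = s / d
    else:
        msq[name] = np.full_like(s, np.nan)
        undefined.add(name)


def per_lot_decomposition(
    dataset: SpectralDataset,
    weighted: bool = False,
) -> dict:
    """Nested decomposition within each lot (subsample, replicate, scan levels).

    Returns a dict keyed by lot id.  A lot with a single subsample yields a
    decomposition whose subsample level is undefined (flagged in
    ``undefined``), not an error.
    """
    out = {}
    for lot in pd.unique(dataset.labels["lot"]):
        sub = dataset.subset_lot(lot)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out[lot] = nested_decomposition(
                sub.absorbance,
                sub.labels[["subsample", "replicate"]],
                weighted=weighted,
            )
    return out


def normalize_msq(decomposition: VarianceDecomposition, levels) -> dict:
    """Scale each selected level's MSQ vector to unit maximum.

    An all-zero (or undefined) vector is returned unchanged with a warning.
    """
    out = {}
    for lvl in levels:
        v = np.atleast_1d(np.asarray(decomposition.msq[lvl], dtype=float))
        m = np.nanmax(v) if np.isfinite(v).any() else 0.0
        if not np.isfinite(m) or m == 0.0:
            warnings.warn(f"MSQ at level {lvl!r} is all zero; not normalized", stacklevel=2)
            out[lvl] = v.copy()
        else:
            out[lvl] = v / m
    return out
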