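"""Spectral preprocessing: wavenumber trimming, artifact screening, MSC.

The pipeline order is fixed: trim the wavenumber range, flag and drop
air/plastic-lid artifact scans, then apply multiplicative scatter
correction (MSC).  MSC regresses every scan x onto a reference spectrum r
(ordinary least squares over wavenumbers, x ~ a + b*r) and replaces the
scan by (x - a) / b, removing additive offsets and multiplicative
scatter.  By default the reference is the mean spectrum of all retained
scans; the fitted :class:`MSCModel` stores it so held-out scans can be
corrected consistently.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from woodvar.dataset import SpectralDataset
from woodvar.errors import DegenerateDataError


def trim_wavenumbers(dataset: SpectralDataset, low: float, high: float) -> SpectralDataset:
    """Keep exactly the columns with low <= wavenumber <= high.

    Labels are untouched.  Bounds outside the axis range leave the dataset
    unchanged (all columns retained); retaining no columns is an error.
    """
    if low >= high:
        raise ValueError(f"trim bounds must satisfy low < high, got ({low}, {high})")
    keep = (dataset.axis >= low) & (dataset.axis <= high)
    if not keep.any():
        raise DegenerateDataError(
            f"no wavenumbers retained in [{low}, {high}] "
            f"(axis spans [{dataset.axis[0]}, {dataset.axis[-1]}])"
        )
    out = replace(
        dataset,
        absorbance=dataset.absorbance[:, keep],
        axis=dataset.axis[keep],
        labels=dataset.labels.copy(),
        provenance={**dataset.provenance, "trim": (float(low), float(high))},
    )
    return out


def detect_artifact_scans(
    dataset: SpectralDataset,
    corr_threshold: float = 0.5,
    abs_floor: float = 0.05,
) -> np.ndarray:
    """Flag scans that look like air or plastic-lid acquisitions.

    A scan is flagged when its Pearson correlation with the median spectrum
    falls below ``corr_threshold`` or its mean absorbance is below
    ``abs_floor``.  Near-flat "air" scans fail both; chemically alien lid
    scans fail the correlation test.  Scans with zero variance across
    wavenumbers (correlation undefined) are always flagged.

    Returns a boolean array, one flag per scan.
    """
    if dataset.n_scans == 0:
        raise DegenerateDataError("empty dataset")
    X = dataset.absorbance
    median = np.median(X, axis=0)
    med_c = median - median.mean()
    med_norm = np.linalg.norm(med_c)
    Xc = X - X.mean(axis=1, keepdims=True)
    row_norm = np.linalg.norm(Xc, axis=1)
    zero_var = row_norm == 0.0
    if med_norm == 0.0:
        # reference itself flat: fall back to the absorbance floor only
        corr = np.zeros(dataset.n_scans)
        corr_flags = np.zeros(dataset.n_scans, dtype=bool)
    else:
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = (Xc @ med_c) / (row_norm * med_norm)
        corr_flags = corr < corr_threshold
    flags = corr_flags | (X.mean(axis=1) < abs_floor) | zero_var
    return flags


def drop_flagged(dataset: SpectralDataset, flags: np.ndarray) -> tuple[SpectralDataset, int]:
    """Remove flagged scans; returns the filtered dataset and the count dropped."""
    flags = np.asarray(flags, dtype=bool)
    if flags.size != dataset.n_scans:
        raise ValueError("flags length must equal the number of scans")
    out = dataset.select(~flags)
    out.provenance = {**dataset.provenance, "artifacts_dropped": int(flags.sum())}
    return out, int(flags.sum())


@dataclass
class MSCModel:
    """Fitted multiplicative-scatter-correction parameters.

    ``reference`` is the spectrum every scan was regressed onto;
    ``intercept``/``slope`` hold the per-scan OLS coefficients (a, b).
    """

    reference: np.ndarray
    intercept: np.ndarray
    slope: np.ndarray
    axis: np.ndarray

    def fit_coefficients(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Closed-form per-scan OLS of each row of X against the reference."""
        r = self.reference
        r_c = r - r.mean()
        denom = float(r_c @ r_c)
        if denom == 0.0:
            raise DegenerateDataError("MSC reference has zero variance")
        X = np.atleast_2d(X)
        b = (X - X.mean(axis=1, keepdims=True)) @ r_c / denom
        a = X.mean(axis=1) - b * r.mean()
        return a, b

    def correct(self, X: np.ndarray) -> np.ndarray:
        """Apply (x - a) / b to new scans using this model's reference."""
        a, b = self.fit_coefficients(X)
        if np.any(b == 0.0):
            raise DegenerateDataError("a scan has zero covariance with the reference")
        return (np.atleast_2d(X) - a[:, None]) / b[:, None]


def msc(
    dataset: SpectralDataset,
    reference: np.ndarray | None = None,
) -> tuple[SpectralDataset, MSCModel]:
    """Multiplicative scatter correction of every scan.

    If ``reference`` is omitted it is the mean spectrum of all scans in
    ``dataset``.  Scans whose OLS slope against the reference is zero
    (zero variance, or exactly orthogonal to the reference) cannot be
    corrected; they are excluded with a warning.
    """
    X = dataset.absorbance
    if reference is None:
        reference = X.mean(axis=0)
    reference = np.asarray(reference, dtype=float)
    if reference.shape != (dataset.n_wavenumbers,):
        raise ValueError("reference length must match the wavenumber axis")
    model = MSCModel(
        reference=reference,
        intercept=np.empty(0),
        slope=np.empty(0),
        axis=dataset.axis.copy(),
    )
    a, b = model.fit_coefficients(X)
    bad = (np.ptp(X, axis=1) == 0.0) | (b == 0.0)
    if bad.any():
        warnings.warn(
            f"{int(bad.sum())} scan(s) have undefined MSC correction "
            "(zero slope against the reference); excluded",
            stacklevel=2,
        )
    keep = ~bad
    corrected = (X[keep] - a[keep, None]) / b[keep, None]
    out = dataset.select(keep)
    out.absorbance = corrected
    out.provenance = {**dataset.provenance, "msc": True}
    model.intercept = a[keep]
    model.slope = b[keep]
    return out, model
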