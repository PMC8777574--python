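"""PCA exploration of variability: MSQ patterns, mean spectra, ellipses.

Principal component analysis is used two ways: on the per-lot MSQ vectors
of the nested ANOVA (one row per lot) to compare how variability differs
between lots, and on replicate-mean spectra (one row per lot x subsample x
replicate tube) to explore groupings.  Per-lot spread in the first two
scores is summarised by a standard-error ellipse: center at the lot's
mean score, axes along the local principal directions, radii equal to the
standard error (sd / sqrt(n)) along each direction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from woodvar.dataset import SpectralDataset
from woodvar.errors import DegenerateDataError

_RANK_TOL = 1e-12


@dataclass
class PCAResult:
    """Scores, loadings and explained variance of a fitted PCA.

    ``scores @ loadings.T + center`` reconstructs the best rank-k
    approximation of the input.  Column signs are fixed so the
    largest-magnitude element of every loading column is positive, making
    the output deterministic across runs and platforms.
    """

    scores: np.ndarray
    loadings: np.ndarray
    explained_variance_ratio: np.ndarray
    center: np.ndarray
    total_variance: float
    row_labels: pd.DataFrame | None = None

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]


def fit_pca(matrix, n_components: int | None = None, center: bool = True) -> PCAResult:
    """PCA by singular value decomposition with a deterministic sign fix.

    ``n_components`` defaults to the full rank; if the matrix rank falls
    below the requested count, the available components are returned with
    a warning.  Explained-variance fractions are relative to the total
    variance of the (centered) input.
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2:
        raise ValueError("matrix must be 2-D")
    if not np.all(np.isfinite(X)):
        raise ValueError("matrix contains non-finite values")
    n, p = X.shape
    mu = X.mean(axis=0) if center else np.zeros(p)
    Xc = X - mu
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    total_ss = float((s**2).sum())
    # degenerate when the leading singular value is at rounding level
    tol = np.finfo(float).eps * max(n, p) * max(float(np.abs(X).max()), 1.0)
    if total_ss == 0.0 or s[0] <= tol:
        raise DegenerateDataError("matrix has zero variance; PCA is undefined")
    rank = int((s > _RANK_TOL * s[0]).sum())
    limit = min(n - 1 if center else n, p)
    k = min(n_components if n_components is not None else rank, limit)
    if rank < k:
        warnings.warn(
            f"requested {k} components but matrix rank is {rank}; returning {rank}",
            stacklevel=2,
        )
        k = rank
    U, s, Vt = U[:, :k], s[:k], Vt[:k]
    # sign convention: largest-|x| loading element positive per component
    flip = np.sign(Vt[np.arange(k), np.argmax(np.abs(Vt), axis=1)])
    flip[flip == 0] = 1.0
    Vt = Vt * flip[:, None]
    U = U * flip[None, :]
    return PCAResult(
        scores=U * s[None, :],
        loadings=Vt.T,
        explained_variance_ratio=s**2 / total_ss,
        center=mu,
        total_variance=total_ss / max(n - 1, 1),
    )


def msq_pca(per_lot: dict, level: str, n_components: int | None = None) -> PCAResult:
    """PCA of the per-lot MSQ vectors at one hierarchy level.

    ``per_lot`` maps lot id to a :class:`~woodvar.anova.VarianceDecomposition`
    (as from :func:`~woodvar.anova.per_lot_decomposition`).  Rows are lots,
    columns wavenumbers; the matrix is mean-centered before fitting.  Lots
    whose MSQ is undefined at ``level`` are excluded with a warning.
    """
    lots, rows = [], []
    for lot, dec in per_lot.items():
        if level in dec.undefined:
            warnings.warn(f"lot {lot!r} has undefined MSQ at level {level!r}; excluded",
                          stacklevel=2)
            continue
        lots.append(lot)
        rows.append(np.atleast_1d(dec.msq[level]))
    if len(rows) < 2:
        raise DegenerateDataError("need at least two lots with defined MSQ")
    res = fit_pca(np.vstack(rows), n_components=n_components, center=True)
    res.row_labels = pd.DataFrame({"lot": lots})
    return res


def subsample_mean_pca(dataset: SpectralDataset, n_components: int | None = None) -> PCAResult:
    """PCA of replicate-tube mean spectra, labelled by the hierarchy.

    Rows are the mean spectra per (lot, subsample, replicate) — e.g.
    16 x 8 = 128 rows for the study design — mean-centered before fitting.
    Identical spectra everywhere (zero variance) raise
    :class:`DegenerateDataError`.
    """
    keys = ["lot", "subsample", "replicate"]
    grouped = (
        pd.DataFrame(dataset.absorbance)
        .groupby([dataset.labels[k] for k in keys], sort=True)
        .mean()
    )
    if len(grouped) < 2:
        raise DegenerateDataError("need at least two replicate-mean spectra")
    res = fit_pca(grouped.to_numpy(), n_components=n_components, center=True)
    res.row_labels = grouped.index.to_frame(index=False)
    res.row_labels.columns = keys
    return res


@dataclass
class LotEllipse:
    """Standard-error ellipse of one lot in the first-two-score plane."""

    lot: object
    center: np.ndarray
    directions: np.ndarray  # (2, 2), rows orthonormal
    radii: np.ndarray  # standard errors along the two directions
    n: int


def lot_ellipses(pca_result: PCAResult, lots=None, components=(0, 1)) -> list[LotEllipse]:
    """Per-lot standard-error ellipses from a score plot.

    For every lot with >= 2 points: center = mean score, directions = the
    principal axes of a local PCA on the lot's points, radius_k =
    sd along axis k (ddof = 1) / sqrt(n).  One-point lots are skipped
    with a warning.
    """
    if lots is None:
        if pca_result.row_labels is None or "lot" not in pca_result.row_labels:
            raise ValueError("lot labels required")
        lots = pca_result.row_labels["lot"].to_numpy()
    lots = np.asarray(lots)
    pts = pca_result.scores[:, list(components)]
    out = []
    for lot in pd.unique(lots):
        P = pts[lots == lot]
        n = P.shape[0]
        if n < 2:
            warnings.warn(f"lot {lot!r} has a single point; ellipse undefined", stacklevel=2)
            continue
        center = P.mean(axis=0)
        cov = np.cov(P.T, ddof=1)
        evals, evecs = np.linalg.eigh(np.atleast_2d(cov))
        order = np.argsort(evals)[::-1]
        evals, evecs = np.clip(evals[order], 0.0, None), evecs[:, order]
        # deterministic sign: largest-|x| element of each direction positive
        for j in range(2):
            i = int(np.argmax(np.abs(evecs[:, j])))
            if evecs[i, j] < 0:
                evecs[:, j] = -evecs[:, j]
        out.append(
            LotEllipse(
                lot=lot,
                center=center,
                directions=evecs.T,
                radii=np.sqrt(evals) / np.sqrt(n),
                n=n,
            )
        )
    return out


def ellipses_frame(ellipses: list[LotEllipse]) -> pd.DataFrame:
    """Plot-ready ellipse parameters (one row per lot)."""
    return pd.DataFrame(
        {
            "lot": [e.lot for e in ellipses],
            "cx": [e.center[0] for e in ellipses],
            "cy": [e.center[1] for e in ellipses],
            "dir1x": [e.directions[0, 0] for e in ellipses],
            "dir1y": [e.directions[0, 1] for e in ellipses],
            "dir2x": [e.directions[1, 0] for e in ellipses],
            "dir2y": [e.directions[1, 1] for e in ellipses],
            "r1": [e.radii[0] for e in ellipses],
            "r2": [e.radii[1] for e in ellipses],
            "n": [e.n for e in ellipses],
        }
    )


def replicate_distance(pca_result: PCAResult, labels: pd.DataFrame | None = None,
                       components=(0, 1)) -> pd.DataFrame:
    """Distance between the two replicate points of each subsample.

    Operates in the first-two-score plane of a replicate-mean PCA (rows
    labelled by lot/subsample/replicate).  Subsamples without exactly two
    replicate points are skipped with a warning.  Returns a frame with one
    row per subsample (lot, subsample, distance); the per-lot aggregate is
    the mean over its subsamples (``groupby("lot")["distance"].mean()``).
    """
    if labels is None:
        labels = pca_result.row_labels
    if labels is None:
        raise ValueError("replicate labels required")
    pts = pca_result.scores[:, list(components)]
    rows = []
    for (lot, sub), idx in labels.groupby(["lot", "subsample"], sort=True).groups.items():
        ii = np.asarray(list(idx))
        if ii.size != 2:
            warnings.warn(
                f"subsample {sub!r} has {ii.size} replicate point(s); skipped",
                stacklevel=2,
            )
            continue
        d = float(np.linalg.norm(pts[ii[0]] - pts[ii[1]]))
        rows.append({"lot": lot, "subsample": sub, "distance": d})
    return pd.DataFrame(rows)
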