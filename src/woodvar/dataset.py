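"""In-memory containers: spectral datasets and bound-water-content tables.

A :class:`SpectralDataset` holds an absorbance matrix (scans x wavenumbers),
its wavenumber axis in cm^-1 and one hierarchy label row per scan
(lot, subsample, replicate, scan ordinal).  Labels must form a proper
nesting: every replicate id belongs to exactly one subsample, every
subsample id to exactly one lot.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from woodvar.errors import NestingError

#: Hierarchy level names, outermost first.  The "scan" column is an ordinal
#: within its replicate tube; the matrix row is the deepest sampling unit.
LEVELS = ("lot", "subsample", "replicate", "scan")

LABEL_COLUMNS = list(LEVELS)


def validate_nesting(labels: pd.DataFrame) -> None:
    """Check that hierarchy labels nest properly.

    Raises :class:`NestingError` naming the offending id if a replicate id
    maps to more than one subsample or a subsample id to more than one lot.
    """
    for child, parent in (("replicate", "subsample"), ("subsample", "lot")):
        parents = labels.groupby(child, sort=False)[parent].nunique()
        bad = parents[parents > 1]
        if len(bad):
            raise NestingError(
                f"{child} id {bad.index[0]!r} appears under "
                f"{bad.iloc[0]} distinct {parent}s"
            )


@dataclass
class SpectralDataset:
    """Absorbance matrix with wavenumber axis and per-scan hierarchy labels.

    Parameters
    ----------
    absorbance
        (n_scans, n_wavenumbers) array of absorbance values.
    axis
        Wavenumber axis in cm^-1.  A descending axis is accepted and flipped
        (together with the matrix columns) so the stored axis is ascending.
    labels
        One row per scan with columns ``lot, subsample, replicate, scan``.
    provenance
        Free-form metadata carried through the pipeline.
    """

    absorbance: np.ndarray
    axis: np.ndarray
    labels: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        self.axis = np.asarray(self.axis, dtype=float)
        if self.absorbance.ndim != 2:
            raise ValueError("absorbance must be a 2-D (scans x wavenumbers) array")
        if self.axis.ndim != 1 or self.axis.size != self.absorbance.shape[1]:
            raise ValueError("axis length must match the number of matrix columns")
        d = np.diff(self.axis)
        if np.all(d < 0):  # descending input: normalise to ascending
            self.axis = self.axis[::-1].copy()
            self.absorbance = self.absorbance[:, ::-1].copy()
        elif not np.all(d > 0):
            raise ValueError("wavenumber axis must be strictly monotonic")
        if not isinstance(self.labels, pd.DataFrame):
            raise TypeError("labels must be a pandas DataFrame")
        missing = [c for c in LABEL_COLUMNS if c not in self.labels.columns]
        if missing:
            raise ValueError(f"labels missing columns {missing}")
        if len(self.labels) != self.absorbance.shape[0]:
            raise ValueError("labels must have one row per scan")
        if not np.all(np.isfinite(self.absorbance)):
            raise ValueError("absorbance contains non-finite values")
        self.labels = self.labels.reset_index(drop=True)
        validate_nesting(self.labels)

    # -- basic geometry -------------------------------------------------
    @property
    def n_scans(self) -> int:
        return self.absorbance.shape[0]

    @property
    def n_wavenumbers(self) -> int:
        return self.absorbance.shape[1]

    def unit_counts(self) -> dict[str, int]:
        """Number of distinct units at each hierarchy level (scan = rows)."""
        return {
            "lot": self.labels["lot"].nunique(),
            "subsample": self.labels.groupby(["lot", "subsample"]).ngroups,
            "replicate": self.labels.groupby(["lot", "subsample", "replicate"]).ngroups,
            "scan": self.n_scans,
        }

    # -- selection ------------------------------------------------------
    def select(self, mask: np.ndarray) -> "SpectralDataset":
        """Row subset by boolean mask or integer index array."""
        mask = np.asarray(mask)
        return replace(
            self,
            absorbance=self.absorbance[mask],
            labels=self.labels.iloc[mask].reset_index(drop=True),
            provenance=dict(self.provenance),
        )

    def subset_lot(self, lot) -> "SpectralDataset":
        """All scans of one lot."""
        return self.select((self.labels["lot"] == lot).to_numpy())

    def copy(self) -> "SpectralDataset":
        return replace(
            self,
            absorbance=self.absorbance.copy(),
            axis=self.axis.copy(),
            labels=self.labels.copy(),
            provenance=dict(self.provenance),
        )


@dataclass
class BWCTable:
    """Per-sample duplicate bound-water-content measurements in percent.

    One row per (lot, subsample) with the two gravimetric duplicates
    ``dup1``/``dup2``; the sample value used downstream is their average.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in ("lot", "subsample", "dup1", "dup2") if c not in self.data.columns]
        if missing:
            raise ValueError(f"BWC table missing columns {missing}")
        vals = self.data[["dup1", "dup2"]].to_numpy(float)
        if not np.all(np.isfinite(vals)):
            raise ValueError("BWC table contains non-finite values")
        if np.any(vals <= 0) or np.any(vals >= 100):
            raise ValueError("BWC values must lie strictly between 0 and 100 %")
        self.data = self.data.reset_index(drop=True)

    @property
    def means(self) -> pd.Series:
        """Per-sample mean of the two duplicates (%)."""
        return (self.data["dup1"] + self.data["dup2"]) / 2.0

    def __len__(self) -> int:
        return len(self.data)
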