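"""Readers and writers for the package's flat CSV interchange formats.

Spectra travel as delimited text with four leading label columns
(lot, subsample, replicate, scan) followed by one column per wavenumber,
the header being the wavenumber in cm^-1 (ascending or descending; a
descending file is flipped on load).  BWC tables are
(lot, subsample, dup1, dup2) CSVs.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from woodvar.dataset import LABEL_COLUMNS, BWCTable, SpectralDataset


def write_spectra(dataset: SpectralDataset, path) -> None:
    """Write the canonical spectra CSV (labels + one column per wavenumber)."""
    df = dataset.labels.copy()
    spec = pd.DataFrame(
        dataset.absorbance, columns=[repr(float(w)) for w in dataset.axis]
    )
    pd.concat([df, spec], axis=1).to_csv(path, index=False)


def read_spectra(path) -> SpectralDataset:
    """Read a spectra CSV written by :func:`write_spectra` (or compatible).

    The wavenumber header must be numeric; a descending axis is flipped to
    ascending.  Broken nesting or ragged rows raise a descriptive error.
    """
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.ParserError as exc:
        raise ValueError(f"cannot parse {path}: {exc}") from exc
    missing = [c for c in LABEL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing label columns {missing}")
    wn_cols = [c for c in df.columns if c not in LABEL_COLUMNS]
    try:
        axis = np.array([float(c) for c in wn_cols])
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric wavenumber header: {exc}") from exc
    matrix = df[wn_cols].to_numpy(dtype=float)
    if not np.all(np.isfinite(matrix)):
        bad = int(np.flatnonzero(~np.isfinite(matrix).all(axis=1))[0]) + 2
        raise ValueError(f"{path}: non-finite value near line {bad}")
    return SpectralDataset(
        absorbance=matrix,
        axis=axis,
        labels=df[LABEL_COLUMNS].copy(),
        provenance={"source": str(path)},
    )


def write_bwc(table: BWCTable, path) -> None:
    table.data[["lot", "subsample", "dup1", "dup2"]].to_csv(path, index=False)


def read_bwc(path) -> BWCTable:
    return BWCTable(pd.read_csv(path, float_precision="round_trip"))


def dataset_hash(dataset: SpectralDataset) -> str:
    """Stable content hash of matrix + axis + labels (for provenance)."""
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(dataset.axis).tobytes())
    h.update(np.ascontiguousarray(dataset.absorbance).tobytes())
    h.update(dataset.labels.to_csv(index=False).encode())
    return h.hexdigest()


def write_sidecar(path, **fields) -> None:
    """JSON sidecar recording preprocessing metadata (trim bounds, counts, ...)."""
    with open(path, "w") as fh:
        json.dump(fields, fh, indent=1, default=str)


def load_study_archive(directory) -> tuple[SpectralDataset, BWCTable | None]:
    """Adapter for a locally stored copy of the study's deposited dataset.

    The deposit (DOI 10.5281/zenodo.4896579) must be converted to the
    canonical CSV layout and placed in ``directory`` as ``spectra.csv``
    and, if present, ``bwc.csv``.  The contract is by content, not by the
    deposit's native file format: the loader only promises to yield a
    :class:`SpectralDataset` (and a :class:`BWCTable` when duplicates are
    available).
    """
    directory = Path(directory)
    spectra = directory / "spectra.csv"
    if not spectra.exists():
        raise FileNotFoundError(
            f"no spectra.csv under {directory}; place a CSV-converted copy of "
            "the deposited dataset there"
        )
    ds = read_spectra(spectra)
    bwc_path = directory / "bwc.csv"
    table = read_bwc(bwc_path) if bwc_path.exists() else None
    return ds, table
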