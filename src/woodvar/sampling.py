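"""Resampling procedure for deciding how many subsamples/replicates/scans.

How many scans must be acquired — and over how many subsamples — before
the measured variability of a lot stabilises?  The procedure draws ``n``
scans from one lot under five constraint levels, recomputes the nested
ANOVA on each draw, summarises the per-wavenumber MSQ to one scalar, and
repeats (default 100 times) to measure the spread of that summary:

* level A — one subsample, its two replicate tubes represented equally
  (the tubes act as two groups);
* level B — one subsample, tubes pooled;
* level C — two subsamples represented equally;
* level D — three subsamples represented equally;
* level E — scans drawn freely across all subsamples.

The spread shrinks as ``n`` grows; levels that cover only one subsample
plateau *below* the lot's overall variability because between-subsample
variance never enters their pool.  The default summary statistic is the
total mean square of the selection (sum of squares about the selection's
grand mean divided by n - 1, averaged over wavenumbers): it is the one
summary for which an exhaustive level-E draw equals the lot's overall
variability exactly, and it exposes the missing between-subsample
variance at levels A/B.  ``"scan"``, ``"all_levels"`` and ``"max"``
summaries are selectable.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from woodvar.anova import VarianceDecomposition, nested_decomposition
from woodvar.dataset import SpectralDataset
from woodvar.errors import SelectionError

#: Scan-count grids per constraint level (full-design totals 210/420/840/
#: 1,260/1,680 scans for 2 tubes x 210 scans per subsample).
DEFAULT_N_GRIDS: dict[str, list[int]] = {
    "A": [25, 50, 75, 100, 125, 150],
    "B": [25, 50, 75, 100, 150, 200, 250, 300],
    "C": [25, 50, 100, 150, 200, 300, 400, 600],
    "D": [25, 50, 100, 150, 250, 400, 600, 900],
    "E": [25, 50, 100, 150, 250, 500, 750, 1000],
}

#: Number of subsamples drawn on per level (None = all available).
LEVEL_SUBSAMPLES: dict[str, int | None] = {"A": 1, "B": 1, "C": 2, "D": 3, "E": None}

SUMMARIES = ("total", "scan", "all_levels", "max")


@dataclass
class ResamplingSpec:
    """One level's resampling request.

    ``subsamples`` fixes the subsample combination; when None (default)
    each repetition draws a combination uniformly from all possibilities,
    so the estimate pools over the arbitrary subsample choice.
    """

    level: str
    n_grid: list[int] | None = None
    repetitions: int = 100
    seed: int = 0
    subsamples: tuple | None = None
    summary: str = "total"

    def __post_init__(self) -> None:
        if self.level not in DEFAULT_N_GRIDS:
            raise ValueError(f"level must be one of A-E, got {self.level!r}")
        if self.n_grid is None:
            self.n_grid = list(DEFAULT_N_GRIDS[self.level])
        if self.repetitions < 2:
            raise ValueError("repetitions must be >= 2")
        if self.summary not in SUMMARIES:
            raise ValueError(f"summary must be one of {SUMMARIES}, got {self.summary!r}")


@dataclass
class ResamplingResult:
    """Per-repetition summaries and their spread for one level."""

    level: str
    records: pd.DataFrame  # columns: level, n, repetition, summary_msq
    spread: pd.DataFrame  # columns: level, n, mean, sd, min, max
    reference: float
    spec: ResamplingSpec = field(repr=False, default=None)


def _split_counts(n: int, groups: list) -> dict:
    """Equal counts per group; remainder assigned in label (sorted) order."""
    g = len(groups)
    base, rem = divmod(n, g)
    return {grp: base + (1 if i < rem else 0) for i, grp in enumerate(sorted(groups, key=str))}


def select_scans(
    dataset: SpectralDataset,
    level: str,
    n: int,
    rng: np.random.Generator,
    subsamples=None,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw ``n`` scans of one lot under a constraint level.

    Returns the selected row indices and a grouping label per selected
    scan, chosen so that a nested ANOVA on the selection sees the
    level-appropriate hierarchy (tubes for level A, subsamples otherwise).
    Draws are without replacement; non-divisible ``n`` is split with the
    remainder assigned to groups in sorted label order.
    """
    labels = dataset.labels
    if labels["lot"].nunique() != 1:
        raise SelectionError("select_scans operates on a single lot")
    all_subs = sorted(pd.unique(labels["subsample"]), key=str)
    want = LEVEL_SUBSAMPLES[level]
    if subsamples is None:
        k = len(all_subs) if want is None else want
        if k > len(all_subs):
            raise SelectionError(f"level {level} needs {k} subsamples, lot has {len(all_subs)}")
        chosen = list(rng.choice(len(all_subs), size=k, replace=False))
        subsamples = [all_subs[i] for i in sorted(chosen)]
    else:
        subsamples = sorted(subsamples, key=str)
        if want is not None and len(subsamples) != want:
            raise SelectionError(
                f"level {level} uses {want} subsample(s), got {len(subsamples)}"
            )
    mask = labels["subsample"].isin(subsamples).to_numpy()
    pool = np.flatnonzero(mask)
    if n > pool.size:
        raise SelectionError(f"n = {n} exceeds the level-{level} pool of {pool.size} scans")

    if level == "A":
        sub = subsamples[0]
        tube_of = labels["replicate"].to_numpy()
        tubes = sorted(pd.unique(labels.loc[mask, "replicate"]), key=str)
        counts = _split_counts(n, tubes)
        groups_by = {t: pool[tube_of[pool] == t] for t in tubes}
    elif level == "B":
        counts = {subsamples[0]: n}
        groups_by = {subsamples[0]: pool}
    else:  # C, D, E
        sub_of = labels["subsample"].to_numpy()
        if level == "E":
            # free draw over the whole pool, then label by membership
            idx = np.sort(rng.choice(pool, size=n, replace=False))
            return idx, sub_of[idx]
        counts = _split_counts(n, subsamples)
        groups_by = {s: pool[sub_of[pool] == s] for s in subsamples}

    picks = []
    grp_labels = []
    for grp in sorted(groups_by, key=str):
        c = counts[grp]
        avail = groups_by[grp]
        if c > avail.size:
            raise SelectionError(
                f"group {grp!r} has {avail.size} scans, {c} requested at level {level}"
            )
        sel = rng.choice(avail, size=c, replace=False)
        picks.append(sel)
        grp_labels.append(np.full(c, grp, dtype=object))
    idx = np.concatenate(picks)
    grp = np.concatenate(grp_labels)
    order = np.argsort(idx, kind="stable")
    return idx[order], grp[order]


def _summarize(dec: VarianceDecomposition, kind: str) -> float:
    if kind == "total":
        return float(np.mean(dec.total_msq()))
    if kind == "scan":
        return float(np.mean(dec.msq["scan"]))
    if kind == "all_levels":
        vals = [dec.msq_mean(lvl) for lvl in dec.levels if lvl not in dec.undefined]
        return float(np.mean(vals))
    if kind == "max":
        return float(np.max(dec.total_msq()))
    raise ValueError(f"unknown summary {kind!r}")


def overall_variability(dataset: SpectralDataset, summary: str = "total") -> float:
    """The lot's reference variability under the chosen summary statistic.

    Computed from the full-data decomposition of the lot with scans
    grouped by subsample (the exhaustive level-E hierarchy), so that an
    unconstrained draw of the complete pool reproduces it exactly.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        dec = nested_decomposition(dataset.absorbance, dataset.labels[["subsample"]])
    return _summarize(dec, summary)


def resample_msq(dataset: SpectralDataset, spec: ResamplingSpec) -> ResamplingResult:
    """Run the repeated-selection nested ANOVA for one constraint level.

    For every ``n`` in the grid and every repetition: draw a (possibly
    random) subsample combination, select ``n`` scans under the level's
    constraints, decompose, and summarise the MSQ to one scalar.  Fully
    reproducible under ``spec.seed``.  A repetition whose group
    constraints cannot be met raises :class:`SelectionError` (no silent
    skipping).
    """
    rng = np.random.default_rng(spec.seed)
    rows = []
    for n in spec.n_grid:
        for rep in range(spec.repetitions):
            idx, grp = select_scans(dataset, spec.level, int(n), rng,
                                    subsamples=spec.subsamples)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                dec = nested_decomposition(
                    dataset.absorbance[idx],
                    pd.DataFrame({"group": grp}),
                )
            rows.append(
                {
                    "level": spec.level,
                    "n": int(n),
                    "repetition": rep,
                    "summary_msq": _summarize(dec, spec.summary),
                }
            )
    records = pd.DataFrame(rows)
    spread = (
        records.groupby(["level", "n"], sort=True)["summary_msq"]
        .agg(mean="mean", sd=lambda s: s.std(ddof=1), min="min", max="max")
        .reset_index()
    )
    return ResamplingResult(
        level=spec.level,
        records=records,
        spread=spread,
        reference=overall_variability(dataset, spec.summary),
        spec=spec,
    )


def recommend_design(
    results: dict[str, ResamplingResult],
    tolerance: float = 0.1,
    undershoot_margin: float = 0.05,
) -> dict:
    """Smallest adequate ``n`` per level, with plateau and undershoot flags.

    For each level the plateau spread is the repetition sd at the largest
    ``n``; the recommended ``n`` is the smallest whose sd is within
    ``tolerance`` (relative) of the plateau.  A level whose plateau mean
    summary falls more than ``undershoot_margin`` (relative) below the
    overall-variability reference is flagged as undershooting — it cannot
    see part of the lot's variability (levels restricted to one
    subsample).  A level whose spread rises back above the band after the
    recommended ``n`` is marked unstable.  The overall pick is the stable,
    non-undershooting level with the smallest recommended ``n``.
    """
    per_level = {}
    for level, res in results.items():
        sp = res.spread.sort_values("n")
        ns = sp["n"].to_numpy()
        sds = sp["sd"].to_numpy()
        means = sp["mean"].to_numpy()
        plateau_sd = sds[-1]
        band = (1.0 + tolerance) * plateau_sd
        ok = sds <= band
        rec_i = int(np.argmax(ok))  # first True; last entry is always True
        rec_n = int(ns[rec_i])
        unstable = bool(np.any(~ok[rec_i:]))
        undershoot = bool(means[-1] < (1.0 - undershoot_margin) * res.reference)
        groups = {"A": 2, "B": 1, "C": 2, "D": 3, "E": 4}[level]
        per_level[level] = {
            "n": rec_n,
            "per_group": int(np.ceil(rec_n / groups)),
            "plateau_sd": float(plateau_sd),
            "plateau_mean": float(means[-1]),
            "reference": float(res.reference),
            "undershoots_reference": undershoot,
            "unstable": unstable,
        }
    eligible = {
        lvl: rec
        for lvl, rec in per_level.items()
        if not rec["undershoots_reference"] and not rec["unstable"]
    }
    chosen = min(eligible, key=lambda lvl: eligible[lvl]["n"]) if eligible else None
    return {"per_level": per_level, "recommended_level": chosen,
            "recommended_n": per_level[chosen]["n"] if chosen else None}


def level_pool_size(dataset: SpectralDataset, level: str) -> int:
    """Scans guaranteed available to the level, whatever combination is drawn.

    The minimum over subsample combinations: k smallest subsample scan
    counts summed (all subsamples for level E).
    """
    counts = dataset.labels.groupby("subsample").size().sort_values()
    k = LEVEL_SUBSAMPLES[level]
    if k is None:
        return int(counts.sum())
    return int(counts.iloc[:k].sum())


def subsample_combinations(dataset: SpectralDataset, level: str):
    """All subsample combinations a level can draw on (sorted, deterministic)."""
    subs = sorted(pd.unique(dataset.labels["subsample"]), key=str)
    k = LEVEL_SUBSAMPLES[level]
    if k is None:
        return [tuple(subs)]
    return list(itertools.combinations(subs, k))
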