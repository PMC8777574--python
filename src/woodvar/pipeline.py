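"""End-to-end pipeline: trim -> artifact filter -> MSC -> ANOVA -> PCA -> design.

:func:`run_pipeline` chains every stage on one dataset and returns the
result bundle as a dict; when an output directory is given, each stage's
tables plus a provenance record (config echo, seed, per-stage scan
counts) are written as CSV/JSON.  No stage mutates its input files.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from woodvar import io
from woodvar.anova import nested_decomposition, normalize_msq, per_lot_decomposition
from woodvar.bwc import bwc_descriptives, bwc_nested_anova, lot_ranges, tukey_outliers
from woodvar.dataset import BWCTable, SpectralDataset
from woodvar.errors import DegenerateDataError
from woodvar.pca import (
    ellipses_frame,
    lot_ellipses,
    msq_pca,
    replicate_distance,
    subsample_mean_pca,
)
from woodvar.preprocess import detect_artifact_scans, drop_flagged, msc, trim_wavenumbers
from woodvar.sampling import (
    ResamplingSpec,
    level_pool_size,
    recommend_design,
    resample_msq,
)

log = logging.getLogger("woodvar.pipeline")


@dataclass
class PipelineConfig:
    """Everything the end-to-end run needs; YAML/JSON round-trippable."""

    spectra_path: str | None = None
    bwc_path: str | None = None
    trim_low: float = 3880.0
    trim_high: float = 9000.0
    artifact_corr_threshold: float = 0.5
    artifact_abs_floor: float = 0.05
    apply_msc: bool = True
    weighted: bool = False
    n_components: int = 2
    sampling_lot: str | None = None
    sampling_levels: tuple = ("A", "B", "C", "D", "E")
    sampling_n_grids: dict | None = None
    repetitions: int = 100
    summary: str = "total"
    tukey_k: float = 3.0
    seed: int = 0
    out_dir: str | None = None

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)
        if "sampling_levels" in data:
            data["sampling_levels"] = tuple(data["sampling_levels"])
        return cls(**data)


def run_pipeline(
    config: PipelineConfig,
    dataset: SpectralDataset | None = None,
    bwc_table: BWCTable | None = None,
) -> dict:
    """Execute the full analysis; returns the result bundle.

    Stage failures abort with the stage name in the exception message.
    Degenerate inputs (e.g. a zero-variance dataset) do not abort: the PCA
    stages record the degeneracy instead of fitting.
    """
    counts: dict = {}
    bundle: dict = {"config": config}

    if dataset is None:
        if config.spectra_path is None:
            raise ValueError("stage load: neither a dataset nor spectra_path given")
        dataset = io.read_spectra(config.spectra_path)
    if bwc_table is None and config.bwc_path is not None:
        bwc_table = io.read_bwc(config.bwc_path)
    counts["loaded"] = dataset.n_scans
    log.info("stage=load scans=%d wavenumbers=%d", dataset.n_scans, dataset.n_wavenumbers)

    ds = trim_wavenumbers(dataset, config.trim_low, config.trim_high)
    counts["after_trim"] = ds.n_scans
    counts["wavenumbers_retained"] = ds.n_wavenumbers
    log.info("stage=trim wavenumbers=%d", ds.n_wavenumbers)

    flags = detect_artifact_scans(
        ds,
        corr_threshold=config.artifact_corr_threshold,
        abs_floor=config.artifact_abs_floor,
    )
    ds, n_dropped = drop_flagged(ds, flags)
    counts["artifacts_dropped"] = n_dropped
    counts["after_filter"] = ds.n_scans
    log.info("stage=artifact_filter dropped=%d", n_dropped)

    msc_model = None
    if config.apply_msc:
        ds, msc_model = msc(ds)
        counts["after_msc"] = ds.n_scans
        log.info("stage=msc scans=%d", ds.n_scans)
    bundle["dataset"] = ds
    bundle["msc_model"] = msc_model

    decomposition = nested_decomposition(
        ds.absorbance,
        ds.labels[["lot", "subsample", "replicate"]],
        weighted=config.weighted,
    )
    bundle["decomposition"] = decomposition
    bundle["normalized_msq"] = normalize_msq(decomposition, ["lot", "subsample"])
    per_lot = per_lot_decomposition(ds, weighted=config.weighted)
    bundle["per_lot"] = per_lot
    log.info("stage=anova lots=%d", len(per_lot))

    try:
        bundle["pca_msq_subsample"] = msq_pca(per_lot, "subsample", config.n_components)
        bundle["pca_msq_replicate"] = msq_pca(per_lot, "replicate", config.n_components)
        pca_spec = subsample_mean_pca(ds)
        bundle["pca_spectra"] = pca_spec
        bundle["ellipses"] = lot_ellipses(pca_spec)
        bundle["replicate_distances"] = replicate_distance(pca_spec)
        counts["pca_rows"] = pca_spec.scores.shape[0]
    except DegenerateDataError as exc:
        bundle["pca_degenerate"] = str(exc)
        log.info("stage=pca degenerate=%s", exc)

    lot_id = config.sampling_lot
    if lot_id is None:
        # focus the design study on the most variable lot (subsample-level MSQ)
        lot_id = max(
            per_lot,
            key=lambda l: (
                -np.inf
                if "subsample" in per_lot[l].undefined
                else float(np.mean(per_lot[l].msq["subsample"]))
            ),
        )
    lot_ds = ds.subset_lot(lot_id)
    sampling_results = {}
    for i, level in enumerate(config.sampling_levels):
        grid = None
        if config.sampling_n_grids is not None:
            grid = config.sampling_n_grids.get(level)
        pool = level_pool_size(lot_ds, level)  # clip to the level's pool
        spec = ResamplingSpec(
            level=level,
            n_grid=grid,
            repetitions=config.repetitions,
            seed=config.seed + i,
            summary=config.summary,
        )
        spec.n_grid = [n for n in spec.n_grid if n <= pool] or [pool]
        sampling_results[level] = resample_msq(lot_ds, spec)
    bundle["sampling"] = sampling_results
    bundle["sampling_lot"] = lot_id
    bundle["recommendation"] = recommend_design(sampling_results)
    log.info("stage=sampling lot=%s", lot_id)

    if bwc_table is not None:
        flags, fences = tukey_outliers(bwc_table.means.to_numpy(), k=config.tukey_k)
        ranges, avg = lot_ranges(bwc_table)
        bundle["bwc"] = {
            "descriptives": bwc_descriptives(bwc_table),
            "outlier_flags": flags,
            "fences": fences,
            "lot_ranges": ranges,
            "average_lot_range": avg,
            "anova": bwc_nested_anova(bwc_table),
        }
        counts["bwc_samples"] = len(bwc_table)
        log.info("stage=bwc samples=%d", len(bwc_table))

    provenance = {
        "config": _jsonable(asdict(config)),
        "seed": config.seed,
        "counts": counts,
        "dataset_hash": io.dataset_hash(ds),
    }
    bundle["provenance"] = provenance

    if config.out_dir is not None:
        _write_bundle(bundle, Path(config.out_dir))
    return bundle


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def _write_bundle(bundle: dict, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    ds = bundle["dataset"]
    dec = bundle["decomposition"]
    dec.to_frame(ds.axis).to_csv(out / "anova_global.csv", index=False)
    per_lot_rows = []
    for lot, d in bundle["per_lot"].items():
        f = d.to_frame(ds.axis)
        f.insert(0, "lot", lot)
        per_lot_rows.append(f)
    pd.concat(per_lot_rows, ignore_index=True).to_csv(out / "anova_per_lot.csv", index=False)
    for name in ("pca_msq_subsample", "pca_msq_replicate", "pca_spectra"):
        if name in bundle:
            res = bundle[name]
            scores = pd.DataFrame(
                res.scores, columns=[f"PC{i + 1}" for i in range(res.n_components)]
            )
            if res.row_labels is not None:
                scores = pd.concat([res.row_labels.reset_index(drop=True), scores], axis=1)
            scores.to_csv(out / f"{name}_scores.csv", index=False)
            pd.DataFrame(
                res.loadings, columns=[f"PC{i + 1}" for i in range(res.n_components)]
            ).to_csv(out / f"{name}_loadings.csv", index=False)
    if "ellipses" in bundle:
        ellipses_frame(bundle["ellipses"]).to_csv(out / "lot_ellipses.csv", index=False)
    if "replicate_distances" in bundle:
        bundle["replicate_distances"].to_csv(out / "replicate_distances.csv", index=False)
    all_records = pd.concat([r.records for r in bundle["sampling"].values()], ignore_index=True)
    all_records.to_csv(out / "sampling_records.csv", index=False)
    all_spread = pd.concat([r.spread for r in bundle["sampling"].values()], ignore_index=True)
    all_spread.to_csv(out / "sampling_spread.csv", index=False)
    with open(out / "recommendation.json", "w") as fh:
        json.dump(_jsonable(bundle["recommendation"]), fh, indent=1)
    if "bwc" in bundle:
        b = bundle["bwc"]
        with open(out / "bwc_summary.json", "w") as fh:
            json.dump(
                _jsonable(
                    {
                        "descriptives": b["descriptives"],
                        "fences": b["fences"],
                        "n_outliers": int(np.sum(b["outlier_flags"])),
                        "average_lot_range": b["average_lot_range"],
                        "msq": {k: b["anova"].msq[k] for k in b["anova"].levels},
                    }
                ),
                fh,
                indent=1,
            )
    with open(out / "provenance.json", "w") as fh:
        json.dump(_jsonable(bundle["provenance"]), fh, indent=1)
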