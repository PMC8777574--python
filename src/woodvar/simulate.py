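"""Synthetic hierarchical NIR-like spectra with known ground truth.

The generator emulates the structure of a hierarchical sampling campaign on
shredded waste wood: material lots, scooped subsamples, replicate measuring
tubes and individual FT-NIR scans (defaults 16 x 4 x 2 x 210).  Spectra are
built from Gaussian absorption bands of the main wood constituents
(cellulose, hemicellulose, lignin, bound water) plus weak glue/urea-resin
bands typical of composite wood.  Composition varies through log-normal
peak-amplitude multipliers with independent random effects at every
hierarchy level; each scan additionally receives multiplicative/additive
scatter (so that MSC has something to correct) and white noise.  Bound
water content (BWC, %) is drawn per sample and drives the water-band
amplitude, so reference chemistry and spectra are coupled.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from woodvar.dataset import BWCTable, SpectralDataset
from woodvar.errors import ConfigError

#: (component, center cm^-1, width cm^-1, base amplitude).  Centers follow
#: standard NIR band assignments for lignocellulose: 1st overtone O-H
#: stretch of cellulose/hemicellulose near 6,800; the water combination
#: band at 5,189 and its 1st O-H overtone near 6,950; cellulose O-H/C-H
#: combinations at 4,760/4,397/4,281; lignin C-H + C-C at 4,004; and
#: methyl/methylene/NH glue bands (5,805, 5,624, 4,617, 4,440).
DEFAULT_PEAK_TABLE: list[tuple[str, float, float, float]] = [
    ("cellulose", 6797.0, 110.0, 0.40),
    ("cellulose", 4760.0, 70.0, 0.55),
    ("cellulose", 4397.0, 55.0, 0.50),
    ("cellulose", 4281.0, 45.0, 0.60),
    ("hemicellulose", 4285.0, 60.0, 0.25),
    ("hemicellulose", 4740.0, 90.0, 0.20),
    ("lignin", 4004.0, 60.0, 0.35),
    ("lignin", 4280.0, 45.0, 0.12),
    ("water", 5189.0, 80.0, 0.70),
    ("water", 6950.0, 120.0, 0.40),
    ("glue", 5805.0, 60.0, 0.12),
    ("glue", 5624.0, 55.0, 0.10),
    ("glue", 4617.0, 50.0, 0.12),
    ("glue", 4440.0, 45.0, 0.10),
]

#: Component whose amplitude is tied to the bound-water content.
WATER = "water"


@dataclass
class SimulationConfig:
    """Generator settings; defaults mirror the study design.

    ``variance_components`` are variances of the zero-mean Gaussian
    log-amplitude effects drawn per unit at each level; ``scatter_slope_sd``
    is the sd of the per-scan log multiplicative scatter factor and
    ``scatter_offset_sd`` the sd of the per-scan additive offset.  BWC is
    drawn as mean + lot effect + subsample effect (sd in %); each sample is
    "measured" twice with duplicate noise ``bwc_dup_sd``.
    """

    n_lots: int = 16
    n_subsamples_per_lot: int = 4
    n_replicates_per_subsample: int = 2
    n_scans_per_replicate: int = 210
    wavenumber_start: float = 3700.0
    wavenumber_end: float = 14885.0
    wavenumber_step: float = 8.0
    peak_table: list = field(default_factory=lambda: list(DEFAULT_PEAK_TABLE))
    variance_components: dict = field(
        default_factory=lambda: {
            "lot": 0.020,
            "subsample": 0.003,
            "replicate": 0.005,
            "scan": 0.001,
        }
    )
    scatter_slope_sd: float = 0.08
    scatter_offset_sd: float = 0.03
    additive_noise_sd: float = 0.003
    baseline: float = 0.15
    bwc_mean: float = 8.0
    bwc_sd_lot: float = 0.632
    bwc_sd_subsample: float = 0.441
    bwc_dup_sd: float = 0.0267
    bwc_lot_sd_scale: dict = field(default_factory=dict)
    artifact_rate: float = 0.0
    artifact_kind: str = "mixed"
    seed: int = 0

    def validate(self) -> None:
        for name in (
            "n_lots",
            "n_subsamples_per_lot",
            "n_replicates_per_subsample",
            "n_scans_per_replicate",
        ):
            if int(getattr(self, name)) < 1:
                raise ConfigError(f"{name} must be >= 1, got {getattr(self, name)}")
        if self.wavenumber_step <= 0:
            raise ConfigError(f"wavenumber_step must be > 0, got {self.wavenumber_step}")
        if self.wavenumber_end <= self.wavenumber_start:
            raise ConfigError("wavenumber_end must exceed wavenumber_start")
        for lvl, v in self.variance_components.items():
            if v < 0:
                raise ConfigError(f"variance_components[{lvl!r}] must be >= 0, got {v}")
        for name in ("scatter_slope_sd", "scatter_offset_sd", "additive_noise_sd",
                     "bwc_sd_lot", "bwc_sd_subsample", "bwc_dup_sd"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0, got {getattr(self, name)}")
        if not (0.0 <= self.artifact_rate < 1.0):
            raise ConfigError(f"artifact_rate must be in [0, 1), got {self.artifact_rate}")
        if self.artifact_kind not in ("air", "lid", "mixed"):
            raise ConfigError(f"artifact_kind must be air|lid|mixed, got {self.artifact_kind!r}")
        if not (0 < self.bwc_mean < 100):
            raise ConfigError(f"bwc_mean must be in (0, 100) %, got {self.bwc_mean}")
        for row in self.peak_table:
            comp, center, width, amp = row
            if width <= 0:
                raise ConfigError(f"peak width must be > 0 for {comp} @ {center}")
            if amp < 0:
                raise ConfigError(f"peak amplitude must be >= 0 for {comp} @ {center}")

    def axis(self) -> np.ndarray:
        """Ascending wavenumber grid implied by start/end/step."""
        n = int(np.floor((self.wavenumber_end - self.wavenumber_start) / self.wavenumber_step)) + 1
        return self.wavenumber_start + self.wavenumber_step * np.arange(n)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["peak_table"] = [list(r) for r in self.peak_table]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "peak_table" in d:
            d["peak_table"] = [tuple(r) for r in d["peak_table"]]
        return cls(**d)


@dataclass
class GroundTruth:
    """What the generator actually drew.

    ``effects`` has one row per unit per level (columns level, unit,
    effect) with the log-amplitude random effects; ``artifact_indices``
    lists the scan rows replaced by air/lid profiles; ``bwc_true`` holds
    the noise-free per-sample BWC (%).
    """

    effects: pd.DataFrame
    artifact_indices: list
    bwc_true: pd.DataFrame

    def level_effects(self, level: str) -> np.ndarray:
        return self.effects.loc[self.effects["level"] == level, "effect"].to_numpy()

    def to_json(self, path) -> None:
        payload = {
            "effects": self.effects.to_dict(orient="list"),
            "artifact_indices": [int(i) for i in self.artifact_indices],
            "bwc_true": self.bwc_true.to_dict(orient="list"),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def peak_basis(axis: np.ndarray, peak_table) -> dict[str, np.ndarray]:
    """Gaussian-mixture component spectra on ``axis``.

    Returns one nonnegative spectrum per component label, the sum of that
    component's Gaussians (height = base amplitude at the stated center).
    Peaks whose center falls outside the axis range are skipped with a
    warning.
    """
    axis = np.asarray(axis, dtype=float)
    if axis.ndim != 1 or axis.size < 2 or not (
        np.all(np.diff(axis) > 0) or np.all(np.diff(axis) < 0)
    ):
        raise ValueError("axis must be a strictly monotonic vector")
    lo, hi = min(axis[0], axis[-1]), max(axis[0], axis[-1])
    out: dict[str, np.ndarray] = {}
    for comp, center, width, amp in peak_table:
        if not (lo <= center <= hi):
            warnings.warn(
                f"peak {comp} @ {center} cm^-1 outside axis range "
                f"[{lo}, {hi}]; skipped",
                stacklevel=2,
            )
            continue
        g = amp * np.exp(-0.5 * ((axis - center) / width) ** 2)
        out[comp] = out.get(comp, np.zeros_like(axis)) + g
    return out


def _artifact_profiles(axis: np.ndarray, rng: np.random.Generator, n_air: int, n_lid: int):
    """Low, near-flat "air" scans and chemically alien "plastic lid" scans."""
    p = axis.size
    air = 0.02 + 0.002 * rng.standard_normal((n_air, p))
    air = np.clip(air, 1e-4, None)
    lid_shape = (
        0.45
        + 0.9 * np.exp(-0.5 * ((axis - 5750.0) / 220.0) ** 2)
        + 0.5 * np.exp(-0.5 * ((axis - 8700.0) / 180.0) ** 2)
    )
    lid = lid_shape[None, :] * np.exp(0.05 * rng.standard_normal((n_lid, 1)))
    lid = lid + 0.003 * rng.standard_normal((n_lid, p))
    return air, np.clip(lid, 1e-4, None)


def inject_artifacts(
    dataset: SpectralDataset,
    rate: float,
    kind: str = "mixed",
    seed: int | None = 0,
) -> tuple[SpectralDataset, list[int]]:
    """Replace a fraction of scans by air/lid artifact profiles.

    The number replaced is ``floor(rate * n_scans + 0.5)`` (round half up);
    indices are drawn without replacement and returned sorted.  ``kind``
    chooses the profile ("air", "lid", or an even random "mixed").
    """
    if not (0.0 <= rate < 1.0):
        raise ConfigError(f"artifact_rate must be in [0, 1), got {rate}")
    n = dataset.n_scans
    count = int(np.floor(rate * n + 0.5))
    if count == 0:
        return dataset.copy(), []
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(n, size=count, replace=False))
    if kind == "air":
        is_air = np.ones(count, dtype=bool)
    elif kind == "lid":
        is_air = np.zeros(count, dtype=bool)
    elif kind == "mixed":
        is_air = rng.random(count) < 0.5
    else:
        raise ConfigError(f"artifact kind must be air|lid|mixed, got {kind!r}")
    air, lid = _artifact_profiles(dataset.axis, rng, int(is_air.sum()), int((~is_air).sum()))
    out = dataset.copy()
    out.absorbance[idx[is_air]] = air
    out.absorbance[idx[~is_air]] = lid
    return out, [int(i) for i in idx]


def generate_dataset(
    config: SimulationConfig,
) -> tuple[SpectralDataset, BWCTable, GroundTruth]:
    """Draw a full hierarchical dataset, its BWC table and the ground truth.

    Deterministic: the same config (including seed) reproduces the output
    bit for bit.  Clean spectra (before scatter/noise/artifacts) are
    nonnegative by construction: baseline plus positive-amplitude Gaussians
    scaled by log-normal multipliers.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    axis = config.axis()
    basis = peak_basis(axis, config.peak_table)
    water = basis.get(WATER, np.zeros_like(axis))
    other = np.zeros_like(axis)
    for comp, spec in basis.items():
        if comp != WATER:
            other = other + spec

    L = config.n_lots
    S = config.n_subsamples_per_lot
    R = config.n_replicates_per_subsample
    K = config.n_scans_per_replicate
    n = L * S * R * K

    sd = {lvl: float(np.sqrt(v)) for lvl, v in config.variance_components.items()}
    e_lot = rng.normal(0.0, sd["lot"], L)
    e_sub = rng.normal(0.0, sd["subsample"], (L, S))
    e_rep = rng.normal(0.0, sd["replicate"], (L, S, R))
    e_scan = rng.normal(0.0, sd["scan"], (L, S, R, K))

    # BWC: mean + lot + subsample effects; per-lot sd scale lets a single
    # lot's within-lot water variability be inflated on purpose.
    b_lot = rng.normal(0.0, config.bwc_sd_lot, L)
    b_sub = rng.normal(0.0, config.bwc_sd_subsample, (L, S))
    lot_ids = [f"L{i + 1:02d}" for i in range(L)]
    for lot, factor in config.bwc_lot_sd_scale.items():
        li = lot_ids.index(lot) if isinstance(lot, str) else int(lot) - 1
        b_sub[li] *= float(factor)
    bwc = np.clip(config.bwc_mean + b_lot[:, None] + b_sub, 0.5, 99.0)

    # per-scan log-amplitude multiplier, broadcast over the hierarchy
    log_mult = (
        e_lot[:, None, None, None]
        + e_sub[:, :, None, None]
        + e_rep[:, :, :, None]
        + e_scan
    ).reshape(n)
    mult = np.exp(log_mult)
    water_scale = np.repeat((bwc / config.bwc_mean).reshape(L * S), R * K)

    clean = (
        config.baseline
        + mult[:, None] * other[None, :]
        + (mult * water_scale)[:, None] * water[None, :]
    )

    slope = np.exp(rng.normal(0.0, config.scatter_slope_sd, n))
    offset = rng.normal(0.0, config.scatter_offset_sd, n)
    noise = rng.normal(0.0, config.additive_noise_sd, (n, axis.size))
    observed = slope[:, None] * clean + offset[:, None] + noise

    sub_ids = [f"{l}S{j + 1}" for l in lot_ids for j in range(S)]
    rep_ids = [f"{s}T{r + 1}" for s in sub_ids for r in range(R)]
    labels = pd.DataFrame(
        {
            "lot": np.repeat(lot_ids, S * R * K),
            "subsample": np.repeat(sub_ids, R * K),
            "replicate": np.repeat(rep_ids, K),
            "scan": np.tile(np.arange(1, K + 1), L * S * R),
        }
    )

    dataset = SpectralDataset(
        absorbance=observed,
        axis=axis,
        labels=labels,
        provenance={"generator": "woodvar.simulate", "seed": config.seed},
    )

    artifact_indices: list[int] = []
    if config.artifact_rate > 0:
        dataset, artifact_indices = inject_artifacts(
            dataset,
            config.artifact_rate,
            kind=config.artifact_kind,
            seed=int(rng.integers(0, 2**31 - 1)),
        )

    dup = rng.normal(0.0, config.bwc_dup_sd, (L * S, 2))
    flat_bwc = bwc.reshape(L * S)
    bwc_table = BWCTable(
        pd.DataFrame(
            {
                "lot": np.repeat(lot_ids, S),
                "subsample": sub_ids,
                "dup1": flat_bwc + dup[:, 0],
                "dup2": flat_bwc + dup[:, 1],
            }
        )
    )

    effects = pd.concat(
        [
            pd.DataFrame({"level": "lot", "unit": lot_ids, "effect": e_lot}),
            pd.DataFrame({"level": "subsample", "unit": sub_ids, "effect": e_sub.reshape(-1)}),
            pd.DataFrame({"level": "replicate", "unit": rep_ids, "effect": e_rep.reshape(-1)}),
            pd.DataFrame(
                {
                    "level": "scan",
                    "unit": [f"{r}#{k + 1}" for r in rep_ids for k in range(K)],
                    "effect": e_scan.reshape(-1),
                }
            ),
        ],
        ignore_index=True,
    )
    truth = GroundTruth(
        effects=effects,
        artifact_indices=artifact_indices,
        bwc_true=pd.DataFrame(
            {"lot": np.repeat(lot_ids, S), "subsample": sub_ids, "bwc": flat_bwc}
        ),
    )
    return dataset, bwc_table, truth
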