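"""Synthetic body-torso PET phantom cohorts.

The generator emulates the statistical structure the standardization method
relies on, not anatomy: a zero background outside an ellipsoidal "body", a
roughly unimodal body uptake distribution, homogeneous liver and spleen
ellipsoids with between-subject biological variability, sparse very-hot foci
("lesions") occupying the extreme upper tail of the body histogram, one
multiplicative per-scan scanner gain, and Gaussian noise with SD proportional
to the local mean.

Two modelling choices matter for what the phantoms probe:

* The per-scan gain is the only technical variability; it is exactly what
  landmark standardization is built to cancel.
* The hot foci are the only *gain-independent* cross-subject chaos.  Each
  subject draws a personal peak L ~ U(lesion_level_range) and focus values
  ~ U(lesion low, L), so upper-tail percentiles vary strongly between
  subjects (iid draws from a common range would yield stable order
  statistics and no chaos for the upper-percentile search to excise).

Everything is deterministic under the supplied seeds, and each phantom comes
with a truth record (gain, organ factors, true organ means) sufficient for
parameter-recovery tests without re-reading voxels.
"""

from __future__ import annotations

import dataclasses
import json
import os
from typing import Mapping

import numpy as np

from .exceptions import DataError
from .image_io import Mask, Modality, ScanMeta, VolumeImage, write_mask, write_volume

__all__ = [
    "PhantomConfig",
    "PhantomSample",
    "PairSample",
    "generate_phantom",
    "generate_cohort",
    "generate_repeat_pairs",
    "write_cohort",
]


@dataclasses.dataclass
class PhantomConfig:
    """Geometry and statistical parameters of one phantom cohort.

    Intensity defaults are on the SUV scale; :meth:`ac_default` gives a
    Bq/mL-scale configuration.  ``gain_range`` spans a 4x multiplicative
    spread, of the order of the scale variability seen between body-torso
    FDG scans; ``organ_cv_between_subjects`` is the true biological
    coefficient of variation of organ uptake; ``lesion_fraction`` is the
    fraction of body voxels occupied by hot foci, which therefore sit above
    the (100 * (1 - lesion_fraction))-th body percentile.
    """

    grid_shape: tuple[int, int, int] = (24, 40, 40)
    spacing: tuple[float, float, float] = (4.0, 4.0, 4.0)
    modality: Modality = Modality.SUV
    background_level: float = 0.0
    body_level: float = 1.0
    organ_levels: Mapping[str, float] = dataclasses.field(
        default_factory=lambda: {"liver": 2.5, "spleen": 2.0})
    organ_cv_between_subjects: float = 0.05
    gain_range: tuple[float, float] = (0.5, 2.0)
    lesion_fraction: float = 0.02
    lesion_level_range: tuple[float, float] = (8.0, 25.0)
    noise_sigma_fraction: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        self.modality = Modality(self.modality)
        if any(n < 8 for n in self.grid_shape):
            raise DataError(f"grid too small: {self.grid_shape}")
        if not (self.background_level < self.body_level):
            raise DataError("background_level must be below body_level")
        if self.organ_levels and min(self.organ_levels.values()) <= self.body_level:
            raise DataError("organ levels must exceed body_level")
        if not (0.0 <= self.lesion_fraction < 0.1):
            raise DataError(f"lesion_fraction must lie in [0, 0.1), got {self.lesion_fraction}")
        if self.organ_levels and self.lesion_level_range[0] <= max(self.organ_levels.values()):
            raise DataError("lesion_level_range must start above every organ level")
        if not (0 < self.gain_range[0] <= self.gain_range[1]):
            raise DataError(f"invalid gain_range {self.gain_range}")
        if self.organ_cv_between_subjects < 0 or self.noise_sigma_fraction < 0:
            raise DataError("variability fractions must be non-negative")

    @classmethod
    def suv_default(cls, **overrides) -> "PhantomConfig":
        return cls(**overrides)

    @classmethod
    def ac_default(cls, **overrides) -> "PhantomConfig":
        """Activity-concentration configuration (Bq/mL scale).

        Levels are placed inside the value ranges typical of clinical
        body-torso FDG scans (organ means of a few thousand to ~2e4 Bq/mL,
        maxima up to a few hundred thousand under gain).
        """
        defaults = dict(
            modality=Modality.AC,
            body_level=5000.0,
            organ_levels={"liver": 12000.0, "spleen": 10000.0},
            lesion_level_range=(40000.0, 125000.0),
        )
        defaults.update(overrides)
        return cls(**defaults)


@dataclasses.dataclass
class PhantomSample:
    volume: VolumeImage
    masks: dict[str, Mask]
    truth: dict
    meta: ScanMeta | None = None


@dataclasses.dataclass
class PairSample:
    scan1: PhantomSample
    scan2: PhantomSample
    truth: dict


def _ellipsoid(shape, center, semi) -> np.ndarray:
    zz, yy, xx = np.ogrid[: shape[0], : shape[1], : shape[2]]
    return (((zz - center[0]) / semi[0]) ** 2
            + ((yy - center[1]) / semi[1]) ** 2
            + ((xx - center[2]) / semi[2]) ** 2) <= 1.0


def _geometry(shape) -> dict[str, np.ndarray]:
    """Fixed phantom anatomy: body, liver and spleen ellipsoids (voxel masks)."""
    nz, ny, nx = shape
    cz, cy, cx = nz / 2, ny / 2, nx / 2
    body = _ellipsoid(shape, (cz, cy, cx), (0.42 * nz, 0.40 * ny, 0.40 * nx))
    liver = _ellipsoid(shape, (cz, 0.40 * ny, 0.68 * nx),
                       (0.20 * nz, 0.17 * ny, 0.15 * nx)) & body
    spleen = _ellipsoid(shape, (cz, 0.40 * ny, 0.30 * nx),
                        (0.13 * nz, 0.12 * ny, 0.10 * nx)) & body
    spleen &= ~liver  # guarantee disjoint organs
    return {"body": body, "liver": liver, "spleen": spleen}


def _subject_params(config: PhantomConfig, rng: np.random.Generator) -> dict:
    """Draw the subject-level biology: organ factors, focus sites and values."""
    geom = _geometry(config.grid_shape)
    organ_factors = {
        name: float(rng.normal(1.0, config.organ_cv_between_subjects))
        for name in config.organ_levels
    }
    for name, f in organ_factors.items():
        if f <= 0:
            raise DataError(f"drawn organ factor for {name} not positive; "
                            "organ_cv_between_subjects too large")
    n_body = int(geom["body"].sum())
    n_les = int(round(config.lesion_fraction * n_body))
    eligible = geom["body"].copy()
    for name in config.organ_levels:
        eligible &= ~geom[name]
    flat_idx = np.flatnonzero(eligible.ravel())
    lesion_idx = rng.choice(flat_idx, size=n_les, replace=False) if n_les else np.empty(0, int)
    lo, hi = config.lesion_level_range
    lesion_peak = float(rng.uniform(lo, hi))
    lesion_values = rng.uniform(lo, max(lesion_peak, lo * (1 + 1e-9)), size=n_les)
    return {
        "geom": geom,
        "organ_factors": organ_factors,
        "lesion_idx": lesion_idx,
        "lesion_values": lesion_values,
        "lesion_peak": lesion_peak,
        "n_body": n_body,
    }


def _render(config: PhantomConfig, params: dict, gain: float,
            rng: np.random.Generator) -> PhantomSample:
    """Compose template -> gain -> noise and wrap with masks and truth."""
    geom = params["geom"]
    vol = np.full(config.grid_shape, config.background_level, dtype=np.float64)
    vol[geom["body"]] = config.body_level
    for name, level in config.organ_levels.items():
        vol[geom[name]] = level * params["organ_factors"][name]
    lesion_mask = np.zeros(config.grid_shape, dtype=bool)
    if params["lesion_idx"].size:
        lesion_mask.ravel()[params["lesion_idx"]] = True
        vol.ravel()[params["lesion_idx"]] = params["lesion_values"]
    vol *= gain
    if config.noise_sigma_fraction > 0:
        vol = vol + rng.normal(0.0, config.noise_sigma_fraction * vol)
        np.clip(vol, 0.0, None, out=vol)
    masks = {
        "body": Mask(geom["body"], kind="body"),
        "liver": Mask(geom["liver"], kind="liver"),
        "spleen": Mask(geom["spleen"], kind="spleen"),
        "lesion": Mask(lesion_mask, kind="lesion"),
    }
    truth = {
        "gain": float(gain),
        "organ_factors": dict(params["organ_factors"]),
        "organ_means_true": {
            name: float(gain * level * params["organ_factors"][name])
            for name, level in config.organ_levels.items()
        },
        "lesion_peak": params["lesion_peak"],
        "n_body": params["n_body"],
        "n_lesion": int(params["lesion_idx"].size),
    }
    volume = VolumeImage(voxels=vol, spacing=config.spacing, modality=config.modality)
    return PhantomSample(volume=volume, masks=masks, truth=truth)


def generate_phantom(config: PhantomConfig, subject_seed) -> PhantomSample:
    """One phantom scan: subject biology, one gain draw, one noise realization."""
    rng = np.random.default_rng(subject_seed)
    params = _subject_params(config, rng)
    gain = float(rng.uniform(*config.gain_range))
    return _render(config, params, gain, rng)


def generate_cohort(config: PhantomConfig, n: int, seed) -> list[PhantomSample]:
    """n independent subjects, each with its own gain, biology and noise."""
    if n < 2:
        raise DataError("cohort size must be at least 2")
    children = np.random.SeedSequence(seed).spawn(n)
    return [generate_phantom(config, child) for child in children]


def generate_repeat_pairs(config: PhantomConfig, n_pairs: int, seed,
                          repeat_jitter: float = 0.03) -> list[PairSample]:
    """Repeat-scan pairs: shared anatomy and biology, independent gain and noise.

    Scan 2 perturbs each organ factor and the focus values by an independent
    multiplicative jitter drawn from U(1 - repeat_jitter, 1 + repeat_jitter),
    emulating small biological change between sessions a few days apart.
    """
    if repeat_jitter < 0:
        raise DataError("repeat_jitter must be non-negative")
    pairs = []
    for child in np.random.SeedSequence(seed).spawn(n_pairs):
        rng = np.random.default_rng(child)
        params = _subject_params(config, rng)
        gain1 = float(rng.uniform(*config.gain_range))
        gain2 = float(rng.uniform(*config.gain_range))
        params2 = dict(params)
        params2["organ_factors"] = {
            name: f * float(rng.uniform(1 - repeat_jitter, 1 + repeat_jitter))
            for name, f in params["organ_factors"].items()
        }
        params2["lesion_values"] = params["lesion_values"] * float(
            rng.uniform(1 - repeat_jitter, 1 + repeat_jitter))
        scan1 = _render(config, params, gain1, rng)
        scan2 = _render(config, params2, gain2, rng)
        truth = {"gain1": gain1, "gain2": gain2,
                 "organ_factors1": scan1.truth["organ_factors"],
                 "organ_factors2": scan2.truth["organ_factors"],
                 "organ_means_true1": scan1.truth["organ_means_true"],
                 "organ_means_true2": scan2.truth["organ_means_true"]}
        pairs.append(PairSample(scan1=scan1, scan2=scan2, truth=truth))
    return pairs


def write_cohort(samples, out_dir: str | os.PathLike) -> list[str]:
    """Write a cohort directory: sub###_img.nii.gz, masks, truth JSON sidecars."""
    os.makedirs(out_dir, exist_ok=True)
    stems = []
    for i, s in enumerate(samples):
        stem = f"sub{i:03d}"
        write_volume(s.volume, os.path.join(out_dir, f"{stem}_img.nii.gz"))
        for name, mask in s.masks.items():
            write_mask(mask, os.path.join(out_dir, f"{stem}_mask_{name}.nii.gz"),
                       spacing=s.volume.spacing)
        with open(os.path.join(out_dir, f"{stem}_truth.json"), "w") as fh:
            json.dump(s.truth, fh, indent=2)
        stems.append(stem)
    return stems
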