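"""Per-image standardization: the piecewise-linear mapping psi = lambda^-1 ∘ eta.

The intermediate mapping eta has two linear segments anchored at the image's
own landmarks: [p_alpha(I), p_m(I)] -> [s_min, s_m] and
[p_m(I), p_beta(I)] -> [s_m, s_max].  Both segments extrapolate linearly, so
intensities above p_beta (the highly variable uptake tail) retain their full
dynamic range instead of being clipped.  The subsequent multiplication by
inv_scale (lambda^-1) restores physically meaningful AC/SUV magnitudes.

Only a body mask of the input image is needed (to locate p_m and p_beta); the
reference organ plays no role outside calibration.  eta is strictly
increasing, so voxel rank order is preserved exactly, and the intermediate
image is never materialized: psi is applied as one fused voxel-wise function.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

from .calibration import StandardScale, calibrate
from .config import RunConfig
from .exceptions import DataError, ModalityError
from .image_io import Mask, Modality, ScanMeta, VolumeImage, ac_to_suv
from .landmarks import LandmarkSet, extract_landmarks

__all__ = ["MappingSpec", "eta", "standardize", "run_strategy", "STRATEGY_TOKENS"]

STRATEGY_TOKENS = ("s-AC", "SUV", "s-SUV")


@dataclasses.dataclass
class MappingSpec:
    """Landmarks of the input image paired with the standard scale."""

    landmarks: LandmarkSet
    scale: StandardScale

    def __post_init__(self) -> None:
        if not self.landmarks.is_strict:
            raise DataError("degenerate landmark set: slopes would not be positive")

    @property
    def slope1(self) -> float:
        return (self.scale.s_m - self.scale.s_min) / (self.landmarks.p_m - self.landmarks.p_alpha)

    @property
    def slope2(self) -> float:
        return (self.scale.s_max - self.scale.s_m) / (self.landmarks.p_beta - self.landmarks.p_m)


def eta(x, spec: MappingSpec):
    """The two-segment piecewise-linear mapping, extrapolated on both tails.

    x <= p_m uses the first segment, x > p_m the second; the segments meet at
    (p_m, s_m), so eta is continuous and strictly increasing everywhere.
    """
    x = np.asarray(x, dtype=np.float64)
    lm, sc = spec.landmarks, spec.scale
    lower = sc.s_min + spec.slope1 * (x - lm.p_alpha)
    upper = sc.s_m + spec.slope2 * (x - lm.p_m)
    return np.where(x <= lm.p_m, lower, upper)


def standardize(volume: VolumeImage, scale: StandardScale,
                mask: Mask | None = None) -> VolumeImage:
    """Apply psi = inv_scale * eta(.) voxel-wise to a whole volume.

    The volume's base modality must match the scale's.  Output modality is
    STD_AC or STD_SUV.  With p_alpha = min(I) and s_min = 0 the mapping
    cannot produce negative values; this is asserted rather than clamped so
    that a violation surfaces as an error instead of silent clipping.
    """
    if volume.modality.base is not scale.modality:
        raise ModalityError(
            f"volume modality {volume.modality.value} does not match "
            f"calibration modality {scale.modality.value}"
        )
    lm = extract_landmarks(volume, scale.beta, mask=mask)
    spec = MappingSpec(landmarks=lm, scale=scale)
    out = scale.inv_scale * eta(volume.voxels, spec)
    if float(out.min()) < -1e-9 * scale.inv_scale * scale.s_max:
        raise DataError("standardization produced negative intensities")
    return VolumeImage(voxels=out, spacing=volume.spacing,
                       modality=volume.modality.base.standardized)


def _parse_strategy(strategy) -> tuple[str, ...]:
    if isinstance(strategy, str):
        strategy = [t.strip() for t in strategy.split(",") if t.strip()]
    tokens = tuple(strategy)
    for t in tokens:
        if t not in STRATEGY_TOKENS:
            raise DataError(f"unknown strategy token {t!r}; expected one of {STRATEGY_TOKENS}")
    if not tokens:
        raise DataError("empty strategy")
    return tokens


def run_strategy(strategy, images: Sequence[VolumeImage],
                 metas: Sequence[ScanMeta] | None = None, *,
                 calib_images: Sequence[VolumeImage] | None = None,
                 calib_organ_masks: Sequence[Mask] | None = None,
                 calib_metas: Sequence[ScanMeta] | None = None,
                 config: RunConfig | None = None):
    """Apply a chain of steps from {s-AC, SUV, s-SUV} left to right.

    Each standardization step calibrates on the *current* state of the
    calibration cohort, which is pushed through the same chain as the test
    images -- so a second standardization re-estimates its parameters on the
    already-standardized calibration set.  SUV steps convert both cohorts via
    the dose/weight metadata.

    Returns ``(final_images, scales)`` where ``scales`` lists the
    :class:`StandardScale` used at each standardization step, in order.
    """
    tokens = _parse_strategy(strategy)
    if config is None:
        config = RunConfig()
    images = list(images)
    calib = list(calib_images) if calib_images is not None else None
    scales: list[StandardScale] = []

    def _require_base(base: Modality, step: str) -> None:
        bad = [v.modality.value for v in images if v.modality.base is not base]
        if bad:
            raise ModalityError(f"step {step!r} requires {base.value}-type images, got {bad[:3]}")

    for tok in tokens:
        if tok == "SUV":
            _require_base(Modality.AC, tok)
            if metas is None or len(metas) != len(images):
                raise DataError("SUV step requires one ScanMeta per image")
            images = [ac_to_suv(v, m) for v, m in zip(images, metas)]
            if calib is not None:
                if calib_metas is None or len(calib_metas) != len(calib):
                    raise DataError("SUV step requires ScanMeta for the calibration cohort")
                calib = [ac_to_suv(v, m) for v, m in zip(calib, calib_metas)]
        else:  # s-AC or s-SUV
            base = Modality.AC if tok == "s-AC" else Modality.SUV
            _require_base(base, tok)
            if calib is None or calib_organ_masks is None:
                raise DataError(f"step {tok!r} requires a calibration cohort and organ masks")
            scale = calibrate(calib, calib_organ_masks, config=config)
            images = [standardize(v, scale) for v in images]
            calib = [standardize(v, scale) for v in calib]
            scales.append(scale)
    return images, scales
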