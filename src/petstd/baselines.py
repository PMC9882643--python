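"""Comparison normalizers: Gaussian, Z-score, and a simplified Nyul-style method.

Gaussian normalization divides every voxel by the within-organ standard
deviation of the image; Z-score normalization first subtracts the
calibration-cohort organ mean.  Both require a reference-organ segmentation
of every image and are only meaningful within that organ, but -- matching the
evaluation protocol -- the whole image is transformed and organ means are
read off afterwards.

The "M-method" is a reduced histogram-landmark standardizer in the spirit of
the classic MRI approach: per-image landmarks at the fixed foreground
percentiles {0, 50, 99.8} are mapped piecewise-linearly onto cohort-mean
positions of a fixed scale.  Unlike the optimized method, the upper cutoff is
not adapted to the data, so on PET it sits inside the chaotic high-uptake
tail; it is provided as a structural comparator only.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .calibration import StandardScale, estimate_sm
from .exceptions import DataError, DegenerateInputError
from .image_io import Mask, Modality, VolumeImage
from .transform import standardize

__all__ = [
    "organ_stats",
    "cohort_organ_mean",
    "gaussian_normalize",
    "zscore_normalize",
    "nyul_calibrate",
    "nyul_standardize",
    "NYUL_UPPER_PERCENTILE",
]

#: fixed upper landmark percentile of the simplified M-method
NYUL_UPPER_PERCENTILE = 99.8


def organ_stats(volume: VolumeImage, organ_mask: Mask, ddof: int = 0) -> tuple[float, float]:
    """(mean, SD) of intensities within the organ mask."""
    organ_mask.check_aligned(volume)
    if organ_mask.n_voxels == 0:
        raise DegenerateInputError("empty organ mask")
    vals = volume.voxels[organ_mask.voxels]
    return float(vals.mean()), float(vals.std(ddof=ddof))


def cohort_organ_mean(cohort: Sequence[VolumeImage], organ_masks: Sequence[Mask]) -> float:
    """Calibration-cohort organ mean: the mean of per-image organ means."""
    if len(cohort) == 0 or len(cohort) != len(organ_masks):
        raise DataError("cohort and organ masks must align 1:1 and be non-empty")
    return float(np.mean([organ_stats(v, m)[0] for v, m in zip(cohort, organ_masks)]))


def gaussian_normalize(volume: VolumeImage, organ_mask: Mask, ddof: int = 0) -> VolumeImage:
    """Divide the image by its within-organ standard deviation."""
    _, sigma = organ_stats(volume, organ_mask, ddof=ddof)
    if sigma == 0:
        raise DegenerateInputError("zero within-organ SD: Gaussian normalization undefined")
    return volume.with_voxels(volume.voxels / sigma)


def zscore_normalize(volume: VolumeImage, organ_mask: Mask, mu_ref: float,
                     ddof: int = 0) -> VolumeImage:
    """Subtract the calibration-cohort organ mean, then divide by the organ SD."""
    _, sigma = organ_stats(volume, organ_mask, ddof=ddof)
    if sigma == 0:
        raise DegenerateInputError("zero within-organ SD: Z-score normalization undefined")
    return volume.with_voxels((volume.voxels - mu_ref) / sigma)


def nyul_calibrate(cohort: Sequence[VolumeImage], s_max: float | None = None) -> StandardScale:
    """Calibrate the simplified M-method on a cohort.

    Landmarks are fixed at foreground percentiles {0, 50, 99.8}; the standard
    median is the cohort mean of the rescaled medians, exactly as in the
    optimized method but without the beta search.  No inverse scaling is
    applied (inv_scale = 1): the original approach maps onto a fixed scale.
    """
    if len(cohort) < 2:
        raise DataError("M-method calibration needs at least 2 images")
    base = cohort[0].modality.base
    for v in cohort:
        if v.modality.base is not base:
            raise DataError("mixed modalities in M-method calibration cohort")
    if s_max is None:
        from .config import default_s_max
        s_max = default_s_max(base)
    s_m = estimate_sm(cohort, NYUL_UPPER_PERCENTILE, s_max)
    return StandardScale(
        s_m=s_m, s_max=float(s_max), beta=NYUL_UPPER_PERCENTILE, inv_scale=1.0,
        modality=base, calibration_n=len(cohort), reference_organ="none",
    )


def nyul_standardize(volume: VolumeImage, scale: StandardScale) -> VolumeImage:
    """Apply the simplified M-method mapping (shares the piecewise machinery)."""
    return standardize(volume, scale)
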