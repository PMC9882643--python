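"""Body-region masking and per-image intensity landmarks.

The standardization mapping of a PET image I is anchored on five intensity
landmarks: min(I), p_alpha(I), the body-region median p_m(I), an upper
percentile p_beta(I), and max(I).  Because whole-body PET background is close
to zero, p_alpha is pinned to min(I); p_m and p_beta are computed over the
body region, obtained by thresholding the volume at its global mean intensity
(the histogram of a body-torso PET volume is bimodal, with a near-zero
background mode and a body mode, so the global mean separates the two).

Percentiles use linear interpolation between order statistics (the inclusive
scheme), which is continuous in the percentile argument -- a property the
upper-percentile grid search in :mod:`petstd.calibration` relies on.
"""

from __future__ import annotations

import dataclasses
import json
import os

import numpy as np

from .exceptions import DataError, DegenerateInputError
from .image_io import Mask, VolumeImage

__all__ = ["LandmarkSet", "body_mask", "percentile", "extract_landmarks"]


@dataclasses.dataclass
class LandmarkSet:
    """Intensity landmarks of one image, with the percentiles that produced them.

    Invariant: i_min <= p_alpha <= p_m <= p_beta <= i_max, with the strict
    ordering p_alpha < p_m < p_beta required for a valid standardization
    mapping (checked by :func:`extract_landmarks`).
    """

    i_min: float
    p_alpha: float
    p_m: float
    p_beta: float
    i_max: float
    alpha: float
    beta: float

    def __post_init__(self) -> None:
        for name in ("i_min", "p_alpha", "p_m", "p_beta", "i_max", "alpha", "beta"):
            setattr(self, name, float(getattr(self, name)))
        if not (self.i_min <= self.p_alpha <= self.p_m <= self.p_beta <= self.i_max):
            raise DataError(f"landmarks out of order: {self}")
        if not (0.0 <= self.alpha <= 100.0 and self.alpha < self.beta <= 100.0):
            raise DataError(f"percentiles out of range: alpha={self.alpha}, beta={self.beta}")

    @property
    def is_strict(self) -> bool:
        """True when p_alpha < p_m < p_beta (non-degenerate mapping)."""
        return self.p_alpha < self.p_m < self.p_beta

    def to_json(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path: str | os.PathLike) -> "LandmarkSet":
        with open(path) as fh:
            return cls(**json.load(fh))


def body_mask(volume: VolumeImage) -> Mask:
    """Threshold a volume at its global mean intensity to isolate the body.

    A voxel belongs to the body region iff I(v) > mean(I) (strict, so the
    result is deterministic on the measure-zero equality case).  Rough
    segmentation suffices here: the downstream landmarks are a median and a
    high percentile, both insensitive to small boundary errors.
    """
    vox = volume.voxels
    if float(vox.max()) == float(vox.min()):
        raise DegenerateInputError("constant volume: body mask would be empty")
    mask = vox > vox.mean()
    if not mask.any():
        raise DegenerateInputError("empty body mask after mean thresholding")
    return Mask(voxels=mask, kind="body")


def percentile(values: np.ndarray, q: float) -> float:
    """Linear-interpolation percentile of a multiset of intensities.

    q=0 gives the minimum, q=100 the maximum, q=50 the median.
    """
    values = np.ravel(np.asarray(values, dtype=np.float64))
    if values.size == 0:
        raise DataError("percentile of empty input")
    if not (0.0 <= q <= 100.0):
        raise DataError(f"percentile q must lie in [0, 100], got {q}")
    return float(np.percentile(values, q))


def extract_landmarks(volume: VolumeImage, beta: float,
                      mask: Mask | None = None) -> LandmarkSet:
    """Compute the landmark set {min, p_alpha, p_m, p_beta, max} of a volume.

    p_alpha is pinned to min(I) (alpha is reported as 0).  p_m and p_beta are
    the 50th and beta-th percentiles of the body-region voxels; the body mask
    is computed by :func:`body_mask` unless one is supplied.

    Raises :class:`DegenerateInputError` when the strict ordering
    p_alpha < p_m < p_beta fails, since no valid two-segment mapping exists
    for such an image.
    """
    if mask is None:
        mask = body_mask(volume)
    else:
        mask.check_aligned(volume)
        if mask.n_voxels == 0:
            raise DegenerateInputError("empty body mask")
    vox = volume.voxels
    body_vals = vox[mask.voxels]
    i_min = float(vox.min())
    i_max = float(vox.max())
    p_m = percentile(body_vals, 50.0)
    p_beta = percentile(body_vals, beta)
    lm = LandmarkSet(i_min=i_min, p_alpha=i_min, p_m=p_m, p_beta=p_beta,
                     i_max=i_max, alpha=0.0, beta=beta)
    if not lm.is_strict:
        raise DegenerateInputError(
            f"degenerate landmark ordering (p_alpha={lm.p_alpha}, p_m={lm.p_m}, "
            f"p_beta={lm.p_beta}); cannot build a standardization mapping"
        )
    return lm
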