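"""One-time calibration of the standard intensity scale.

Calibration consumes a cohort of normal PET images together with a reference
organ mask (liver or spleen) per image and produces:

* the optimal upper percentile ``beta``, chosen so that linearly rescaling
  each image by its [p_alpha, p_beta] range minimizes the coefficient of
  variation of the reference-organ mean across the cohort -- the largest
  percentile attaining the minimum is taken, which places the cut just below
  the chaotic high-uptake tail;
* the standard-scale median ``s_m``: the cohort mean of the rescaled
  body-region medians;
* the inverse scale factor ``inv_scale`` (lambda^-1): the reciprocal of the
  trimmed mean of the per-image rescaling factors, which restores the
  standardized values to physically meaningful AC/SUV magnitudes.

The rescaling used throughout this module is the two-landmark linear map
lambda: [p_alpha(I), p_b(I)] -> [0, s_max].  (The three-landmark piecewise
map of :mod:`petstd.transform` cannot be used during calibration because its
middle landmark s_m only exists once beta has been chosen.)

Standard deviations are population (divide-by-n) by default; the convention
is exposed through ``ddof`` arguments and :class:`petstd.config.RunConfig`.
"""

from __future__ import annotations

import dataclasses
import datetime
import json
import os
from typing import Sequence

import numpy as np

from .config import RunConfig
from .exceptions import DataError, DegenerateInputError
from .image_io import Mask, Modality, VolumeImage
from .landmarks import LandmarkSet, body_mask, extract_landmarks

__all__ = [
    "StandardScale",
    "BetaSearchResult",
    "lambda_map",
    "delta_O",
    "optimize_beta",
    "estimate_sm",
    "estimate_inv_scale",
    "calibrate",
]


@dataclasses.dataclass
class StandardScale:
    """The calibration product: everything the transformation step needs."""

    s_m: float
    s_max: float
    beta: float
    inv_scale: float
    modality: Modality
    calibration_n: int
    reference_organ: str
    s_min: float = 0.0
    created: str = ""

    def __post_init__(self) -> None:
        self.modality = Modality(self.modality).base
        if not (self.s_min == 0.0 < self.s_m < self.s_max):
            raise DataError(
                f"standard scale requires s_min = 0 < s_m < s_max, got "
                f"({self.s_min}, {self.s_m}, {self.s_max})"
            )
        if not (90.0 <= self.beta <= 100.0):
            raise DataError(f"beta must lie in [90, 100], got {self.beta}")
        if self.inv_scale <= 0:
            raise DataError(f"inv_scale must be positive, got {self.inv_scale}")
        if not self.created:
            self.created = datetime.datetime.now(datetime.timezone.utc).isoformat()

    def to_dict(self) -> dict:
        return {
            "modality": self.modality.value,
            "s_min": self.s_min,
            "s_m": self.s_m,
            "s_max": self.s_max,
            "beta": self.beta,
            "inv_scale": self.inv_scale,
            "calibration_n": self.calibration_n,
            "reference_organ": self.reference_organ,
            "created": self.created,
        }

    def save(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def load(cls, path: str | os.PathLike) -> "StandardScale":
        with open(path) as fh:
            return cls(**json.load(fh))


@dataclasses.dataclass
class BetaSearchResult:
    """Grid of (b, delta_O(b)) values and the selected beta."""

    grid: list[tuple[float, float]]
    beta: float
    delta_at_beta: float


def lambda_map(x, landmarks: LandmarkSet, s_max: float):
    """Two-landmark linear rescaling [p_alpha, p_beta] -> [0, s_max]."""
    span = landmarks.p_beta - landmarks.p_alpha
    if span <= 0:
        raise DegenerateInputError("p_beta must exceed p_alpha for the linear rescaling")
    return (np.asarray(x, dtype=np.float64) - landmarks.p_alpha) * (s_max / span)


def _check_cohort(cohort: Sequence[VolumeImage], masks: Sequence[Mask]) -> None:
    if len(cohort) != len(masks):
        raise DataError(f"cohort ({len(cohort)}) and masks ({len(masks)}) not aligned 1:1")
    if len(cohort) < 2:
        raise DataError("calibration cohort must contain at least 2 images")
    for vol, m in zip(cohort, masks):
        m.check_aligned(vol)
        if m.n_voxels == 0:
            raise DegenerateInputError("empty reference-organ mask in cohort")


def delta_O(cohort: Sequence[VolumeImage], organ_masks: Sequence[Mask],
            b: float, s_max: float, ddof: int = 0) -> float:
    """Coefficient of variation of the rescaled reference-organ mean at percentile b.

    Each image is rescaled linearly from [p_alpha(I), p_b(I)] to [0, s_max],
    the mean within the organ mask is taken, and std/mean of those means over
    the cohort is returned.
    """
    _check_cohort(cohort, organ_masks)
    means = []
    for vol, m in zip(cohort, organ_masks):
        lm = extract_landmarks(vol, b)
        mapped = lambda_map(vol.voxels, lm, s_max)
        means.append(float(mapped[m.voxels].mean()))
    means = np.asarray(means)
    m_mean = means.mean()
    if m_mean == 0:
        raise DegenerateInputError("zero mean organ intensity across cohort")
    return float(means.std(ddof=ddof) / m_mean)


def _beta_grid(b_low: float, b_high: float, step: float) -> np.ndarray:
    if b_low > b_high:
        raise DataError(f"b_low must not exceed b_high, got [{b_low}, {b_high}]")
    if step <= 0:
        raise DataError(f"step must be positive, got {step}")
    n = int(round((b_high - b_low) / step))
    grid = b_low + step * np.arange(n + 1)
    grid[-1] = b_high  # guard against float drift
    return np.clip(grid, 0.0, 100.0)


def optimize_beta(cohort: Sequence[VolumeImage], organ_masks: Sequence[Mask],
                  b_low: float = 90.0, b_high: float = 100.0, step: float = 0.1,
                  s_max: float = 1.0, ddof: int = 0,
                  tie_atol: float = 1e-12) -> BetaSearchResult:
    """Grid search for the upper percentile minimizing delta_O.

    Evaluates delta_O(b) on the grid b_low, b_low+step, ..., b_high and
    returns the largest b attaining the minimum.  Deltas within ``tie_atol``
    of the minimum count as tied: on a cohort differing only by multiplicative
    gain the rescaling cancels the gain exactly in real arithmetic, so all
    grid deltas tie at zero up to float rounding, and the tie rule then
    selects b_high.
    """
    _check_cohort(cohort, organ_masks)
    grid = _beta_grid(b_low, b_high, step)

    # Per-image quantities are b-independent except for p_b itself, so the
    # whole grid is evaluated from one sorted pass per image.  Because the
    # rescaling is affine, the organ mean maps exactly like a single voxel.
    n_img = len(cohort)
    means = np.empty((n_img, grid.size))
    for i, (vol, m) in enumerate(zip(cohort, organ_masks)):
        bm = body_mask(vol)
        body_vals = vol.voxels[bm.voxels]
        p_alpha = float(vol.voxels.min())
        p_m = float(np.percentile(body_vals, 50.0))
        p_grid = np.percentile(body_vals, grid)
        if np.any(p_grid <= p_m) or p_m <= p_alpha:
            raise DegenerateInputError(
                "degenerate landmark ordering within the beta search grid"
            )
        mu_raw = float(vol.voxels[m.voxels].mean())
        means[i] = (mu_raw - p_alpha) * s_max / (p_grid - p_alpha)
    m_of_means = means.mean(axis=0)
    if np.any(m_of_means == 0):
        raise DegenerateInputError("zero mean organ intensity across cohort")
    deltas = means.std(axis=0, ddof=ddof) / m_of_means

    d_min = float(deltas.min())
    tied = np.flatnonzero(deltas <= d_min + tie_atol)
    best = int(tied[-1])  # largest percentile among ties
    return BetaSearchResult(
        grid=[(float(b), float(d)) for b, d in zip(grid, deltas)],
        beta=float(grid[best]),
        delta_at_beta=float(deltas[best]),
    )


def estimate_sm(cohort: Sequence[VolumeImage], beta: float, s_max: float) -> float:
    """Cohort mean of the rescaled body-region medians lambda(p_m(I))."""
    if len(cohort) == 0:
        raise DataError("empty cohort")
    vals = []
    for vol in cohort:
        lm = extract_landmarks(vol, beta)
        vals.append(float(lambda_map(lm.p_m, lm, s_max)))
    return float(np.mean(vals))


def estimate_inv_scale(cohort: Sequence[VolumeImage], beta: float, s_max: float,
                       ddof: int = 0) -> float:
    """Reciprocal of the trimmed mean of the per-image rescaling factors.

    Each image contributes the factor f = s_max / (p_beta - p_alpha) (equal to
    s_max / p_beta when min(I) = 0, the typical PET case).  Factors more than
    one standard deviation from their mean are dropped before averaging; if
    the trim would empty the set, the untrimmed mean is used.
    """
    if len(cohort) < 2:
        raise DataError("inv-scale estimation needs a cohort of at least 2 images")
    factors = []
    for vol in cohort:
        lm = extract_landmarks(vol, beta)
        span = lm.p_beta - lm.p_alpha
        if span <= 0 or lm.p_beta <= 0:
            raise DegenerateInputError(f"non-positive p_beta span ({span}) in cohort")
        factors.append(s_max / span)
    factors = np.asarray(factors)
    mean_f = factors.mean()
    sd_f = factors.std(ddof=ddof)
    kept = factors[np.abs(factors - mean_f) <= sd_f]
    if kept.size == 0:
        kept = factors
    return float(1.0 / kept.mean())


def calibrate(cohort: Sequence[VolumeImage], organ_masks: Sequence[Mask],
              config: RunConfig | None = None,
              return_search: bool = False):
    """Run the full calibration and return the :class:`StandardScale`.

    With ``return_search=True`` also returns the :class:`BetaSearchResult`
    (the delta_O grid), which the CLI persists for auditability.
    Deterministic: same cohort and config give a bit-identical scale
    (up to the creation timestamp).
    """
    if config is None:
        config = RunConfig()
    _check_cohort(cohort, organ_masks)
    base = cohort[0].modality.base
    for vol in cohort:
        if vol.modality.base is not base:
            raise DataError("mixed modalities in calibration cohort")
    s_max = config.resolved_s_max(base)
    search = optimize_beta(cohort, organ_masks, b_low=config.b_low,
                           b_high=config.b_high, step=config.b_step,
                           s_max=s_max, ddof=config.ddof,
                           tie_atol=config.tie_atol)
    s_m = estimate_sm(cohort, search.beta, s_max)
    inv_scale = estimate_inv_scale(cohort, search.beta, s_max, ddof=config.ddof)
    scale = StandardScale(
        s_m=s_m,
        s_max=s_max,
        beta=search.beta,
        inv_scale=inv_scale,
        modality=base,
        calibration_n=len(cohort),
        reference_organ=organ_masks[0].kind,
    )
    return (scale, search) if return_search else scale
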