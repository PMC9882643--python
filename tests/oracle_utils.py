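"""Independent brute-force oracles used to cross-check the implementation.

These are deliberately written as plain loops over Python floats, sharing no
code path with the package: sort-and-interpolate percentiles, explicit
per-voxel linear maps, and hand-rolled mean/SD accumulation.
"""

from __future__ import annotations

import math


def percentile_oracle(values, q: float) -> float:
    """Linear-interpolation percentile by explicit sort and index arithmetic."""
    vals = sorted(float(v) for v in values)
    n = len(vals)
    if n == 1:
        return vals[0]
    h = (n - 1) * q / 100.0
    lo = math.floor(h)
    hi = min(lo + 1, n - 1)
    frac = h - lo
    return vals[lo] + frac * (vals[hi] - vals[lo])


def mean_oracle(xs) -> float:
    xs = list(xs)
    return sum(xs) / len(xs)


def sd_oracle(xs, ddof: int = 0) -> float:
    xs = [float(x) for x in xs]
    m = mean_oracle(xs)
    return math.sqrt(sum((x - m) ** 2 for x in xs) / (len(xs) - ddof))


def cv_oracle(means, ddof: int = 0) -> float:
    return sd_oracle(means, ddof) / mean_oracle(means)


def md_oracle(pairs) -> float:
    terms = [abs(m1 - m2) / ((m1 + m2) / 2.0) for m1, m2 in pairs]
    return mean_oracle(terms)


def body_values_oracle(voxels):
    """Flat list of voxels strictly above the volume mean."""
    flat = [float(v) for v in voxels.ravel()]
    m = mean_oracle(flat)
    return [v for v in flat if v > m]


def rescaled_organ_mean_oracle(voxels, organ_bool, b: float, s_max: float) -> float:
    """Organ mean after the two-landmark map [p_alpha, p_b] -> [0, s_max]."""
    body = body_values_oracle(voxels)
    p_alpha = min(float(v) for v in voxels.ravel())
    p_b = percentile_oracle(body, b)
    organ_vals = [float(v) for v in voxels[organ_bool]]
    mapped = [(v - p_alpha) * s_max / (p_b - p_alpha) for v in organ_vals]
    return mean_oracle(mapped)


def delta_oracle(vox_list, organ_bool_list, b: float, s_max: float, ddof: int = 0) -> float:
    means = [rescaled_organ_mean_oracle(v, o, b, s_max)
             for v, o in zip(vox_list, organ_bool_list)]
    return cv_oracle(means, ddof)


def sm_oracle(vox_list, beta: float, s_max: float) -> float:
    vals = []
    for vox in vox_list:
        body = body_values_oracle(vox)
        p_alpha = min(float(v) for v in vox.ravel())
        p_m = percentile_oracle(body, 50.0)
        p_b = percentile_oracle(body, beta)
        vals.append((p_m - p_alpha) * s_max / (p_b - p_alpha))
    return mean_oracle(vals)


def eta_oracle(x: float, p_alpha: float, p_m: float, p_beta: float,
               s_min: float, s_m: float, s_max: float) -> float:
    """Two-segment piecewise-linear map evaluated one scalar at a time."""
    if x <= p_m:
        return s_min + (s_m - s_min) / (p_m - p_alpha) * (x - p_alpha)
    return s_m + (s_max - s_m) / (p_beta - p_m) * (x - p_m)
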