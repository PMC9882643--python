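"""Evaluation statistics: CV_O, MD_O, and inter-scanner group comparison.

CV_O is the coefficient of variation of the within-organ mean intensity over
a cohort of normal images: low CV_O means the organ carries similar numeric
meaning across subjects.  MD_O is the mean, over repeat-scan pairs, of the
absolute difference of the two organ means normalized by their average --
a per-pair percentage of which the cohort average is reported.  The
inter-scanner comparison is a two-sample t-test (Welch by default) on organ
means from two scanner groups.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import DataError, DegenerateInputError
from .image_io import Mask, VolumeImage

__all__ = [
    "organ_mean",
    "cv_metric",
    "md_metric",
    "interscanner_compare",
    "GroupComparison",
    "CohortReport",
    "report_to_csv",
    "format_report",
]


def organ_mean(volume: VolumeImage, organ_mask: Mask) -> float:
    """Arithmetic mean of the voxels under the mask."""
    organ_mask.check_aligned(volume)
    if organ_mask.n_voxels == 0:
        raise DegenerateInputError("empty organ mask")
    return float(volume.voxels[organ_mask.voxels].mean())


def cv_metric(means: Sequence[float], ddof: int = 0) -> float:
    """SD of the organ means divided by their mean (population SD by default)."""
    means = np.asarray(means, dtype=np.float64)
    if means.size < 2:
        raise DataError("CV needs at least 2 organ means")
    m = means.mean()
    if m == 0:
        raise DegenerateInputError("zero mean of organ means: CV undefined")
    return float(means.std(ddof=ddof) / m)


def md_metric(pairs: Sequence[tuple[float, float]]) -> float:
    """Mean over pairs of |mu1 - mu2| / ((mu1 + mu2)/2).

    The normalizing count is the number of repeat-scan *pairs*, so a single
    identical pair gives 0 and a single (1, 3) pair gives 1.0 (100%).
    """
    if len(pairs) == 0:
        raise DataError("MD needs at least one repeat-scan pair")
    terms = []
    for m1, m2 in pairs:
        s = m1 + m2
        if s <= 0:
            raise DataError(f"non-positive pair sum ({m1}, {m2}): MD undefined")
        terms.append(abs(m1 - m2) / (s / 2.0))
    return float(np.mean(terms))


@dataclasses.dataclass
class GroupComparison:
    m1: float
    s1: float
    m2: float
    s2: float
    t: float
    p: float


def interscanner_compare(means_group1: Sequence[float], means_group2: Sequence[float],
                         equal_var: bool = False, ddof: int = 0) -> GroupComparison:
    """Two-sample t-test on organ means from two scanner groups (Welch default).

    Degenerate groups (zero variance on both sides) are handled explicitly:
    equal means give t = 0, p = 1; distinct means give p = 0.
    """
    g1 = np.asarray(means_group1, dtype=np.float64)
    g2 = np.asarray(means_group2, dtype=np.float64)
    if g1.size < 2 or g2.size < 2:
        raise DataError("each scanner group needs at least 2 organ means")
    summary = (float(g1.mean()), float(g1.std(ddof=ddof)),
               float(g2.mean()), float(g2.std(ddof=ddof)))
    if g1.std() == 0 and g2.std() == 0:
        if g1.mean() == g2.mean():
            return GroupComparison(*summary, t=0.0, p=1.0)
        return GroupComparison(*summary, t=float("inf"), p=0.0)
    t, p = stats.ttest_ind(g1, g2, equal_var=equal_var)
    return GroupComparison(*summary, t=float(t), p=float(p))


@dataclasses.dataclass
class CohortReport:
    """Evaluation results for one (metric, organ, method) cell, table-style."""

    metric: str                     # "CV" | "MD" | "interscanner"
    organ: str
    method: str                     # e.g. "raw", "s-AC", "G-SUV"
    value_pct: float | None = None  # CV/MD as a percentage
    means: list[float] = dataclasses.field(default_factory=list)
    group_stats: GroupComparison | None = None

    def row(self) -> dict:
        d = {"metric": self.metric, "organ": self.organ, "method": self.method,
             "value_pct": self.value_pct}
        if self.group_stats is not None:
            g = self.group_stats
            d.update({"M1": g.m1, "S1": g.s1, "M2": g.m2, "S2": g.s2,
                      "t": g.t, "p": g.p})
        return d


def report_to_csv(reports: Sequence[CohortReport], path) -> pd.DataFrame:
    df = pd.DataFrame([r.row() for r in reports])
    df.to_csv(path, index=False)
    return df


def format_report(reports: Sequence[CohortReport]) -> str:
    """Human-readable text table of the evaluation results."""
    df = pd.DataFrame([r.row() for r in reports])
    return df.to_string(index=False, float_format=lambda x: f"{x:.4g}")
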