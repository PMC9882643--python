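"""Run configuration: calibration grid, scale length, SD convention.

Defaults follow the method's operating point: upper-percentile search window
[90, 100] at 0.1-percentile resolution, standard-scale length s_max = 5.00 for
SUV volumes and 50 000 Bq/mL for AC volumes (both chosen so that an SUV
difference of 0.01 -- the clinically meaningful discriminability -- survives
the mapping), and population (divide-by-n) standard deviations.
"""

from __future__ import annotations

import dataclasses
import os
from typing import Sequence

import yaml

from .exceptions import DataError
from .image_io import Modality

__all__ = ["RunConfig", "S_MAX_DEFAULTS", "default_s_max"]

S_MAX_DEFAULTS = {Modality.AC: 50_000.0, Modality.SUV: 5.00}


def default_s_max(modality: Modality | str) -> float:
    return S_MAX_DEFAULTS[Modality(modality).base]


@dataclasses.dataclass
class RunConfig:
    """Parameters shared by calibration, transformation and evaluation."""

    modality: str | None = None
    s_max: float | None = None          # None -> modality default
    b_low: float = 90.0
    b_high: float = 100.0
    b_step: float = 0.1
    sd_convention: str = "population"   # "population" (ddof=0) or "sample" (ddof=1)
    strategy: Sequence[str] = ()
    seed: int = 0
    tie_atol: float = 1e-12             # delta ties in the beta grid search
    equal_var_ttest: bool = False       # False -> Welch

    def __post_init__(self) -> None:
        if self.sd_convention not in ("population", "sample"):
            raise DataError(f"sd_convention must be 'population' or 'sample', "
                            f"got {self.sd_convention!r}")
        if not (0.0 <= self.b_low <= self.b_high <= 100.0):
            raise DataError(f"need 0 <= b_low <= b_high <= 100, got "
                            f"[{self.b_low}, {self.b_high}]")
        if self.b_step <= 0:
            raise DataError(f"b_step must be positive, got {self.b_step}")
        if self.s_max is not None and self.s_max <= 0:
            raise DataError(f"s_max must be positive, got {self.s_max}")
        if isinstance(self.strategy, str):
            self.strategy = tuple(t.strip() for t in self.strategy.split(",") if t.strip())
        else:
            self.strategy = tuple(self.strategy)

    @property
    def ddof(self) -> int:
        return 0 if self.sd_convention == "population" else 1

    def resolved_s_max(self, modality: Modality | str) -> float:
        return default_s_max(modality) if self.s_max is None else float(self.s_max)

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise DataError(f"config file {path} must contain a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise DataError(f"unknown config keys in {path}: {sorted(unknown)}")
        return cls(**raw)
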