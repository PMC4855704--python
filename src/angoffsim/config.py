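"""Simulation configuration.

All under-determined modelling choices are collected in one dataclass so a
run is fully described by (config, seed).  The defaults are the study
conditions; the alternatives are preserved as explicit switches rather than
silent edits.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Any

import yaml

#: Allowed transforms mapping the standard-normal accuracy draw z_A to a
#: valid (nonnegative) dispersion for the judge's raw item error.
ACCURACY_TRANSFORMS = ("abs", "square", "truncate")


@dataclass(frozen=True)
class SimulationConfig:
    """Resolved values of every modelling choice the formulas leave open.

    Parameters
    ----------
    accuracy_transform : {"abs", "square", "truncate"}
        How the standard-normal accuracy draw ``z_A`` becomes a nonnegative
        dispersion A.  ``"abs"`` (default) uses ``|z_A|`` (half-normal,
        mean ``sqrt(2/pi)``); ``"square"`` uses ``z_A**2`` (chi-square, mean
        1); ``"truncate"`` clips negative draws to 0.
    weight_floor : float
        Lower bound applied to the attribute weights Wa and Ws, each drawn
        as ``(N(0,1)+3)/3`` and therefore negative with probability
        ``P(Z < -3) ~= 0.00135``.  The round-1 score divides by Wa+Ws, so
        the floor keeps the divisor positive while being statistically
        invisible.
    zero_stringency : bool
        Diagnostic mode: draw the accuracy-on-stringency coupling Sa with
        mean 0 instead of ``1 - A``, removing the only non-zero-mean
        component of the round-1 score.  Used to verify that the grand mean
        cut-score collapses onto the true value 0.
    round2_normalize : bool
        If True, divide the round-2 score by the sum of the leadership
        weights (a proper weighted average) instead of by ``n*k``.
    """

    accuracy_transform: str = "abs"
    weight_floor: float = 1e-6
    zero_stringency: bool = False
    round2_normalize: bool = False

    def __post_init__(self) -> None:
        if self.accuracy_transform not in ACCURACY_TRANSFORMS:
            raise ValueError(
                f"accuracy_transform must be one of {ACCURACY_TRANSFORMS}, "
                f"got {self.accuracy_transform!r}"
            )
        if not (0 < self.weight_floor < 1):
            raise ValueError("weight_floor must lie in (0, 1)")

    def to_dict(self) -> dict[str, Any]:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "SimulationConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        return cls.from_dict(data)


DEFAULT_CONFIG = SimulationConfig()
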