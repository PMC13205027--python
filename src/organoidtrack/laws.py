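"""Small sampling-distribution descriptions used by the cohort generator.

Each law knows its own median, so generator code can state arm-level effects
on the scale the downstream statistics summarise (medians), and tests can
check empirical medians against the law's.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

_FAMILIES = ("normal", "lognormal", "constant", "uniform")


@dataclass(frozen=True)
class Law:
    """A one-dimensional sampling law: ``family`` plus its parameters.

    Families
    --------
    normal     : params ``loc`` (median = mean) and ``scale``
    lognormal  : params ``median`` and ``sigma_log`` (SD on the log scale)
    constant   : param ``value``
    uniform    : params ``low``, ``high``
    """

    family: str
    params: Mapping[str, float]

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ValueError(f"unknown law family {self.family!r}; known: {_FAMILIES}")
        object.__setattr__(self, "params", dict(self.params))

    # -- constructors ---------------------------------------------------
    @classmethod
    def normal(cls, loc: float, scale: float) -> "Law":
        if scale < 0:
            raise ValueError("scale must be >= 0")
        return cls("normal", {"loc": float(loc), "scale": float(scale)})

    @classmethod
    def lognormal(cls, median: float, sigma_log: float) -> "Law":
        if median <= 0:
            raise ValueError("lognormal median must be > 0")
        return cls("lognormal", {"median": float(median), "sigma_log": float(sigma_log)})

    @classmethod
    def constant(cls, value: float) -> "Law":
        return cls("constant", {"value": float(value)})

    @classmethod
    def uniform(cls, low: float, high: float) -> "Law":
        if high < low:
            raise ValueError("uniform requires high >= low")
        return cls("uniform", {"low": float(low), "high": float(high)})

    # -- behaviour ------------------------------------------------------
    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        p = self.params
        if self.family == "normal":
            return rng.normal(p["loc"], p["scale"], size)
        if self.family == "lognormal":
            return p["median"] * np.exp(rng.normal(0.0, p["sigma_log"], size))
        if self.family == "constant":
            return np.full(size, p["value"])
        return rng.uniform(p["low"], p["high"], size)

    def median(self) -> float:
        p = self.params
        if self.family == "normal":
            return p["loc"]
        if self.family == "lognormal":
            return p["median"]
        if self.family == "constant":
            return p["value"]
        return 0.5 * (p["low"] + p["high"])

    # -- serialization --------------------------------------------------
    def to_dict(self) -> dict:
        return {"family": self.family, **self.params}

    @classmethod
    def from_dict(cls, d: Mapping[str, float | str]) -> "Law":
        d = dict(d)
        family = str(d.pop("family"))
        return cls(family, {k: float(v) for k, v in d.items()})
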