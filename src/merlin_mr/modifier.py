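"""Effect-modifier specification and its moment functions.

The modifier ``E`` (sex, age group, a standardized continuous covariate, ...)
always enters the model on a standardized scale: mean 0, variance 1.  For a
binary modifier observed as a Bernoulli(p) indicator, the standardized levels
are

    e1 = sqrt((1 - p) / p)     for stratum 1,
    e0 = -sqrt(p / (1 - p))    for stratum 0,

which reduces to the familiar +/-1 coding when p = 1/2 (e.g. sex in a balanced
cohort, Male = +1, Female = -1).  The third central moment of the standardized
variable,

    mu3 = (1 - 2 p) / sqrt(p (1 - p)),

quantifies its skewness and appears in the mean structure of the outcome-GWIS
likelihood block; it vanishes for a balanced binary modifier and for any
symmetric continuous modifier.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np

__all__ = [
    "ModifierSpec",
    "standardized_levels",
    "mu3",
    "standardize",
]


def standardized_levels(p: float) -> Tuple[float, float]:
    """Standardized values taken by a binary modifier with stratum-1 proportion ``p``.

    Returns ``(e1, e0)`` such that a random variable equal to ``e1`` with
    probability ``p`` and ``e0`` with probability ``1 - p`` has mean 0 and
    variance 1 exactly.
    """
    if not 0.0 < p < 1.0:
        raise ValueError(f"stratum proportion p must lie in (0, 1), got {p}")
    e1 = math.sqrt((1.0 - p) / p)
    e0 = -math.sqrt(p / (1.0 - p))
    return e1, e0


def mu3(p: float) -> float:
    """Third central moment (skewness) of the standardized Bernoulli(p) modifier."""
    if not 0.0 < p < 1.0:
        raise ValueError(f"stratum proportion p must lie in (0, 1), got {p}")
    return (1.0 - 2.0 * p) / math.sqrt(p * (1.0 - p))


def standardize(values: np.ndarray) -> np.ndarray:
    """Center and scale a continuous modifier to mean 0, sd 1 (ddof=0)."""
    values = np.asarray(values, dtype=float)
    sd = values.std()
    if sd == 0:
        raise ValueError("modifier has zero variance; cannot standardize")
    return (values - values.mean()) / sd


@dataclass(frozen=True)
class ModifierSpec:
    """Type and moments of the effect modifier E.

    Parameters
    ----------
    kind:
        ``"binary"`` or ``"continuous"``.
    p:
        Stratum-1 proportion for a binary modifier (ignored otherwise).
    mu3:
        Third central moment of the standardized modifier.  Derived from ``p``
        for binary modifiers; defaults to 0 for continuous ones (symmetric E).
    """

    kind: str
    p: Optional[float] = None
    mu3: float = field(default=0.0)

    def __post_init__(self) -> None:
        if self.kind not in ("binary", "continuous"):
            raise ValueError(f"modifier kind must be 'binary' or 'continuous', got {self.kind!r}")
        if self.kind == "binary":
            if self.p is None:
                raise ValueError("binary modifier requires stratum proportion p")
            if not 0.0 < self.p < 1.0:
                raise ValueError(f"stratum proportion p must lie in (0, 1), got {self.p}")

    @classmethod
    def binary(cls, p: float = 0.5) -> "ModifierSpec":
        return cls(kind="binary", p=p, mu3=mu3(p))

    @classmethod
    def continuous(cls, mu3: float = 0.0) -> "ModifierSpec":
        return cls(kind="continuous", p=None, mu3=mu3)

    @property
    def levels(self) -> Tuple[float, float]:
        """Standardized ``(e1, e0)`` levels (binary only)."""
        if self.kind != "binary":
            raise ValueError("levels are defined only for binary modifiers")
        return standardized_levels(self.p)

    def to_dict(self) -> dict:
        return {"kind": self.kind, "p": self.p, "mu3": self.mu3}

    @classmethod
    def from_dict(cls, d: dict) -> "ModifierSpec":
        kind = d["kind"]
        if kind == "binary":
            spec = cls.binary(float(d["p"]))
            # honour an explicit override of mu3 if present and different
            if "mu3" in d and d["mu3"] is not None and not math.isclose(float(d["mu3"]), spec.mu3, abs_tol=1e-9):
                spec = cls(kind="binary", p=float(d["p"]), mu3=float(d["mu3"]))
            return spec
        return cls.continuous(float(d.get("mu3") or 0.0))
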