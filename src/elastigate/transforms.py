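"""Per-parameter display transforms mapping raw data onto normalized plot units.

Every parameter used by a plot carries exactly one transform; the same
transform configuration is applied to training and target samples so that
all plots share an identical scale range and registration only has to
account for genuine data movement.  Each transform maps its stated data
range onto [0, 1], is strictly monotone, and has a closed-form inverse.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "LinearTransform",
    "Log10Transform",
    "BiexponentialTransform",
    "TransformConfig",
    "transform_from_dict",
]


@dataclass(frozen=True)
class LinearTransform:
    """Affine map of [vmin, vmax] onto [0, 1]."""

    vmin: float
    vmax: float
    kind = "linear"

    def __post_init__(self):
        if not self.vmax > self.vmin:
            raise ValueError("linear transform requires vmax > vmin")

    def apply(self, v):
        v = np.asarray(v, dtype=float)
        return (v - self.vmin) / (self.vmax - self.vmin)

    def inverse(self, u):
        u = np.asarray(u, dtype=float)
        return self.vmin + u * (self.vmax - self.vmin)

    def to_dict(self):
        return {"type": "linear", "min": float(self.vmin), "max": float(self.vmax)}


@dataclass(frozen=True)
class Log10Transform:
    """Log-decade map of [vmin, vmax] onto [0, 1]; vmin must be positive."""

    vmin: float
    vmax: float
    kind = "log10"

    def __post_init__(self):
        if not (self.vmin > 0 and self.vmax > self.vmin):
            raise ValueError("log10 transform requires 0 < vmin < vmax")

    def apply(self, v):
        v = np.maximum(np.asarray(v, dtype=float), self.vmin)
        return (np.log10(v) - np.log10(self.vmin)) / (
            np.log10(self.vmax) - np.log10(self.vmin)
        )

    def inverse(self, u):
        u = np.asarray(u, dtype=float)
        return 10.0 ** (np.log10(self.vmin) + u * (np.log10(self.vmax) - np.log10(self.vmin)))

    def to_dict(self):
        return {"type": "log10", "min": float(self.vmin), "max": float(self.vmax)}


@dataclass(frozen=True)
class BiexponentialTransform:
    """Scaled-asinh biexponential: linear near zero, logarithmic at range top.

    The linearization half-width is ``|width_basis|`` (the conventional
    width basis is quoted negative, e.g. -100).  The displayed range runs
    from ``-w * 10**negative_decades`` to ``w * 10**positive_decades`` with
    ``w = |width_basis|``; asinh interpolates smoothly between the linear
    and logarithmic regimes.  This is a member of the logicle family, not a
    replica of any particular vendor dialect.
    """

    width_basis: float = -100.0
    negative_decades: float = 0.5
    positive_decades: float = 4.5
    kind = "biexponential"

    def __post_init__(self):
        if self.width_basis == 0:
            raise ValueError("width_basis must be nonzero")
        if self.positive_decades <= 0 or self.negative_decades < 0:
            raise ValueError("decades must be positive (negative_decades >= 0)")

    @property
    def _w(self) -> float:
        return abs(self.width_basis)

    @property
    def _lo(self) -> float:
        return float(np.arcsinh(-(10.0 ** self.negative_decades)))

    @property
    def _hi(self) -> float:
        return float(np.arcsinh(10.0 ** self.positive_decades))

    def apply(self, v):
        v = np.asarray(v, dtype=float)
        return (np.arcsinh(v / self._w) - self._lo) / (self._hi - self._lo)

    def inverse(self, u):
        u = np.asarray(u, dtype=float)
        return self._w * np.sinh(self._lo + u * (self._hi - self._lo))

    def to_dict(self):
        return {
            "type": "biexponential",
            "width_basis": self.width_basis,
            "negative_decades": self.negative_decades,
            "positive_decades": self.positive_decades,
        }


def transform_from_dict(d: dict):
    t = d.get("type")
    if t == "linear":
        return LinearTransform(float(d["min"]), float(d["max"]))
    if t == "log10":
        return Log10Transform(float(d["min"]), float(d["max"]))
    if t == "biexponential":
        return BiexponentialTransform(
            float(d.get("width_basis", -100.0)),
            float(d.get("negative_decades", 0.5)),
            float(d.get("positive_decades", 4.5)),
        )
    raise ValueError(f"unknown transform type: {t!r}")


class TransformConfig:
    """Mapping from parameter name to its display transform."""

    def __init__(self, transforms: dict):
        self._transforms = dict(transforms)

    def __getitem__(self, param: str):
        try:
            return self._transforms[param]
        except KeyError:
            raise KeyError(f"no transform configured for parameter {param!r}") from None

    def __contains__(self, param: str) -> bool:
        return param in self._transforms

    def parameters(self):
        return list(self._transforms)

    def items(self):
        return self._transforms.items()

    def apply(self, param: str, values):
        return self[param].apply(values)

    def to_dict(self) -> dict:
        return {p: t.to_dict() for p, t in sorted(self._transforms.items())}

    @classmethod
    def from_dict(cls, d: dict) -> "TransformConfig":
        return cls({p: transform_from_dict(spec) for p, spec in d.items()})

    def __eq__(self, other):
        return isinstance(other, TransformConfig) and self.to_dict() == other.to_dict()
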