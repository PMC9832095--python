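"""Calibration input space: named, bounded, unit-annotated parameters.

All internal computation (sampling, emulation, implausibility scoring)
operates on the unit hypercube ``[0, 1]^d``; natural units appear only at
the simulator boundary and in reports.  The affine maps between the two
frames live here.

The default space is the 14-dimensional cardiac electrophysiology space:
nine statistical-shape-model (SSM) mode weights describing the anatomy,
followed by five functional parameters of the mono-domain reaction-eikonal
setup — fibre angle, fast-endocardial-conduction (FEC) layer height,
fibre-direction conduction velocity and the two anisotropy scalars.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "ParameterSpace",
    "DesignMatrix",
    "make_default_space",
    "NATURAL",
    "UNIT",
]

NATURAL = "natural"
UNIT = "unit"


@dataclass(frozen=True)
class DesignMatrix:
    """An ``n x d`` matrix of design points tagged with its coordinate frame.

    ``frame`` is either ``"unit"`` (all entries in ``[0, 1]``) or
    ``"natural"`` (each column in its parameter's physical bounds).
    """

    points: np.ndarray
    frame: str = UNIT

    def __post_init__(self) -> None:
        pts = np.atleast_2d(np.asarray(self.points, dtype=float))
        object.__setattr__(self, "points", pts)
        if self.frame not in (NATURAL, UNIT):
            raise ValueError(f"unknown frame {self.frame!r}")

    @property
    def n(self) -> int:
        return self.points.shape[0]

    @property
    def d(self) -> int:
        return self.points.shape[1]


def _as_points(X) -> np.ndarray:
    if isinstance(X, DesignMatrix):
        return X.points
    return np.atleast_2d(np.asarray(X, dtype=float))


@dataclass(frozen=True)
class ParameterSpace:
    """Named, bounded input dimensions with natural <-> unit-cube scaling."""

    names: tuple
    lower: np.ndarray
    upper: np.ndarray
    units: tuple = field(default=())

    def __post_init__(self) -> None:
        names = tuple(self.names)
        lower = np.asarray(self.lower, dtype=float)
        upper = np.asarray(self.upper, dtype=float)
        units = tuple(self.units) if self.units else ("-",) * len(names)
        if len(set(names)) != len(names):
            raise ValueError("parameter names must be unique")
        if not (len(names) == lower.size == upper.size == len(units)):
            raise ValueError("names, bounds and units must have equal length")
        if not np.all(lower < upper):
            bad = [names[i] for i in np.nonzero(~(lower < upper))[0]]
            raise ValueError(f"lower must be < upper for parameters {bad}")
        object.__setattr__(self, "names", names)
        object.__setattr__(self, "lower", lower)
        object.__setattr__(self, "upper", upper)
        object.__setattr__(self, "units", units)

    @property
    def d(self) -> int:
        return len(self.names)

    @property
    def span(self) -> np.ndarray:
        return self.upper - self.lower

    def index(self, name: str) -> int:
        return self.names.index(name)

    # -- frame conversion ---------------------------------------------------

    def to_unit(self, X) -> DesignMatrix:
        """Affine map ``u_i = (x_i - lower_i) / (upper_i - lower_i)``.

        ``X`` must be in the natural frame and inside the bounds.
        """
        if isinstance(X, DesignMatrix) and X.frame == UNIT:
            raise ValueError("X is already in the unit frame")
        pts = _as_points(X)
        self._check_dim(pts)
        eps = 1e-12 * np.maximum(1.0, np.abs(self.span))
        low_ok = pts >= self.lower - eps
        high_ok = pts <= self.upper + eps
        if not (low_ok.all() and high_ok.all()):
            j = int(np.nonzero(~(low_ok & high_ok))[1][0])
            raise ValueError(
                f"value out of bounds for parameter {self.names[j]!r} "
                f"[{self.lower[j]}, {self.upper[j]}]"
            )
        u = (pts - self.lower) / self.span
        return DesignMatrix(np.clip(u, 0.0, 1.0), frame=UNIT)

    def from_unit(self, U) -> DesignMatrix:
        """Inverse of :meth:`to_unit`; entries must lie in ``[0, 1]``."""
        if isinstance(U, DesignMatrix) and U.frame == NATURAL:
            raise ValueError("U is already in the natural frame")
        u = _as_points(U)
        self._check_dim(u)
        if (u < -1e-12).any() or (u > 1 + 1e-12).any():
            j = int(np.nonzero((u < -1e-12) | (u > 1 + 1e-12))[1][0])
            raise ValueError(
                f"unit-frame value outside [0, 1] for parameter {self.names[j]!r}"
            )
        x = self.lower + np.clip(u, 0.0, 1.0) * self.span
        return DesignMatrix(x, frame=NATURAL)

    def _check_dim(self, pts: np.ndarray) -> None:
        if pts.shape[1] != self.d:
            raise ValueError(f"expected {self.d} columns, got {pts.shape[1]}")

    # -- serialization ------------------------------------------------------

    def to_json(self) -> str:
        return json.dumps(
            [
                {"name": n, "lower": lo, "upper": hi, "unit": u}
                for n, lo, hi, u in zip(self.names, self.lower, self.upper, self.units)
            ],
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "ParameterSpace":
        rows = json.loads(text)
        return cls(
            names=[r["name"] for r in rows],
            lower=[r["lower"] for r in rows],
            upper=[r["upper"] for r in rows],
            units=[r.get("unit", "-") for r in rows],
        )


#: EP parameter rows: (name, lower, upper, unit)
_EP_ROWS = (
    ("fibre_angle", 40.0, 90.0, "deg"),
    ("fec_height", 33.0, 100.0, "% apico-basal"),
    ("cv", 0.64, 0.92, "m/s"),
    ("k_xf", 0.11, 0.35, "-"),
    ("k_fec", 1.1, 8.75, "-"),
)


def make_default_space(mode_bounds: tuple[float, float] = (-3.0, 3.0)) -> ParameterSpace:
    """The default 14-dim space: SSM modes 1-9 then the five EP parameters.

    Mode weights default to ``[-3, 3]`` (interpretable as SD units of each
    shape mode); they are configurable because the tight cohort-specific
    intervals depend on the anatomical atlas in use.
    """
    lo, hi = mode_bounds
    names = [f"mode{i}" for i in range(1, 10)] + [r[0] for r in _EP_ROWS]
    lower = [lo] * 9 + [r[1] for r in _EP_ROWS]
    upper = [hi] * 9 + [r[2] for r in _EP_ROWS]
    units = ["SD"] * 9 + [r[3] for r in _EP_ROWS]
    return ParameterSpace(names=names, lower=lower, upper=upper, units=units)
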