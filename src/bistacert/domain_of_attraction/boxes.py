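"""Axis-aligned boxes in state space, with face-normal and vertex views."""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

__all__ = ["AxisBox", "to_shifted", "to_absolute"]

_FRAMES = ("absolute", "shifted")


@dataclass
class AxisBox:
    """Box ``{x : lower <= x <= upper}`` in absolute or equilibrium-shifted
    coordinates.

    In the shifted frame the origin must be strictly interior
    (``lower < 0 < upper``), which is what the certification conditions
    require.  The box doubles as a polytope: ``face_normals`` returns the
    2n vectors ``a_k`` with ``a_k' x <= 1`` (shifted frame only, where the
    normalization is well defined), ``vertices`` the 2^n corners.
    """

    lower: np.ndarray
    upper: np.ndarray
    frame: str = "absolute"

    def __post_init__(self) -> None:
        self.lower = np.asarray(self.lower, dtype=float)
        self.upper = np.asarray(self.upper, dtype=float)
        if self.lower.shape != self.upper.shape or self.lower.ndim != 1:
            raise ValueError("lower/upper must be 1-D vectors of equal length")
        if not np.all(self.lower < self.upper):
            raise ValueError("box requires lower < upper componentwise")
        if self.frame not in _FRAMES:
            raise ValueError(f"frame must be one of {_FRAMES}")
        if self.frame == "shifted" and not (
            np.all(self.lower < 0) and np.all(self.upper > 0)
        ):
            raise ValueError("shifted box must contain the origin strictly")

    @property
    def n(self) -> int:
        return self.lower.shape[0]

    @property
    def widths(self) -> np.ndarray:
        return self.upper - self.lower

    @property
    def center(self) -> np.ndarray:
        return 0.5 * (self.lower + self.upper)

    def volume(self) -> float:
        return float(np.prod(self.widths))

    def contains(self, x, tol: float = 0.0) -> bool:
        x = np.asarray(x, dtype=float)
        w = np.maximum(self.widths, 1.0) * tol
        return bool(np.all(x >= self.lower - w) and np.all(x <= self.upper + w))

    def strictly_contains(self, x) -> bool:
        x = np.asarray(x, dtype=float)
        return bool(np.all(x > self.lower) and np.all(x < self.upper))

    def face_normals(self) -> np.ndarray:
        """The q = 2n rows ``a_k`` with the box equal to ``{a_k' x <= 1}``."""
        if self.frame != "shifted":
            raise ValueError("face normals in a' x <= 1 form require the shifted frame")
        return np.vstack([np.diag(1.0 / self.upper), np.diag(1.0 / self.lower)])

    def vertices(self, max_dim: int = 16) -> np.ndarray:
        """All 2^n corners, shape (2^n, n)."""
        if self.n > max_dim:
            raise ValueError(f"refusing to enumerate 2^{self.n} vertices")
        grids = np.meshgrid(*[(self.lower[i], self.upper[i]) for i in range(self.n)],
                            indexing="ij")
        return np.stack([g.ravel() for g in grids], axis=1)

    def scaled(self, factor: float) -> "AxisBox":
        """Scale toward the frame origin (shifted) or the center (absolute)."""
        if self.frame == "shifted":
            return AxisBox(self.lower * factor, self.upper * factor, "shifted")
        c = self.center
        return AxisBox(
            c + factor * (self.lower - c), c + factor * (self.upper - c), "absolute"
        )

    def intersects(self, other: "AxisBox") -> bool:
        return bool(
            np.all(self.lower <= other.upper) and np.all(other.lower <= self.upper)
        )

    # -- serialization -----------------------------------------------------

    def to_dict(self, names=None) -> dict:
        d = {"frame": self.frame}
        if names is not None:
            d["intervals"] = {
                nm: [float(l), float(u)]
                for nm, l, u in zip(names, self.lower, self.upper)
            }
        else:
            d["lower"] = self.lower.tolist()
            d["upper"] = self.upper.tolist()
        return d

    @classmethod
    def from_dict(cls, d: dict, names=None) -> "AxisBox":
        if "intervals" in d:
            iv = d["intervals"]
            keys = list(names) if names is not None else list(iv)
            lo = np.array([iv[k][0] for k in keys])
            hi = np.array([iv[k][1] for k in keys])
            return cls(lo, hi, d.get("frame", "absolute"))
        return cls(np.asarray(d["lower"]), np.asarray(d["upper"]),
                   d.get("frame", "absolute"))

    def to_json(self, names=None) -> str:
        return json.dumps(self.to_dict(names), indent=1)


def to_shifted(box: AxisBox, equilibrium) -> AxisBox:
    """Shift an absolute-frame box so the equilibrium becomes the origin.

    The equilibrium must lie strictly inside the box.
    """
    if box.frame != "absolute":
        raise ValueError("box is already shifted")
    xe = np.asarray(getattr(equilibrium, "state", equilibrium), dtype=float)
    if not box.strictly_contains(xe):
        raise ValueError("equilibrium must lie strictly inside the box")
    return AxisBox(box.lower - xe, box.upper - xe, "shifted")


def to_absolute(box: AxisBox, equilibrium) -> AxisBox:
    if box.frame != "shifted":
        raise ValueError("box is not in the shifted frame")
    xe = np.asarray(getattr(equilibrium, "state", equilibrium), dtype=float)
    return AxisBox(box.lower + xe, box.upper + xe, "absolute")
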