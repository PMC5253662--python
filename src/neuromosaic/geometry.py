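"""Axis-aligned observation windows and 3D point patterns.

All coordinates are in micrometres. A :class:`PointPattern` is the basic
object consumed by the spatial-statistics modules: a set of cell positions
(typically motor-neuron centroids) together with the axis-aligned box that
was actually surveyed, which is required for edge correction and for any
density statement.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["Box3D", "PointPattern"]


@dataclass(frozen=True)
class Box3D:
    """Axis-aligned box ``[lo, hi)`` in μm, the observation window (ROI).

    The box is half-open: points may sit on the low faces but not on the
    high faces, which keeps translation edge-correction weights finite.
    """

    lo: np.ndarray
    hi: np.ndarray

    def __init__(self, lo, hi):
        lo = np.asarray(lo, dtype=float)
        hi = np.asarray(hi, dtype=float)
        if lo.shape != (3,) or hi.shape != (3,):
            raise ValueError("lo and hi must be 3-vectors")
        if not np.all(hi > lo):
            raise ValueError(f"box must satisfy hi > lo on every axis, got lo={lo}, hi={hi}")
        object.__setattr__(self, "lo", lo)
        object.__setattr__(self, "hi", hi)

    @classmethod
    def cube(cls, side: float, origin=(0.0, 0.0, 0.0)) -> "Box3D":
        origin = np.asarray(origin, dtype=float)
        return cls(origin, origin + float(side))

    @property
    def sides(self) -> np.ndarray:
        return self.hi - self.lo

    @property
    def volume(self) -> float:
        return float(np.prod(self.sides))

    @property
    def min_side(self) -> float:
        return float(self.sides.min())

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Boolean mask of points inside ``[lo, hi)``."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return np.all((pts >= self.lo) & (pts < self.hi), axis=1)

    def to_dict(self) -> dict:
        return {"lo": self.lo.tolist(), "hi": self.hi.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "Box3D":
        return cls(d["lo"], d["hi"])


@dataclass
class PointPattern:
    """A finite set of 3D points (μm) observed in a :class:`Box3D`.

    Parameters
    ----------
    points : (n, 3) array
        Cell positions in μm.
    box : Box3D
        The observation window; every point must lie in ``[lo, hi)``.
    labels : sequence of str, optional
        Per-point size-class tag (e.g. ``"motor_neuron"``).
    """

    points: np.ndarray
    box: Box3D
    labels: np.ndarray | None = field(default=None)

    def __post_init__(self):
        pts = np.asarray(self.points, dtype=float).reshape(-1, 3)
        self.points = pts
        if len(pts) and not np.all(self.box.contains(pts)):
            bad = np.nonzero(~self.box.contains(pts))[0]
            raise ValueError(
                f"{len(bad)} point(s) outside the box [lo, hi): indices {bad[:10].tolist()}"
            )
        if len(pts) > 1:
            # duplicate positions break Voronoi tessellation and are
            # physically meaningless for cell somata
            uniq = np.unique(pts, axis=0)
            if len(uniq) != len(pts):
                raise ValueError("point pattern contains duplicate positions")
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if len(self.labels) != len(pts):
                raise ValueError("labels length must match number of points")

    def __len__(self) -> int:
        return len(self.points)

    @property
    def n(self) -> int:
        return len(self.points)

    def density_mm3(self) -> float:
        """Intensity in points per mm³ (1 mm³ = 10⁹ μm³)."""
        return self.n / self.box.volume * 1e9

    def subset(self, mask) -> "PointPattern":
        mask = np.asarray(mask)
        labels = self.labels[mask] if self.labels is not None else None
        return PointPattern(self.points[mask], self.box, labels)

    # ------------------------------------------------------------------ I/O

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.points, columns=["x_um", "y_um", "z_um"])
        if self.labels is not None:
            df["class"] = self.labels
        return df

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, box: Box3D) -> "PointPattern":
        df = pd.read_csv(path)
        pts = df[["x_um", "y_um", "z_um"]].to_numpy(dtype=float)
        labels = df["class"].to_numpy() if "class" in df.columns else None
        return cls(pts, box, labels)
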