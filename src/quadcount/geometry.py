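"""Uniform-random square quadrat grids: placement, tilt and point location.

The sampling design is a square lattice of square quadrats.  One quadrat of
side ``t`` sits in every fundamental box of side ``T`` (``0 < t <= T``); the
whole grid is dragged by a single uniform-random offset inside one box, which
is what makes the count-based size estimator design-unbiased.  The grid may be
tilted by an arbitrary fixed angle; tilt is realised by rotating the grid
about the centre of the observation window, which is equivalent to rotating
the picture the other way.

Quadrats are half-open ``[x, x+t) x [y, y+t)`` in the grid's own frame, so a
point is never assigned to two quadrats and the discrete exhaustive-offset
identity (every integer point is captured by exactly ``t**2`` of the ``T**2``
integer offsets) holds exactly.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
import yaml
from shapely.geometry import Polygon, box

__all__ = [
    "InvalidRegionError",
    "Rect",
    "GridSpec",
    "QuadratAddress",
    "PointPattern",
    "GridLayout",
    "make_uniform_offset",
    "grid_quadrats",
    "locate_point",
]

# Grid origins that land within a sub-nanopixel of an integer are snapped to
# it, so that integer-offset sweeps over integer coordinates are exact in
# floating point.  The snap is far below any physical pixel resolution.
_OFFSET_SNAP = 1e-9


class InvalidRegionError(ValueError):
    """Raised for empty or degenerate observation windows."""


@dataclass(frozen=True)
class Rect:
    """Axis-aligned rectangle, used as the observation window."""

    xmin: float
    ymin: float
    xmax: float
    ymax: float

    def __post_init__(self) -> None:
        if not (
            math.isfinite(self.xmin)
            and math.isfinite(self.ymin)
            and math.isfinite(self.xmax)
            and math.isfinite(self.ymax)
        ):
            raise InvalidRegionError("region coordinates must be finite")
        if self.xmax <= self.xmin or self.ymax <= self.ymin:
            raise InvalidRegionError(
                f"degenerate region: [{self.xmin}, {self.xmax}] x "
                f"[{self.ymin}, {self.ymax}]"
            )

    @classmethod
    def from_size(cls, width: float, height: float) -> "Rect":
        return cls(0.0, 0.0, float(width), float(height))

    @property
    def width(self) -> float:
        return self.xmax - self.xmin

    @property
    def height(self) -> float:
        return self.ymax - self.ymin

    @property
    def center(self) -> tuple[float, float]:
        return (0.5 * (self.xmin + self.xmax), 0.5 * (self.ymin + self.ymax))

    @property
    def area(self) -> float:
        return self.width * self.height

    def corners(self) -> np.ndarray:
        """Corner coordinates, counter-clockwise from the lower left."""
        return np.array(
            [
                [self.xmin, self.ymin],
                [self.xmax, self.ymin],
                [self.xmax, self.ymax],
                [self.xmin, self.ymax],
            ]
        )

    def contains(self, points: np.ndarray, tol: float = 1e-9) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        return (
            (pts[:, 0] >= self.xmin - tol)
            & (pts[:, 0] <= self.xmax + tol)
            & (pts[:, 1] >= self.ymin - tol)
            & (pts[:, 1] <= self.ymax + tol)
        )


def make_uniform_offset(seed: int) -> tuple[float, float]:
    """Draw the pair of unit-interval fractions that positions the grid.

    The whole grid placement is determined by this single pair: the lower
    left corner of one quadrat is put at ``(u1*T, u2*T)`` inside the
    fundamental box, dragging the rest of the grid along.
    """
    rng = np.random.default_rng(seed)
    u1, u2 = rng.random(2)
    return float(u1), float(u2)


@dataclass(frozen=True)
class GridSpec:
    """The sampling design: quadrat side, box side, tilt and UR offset.

    ``offset`` holds the pair of unit-interval fractions ``(u1, u2)``;
    the grid origin in its own frame is ``(u1*T, u2*T)``.
    """

    t: float
    T: float
    theta_deg: float = 0.0
    offset: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if not (0.0 < self.t <= self.T and math.isfinite(self.T)):
            raise ValueError(f"need 0 < t <= T < inf, got t={self.t}, T={self.T}")
        u1, u2 = self.offset
        if not (0.0 <= u1 < 1.0 and 0.0 <= u2 < 1.0):
            raise ValueError(f"offset fractions must lie in [0, 1), got {self.offset}")

    @property
    def tau(self) -> float:
        """Linear (stripe) sampling fraction t/T."""
        return self.t / self.T

    @property
    def sampling_fraction(self) -> float:
        """Areal sampling fraction t^2/T^2."""
        return (self.t / self.T) ** 2

    @property
    def inflation(self) -> float:
        """The count multiplier (T/t)^2 of the size estimator."""
        return (self.T / self.t) ** 2

    def with_offset(self, u1: float, u2: float) -> "GridSpec":
        return replace(self, offset=(float(u1), float(u2)))

    def with_seeded_offset(self, seed: int) -> "GridSpec":
        return self.with_offset(*make_uniform_offset(seed))

    # -- flat-config serialization (JSON and YAML dialects) ------------------

    def to_dict(self) -> dict:
        return {
            "t": self.t,
            "T": self.T,
            "theta_deg": self.theta_deg,
            "u1": self.offset[0],
            "u2": self.offset[1],
        }

    @classmethod
    def from_dict(cls, cfg: dict) -> "GridSpec":
        if "u1" in cfg or "u2" in cfg:
            offset = (float(cfg.get("u1", 0.0)), float(cfg.get("u2", 0.0)))
        elif cfg.get("seed") is not None:
            offset = make_uniform_offset(int(cfg["seed"]))
        else:
            offset = (0.0, 0.0)
        return cls(
            t=float(cfg["t"]),
            T=float(cfg["T"]),
            theta_deg=float(cfg.get("theta_deg", 0.0)),
            offset=offset,
        )

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "GridSpec":
        return cls.from_dict(json.loads(text))

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "GridSpec":
        return cls.from_dict(yaml.safe_load(text))

    @classmethod
    def load(cls, path: str | Path) -> "GridSpec":
        path = Path(path)
        text = path.read_text()
        if path.suffix.lower() in {".yaml", ".yml"}:
            return cls.from_yaml(text)
        return cls.from_json(text)


class QuadratAddress(NamedTuple):
    """(stripe, position-within-stripe) label of one quadrat.

    Stripes are columns of quadrats along the grid's own y axis, numbered
    left to right; positions within a stripe run bottom to top.  Addresses
    produced for a bounded window are 1-based over the enumerated quadrats.
    """

    stripe_index: int
    within_index: int


@dataclass
class PointPattern:
    """A population given as one associated point per particle."""

    points: np.ndarray
    bounds: Rect
    true_n: int | None = None

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.size == 0:
            pts = pts.reshape(0, 2)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ValueError(f"points must have shape (N, 2), got {pts.shape}")
        self.points = pts
        if not bool(np.all(self.bounds.contains(pts))):
            raise ValueError("all points must lie within the bounds rectangle")
        if self.true_n is not None and self.true_n != len(pts):
            raise ValueError(
                f"true_n={self.true_n} does not match {len(pts)} points"
            )

    @property
    def n(self) -> int:
        return len(self.points)

    @classmethod
    def from_csv(
        cls,
        path: str | Path,
        bounds: Rect | None = None,
        y_down: bool = False,
        true_n: int | None = None,
    ) -> "PointPattern":
        """Read a pattern from a CSV with header columns ``x,y`` (pixels).

        With ``y_down=True`` the raster convention (origin top-left, y
        increasing downwards) is converted to the mathematical one so that
        "bottom to top" within stripes is unambiguous; ``bounds`` is then
        required to supply the picture height.
        """
        df = pd.read_csv(path)
        missing = {"x", "y"} - set(df.columns)
        if missing:
            raise ValueError(f"points CSV must have columns x,y; missing {missing}")
        pts = df[["x", "y"]].to_numpy(dtype=float)
        if y_down:
            if bounds is None:
                raise ValueError("y_down conversion requires explicit bounds")
            pts[:, 1] = bounds.ymax - (pts[:, 1] - bounds.ymin)
        if bounds is None:
            if len(pts) == 0:
                bounds = Rect.from_size(1.0, 1.0)
            else:
                xmax = float(max(np.max(pts[:, 0]), 1.0))
                ymax = float(max(np.max(pts[:, 1]), 1.0))
                xmin = float(min(np.min(pts[:, 0]), 0.0))
                ymin = float(min(np.min(pts[:, 1]), 0.0))
                bounds = Rect(xmin, ymin, xmax, ymax)
        return cls(points=pts, bounds=bounds, true_n=true_n)

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(self.points, columns=["x", "y"]).to_csv(path, index=False)


def _snap(value: float) -> float:
    nearest = round(value)
    if abs(value - nearest) < _OFFSET_SNAP:
        return float(nearest)
    return value


class GridLayout:
    """A grid placement resolved against a bounded observation window.

    Precomputes, in the grid frame, the lattice index range of every stripe
    that can meet the window (grazing quadrats included: a quadrat is
    enumerated whenever its closure intersects the closed window), so that
    quadrat enumeration and vectorized point location share one indexing.
    """

    def __init__(self, spec: GridSpec, bounds: Rect):
        self.spec = spec
        self.bounds = bounds
        self._cx, self._cy = bounds.center
        th = math.radians(spec.theta_deg)
        self._cos = math.cos(th)
        self._sin = math.sin(th)
        self._offx = _snap(spec.offset[0] * spec.T)
        self._offy = _snap(spec.offset[1] * spec.T)

        corners = self.to_grid(bounds.corners())
        self._poly = Polygon(corners)
        # strict ranges: quadrats whose closure intersects the closed window;
        # these define the manual-count positions (odd/even parity)
        self._cols = self._ranges(spec.t)
        if not self._cols:
            raise InvalidRegionError("grid does not meet the observation window")
        self._i_lo = min(self._cols)

    # -- frame changes -------------------------------------------------------

    def to_grid(self, points: np.ndarray) -> np.ndarray:
        """World -> grid frame: rotate by -theta about the window centre."""
        pts = np.asarray(points, dtype=float)
        x = pts[..., 0] - self._cx
        y = pts[..., 1] - self._cy
        gx = self._cos * x + self._sin * y + self._cx
        gy = -self._sin * x + self._cos * y + self._cy
        return np.stack([gx, gy], axis=-1)

    def to_world(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        x = pts[..., 0] - self._cx
        y = pts[..., 1] - self._cy
        wx = self._cos * x - self._sin * y + self._cx
        wy = self._sin * x + self._cos * y + self._cy
        return np.stack([wx, wy], axis=-1)

    # -- lattice bookkeeping -------------------------------------------------

    def _column_range(
        self, i: int, footprint: float, gy0: float, gy1: float
    ) -> tuple[int, int] | None:
        T = self.spec.T
        x0 = self._offx + i * T
        slab = box(x0, gy0 - T, x0 + footprint, gy1 + T)
        clip = self._poly.intersection(slab)
        if clip.is_empty:
            return None
        cy0, cy1 = clip.bounds[1], clip.bounds[3]
        j_lo = math.ceil((cy0 - footprint - self._offy) / T)
        j_hi = math.floor((cy1 - self._offy) / T)
        if j_hi < j_lo:
            return None
        return j_lo, j_hi

    def _ranges(self, footprint: float) -> dict[int, tuple[int, int]]:
        """Columns of lattice cells whose [0, footprint]^2 patch meets the
        window; footprint = t gives the strict quadrat set, footprint = T the
        conservative fundamental-box superset."""
        gx0, gy0, gx1, gy1 = self._poly.bounds
        T = self.spec.T
        i_lo = math.ceil((gx0 - footprint - self._offx) / T)
        i_hi = math.floor((gx1 - self._offx) / T)
        out: dict[int, tuple[int, int]] = {}
        for i in range(i_lo, i_hi + 1):
            jr = self._column_range(i, footprint, gy0, gy1)
            if jr is not None:
                out[i] = jr
        return out

    def address(self, i: int, j: int) -> QuadratAddress:
        """Address of the quadrat with lattice indices ``(i, j)``.

        Anchored at the strictly window-intersecting set: its bottom-left
        quadrat is (1, 1).  Cells outside that set get extrapolated (possibly
        nonpositive) indices; they can never hold a point of the window.
        """
        jr = self._cols.get(i)
        if jr is None:
            gx0, gy0, gx1, gy1 = self._poly.bounds
            jr = self._column_range(i, self.spec.t, gy0, gy1) or (j, j)
            self._cols[i] = jr
        return QuadratAddress(i - self._i_lo + 1, j - jr[0] + 1)

    def corner(self, i: int, j: int) -> tuple[float, float]:
        """World-frame lower-left corner of quadrat ``(i, j)``."""
        g = np.array(
            [self._offx + i * self.spec.T, self._offy + j * self.spec.T]
        )
        w = self.to_world(g)
        return float(w[0]), float(w[1])

    def quadrats(self) -> list[tuple[QuadratAddress, tuple[float, float]]]:
        """Conservative enumeration: every quadrat whose fundamental box can
        meet the window, so no grazing quadrat is ever missed."""
        cells = self._ranges(self.spec.T)
        out = []
        for i in sorted(cells):
            j_lo, j_hi = cells[i]
            for j in range(j_lo, j_hi + 1):
                out.append((self.address(i, j), self.corner(i, j)))
        return out

    def lattice_columns(self) -> dict[int, tuple[int, int]]:
        return dict(self._cols)

    def locate(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Lattice indices and in-quadrat mask for an ``(N, 2)`` array.

        A point belongs to the quadrat of its fundamental box iff its
        residual in both axes is below ``t`` (half-open convention); points
        in the gap between quadrats are masked out.
        """
        pts = np.asarray(points, dtype=float).reshape(-1, 2)
        g = self.to_grid(pts)
        g[:, 0] -= self._offx
        g[:, 1] -= self._offy
        T = self.spec.T
        ij = np.floor(g / T).astype(np.int64)
        frac = g - ij * T
        inside = (frac[:, 0] < self.spec.t) & (frac[:, 1] < self.spec.t)
        return ij, inside


def grid_quadrats(
    spec: GridSpec, bounds: Rect
) -> list[tuple[QuadratAddress, tuple[float, float]]]:
    """Enumerate every quadrat whose closure can intersect ``bounds``.

    Returns ``(address, world-frame lower-left corner)`` pairs.  Grazing
    quadrats (closure touching the window boundary) are included: the grid is
    conceptually unbounded and grazing quadrats hitting particles count.
    """
    return GridLayout(spec, bounds).quadrats()


def locate_point(
    p: Sequence[float], spec: GridSpec, bounds: Rect | None = None
) -> QuadratAddress | None:
    """Address of the half-open quadrat containing ``p``, or ``None``.

    With ``bounds`` the address is 1-based and consistent with
    :func:`grid_quadrats`; without it, raw lattice indices are returned (the
    tilt is then taken about the origin) and may be zero or negative.
    """
    pt = np.asarray(p, dtype=float).reshape(1, 2)
    if bounds is not None:
        layout = GridLayout(spec, bounds)
        ij, inside = layout.locate(pt)
        if not inside[0]:
            return None
        return layout.address(int(ij[0, 0]), int(ij[0, 1]))
    th = math.radians(spec.theta_deg)
    c, s = math.cos(th), math.sin(th)
    gx = c * pt[0, 0] + s * pt[0, 1] - _snap(spec.offset[0] * spec.T)
    gy = -s * pt[0, 0] + c * pt[0, 1] - _snap(spec.offset[1] * spec.T)
    i = math.floor(gx / spec.T)
    j = math.floor(gy / spec.T)
    if gx - i * spec.T < spec.t and gy - j * spec.T < spec.t:
        return QuadratAddress(i, j)
    return None
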