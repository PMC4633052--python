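"""Per-quadrat particle counts under edge-effect-unbiased counting rules.

Two rules are provided.  The associated-point rule counts a particle in the
(half-open) quadrat containing its associated point; it suits digitized
patterns and simulation.  The forbidden-line rule counts a particle in a
quadrat it touches unless it also touches the quadrat's forbidden boundary;
it suits manual counting of extended particles, and at full tiling (t = T)
it assigns every particle to exactly one quadrat.

The forbidden boundary adopted here is the classical unbiased-counting-frame
trace: the quadrat's left edge extended upward without limit, the bottom
edge, and the right edge's line extended downward from the lower-right
corner.  This trace is the one that makes the t = T tiling a partition for
arbitrary connected particles (touching the top or right edge is accepted;
touching the trace rejects).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from shapely.geometry import LineString, Polygon, box

from .geometry import GridLayout, GridSpec, PointPattern, QuadratAddress, Rect

__all__ = [
    "InvalidParticleError",
    "PolygonParticle",
    "QuadratSample",
    "count_points",
    "count_polygons_forbidden_line",
    "apply_border_rule",
    "forbidden_trace",
    "load_particles_json",
]


class InvalidParticleError(ValueError):
    """Raised for self-intersecting or degenerate particle outlines."""


@dataclass(frozen=True)
class PolygonParticle:
    """A particle given by its simple closed outline (>= 3 vertices)."""

    ring: tuple[tuple[float, float], ...]
    id: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "ring", tuple((float(x), float(y)) for x, y in self.ring)
        )
        if len(self.ring) < 3:
            raise InvalidParticleError(
                f"particle {self.id!r}: ring needs >= 3 vertices"
            )

    def to_shapely(self) -> Polygon:
        poly = Polygon(self.ring)
        if not poly.is_valid or poly.area <= 0:
            raise InvalidParticleError(
                f"particle {self.id!r}: ring must be simple with positive area"
            )
        return poly


def load_particles_json(path: str | Path) -> list[PolygonParticle]:
    """Read particles from a JSON list of ``{"id": ..., "ring": [[x,y],...]}``."""
    raw = json.loads(Path(path).read_text())
    return [
        PolygonParticle(ring=tuple(map(tuple, item["ring"])), id=str(item.get("id", k)))
        for k, item in enumerate(raw)
    ]


@dataclass
class QuadratSample:
    """Counts per (stripe, within-stripe) quadrat: the estimators' input."""

    counts: dict[QuadratAddress, int]
    spec: GridSpec
    bounds: Rect | None = None

    def __post_init__(self) -> None:
        for addr, c in self.counts.items():
            if c < 0:
                raise ValueError(f"negative count {c} at {addr}")

    @property
    def total_q(self) -> int:
        return int(sum(self.counts.values()))

    @property
    def n_nonempty(self) -> int:
        return sum(1 for c in self.counts.values() if c > 0)

    def nonempty_counts(self) -> np.ndarray:
        return np.array([c for c in self.counts.values() if c > 0], dtype=float)


def count_points(pattern: PointPattern, spec: GridSpec) -> QuadratSample:
    """Tally the associated points of ``pattern`` into quadrats."""
    layout = GridLayout(spec, pattern.bounds)
    counts: dict[QuadratAddress, int] = {}
    if pattern.n:
        ij, inside = layout.locate(pattern.points)
        kept = ij[inside]
        if len(kept):
            cells, ncell = np.unique(kept, axis=0, return_counts=True)
            for (i, j), c in zip(cells, ncell):
                counts[layout.address(int(i), int(j))] = int(c)
    return QuadratSample(counts=counts, spec=spec, bounds=pattern.bounds)


def forbidden_trace(
    corner: tuple[float, float], t: float, reach: float
) -> LineString:
    """Forbidden boundary of the quadrat with lower-left ``corner``.

    Runs down the left edge's line from ``reach`` above the corner, along
    the bottom edge, then down the right edge's line for ``reach`` below.
    """
    x0, y0 = corner
    return LineString(
        [(x0, y0 + reach), (x0, y0), (x0 + t, y0), (x0 + t, y0 - reach)]
    )


def _particles_bounds(particles: Sequence[PolygonParticle], spec: GridSpec) -> Rect:
    rings = np.concatenate([np.asarray(p.ring, dtype=float) for p in particles])
    xmin, ymin = rings.min(axis=0)
    xmax, ymax = rings.max(axis=0)
    pad = max(spec.t, 1.0)
    return Rect(xmin - pad, ymin - pad, xmax + pad, ymax + pad)


def count_polygons_forbidden_line(
    particles: Sequence[PolygonParticle],
    spec: GridSpec,
    bounds: Rect | None = None,
) -> QuadratSample:
    """Tally polygon particles into quadrats by the forbidden-line rule.

    A particle is counted in a quadrat iff it has points in common with the
    closed quadrat and does not hit the quadrat's forbidden trace.
    """
    if bounds is None:
        if not particles:
            raise ValueError("need bounds when the particle list is empty")
        bounds = _particles_bounds(particles, spec)
    layout = GridLayout(spec, bounds)
    t, T = spec.t, spec.T
    offx, offy = layout._offx, layout._offy
    gx0, gy0, gx1, gy1 = layout._poly.bounds
    reach = 4.0 * (max(gx1 - gx0, gy1 - gy0) + T)

    counts: dict[QuadratAddress, int] = {}
    for particle in particles:
        particle.to_shapely()  # validates against the original ring
        ring_g = layout.to_grid(np.asarray(particle.ring, dtype=float))
        poly = Polygon(ring_g)
        if not poly.is_valid:
            raise InvalidParticleError(
                f"particle {particle.id!r}: ring must be simple"
            )
        bx0, by0, bx1, by1 = poly.bounds
        i_lo = int(np.ceil((bx0 - t - offx) / T))
        i_hi = int(np.floor((bx1 - offx) / T))
        j_lo = int(np.ceil((by0 - t - offy) / T))
        j_hi = int(np.floor((by1 - offy) / T))
        for i in range(i_lo, i_hi + 1):
            for j in range(j_lo, j_hi + 1):
                x0 = offx + i * T
                y0 = offy + j * T
                if not poly.intersects(box(x0, y0, x0 + t, y0 + t)):
                    continue
                if poly.intersects(forbidden_trace((x0, y0), t, reach)):
                    continue
                addr = layout.address(i, j)
                counts[addr] = counts.get(addr, 0) + 1
    return QuadratSample(counts=counts, spec=spec, bounds=bounds)


def apply_border_rule(units, bounds: Rect):
    """Discard units hitting the window's left border; retain the rest.

    Units touching the right (and top/bottom) borders are kept, which avoids
    double counting across horizontally adjacent pictures.  Accepts either a
    :class:`PointPattern` or an iterable of :class:`PolygonParticle`.
    """
    if isinstance(units, PointPattern):
        keep = units.points[:, 0] > bounds.xmin
        return PointPattern(points=units.points[keep], bounds=units.bounds)
    left = LineString([(bounds.xmin, bounds.ymin), (bounds.xmin, bounds.ymax)])
    return [p for p in units if not p.to_shapely().intersects(left)]
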