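"""Grid-design planning from region size and target sampling effort.

The planning heuristics: aim at a total count of about 50 particles for a
fairly homogeneous pattern or about 150 for a heterogeneous one, spread over
20-50 quadrats, counting no more than 4-5 particles per quadrat.  The box
side follows from the region area and the quadrat budget; no pilot estimate
of the population size is needed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import NamedTuple

from .geometry import GridSpec

__all__ = ["BoxSide", "DesignAdvice", "recommend_box_side", "recommend_design"]

# Planning rules of thumb.
TARGET_Q = {"homogeneous": 50, "heterogeneous": 150}
QUADRAT_RANGE = (20, 50)
MAX_PER_QUADRAT = 5.0
DEFAULT_TILT_DEG = 45.0


class BoxSide(NamedTuple):
    exact: float
    adopted: float


def recommend_box_side(
    region_width: float, region_height: float, target_quadrats: int
) -> BoxSide:
    """Box side so that about ``target_quadrats`` quadrats cover the region.

    Returns the exact value ``sqrt(W*H/n)`` together with an adopted
    suggestion rounded to the nearest 10 pixels.
    """
    if region_width <= 0 or region_height <= 0:
        raise ValueError("region dimensions must be positive")
    if target_quadrats < 1:
        raise ValueError("target_quadrats must be >= 1")
    exact = math.sqrt(region_width * region_height / target_quadrats)
    adopted = float(round(exact / 10.0) * 10) if exact >= 10 else round(exact, 1)
    return BoxSide(exact=exact, adopted=adopted)


@dataclass
class DesignAdvice:
    """Planner output: draft grid parameters plus reasoning notes."""

    region_width: float
    region_height: float
    heterogeneity: str
    target_q: int
    target_quadrats: int
    box_side_exact: float
    box_side: float
    quadrat_side: float | None
    theta_deg: float
    expected_per_quadrat: float | None
    notes: tuple[str, ...]

    def grid_spec(self, seed: int | None = None) -> GridSpec:
        if self.quadrat_side is None:
            raise ValueError(
                "quadrat side is unresolved: supply a density hint or pick t "
                "by eye so one quadrat captures 1-6 units"
            )
        spec = GridSpec(t=self.quadrat_side, T=self.box_side, theta_deg=self.theta_deg)
        if seed is not None:
            spec = spec.with_seeded_offset(seed)
        return spec

    def to_dict(self) -> dict:
        return {
            "region_width": self.region_width,
            "region_height": self.region_height,
            "heterogeneity": self.heterogeneity,
            "target_q": self.target_q,
            "target_quadrats": self.target_quadrats,
            "box_side_exact": self.box_side_exact,
            "box_side": self.box_side,
            "quadrat_side": self.quadrat_side,
            "theta_deg": self.theta_deg,
            "expected_per_quadrat": self.expected_per_quadrat,
            "notes": list(self.notes),
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)

    def to_text(self) -> str:
        lines = [
            f"region: {self.region_width:g} x {self.region_height:g} px"
            f" ({self.heterogeneity})",
            f"aim at Q ~ {self.target_q} particles"
            f" in ~{self.target_quadrats} quadrats",
            f"fundamental box side T: {self.box_side:g} px"
            f" (exact {self.box_side_exact:.1f})",
            f"grid tilt: {self.theta_deg:g} deg",
        ]
        if self.quadrat_side is not None:
            lines.append(
                f"quadrat side t: {self.quadrat_side:g} px"
                f" (~{self.expected_per_quadrat:.1f} per quadrat)"
            )
        lines += [f"note: {n}" for n in self.notes]
        return "\n".join(lines)


def recommend_design(
    region_width: float,
    region_height: float,
    heterogeneity: str = "heterogeneous",
    density_hint: float | None = None,
    target_quadrats: int | None = None,
    theta_deg: float = DEFAULT_TILT_DEG,
) -> DesignAdvice:
    """Draft a grid design for a region, with no pilot size estimate needed.

    ``density_hint``, if given, is the particle density in px^-2 and is used
    to resolve the quadrat side so the expected count per quadrat is about
    ``target_q / target_quadrats`` and never above 5.
    """
    if heterogeneity not in TARGET_Q:
        raise ValueError(
            f"heterogeneity must be one of {sorted(TARGET_Q)}, got {heterogeneity!r}"
        )
    target_q = TARGET_Q[heterogeneity]
    if target_quadrats is None:
        target_quadrats = (
            QUADRAT_RANGE[1] if heterogeneity == "heterogeneous" else QUADRAT_RANGE[0]
        )
    if not (1 <= target_quadrats):
        raise ValueError("target_quadrats must be >= 1")

    box = recommend_box_side(region_width, region_height, target_quadrats)
    per_quadrat_goal = min(MAX_PER_QUADRAT, target_q / target_quadrats)
    notes = [
        "no pilot estimate of the population size is needed",
        f"plan {QUADRAT_RANGE[0]}-{QUADRAT_RANGE[1]} nonempty quadrats with "
        "1-5 particles each",
    ]

    quadrat_side = None
    expected = None
    if density_hint is not None:
        if density_hint <= 0:
            raise ValueError("density_hint must be positive")
        quadrat_side = min(math.sqrt(per_quadrat_goal / density_hint), box.adopted)
        expected = density_hint * quadrat_side**2
        notes.append(
            f"expected count per quadrat ~ {expected:.2f} at t = {quadrat_side:.1f}"
        )
    else:
        notes.append(
            "quadrat side left unresolved: eyeball a quadrat capturing 1-6 units"
        )
        expected = per_quadrat_goal
    return DesignAdvice(
        region_width=float(region_width),
        region_height=float(region_height),
        heterogeneity=heterogeneity,
        target_q=target_q,
        target_quadrats=int(target_quadrats),
        box_side_exact=box.exact,
        box_side=box.adopted,
        quadrat_side=quadrat_side,
        theta_deg=theta_deg,
        expected_per_quadrat=expected,
        notes=tuple(notes),
    )
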