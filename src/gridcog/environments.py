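"""Arenas: square, circle, and connected multi-compartment environments.

Each environment is a union of axis-aligned rectangular regions (or a single
disc) with one place-cell frame per compartment.  The reference compartment's
frame doubles as the global frame; corridor regions carry no frame of their
own and are handled in the reference frame.  Wall thickness between
compartments defaults to 0.1 m.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import Point, box
from shapely.ops import unary_union

from . import frames
from .frames import FrameTransform

__all__ = ["Region", "Environment", "build_environment", "compartment_of"]

WALL = 0.1  # m, wall thickness between compartments


@dataclass(frozen=True)
class Region:
    """A labelled axis-aligned rectangle [xmin, xmax] x [ymin, ymax]."""

    name: str
    bounds: tuple[float, float, float, float]  # xmin, ymin, xmax, ymax
    corridor: bool = False

    def contains_point(self, x: float, y: float, tol: float = 1e-9) -> bool:
        xmin, ymin, xmax, ymax = self.bounds
        return (xmin - tol <= x <= xmax + tol) and (ymin - tol <= y <= ymax + tol)


def _frame_from_anchor(origin, orientation: float) -> FrameTransform:
    """World->place transform for a frame anchored at ``origin`` with axes
    rotated by ``orientation`` in the world: p_place = Rot(-psi) @ (p - o)."""
    o = np.asarray(origin, dtype=float)
    phi = -float(orientation)
    c, s = math.cos(phi), math.sin(phi)
    R = np.array([[c, -s], [s, c]])
    return FrameTransform(frames.wrap_angle(phi), -(R @ o))


@dataclass
class Environment:
    kind: str
    regions: list[Region]
    frames: dict[str, FrameTransform]
    reference: str
    circle: tuple[float, float, float] | None = None  # (cx, cy, r)
    start: np.ndarray = field(default_factory=lambda: np.zeros(2))

    def __post_init__(self) -> None:
        names = [r.name for r in self.regions if not r.corridor]
        if self.reference not in names:
            raise ValueError(f"reference compartment {self.reference!r} not found")

    @property
    def compartments(self) -> list[Region]:
        return [r for r in self.regions if not r.corridor]

    @property
    def corridors(self) -> list[Region]:
        return [r for r in self.regions if r.corridor]

    @property
    def bbox(self) -> tuple[float, float, float, float]:
        if self.circle is not None:
            cx, cy, r = self.circle
            return (cx - r, cy - r, cx + r, cy + r)
        b = np.array([r.bounds for r in self.regions])
        return (b[:, 0].min(), b[:, 1].min(), b[:, 2].max(), b[:, 3].max())

    @property
    def polygon(self):
        """Shapely geometry of the full accessible area."""
        if self.circle is not None:
            cx, cy, r = self.circle
            return Point(cx, cy).buffer(r, quad_segs=256)
        return unary_union([box(*r.bounds) for r in self.regions])

    @property
    def area(self) -> float:
        if self.circle is not None:
            return math.pi * self.circle[2] ** 2
        return self.polygon.area

    def contains_point(self, x: float, y: float, tol: float = 1e-9) -> bool:
        if self.circle is not None:
            cx, cy, r = self.circle
            return (x - cx) ** 2 + (y - cy) ** 2 <= (r + tol) ** 2
        return any(reg.contains_point(x, y, tol) for reg in self.regions)

    def contains(self, points, tol: float = 1e-9) -> np.ndarray:
        """Vectorised containment test for an (n, 2) array of points."""
        p = np.atleast_2d(np.asarray(points, dtype=float))
        if self.circle is not None:
            cx, cy, r = self.circle
            return (p[:, 0] - cx) ** 2 + (p[:, 1] - cy) ** 2 <= (r + tol) ** 2
        mask = np.zeros(len(p), dtype=bool)
        for reg in self.regions:
            xmin, ymin, xmax, ymax = reg.bounds
            mask |= (
                (p[:, 0] >= xmin - tol)
                & (p[:, 0] <= xmax + tol)
                & (p[:, 1] >= ymin - tol)
                & (p[:, 1] <= ymax + tol)
            )
        return mask

    def label_points(self, points, tol: float = 1e-9) -> np.ndarray:
        """Compartment/corridor label for each point (vectorised first-match).

        Compartments are checked before corridors, in listing order, so a
        point on a shared edge deterministically belongs to the
        lowest-indexed region.
        """
        p = np.atleast_2d(np.asarray(points, dtype=float))
        labels = np.full(len(p), "", dtype=object)
        for reg in self.compartments + self.corridors:
            xmin, ymin, xmax, ymax = reg.bounds
            hit = (
                (labels == "")
                & (p[:, 0] >= xmin - tol)
                & (p[:, 0] <= xmax + tol)
                & (p[:, 1] >= ymin - tol)
                & (p[:, 1] <= ymax + tol)
            )
            labels[hit] = reg.name
        if self.circle is not None:
            inside = self.contains(p, tol)
            labels[inside] = self.compartments[0].name
        if np.any(labels == ""):
            raise ValueError("point outside environment boundary")
        return labels


def compartment_of(env: Environment, p) -> str:
    """Label of the compartment (or corridor) containing point ``p``."""
    return env.label_points(np.asarray(p, dtype=float).reshape(1, 2))[0]


def build_environment(kind: str, **params) -> Environment:
    """Construct one of the four study arenas.

    kind:
      - ``square``: side (default 5 m), place frame at the origin corner.
      - ``circle``: radius (default 2 m), frame at the centre.
      - ``two_compartment``: two 5 x 4 m rooms side by side, joined by a 1 m
        corridor along the top; both place frames have the same orientation,
        origins at each room's left-bottom corner; the left room is the
        reference/global frame.
      - ``four_compartment``: a 2 x 2 grid of 3 x 3 m rooms joined by 1 m
        doorways; place frames differ in both origin and orientation
        (0, 90, 180, 270 degrees by default).
    """
    if kind == "square":
        side = float(params.get("side", 5.0))
        if side <= 0:
            raise ValueError("side must be positive")
        reg = Region("C1", (0.0, 0.0, side, side))
        return Environment(
            kind, [reg], {"C1": frames.identity()}, "C1", start=np.zeros(2)
        )

    if kind == "circle":
        r = float(params.get("radius", 2.0))
        if r <= 0:
            raise ValueError("radius must be positive")
        reg = Region("C1", (-r, -r, r, r))
        return Environment(
            kind,
            [reg],
            {"C1": frames.identity()},
            "C1",
            circle=(0.0, 0.0, r),
            start=np.zeros(2),
        )

    if kind == "two_compartment":
        w = float(params.get("width", 5.0))
        h = float(params.get("height", 4.0))
        cw = float(params.get("corridor_width", 1.0))
        if min(w, h, cw) <= 0:
            raise ValueError("dimensions must be positive")
        x2 = w + WALL  # right room offset past the dividing wall
        # the corridor is an open 1 m strip along the top of both rooms; the
        # only interior wall is the one separating the two rooms below it
        regions = [
            Region("C1", (0.0, 0.0, w, h)),
            Region("C2", (x2, 0.0, x2 + w, h)),
            Region("corridor", (0.0, h, x2 + w, h + cw), corridor=True),
        ]
        fr = {
            "C1": _frame_from_anchor((0.0, 0.0), 0.0),
            "C2": _frame_from_anchor((x2, 0.0), 0.0),
        }
        return Environment(kind, regions, fr, "C1", start=np.array([w / 2, h / 2]))

    if kind == "four_compartment":
        a = float(params.get("side", 3.0))
        dw = float(params.get("door_width", 2.0))
        if min(a, dw) <= 0:
            raise ValueError("dimensions must be positive")
        o = a + WALL  # offset of the second row/column
        rooms = {
            "C1": (0.0, 0.0),
            "C2": (o, 0.0),
            "C3": (0.0, o),
            "C4": (o, o),
        }
        regions = [Region(n, (x, y, x + a, y + a)) for n, (x, y) in rooms.items()]
        mid = (a - dw) / 2
        regions += [
            Region("door12", (a, mid, o, mid + dw), corridor=True),
            Region("door13", (mid, a, mid + dw, o), corridor=True),
            Region("door24", (o + mid, a, o + mid + dw, o), corridor=True),
            Region("door34", (a, o + mid, o, o + mid + dw), corridor=True),
        ]
        orientations = params.get(
            "orientations",
            {"C1": 0.0, "C2": math.pi / 2, "C3": math.pi, "C4": 3 * math.pi / 2},
        )
        fr = {
            n: _frame_from_anchor((x, y), orientations[n]) for n, (x, y) in rooms.items()
        }
        return Environment(kind, regions, fr, "C1", start=np.array([a / 2, a / 2]))

    raise ValueError(f"unknown environment kind: {kind!r}")
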