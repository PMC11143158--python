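"""Single grid-cell model: lattice basis, cognitive-space transform, firing rate.

A grid cell is parameterised by its spacing ``s`` (metres), orientation
``theta`` (radians, hexagonal symmetry folds it into [0, pi/3)) and a
two-component phase in lattice units.  Its "cognitive space" is the oblique
coordinate system spanned by two basis vectors 60 degrees apart; a position in
the place-cell frame is mapped into that space linearly, and the firing rate
is a decreasing sigmoid of the distance to the nearest integer lattice point
(the cell's preferred firing positions).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import frames
from .frames import FrameTransform

__all__ = [
    "GridCell",
    "FiringParams",
    "basis_vectors",
    "place_to_grid_matrix",
    "place_to_grid",
    "round_half_away",
    "lattice_distance",
    "firing_rate",
    "field_centers",
    "nearest_center_distance_along_axis",
]

_SIXTY = math.pi / 3.0


@dataclass(frozen=True, eq=False)
class GridCell:
    """A grid cell ``[s, theta, phase_1, phase_2]``.

    Parameters
    ----------
    s : float
        Lattice spacing in metres; distance between adjacent field centers.
    theta : float
        Orientation of the first basis vector, radians.  Stored wrapped into
        [0, pi/3) because the hexagonal lattice is invariant under 60-degree
        rotations.
    phase : array-like of length 2
        Offset of the firing lattice relative to the place-frame origin, in
        lattice units, each component wrapped into [0, 1).
    """

    s: float
    theta: float = 0.0
    phase: np.ndarray = field(default_factory=lambda: np.zeros(2))

    def __post_init__(self) -> None:
        if not (np.isfinite(self.s) and self.s > 0):
            raise ValueError(f"spacing must be positive and finite, got {self.s}")
        object.__setattr__(self, "theta", float(self.theta) % _SIXTY)
        phase = np.asarray(self.phase, dtype=float).reshape(2) % 1.0
        object.__setattr__(self, "phase", phase)


@dataclass(frozen=True)
class FiringParams:
    """Firing-rate shape parameters: threshold ``zeta``, sharpness ``kappa``."""

    zeta: float = 0.4
    kappa: float = 3.0

    def __post_init__(self) -> None:
        if not self.kappa > 0:
            raise ValueError("kappa must be positive")
        if not self.zeta >= 0:
            raise ValueError("zeta must be non-negative")


def basis_vectors(cell: GridCell):
    """The two lattice basis vectors, length ``s``, 60 degrees apart."""
    eps1 = cell.s * np.array([math.cos(cell.theta), math.sin(cell.theta)])
    eps2 = cell.s * np.array(
        [math.cos(cell.theta + _SIXTY), math.sin(cell.theta + _SIXTY)]
    )
    return eps1, eps2


def basis_matrix(cell: GridCell) -> np.ndarray:
    """Basis vectors as columns of a 2x2 matrix (lattice -> place map)."""
    eps1, eps2 = basis_vectors(cell)
    return np.column_stack([eps1, eps2])


def place_to_grid_matrix(cell: GridCell) -> np.ndarray:
    """Inverse basis matrix mapping place coordinates to lattice coordinates.

    Its determinant is ``1 / (s^2 sin 60)``, the reciprocal unit-cell area.
    """
    return np.linalg.inv(basis_matrix(cell))


def place_to_grid(cell: GridCell, p_place) -> np.ndarray:
    """Map place-frame position(s) into lattice (cognitive-space) coordinates.

    ``g = R_pg @ p - phase``; accepts a single point (2,) or stacked (n, 2).
    """
    p = np.asarray(p_place, dtype=float)
    R = place_to_grid_matrix(cell)
    if p.ndim == 1:
        return R @ p - cell.phase
    return p @ R.T - cell.phase


def round_half_away(x: np.ndarray) -> np.ndarray:
    """Round to nearest integer, ties away from zero (platform independent)."""
    x = np.asarray(x, dtype=float)
    return np.copysign(np.floor(np.abs(x) + 0.5), x)


def lattice_distance(g_coord, squared: bool = False):
    """Distance (lattice units) from coordinate(s) to the nearest integer point.

    Each component is rounded to the nearest integer (ties away from zero) and
    the Euclidean norm of the residual is returned.  ``squared=True`` returns
    the squared norm instead.
    """
    g = np.asarray(g_coord, dtype=float)
    resid = g - round_half_away(g)
    d2 = np.sum(resid * resid, axis=-1)
    return d2 if squared else np.sqrt(d2)


def firing_rate(cell: GridCell, params: FiringParams, p_place, squared: bool = False):
    """Firing rate in [0, 1] at place-frame position(s).

    rate = clip(1/2 - arctan(kappa * (d/s - zeta)) / pi, 0, 1)

    with ``d`` the lattice distance of the cognitive-space coordinate.  The
    rate is maximal (> 1/2) at lattice points, crosses 1/2 where ``d/s``
    equals the threshold ``zeta``, and decays towards 0 away from the field;
    ``kappa`` sets how sharp that transition is.
    """
    d = lattice_distance(place_to_grid(cell, p_place), squared=squared)
    rate = 0.5 - np.arctan(params.kappa * (d / cell.s - params.zeta)) / math.pi
    return np.clip(rate, 0.0, 1.0)


def _as_bbox(region):
    """Accept an Environment-like (with .bbox) or a (xmin, ymin, xmax, ymax)."""
    bbox = getattr(region, "bbox", region)
    xmin, ymin, xmax, ymax = (float(v) for v in bbox)
    if not all(map(math.isfinite, (xmin, ymin, xmax, ymax))):
        raise ValueError("field_centers requires a bounded region")
    return xmin, ymin, xmax, ymax


def field_centers(
    cell: GridCell,
    frame: FrameTransform | None = None,
    region=(0.0, 0.0, 5.0, 5.0),
) -> np.ndarray:
    """Enumerate all firing-field centers inside a bounded region, world coords.

    Centers are the pre-images of integer lattice coordinates: points
    ``B @ (n + phase)`` in place coordinates for integer 2-vectors ``n``,
    mapped to the world through the inverse of ``frame`` (the world->place
    transform; identity if omitted).  ``region`` is an Environment (its
    containment test and bounding box are used) or a bare bounding box.
    Points on the region boundary are included (1e-9 tolerance).
    """
    frame = frames.IDENTITY if frame is None else frame
    xmin, ymin, xmax, ymax = _as_bbox(region)
    B = basis_matrix(cell)
    place_to_world = frames.invert(frame)

    # Lattice index range covering the region: map bbox corners to lattice
    # coordinates and pad generously for obliquity.
    corners_w = np.array(
        [[xmin, ymin], [xmin, ymax], [xmax, ymin], [xmax, ymax]], dtype=float
    )
    corners_g = place_to_grid(cell, frames.apply(frame, corners_w))
    lo = np.floor(corners_g.min(axis=0)).astype(int) - 2
    hi = np.ceil(corners_g.max(axis=0)).astype(int) + 2

    n1, n2 = np.meshgrid(
        np.arange(lo[0], hi[0] + 1), np.arange(lo[1], hi[1] + 1), indexing="ij"
    )
    n = np.column_stack([n1.ravel(), n2.ravel()]).astype(float)
    centers_place = (n + cell.phase) @ B.T
    centers_world = frames.apply(place_to_world, centers_place)

    contains = getattr(region, "contains", None)
    if contains is not None:
        mask = contains(centers_world, tol=1e-9)
    else:
        eps = 1e-9
        mask = (
            (centers_world[:, 0] >= xmin - eps)
            & (centers_world[:, 0] <= xmax + eps)
            & (centers_world[:, 1] >= ymin - eps)
            & (centers_world[:, 1] <= ymax + eps)
        )
    return centers_world[mask]


def nearest_center_distance_along_axis(cell: GridCell, axis: int) -> float:
    """Offset of the nearest rate bump from the origin along a basis-vector ray.

    Along the ray of basis vector ``axis`` (1 or 2), the rate profile peaks
    where that axis' lattice coordinate is an integer, i.e. at offsets
    ``s * (n + phase_axis)``; the nearest bump therefore sits at
    ``s * min(w, 1 - w)`` with ``w`` the wrapped phase component.
    """
    if axis not in (1, 2):
        raise ValueError("axis must be 1 or 2")
    w = cell.phase[axis - 1]
    return cell.s * min(w, 1.0 - w)
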