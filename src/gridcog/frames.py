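"""2D rigid-frame algebra for place-cell local frames.

Every place-cell frame (and the global frame) is related to the world by a
rigid transform: a rotation angle ``phi`` and a translation ``varpi``.
Applying a transform maps a point ``p`` to ``Rot(phi) @ p + varpi``.  The
convention is fixed once here; compositions, inverses and differences are all
expressed in it, so no matrix inverses appear in user code.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FrameTransform",
    "identity",
    "from_angle_translation",
    "apply",
    "compose",
    "invert",
    "frame_difference",
    "wrap_angle",
]


def wrap_angle(angle: float) -> float:
    """Wrap an angle to the half-open interval (-pi, pi]."""
    a = math.remainder(angle, 2.0 * math.pi)
    if a <= -math.pi:  # remainder returns [-pi, pi]; fold the lower endpoint
        a += 2.0 * math.pi
    return a


@dataclass(frozen=True, eq=False)
class FrameTransform:
    """Rigid 2D transform: rotation by ``phi`` (radians) then translation.

    ``apply(T, p) == Rot(phi) @ p + varpi``.  The implied rotation matrix is
    orthonormal with determinant +1 by construction.
    """

    phi: float
    varpi: np.ndarray = field(default_factory=lambda: np.zeros(2))

    def __post_init__(self) -> None:
        varpi = np.asarray(self.varpi, dtype=float).reshape(2)
        if not (np.isfinite(self.phi) and np.all(np.isfinite(varpi))):
            raise ValueError("FrameTransform requires finite phi and varpi")
        object.__setattr__(self, "varpi", varpi)

    @property
    def rotation(self) -> np.ndarray:
        c, s = math.cos(self.phi), math.sin(self.phi)
        return np.array([[c, -s], [s, c]])

    def __call__(self, p):
        return apply(self, p)


IDENTITY = FrameTransform(0.0, np.zeros(2))


def identity() -> FrameTransform:
    return IDENTITY


def from_angle_translation(phi: float, varpi) -> FrameTransform:
    """Build a transform from a rotation angle and a translation 2-vector."""
    return FrameTransform(float(phi), np.asarray(varpi, dtype=float))


def apply(T: FrameTransform, p):
    """Apply ``T`` to a point (2,) or an array of points (n, 2)."""
    p = np.asarray(p, dtype=float)
    if p.ndim == 1:
        return T.rotation @ p + T.varpi
    return p @ T.rotation.T + T.varpi


def compose(T_outer: FrameTransform, T_inner: FrameTransform) -> FrameTransform:
    """Transform equal to applying ``T_inner`` first, then ``T_outer``."""
    phi = wrap_angle(T_outer.phi + T_inner.phi)
    varpi = T_outer.rotation @ T_inner.varpi + T_outer.varpi
    return FrameTransform(phi, varpi)


def invert(T: FrameTransform) -> FrameTransform:
    phi = -T.phi
    c, s = math.cos(phi), math.sin(phi)
    R_inv = np.array([[c, -s], [s, c]])
    return FrameTransform(wrap_angle(phi), -(R_inv @ T.varpi))


def frame_difference(T_a: FrameTransform, T_b: FrameTransform):
    """Angle and translation taking ``T_b``'s parameters to ``T_a``'s.

    Returns ``(phi_diff, varpi_diff)`` with ``phi_diff = wrap(phi_a - phi_b)``
    in (-pi, pi] and ``varpi_diff = varpi_a - varpi_b``.  Both are zero iff
    the frames coincide; the experience-dependent adjustment shrinks exactly
    these two quantities.
    """
    return wrap_angle(T_a.phi - T_b.phi), T_a.varpi - T_b.varpi
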