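"""Experience-dependent adjustment of place-cell frames toward the global frame.

In a connected multi-compartment arena each non-reference compartment starts
with its own cue-anchored place frame, so the grid pattern replicates locally.
As the animal accumulates steps ``N_t`` inside a non-reference compartment,
that compartment's frame is pulled toward the reference (global) frame by a
fraction ``gamma`` per step, where

    gamma = alpha / (beta + exp(-xi * (N_t - M)))

is a sigmoid of experience: negligible before ``M`` steps, saturating at
``alpha / beta`` afterwards.  Each adjustment multiplies both the angular and
the translation difference to the reference frame by (1 - gamma), giving
geometric convergence and, downstream, a globally coherent firing field.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import frames
from .frames import FrameTransform

__all__ = ["AdjustmentSchedule", "AdjustmentState", "gamma", "step_adjustment", "has_converged"]


@dataclass
class AdjustmentSchedule:
    """Sigmoid experience schedule (alpha, beta, xi, M) with counter N_t."""

    alpha: float = 0.5
    beta: float = 1.0
    xi: float = 0.1
    M: int = 100_000
    N_t: int = 0

    def __post_init__(self) -> None:
        if not (self.alpha > 0 and self.beta > 0):
            raise ValueError("alpha and beta must be positive")
        if self.xi < 0 or self.M < 0 or self.N_t < 0:
            raise ValueError("xi, M and N_t must be non-negative")


def gamma(schedule: AdjustmentSchedule) -> float:
    """Adjustment fraction alpha / (beta + exp(-xi (N_t - M))), in (0, alpha/beta)."""
    z = -schedule.xi * (schedule.N_t - schedule.M)
    return schedule.alpha / (schedule.beta + np.exp(min(z, 700.0)))


@dataclass
class AdjustmentState:
    """Current world->place transforms per compartment plus their schedules.

    The reference compartment's transform is the global frame and never
    changes; every other compartment carries its own schedule and counter.
    """

    frames: dict[str, FrameTransform]
    reference: str
    schedules: dict[str, AdjustmentSchedule] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.reference not in self.frames:
            raise ValueError(f"reference {self.reference!r} missing from frames")
        for name in self.frames:
            if name != self.reference and name not in self.schedules:
                self.schedules[name] = AdjustmentSchedule()

    @property
    def target(self) -> FrameTransform:
        return self.frames[self.reference]

    def record_step(self, compartment: str) -> float:
        """Count one step of experience in ``compartment`` and adjust its
        frame; returns the gamma used."""
        if compartment == self.reference:
            raise ValueError("reference compartment accrues no adjustment")
        self.schedules[compartment].N_t += 1
        return step_adjustment(self, compartment)


def step_adjustment(state: AdjustmentState, compartment: str) -> float:
    """One adjustment of ``compartment``'s frame toward the reference frame.

    With (phi_d, varpi_d) the current frame difference (current minus
    target), the frame moves to ``current - gamma * difference`` in both
    angle and translation, leaving a difference of (1 - gamma) times the old
    one.  Returns the gamma applied.
    """
    if compartment == state.reference:
        raise ValueError("cannot adjust the reference frame")
    if compartment not in state.frames:
        raise ValueError(f"unknown compartment {compartment!r}")
    g = gamma(state.schedules[compartment])
    cur = state.frames[compartment]
    phi_d, varpi_d = frames.frame_difference(cur, state.target)
    state.frames[compartment] = FrameTransform(
        frames.wrap_angle(cur.phi - g * phi_d), cur.varpi - g * varpi_d
    )
    return g


def has_converged(
    state: AdjustmentState, tol_angle: float = 1e-3, tol_trans: float = 1e-3
) -> bool:
    """True iff every non-reference frame is within both tolerances of the
    reference frame (angle in radians, translation as Euclidean norm)."""
    if tol_angle <= 0 or tol_trans <= 0:
        raise ValueError("tolerances must be positive")
    for name, T in state.frames.items():
        if name == state.reference:
            continue
        phi_d, varpi_d = frames.frame_difference(T, state.target)
        if abs(phi_d) >= tol_angle or np.linalg.norm(varpi_d) >= tol_trans:
            return False
    return True
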