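"""Seedable random-walk trajectories and path integration.

The walk is a standard rodent-foraging surrogate: constant nominal speed with
multiplicative jitter, heading evolving as a wrapped Gaussian random walk,
and wall encounters resolved by sliding along the wall (thigmotaxis), with a
random heading re-draw only when fully cornered.  Trajectories are a pure
function of (environment, parameters, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .environments import Environment

__all__ = ["Trajectory", "random_walk", "path_integrate", "write_trajectory", "read_trajectory"]

_TWO_PI = 2.0 * math.pi


@dataclass
class Trajectory:
    """Columnar trajectory: one row per sample, world coordinates."""

    t: np.ndarray  # seconds
    xy: np.ndarray  # (n, 2) metres
    v: np.ndarray  # speed, m/s
    alpha: np.ndarray  # heading, radians
    compartment: np.ndarray  # region label per sample

    def __len__(self) -> int:
        return len(self.t)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t": self.t,
                "x": self.xy[:, 0],
                "y": self.xy[:, 1],
                "v": self.v,
                "alpha": self.alpha,
                "compartment": self.compartment,
            }
        )


def random_walk(
    env: Environment,
    n_steps: int,
    dt: float = 0.1,
    speed: float = 0.3,
    speed_jitter: float = 0.2,
    turn_sd: float = 0.15,
    seed: int = 0,
    start=None,
) -> Trajectory:
    """Simulate a bounded random walk of ``n_steps`` samples.

    Parameters
    ----------
    speed : float
        Nominal speed in m/s; each step uses ``speed * max(0, 1 + jitter)``
        with Gaussian ``jitter`` of s.d. ``speed_jitter``.
    turn_sd : float
        S.d. of the per-step Gaussian heading increment, radians.
    seed : int
        Seed for the walk's private generator; identical seeds give
        identical trajectories.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    if dt <= 0:
        raise ValueError("dt must be positive")
    if env.area <= 0:
        raise ValueError("degenerate environment with zero area")

    rng = np.random.default_rng(seed)
    jitter = 1.0 + speed_jitter * rng.standard_normal(n_steps)
    np.maximum(jitter, 0.0, out=jitter)
    turns = turn_sd * rng.standard_normal(n_steps)

    x, y = (float(c) for c in (env.start if start is None else np.asarray(start)))
    if not env.contains_point(x, y):
        raise ValueError("start point outside environment")
    alpha = float(rng.uniform(-math.pi, math.pi))

    xs = np.empty(n_steps)
    ys = np.empty(n_steps)
    vs = np.empty(n_steps)
    alphas = np.empty(n_steps)
    contains = env.contains_point
    for i in range(n_steps):
        v = speed * jitter[i]
        a = math.remainder(alpha + turns[i], _TWO_PI)
        step = v * dt
        nx = x + step * math.cos(a)
        ny = y + step * math.sin(a)
        if not contains(nx, ny):
            # wall: follow it (thigmotaxis) at full speed along the tangent
            # closest to the heading; re-draw the heading only if cornered
            ca, sa = math.cos(a), math.sin(a)
            horiz = (math.copysign(1.0, ca) if ca else 0.0, 0.0)
            vert = (0.0, math.copysign(1.0, sa) if sa else 0.0)
            for tx, ty in (horiz, vert) if abs(ca) >= abs(sa) else (vert, horiz):
                if (tx or ty) and contains(x + step * tx, y + step * ty):
                    nx, ny = x + step * tx, y + step * ty
                    a = math.atan2(ty, tx)
                    break
            else:
                for _ in range(100):
                    a = float(rng.uniform(-math.pi, math.pi))
                    nx = x + step * math.cos(a)
                    ny = y + step * math.sin(a)
                    if contains(nx, ny):
                        break
                else:  # cornered; stand still this step
                    nx, ny = x, y
                    v = 0.0
        x, y, alpha = nx, ny, a
        xs[i] = x
        ys[i] = y
        vs[i] = v
        alphas[i] = a

    xy = np.column_stack([xs, ys])
    t = dt * np.arange(1, n_steps + 1)
    labels = env.label_points(xy)
    return Trajectory(t=t, xy=xy, v=vs, alpha=alphas, compartment=labels)


def path_integrate(start, samples) -> np.ndarray:
    """Integrate (v, alpha, dt) steps from ``start``; rectangular rule.

    ``samples`` is an iterable of (speed, heading, dt) triples.  Returns the
    (n+1, 2) array of positions including the start point: each step adds
    ``(v cos(alpha) dt, v sin(alpha) dt)``.
    """
    arr = np.asarray(list(samples), dtype=float).reshape(-1, 3)
    if not np.all(np.isfinite(arr)):
        raise ValueError("non-finite sample in path integration")
    d = arr[:, 0:1] * arr[:, 2:3] * np.column_stack([np.cos(arr[:, 1]), np.sin(arr[:, 1])])
    out = np.vstack([np.zeros(2), np.cumsum(d, axis=0)])
    return out + np.asarray(start, dtype=float)


def write_trajectory(traj: Trajectory, path) -> None:
    traj.to_dataframe().to_csv(path, index=False, float_format="%.9g")


def read_trajectory(path) -> Trajectory:
    df = pd.read_csv(path)
    return Trajectory(
        t=df["t"].to_numpy(float),
        xy=df[["x", "y"]].to_numpy(float),
        v=df["v"].to_numpy(float),
        alpha=df["alpha"].to_numpy(float),
        compartment=df["compartment"].to_numpy(object),
    )
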