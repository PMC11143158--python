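"""Configuration-driven experiment runners wiring all modules together.

Four experiment kinds are provided, mirroring the study conditions:

- ``single_cell``: random walk in a square (or circular) arena, firing field
  of one grid cell, lattice-parameter recovery and axis profiles.
- ``multi_cell``: sweeps of spacing, orientation and phase in the circular
  arena, one map per cell.
- ``two_compartment`` / ``four_compartment``: connected environments with
  per-compartment place frames and experience-dependent frame adjustment,
  producing snapshot maps, the global-fit correlation curve and an
  adjustment trace.

Each runner takes an :class:`ExperimentConfig`, writes CSV/PNG/JSON artifacts
to the output directory, and returns the summary dictionary.  Runs are a pure
function of (config, seed).
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import yaml

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from . import frames as fr
from .adjustment import AdjustmentSchedule, AdjustmentState, gamma, has_converged
from .cells import (
    FiringParams,
    GridCell,
    field_centers,
    firing_rate,
    nearest_center_distance_along_axis,
    place_to_grid_matrix,
)
from .environments import Environment, build_environment
from .ratemaps import (
    bin_rate_map,
    detect_peaks,
    estimate_lattice_params,
    global_fit_correlation,
    profile_along_axis,
    profile_peaks,
)
from .trajectory import Trajectory, random_walk, write_trajectory

__all__ = [
    "ConfigError",
    "ExperimentConfig",
    "default_config",
    "load_config",
    "run_single_cell",
    "run_multi_cell",
    "run_connected",
    "run",
]

EXPERIMENTS = ("single_cell", "multi_cell", "two_compartment", "four_compartment")

#: scale divisor applied by ``scaled()`` to step counts and M (and the
#: matching multiplier on xi, so the experience sigmoid saturates at the same
#: fraction of the run)
SCALE = 50


class ConfigError(ValueError):
    """Invalid experiment configuration; the message names the offending key."""


@dataclass
class ExperimentConfig:
    experiment: str = "single_cell"
    environment: dict = dc_field(default_factory=lambda: {"kind": "square", "side": 5.0})
    cells: list = dc_field(default_factory=lambda: [{"s": 1.0, "theta": math.pi / 4, "phase": [0.5, 0.0]}])
    zeta: float = 0.4
    kappa: float = 3.0
    alpha: float = 0.5
    beta: float = 1.0
    xi: float = 0.1
    M: int = 100_000
    n_steps: int = 200_000
    dt: float = 0.1
    speed: float = 0.3
    speed_jitter: float = 0.2
    turn_sd: float = 0.15
    seed: int = 0
    adjust: bool = True
    snapshots: list = dc_field(default_factory=list)
    bin_size: float = 0.1
    curve_every: int = 0  # 0 -> n_steps // 40
    trajectory_file: str | None = None  # precomputed trajectory CSV, else simulate
    out: str = "out"

    def validate(self) -> "ExperimentConfig":
        if self.experiment not in EXPERIMENTS:
            raise ConfigError(f"experiment: unknown kind {self.experiment!r}")
        if self.n_steps < 1:
            raise ConfigError(f"n_steps: must be >= 1, got {self.n_steps}")
        if self.dt <= 0:
            raise ConfigError(f"dt: must be positive, got {self.dt}")
        if self.speed <= 0:
            raise ConfigError(f"speed: must be positive, got {self.speed}")
        if self.bin_size <= 0:
            raise ConfigError(f"bin_size: must be positive, got {self.bin_size}")
        if not self.cells:
            raise ConfigError("cells: at least one grid cell is required")
        if self.seed is None:
            raise ConfigError("seed: a seed is mandatory for reproducibility")
        snaps = sorted(int(s) for s in self.snapshots)
        if snaps and snaps[-1] > self.n_steps:
            raise ConfigError(f"snapshots: step {snaps[-1]} exceeds n_steps")
        self.snapshots = snaps
        try:
            FiringParams(self.zeta, self.kappa)
        except ValueError as e:
            raise ConfigError(f"zeta/kappa: {e}") from None
        try:
            AdjustmentSchedule(self.alpha, self.beta, self.xi, self.M)
        except ValueError as e:
            raise ConfigError(f"alpha/beta/xi/M: {e}") from None
        return self

    def scaled(self) -> "ExperimentConfig":
        """Preset dividing step counts and M by SCALE and raising xi to match,
        so the experience sigmoid still saturates within the run."""
        c = dataclasses.replace(self)
        c.n_steps = max(1, self.n_steps // SCALE)
        c.M = max(1, self.M // SCALE)
        c.xi = self.xi * SCALE
        c.snapshots = [max(1, s // SCALE) for s in self.snapshots]
        return c

    def grid_cells(self) -> list[GridCell]:
        out = []
        for i, spec in enumerate(self.cells):
            try:
                out.append(
                    GridCell(spec["s"], spec.get("theta", 0.0), spec.get("phase", (0.0, 0.0)))
                )
            except (KeyError, ValueError, TypeError) as e:
                raise ConfigError(f"cells[{i}]: {e}") from None
        return out

    def firing_params(self) -> FiringParams:
        return FiringParams(self.zeta, self.kappa)

    def build_env(self) -> Environment:
        env = dict(self.environment)
        kind = env.pop("kind", None)
        if kind is None:
            raise ConfigError("environment.kind: missing")
        try:
            return build_environment(kind, **env)
        except (ValueError, TypeError) as e:
            raise ConfigError(f"environment: {e}") from None


def default_config(experiment: str) -> ExperimentConfig:
    """Study-condition defaults for each experiment kind."""
    if experiment == "single_cell":
        return ExperimentConfig(experiment="single_cell")
    if experiment == "multi_cell":
        sweep = (
            # spacing sweep: starts at 0.5, +0.3 each panel
            [{"s": s, "theta": 0.0, "phase": [0.0, 0.0]} for s in (0.5, 0.8, 1.1)]
            # orientation sweep at spacing 1.2, phase (0, 0)
            + [{"s": 1.2, "theta": th, "phase": [0.0, 0.0]} for th in (0.0, math.pi / 12, math.pi / 6, math.pi / 4)]
            # phase pair
            + [{"s": 1.0, "theta": 0.0, "phase": [0.0, 0.0]}, {"s": 1.0, "theta": 0.0, "phase": [0.4, 0.8]}]
        )
        return ExperimentConfig(
            experiment="multi_cell",
            environment={"kind": "circle", "radius": 2.0},
            cells=sweep,
            n_steps=200_000,
        )
    if experiment == "two_compartment":
        return ExperimentConfig(
            experiment="two_compartment",
            environment={"kind": "two_compartment"},
            cells=[{"s": 1.5, "theta": math.pi / 4, "phase": [0.0, 0.0]}],
            alpha=0.5, beta=1.0, xi=0.1, M=100_000,
            n_steps=770_000,
            snapshots=[10_000, 145_000, 395_000, 770_000],
        )
    if experiment == "four_compartment":
        return ExperimentConfig(
            experiment="four_compartment",
            environment={"kind": "four_compartment"},
            cells=[{"s": 1.0, "theta": math.pi / 4, "phase": [0.0, 0.0]}],
            alpha=0.8, beta=1.0, xi=0.2, M=100_000,
            n_steps=833_000,
            snapshots=[50_000, 320_000, 575_000, 833_000],
        )
    raise ConfigError(f"experiment: unknown kind {experiment!r}")


def load_config(path, scaled: bool = False, **overrides) -> ExperimentConfig:
    """Read a YAML config file; unknown keys are rejected by name."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ConfigError("config: top level must be a mapping")
    experiment = data.pop("experiment", overrides.get("experiment", "single_cell"))
    cfg = default_config(experiment)
    known = {f.name for f in dataclasses.fields(ExperimentConfig)}
    for key, value in {**data, **overrides}.items():
        if key not in known:
            raise ConfigError(f"{key}: unknown configuration key")
        setattr(cfg, key, value)
    cfg.validate()
    return cfg.scaled() if scaled else cfg


# ---------------------------------------------------------------------------
# runners


def _trajectory(cfg: ExperimentConfig, env: Environment) -> Trajectory:
    """The configured trajectory: read from file if given, else simulate."""
    if cfg.trajectory_file:
        from .trajectory import read_trajectory

        traj = read_trajectory(cfg.trajectory_file)
        if not np.all(env.contains(traj.xy)):
            raise ConfigError("trajectory_file: positions fall outside the environment")
        return traj
    return random_walk(
        env, cfg.n_steps, cfg.dt, cfg.speed, cfg.speed_jitter, cfg.turn_sd, cfg.seed
    )


def _outdir(cfg: ExperimentConfig) -> Path:
    out = Path(cfg.out)
    out.mkdir(parents=True, exist_ok=True)
    return out


def _write_json(path: Path, obj) -> None:
    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        raise TypeError(type(o))

    path.write_text(json.dumps(obj, indent=2, default=default) + "\n")


def _save_map_png(path: Path, ratemap, title: str) -> None:
    fig, ax = plt.subplots(figsize=(5, 4))
    xmin, ymin, xmax, ymax = ratemap.extent
    im = ax.imshow(
        ratemap.mean_rate.T,
        origin="lower",
        extent=(xmin, xmax, ymin, ymax),
        cmap="jet",
        vmin=0.0,
        vmax=1.0,
        interpolation="nearest",
    )
    fig.colorbar(im, ax=ax, label="firing rate")
    ax.set(title=title, xlabel="x (m)", ylabel="y (m)", aspect="equal")
    fig.savefig(path, dpi=110)
    plt.close(fig)


def _estimates_for_cell(cell, fparams, env, ratemap):
    """Lattice-parameter estimates from analytic centers and from map peaks."""
    centers = field_centers(cell, env.frames[env.reference], env)
    out = {"n_centers": int(len(centers))}
    if len(centers) >= 7:
        s_a, th_a, ph_a = estimate_lattice_params(centers)
        out["analytic"] = {"s": s_a, "theta": th_a, "phase": ph_a.tolist()}
    peaks = detect_peaks(ratemap, threshold=None, edge_margin=3 * ratemap.bin_size)
    out["n_map_peaks"] = int(len(peaks))
    if len(peaks) >= 7:
        try:
            s_m, th_m, ph_m = estimate_lattice_params(peaks)
            out["map"] = {"s": s_m, "theta": th_m, "phase": ph_m.tolist()}
        except ValueError:
            pass
    off1, r1 = profile_along_axis(cell, fparams, 1, half_length=3.0)
    off2, r2 = profile_along_axis(cell, fparams, 2, half_length=3.0)
    p1, p2 = profile_peaks(off1, r1), profile_peaks(off2, r2)
    out["profile_first_peak"] = [
        float(p1[0]) if len(p1) else None,
        float(p2[0]) if len(p2) else None,
    ]
    out["nearest_center_along_axis"] = [
        nearest_center_distance_along_axis(cell, 1),
        nearest_center_distance_along_axis(cell, 2),
    ]
    return out


def run_single_cell(config: ExperimentConfig) -> dict:
    """Random walk + firing field of a single grid cell; parameter recovery."""
    config.validate()
    out = _outdir(config)
    env = config.build_env()
    cell = config.grid_cells()[0]
    fparams = config.firing_params()

    traj = _trajectory(config, env)
    rates = firing_rate(cell, fparams, traj.xy)  # frame is identity here

    act = traj.to_dataframe()[["t", "x", "y"]]
    act["rate"] = rates
    act.to_csv(out / "activation.csv", index=False, float_format="%.9g")
    write_trajectory(traj, out / "trajectory.csv")

    ratemap = bin_rate_map(traj.xy, rates, config.bin_size, env.bbox)
    ratemap.to_dataframe().to_csv(out / "ratemap.csv", index=False, float_format="%.6g")
    _save_map_png(out / "ratemap.png", ratemap, f"{config.experiment}: {env.kind}")

    summary = {
        "experiment": config.experiment,
        "environment": env.kind,
        "n_steps": config.n_steps,
        "seed": config.seed,
        "cell": {"s": cell.s, "theta": cell.theta, "phase": cell.phase.tolist()},
        "rate_min": float(rates.min()),
        "rate_max": float(rates.max()),
        "estimates": _estimates_for_cell(cell, fparams, env, ratemap),
    }
    _write_json(out / "summary.json", summary)
    return summary


def run_multi_cell(config: ExperimentConfig) -> dict:
    """One map per configured grid cell over a shared trajectory."""
    config.validate()
    out = _outdir(config)
    env = config.build_env()
    cells = config.grid_cells()
    fparams = config.firing_params()

    traj = _trajectory(config, env)
    per_cell = []
    ncols = min(4, len(cells))
    nrows = (len(cells) + ncols - 1) // ncols
    fig, axes = plt.subplots(nrows, ncols, figsize=(3.2 * ncols, 3.0 * nrows), squeeze=False)
    for i, cell in enumerate(cells):
        rates = firing_rate(cell, fparams, traj.xy)
        ratemap = bin_rate_map(traj.xy, rates, config.bin_size, env.bbox)
        ratemap.to_dataframe().to_csv(out / f"cell_{i:02d}_map.csv", index=False, float_format="%.6g")
        est = _estimates_for_cell(cell, fparams, env, ratemap)
        per_cell.append(
            {"cell": {"s": cell.s, "theta": cell.theta, "phase": cell.phase.tolist()}, "estimates": est}
        )
        ax = axes[i // ncols][i % ncols]
        xmin, ymin, xmax, ymax = ratemap.extent
        ax.imshow(ratemap.mean_rate.T, origin="lower", extent=(xmin, xmax, ymin, ymax),
                  cmap="jet", vmin=0, vmax=1, interpolation="nearest")
        ax.set_title(f"s={cell.s:g} th={cell.theta:.2f} ph={cell.phase.round(2).tolist()}", fontsize=8)
        ax.set_aspect("equal")
    for j in range(len(cells), nrows * ncols):
        axes[j // ncols][j % ncols].axis("off")
    fig.tight_layout()
    fig.savefig(out / "sweep.png", dpi=110)
    plt.close(fig)

    summary = {"experiment": config.experiment, "seed": config.seed, "cells": per_cell}
    _write_json(out / "summary.json", summary)
    return summary


# -- connected environments --------------------------------------------------


def aligned_compartment_maps(env, traj, rates, bin_size: float = 0.1) -> dict:
    """Per-compartment rate maps binned in each compartment's LOCAL frame.

    Expressing every compartment's samples in its own place-frame coordinates
    aligns the maps bin-for-bin, so replicated local patterns (adjustment
    off) show up as near-perfect correlation between any two compartments'
    maps.  Corridor samples are dropped.
    """
    maps = {}
    for reg in env.compartments:
        sel = traj.compartment == reg.name
        if not np.any(sel):
            continue
        local = fr.apply(env.frames[reg.name], traj.xy[sel])
        xmin, ymin, xmax, ymax = reg.bounds
        extent = (0.0, 0.0, xmax - xmin, ymax - ymin)
        maps[reg.name] = bin_rate_map(local, np.asarray(rates)[sel], bin_size, extent)
    return maps


def _rates_under_frames(cell, fparams, state, env, xy, labels):
    """Rates for all samples with each compartment's CURRENT frame applied;
    corridor samples use the reference (global) frame."""
    rates = np.empty(len(xy))
    comp_names = {r.name for r in env.compartments}
    for name in np.unique(labels):
        sel = labels == name
        T = state.frames[name] if name in comp_names else state.target
        rates[sel] = firing_rate(cell, fparams, fr.apply(T, xy[sel]))
    return rates


def simulate_connected(
    env: Environment,
    cell: GridCell,
    fparams: FiringParams,
    traj: Trajectory,
    schedule: AdjustmentSchedule,
    adjust: bool = True,
    snapshot_steps=(),
    curve_every: int = 0,
    bin_size: float = 0.1,
):
    """Step through a trajectory in a connected arena, adjusting frames.

    Per sample: the firing rate is computed in the current frame of the
    containing compartment (corridor samples use the global frame).  While
    the animal is inside a non-reference compartment, that compartment's
    experience counter is incremented and its frame takes one adjustment
    step toward the reference frame.  At checkpoint steps the global-fit
    correlation between the map under the current frames and the
    single-global-frame ideal map is recorded (corridor samples excluded).

    Returns (rates_hist, curve, state, trace, snapshots) where ``curve`` is a
    list of (step, r), ``trace`` rows are per-adjustment diagnostics, and
    ``snapshots`` maps step -> RateMap of the rates as experienced so far.
    """
    n = len(traj)
    xy = traj.xy
    labels = traj.compartment
    comp_names = [r.name for r in env.compartments]
    non_ref = [c for c in comp_names if c != env.reference]
    state = AdjustmentState(
        frames=dict(env.frames),
        reference=env.reference,
        schedules={c: dataclasses.replace(schedule) for c in non_ref},
    )

    rates_ref = firing_rate(cell, fparams, fr.apply(state.target, xy))
    keep = np.isin(labels, comp_names)  # corridor ignored in maps

    curve_every = curve_every or max(1, n // 40)
    checkpoints = sorted(set(range(curve_every, n + 1, curve_every)) | set(snapshot_steps) | {n})
    snapshot_steps = set(snapshot_steps)

    # fast scalar rate in the current frame of one sample
    R_pg = place_to_grid_matrix(cell)
    phase = cell.phase

    def rate_at(T, x, y):
        px, py = T.rotation @ (x, y) + T.varpi
        g = R_pg @ (px, py) - phase
        resid = g - np.copysign(np.floor(np.abs(g) + 0.5), g)
        d = math.hypot(*resid)
        r = 0.5 - math.atan(fparams.kappa * (d / cell.s - fparams.zeta)) / math.pi
        return min(max(r, 0.0), 1.0)

    rates_hist = np.empty(n)
    trace = []
    curve = []
    snapshots = {}
    non_ref_set = set(non_ref)
    ck = iter(checkpoints)
    next_ck = next(ck)
    for i in range(n):
        lab = labels[i]
        T = state.frames[lab] if lab in state.frames else state.target
        rates_hist[i] = rate_at(T, xy[i, 0], xy[i, 1])
        if adjust and lab in non_ref_set:
            g = state.record_step(lab)
            sched = state.schedules[lab]
            phi_d, varpi_d = fr.frame_difference(state.frames[lab], state.target)
            trace.append((i + 1, lab, sched.N_t, g, phi_d, varpi_d[0], varpi_d[1]))
        step = i + 1
        if step == next_ck:
            upto = keep[:step]
            cur = _rates_under_frames(cell, fparams, state, env, xy[:step][upto], labels[:step][upto])
            map_cur = bin_rate_map(xy[:step][upto], cur, bin_size, env.bbox)
            map_ref = bin_rate_map(xy[:step][upto], rates_ref[:step][upto], bin_size, env.bbox)
            try:
                r = global_fit_correlation(map_cur, map_ref)
            except ValueError:
                r = float("nan")
            curve.append((step, r))
            if step in snapshot_steps:
                snapshots[step] = bin_rate_map(
                    xy[:step][upto], rates_hist[:step][upto], bin_size, env.bbox
                )
            next_ck = next(ck, None)

    return rates_hist, curve, state, trace, snapshots


def run_connected(config: ExperimentConfig) -> dict:
    """Connected-environment experiment (two or four compartments)."""
    config.validate()
    if config.experiment not in ("two_compartment", "four_compartment"):
        raise ConfigError(f"experiment: run_connected needs a connected kind, got {config.experiment!r}")
    out = _outdir(config)
    env = config.build_env()
    cell = config.grid_cells()[0]
    fparams = config.firing_params()
    schedule = AdjustmentSchedule(config.alpha, config.beta, config.xi, config.M)

    traj = _trajectory(config, env)
    rates_hist, curve, state, trace, snapshots = simulate_connected(
        env, cell, fparams, traj, schedule,
        adjust=config.adjust,
        snapshot_steps=config.snapshots,
        curve_every=config.curve_every,
        bin_size=config.bin_size,
    )

    write_trajectory(traj, out / "trajectory.csv")
    np.savetxt(
        out / "correlation_curve.csv",
        np.asarray(curve, dtype=float),
        delimiter=",", header="step,r", comments="", fmt="%.9g",
    )
    if trace:
        import pandas as pd

        pd.DataFrame(
            trace,
            columns=["step", "compartment", "N_t", "gamma", "angle_diff", "trans_diff_x", "trans_diff_y"],
        ).to_csv(out / "adjustment_trace.csv", index=False, float_format="%.9g")
    for step, smap in snapshots.items():
        smap.to_dataframe().to_csv(out / f"snapshot_{step:07d}.csv", index=False, float_format="%.6g")
        _save_map_png(out / f"snapshot_{step:07d}.png", smap, f"step {step}")

    diffs = {
        name: {
            "angle": fr.frame_difference(T, state.target)[0],
            "translation": fr.frame_difference(T, state.target)[1].tolist(),
        }
        for name, T in state.frames.items()
        if name != state.reference
    }
    final_gamma = {name: gamma(s) for name, s in state.schedules.items()}
    summary = {
        "experiment": config.experiment,
        "seed": config.seed,
        "n_steps": config.n_steps,
        "adjust": config.adjust,
        "final_correlation": curve[-1][1] if curve else None,
        "converged": has_converged(state) if config.adjust else False,
        "frame_differences": diffs,
        "final_gamma": final_gamma,
        "rate_min": float(rates_hist.min()),
        "rate_max": float(rates_hist.max()),
    }
    _write_json(out / "summary.json", summary)
    return summary


def run(config: ExperimentConfig) -> dict:
    """Dispatch on the configured experiment kind."""
    if config.experiment == "single_cell":
        return run_single_cell(config)
    if config.experiment == "multi_cell":
        return run_multi_cell(config)
    return run_connected(config)
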