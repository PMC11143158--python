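"""Binned rate maps, the global-fit correlation, and lattice-parameter recovery."""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.stats import pearsonr
from scipy import ndimage

from .cells import FiringParams, GridCell, basis_matrix, basis_vectors, firing_rate

__all__ = [
    "RateMap",
    "bin_rate_map",
    "global_fit_correlation",
    "estimate_lattice_params",
    "profile_along_axis",
    "profile_peaks",
    "detect_peaks",
]

_SIXTY = math.pi / 3.0


@dataclass
class RateMap:
    """Occupancy-normalised binned firing-rate map.

    ``mean_rate[i, j]`` is the mean rate of samples in bin (i, j) of the
    half-open grid ``[xmin + i*b, xmin + (i+1)*b) x [ymin + j*b, ...)``;
    unvisited bins hold NaN.  ``occupancy`` holds sample counts.
    """

    bin_size: float
    extent: tuple[float, float, float, float]  # xmin, ymin, xmax, ymax
    mean_rate: np.ndarray  # (nx, ny), NaN where unvisited
    occupancy: np.ndarray  # (nx, ny) int

    @property
    def shape(self):
        return self.mean_rate.shape

    def bin_centers(self):
        xmin, ymin, _, _ = self.extent
        nx, ny = self.shape
        xs = xmin + self.bin_size * (np.arange(nx) + 0.5)
        ys = ymin + self.bin_size * (np.arange(ny) + 0.5)
        return xs, ys

    def to_dataframe(self) -> pd.DataFrame:
        xs, ys = self.bin_centers()
        xi, yi = np.meshgrid(range(self.shape[0]), range(self.shape[1]), indexing="ij")
        return pd.DataFrame(
            {
                "x": xs[xi.ravel()],
                "y": ys[yi.ravel()],
                "rate": self.mean_rate.ravel(),
                "occupancy": self.occupancy.ravel(),
            }
        )


def bin_rate_map(positions, rates, bin_size: float, extent=None) -> RateMap:
    """Bin (position, rate) samples into an occupancy-normalised map."""
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    p = np.atleast_2d(np.asarray(positions, dtype=float))
    r = np.asarray(rates, dtype=float).ravel()
    if len(p) == 0:
        raise ValueError("no samples to bin")
    if extent is None:
        extent = (p[:, 0].min(), p[:, 1].min(), p[:, 0].max(), p[:, 1].max())
    xmin, ymin, xmax, ymax = (float(v) for v in extent)
    nx = max(1, int(math.ceil((xmax - xmin) / bin_size - 1e-9)))
    ny = max(1, int(math.ceil((ymax - ymin) / bin_size - 1e-9)))
    ix = np.floor((p[:, 0] - xmin) / bin_size).astype(int)
    iy = np.floor((p[:, 1] - ymin) / bin_size).astype(int)
    ok = (ix >= 0) & (ix < nx) & (iy >= 0) & (iy < ny)
    ix, iy, r = ix[ok], iy[ok], r[ok]

    occ = np.zeros((nx, ny), dtype=int)
    tot = np.zeros((nx, ny))
    np.add.at(occ, (ix, iy), 1)
    np.add.at(tot, (ix, iy), r)
    with np.errstate(invalid="ignore"):
        mean = np.where(occ > 0, tot / np.maximum(occ, 1), np.nan)
    return RateMap(bin_size, (xmin, ymin, xmax, ymax), mean, occ)


def global_fit_correlation(current: RateMap, reference: RateMap, exclude=None) -> float:
    """Pearson r between two maps over jointly visited (non-excluded) bins.

    Quantifies how close the pattern produced under the current
    (possibly mid-adjustment) place frames is to the single-global-frame
    ideal: ~0 for replicated local fields, 1 for a coherent global field.
    ``exclude`` is an optional boolean array marking bins (e.g. corridor
    bins) to leave out.
    """
    if current.shape != reference.shape or current.extent != reference.extent:
        raise ValueError("rate maps must share the same bin grid")
    joint = ~np.isnan(current.mean_rate) & ~np.isnan(reference.mean_rate)
    if exclude is not None:
        joint &= ~np.asarray(exclude, dtype=bool)
    a = current.mean_rate[joint]
    b = reference.mean_rate[joint]
    if a.size < 2:
        raise ValueError("fewer than 2 jointly visited bins")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("zero variance in a rate map; correlation undefined")
    return float(pearsonr(a, b).statistic)


def estimate_lattice_params(centers) -> tuple[float, float, np.ndarray]:
    """Recover (spacing, orientation, phase) from a set of field centers.

    Spacing is the typical (median) nearest-neighbour distance; orientation
    is the circular mean of neighbour directions folded by the lattice's
    six-fold symmetry into [0, pi/3); the phase is the per-component circular
    mean of the centers' fractional lattice coordinates, in [0, 1)^2.
    Requires at least 7 centers (an interior point plus its hexagonal ring)
    that are not collinear.
    """
    c = np.atleast_2d(np.asarray(centers, dtype=float))
    if len(c) < 7:
        raise ValueError("need at least 7 centers to estimate lattice parameters")
    sv = np.linalg.svd(c - c.mean(axis=0), compute_uv=False)
    if sv[1] < 1e-9 * sv[0]:
        raise ValueError("degenerate (collinear) center set")

    tree = cKDTree(c)
    nn_dist, _ = tree.query(c, k=2)
    s_hat = float(np.median(nn_dist[:, 1]))

    # neighbour directions, folded by the 60-degree lattice symmetry
    pairs = tree.query_pairs(1.25 * s_hat, output_type="ndarray")
    if len(pairs) == 0:
        raise ValueError("no neighbour pairs at the estimated spacing")
    d = c[pairs[:, 1]] - c[pairs[:, 0]]
    ang = np.arctan2(d[:, 1], d[:, 0])
    theta_hat = float(np.angle(np.exp(6j * ang).mean()) / 6.0) % _SIXTY
    if _SIXTY - theta_hat < 1e-9:  # fold numerical noise at the sector edge
        theta_hat = 0.0

    B = basis_matrix(GridCell(s_hat, theta_hat))
    g = c @ np.linalg.inv(B).T  # lattice coordinates of every center
    phase_hat = (np.angle(np.exp(2j * math.pi * g).mean(axis=0)) / (2 * math.pi)) % 1.0

    # refine by least squares: assign integer lattice indices under the
    # current estimate and refit (basis, offset) jointly; two passes remove
    # the drift a small spacing error accumulates across the arena
    for _ in range(2):
        B = basis_matrix(GridCell(s_hat, theta_hat))
        g = c @ np.linalg.inv(B).T
        mu = np.angle(np.exp(2j * math.pi * g).mean(axis=0)) / (2 * math.pi)
        n = np.round(g - mu)
        A = np.column_stack([n, np.ones(len(c))])  # [n1 n2 1] @ [b1 b2 t]^T
        coef, *_ = np.linalg.lstsq(A, c, rcond=None)
        b1, b2, t = coef[0], coef[1], coef[2]
        s_hat = float((np.linalg.norm(b1) + np.linalg.norm(b2)) / 2.0)
        ang = np.arctan2([b1[1], b2[1]], [b1[0], b2[0]])
        theta_hat = float(np.angle(np.exp(6j * ang).mean()) / 6.0) % _SIXTY
        if _SIXTY - theta_hat < 1e-9:
            theta_hat = 0.0
    Bfit = np.column_stack([b1, b2])
    phase_hat = np.linalg.solve(Bfit, t) % 1.0  # t = B @ phase when n is exact
    return s_hat, theta_hat, phase_hat


def profile_along_axis(
    cell: GridCell,
    params: FiringParams,
    axis: int,
    half_length: float = 5.0,
    step: float = 0.01,
):
    """Firing rate sampled along the ray from the origin in a basis direction.

    Returns ``(offsets, rates)``; the local maxima of the profile are the
    "bumps" whose positions reveal the cell's phase and spacing.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    eps = basis_vectors(cell)[axis - 1]
    unit = eps / np.linalg.norm(eps)
    offsets = np.arange(0.0, half_length + step / 2, step)
    rates = firing_rate(cell, params, offsets[:, None] * unit)
    return offsets, rates


def profile_peaks(offsets, rates) -> np.ndarray:
    """Offsets of strict interior local maxima of a 1D profile."""
    r = np.asarray(rates)
    idx = np.flatnonzero((r[1:-1] >= r[:-2]) & (r[1:-1] > r[2:])) + 1
    # merge flat-topped runs: keep first index of each run
    keep = np.ones(len(idx), dtype=bool)
    keep[1:] = np.diff(idx) > 1
    idx = idx[keep]
    if len(r) > 1 and r[0] > r[1]:  # a bump sitting exactly at the ray origin
        idx = np.concatenate([[0], idx])
    return np.asarray(offsets)[idx]


def smooth_rate_map(ratemap: RateMap, sigma_bins: float = 1.5) -> np.ndarray:
    """Occupancy-weighted Gaussian smoothing of the mean-rate array.

    The numerator (rate x visited) and denominator (visited) are smoothed
    separately so unvisited bins neither leak zeros nor block the kernel —
    the standard treatment for spike/rate maps.  Bins far from any visited
    bin stay NaN.
    """
    visited = (ratemap.occupancy > 0).astype(float)
    val = np.where(visited > 0, np.nan_to_num(ratemap.mean_rate), 0.0)
    num = ndimage.gaussian_filter(val, sigma_bins, mode="constant")
    den = ndimage.gaussian_filter(visited, sigma_bins, mode="constant")
    with np.errstate(invalid="ignore", divide="ignore"):
        out = num / den
    out[den < 1e-3] = np.nan
    return out


def detect_peaks(
    ratemap: RateMap,
    threshold: float | None = 0.5,
    refine: bool = True,
    sigma_bins: float = 1.5,
    edge_margin: float = 0.0,
) -> np.ndarray:
    """Field-center candidates from a binned map: 8-connected local maxima
    of the smoothed map above ``threshold``, refined by a 3x3 center-of-mass.

    ``threshold=None`` uses the midpoint of the smoothed map's range, which
    also works for low-contrast (large-spacing) fields.  ``edge_margin``
    (metres) drops maxima near the map boundary, where bumps whose true
    centers lie outside the mapped region are clipped and would otherwise
    masquerade as interior centers.  Returns an (n, 2) array of world
    coordinates.
    """
    sm = smooth_rate_map(ratemap, sigma_bins) if sigma_bins else ratemap.mean_rate
    if threshold is None:
        lo, hi = np.nanmin(sm), np.nanmax(sm)
        threshold = lo + 0.5 * (hi - lo)
    m = np.where(np.isnan(sm), -np.inf, sm)
    local_max = m == ndimage.maximum_filter(m, size=3, mode="constant", cval=-np.inf)
    peaks = np.argwhere(local_max & (m > threshold))
    xs, ys = ratemap.bin_centers()
    out = []
    nx, ny = ratemap.shape
    for i, j in peaks:
        if refine and 0 < i < nx - 1 and 0 < j < ny - 1:
            w = m[i - 1 : i + 2, j - 1 : j + 2].copy()
            w[~np.isfinite(w)] = 0.0
            w = np.clip(w - w.min(), 0.0, None)
            if w.sum() > 0:
                di = float((w.sum(axis=1) * np.array([-1, 0, 1])).sum() / w.sum())
                dj = float((w.sum(axis=0) * np.array([-1, 0, 1])).sum() / w.sum())
                out.append([xs[i] + di * ratemap.bin_size, ys[j] + dj * ratemap.bin_size])
                continue
        out.append([xs[i], ys[j]])
    pk = np.array(out).reshape(-1, 2)
    if edge_margin > 0 and len(pk):
        xmin, ymin, xmax, ymax = ratemap.extent
        inner = (
            (pk[:, 0] >= xmin + edge_margin)
            & (pk[:, 0] <= xmax - edge_margin)
            & (pk[:, 1] >= ymin + edge_margin)
            & (pk[:, 1] <= ymax - edge_margin)
        )
        pk = pk[inner]
    return pk
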