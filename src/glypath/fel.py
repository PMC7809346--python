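"""Free-energy-landscape reconstruction and path analysis.

A converged well-tempered metadynamics run gives the free energy over the
biased collective variables as F(s) = −(γ/(γ−1)) · V_bias(s) (up to an
additive constant; grids here are normalized to min F = 0).  On the gridded
landscape this module finds local minima with a depth (prominence) filter,
traces the minimum-free-energy path between basins as the minimax path over
grid moves (the path whose highest point is lowest, computed with a
Dijkstra-style search and ties broken by lower path-integrated energy),
lower-dimensional Boltzmann projections, convergence monitoring of the
basin free-energy difference, and the Gaussian-height sensitivity protocol
(independent runs restarted at a stated bias-fill level with different hill
heights, reporting the spread of barrier estimates).
"""

from __future__ import annotations

import heapq
import itertools
import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .sampling import (HillsLog, LangevinParams, MetadParams, evaluate_bias_grid,
                       run_wt_metadynamics)
from .synthetic import KB_KCAL


class FELError(ValueError):
    """Raised for unusable grids or landscapes."""


@dataclass(frozen=True)
class Axis:
    name: str
    lo: float
    hi: float
    n: int

    @property
    def values(self) -> np.ndarray:
        return np.linspace(self.lo, self.hi, self.n)

    @property
    def spacing(self) -> float:
        return (self.hi - self.lo) / (self.n - 1)


@dataclass
class FELGrid:
    """Gridded free energy over 1–3 collective variables, min-normalized."""

    axes: tuple[Axis, ...]
    values: np.ndarray   # kcal/mol, shape (n1, [n2, [n3]])

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != tuple(a.n for a in self.axes):
            raise FELError(f"values shape {self.values.shape} does not match axes")
        if not np.isfinite(self.values).all():
            raise FELError("free energy grid contains non-finite values")

    @property
    def ndim(self) -> int:
        return len(self.axes)

    def normalized(self) -> "FELGrid":
        return FELGrid(self.axes, self.values - self.values.min())

    def point(self, idx: tuple[int, ...]) -> np.ndarray:
        return np.array([ax.values[i] for ax, i in zip(self.axes, idx)])

    def nearest_index(self, point: Sequence[float]) -> tuple[int, ...]:
        return tuple(
            int(np.clip(round((p - ax.lo) / ax.spacing), 0, ax.n - 1))
            for ax, p in zip(self.axes, np.asarray(point, dtype=float))
        )

    def mesh_points(self) -> np.ndarray:
        """All grid points, shape (prod(n), ndim), C-order."""
        grids = np.meshgrid(*[a.values for a in self.axes], indexing="ij")
        return np.stack([g.ravel() for g in grids], axis=-1)

    def to_text(self, path: str | Path, metadata: dict | None = None) -> Path:
        """Gridded text export: one row per point, coordinates then energy."""
        path = Path(path)
        lines = ["# " + " ".join(a.name for a in self.axes) + " free_energy_kcal_mol"]
        if metadata:
            for k, v in metadata.items():
                lines.append(f"# {k} = {v}")
        pts = self.mesh_points()
        for p, v in zip(pts, self.values.ravel()):
            lines.append(" ".join(f"{c:.6f}" for c in p) + f" {v:.6f}")
        path.write_text("\n".join(lines) + "\n")
        return path


@dataclass(frozen=True)
class Minimum:
    index: tuple[int, ...]
    point: np.ndarray
    energy: float


@dataclass
class PathResult:
    """Minimax path between two minima on a gridded landscape."""

    indices: list[tuple[int, ...]]
    points: np.ndarray            # (n, d)
    energies: np.ndarray          # (n,)
    barrier: float                # max(energy along path) - energy(start)
    saddle_index: int             # position of the maximum along the path

    @property
    def saddle_point(self) -> np.ndarray:
        return self.points[self.saddle_index]

    @property
    def saddle_energy(self) -> float:
        return float(self.energies[self.saddle_index])


# ---------------------------------------------------------------------------
# Reconstruction and projection
# ---------------------------------------------------------------------------

def default_axes(hills: HillsLog, n: int = 101, margin_sigmas: float = 3.0) -> tuple[Axis, ...]:
    """Grid covering the bounding box of hill centers plus a 3σ margin."""
    _, c, s, _ = hills.as_arrays()
    axes = []
    for j, name in enumerate(hills.cv_names):
        pad = margin_sigmas * s[:, j].max()
        axes.append(Axis(name, c[:, j].min() - pad, c[:, j].max() + pad, n))
    return tuple(axes)


def reconstruct_fel(hills: HillsLog, axes: tuple[Axis, ...] | None = None,
                    n: int = 101) -> FELGrid:
    """Well-tempered estimator F(s) = −(γ/(γ−1)) Σ hills(s), min-normalized.

    For γ = ∞ (standard metadynamics) the prefactor is 1.  Warns when the
    grid does not cover all hill centers.
    """
    if len(hills) == 0:
        raise FELError("cannot reconstruct a free energy landscape from an empty hills log")
    gamma = hills.bias_factor
    factor = 1.0 if math.isinf(gamma) else gamma / (gamma - 1.0)
    if not math.isinf(gamma) and gamma <= 1.0:
        raise FELError(f"bias factor {gamma} must exceed 1")
    if axes is None:
        axes = default_axes(hills, n=n)
    _, c, _, _ = hills.as_arrays()
    for j, ax in enumerate(axes):
        if c[:, j].min() < ax.lo or c[:, j].max() > ax.hi:
            import warnings
            warnings.warn(f"grid axis {ax.name} does not cover all hill centers", stacklevel=2)
    shape = tuple(a.n for a in axes)
    grid = FELGrid(tuple(axes), np.zeros(shape))
    bias = evaluate_bias_grid(hills, grid.mesh_points())
    return FELGrid(tuple(axes), (-factor * bias).reshape(shape)).normalized()


def project_fel(fel: FELGrid, keep: Sequence[str], temperature: float = 300.0) -> FELGrid:
    """Boltzmann projection onto a subset of axes.

    F_proj(a) = −kT ln ∫ exp(−F(a, b)/kT) db, renormalized to min 0.  The
    projection can only lower (never raise) minimax barriers between fixed
    basins relative to the full-dimensional landscape.
    """
    kt = KB_KCAL * temperature
    if kt <= 0:
        raise FELError("temperature must be positive")
    names = [a.name for a in fel.axes]
    keep_idx = []
    for k in keep:
        if k not in names:
            raise FELError(f"axis {k!r} not in grid axes {names}")
        keep_idx.append(names.index(k))
    if len(keep_idx) >= fel.ndim:
        raise FELError("projection must integrate out at least one axis")
    drop_idx = [i for i in range(fel.ndim) if i not in keep_idx]
    # move kept axes to the front, in requested order
    perm = keep_idx + drop_idx
    vals = np.transpose(fel.values, perm)
    log_vol = sum(math.log(fel.axes[i].spacing) for i in drop_idx)
    flat = vals.reshape(vals.shape[: len(keep_idx)] + (-1,))
    from scipy.special import logsumexp
    proj = -kt * (logsumexp(-flat / kt, axis=-1) + log_vol)
    return FELGrid(tuple(fel.axes[i] for i in keep_idx), proj).normalized()


# ---------------------------------------------------------------------------
# Minima, minimax paths
# ---------------------------------------------------------------------------

def _neighbor_offsets(ndim: int) -> list[tuple[int, ...]]:
    return [o for o in itertools.product((-1, 0, 1), repeat=ndim) if any(o)]


def _local_minima_indices(values: np.ndarray) -> list[tuple[int, ...]]:
    from scipy import ndimage
    footprint = np.ones((3,) * values.ndim, dtype=bool)
    mins = ndimage.minimum_filter(values, footprint=footprint, mode="nearest")
    cand = np.argwhere(values == mins)
    # deduplicate flat plateaus: keep one representative per connected plateau
    out: list[tuple[int, ...]] = []
    seen = np.zeros(values.shape, dtype=bool)
    for idx in map(tuple, cand):
        if seen[idx]:
            continue
        # flood the plateau of equal value
        stack, plateau = [idx], [idx]
        seen[idx] = True
        while stack:
            cur = stack.pop()
            for off in _neighbor_offsets(values.ndim):
                nb = tuple(c + o for c, o in zip(cur, off))
                if all(0 <= v < s for v, s in zip(nb, values.shape)) and not seen[nb] \
                        and values[nb] == values[idx]:
                    seen[nb] = True
                    stack.append(nb)
                    plateau.append(nb)
        out.append(plateau[0])
    return out


def _escape_level(values: np.ndarray, start: tuple[int, ...]) -> float:
    """Minimax level at which ``start`` connects to any strictly lower cell."""
    target = values[start]
    heap = [(values[start], start)]
    visited = {start}
    offsets = _neighbor_offsets(values.ndim)
    while heap:
        level, cur = heapq.heappop(heap)
        if values[cur] < target:
            return level
        for off in offsets:
            nb = tuple(c + o for c, o in zip(cur, off))
            if all(0 <= v < s for v, s in zip(nb, values.shape)) and nb not in visited:
                visited.add(nb)
                heapq.heappush(heap, (max(level, values[nb]), nb))
    return math.inf  # global minimum: no lower cell anywhere


def find_minima(fel: FELGrid, depth_threshold: float = 1.0) -> list[Minimum]:
    """Local minima deeper than ``depth_threshold`` below their escape saddle.

    A candidate survives when the lowest level at which it drains into any
    lower region exceeds its own energy by more than the threshold
    (topographic prominence); the global minimum always survives.  Sorted by
    energy.  A flat grid has no minima.
    """
    v = fel.values
    if np.ptp(v) == 0:
        return []
    minima = []
    for idx in _local_minima_indices(v):
        level = _escape_level(v, idx)
        prominence = level - v[idx]
        if prominence > depth_threshold:
            minima.append(Minimum(index=idx, point=fel.point(idx), energy=float(v[idx])))
    return sorted(minima, key=lambda m: m.energy)


def trace_mfep(fel: FELGrid, start: Minimum | tuple[int, ...],
               end: Minimum | tuple[int, ...]) -> PathResult:
    """Minimax path between two grid minima.

    Over 8-connected grid moves (26-connected in 3-D) the returned path
    minimizes the maximum energy encountered; among such paths the one with
    the lowest path-integrated energy is chosen.  The saddle is the argmax
    along the path; the barrier is measured from the start minimum.
    """
    s_idx = start.index if isinstance(start, Minimum) else tuple(start)
    e_idx = end.index if isinstance(end, Minimum) else tuple(end)
    v = fel.values
    if not np.isfinite(v[s_idx]) or not np.isfinite(v[e_idx]):
        raise FELError("path endpoints must have finite energy")
    offsets = _neighbor_offsets(v.ndim)
    best: dict[tuple[int, ...], tuple[float, float]] = {s_idx: (v[s_idx], v[s_idx])}
    prev: dict[tuple[int, ...], tuple[int, ...]] = {}
    heap = [(v[s_idx], v[s_idx], s_idx)]
    while heap:
        level, cost, cur = heapq.heappop(heap)
        if (level, cost) > best.get(cur, (math.inf, math.inf)):
            continue
        if cur == e_idx:
            break
        for off in offsets:
            nb = tuple(c + o for c, o in zip(cur, off))
            if not all(0 <= val < s for val, s in zip(nb, v.shape)):
                continue
            if not np.isfinite(v[nb]):
                continue
            cand = (max(level, v[nb]), cost + v[nb])
            if cand < best.get(nb, (math.inf, math.inf)):
                best[nb] = cand
                prev[nb] = cur
                heapq.heappush(heap, (cand[0], cand[1], nb))
    if e_idx not in best:
        raise FELError("end minimum unreachable from start (disconnected grid regions)")
    path = [e_idx]
    while path[-1] != s_idx:
        path.append(prev[path[-1]])
    path.reverse()
    energies = np.array([v[i] for i in path])
    return PathResult(
        indices=path,
        points=np.array([fel.point(i) for i in path]),
        energies=energies,
        barrier=float(energies.max() - energies[0]),
        saddle_index=int(np.argmax(energies)),
    )


# ---------------------------------------------------------------------------
# Convergence and height-sensitivity protocols
# ---------------------------------------------------------------------------

def basin_delta_f(fel: FELGrid, center_a: Sequence[float], center_b: Sequence[float],
                  radius: float = 0.2, temperature: float = 300.0) -> float:
    """Boltzmann-integrated basin free-energy difference F(a) − F(b).

    Each basin free energy is −kT ln Σ exp(−F/kT) over grid points within
    ``radius`` Å of the basin center.  Integrating over the basin instead of
    reading the landscape at a single grid minimum averages out the
    deposition ripple of a metadynamics reconstruction; for basins of equal
    curvature (as in the synthetic landscapes) the difference estimates the
    minima free-energy gap without bias.
    """
    kt = KB_KCAL * temperature
    pts = fel.mesh_points()
    vals = fel.values.ravel()
    out = []
    for c in (center_a, center_b):
        mask = np.linalg.norm(pts - np.asarray(c, dtype=float), axis=1) < radius
        if not mask.any():
            raise FELError(f"no grid points within {radius} Å of basin center {c}")
        out.append(-kt * math.log(np.exp(-vals[mask] / kt).sum()))
    return out[0] - out[1]


@dataclass
class ConvergenceReport:
    checkpoints: list[int]                  # hill counts
    delta_f: list[float | None]             # ΔF(min1, min2) per checkpoint; None if <2 minima
    converged: bool
    tolerance: float


def convergence_check(hills: HillsLog, checkpoints: Sequence[int],
                      tolerance: float = 0.25, k_last: int = 3,
                      depth_threshold: float = 1.0, basin_radius: float = 0.2,
                      temperature: float = 300.0,
                      axes: tuple[Axis, ...] | None = None, n: int = 101) -> ConvergenceReport:
    """Free-energy-difference convergence of a metadynamics run.

    Reconstructs the landscape at increasing hill counts and tracks the
    basin-integrated free-energy difference between the two lowest minima;
    the run is converged when the last ``k_last`` checkpoints vary by less
    than ``tolerance`` kcal/mol.  Checkpoints with fewer than two minima
    count as not yet converged.
    """
    if len(checkpoints) < 2:
        raise FELError("need at least 2 checkpoints")
    if axes is None:
        axes = default_axes(hills, n=n)
    series: list[float | None] = []
    for cp in checkpoints:
        partial = hills[: int(cp)]
        if len(partial) == 0:
            series.append(None)
            continue
        fel = reconstruct_fel(partial, axes=axes)
        minima = find_minima(fel, depth_threshold=depth_threshold)
        if len(minima) < 2:
            series.append(None)
        else:
            series.append(basin_delta_f(fel, minima[1].point, minima[0].point,
                                        radius=basin_radius, temperature=temperature))
    tail = series[-k_last:]
    converged = all(x is not None for x in tail) and \
        (max(tail) - min(tail)) < tolerance  # type: ignore[type-var]
    return ConvergenceReport(checkpoints=list(checkpoints), delta_f=series,
                             converged=converged, tolerance=tolerance)


@dataclass
class HeightSensitivityResult:
    barriers: dict[float, float]     # hill height -> barrier estimate, kcal/mol
    spread: float                    # max - min over heights
    restart_point: np.ndarray
    basin_order_consistent: bool     # same basin is lower across all heights


def barrier_from_run(hills: HillsLog, depth_threshold: float = 1.0,
                     axes: tuple[Axis, ...] | None = None,
                     n: int = 101) -> tuple[float, float]:
    """(barrier from the start-side basin, ΔF between the two lowest minima).

    The start-side basin is taken as the minimum closest to the first hill
    center (metadynamics starts in the reactant basin).
    """
    fel = reconstruct_fel(hills, axes=axes, n=n)
    minima = find_minima(fel, depth_threshold=depth_threshold)
    if len(minima) < 2:
        raise FELError(f"found {len(minima)} minima; need 2 for a barrier")
    first_center = np.array(hills[0].center)
    start = min(minima[:2], key=lambda m: np.linalg.norm(m.point - first_center))
    other = minima[1] if start is minima[0] else minima[0]
    path = trace_mfep(fel, start, other)
    return path.barrier, minima[1].energy - minima[0].energy


def height_sensitivity(potential, heights: Sequence[float], langevin: LangevinParams,
                       metad: MetadParams, start: Sequence[float],
                       reference_barrier: float, fill_fraction: float = 0.55,
                       depth_threshold: float = 1.0,
                       n_grid: int = 101) -> HeightSensitivityResult:
    """Barrier estimates from metadynamics restarted with different hill heights.

    A base run with the default parameters is propagated until the deposited
    bias at the start basin reaches ``fill_fraction`` of the reference
    barrier; each listed Gaussian height is then run as an independent
    simulation from that restart configuration and its barrier is estimated
    from the reconstructed landscape.  The spread across heights measures the
    protocol's robustness.
    """
    if len(heights) < 2:
        raise ValueError("need at least 2 Gaussian heights to compare")
    base_log, base_traj = run_wt_metadynamics(potential, langevin, metad, start)
    target = fill_fraction * reference_barrier
    start_arr = np.asarray(start, dtype=float)
    restart = None
    for k in range(1, len(base_log) + 1):
        if evaluate_bias_grid(base_log[:k], start_arr[None, :])[0] >= target:
            restart = base_traj[k * metad.pace]
            break
    if restart is None:
        restart = base_traj[-1]
    barriers: dict[float, float] = {}
    delta_fs: list[float] = []
    for i, h in enumerate(heights):
        lp = replace(langevin, seed=langevin.seed + 1000 + i)
        mp = replace(metad, height=h)
        log, _ = run_wt_metadynamics(potential, lp, mp, restart)
        b, df = barrier_from_run(log, depth_threshold=depth_threshold, n=n_grid)
        barriers[h] = b
        delta_fs.append(df)
    vals = list(barriers.values())
    return HeightSensitivityResult(
        barriers=barriers,
        spread=max(vals) - min(vals),
        restart_point=np.asarray(restart),
        basin_order_consistent=all(df > 0 for df in delta_fs) or all(df < 0 for df in delta_fs),
    )


def grid_from_potential(potential, n: int = 41, margin: float = 0.3,
                        bounds: tuple[float, float] | None = None) -> FELGrid:
    """Evaluate an analytic potential on a grid, min-normalized.

    The grid spans the bounding box of the potential's wells plus ``margin``
    (Å) on each side, or explicit ``bounds`` shared by all axes.
    """
    if bounds is None:
        lo = min(float(w.center.min()) for w in potential.wells) - margin
        hi = max(float(w.center.max()) for w in potential.wells) + margin
    else:
        lo, hi = bounds
    axes = tuple(Axis(name, lo, hi, n) for name in potential.cv_names)
    grid = FELGrid(axes, np.zeros(tuple(a.n for a in axes)))
    vals = potential.energy(grid.mesh_points()).reshape(grid.values.shape)
    return FELGrid(axes, vals).normalized()


def contour_levels(fel: FELGrid, interval: float = 1.0) -> np.ndarray:
    """Isoline levels at fixed intervals (kcal/mol), mirroring FEL figures."""
    return np.arange(0.0, fel.values.max() + interval, interval)
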