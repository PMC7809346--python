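"""Langevin dynamics on analytic potentials and well-tempered metadynamics.

The dynamics is a desk-scale stand-in for first-principles propagation: the
collective variables themselves are treated as Langevin degrees of freedom
moving on an analytic potential.  The metadynamics bias logic — periodic
deposition of repulsive Gaussians whose heights decay with the accumulated
bias at the deposition point (well-tempered scheme, bias factor γ) — is the
same algorithm used in production enhanced-sampling engines, and is what
this module exists to verify.

Units: energy kcal/mol, length Å, time fs, temperature K.
k_B = 0.0019872 kcal mol^-1 K^-1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from .synthetic import KB_KCAL

KJ_PER_KCAL = 4.184


class HillsError(ValueError):
    """Raised for malformed hills logs."""


@dataclass(frozen=True)
class LangevinParams:
    """Parameters of the BAOAB Langevin integrator.

    ``friction`` in fs^-1, ``timestep`` in fs, ``mass`` in internal units
    (kcal/mol fs² Å^-2) — only ratios kT/m and friction·dt matter for the
    sampled configurational distribution.  The default friction (0.1 fs^-1)
    keeps the velocity relaxation time shorter than typical metadynamics
    deposition intervals; much lighter friction lets consecutive hills
    correlate with the walker's ballistic motion ("hill surfing"), which
    visibly distorts reconstructed free-energy profiles.
    """

    temperature: float = 300.0
    friction: float = 0.1
    timestep: float = 0.12
    mass: float = 50.0
    seed: int = 0

    def __post_init__(self):
        if self.timestep <= 0:
            raise ValueError("timestep must be positive")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")

    @property
    def kt(self) -> float:
        return KB_KCAL * self.temperature


@dataclass(frozen=True)
class MetadParams:
    """Well-tempered metadynamics parameters.

    ``bias_factor`` γ > 1, or ``math.inf`` for standard (non-tempered)
    metadynamics in which every hill keeps the full height.
    """

    height: float = 1.0                  # w, kcal/mol
    widths: tuple[float, ...] = (0.1, 0.1)  # σ per CV, Å
    pace: int = 200                      # MD steps between depositions
    bias_factor: float = 10.0            # γ
    max_hills: int = 2000

    def __post_init__(self):
        if self.height <= 0:
            raise ValueError("hill height must be positive")
        if any(s <= 0 for s in self.widths):
            raise ValueError("hill widths must be positive")
        if not (self.bias_factor > 1.0):
            raise ValueError("bias factor must be > 1 (use math.inf for standard metadynamics)")


@dataclass(frozen=True)
class Hill:
    """One deposited Gaussian."""

    time: float                 # fs
    center: tuple[float, ...]   # Å per CV
    widths: tuple[float, ...]   # Å per CV
    height: float               # kcal/mol (already tempered)
    bias_factor: float


@dataclass
class HillsLog:
    """Time-ordered Gaussian deposits with well-tempered metadata."""

    cv_names: tuple[str, ...]
    energy_unit: str = "kcal/mol"
    hills: list[Hill] = field(default_factory=list)

    def append(self, hill: Hill) -> None:
        if self.hills and hill.time <= self.hills[-1].time:
            raise HillsError(
                f"non-monotonic deposit time {hill.time} after {self.hills[-1].time}"
            )
        if len(hill.center) != len(self.cv_names):
            raise HillsError("hill dimensionality does not match CV names")
        self.hills.append(hill)

    def __len__(self) -> int:
        return len(self.hills)

    def __getitem__(self, i):
        if isinstance(i, slice):
            return HillsLog(self.cv_names, self.energy_unit, self.hills[i])
        return self.hills[i]

    def as_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """(times, centers (n,d), widths (n,d), heights (n,))."""
        n = len(self.hills)
        d = len(self.cv_names)
        t = np.array([h.time for h in self.hills])
        c = np.array([h.center for h in self.hills]).reshape(n, d)
        s = np.array([h.widths for h in self.hills]).reshape(n, d)
        w = np.array([h.height for h in self.hills])
        return t, c, s, w

    @property
    def bias_factor(self) -> float:
        if not self.hills:
            raise HillsError("empty hills log has no bias factor")
        return self.hills[0].bias_factor


def evaluate_bias(hills: HillsLog, point: Sequence[float]) -> float:
    """Total deposited bias at ``point``, exact sum over all Gaussians."""
    if len(hills) == 0:
        return 0.0
    point = np.asarray(point, dtype=float)
    if point.shape != (len(hills.cv_names),):
        raise HillsError(
            f"point has dimension {point.shape}, hills have {len(hills.cv_names)} CVs"
        )
    _, c, s, w = hills.as_arrays()
    return float((w * np.exp(-0.5 * (((point - c) / s) ** 2).sum(axis=1))).sum())


def evaluate_bias_grid(hills: HillsLog, points: np.ndarray, chunk: int = 256) -> np.ndarray:
    """Vectorized bias over many points, shape (m, d) -> (m,)."""
    if len(hills) == 0:
        return np.zeros(len(points))
    _, c, s, w = hills.as_arrays()
    points = np.asarray(points, dtype=float)
    out = np.zeros(len(points))
    for i in range(0, len(c), chunk):
        diff = points[:, None, :] - c[None, i:i + chunk, :]
        out += (w[None, i:i + chunk] * np.exp(-0.5 * ((diff / s[None, i:i + chunk, :]) ** 2).sum(-1))).sum(1)
    return out


# ---------------------------------------------------------------------------
# Integrators
# ---------------------------------------------------------------------------

def _baoab_coefficients(params: LangevinParams) -> tuple[float, float]:
    c1 = math.exp(-params.friction * params.timestep)
    c2 = math.sqrt((1.0 - c1 * c1) * params.kt / params.mass)
    return c1, c2


def run_langevin(potential, params: LangevinParams, start: Sequence[float],
                 n_steps: int,
                 bias_force: Callable[[np.ndarray], np.ndarray] | None = None,
                 stop: Callable[[np.ndarray], bool] | None = None,
                 rng: np.random.Generator | None = None) -> np.ndarray:
    """Propagate BAOAB Langevin dynamics on ``potential``.

    Returns the CV trajectory of shape (n_steps+1, d) (shorter if ``stop``
    fires).  Velocities start Maxwell–Boltzmann distributed.  Deterministic
    for a fixed seed; at zero temperature from a stationary point the system
    stays put.
    """
    rng = rng if rng is not None else np.random.default_rng(params.seed)
    x = np.array(start, dtype=float)
    d = x.shape[0]
    v = rng.normal(0.0, math.sqrt(params.kt / params.mass), size=d) if params.kt > 0 else np.zeros(d)
    dt, m = params.timestep, params.mass
    c1, c2 = _baoab_coefficients(params)
    traj = np.empty((n_steps + 1, d))
    traj[0] = x
    force = -potential.gradient(x)
    if bias_force is not None:
        force = force + bias_force(x)
    for k in range(1, n_steps + 1):
        v += 0.5 * dt * force / m
        x += 0.5 * dt * v
        v = c1 * v + c2 * rng.standard_normal(d)
        x += 0.5 * dt * v
        force = -potential.gradient(x)
        if bias_force is not None:
            force = force + bias_force(x)
        v += 0.5 * dt * force / m
        if not np.isfinite(force).all() or not np.isfinite(x).all():
            raise FloatingPointError(f"non-finite energy/force at step {k}, x={x}")
        traj[k] = x
        if stop is not None and stop(x):
            return traj[: k + 1]
    return traj


def run_wt_metadynamics(potential, langevin: LangevinParams, metad: MetadParams,
                        start: Sequence[float]) -> tuple[HillsLog, np.ndarray]:
    """Well-tempered metadynamics on an analytic potential.

    Every ``pace`` steps a Gaussian of height w·exp(−V_bias(s)/(k_B ΔT)) with
    ΔT = (γ−1)·T is deposited at the current CV position (constant height w
    when γ = ∞).  Stops after ``max_hills`` deposits.  Returns the hills log
    and the full CV trajectory.  Deterministic under the Langevin seed.
    """
    rng = np.random.default_rng(langevin.seed)
    x = np.array(start, dtype=float)
    d = x.shape[0]
    if len(metad.widths) != d:
        raise ValueError(f"metad widths have dim {len(metad.widths)}, start has dim {d}")
    kt = langevin.kt
    v = rng.normal(0.0, math.sqrt(kt / langevin.mass), size=d)
    dt, m = langevin.timestep, langevin.mass
    c1, c2 = _baoab_coefficients(langevin)
    gamma = metad.bias_factor
    kb_dt = KB_KCAL * (gamma - 1.0) * langevin.temperature if math.isfinite(gamma) else math.inf

    n_steps = metad.pace * metad.max_hills
    traj = np.empty((n_steps + 1, d))
    traj[0] = x
    # growing hill arrays for fast bias evaluation
    centers = np.empty((metad.max_hills, d))
    inv_two_sigma2 = 0.5 / np.asarray(metad.widths, dtype=float) ** 2
    sigma2 = np.asarray(metad.widths, dtype=float) ** 2
    heights = np.empty(metad.max_hills)
    n_hills = 0
    log = HillsLog(cv_names=tuple(getattr(potential, "cv_names", tuple(f"cv{i+1}" for i in range(d)))))

    def bias_and_force(pt: np.ndarray) -> tuple[float, np.ndarray]:
        if n_hills == 0:
            return 0.0, np.zeros(d)
        diff = pt - centers[:n_hills]
        g = heights[:n_hills] * np.exp(-(diff * diff * inv_two_sigma2).sum(axis=1))
        return float(g.sum()), (g[:, None] * diff / sigma2).sum(axis=0)

    _, bias_f = bias_and_force(x)
    force = -potential.gradient(x) + bias_f
    for k in range(1, n_steps + 1):
        v += 0.5 * dt * force / m
        x += 0.5 * dt * v
        v = c1 * v + c2 * rng.standard_normal(d)
        x += 0.5 * dt * v
        bias_v, bias_f = bias_and_force(x)
        force = -potential.gradient(x) + bias_f
        v += 0.5 * dt * force / m
        traj[k] = x
        if k % metad.pace == 0:
            h = metad.height if not math.isfinite(gamma) else metad.height * math.exp(-bias_v / kb_dt)
            centers[n_hills] = x
            heights[n_hills] = h
            n_hills += 1
            log.append(Hill(time=k * dt, center=tuple(x), widths=tuple(metad.widths),
                            height=h, bias_factor=gamma))
            bias_v, bias_f = bias_and_force(x)
            force = -potential.gradient(x) + bias_f
            if n_hills >= metad.max_hills:
                return log, traj[: k + 1]
    return log, traj


# ---------------------------------------------------------------------------
# Hills / COLVAR text I/O (PLUMED-style dialect)
# ---------------------------------------------------------------------------

def write_hills(hills: HillsLog, path: str | Path) -> Path:
    """Write a hills log: header naming CVs and units, then one row per hill
    with columns time, centers..., sigmas..., height, biasf."""
    path = Path(path)
    names = hills.cv_names
    cols = ["time", *names, *[f"sigma_{n}" for n in names], "height", "biasf"]
    lines = [
        "#! FIELDS " + " ".join(cols),
        f"#! SET units_energy {hills.energy_unit}",
        "#! SET units_length A",
    ]
    for h in hills.hills:
        biasf = "inf" if math.isinf(h.bias_factor) else f"{h.bias_factor:.6f}"
        lines.append(
            f"{h.time:.4f} "
            + " ".join(f"{c:.8f}" for c in h.center) + " "
            + " ".join(f"{s:.8f}" for s in h.widths) + " "
            + f"{h.height:.8f} {biasf}"
        )
    path.write_text("\n".join(lines) + "\n")
    return path


def read_hills(path: str | Path) -> HillsLog:
    """Read a hills log written in the dialect of :func:`write_hills`.

    Heights declared in kJ/mol are converted to kcal/mol on read.  Malformed
    lines and non-monotonic deposit times raise :class:`HillsError` with the
    offending line number.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    cv_names: list[str] = []
    unit: str | None = None
    log: HillsLog | None = None
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#!"):
            parts = line.split()
            if parts[1] == "FIELDS":
                fields = parts[2:]
                n = (len(fields) - 3) // 2
                cv_names = fields[1:1 + n]
            elif parts[1] == "SET" and parts[2] == "units_energy":
                unit = parts[3]
            continue
        if not cv_names:
            raise HillsError(f"{path}:{lineno}: data before FIELDS header")
        if unit is None:
            raise HillsError(f"{path}:{lineno}: energy units not declared")
        if unit not in ("kcal/mol", "kJ/mol"):
            raise HillsError(f"{path}: unsupported energy unit {unit!r}")
        if log is None:
            log = HillsLog(cv_names=tuple(cv_names))
        vals = line.split()
        d = len(cv_names)
        if len(vals) != 2 * d + 3:
            raise HillsError(f"{path}:{lineno}: expected {2*d+3} columns, got {len(vals)}")
        try:
            t = float(vals[0])
            center = tuple(float(v) for v in vals[1:1 + d])
            widths = tuple(float(v) for v in vals[1 + d:1 + 2 * d])
            height = float(vals[1 + 2 * d])
            biasf = math.inf if vals[2 + 2 * d] == "inf" else float(vals[2 + 2 * d])
        except ValueError as exc:
            raise HillsError(f"{path}:{lineno}: {exc}") from None
        if unit == "kJ/mol":
            height /= KJ_PER_KCAL
        try:
            log.append(Hill(time=t, center=center, widths=widths, height=height, bias_factor=biasf))
        except HillsError as exc:
            raise HillsError(f"{path}:{lineno}: {exc}") from None
    if log is None:
        raise HillsError(f"{path}: no hills found")
    return log


def write_colvar(traj: np.ndarray, cv_names: Sequence[str], timestep: float,
                 path: str | Path, stride: int = 1, seed: int | None = None) -> Path:
    """Write a CV trajectory as COLVAR-style text (time + one column per CV)."""
    path = Path(path)
    lines = ["#! FIELDS time " + " ".join(cv_names)]
    if seed is not None:
        lines.append(f"#! SET seed {seed}")
    for k in range(0, len(traj), stride):
        lines.append(f"{k * timestep:.4f} " + " ".join(f"{v:.6f}" for v in np.atleast_1d(traj[k])))
    path.write_text("\n".join(lines) + "\n")
    return path
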