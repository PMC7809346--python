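"""Synthetic-data generators: analytic energy landscapes, ring trajectories
and kinetics datasets with known ground truth.

The landscapes stand in for the electronic-structure energy surface of the
real enzyme system at desk scale: sums of negative isotropic Gaussians
(basins) confined by quartic walls, whose minima, first-order saddle and
barrier are known analytically/numerically at construction and returned
alongside the potential.  Every downstream estimate (metadynamics FEL,
minimum-free-energy path, committor, kinetics fit) can therefore be compared
against stored truth rather than re-derived numbers.

Defaults encode the study conditions of a GH43 exo-oligoxylanase:

* a two-basin conformational landscape over the Cremer–Pople (qx, qy) disk,
  with a 4C1 chair basin at the disk center and a distorted 2SO/2,5B basin
  on the equator at radius 0.55 Å, the distorted basin 1 kcal/mol below the
  chair;
* a three-CV reaction landscape with a reactant (Michaelis-complex) basin,
  a product basin and a single transition state, whose reactant-side barrier
  defaults to 14.1 kcal/mol scaled by a desk factor so unbiased trajectories
  commit within short runs;
* idealized six-membered-ring trajectories that dwell in named conformers;
* Michaelis–Menten initial-velocity datasets read out as internal-standard
  intensity ratios.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field


import numpy as np
import pandas as pd
from scipy import optimize

from .pucker import CANONICAL_CONFORMERS, RingCoordinates, build_canonical

KB_KCAL = 0.0019872  # Boltzmann constant, kcal mol^-1 K^-1


# ---------------------------------------------------------------------------
# Analytic potentials
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GaussianWell:
    """Isotropic negative-Gaussian basin: -depth * exp(-|x-c|^2 / 2 sigma^2)."""

    center: np.ndarray
    depth: float       # kcal/mol, > 0
    width: float       # Å, > 0

    def __post_init__(self):
        object.__setattr__(self, "center", np.asarray(self.center, dtype=float))
        if self.depth <= 0 or self.width <= 0:
            raise ValueError("well depth and width must be positive")


@dataclass(frozen=True)
class QuarticWall:
    """Confinement k * (excess)^4 outside a sphere (radial) or box (per axis)."""

    kind: str            # "radial" | "box"
    bound: float         # disk/sphere radius, or half-width of the box, Å
    k: float = 400.0     # kcal/mol/Å^4

    def energy(self, x: np.ndarray) -> np.ndarray:
        if self.kind == "radial":
            r = np.linalg.norm(x, axis=-1)
            excess = np.maximum(0.0, r - self.bound)
            return self.k * excess**4
        excess = np.maximum(0.0, np.abs(x) - self.bound)
        return self.k * (excess**4).sum(axis=-1)

    def gradient(self, x: np.ndarray) -> np.ndarray:
        if self.kind == "radial":
            r = np.linalg.norm(x, axis=-1, keepdims=True)
            excess = np.maximum(0.0, r - self.bound)
            safe_r = np.where(r > 0, r, 1.0)
            return 4.0 * self.k * excess**3 * x / safe_r
        excess = np.maximum(0.0, np.abs(x) - self.bound)
        return 4.0 * self.k * excess**3 * np.sign(x)


@dataclass(frozen=True)
class GroundTruth:
    """Analytic reference features of a two-basin landscape."""

    minima: tuple[np.ndarray, ...]          # positions, deepest last-listed basin order
    minima_energies: tuple[float, ...]
    saddle: np.ndarray | None
    saddle_energy: float | None
    barrier: float | None                   # saddle - E(start basin), kcal/mol
    delta_f: float                          # E(first minimum) - E(second minimum)


@dataclass
class PotentialSpec:
    """Analytic potential over 1–3 collective variables (Å, kcal/mol)."""

    cv_names: tuple[str, ...]
    wells: list[GaussianWell]
    wall: QuarticWall
    truth: GroundTruth | None = None
    labels: dict = field(default_factory=dict)   # basin/TS display names etc.

    @property
    def ndim(self) -> int:
        return len(self.cv_names)

    def energy(self, x) -> np.ndarray:
        """Potential energy at point(s) x, shape (..., ndim) -> (...)."""
        x = np.asarray(x, dtype=float)
        e = self.wall.energy(x)
        for w in self.wells:
            d2 = ((x - w.center) ** 2).sum(axis=-1)
            e = e - w.depth * np.exp(-0.5 * d2 / w.width**2)
        return e

    def gradient(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        g = self.wall.gradient(x)
        for w in self.wells:
            d = x - w.center
            d2 = (d**2).sum(axis=-1, keepdims=True)
            g = g + (w.depth / w.width**2) * np.exp(-0.5 * d2 / w.width**2) * d
        return g

    def to_json(self) -> str:
        payload = {
            "cv_names": list(self.cv_names),
            "wells": [
                {"center": w.center.tolist(), "depth": w.depth, "width": w.width}
                for w in self.wells
            ],
            "wall": {"kind": self.wall.kind, "bound": self.wall.bound, "k": self.wall.k},
            "labels": self.labels,
        }
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "PotentialSpec":
        d = json.loads(text)
        spec = cls(
            cv_names=tuple(d["cv_names"]),
            wells=[GaussianWell(np.array(w["center"]), w["depth"], w["width"]) for w in d["wells"]],
            wall=QuarticWall(d["wall"]["kind"], d["wall"]["bound"], d["wall"]["k"]),
            labels=d.get("labels", {}),
        )
        if len(spec.wells) == 2:
            spec.truth = solve_two_well_truth(spec)
        return spec


def _line_critical_points(spec: PotentialSpec) -> tuple[list[float], list[float]]:
    """Critical points of the energy along the segment joining the two wells.

    Returns (t values, energies) of [min_A, saddle, min_B] where t parametrizes
    the line through the well centers.  Valid for two isotropic wells (by
    symmetry the full-space saddle lies on this line, and the perpendicular
    Hessian is positive there).
    """
    a, b = spec.wells[0].center, spec.wells[1].center
    u = b - a
    L = float(np.linalg.norm(u))
    u = u / L

    def e(t: float) -> float:
        return float(spec.energy(a + t * u))

    def de(t: float) -> float:
        return float(spec.gradient(a + t * u) @ u)

    # bracket the three critical points: minimum near 0, saddle interior, minimum near L
    ts = np.linspace(-0.5 * L, 1.5 * L, 2001)
    des = np.array([de(t) for t in ts])
    roots = []
    for i in range(len(ts) - 1):
        if des[i] == 0.0:
            roots.append(ts[i])
        elif des[i] * des[i + 1] < 0:
            roots.append(optimize.brentq(de, ts[i], ts[i + 1], xtol=1e-12))
    roots = sorted(roots)
    if len(roots) != 3:
        raise RuntimeError(f"expected 3 critical points along well axis, found {len(roots)}")
    return roots, [e(t) for t in roots]


def solve_two_well_truth(spec: PotentialSpec) -> GroundTruth:
    """Exact minima/saddle/barrier of a two-well landscape (collinear saddle)."""
    a = spec.wells[0].center
    u = spec.wells[1].center - a
    u = u / np.linalg.norm(u)
    ts, es = _line_critical_points(spec)
    pts = [a + t * u for t in ts]
    return GroundTruth(
        minima=(pts[0], pts[2]),
        minima_energies=(es[0], es[2]),
        saddle=pts[1],
        saddle_energy=es[1],
        barrier=es[1] - min(es[0], es[2]),
        delta_f=es[0] - es[2],
    )


def _calibrate_two_well(spec_builder, delta_f: float, barrier: float,
                        x0: tuple[float, float]) -> PotentialSpec:
    """Solve for the two well depths achieving (delta_f, barrier) exactly.

    ``delta_f`` is E(first minimum) − E(second minimum); ``barrier`` is
    measured from the deeper (global) minimum to the saddle.
    """

    def residual(depths):
        spec = spec_builder(max(depths[0], 1e-3), max(depths[1], 1e-3))
        t = solve_two_well_truth(spec)
        return [t.delta_f - delta_f, (t.saddle_energy - min(t.minima_energies)) - barrier]

    sol = optimize.fsolve(residual, x0=list(x0), full_output=True, xtol=1e-12)
    depths, info, ier, msg = sol
    if ier != 1:
        raise RuntimeError(f"landscape depth calibration failed: {msg}")
    spec = spec_builder(depths[0], depths[1])
    spec.truth = solve_two_well_truth(spec)
    return spec


# ---------------------------------------------------------------------------
# Landscape generators
# ---------------------------------------------------------------------------

def distorted_basin_phi() -> float:
    """Longitude (deg) midway between the 2SO and 2,5B reference meridians."""
    p1 = CANONICAL_CONFORMERS["2SO"].phi_ref
    p2 = CANONICAL_CONFORMERS["2,5B"].phi_ref
    if abs(p1 - p2) > 180:
        return ((p1 + p2 + 360.0) / 2.0) % 360.0
    return (p1 + p2) / 2.0


def make_conformational_landscape(
    delta_f: float = 1.0,
    barrier: float = 4.0,
    pucker_radius: float = 0.55,
    width: float = 0.12,
    wall_radius: float = 0.85,
    single_well: bool = False,
) -> PotentialSpec:
    """Two-basin conformational landscape on the (qx, qy) pucker disk.

    One basin sits at the disk center (the 4C1 chair projects to the origin)
    and one at the 2SO/2,5B midpoint longitude at ``pucker_radius`` Å.  Well
    depths are calibrated so the distorted basin lies exactly ``delta_f``
    kcal/mol below the chair basin and the saddle sits ``barrier`` kcal/mol
    above the distorted (global) minimum.  Ground truth is attached.
    """
    phi = math.radians(distorted_basin_phi())
    chair_center = np.zeros(2)
    distorted_center = pucker_radius * np.array([math.cos(phi), math.sin(phi)])
    if np.linalg.norm(distorted_center - chair_center) < width:
        warnings.warn("conformational wells overlap within one width", stacklevel=2)
    wall = QuarticWall("radial", wall_radius)

    if single_well:
        spec = PotentialSpec(
            cv_names=("qx", "qy"),
            wells=[GaussianWell(distorted_center, 4.0, width)],
            wall=wall,
            labels={"basins": ["2SO/2,5B"]},
        )
        x = optimize.minimize(lambda p: float(spec.energy(p)), distorted_center,
                              jac=lambda p: spec.gradient(p)).x
        spec.truth = GroundTruth(minima=(x,), minima_energies=(float(spec.energy(x)),),
                                 saddle=None, saddle_energy=None, barrier=None, delta_f=0.0)
        return spec

    def builder(d_chair: float, d_dist: float) -> PotentialSpec:
        return PotentialSpec(
            cv_names=("qx", "qy"),
            wells=[
                GaussianWell(chair_center, d_chair, width),
                GaussianWell(distorted_center, d_dist, width),
            ],
            wall=wall,
            labels={"basins": ["4C1", "2SO/2,5B"], "pucker_radius": pucker_radius},
        )

    return _calibrate_two_well(builder, delta_f=delta_f, barrier=barrier,
                               x0=(barrier - delta_f, barrier))


def make_reaction_landscape(
    barrier: float = 14.1,
    reaction_free_energy: float = -3.0,
    desk_factor: float = 0.35,
    width: float = 0.55,
    box_halfwidth: float = 1.6,
) -> PotentialSpec:
    """Three-CV reaction landscape: reactant and product basins, one saddle.

    The collective variables are difference-of-distance coordinates for the
    three bond changes of an inverting glycosidase (base–water proton
    transfer, nucleophilic attack/glycosidic cleavage, acid proton transfer);
    reactants sit at negative CV values, products at positive ones.  Both the
    reactant-side barrier and the reaction free energy are scaled by
    ``desk_factor`` so that barrier crossing and unbiased committor shooting
    are affordable without enhanced hardware; set ``desk_factor=1`` for the
    full-scale landscape.
    """
    f = desk_factor
    r_center = np.array([-0.75, -0.75, -0.75])
    p_center = np.array([0.75, 0.75, 0.75])
    wall = QuarticWall("box", box_halfwidth)

    def builder(d_r: float, d_p: float) -> PotentialSpec:
        return PotentialSpec(
            cv_names=("CV1", "CV2", "CV3"),
            wells=[GaussianWell(r_center, d_r, width), GaussianWell(p_center, d_p, width)],
            wall=wall,
            labels={"basins": ["R", "P"], "ts": "TS", "desk_factor": f},
        )

    # delta_f convention: E(R) - E(P) = -reaction_free_energy
    spec = _calibrate_two_well(
        builder,
        delta_f=-reaction_free_energy * f,
        barrier=(barrier - reaction_free_energy) * f,
        x0=(barrier * f * 0.9, (barrier - reaction_free_energy) * f * 0.9),
    )
    # by construction: saddle - E(R) = barrier * f, saddle - E(P) = (barrier - dG) * f
    return spec


def make_double_well_1d(delta_f: float = 0.5, barrier: float = 3.0,
                        separation: float = 1.0, width: float = 0.15,
                        wall_bound: float = 1.2) -> PotentialSpec:
    """One-dimensional double well with exact calibrated ground truth.

    ``delta_f`` = E(left minimum) − E(right minimum); ``barrier`` is measured
    from the deeper minimum to the interior maximum.  Useful as the smallest
    landscape on which barrier-recovery protocols can be exercised.
    """
    a, b = np.array([-separation / 2.0]), np.array([separation / 2.0])
    wall = QuarticWall("box", wall_bound)

    def builder(d1: float, d2: float) -> PotentialSpec:
        return PotentialSpec(
            cv_names=("s",),
            wells=[GaussianWell(a, d1, width), GaussianWell(b, d2, width)],
            wall=wall,
            labels={"basins": ["L", "R"]},
        )

    return _calibrate_two_well(builder, delta_f=delta_f, barrier=barrier,
                               x0=(barrier - delta_f, barrier))


# ---------------------------------------------------------------------------
# Ring trajectories
# ---------------------------------------------------------------------------

@dataclass
class RingTrajectory:
    """Frames plus the generator's ground truth."""

    frames: list[RingCoordinates]
    dwell_plan: dict[str, float]
    noise_sd: float
    n_rejected: int
    seed: int


def make_ring_trajectory(dwell_plan: dict[str, float], n_frames: int = 1000,
                         Q: float = 0.55, noise_sd: float = 0.02,
                         seed: int = 0) -> RingTrajectory:
    """Trajectory of idealized rings dwelling in named canonical conformers.

    Frames are drawn as contiguous dwell blocks whose lengths follow the
    plan's fractions, with isotropic Gaussian noise (``noise_sd`` Å) on every
    coordinate.  Frames whose noise breaks the ring-bond invariants are
    rejected (and counted) rather than emitted.  Deterministic under ``seed``.
    """
    total = sum(dwell_plan.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"dwell fractions must sum to 1, got {total}")
    for name in dwell_plan:
        if name not in CANONICAL_CONFORMERS:
            raise ValueError(f"unknown conformer {name!r} in dwell plan")
    rng = np.random.default_rng(seed)
    names = list(dwell_plan)
    counts = [int(round(frac * n_frames)) for frac in dwell_plan.values()]
    counts[-1] = n_frames - sum(counts[:-1])
    frames: list[RingCoordinates] = []
    n_rejected = 0
    for name, count in zip(names, counts):
        base = build_canonical(name, Q=Q).coords
        for _ in range(count):
            for _attempt in range(20):
                ring = RingCoordinates(base + rng.normal(0.0, noise_sd, size=(6, 3)))
                try:
                    ring.validate()
                except Exception:
                    n_rejected += 1
                    continue
                frames.append(ring)
                break
            else:
                raise RuntimeError(f"noise_sd={noise_sd} keeps breaking ring invariants")
    return RingTrajectory(frames=frames, dwell_plan=dict(dwell_plan), noise_sd=noise_sd,
                          n_rejected=n_rejected, seed=seed)


# ---------------------------------------------------------------------------
# Kinetics datasets
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KineticsDatasetSpec:
    """Ground truth and design of a synthetic initial-velocity experiment.

    ``kcat`` in s^-1, ``km`` in mM; substrate concentrations in mM.  Product
    readout is a mass-spectrometric intensity ratio (product over internal
    standard) proportional to product concentration with relative Gaussian
    noise.  ``t_reaction`` (s) converts initial velocity to accumulated
    product, assuming the linear initial-rate regime.
    """

    kcat: float = 10.0
    km: float = 2.0
    concentrations: tuple[float, ...] = (0.25, 0.5, 1.0, 2.0, 4.0, 8.0, 16.0, 32.0)
    replicates: int = 3
    noise_sd: float = 0.01          # relative SD of the intensity ratio
    standard_slope: float = 2.0     # intensity ratio per mM of product
    enzyme_conc: float = 1.0        # arbitrary units; v0/[E] has units of kcat
    t_reaction: float = 1.0         # s

    def __post_init__(self):
        if any(c <= 0 for c in self.concentrations):
            raise ValueError("substrate concentrations must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise SD must be non-negative")


def make_kinetics_dataset(spec: KineticsDatasetSpec = KineticsDatasetSpec(),
                          seed: int = 0) -> pd.DataFrame:
    """Synthetic Michaelis–Menten dataset as (concentration, ratio, replicate).

    Initial velocities follow v0 = kcat·[E]·[S]/(Km + [S]); the observed
    intensity ratio is slope × product concentration × (1 + noise).  The true
    parameters travel with the frame in ``df.attrs['truth']``.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for s in spec.concentrations:
        v0 = spec.kcat * spec.enzyme_conc * s / (spec.km + s)
        product = v0 * spec.t_reaction
        for rep in range(spec.replicates):
            ratio = spec.standard_slope * product * (1.0 + rng.normal(0.0, spec.noise_sd))
            rows.append({"concentration_mM": s, "intensity_ratio": ratio, "replicate": rep})
    df = pd.DataFrame(rows)
    df.attrs["truth"] = {
        "kcat": spec.kcat, "km": spec.km, "standard_slope": spec.standard_slope,
        "enzyme_conc": spec.enzyme_conc, "t_reaction": spec.t_reaction, "seed": seed,
    }
    return df
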