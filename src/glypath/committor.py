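"""Isocommittor refinement of transition states by unbiased shooting.

The committor of a configuration is the probability that an unbiased
trajectory started from it (with Maxwell–Boltzmann velocities) reaches the
product basin before the reactant basin; the transition-state ensemble is
the 0.5 isocommittor surface.  Following the protocol used for glycosidase
reaction landscapes, candidate configurations are drawn from the region
around the highest-energy point of the minimum-free-energy path, each is
shot with a small number of independent unbiased trajectories (20 by
default), and the accepted transition state is the candidate whose
reactants/products split is closest to 50% within a binomial acceptance
window.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .fel import PathResult
from .sampling import LangevinParams, run_langevin

logger = logging.getLogger(__name__)

#: default number of candidate configurations tested around the saddle
DEFAULT_N_CANDIDATES = 23
#: default number of unbiased shooting trajectories per candidate
DEFAULT_N_TRAJ = 20
#: committor acceptance window, ~±1.5 binomial SD around 0.5 at n = 20
DEFAULT_WINDOW = (0.35, 0.65)
#: maximum tolerated fraction of uncommitted (max-step) trajectories
MAX_UNCOMMITTED_FRACTION = 0.10


class CommittorError(RuntimeError):
    """Raised when the refinement protocol cannot produce a valid result."""


@dataclass(frozen=True)
class BasinSpec:
    """Ellipsoidal commitment region around a free-energy minimum."""

    center: np.ndarray
    radius: np.ndarray | float      # Å, scalar or per-CV
    label: str                      # "reactants" | "products"

    def __post_init__(self):
        center = np.asarray(self.center, dtype=float)
        radius = np.broadcast_to(np.asarray(self.radius, dtype=float), center.shape).copy()
        if np.any(radius <= 0):
            raise ValueError("basin radii must be positive")
        object.__setattr__(self, "center", center)
        object.__setattr__(self, "radius", radius)

    def contains(self, x: np.ndarray) -> bool:
        return float((((x - self.center) / self.radius) ** 2).sum()) <= 1.0


def basins_from_landscape(spec, labels: tuple[str, str] = ("reactants", "products"),
                          radius_scale: float = 1.0) -> tuple[BasinSpec, BasinSpec]:
    """Commitment basins centered on a two-well landscape's minima.

    Radii default to the generator wells' widths (scaled), the natural size
    of the basin cores.  Raises if the basins would overlap.
    """
    truth = spec.truth
    if truth is None or len(truth.minima) != 2:
        raise ValueError("landscape must carry two-minimum ground truth")
    b1 = BasinSpec(truth.minima[0], radius_scale * spec.wells[0].width, labels[0])
    b2 = BasinSpec(truth.minima[1], radius_scale * spec.wells[1].width, labels[1])
    gap = np.linalg.norm(b1.center - b2.center)
    if gap <= float(np.max(b1.radius) + np.max(b2.radius)):
        raise ValueError("commitment basins overlap; shrink radius_scale")
    return b1, b2


def commit_trajectory(potential, start: Sequence[float], basins: Sequence[BasinSpec],
                      params: LangevinParams, max_steps: int = 200_000,
                      rng: np.random.Generator | None = None) -> str:
    """Label of the first basin entered by one unbiased trajectory.

    Velocities are drawn Maxwell–Boltzmann at the Langevin temperature.
    Returns the basin label, or ``"uncommitted"`` when ``max_steps`` elapse
    without commitment.  Deterministic for a fixed seed/generator.
    """
    start = np.asarray(start, dtype=float)
    for b in basins:
        if b.contains(start):
            return b.label

    hit: list[str] = []

    def stop(x: np.ndarray) -> bool:
        for b in basins:
            if b.contains(x):
                hit.append(b.label)
                return True
        return False

    run_langevin(potential, params, start, max_steps, stop=stop, rng=rng)
    return hit[0] if hit else "uncommitted"


@dataclass(frozen=True)
class CommittorResult:
    """Commitment statistics of one candidate configuration."""

    candidate: np.ndarray
    n_trajectories: int
    n_reactants: int
    n_products: int
    n_uncommitted: int
    accepted: bool = False

    @property
    def committor(self) -> float:
        committed = self.n_reactants + self.n_products
        if committed == 0:
            return float("nan")
        return self.n_products / committed

    @property
    def valid(self) -> bool:
        return self.n_uncommitted <= MAX_UNCOMMITTED_FRACTION * self.n_trajectories


def committor_estimate(potential, point: Sequence[float], basins: Sequence[BasinSpec],
                       params: LangevinParams, n_traj: int = DEFAULT_N_TRAJ,
                       seed: int = 0, max_steps: int = 200_000) -> CommittorResult:
    """Shoot ``n_traj`` unbiased trajectories from one configuration."""
    ss = np.random.SeedSequence(entropy=seed)
    counts = {"reactants": 0, "products": 0, "uncommitted": 0}
    for child in ss.spawn(n_traj):
        rng = np.random.default_rng(child)
        label = commit_trajectory(potential, point, basins, params,
                                  max_steps=max_steps, rng=rng)
        counts[label] += 1
    return CommittorResult(
        candidate=np.asarray(point, dtype=float),
        n_trajectories=n_traj,
        n_reactants=counts["reactants"],
        n_products=counts["products"],
        n_uncommitted=counts["uncommitted"],
    )


def refine_ts(potential, path: PathResult, basins: Sequence[BasinSpec],
              params: LangevinParams, n_candidates: int = DEFAULT_N_CANDIDATES,
              n_traj: int = DEFAULT_N_TRAJ,
              window: tuple[float, float] = DEFAULT_WINDOW,
              region_radius: float = 0.15, seed: int = 0,
              max_steps: int = 200_000) -> tuple[list[CommittorResult], CommittorResult]:
    """Isocommittor refinement of the transition state.

    Candidates are sampled uniformly in a ball of ``region_radius`` Å around
    the highest-energy point of the minimum-free-energy path (the first
    candidate is the saddle point itself); each is shot ``n_traj`` times.
    The accepted transition state is the candidate with committor nearest
    0.5 that (a) falls inside the acceptance ``window`` and (b) has fewer
    than 10% uncommitted trajectories.  Raises :class:`CommittorError` when
    no candidate qualifies.
    """
    if n_traj < 2:
        raise ValueError("need at least 2 trajectories per candidate")
    lo, hi = window
    saddle = np.asarray(path.saddle_point, dtype=float)
    rng = np.random.default_rng(seed)
    candidates = [saddle]
    d = saddle.shape[0]
    while len(candidates) < n_candidates:
        offset = rng.uniform(-region_radius, region_radius, size=d)
        if np.linalg.norm(offset) <= region_radius:
            candidates.append(saddle + offset)
    results = []
    for i, cand in enumerate(candidates):
        res = committor_estimate(potential, cand, basins, params, n_traj=n_traj,
                                 seed=seed * 100_003 + i, max_steps=max_steps)
        if not res.valid:
            logger.warning("candidate %d flagged invalid: %d/%d uncommitted",
                           i, res.n_uncommitted, res.n_trajectories)
        results.append(res)
    qualified = [r for r in results if r.valid and lo <= r.committor <= hi]
    if not qualified:
        raise CommittorError(
            "no candidate committor inside the acceptance window "
            f"[{lo}, {hi}]; enlarge the saddle region or test more candidates"
        )
    best = min(qualified, key=lambda r: abs(r.committor - 0.5))
    results = [
        CommittorResult(r.candidate, r.n_trajectories, r.n_reactants, r.n_products,
                        r.n_uncommitted, accepted=(r is best))
        for r in results
    ]
    accepted = next(r for r in results if r.accepted)
    return results, accepted


def results_tsv(results: Sequence[CommittorResult], cv_names: Sequence[str]) -> str:
    """TSV table of candidate coordinates and commitment counts."""
    header = "\t".join([*cv_names, "n_traj", "n_reactants", "n_products",
                        "n_uncommitted", "committor", "accepted"])
    lines = [header]
    for r in results:
        coords = "\t".join(f"{c:.5f}" for c in r.candidate)
        lines.append(f"{coords}\t{r.n_trajectories}\t{r.n_reactants}\t{r.n_products}"
                     f"\t{r.n_uncommitted}\t{r.committor:.3f}\t{int(r.accepted)}")
    return "\n".join(lines) + "\n"
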