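"""Cremer–Pople puckering analysis of six-membered (pyranose) rings.

A six-membered ring has 3 out-of-plane degrees of freedom, parameterized by a
total puckering amplitude Q (Å), a polar angle theta (0–180°) and an azimuthal
phase phi (0–360°).  The north pole (theta = 0) is the 4C1 chair of a
beta-D-pyranose when the ring is traversed O5, C1, C2, C3, C4, C5 with O5 as
atom 1; the south pole is the inverted 1C4 chair; the equator carries the six
boats and six skew-boats; envelopes and half-chairs live at tropical
latitudes.  The Cartesian projections (qx, qy, qz) of the same sphere are the
collective variables used to bias conformational sampling of sugars.

The canonical conformer table (38 entries: 2 chairs, 6 boats, 6 skew-boats,
12 envelopes, 12 half-chairs) is generated at import time from ideal
out-of-plane displacement patterns rather than hand-typed reference angles,
so the phase convention of the classifier is identical, by construction, to
the phase convention of the forward transform.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

#: Ring traversal order; O5 is atom j = 1 of the Cremer–Pople sums.
RING_ATOM_ORDER: tuple[str, ...] = ("O5", "C1", "C2", "C3", "C4", "C5")

#: Below this total amplitude (Å) the ring is reported planar and the
#: angular coordinates are undefined (arccos is numerically unstable).
PLANARITY_THRESHOLD = 0.05

#: A secondary conformer is reported when the second-nearest canonical
#: reference lies closer than this multiple of the nearest distance.
DUAL_THRESHOLD = 1.5

_J = np.arange(6)
_BETA = 2.0 * np.pi * _J / 6.0  # ring phase angles 2*pi*(j-1)/6


class RingError(ValueError):
    """Raised for rings that violate the six-membered-ring contract."""


@dataclass(frozen=True)
class RingCoordinates:
    """Ordered heavy-atom coordinates of one six-membered ring (Å).

    Atoms must follow :data:`RING_ATOM_ORDER` (O5, C1, ..., C5).
    """

    coords: np.ndarray
    labels: tuple[str, ...] = RING_ATOM_ORDER

    def __post_init__(self):
        coords = np.asarray(self.coords, dtype=float)
        if coords.shape != (6, 3):
            raise RingError(f"expected 6 atoms with xyz coordinates, got shape {coords.shape}")
        if len(self.labels) != 6:
            raise RingError(f"expected 6 atom labels, got {len(self.labels)}")
        object.__setattr__(self, "coords", coords)
        object.__setattr__(self, "labels", tuple(self.labels))

    def validate(self, bond_range: tuple[float, float] = (1.0, 2.2)) -> None:
        """Check that consecutive ring atoms are at bonding distance.

        Raises :class:`RingError` if any of the six cycle bonds falls outside
        ``bond_range`` (Å) or if the ring is degenerate.
        """
        d = np.linalg.norm(self.coords - np.roll(self.coords, -1, axis=0), axis=1)
        lo, hi = bond_range
        if np.any(d <= lo) or np.any(d >= hi):
            bad = [
                f"{self.labels[i]}-{self.labels[(i + 1) % 6]}={d[i]:.2f}"
                for i in range(6)
                if not (lo < d[i] < hi)
            ]
            raise RingError("ring bond lengths outside (%.1f, %.1f) Å: %s" % (lo, hi, ", ".join(bad)))


@dataclass(frozen=True)
class PuckerState:
    """Spherical + Cartesian Cremer–Pople coordinates of one ring."""

    Q: float          # total puckering amplitude, Å
    theta: float      # polar angle, degrees in [0, 180]; NaN if planar
    phi: float        # azimuthal angle, degrees in [0, 360); NaN if planar
    qx: float         # Q sin(theta) cos(phi), Å
    qy: float         # Q sin(theta) sin(phi), Å
    qz: float         # Q cos(theta), Å
    planar: bool = False


@dataclass(frozen=True)
class CanonicalConformer:
    """One of the 38 canonical IUPAC ring shapes with its reference angles."""

    name: str
    theta_ref: float
    phi_ref: float
    family: str  # chair | boat | skew-boat | envelope | half-chair


@dataclass(frozen=True)
class ConformerAssignment:
    """Nearest canonical conformer(s) for a pucker state."""

    primary: str
    secondary: str            # empty string when unambiguous
    distance_deg: float       # geodesic distance to primary, degrees
    label: str                # "2SO" or dual "2SO/2,5B"


# ---------------------------------------------------------------------------
# Forward transform
# ---------------------------------------------------------------------------

def _ring_plane_displacements(coords: np.ndarray) -> np.ndarray:
    """Out-of-plane displacements z_j from the Cremer–Pople mean plane.

    The plane passes through the geometric center with unit normal
    n = R' x R'' (R' and R'' are the sin/cos-weighted position sums), oriented
    so that the 4C1 chair of a beta-D-pyranose comes out at theta = 0.
    """
    centered = coords - coords.mean(axis=0)
    r_prime = (centered * np.sin(_BETA)[:, None]).sum(axis=0)
    r_dprime = (centered * np.cos(_BETA)[:, None]).sum(axis=0)
    normal = np.cross(r_prime, r_dprime)
    norm = np.linalg.norm(normal)
    if norm < 1e-12:
        raise RingError("degenerate ring: atoms are collinear, mean plane undefined")
    return centered @ (normal / norm)


def cremer_pople(ring: RingCoordinates) -> PuckerState:
    """Forward Cremer–Pople transform of a six-membered ring.

    Returns the puckering amplitude Q, the spherical angles (theta, phi, in
    degrees) and the Cartesian projections (qx, qy, qz).  Rings with
    Q < :data:`PLANARITY_THRESHOLD` are flagged planar; theta and phi are then
    NaN.  The sum of mean-plane displacements and both plane conditions vanish
    by construction (to 1e-9, testable).
    """
    z = _ring_plane_displacements(ring.coords)
    # m = 2 cosine/sine sums and the alternating m = 3 sum
    q2c = math.sqrt(1.0 / 3.0) * float((z * np.cos(2.0 * _BETA)).sum())
    q2s = -math.sqrt(1.0 / 3.0) * float((z * np.sin(2.0 * _BETA)).sum())
    q3 = math.sqrt(1.0 / 6.0) * float((z * (-1.0) ** _J).sum())
    # With n = R' x R'' and O5 as atom 1, the 4C1 chair of a beta-D-pyranose
    # yields q3 > 0, i.e. theta ~ 0 (checked against relaxed 3-D sugar
    # geometries); no extra orientation flip is needed.
    qx, qy = q2c, q2s
    Q = math.sqrt(q2c * q2c + q2s * q2s + q3 * q3)
    if Q < PLANARITY_THRESHOLD:
        return PuckerState(Q=Q, theta=math.nan, phi=math.nan, qx=qx, qy=qy, qz=q3, planar=True)
    theta = math.degrees(math.acos(max(-1.0, min(1.0, q3 / Q))))
    phi = math.degrees(math.atan2(q2s, q2c)) % 360.0
    return PuckerState(Q=Q, theta=theta, phi=phi, qx=qx, qy=qy, qz=q3)


# ---------------------------------------------------------------------------
# Canonical conformer table, generated from ideal displacement patterns
# ---------------------------------------------------------------------------

_ATOM_KEY = {"O": 0, "1": 1, "2": 2, "3": 3, "4": 4, "5": 5}


def _pattern_ring(up: Iterable[str], down: Iterable[str]) -> RingCoordinates:
    """Ring with unit out-of-plane displacement at ``up``/``down`` atoms."""
    z = np.zeros(6)
    for a in up:
        z[_ATOM_KEY[a]] = 1.0
    for a in down:
        z[_ATOM_KEY[a]] = -1.0
    z = (z - z.mean()) * 0.35  # amplitude arbitrary; angles are scale-free
    # clockwise in-plane placement puts the CP normal along +z, so the
    # "up" atoms of the pattern are up in the CP sense as well
    xy = 1.45 * np.c_[np.cos(_BETA), -np.sin(_BETA)]
    return RingCoordinates(np.c_[xy, z])


def _conformer_patterns() -> list[tuple[str, str, tuple[str, ...], tuple[str, ...]]]:
    atoms = ["O", "1", "2", "3", "4", "5"]
    entries: list[tuple[str, str, tuple[str, ...], tuple[str, ...]]] = []
    # chairs: alternating displacement; 4C1 has O5/C2/C4 up, C1/C3/C5 down
    entries.append(("4C1", "chair", ("O", "2", "4"), ("1", "3", "5")))
    entries.append(("1C4", "chair", ("1", "3", "5"), ("O", "2", "4")))
    # boats: the two para (1,4-related) prow atoms displaced together
    for a, b in (("1", "4"), ("2", "5"), ("O", "3")):
        up_name = f"{a},{b}B" if a != "O" else f"{a},{b}B"
        entries.append((up_name, "boat", (a, b), ()))
        entries.append((f"B{a},{b}", "boat", (), (a, b)))
    # skew-boats: two meta (1,3-related) atoms displaced oppositely
    for a, b in (("1", "3"), ("1", "5"), ("2", "O"), ("3", "1"), ("5", "1"), ("O", "2")):
        entries.append((f"{a}S{b}", "skew-boat", (a,), (b,)))
    # envelopes: a single atom out of plane
    for a in atoms:
        entries.append((f"{a}E", "envelope", (a,), ()))
        entries.append((f"E{a}", "envelope", (), (a,)))
    # half-chairs: two adjacent atoms displaced oppositely
    ring_cycle = ["O", "1", "2", "3", "4", "5"]
    for i, a in enumerate(ring_cycle):
        b = ring_cycle[(i + 1) % 6]
        entries.append((f"{a}H{b}", "half-chair", (a,), (b,)))
        entries.append((f"{b}H{a}", "half-chair", (b,), (a,)))
    return entries


def _build_canonical_table() -> dict[str, CanonicalConformer]:
    table: dict[str, CanonicalConformer] = {}
    for name, family, up, down in _conformer_patterns():
        p = cremer_pople(_pattern_ring(up, down))
        theta = 0.0 if family == "chair" and p.theta < 1e-6 else p.theta
        if family == "chair":
            phi = 0.0  # undefined at the poles; stored as 0 by convention
            theta = round(p.theta)  # exactly 0 or 180
        elif family in ("boat", "skew-boat"):
            theta = 90.0
            phi = p.phi
        else:
            theta, phi = p.theta, p.phi
        table[name] = CanonicalConformer(name=name, theta_ref=theta, phi_ref=phi, family=family)
    assert len(table) == 38, f"canonical table has {len(table)} entries"
    return table


CANONICAL_CONFORMERS: dict[str, CanonicalConformer] = _build_canonical_table()


# ---------------------------------------------------------------------------
# Inverse construction and classification
# ---------------------------------------------------------------------------

def ring_from_pucker(Q: float, theta: float, phi: float, bond_length: float = 1.52) -> RingCoordinates:
    """Build idealized ring coordinates with a prescribed pucker state.

    The out-of-plane displacements are the exact inverse of the forward
    transform; the in-plane hexagon radius is chosen so consecutive atoms sit
    near ``bond_length`` Å apart.  Angles in degrees, lengths in Å.
    """
    if Q <= 0:
        raise ValueError("puckering amplitude Q must be positive")
    th, ph = math.radians(theta), math.radians(phi)
    z = (
        math.sqrt(1.0 / 3.0) * Q * math.sin(th) * np.cos(ph + 2.0 * _BETA)
        + math.sqrt(1.0 / 6.0) * Q * math.cos(th) * (-1.0) ** _J
    )
    dz2 = float(np.mean((z - np.roll(z, -1)) ** 2))
    side2 = bond_length**2 - dz2
    if side2 <= 0.25:
        raise ValueError(f"amplitude Q={Q} too large for bond length {bond_length}")
    radius = math.sqrt(side2)  # regular hexagon: side length == radius
    xy = radius * np.c_[np.cos(_BETA), -np.sin(_BETA)]  # clockwise: CP normal = +z
    return RingCoordinates(np.c_[xy, z])


def build_canonical(name: str, Q: float = 0.55, bond_length: float = 1.52) -> RingCoordinates:
    """Idealized ring coordinates of a named canonical conformer.

    ``cremer_pople(build_canonical(name, Q))`` reproduces the conformer's
    reference angles (within 2°) and the requested amplitude (within 1e-3 Å).
    """
    try:
        ref = CANONICAL_CONFORMERS[name]
    except KeyError:
        raise ValueError(
            f"unknown conformer {name!r}; valid names: {', '.join(sorted(CANONICAL_CONFORMERS))}"
        ) from None
    return ring_from_pucker(Q, ref.theta_ref, ref.phi_ref, bond_length=bond_length)


def geodesic_distance_deg(theta1: float, phi1: float, theta2: float, phi2: float) -> float:
    """Great-circle distance (degrees) between two points of the pucker sphere."""
    t1, p1, t2, p2 = map(math.radians, (theta1, phi1, theta2, phi2))
    c = math.cos(t1) * math.cos(t2) + math.sin(t1) * math.sin(t2) * math.cos(p1 - p2)
    return math.degrees(math.acos(max(-1.0, min(1.0, c))))


def classify_conformer(p: PuckerState, dual_threshold: float = DUAL_THRESHOLD) -> ConformerAssignment:
    """Assign a pucker state to the nearest canonical conformer(s).

    The primary assignment minimizes the geodesic distance on the
    (theta, phi) sphere.  A secondary conformer is reported (dual label such
    as "2SO/2,5B") when the runner-up is closer than ``dual_threshold`` times
    the nearest distance — the situation of a ring caught between two ideal
    shapes.
    """
    if p.planar or not math.isfinite(p.theta):
        raise RingError("planar ring: no conformer defined")
    dists = sorted(
        (geodesic_distance_deg(p.theta, p.phi, c.theta_ref, c.phi_ref), c.name)
        for c in CANONICAL_CONFORMERS.values()
    )
    (d1, n1), (d2, n2) = dists[0], dists[1]
    if d2 < dual_threshold * d1:
        return ConformerAssignment(primary=n1, secondary=n2, distance_deg=d1, label=f"{n1}/{n2}")
    return ConformerAssignment(primary=n1, secondary="", distance_deg=d1, label=n1)


def classify_disk_point(qx: float, qy: float, Q: float = 0.55,
                        dual_threshold: float = DUAL_THRESHOLD) -> ConformerAssignment:
    """Classify a point of the equatorial (qx, qy) pucker disk.

    The conformational free-energy landscape of a pyranose is computed over
    the Cartesian projections (qx, qy) at roughly constant total amplitude Q;
    the disk center maps to the 4C1 pole and the rim to the equator.
    """
    r = math.hypot(qx, qy)
    theta = math.degrees(math.asin(min(1.0, r / Q)))
    phi = math.degrees(math.atan2(qy, qx)) % 360.0
    state = PuckerState(Q=Q, theta=theta, phi=phi, qx=qx, qy=qy,
                        qz=Q * math.cos(math.radians(theta)))
    return classify_conformer(state, dual_threshold=dual_threshold)


# ---------------------------------------------------------------------------
# Trajectory analysis
# ---------------------------------------------------------------------------

@dataclass
class PuckerSeries:
    """Per-frame pucker states and conformer assignments of a ring trajectory."""

    states: list[PuckerState]
    assignments: list[ConformerAssignment]
    skipped_frames: list[int] = field(default_factory=list)

    def occupancy_histogram(self) -> dict[str, float]:
        """Fraction of frames assigned to each primary conformer."""
        counts: dict[str, int] = {}
        for a in self.assignments:
            counts[a.primary] = counts.get(a.primary, 0) + 1
        total = len(self.assignments)
        return {k: v / total for k, v in sorted(counts.items())}


def pucker_series(trajectory: Sequence[RingCoordinates],
                  dual_threshold: float = DUAL_THRESHOLD) -> PuckerSeries:
    """Classify every frame of a ring trajectory, preserving order.

    Frames that fail the ring invariants (wrong atom count, broken bonds,
    planar ring) are skipped and logged, never silently dropped.
    """
    states: list[PuckerState] = []
    assignments: list[ConformerAssignment] = []
    skipped: list[int] = []
    for i, ring in enumerate(trajectory):
        try:
            ring.validate()
            p = cremer_pople(ring)
            a = classify_conformer(p, dual_threshold=dual_threshold)
        except RingError as exc:
            logger.warning("frame %d skipped: %s", i, exc)
            skipped.append(i)
            continue
        states.append(p)
        assignments.append(a)
    return PuckerSeries(states=states, assignments=assignments, skipped_frames=skipped)


def format_itinerary(reactant: str, ts: str, product: str) -> str:
    """Catalytic-itinerary string in the field's notation, e.g. ``2SO/2,5B → [2,5B]‡ → 5S1``."""
    return f"{reactant} → [{ts}]‡ → {product}"
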