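"""Reaction collective variables and geometric series from labeled frames.

A frame is a mapping from atom labels to 3-D positions (Å).  The reaction
CVs of an inverting glycosidase are differences of two interatomic
distances, CV = d(A) − d(B): proton transfer from the catalytic water to the
general base (CV1), nucleophilic attack concerted with glycosidic-bond
cleavage (CV2), and proton transfer from the general acid to the leaving
oxygen (CV3).  This module computes such CVs, distance and dihedral time
series with running averages, and per-state (reactant / transition state /
product) mean ± SD summaries including the ring-conformer label.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .pucker import RING_ATOM_ORDER, RingCoordinates, pucker_series

Frame = Mapping[str, np.ndarray]


class GeometryError(ValueError):
    """Raised for frames missing atoms or degenerate geometry."""


@dataclass(frozen=True)
class CVSpec:
    """Difference-of-distances collective variable, CV = d(A) − d(B)."""

    name: str
    pair_a: tuple[str, str]
    pair_b: tuple[str, str]

    def __post_init__(self):
        refs = [*self.pair_a, *self.pair_b]
        if len(set(refs)) < 3:  # the two pairs may share one atom (e.g. C1)
            raise ValueError(f"CV {self.name}: atom pairs are degenerate: {refs}")


def _get(frame: Frame, atom: str) -> np.ndarray:
    try:
        return np.asarray(frame[atom], dtype=float)
    except KeyError:
        raise GeometryError(f"atom {atom!r} missing from frame") from None


def distance(frame: Frame, a: str, b: str) -> float:
    """Interatomic distance (Å)."""
    return float(np.linalg.norm(_get(frame, a) - _get(frame, b)))


def compute_cv(frame: Frame, spec: CVSpec) -> float:
    """CV = d(pair_a) − d(pair_b); sign fixed by the spec's pair order."""
    return distance(frame, *spec.pair_a) - distance(frame, *spec.pair_b)


def running_average(series: Sequence[float], window: int = 5) -> np.ndarray:
    """Centered moving mean with truncated edge windows.

    The window must be odd so the mean is centered; edges average over the
    available points only (no reflected or invented data), and the output
    has the same length as the input.  ``window=1`` is the identity.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be odd and >= 1")
    s = pd.Series(np.asarray(series, dtype=float))
    if s.empty:
        raise ValueError("empty series")
    return s.rolling(window, center=True, min_periods=1).mean().to_numpy()


def dihedral(frame: Frame, atoms: tuple[str, str, str, str]) -> float:
    """Signed torsion angle (degrees in (−180, 180]) of four atoms.

    Standard convention: looking down the central bond, the angle from the
    plane of the first three atoms to the plane of the last three; cis = 0,
    trans = 180.  Raises for collinear triples (undefined torsion).
    """
    p = [_get(frame, a) for a in atoms]
    b0, b1, b2 = p[1] - p[0], p[2] - p[1], p[3] - p[2]
    n1, n2 = np.cross(b0, b1), np.cross(b1, b2)
    if np.linalg.norm(n1) < 1e-10 or np.linalg.norm(n2) < 1e-10:
        raise GeometryError(f"collinear atoms among {atoms}: dihedral undefined")
    b1u = b1 / np.linalg.norm(b1)
    x = float(n1 @ n2)
    y = float(np.cross(n1, n2) @ b1u)
    ang = math.degrees(math.atan2(y, x))
    return 180.0 if ang <= -180.0 + 1e-12 else ang


@dataclass(frozen=True)
class StateSummary:
    """Mean ± SD of tracked distances and the ring conformer in one state."""

    label: str                               # R | TS | P (or any window name)
    distances: dict[str, tuple[float, float]]  # name -> (mean, sd), Å
    conformer: str                           # majority-vote ring label, "" if no ring


def summarize_states(frames: Sequence[Frame], windows: Mapping[str, Sequence[int]],
                     distance_specs: Mapping[str, tuple[str, str]],
                     ring_atoms: Sequence[str] | None = None) -> list[StateSummary]:
    """Per-state distance statistics and ring-conformer assignment.

    ``windows`` maps state labels (e.g. R/TS/P) to frame index sequences,
    which must not overlap.  For each state, every named distance is reported
    as mean ± SD over the window; if ``ring_atoms`` (six labels, O5-first
    order) are given, the state's conformer is the majority primary label of
    its frames.
    """
    all_idx: list[int] = []
    for label, idx in windows.items():
        if len(idx) == 0:
            raise GeometryError(f"state window {label!r} is empty")
        all_idx.extend(idx)
    if len(set(all_idx)) != len(all_idx):
        raise GeometryError("state windows overlap")

    summaries = []
    for label, idx in windows.items():
        dists = {}
        for name, (a, b) in distance_specs.items():
            vals = np.array([distance(frames[i], a, b) for i in idx])
            dists[name] = (float(vals.mean()), float(vals.std(ddof=1)) if len(vals) > 1 else 0.0)
        conformer = ""
        if ring_atoms is not None:
            rings = [
                RingCoordinates(np.array([_get(frames[i], a) for a in ring_atoms]),
                                labels=RING_ATOM_ORDER)
                for i in idx
            ]
            series = pucker_series(rings)
            if series.assignments:
                hist = series.occupancy_histogram()
                conformer = max(hist, key=hist.get)  # type: ignore[arg-type]
        summaries.append(StateSummary(label=label, distances=dists, conformer=conformer))
    return summaries


def read_labeled_frames(path) -> list[dict[str, np.ndarray]]:
    """Read frames of ``label x y z`` lines; blank lines separate frames."""
    frames: list[dict[str, np.ndarray]] = []
    current: dict[str, np.ndarray] = {}
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if line.startswith("#"):
                continue
            if not line:
                if current:
                    frames.append(current)
                    current = {}
                continue
            parts = line.split()
            if len(parts) != 4:
                raise GeometryError(f"expected 'label x y z', got {line!r}")
            current[parts[0]] = np.array([float(v) for v in parts[1:]])
    if current:
        frames.append(current)
    return frames
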