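"""PDB structure input/output for carbohydrate ring extraction.

Reads PDB files through gemmi, pulls out six-membered sugar rings
(xylose-style atom naming O5, C1–C5) with alternate-location and occupancy
awareness, and writes small synthetic PDB fixtures — e.g. a dual-altloc
xylosyl residue mimicking a crystallographic Michaelis complex in which the
−1 sugar is caught in two conformations at partial occupancy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import gemmi
import numpy as np

from .pucker import RING_ATOM_ORDER, RingCoordinates, build_canonical

logger = logging.getLogger(__name__)


class StructureError(ValueError):
    """Raised for unusable structures or selections."""


@dataclass(frozen=True)
class RingSelection:
    """Identity of one extracted ring copy within a structure."""

    chain: str
    resnum: int
    resname: str
    altloc: str      # "" for single-conformer residues
    occupancy: float

    def __post_init__(self):
        if not 0.0 <= self.occupancy <= 1.0 + 1e-6:
            raise StructureError(f"occupancy {self.occupancy} outside [0, 1]")


@dataclass(frozen=True)
class ExtractedRing:
    """A ring's coordinates together with where it came from."""

    selection: RingSelection
    ring: RingCoordinates


def _residue_altloc_rings(res: gemmi.Residue, chain_name: str) -> list[ExtractedRing]:
    """Split a residue's ring atoms by altloc and assemble ring copies."""
    by_altloc: dict[str, dict[str, gemmi.Atom]] = {}
    for atom in res:
        name = atom.name.strip().rstrip("'")
        if name not in RING_ATOM_ORDER:
            continue
        altloc = "" if atom.altloc in ("", "\0", " ") else atom.altloc
        by_altloc.setdefault(altloc, {})[name] = atom
    if not by_altloc:
        raise StructureError(
            f"residue {res.name} {res.seqid.num} has no ring atoms ({'/'.join(RING_ATOM_ORDER)})"
        )
    shared = by_altloc.pop("", {})
    copies = by_altloc if by_altloc else {"": shared}
    rings: list[ExtractedRing] = []
    for altloc in sorted(copies):
        atoms = dict(shared)
        atoms.update(copies[altloc])
        missing = [n for n in RING_ATOM_ORDER if n not in atoms]
        if missing:
            raise StructureError(
                f"residue {res.name} {res.seqid.num} altloc {altloc or '(blank)'} "
                f"is missing ring atom(s) {', '.join(missing)}"
            )
        coords = np.array([[atoms[n].pos.x, atoms[n].pos.y, atoms[n].pos.z] for n in RING_ATOM_ORDER])
        occs = [atoms[n].occ for n in RING_ATOM_ORDER]
        occ = float(np.mean(occs))
        if all(o == 0.0 for o in occs):
            logger.warning("occupancy absent for %s %d %s; defaulting to 1.0",
                           res.name, res.seqid.num, altloc)
            occ = 1.0
        rings.append(
            ExtractedRing(
                selection=RingSelection(chain=chain_name, resnum=res.seqid.num,
                                        resname=res.name, altloc=altloc, occupancy=occ),
                ring=RingCoordinates(coords),
            )
        )
    return rings


def extract_rings(path: str | Path, chain: str, resnum: int) -> list[ExtractedRing]:
    """Extract all altloc copies of a sugar ring from a PDB file.

    Returns one :class:`ExtractedRing` per alternate location (a residue
    without altlocs yields a single copy), each carrying its occupancy and
    with atom ordering normalized to O5-first.  Hydrogens and non-ring atoms
    are ignored.
    """
    st = gemmi.read_structure(str(path))
    if len(st) == 0:
        raise StructureError(f"{path}: no models in structure")
    model = st[0]
    ch = model.find_chain(chain)
    if ch is None:
        raise StructureError(f"{path}: chain {chain!r} not found "
                             f"(have {', '.join(c.name for c in model)})")
    residues = [r for r in ch if r.seqid.num == resnum]
    if not residues:
        raise StructureError(f"{path}: no residue {resnum} in chain {chain}")
    rings: list[ExtractedRing] = []
    for res in residues:
        rings.extend(_residue_altloc_rings(res, chain))
    return rings


def write_fixture(rings: Sequence[tuple[str, float, float, str]], path: str | Path,
                  chain: str = "A", resnum: int = 1, resname: str = "XYP",
                  synthetic_remark: str | None = None) -> Path:
    """Write a synthetic single-residue PDB fixture with altloc ring copies.

    ``rings`` is a sequence of ``(conformer_name, Q, occupancy, altloc)``
    tuples; each entry becomes one alternate location of a xylopyranose-like
    residue built from idealized canonical geometry.  Occupancies of the
    residue must sum to at most 1.  The emitted file re-parses under
    :func:`extract_rings` with identical altlocs and occupancies.
    """
    total_occ = sum(occ for _, _, occ, _ in rings)
    if total_occ > 1.0 + 1e-6:
        raise StructureError(f"altloc occupancies sum to {total_occ:.2f} > 1")
    seen = set()
    for _, _, _, altloc in rings:
        if altloc in seen:
            raise StructureError(f"duplicate altloc {altloc!r}")
        seen.add(altloc)

    st = gemmi.Structure()
    st.name = "glypath synthetic ring fixture"
    model = gemmi.Model("1")
    ch = gemmi.Chain(chain)
    res = gemmi.Residue()
    res.name = resname
    res.seqid = gemmi.SeqId(resnum, " ")
    res.het_flag = "H"
    for name, Q, occ, altloc in rings:
        coords = build_canonical(name, Q=Q).coords
        for atom_name, xyz in zip(RING_ATOM_ORDER, coords):
            atom = gemmi.Atom()
            atom.name = atom_name
            atom.element = gemmi.Element(atom_name[0])
            atom.pos = gemmi.Position(*xyz)
            atom.occ = occ
            atom.altloc = altloc if altloc else "\0"
            atom.b_iso = 20.0
            res.add_atom(atom)
    ch.add_residue(res)
    model.add_chain(ch)
    st.add_model(model)
    st.setup_entities()
    path = Path(path)
    pdb_text = st.make_pdb_string()
    if synthetic_remark:
        pdb_text = f"REMARK 999 {synthetic_remark}\n" + pdb_text
    path.write_text(pdb_text)
    return path


def report_rings(rings: Sequence[ExtractedRing]) -> str:
    """TSV report (one line per ring copy) with pucker and conformer columns."""
    from .pucker import classify_conformer, cremer_pople

    lines = ["chain\tresnum\tresname\taltloc\toccupancy\tQ\ttheta\tphi\tqx\tqy\tqz\tlabel"]
    for er in rings:
        p = cremer_pople(er.ring)
        label = "planar" if p.planar else classify_conformer(p).label
        s = er.selection
        lines.append(
            f"{s.chain}\t{s.resnum}\t{s.resname}\t{s.altloc}\t{s.occupancy:.2f}\t"
            f"{p.Q:.4f}\t{p.theta:.2f}\t{p.phi:.2f}\t{p.qx:.4f}\t{p.qy:.4f}\t{p.qz:.4f}\t{label}"
        )
    return "\n".join(lines) + "\n"
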