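"""Structure-quality and comparison metrics.

Backbone phi/psi dihedrals with a coarse rectangular Ramachandran
classification (deliberately simpler than empirical density maps — it is a
sanity check, not a validation service), radius of gyration, and RMSD with
optional Kabsch superposition.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from .io_bio import Structure

logger = logging.getLogger(__name__)

ResKey = Tuple[str, int, str]

# (phi_lo, phi_hi, psi_lo, psi_hi) rectangles treated as favoured
_CORE_BOXES = [
    (-180.0, -30.0, -90.0, 180.0),    # beta + right half of helical region
    (-180.0, -30.0, -180.0, -150.0),  # psi wrap-around of the beta strip
    (30.0, 90.0, -20.0, 60.0),        # left-handed helical box
]
_ALLOWED_MARGIN = 20.0


@dataclass(frozen=True)
class DihedralRecord:
    residue_key: ResKey
    phi: Optional[float]   # degrees in (-180, 180]
    psi: Optional[float]
    region: str            # core | allowed | outlier | incomplete


def dihedral(p0, p1, p2, p3) -> Optional[float]:
    """Torsion angle in degrees, IUPAC sign convention; None if degenerate."""
    p0, p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p0, p1, p2, p3))
    b1, b2, b3 = p1 - p0, p2 - p1, p3 - p2
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < 1e-9 or np.linalg.norm(n2) < 1e-9:
        return None  # collinear atoms: torsion undefined
    m1 = np.cross(n1, b2 / np.linalg.norm(b2))
    x = float(np.dot(n1, n2))
    y = float(np.dot(m1, n2))
    angle = math.degrees(math.atan2(y, x))
    return 180.0 if angle <= -180.0 else angle


def _in_boxes(phi: float, psi: float, margin: float = 0.0) -> bool:
    for plo, phi_hi, slo, shi in _CORE_BOXES:
        if (plo - margin) <= phi <= (phi_hi + margin) and (slo - margin) <= psi <= (shi + margin):
            return True
    return False


def classify_region(phi: Optional[float], psi: Optional[float]) -> str:
    if phi is None or psi is None:
        return "incomplete"
    if _in_boxes(phi, psi):
        return "core"
    if _in_boxes(phi, psi, _ALLOWED_MARGIN):
        return "allowed"
    return "outlier"


def backbone_dihedrals(structure: Structure) -> list[DihedralRecord]:
    """Per-residue phi/psi with coarse Ramachandran region labels.

    Terminal residues (and residues lacking backbone atoms) are marked
    ``incomplete``.
    """
    records: list[DihedralRecord] = []
    for chain in structure.chains:
        residues = [r for r in chain.residues if not all(a.het for a in r.atoms)]
        for i, res in enumerate(residues):
            phi = psi = None
            have_bb = all(res.has_atom(n) for n in ("N", "CA", "C"))
            if have_bb and 0 < i:
                prev = residues[i - 1]
                if prev.has_atom("C"):
                    phi = dihedral(prev.atom("C").coords, res.atom("N").coords,
                                   res.atom("CA").coords, res.atom("C").coords)
            if have_bb and i < len(residues) - 1:
                nxt = residues[i + 1]
                if nxt.has_atom("N"):
                    psi = dihedral(res.atom("N").coords, res.atom("CA").coords,
                                   res.atom("C").coords, nxt.atom("N").coords)
            if have_bb and (phi is None or psi is None) and 0 < i < len(residues) - 1:
                logger.warning("degenerate or incomplete dihedral at %s", res.key)
            records.append(DihedralRecord(res.key, phi, psi, classify_region(phi, psi)))
    return records


def _heavy_coords(structure: Structure) -> np.ndarray:
    coords = [a.coords for _, a in structure.atoms() if not a.is_hydrogen]
    if not coords:
        raise ValueError("structure has no heavy atoms")
    return np.asarray(coords, dtype=float)


def radius_of_gyration(structure: Structure, mass_weighted: bool = False) -> float:
    """Root-mean-square heavy-atom distance from the centroid, in Angstrom."""
    coords = _heavy_coords(structure)
    if mass_weighted:
        from .sasa import DEFAULT_RADII  # element list only
        masses = {"C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06, "P": 30.974, "H": 1.008}
        w = np.asarray([masses.get(a.element, 12.0) for _, a in structure.atoms()
                        if not a.is_hydrogen])
    else:
        w = np.ones(len(coords))
    centroid = np.average(coords, axis=0, weights=w)
    d2 = np.sum((coords - centroid) ** 2, axis=1)
    return float(np.sqrt(np.average(d2, weights=w)))


def _matched_coords(a: Structure, b: Structure) -> Tuple[np.ndarray, np.ndarray]:
    ka = [(r.key, at.name) for r, at in a.atoms()]
    kb = [(r.key, at.name) for r, at in b.atoms()]
    if ka != kb:
        mismatch = next((x for x, y in zip(ka, kb) if x != y), None)
        if mismatch is None:
            mismatch = ka[len(kb)] if len(ka) > len(kb) else kb[len(ka)]
        raise ValueError(f"atom sets differ; first mismatch: {mismatch}")
    xa = np.asarray([at.coords for _, at in a.atoms()], dtype=float)
    xb = np.asarray([at.coords for _, at in b.atoms()], dtype=float)
    return xa, xb


def kabsch_rotation(p: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Optimal rotation matrix aligning centred ``p`` onto centred ``q``."""
    h = p.T @ q
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    flip = np.diag([1.0, 1.0, d])
    return vt.T @ flip @ u.T


def rmsd(a: Structure, b: Structure, superpose: bool = True) -> float:
    """RMSD between corresponding atoms; optional Kabsch superposition."""
    xa, xb = _matched_coords(a, b)
    if superpose:
        ca, cb = xa.mean(axis=0), xb.mean(axis=0)
        pa, pb = xa - ca, xb - cb
        rot = kabsch_rotation(pa, pb)
        pa = pa @ rot.T
        diff = pa - pb
    else:
        diff = xa - xb
    return float(np.sqrt(np.mean(np.sum(diff ** 2, axis=1))))
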