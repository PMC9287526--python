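"""Shrake-Rupley solvent-accessible surface area with a Monte-Carlo oracle.

Each atom's sphere is inflated by the probe radius and sampled with a
deterministic golden-section spiral; a sample point is exposed when it lies
outside every neighbour's inflated sphere.  Neighbour lookup uses a uniform
spatial grid so results do not depend on atom order and scale linearly.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Dict, Optional, Tuple

import numpy as np

from .io_bio import Atom, Residue, Structure

logger = logging.getLogger(__name__)

#: Bondi-style van der Waals radii (Angstrom) for heavy protein atoms.
DEFAULT_RADII: Dict[str, float] = {
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "H": 1.20,
    "P": 1.80,
}

ResKey = Tuple[str, int, str]
AtomKey = Tuple[str, int, str, str]


@dataclass(frozen=True)
class SasaParams:
    probe_radius: float = 1.4
    n_sphere_points: int = 960
    radii_table: Dict[str, float] = field(default_factory=lambda: dict(DEFAULT_RADII))
    include_hydrogens: bool = False

    def __post_init__(self) -> None:
        if self.probe_radius < 0:
            raise ValueError("probe_radius must be >= 0")
        if self.n_sphere_points < 12:
            raise ValueError("n_sphere_points must be >= 12")
        if any(r <= 0 for r in self.radii_table.values()):
            raise ValueError("all van der Waals radii must be positive")


@dataclass
class SasaResult:
    per_atom: Dict[AtomKey, float]
    per_residue: Dict[ResKey, float]
    relative_per_residue: Dict[ResKey, float]
    params: SasaParams

    def total(self) -> float:
        return float(sum(self.per_atom.values()))


def sphere_points(n: int) -> np.ndarray:
    """Deterministic golden-section spiral of ``n`` points on the unit sphere."""
    if n < 12:
        raise ValueError(f"need at least 12 sphere points, got {n}")
    k = np.arange(n, dtype=float)
    # evenly spaced heights, offset half a step to avoid the poles
    z = 1.0 - (2.0 * k + 1.0) / n
    theta = np.pi * (1.0 + 5.0 ** 0.5) * k
    rho = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    pts = np.column_stack([rho * np.cos(theta), rho * np.sin(theta), z])
    return pts / np.linalg.norm(pts, axis=1, keepdims=True)


def _collect_atoms(structure: Structure, params: SasaParams):
    """Flatten heavy atoms (or all, if configured) with assigned radii."""
    keys: list[AtomKey] = []
    reskeys: list[ResKey] = []
    coords = []
    radii = []
    for res in structure.residues():
        for atom in res.atoms:
            if atom.is_hydrogen and not params.include_hydrogens:
                continue
            if atom.element not in params.radii_table:
                raise ValueError(
                    f"no van der Waals radius for element {atom.element!r} "
                    f"(atom {atom.name} in residue {res.key})"
                )
            keys.append((res.chain_id, res.seq_number, res.insertion_code, atom.name))
            reskeys.append(res.key)
            coords.append(atom.coords)
            radii.append(params.radii_table[atom.element])
    if not keys:
        raise ValueError("structure has no heavy atoms")
    return keys, reskeys, np.asarray(coords, dtype=float), np.asarray(radii, dtype=float)


class _NeighborGrid:
    """Uniform grid over atom centres; cell size 2*(max radius + probe)."""

    def __init__(self, coords: np.ndarray, cell: float):
        self.coords = coords
        self.cell = cell
        self.origin = coords.min(axis=0)
        idx = np.floor((coords - self.origin) / cell).astype(np.int64)
        self.cells: Dict[Tuple[int, int, int], list[int]] = {}
        for i, c in enumerate(map(tuple, idx)):
            self.cells.setdefault(c, []).append(i)
        self.idx = idx

    def neighbors(self, i: int) -> np.ndarray:
        cx, cy, cz = self.idx[i]
        out: list[int] = []
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                for dz in (-1, 0, 1):
                    out.extend(self.cells.get((cx + dx, cy + dy, cz + dz), ()))
        return np.asarray([j for j in out if j != i], dtype=np.int64)


def _exposed_fraction(i: int, coords: np.ndarray, aug: np.ndarray,
                      grid: _NeighborGrid, pts: np.ndarray) -> float:
    """Fraction of sample points on atom i's inflated sphere outside all neighbours."""
    nbr = grid.neighbors(i)
    if nbr.size == 0:
        return 1.0
    d = coords[nbr] - coords[i]
    dist2 = np.einsum("ij,ij->i", d, d)
    cut = (aug[nbr] + aug[i]) ** 2
    close = nbr[dist2 < cut]
    if close.size == 0:
        return 1.0
    sample = coords[i] + aug[i] * pts  # (n, 3)
    diff = sample[:, None, :] - coords[close][None, :, :]
    inside = np.einsum("ijk,ijk->ij", diff, diff) < (aug[close] ** 2)[None, :]
    return float(np.mean(~inside.any(axis=1)))


def compute_sasa(structure: Structure, params: Optional[SasaParams] = None) -> SasaResult:
    """Per-atom and per-residue absolute SASA in A^2 (Shrake-Rupley)."""
    params = params or SasaParams()
    keys, reskeys, coords, radii = _collect_atoms(structure, params)
    aug = radii + params.probe_radius
    pts = sphere_points(params.n_sphere_points)
    grid = _NeighborGrid(coords, cell=2.0 * float(aug.max()))

    per_atom: Dict[AtomKey, float] = {}
    per_residue: Dict[ResKey, float] = {}
    for i, key in enumerate(keys):
        frac = _exposed_fraction(i, coords, aug, grid, pts)
        area = frac * 4.0 * np.pi * aug[i] ** 2
        per_atom[key] = float(area)
        per_residue[reskeys[i]] = per_residue.get(reskeys[i], 0.0) + float(area)
    return SasaResult(per_atom=per_atom, per_residue=per_residue,
                      relative_per_residue={}, params=params)


# ---------------------------------------------------------------------------
# Relative SASA

_MAX_ASA_CACHE: Optional[Dict[str, float]] = None


def load_max_asa_table(path: Optional[str | Path] = None) -> Dict[str, float]:
    """Theoretical maximum residue SASA table (residue name -> A^2).

    Ships Tien et al. (2013) theoretical values; a custom two-column
    whitespace-separated file may be supplied instead.
    """
    global _MAX_ASA_CACHE
    if path is None:
        if _MAX_ASA_CACHE is not None:
            return dict(_MAX_ASA_CACHE)
        text = resources.files("dopasight.data").joinpath("max_asa.tsv").read_text()
    else:
        text = Path(path).read_text()
    table: Dict[str, float] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        name, value = line.split()[:2]
        table[name.upper()] = float(value)
    if path is None:
        _MAX_ASA_CACHE = dict(table)
    return table


def relative_sasa(result: SasaResult, structure: Structure,
                  reference_table: Optional[Dict[str, float]] = None,
                  cap: float = 1.5) -> SasaResult:
    """Fill ``relative_per_residue`` = absolute residue SASA / reference maximum.

    Values above ``cap`` (extended conformations) are capped with a warning.
    Residues made only of HETATM records (e.g. blocker pseudo-atoms) are
    skipped: they have no meaningful reference state.
    """
    table = reference_table if reference_table is not None else load_max_asa_table()
    rel: Dict[ResKey, float] = {}
    for res in structure.residues():
        if res.key not in result.per_residue:
            continue
        if all(a.het for a in res.atoms):
            continue
        if res.name not in table:
            raise KeyError(f"no reference maximum SASA for residue name {res.name!r}")
        value = result.per_residue[res.key] / table[res.name]
        if value > cap:
            warnings.warn(
                f"relative SASA {value:.2f} for {res.key} exceeds {cap}; capping",
                stacklevel=2,
            )
            value = cap
        rel[res.key] = value
    return replace(result, relative_per_residue=rel)


# ---------------------------------------------------------------------------
# Monte-Carlo oracle


def mc_sasa_oracle(structure: Structure, params: Optional[SasaParams] = None,
                   n_samples: int = 10000, seed: int = 0):
    """Seeded rejection-sampling SASA estimate with per-atom standard errors.

    Independent of :func:`compute_sasa`'s spiral sampling; used as a test
    oracle.  Returns ``(per_atom_area, per_atom_se)`` dictionaries.
    """
    params = params or SasaParams()
    if n_samples < 1000:
        raise ValueError("n_samples must be >= 1000 for a usable estimate")
    keys, _, coords, radii = _collect_atoms(structure, params)
    aug = radii + params.probe_radius
    rng = np.random.default_rng(seed)
    areas: Dict[AtomKey, float] = {}
    ses: Dict[AtomKey, float] = {}
    for i, key in enumerate(keys):
        dirs = rng.normal(size=(n_samples, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        sample = coords[i] + aug[i] * dirs
        exposed = np.ones(n_samples, dtype=bool)
        for j in range(len(keys)):
            if j == i:
                continue
            d = sample - coords[j]
            exposed &= np.einsum("ij,ij->i", d, d) >= aug[j] ** 2
            if not exposed.any():
                break
        p = float(exposed.mean())
        full = 4.0 * np.pi * aug[i] ** 2
        areas[key] = p * full
        ses[key] = float(np.sqrt(max(p * (1.0 - p), 1e-12) / n_samples) * full)
    return areas, ses
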