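"""Deterministic toy structures with known, controllable properties.

Peptides are built from ideal internal coordinates (NeRF chain extension),
so every fixture is a pure function of its spec: same spec, byte-identical
PDB.  Burial is controlled by surrounding a target residue with a lattice
shell of HETATM carbon blockers in a separate chain, so residue-level logic
ignores the blockers while SASA sees them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, List, Optional, Tuple

import numpy as np

from .io_bio import Atom, Chain, Residue, SequenceRecord, Structure, read_fasta

# ideal backbone internal coordinates (Angstrom / degrees)
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 120.8
OMEGA = 180.0

FIXTURE_KINDS = (
    "isolated_atom", "atom_pair", "buried_atom", "extended_peptide",
    "helix", "strand", "exposed_tyr", "buried_tyr", "toy_chimera",
)

_ONE_TO_THREE = {"G": "GLY", "A": "ALA", "Y": "TYR"}


@dataclass(frozen=True)
class FixtureSpec:
    kind: str
    parameters: Dict[str, object] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in FIXTURE_KINDS:
            raise ValueError(f"unknown fixture kind {self.kind!r}; "
                             f"choose from {FIXTURE_KINDS}")

    def param(self, name: str, default):
        return self.parameters.get(name, default)


@dataclass
class Fixture:
    structure: Structure
    sequence: Optional[SequenceRecord] = None
    #: residue keys of tyrosines constructed exposed / buried (peptide kinds)
    exposed_tyr: List[Tuple[str, int, str]] = field(default_factory=list)
    buried_tyr: List[Tuple[str, int, str]] = field(default_factory=list)


def _place(a, b, c, bond: float, angle: float, torsion: float) -> np.ndarray:
    """NeRF: position D with |c-D| = bond, angle(b,c,D) = angle and
    torsion(a,b,c,D) = torsion (degrees)."""
    a, b, c = (np.asarray(p, dtype=float) for p in (a, b, c))
    # negated torsion so the measured IUPAC dihedral equals the request
    ang, tor = math.radians(angle), -math.radians(torsion)
    d_local = np.array([
        -bond * math.cos(ang),
        bond * math.sin(ang) * math.cos(tor),
        bond * math.sin(ang) * math.sin(tor),
    ])
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    rot = np.column_stack([bc, m, n])
    return c + rot @ d_local


def _tyr_sidechain(n, ca, cb) -> Dict[str, np.ndarray]:
    """Idealized planar tyrosine ring grown from CB (chi1 trans, chi2 90)."""
    cg = _place(n, ca, cb, 1.51, 113.9, 180.0)
    cd1 = _place(ca, cb, cg, 1.39, 120.9, 90.0)
    cd2 = _place(ca, cb, cg, 1.39, 120.9, -90.0)
    ce1 = _place(cb, cg, cd1, 1.39, 121.0, 180.0)
    ce2 = _place(cb, cg, cd2, 1.39, 121.0, 180.0)
    cz = _place(cg, cd1, ce1, 1.39, 120.0, 0.0)
    oh = _place(cd1, ce1, cz, 1.38, 120.0, 180.0)
    return {"CG": cg, "CD1": cd1, "CD2": cd2, "CE1": ce1, "CE2": ce2,
            "CZ": cz, "OH": oh}


def build_peptide(sequence: str, phi: float | List[float], psi: float | List[float],
                  chain_id: str = "A", first_resnum: int = 1) -> Structure:
    """Build an ideal-geometry peptide with the requested phi/psi angles.

    Supported residue types: G, A, Y (glycine host, alanine, tyrosine with a
    full ring).  ``phi``/``psi`` may be scalars or per-residue lists.
    """
    n_res = len(sequence)
    phis = [float(phi)] * n_res if np.isscalar(phi) else list(phi)
    psis = [float(psi)] * n_res if np.isscalar(psi) else list(psi)
    if len(phis) != n_res or len(psis) != n_res:
        raise ValueError("phi/psi lists must match sequence length")
    for aa in sequence:
        if aa not in _ONE_TO_THREE:
            raise ValueError(f"peptide builder supports G/A/Y only, got {aa!r}")

    structure = Structure(title=f"peptide_{sequence}")
    chain = Chain(chain_id)
    structure.chains.append(chain)

    prev_n = prev_ca = prev_c = None
    for i, aa in enumerate(sequence):
        if i == 0:
            n = np.array([0.0, 0.0, 0.0])
            ca = np.array([BOND_N_CA, 0.0, 0.0])
            ang = math.radians(ANGLE_N_CA_C)
            c = ca + BOND_CA_C * np.array([-math.cos(ang), math.sin(ang), 0.0])
        else:
            n = _place(prev_n, prev_ca, prev_c, BOND_C_N, ANGLE_CA_C_N, psis[i - 1])
            ca = _place(prev_ca, prev_c, n, BOND_N_CA, ANGLE_C_N_CA, OMEGA)
            c = _place(prev_c, n, ca, BOND_CA_C, ANGLE_N_CA_C, phis[i])
        o = _place(n, ca, c, BOND_C_O, ANGLE_CA_C_O, psis[i] - 180.0)

        res = Residue(chain_id=chain_id, seq_number=first_resnum + i,
                      name=_ONE_TO_THREE[aa])
        for name, pos, elem in (("N", n, "N"), ("CA", ca, "C"), ("C", c, "C"), ("O", o, "O")):
            res.add_atom(Atom(name=name, element=elem, coords=tuple(np.round(pos, 3))))
        if aa != "G":
            cb = _place(c, n, ca, 1.53, 110.5, -122.6)
            res.add_atom(Atom(name="CB", element="C", coords=tuple(np.round(cb, 3))))
            if aa == "Y":
                for name, pos in _tyr_sidechain(n, ca, cb).items():
                    elem = "O" if name.startswith("O") else "C"
                    res.add_atom(Atom(name=name, element=elem, coords=tuple(np.round(pos, 3))))
        chain.residues.append(res)
        prev_n, prev_ca, prev_c = n, ca, c
    return structure


def _add_blocker_shell(structure: Structure, target_keys, spacing: float = 3.0,
                       margin: float = 4.5, clearance: float = 2.7,
                       chain_id: str = "Z") -> List[Tuple[str, int, str]]:
    """Surround the target residues with a lattice of HETATM carbon blockers.

    Lattice points within ``clearance`` of any existing atom are dropped so
    the shell does not clash with the structure it buries.
    """
    target_keys = {(k[0], k[1], "") if len(k) == 2 else tuple(k) for k in target_keys}
    targets = []
    everything = []
    for res in structure.residues():
        for atom in res.atoms:
            everything.append(atom.coords)
            if res.key in target_keys:
                targets.append(atom.coords)
    if not targets:
        raise ValueError(f"no atoms found for target residues {sorted(target_keys)}")
    targets = np.asarray(targets)
    everything = np.asarray(everything)

    lo = targets.min(axis=0) - margin
    hi = targets.max(axis=0) + margin
    axes = [np.arange(lo[d], hi[d] + 1e-9, spacing) for d in range(3)]
    grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    d2 = ((grid[:, None, :] - everything[None, :, :]) ** 2).sum(axis=2)
    keep = grid[d2.min(axis=1) >= clearance ** 2]

    chain = structure.get_or_create_chain(chain_id)
    start = (chain.residues[-1].seq_number + 1) if chain.residues else 1
    keys = []
    for i, pos in enumerate(keep):
        res = Residue(chain_id=chain_id, seq_number=start + i, name="BLK")
        res.add_atom(Atom(name="C", element="C", coords=tuple(np.round(pos, 3)), het=True))
        chain.residues.append(res)
        keys.append(res.key)
    return keys


def _single_atom_structure(title: str, positions, het: bool = True) -> Structure:
    structure = Structure(title=title)
    chain = Chain("A")
    structure.chains.append(chain)
    for i, pos in enumerate(positions, start=1):
        res = Residue(chain_id="A", seq_number=i, name="BLK")
        res.add_atom(Atom(name="C", element="C", coords=tuple(float(x) for x in pos), het=het))
        chain.residues.append(res)
    return structure


def build_fixture(spec: FixtureSpec) -> Fixture:
    """Build the structure (and sequence, for peptide kinds) for a spec."""
    kind = spec.kind
    if kind == "isolated_atom":
        return Fixture(_single_atom_structure("isolated_atom", [(0.0, 0.0, 0.0)]))

    if kind == "atom_pair":
        d = float(spec.param("distance", 3.1))
        if d <= 0:
            raise ValueError("distance must be positive")
        return Fixture(_single_atom_structure(
            "atom_pair", [(0.0, 0.0, 0.0), (d, 0.0, 0.0)]))

    if kind == "buried_atom":
        spacing = float(spec.param("spacing", 2.0))
        positions = [(0.0, 0.0, 0.0)]
        for ix in (-1, 0, 1):
            for iy in (-1, 0, 1):
                for iz in (-1, 0, 1):
                    if (ix, iy, iz) != (0, 0, 0):
                        positions.append((ix * spacing, iy * spacing, iz * spacing))
        return Fixture(_single_atom_structure("buried_atom", positions))

    if kind in ("extended_peptide", "helix", "strand"):
        defaults = {
            "extended_peptide": ("GGGGG", -180.0, 180.0),
            "helix": ("AAAAAAAA", -57.0, -47.0),
            "strand": ("AAAAAAAA", -120.0, 120.0),
        }
        seq_d, phi_d, psi_d = defaults[kind]
        seq = str(spec.param("sequence", seq_d))
        structure = build_peptide(seq, float(spec.param("phi", phi_d)),
                                  float(spec.param("psi", psi_d)))
        record = SequenceRecord(identifier=kind, residues=seq)
        return Fixture(structure, sequence=record)

    if kind == "exposed_tyr":
        structure = build_peptide("GYG", -180.0, 180.0)
        return Fixture(structure, sequence=SequenceRecord("exposed_tyr", "GYG"),
                       exposed_tyr=[("A", 2, "")])

    if kind == "buried_tyr":
        structure = build_peptide("GYG", -180.0, 180.0)
        _add_blocker_shell(structure, [("A", 2, "")],
                           spacing=float(spec.param("spacing", 3.0)),
                           margin=float(spec.param("margin", 4.5)))
        return Fixture(structure, sequence=SequenceRecord("buried_tyr", "GYG"),
                       buried_tyr=[("A", 2, "")])

    if kind == "toy_chimera":
        return _build_toy_chimera(spec)

    raise ValueError(f"unknown fixture kind {kind!r}")  # pragma: no cover


def _build_toy_chimera(spec: FixtureSpec) -> Fixture:
    """Strand-rich segment followed by an extended Tyr-rich segment with
    ``k`` exposed and ``m`` shell-buried tyrosines."""
    k = int(spec.param("k", 4))
    m = int(spec.param("m", 3))
    if k < 0 or m < 0:
        raise ValueError("k and m must be >= 0")
    strand_len = int(spec.param("strand_length", 6))

    # tyrosines every 4th residue so blocker shells cannot reach neighbours
    tyr_seq = "".join("YGGG" for _ in range(k + m)).rstrip("G") or ""
    seq = "A" * strand_len + ("G" + tyr_seq if tyr_seq else "")
    phis = [-120.0] * strand_len + [-180.0] * (len(seq) - strand_len)
    psis = [120.0] * strand_len + [180.0] * (len(seq) - strand_len)
    structure = build_peptide(seq, phis, psis)

    tyr_keys = [res.key for res in structure.residues() if res.name == "TYR"]
    assert len(tyr_keys) == k + m
    exposed, buried = tyr_keys[:k], tyr_keys[k:]
    for key in buried:
        _add_blocker_shell(structure, [key])
    structure.title = f"toy_chimera_k{k}_m{m}"
    return Fixture(structure, sequence=SequenceRecord("toy_chimera", seq),
                   exposed_tyr=list(exposed), buried_tyr=list(buried))


def table1_fixtures() -> Tuple[SequenceRecord, SequenceRecord]:
    """The two bundled precursor sequences with signal/mature annotation.

    Returns (MFP3 precursor, CsgA precursor); signal peptides span residues
    1-24 and 1-20 respectively.
    """
    records = []
    for fname, signal_end in (("mfp3_precursor.fasta", 24), ("csga_precursor.fasta", 20)):
        with resources.as_file(resources.files("dopasight.data").joinpath(fname)) as path:
            raw = read_fasta(path)[0]
        records.append(SequenceRecord(
            identifier=raw.identifier,
            residues=raw.residues,
            description=raw.description,
            signal_range=(1, signal_end),
            mature_range=(signal_end + 1, len(raw.residues)),
        ))
    return records[0], records[1]
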