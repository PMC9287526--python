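"""Tyrosine accessibility classification and in-structure DOPA conversion.

Two classification schemes are supported: whole-residue relative SASA
against a strict threshold, and per-atom exposure of the two ring carbons
ortho to the existing hydroxyl (CE1/CE2) — the positions tyrosinase
hydroxylates.  Conversion renames the residue and adds the second ring
oxygen in the ring plane.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, Optional, Tuple

import numpy as np

from .io_bio import Atom, Residue, Structure
from .sasa import SasaParams, SasaResult, compute_sasa, relative_sasa

logger = logging.getLogger(__name__)

ResKey = Tuple[str, int, str]

#: residue name used for converted tyrosines (chemical-component code for
#: 3,4-dihydroxyphenylalanine)
DOPA_RESNAME = "DAH"

#: name given to the added ring oxygen
ADDED_OXYGEN_NAME = "OH3"

TYR_RING_ATOMS = ("CG", "CD1", "CD2", "CE1", "CE2", "CZ")


@dataclass(frozen=True)
class AccessibilityParams:
    threshold: float = 0.55
    mode: str = "whole_residue"  # or "ring_carbon"
    ring_atoms: FrozenSet[str] = frozenset({"CE1", "CE2"})
    ring_atom_min_area: float = 5.0

    def __post_init__(self) -> None:
        if not 0.0 < self.threshold < 1.0:
            raise ValueError(f"threshold must be in (0, 1), got {self.threshold}")
        if self.mode not in ("whole_residue", "ring_carbon"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "ring_carbon" and not self.ring_atoms:
            raise ValueError("ring_carbon mode needs a non-empty ring_atoms set")


@dataclass
class TyrosineCall:
    residue_key: ResKey
    relative_sa: float
    ring_exposed: bool
    modifiable: bool


@dataclass
class ModificationReport:
    per_tyrosine: list[TyrosineCall]
    params: AccessibilityParams

    @property
    def n_total(self) -> int:
        return len(self.per_tyrosine)

    @property
    def n_modifiable(self) -> int:
        return sum(1 for c in self.per_tyrosine if c.modifiable)

    @property
    def modifiable_keys(self) -> set[ResKey]:
        return {c.residue_key for c in self.per_tyrosine if c.modifiable}

    @property
    def fraction_modifiable(self) -> float:
        return self.n_modifiable / self.n_total if self.n_total else 0.0

    @property
    def per_chain_counts(self) -> Dict[str, Tuple[int, int]]:
        counts: Dict[str, list[int]] = {}
        for call in self.per_tyrosine:
            chain = call.residue_key[0]
            c = counts.setdefault(chain, [0, 0])
            c[0] += 1
            c[1] += int(call.modifiable)
        return {k: (v[0], v[1]) for k, v in counts.items()}


def classify_tyrosines(structure: Structure, sasa: SasaResult,
                       params: Optional[AccessibilityParams] = None) -> ModificationReport:
    """Classify each tyrosine as tyrosinase-modifiable or not.

    whole_residue mode: modifiable iff relative SASA is strictly above the
    threshold.  ring_carbon mode: modifiable iff every named ring atom has
    at least ``ring_atom_min_area`` of exposed area.
    """
    params = params or AccessibilityParams()
    calls: list[TyrosineCall] = []
    tyrosines = [res for res in structure.residues() if res.name == "TYR"]
    if not tyrosines:
        logger.warning("structure contains no tyrosines; empty report")
    for res in sorted(tyrosines, key=lambda r: (r.chain_id, r.seq_number, r.insertion_code)):
        if res.key not in sasa.per_residue:
            raise ValueError(f"SASA result does not cover residue {res.key}; "
                             "was it computed on the same structure?")
        rel = sasa.relative_per_residue.get(res.key)
        if rel is None:
            raise ValueError("relative SASA missing; run relative_sasa() first")
        ring_ok = True
        for aname in sorted(params.ring_atoms):
            akey = (res.chain_id, res.seq_number, res.insertion_code, aname)
            if akey not in sasa.per_atom:
                raise ValueError(f"atom {aname} of {res.key} missing from SASA result")
            if sasa.per_atom[akey] < params.ring_atom_min_area:
                ring_ok = False
        modifiable = rel > params.threshold if params.mode == "whole_residue" else ring_ok
        calls.append(TyrosineCall(res.key, rel, ring_ok, modifiable))
    return ModificationReport(per_tyrosine=calls, params=params)


def _dopa_oxygen_position(res: Residue) -> Tuple[float, float, float]:
    """Place the new ring oxygen 1.36 A from CE1, in the ring plane,
    along the external bisector of the CD1-CE1-CZ angle."""
    coords = {a: np.asarray(res.atom(a).coords) for a in TYR_RING_ATOMS}
    ce1, cd1, cz = coords["CE1"], coords["CD1"], coords["CZ"]
    # ring least-squares plane normal
    ring = np.stack(list(coords.values()))
    centred = ring - ring.mean(axis=0)
    normal = np.linalg.svd(centred)[2][-1]
    u1 = (cd1 - ce1) / np.linalg.norm(cd1 - ce1)
    u2 = (cz - ce1) / np.linalg.norm(cz - ce1)
    ext = -(u1 + u2)
    ext -= normal * np.dot(ext, normal)  # keep it in-plane
    ext /= np.linalg.norm(ext)
    pos = ce1 + 1.36 * ext
    return (float(pos[0]), float(pos[1]), float(pos[2]))


def apply_dopa(structure: Structure, residue_keys: Iterable[ResKey],
               dopa_resname: str = DOPA_RESNAME) -> Structure:
    """Return a new structure with the selected tyrosines converted to DOPA.

    Each selected residue is renamed and gains one oxygen (``OH3``) bonded
    to CE1; all existing coordinates are untouched.  Keys that are not
    tyrosines (including already-converted residues) are rejected.
    """
    keys = {(k[0], k[1], "") if len(k) == 2 else tuple(k) for k in residue_keys}
    out = structure.copy()
    found: set[ResKey] = set()
    offenders: list[ResKey] = []
    for res in out.residues():
        if res.key in keys:
            found.add(res.key)
            if res.name != "TYR":
                offenders.append(res.key)
                continue
            missing = [a for a in TYR_RING_ATOMS if not res.has_atom(a)]
            if missing:
                raise ValueError(f"residue {res.key} lacks ring atoms {missing}")
            res.name = dopa_resname
            res.add_atom(Atom(name=ADDED_OXYGEN_NAME, element="O",
                              coords=_dopa_oxygen_position(res)))
    not_found = keys - found
    if not_found or offenders:
        raise ValueError(
            f"cannot convert: missing residues {sorted(not_found)}, "
            f"non-tyrosine residues {sorted(offenders)}"
        )
    return out


def modification_pipeline(structure: Structure,
                          sasa_params: Optional[SasaParams] = None,
                          acc_params: Optional[AccessibilityParams] = None,
                          reference_table: Optional[Dict[str, float]] = None,
                          ) -> Tuple[Structure, ModificationReport]:
    """SASA -> relative SASA -> classification -> DOPA conversion, end to end."""
    acc_params = acc_params or AccessibilityParams()
    sasa = compute_sasa(structure, sasa_params)
    sasa = relative_sasa(sasa, structure, reference_table)
    report = classify_tyrosines(structure, sasa, acc_params)
    if report.n_modifiable:
        modified = apply_dopa(structure, report.modifiable_keys)
    else:
        modified = structure.copy()
    return modified, report
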