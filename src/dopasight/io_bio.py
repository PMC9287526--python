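"""Sequence and structure I/O: FASTA records, precursor splitting, PDB v3.3.

The structure model is a plain chain -> residue -> atom hierarchy holding
exactly what the rest of the package needs (names, numbering, coordinates,
occupancy, assigned radii).  Only single-model PDB files are supported;
the first MODEL of a multi-model file is read with a warning.
"""

from __future__ import annotations

import copy
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Optional, Sequence, Tuple

from Bio import SeqIO

logger = logging.getLogger(__name__)

STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")

#: 3-letter -> 1-letter for the standard 20 (used for validation and counting)
THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLU": "E", "GLN": "Q", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

# Two-letter element symbols that can appear in protein-context PDB files.
_TWO_LETTER_ELEMENTS = {"FE", "ZN", "MG", "MN", "CU", "NA", "CL", "CA", "SE", "BR", "NI", "CO"}


class FastaError(ValueError):
    """Malformed or empty FASTA input."""


class PdbError(ValueError):
    """Malformed PDB input or unwritable structure."""


@dataclass(frozen=True)
class SequenceRecord:
    """A named amino-acid sequence with optional signal/mature annotation.

    Ranges are 1-based inclusive ``(start, stop)`` tuples.  If both ranges
    are present they must be disjoint, contiguous and together cover the
    whole sequence.
    """

    identifier: str
    residues: str
    description: str = ""
    signal_range: Optional[Tuple[int, int]] = None
    mature_range: Optional[Tuple[int, int]] = None

    def __post_init__(self) -> None:
        bad = sorted(set(self.residues) - STANDARD_AA)
        if bad:
            raise FastaError(
                f"record {self.identifier!r}: non-standard residue character(s) {bad}"
            )
        if not self.residues:
            raise FastaError(f"record {self.identifier!r}: empty sequence")
        for rng in (self.signal_range, self.mature_range):
            if rng is not None:
                lo, hi = rng
                if not (1 <= lo <= hi <= len(self.residues)):
                    raise FastaError(
                        f"record {self.identifier!r}: range {rng} outside 1..{len(self.residues)}"
                    )
        if self.signal_range is not None and self.mature_range is not None:
            s, m = self.signal_range, self.mature_range
            lo, hi = min(s, m), max(s, m)
            if lo[1] + 1 != hi[0] or lo[0] != 1 or hi[1] != len(self.residues):
                raise FastaError(
                    f"record {self.identifier!r}: signal/mature ranges {s}, {m} "
                    f"must be contiguous and cover 1..{len(self.residues)}"
                )

    def __len__(self) -> int:
        return len(self.residues)

    def subrecord(self, rng: Tuple[int, int], identifier: str, description: str = "") -> "SequenceRecord":
        lo, hi = rng
        return SequenceRecord(identifier, self.residues[lo - 1:hi], description)


@dataclass
class Atom:
    name: str
    element: str
    coords: Tuple[float, float, float]
    occupancy: float = 1.0
    radius: Optional[float] = None
    is_hydrogen: bool = False
    het: bool = False
    serial: int = 0

    def __post_init__(self) -> None:
        if not all(math.isfinite(c) for c in self.coords):
            raise PdbError(f"atom {self.name}: non-finite coordinates {self.coords}")
        if self.radius is not None and self.radius <= 0:
            raise PdbError(f"atom {self.name}: radius must be positive")


@dataclass
class Residue:
    chain_id: str
    seq_number: int
    name: str
    atoms: list[Atom] = field(default_factory=list)
    insertion_code: str = ""

    @property
    def key(self) -> Tuple[str, int, str]:
        return (self.chain_id, self.seq_number, self.insertion_code)

    def atom(self, name: str) -> Atom:
        for a in self.atoms:
            if a.name == name:
                return a
        raise KeyError(f"residue {self.key} has no atom {name!r}")

    def has_atom(self, name: str) -> bool:
        return any(a.name == name for a in self.atoms)

    def add_atom(self, atom: Atom) -> None:
        if self.has_atom(atom.name):
            raise PdbError(f"duplicate atom name {atom.name!r} in residue {self.key}")
        self.atoms.append(atom)


@dataclass
class Chain:
    chain_id: str
    residues: list[Residue] = field(default_factory=list)

    def __iter__(self) -> Iterator[Residue]:
        return iter(self.residues)


@dataclass
class Structure:
    title: str = ""
    chains: list[Chain] = field(default_factory=list)

    def __iter__(self) -> Iterator[Chain]:
        return iter(self.chains)

    def residues(self) -> Iterator[Residue]:
        for chain in self.chains:
            yield from chain.residues

    def atoms(self) -> Iterator[Tuple[Residue, Atom]]:
        for res in self.residues():
            for atom in res.atoms:
                yield res, atom

    def n_atoms(self) -> int:
        return sum(len(r.atoms) for r in self.residues())

    def chain(self, chain_id: str) -> Chain:
        for c in self.chains:
            if c.chain_id == chain_id:
                return c
        raise KeyError(f"no chain {chain_id!r}")

    def get_or_create_chain(self, chain_id: str) -> Chain:
        for c in self.chains:
            if c.chain_id == chain_id:
                return c
        c = Chain(chain_id)
        self.chains.append(c)
        return c

    def residue(self, key: Tuple[str, int, str] | Tuple[str, int]) -> Residue:
        if len(key) == 2:
            key = (key[0], key[1], "")
        for res in self.residues():
            if res.key == key:
                return res
        raise KeyError(f"no residue {key}")

    def copy(self) -> "Structure":
        return copy.deepcopy(self)


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a FASTA file into :class:`SequenceRecord` objects.

    Sequences are uppercased and whitespace-stripped; characters outside
    the 20 standard one-letter codes raise :class:`FastaError` naming the
    offending character and record.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = "".join(str(rec.seq).split()).upper()
        if not seq:
            raise FastaError(f"record {rec.id!r}: empty sequence")
        records.append(SequenceRecord(identifier=rec.id, residues=seq, description=rec.description))
    if not records:
        raise FastaError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Sequence[SequenceRecord], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = rec.identifier if not rec.description or rec.description == rec.identifier else f"{rec.identifier} {rec.description}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i:i + width] + "\n")


def split_precursor(record: SequenceRecord, signal_length: int) -> Tuple[SequenceRecord, SequenceRecord]:
    """Split a precursor into (signal peptide, mature chain) records."""
    n = len(record)
    if not 0 < signal_length < n:
        raise ValueError(
            f"signal_length must be in 1..{n - 1} for {record.identifier!r}, got {signal_length}"
        )
    signal = record.subrecord((1, signal_length), f"{record.identifier}_signal",
                              f"signal peptide 1-{signal_length}")
    mature = record.subrecord((signal_length + 1, n), f"{record.identifier}_mature",
                              f"mature chain {signal_length + 1}-{n}")
    return signal, mature


def count_residue(record: SequenceRecord, amino_acid: str) -> int:
    """Count occurrences of one amino acid (one-letter code) in a record."""
    if len(amino_acid) != 1 or amino_acid.upper() not in STANDARD_AA:
        raise ValueError(f"not a standard one-letter amino-acid code: {amino_acid!r}")
    return record.residues.count(amino_acid.upper())


# ---------------------------------------------------------------------------
# PDB


def _infer_element(atom_name: str) -> str:
    stripped = atom_name.strip()
    if not stripped:
        raise PdbError("blank atom name")
    # Leading digit (e.g. 1HB) marks a hydrogen variant.
    if stripped[0].isdigit():
        return "H"
    two = stripped[:2].upper()
    if two in _TWO_LETTER_ELEMENTS and len(atom_name.strip()) <= 2:
        return two.capitalize()
    return stripped[0].upper()


def read_structure(path: str | Path, allow_nonstandard: bool = True) -> Structure:
    """Parse a PDB v3.3 file (ATOM/HETATM, fixed columns) into a Structure.

    Only the first MODEL is read; altLoc conflicts keep the highest
    occupancy conformer; hydrogens are kept but flagged.
    """
    path = Path(path)
    structure = Structure(title=path.stem)
    in_model = 0
    seen_first_model = False
    # (chain, resnum, icode, atom name) -> (occupancy, Residue index ref)
    altloc_best: dict[tuple, float] = {}
    residues: dict[tuple, Residue] = {}

    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            rec = line[:6]
            if rec == "MODEL ":
                in_model += 1
                if in_model > 1:
                    logger.warning("%s: multiple MODEL blocks; reading first model only", path)
                    break
                seen_first_model = True
                continue
            if rec == "ENDMDL" and seen_first_model:
                break
            if rec == "TITLE ":
                structure.title = (structure.title + " " + line[10:80].strip()).strip()
                continue
            if rec not in ("ATOM  ", "HETATM"):
                continue
            try:
                name = line[12:16].strip()
                altloc = line[16]
                resname = line[17:20].strip()
                chain_id = line[21].strip() or "A"
                resseq = int(line[22:26])
                icode = line[26].strip()
                x = float(line[30:38])
                y = float(line[38:46])
                z = float(line[46:54])
                occ_field = line[54:60].strip()
                occupancy = float(occ_field) if occ_field else 1.0
                elem_field = line[76:78].strip() if len(line) >= 78 else ""
            except ValueError as exc:
                raise PdbError(f"{path}:{lineno}: unreadable coordinate record: {exc}") from exc

            element = elem_field.capitalize() if elem_field else _infer_element(name)
            akey = (chain_id, resseq, icode, name)
            if altloc not in (" ", "") and akey in altloc_best:
                if occupancy <= altloc_best[akey]:
                    continue  # keep the higher-occupancy conformer
                # replace: drop the previously stored atom
                res = residues[(chain_id, resseq, icode)]
                res.atoms = [a for a in res.atoms if a.name != name]
            altloc_best[akey] = occupancy

            rkey = (chain_id, resseq, icode)
            if rkey not in residues:
                residue = Residue(chain_id=chain_id, seq_number=resseq, name=resname,
                                  insertion_code=icode)
                residues[rkey] = residue
                structure.get_or_create_chain(chain_id).residues.append(residue)
            residues[rkey].add_atom(Atom(
                name=name,
                element=element,
                coords=(x, y, z),
                occupancy=occupancy,
                is_hydrogen=(element == "H"),
                het=(rec == "HETATM"),
                serial=len(altloc_best),
            ))

    if structure.n_atoms() == 0:
        raise PdbError(f"{path}: no atoms found")
    if not allow_nonstandard:
        for res in structure.residues():
            if res.name not in THREE_TO_ONE and not all(a.het for a in res.atoms):
                raise PdbError(f"{path}: non-standard residue {res.name} at {res.key} "
                               "(pass allow_nonstandard=True to keep it)")
    return structure


def write_structure(structure: Structure, path: str | Path) -> None:
    """Write a Structure as fixed-width PDB v3.3 ATOM/HETATM records."""
    if structure.n_atoms() == 0:
        raise PdbError("refusing to write an empty structure")
    serial = 0
    with open(path, "w") as fh:
        if structure.title:
            fh.write(f"TITLE     {structure.title[:70]}\n")
        for chain in structure.chains:
            for res in chain.residues:
                for atom in res.atoms:
                    serial += 1
                    if len(atom.name) > 4:
                        raise PdbError(f"atom name {atom.name!r} exceeds 4 characters")
                    # column-13 alignment rule: 1-3 char names start in col 14
                    # unless the name begins with a digit
                    if len(atom.name) == 4 or atom.name[:1].isdigit():
                        name_field = f"{atom.name:<4s}"
                    else:
                        name_field = f" {atom.name:<3s}"
                    rec = "HETATM" if atom.het else "ATOM  "
                    x, y, z = atom.coords
                    fh.write(
                        f"{rec}{serial:>5d} {name_field}{'':1s}{res.name:>3s} "
                        f"{res.chain_id:1s}{res.seq_number:>4d}{res.insertion_code or ' ':1s}   "
                        f"{x:8.3f}{y:8.3f}{z:8.3f}{atom.occupancy:6.2f}{0.0:6.2f}"
                        f"          {atom.element.upper():>2s}\n"
                    )
            fh.write("TER\n")
        fh.write("END\n")
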