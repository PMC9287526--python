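"""Molecular-weight bookkeeping for tyrosine-to-DOPA modification.

Two oxygen-accounting conventions are first-class:

* ``paper``: both hydroxyls of each DOPA count as added mass
  (2 x 16 Da per DOPA), reproducing kDa-scale arithmetic that treats every
  ring OH as newly bound;
* ``chemical``: hydroxylation adds exactly one oxygen per DOPA (+16 Da),
  the standard mass shift for Tyr -> DOPA.

Every result names its convention.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict

from .io_bio import SequenceRecord

logger = logging.getLogger(__name__)

#: Average residue masses (Da) for the 20 standard amino acids
AVERAGE_RESIDUE_MASS: Dict[str, float] = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886, "C": 103.1388,
    "E": 129.1155, "Q": 128.1307, "G": 57.0519, "H": 137.1411, "I": 113.1594,
    "L": 113.1594, "K": 128.1741, "M": 131.1926, "F": 147.1766, "P": 97.1167,
    "S": 87.0782, "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
}

WATER_MASS = 18.0153


def _default_masses() -> Dict[str, float]:
    return dict(AVERAGE_RESIDUE_MASS)


@dataclass(frozen=True)
class MassModel:
    """Parameters of the oxygen-addition mass model.

    ``ow`` is the oxygen atomic weight (16.0 by default so printed kDa
    arithmetic reproduces exactly; 15.9994 available); ``oh_per_dopa`` is
    the number of oxygens booked per DOPA (2 = paper convention,
    1 = chemical convention).
    """

    ow: float = 16.0
    oh_per_dopa: int = 2
    residue_masses: Dict[str, float] = field(default_factory=_default_masses)
    water: float = WATER_MASS

    def __post_init__(self) -> None:
        if self.ow <= 0:
            raise ValueError("oxygen weight must be positive")
        if self.oh_per_dopa not in (1, 2):
            raise ValueError("oh_per_dopa must be 1 (chemical) or 2 (paper)")

    @property
    def convention(self) -> str:
        return "paper" if self.oh_per_dopa == 2 else "chemical"

    @classmethod
    def paper(cls) -> "MassModel":
        return cls(ow=16.0, oh_per_dopa=2)

    @classmethod
    def chemical(cls) -> "MassModel":
        return cls(ow=16.0, oh_per_dopa=1)


@dataclass(frozen=True)
class MassResult:
    uw: float       # unmodified mass, kDa
    n: int          # oxygens added
    mw: float       # modified mass, kDa
    n_dopa: int
    convention: str


def average_mass(record: SequenceRecord, model: MassModel | None = None) -> float:
    """Average molecular mass in Da: sum of residue masses plus one water."""
    model = model or MassModel()
    if not record.residues:
        raise ValueError("empty sequence")
    try:
        total = sum(model.residue_masses[aa] for aa in record.residues)
    except KeyError as exc:
        raise ValueError(f"no mass for residue {exc.args[0]!r}") from exc
    return total + model.water


def modified_mass(uw: float, n_dopa: int, model: MassModel | None = None) -> MassResult:
    """Modified mass in kDa after converting ``n_dopa`` tyrosines to DOPA.

    mw = uw + (ow x n) / 1000 with n = oh_per_dopa x n_dopa.
    """
    model = model or MassModel.paper()
    if uw <= 0:
        raise ValueError("unmodified mass must be positive")
    if n_dopa < 0:
        raise ValueError("n_dopa must be >= 0")
    n = model.oh_per_dopa * n_dopa
    mw = uw + (model.ow * n) / 1000.0
    return MassResult(uw=uw, n=n, mw=mw, n_dopa=n_dopa, convention=model.convention)


def dopa_count_from_delta(delta: float, model: MassModel | None = None) -> int:
    """Infer the DOPA count from a modified-minus-unmodified mass delta (Da)."""
    model = model or MassModel.paper()
    if delta < 0:
        raise ValueError("mass delta must be >= 0")
    per_dopa = model.ow * model.oh_per_dopa
    count = round(delta / per_dopa)
    residual = abs(delta - count * per_dopa)
    if residual > model.ow / 2:
        warnings.warn(
            f"mass delta {delta:.3f} Da leaves residual {residual:.3f} Da "
            f"(> {model.ow / 2:.1f}); DOPA count {count} is uncertain",
            stacklevel=2,
        )
    return count
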