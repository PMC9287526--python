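"""Rule-based DOPA redox state versus pH and qualitative adhesion.

This is an explicit step-function model: catechol (reduced, hydrogen-bond
donating, adhesive) below the oxidation threshold, quinone (auto-oxidized,
non-donating, non-adhesive) above it.  No titration curve is fitted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence


@dataclass(frozen=True)
class PhRules:
    oxidation_pH: float = 6.5       # above: quinone via auto-oxidation
    strong_acid_pH: float = 3.5     # below: expanded-surface regime flag
    hbond_donors_per_catechol: int = 2

    def __post_init__(self) -> None:
        if not (0.0 <= self.strong_acid_pH < self.oxidation_pH <= 14.0):
            raise ValueError(
                f"need 0 <= strong_acid_pH < oxidation_pH <= 14, "
                f"got {self.strong_acid_pH}, {self.oxidation_pH}"
            )
        if self.hbond_donors_per_catechol < 0:
            raise ValueError("hbond_donors_per_catechol must be >= 0")


@dataclass(frozen=True)
class AdhesionAssessment:
    pH: float
    state: str                # "catechol" | "quinone"
    hbond_donors: int
    adhesive: bool
    notes: str = ""


def dopa_state(pH: float, rules: PhRules | None = None) -> str:
    """Redox state of DOPA at a given pH: 'catechol' or 'quinone'."""
    rules = rules or PhRules()
    if not 0.0 <= pH <= 14.0:
        raise ValueError(f"pH must be within 0..14, got {pH}")
    return "catechol" if pH <= rules.oxidation_pH else "quinone"


def assess_adhesion(n_dopa: int, pH: float, rules: PhRules | None = None) -> AdhesionAssessment:
    """Qualitative adhesion call for a structure carrying ``n_dopa`` DOPA."""
    rules = rules or PhRules()
    if n_dopa < 0:
        raise ValueError("n_dopa must be >= 0")
    state = dopa_state(pH, rules)
    donors = n_dopa * rules.hbond_donors_per_catechol if state == "catechol" else 0
    adhesive = state == "catechol" and n_dopa > 0
    notes = []
    if pH < rules.strong_acid_pH:
        notes.append("strong-acid regime: expanded surface expected")
    if state == "quinone":
        notes.append("auto-oxidized: ring oxygens double-bonded, no H-bond donors")
    if n_dopa == 0:
        notes.append("unmodified: behaves identically at all pH")
    return AdhesionAssessment(pH=pH, state=state, hbond_donors=donors,
                              adhesive=adhesive, notes="; ".join(notes))


def ph_series(n_dopa: int, pH_list: Sequence[float],
              rules: PhRules | None = None) -> list[AdhesionAssessment]:
    """Assess adhesion over an ordered pH series (e.g. 3, 5, 7.4, 9)."""
    if not pH_list:
        raise ValueError("pH list must not be empty")
    return [assess_adhesion(n_dopa, pH, rules) for pH in pH_list]
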