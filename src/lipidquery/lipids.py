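"""Glycerophospholipid class knowledge shared by the generator and quantifier.

Diacyl glycerophospholipids are modelled as

    neutral species = head-group/backbone residue + acyl anion 1
                      + acyl anion 2 + H

where the head residue is the composition that, added to the two acyl
anions, reproduces the intact species (for phosphatidylethanolamine this is
C5 H11 O4 N1 P1, i.e. phosphoethanolamine head plus glycerol backbone minus
the two esterified positions).  An n:d fatty-acid moiety yields the acyl
(carboxylate) anion C_n H_{2n-1-2d} O2 in negative-mode fragmentation.

Registered classes: PE (phosphatidylethanolamine) and PG
(phosphatidylglycerol), the two dominant classes of the E. coli lipidome.
Negative-mode precursors are [M-H]-; positive-mode precursors are [M+H]+
for PE and the ammonium adduct [M+NH4]+ for PG, with the characteristic
head-group neutral losses Δ 141.02 (C2H8NO4P) and Δ 189.04 (C3H12NO6P)
respectively.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Tuple

from .chem_core import ElementalComposition, double_bond_equivalents

__all__ = [
    "LipidClass",
    "LIPID_CLASSES",
    "acyl_anion",
    "species_neutral",
    "sum_annotation",
    "neutral_from_ion",
    "annotation_from_ion",
]

_H = ElementalComposition({"H": 1})
_NH4 = ElementalComposition({"N": 1, "H": 4})


@dataclass(frozen=True)
class LipidClass:
    """One diacyl glycerophospholipid class and its ionization chemistry."""

    name: str
    #: head group + glycerol backbone residue (adds to the two acyl anions)
    head_residue: ElementalComposition
    #: composition added to the neutral species in positive mode
    positive_adduct: ElementalComposition
    #: head-group neutral loss of the positive-mode precursor
    positive_neutral_loss: ElementalComposition

    @property
    def positive_loss_mass(self) -> float:
        return self.positive_neutral_loss.mass


LIPID_CLASSES: Dict[str, LipidClass] = {
    "PE": LipidClass(
        name="PE",
        head_residue=ElementalComposition.from_formula("C5 H11 O4 N1 P1"),
        positive_adduct=_H,  # [M+H]+
        positive_neutral_loss=ElementalComposition.from_formula("C2 H8 N1 O4 P1"),
    ),
    "PG": LipidClass(
        name="PG",
        head_residue=ElementalComposition.from_formula("C6 H12 O6 P1"),
        positive_adduct=_NH4,  # [M+NH4]+
        positive_neutral_loss=ElementalComposition.from_formula("C3 H12 N1 O6 P1"),
    ),
}


def acyl_anion(n_carbons: int, double_bonds: int) -> ElementalComposition:
    """Carboxylate anion of an n:d fatty-acid moiety (C_n H_{2n-1-2d} O2)."""
    h = 2 * n_carbons - 1 - 2 * double_bonds
    if n_carbons < 2 or h < 1:
        raise ValueError(f"implausible fatty acid {n_carbons}:{double_bonds}")
    return ElementalComposition({"C": n_carbons, "H": h, "O": 2})


def species_neutral(
    lipid_class: str, fa1: Tuple[int, int], fa2: Tuple[int, int]
) -> ElementalComposition:
    """Neutral composition of a diacyl species, e.g. PE 16:0/17:1 -> C38H74NO8P."""
    cls = LIPID_CLASSES[lipid_class]
    return cls.head_residue + acyl_anion(*fa1) + acyl_anion(*fa2) + _H


def _fmt_db(d: float) -> str:
    return str(int(d)) if float(d).is_integer() else f"{d:g}"


def sum_annotation(lipid_class: str, neutral: ElementalComposition) -> str:
    """Species annotation "Class C:D" from the neutral composition.

    C is the total fatty-acid carbon count (total C minus the head residue's)
    and D the total number of double bonds; for a diacyl species D equals
    the neutral DBE minus the two ester carbonyls.
    """
    cls = LIPID_CLASSES[lipid_class]
    c_total = neutral["C"] - cls.head_residue["C"]
    d_total = double_bond_equivalents(neutral) - 2.0
    return f"{lipid_class} {c_total}:{_fmt_db(d_total)}"


def neutral_from_ion(
    lipid_class: str, ion: ElementalComposition, charge: int
) -> ElementalComposition:
    """Invert the class's ionization: [M-H]- (charge<0) or the positive adduct."""
    cls = LIPID_CLASSES[lipid_class]
    if charge < 0:
        return ion + _H
    if charge > 0:
        return ion - cls.positive_adduct
    return ion


def annotation_from_ion(lipid_class: str, ion: ElementalComposition, charge: int) -> str:
    return sum_annotation(lipid_class, neutral_from_ion(lipid_class, ion, charge))
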