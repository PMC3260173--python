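"""Elemental-composition algebra for shotgun lipidomics.

This module is the numeric foundation of the package: every identification
ultimately reduces to arithmetic over elemental compositions ("sum
compositions" in lipidomics usage).  It provides

* :class:`ElementalComposition` -- integer element counts with element-wise
  addition/subtraction, monoisotopic mass and ion m/z;
* :class:`SumCompositionConstraint` -- per-element count ranges plus a
  double-bond-equivalent (DBE) window and a charge, i.e. the payload of a
  query's ``DEFINE`` clause;
* :func:`enumerate_compositions` -- exhaustive enumeration of all
  compositions inside a constraint box whose ion m/z falls within a mass
  tolerance of an observed peak;
* :func:`isotope_pattern` -- relative isotopologue abundances (M+0, M+1,
  ...) from per-element convolution of natural isotope abundances, used for
  isotopic correction of overlapping species.

Monoisotopic atomic masses and natural isotope abundances are hard-coded
from IUPAC values; no external lookup is performed.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Tuple

import numpy as np

__all__ = [
    "ATOMIC_MASSES",
    "ISOTOPE_ABUNDANCES",
    "ELECTRON_MASS",
    "NEUTRON_MASS_SHIFT",
    "ElementalComposition",
    "SumCompositionConstraint",
    "Tolerance",
    "IsotopePattern",
    "monoisotopic_mass",
    "ion_mz",
    "double_bond_equivalents",
    "enumerate_compositions",
    "isotope_pattern",
]

#: Monoisotopic atomic masses in Da (IUPAC).  Exported constant; extend by
#: adding entries here and in :data:`ISOTOPE_ABUNDANCES`.
ATOMIC_MASSES: Dict[str, float] = {
    "H": 1.00782503207,
    "C": 12.0,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "P": 30.97376163,
    "S": 31.97207100,
}

#: Natural isotope abundances per element, indexed by neutron excess over the
#: lightest isotope (M+0, M+1, M+2).  Fractions, each list sums to ~1.
ISOTOPE_ABUNDANCES: Dict[str, Tuple[float, ...]] = {
    "H": (0.999885, 0.000115),
    "C": (0.9893, 0.0107),
    "N": (0.99636, 0.00364),
    "O": (0.99757, 0.00038, 0.00205),
    "P": (1.0,),
    "S": (0.9499, 0.0075, 0.0425),
}

#: Electron rest mass in Da; subtracted/added when converting a composition
#: to the m/z of its ion.
ELECTRON_MASS = 0.00054858

#: Mass spacing between adjacent isotopologues of carbon-dominated organics
#: (13C - 12C), in Da.  Used to locate M+1, M+2 ... overlaps.
NEUTRON_MASS_SHIFT = 1.00336

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def _check_element(symbol: str) -> None:
    if symbol not in ATOMIC_MASSES:
        raise ValueError(f"unknown element symbol: {symbol!r}")


class ElementalComposition(Mapping[str, int]):
    """Immutable map of element symbol -> non-negative count.

    Supports ``+`` and ``-`` element-wise; subtraction that would produce a
    negative count raises ``ValueError``.  Absent elements read as 0.
    """

    __slots__ = ("_counts", "_hash")

    def __init__(self, counts: Mapping[str, int] | Iterable[Tuple[str, int]] = ()):
        items = dict(counts)
        clean: Dict[str, int] = {}
        for sym, n in items.items():
            _check_element(sym)
            n = int(n)
            if n < 0:
                raise ValueError(f"negative count for element {sym}: {n}")
            if n > 0:
                clean[sym] = n
        # canonical order: C, H, then alphabetical (Hill convention)
        order = sorted(clean, key=lambda s: (s != "C", s != "H", s))
        self._counts: Dict[str, int] = {s: clean[s] for s in order}
        self._hash = hash(tuple(self._counts.items()))

    @classmethod
    def from_formula(cls, formula: str) -> "ElementalComposition":
        """Parse formulas like ``C5H11O4N1P1`` or ``C5 H11 O4 N1 P1``."""
        text = formula.replace(" ", "")
        counts: Dict[str, int] = {}
        pos = 0
        while pos < len(text):
            m = _FORMULA_TOKEN.match(text, pos)
            if not m or m.start() != pos or not m.group(1):
                raise ValueError(f"cannot parse formula {formula!r} at offset {pos}")
            sym, num = m.group(1), m.group(2)
            _check_element(sym)
            counts[sym] = counts.get(sym, 0) + (int(num) if num else 1)
            pos = m.end()
        return cls(counts)

    # Mapping interface -------------------------------------------------
    def __getitem__(self, symbol: str) -> int:
        return self._counts.get(symbol, 0)

    def __iter__(self):
        return iter(self._counts)

    def __len__(self) -> int:
        return len(self._counts)

    def __contains__(self, symbol) -> bool:  # absent element reads as 0 but is not "in"
        return symbol in self._counts

    # algebra ------------------------------------------------------------
    def __add__(self, other: "ElementalComposition") -> "ElementalComposition":
        if not isinstance(other, ElementalComposition):
            return NotImplemented
        merged = dict(self._counts)
        for sym, n in other._counts.items():
            merged[sym] = merged.get(sym, 0) + n
        return ElementalComposition(merged)

    def __sub__(self, other: "ElementalComposition") -> "ElementalComposition":
        if not isinstance(other, ElementalComposition):
            return NotImplemented
        merged = dict(self._counts)
        for sym, n in other._counts.items():
            new = merged.get(sym, 0) - n
            if new < 0:
                raise ValueError(
                    f"subtraction yields negative {sym} count: {self} - {other}"
                )
            merged[sym] = new
        return ElementalComposition(merged)

    def __eq__(self, other) -> bool:
        if not isinstance(other, ElementalComposition):
            return NotImplemented
        return self._counts == other._counts

    def __hash__(self) -> int:
        return self._hash

    def __repr__(self) -> str:
        return f"ElementalComposition({str(self)!r})"

    def __str__(self) -> str:
        if not self._counts:
            return ""
        return " ".join(f"{s}{n}" for s, n in self._counts.items())

    # derived quantities -------------------------------------------------
    @property
    def mass(self) -> float:
        return monoisotopic_mass(self)

    @property
    def dbe(self) -> float:
        return double_bond_equivalents(self)


def monoisotopic_mass(c: Mapping[str, int]) -> float:
    """Monoisotopic mass in Da: sum of count x monoisotopic atomic mass."""
    total = 0.0
    for sym, n in c.items():
        _check_element(sym)
        total += n * ATOMIC_MASSES[sym]
    return total


def ion_mz(c: Mapping[str, int], charge: int) -> float:
    """m/z (Th) of an ion whose *full* atomic composition is ``c``.

    ``c`` must already include/exclude the protons that create the charge;
    this function only accounts for the electron imbalance:
    ``(mass - charge * m_e) / |charge|``.
    """
    if charge == 0:
        raise ValueError("charge must be nonzero; use monoisotopic_mass for neutrals")
    return (monoisotopic_mass(c) - charge * ELECTRON_MASS) / abs(charge)


def double_bond_equivalents(c: Mapping[str, int]) -> float:
    """Double-bond equivalents, DBE = C + 1 - H/2 + (N + P)/2.

    N and P are treated as trivalent.  For odd-electron or deprotonated
    compositions the value is half-integral (e.g. the saturated acyl anion
    C16H31O2 has DBE 1.5).
    """
    get = c.get if hasattr(c, "get") else lambda s, d=0: c[s] if s in c else d
    return get("C", 0) + 1.0 - get("H", 0) / 2.0 + (get("N", 0) + get("P", 0)) / 2.0


@dataclass(frozen=True)
class Tolerance:
    """Mass tolerance, either relative (``ppm``) or absolute (``da``, in Th)."""

    value: float
    unit: str = "ppm"

    def __post_init__(self):
        if self.unit not in ("ppm", "da"):
            raise ValueError(f"tolerance unit must be 'ppm' or 'da', got {self.unit!r}")
        if self.value < 0:
            raise ValueError("tolerance must be nonnegative")

    def window(self, mz: float) -> float:
        """Half-width of the acceptance window at ``mz``, in Th."""
        if self.unit == "ppm":
            return abs(mz) * self.value * 1e-6
        return self.value


_RANGE_TOKEN = re.compile(r"([A-Z][a-z]?)(?:\[(\d+)\.\.(\d+)\]|(\d*))")


@dataclass(frozen=True)
class SumCompositionConstraint:
    """Per-element closed count ranges + DBE range + charge.

    The textual form is shared with the query language, e.g.
    ``C[30..50] H[40..100] N[1..1] O[8..8] P[1..1]``; an exact formula such
    as ``C2 H8 N1 O4 P1`` denotes degenerate one-point ranges.  Charge 0
    denotes a neutral fragment or loss.
    """

    element_ranges: Tuple[Tuple[str, int, int], ...]
    dbr: Tuple[float, float] | None = None
    charge: int = 0

    def __post_init__(self):
        for sym, lo, hi in self.element_ranges:
            _check_element(sym)
            if lo < 0 or hi < lo:
                raise ValueError(f"invalid range for {sym}: [{lo}..{hi}]")
        if self.dbr is not None and self.dbr[0] > self.dbr[1]:
            raise ValueError(f"invalid DBE range: {self.dbr}")

    @classmethod
    def from_string(
        cls,
        pattern: str,
        dbr: Tuple[float, float] | None = None,
        charge: int = 0,
    ) -> "SumCompositionConstraint":
        text = pattern.replace(" ", "")
        ranges: List[Tuple[str, int, int]] = []
        pos = 0
        while pos < len(text):
            m = _RANGE_TOKEN.match(text, pos)
            if not m or m.start() != pos or not m.group(1):
                raise ValueError(f"cannot parse constraint {pattern!r} at offset {pos}")
            sym = m.group(1)
            _check_element(sym)
            if m.group(2) is not None:
                lo, hi = int(m.group(2)), int(m.group(3))
            else:
                n = int(m.group(4)) if m.group(4) else 1
                lo = hi = n
            ranges.append((sym, lo, hi))
            pos = m.end()
        return cls(tuple(ranges), dbr=dbr, charge=charge)

    @property
    def is_exact(self) -> bool:
        return all(lo == hi for _, lo, hi in self.element_ranges)

    def exact_composition(self) -> ElementalComposition:
        if not self.is_exact:
            raise ValueError("constraint has non-degenerate ranges")
        return ElementalComposition({s: lo for s, lo, _ in self.element_ranges})

    def contains(self, c: Mapping[str, int]) -> bool:
        box = {s: (lo, hi) for s, lo, hi in self.element_ranges}
        for sym, n in c.items():
            if sym not in box:
                if n != 0:
                    return False
                continue
            lo, hi = box[sym]
            if not lo <= n <= hi:
                return False
        for sym, (lo, hi) in box.items():
            n = c[sym] if sym in c else 0
            if not lo <= n <= hi:
                return False
        if self.dbr is not None:
            d = double_bond_equivalents(c)
            if not self.dbr[0] - 1e-9 <= d <= self.dbr[1] + 1e-9:
                return False
        return True

    def __str__(self) -> str:
        body = " ".join(f"{s}[{lo}..{hi}]" for s, lo, hi in self.element_ranges)
        return body


def enumerate_compositions(
    mz: float,
    tol: Tolerance,
    constraint: SumCompositionConstraint,
) -> List[ElementalComposition]:
    """All compositions in the constraint box matching an observed m/z.

    A composition qualifies when (a) every element count lies in its range,
    (b) its ion m/z at ``constraint.charge`` (monoisotopic mass when the
    charge is 0, i.e. a neutral loss) lies within ``tol`` of ``mz``, and
    (c) its DBE lies inside the constraint's DBE range, if one is set.
    Results are sorted by absolute mass error, ascending; the enumeration is
    exhaustive over the box (equivalent to brute force, with mass-bound
    pruning for speed).
    """
    ranges = constraint.element_ranges
    if not ranges:
        return []
    charge = constraint.charge
    half = tol.window(mz)
    # target window on the summed atomic mass
    if charge != 0:
        lo_mass = (mz - half) * abs(charge) + charge * ELECTRON_MASS
        hi_mass = (mz + half) * abs(charge) + charge * ELECTRON_MASS
    else:
        lo_mass, hi_mass = mz - half, mz + half

    # heaviest elements first: tighter pruning
    order = sorted(ranges, key=lambda r: -ATOMIC_MASSES[r[0]])
    # min/max achievable mass of the remaining suffix
    n = len(order)
    suffix_min = [0.0] * (n + 1)
    suffix_max = [0.0] * (n + 1)
    for i in range(n - 1, -1, -1):
        sym, lo, hi = order[i]
        suffix_min[i] = suffix_min[i + 1] + lo * ATOMIC_MASSES[sym]
        suffix_max[i] = suffix_max[i + 1] + hi * ATOMIC_MASSES[sym]

    results: List[Tuple[float, ElementalComposition]] = []
    counts: Dict[str, int] = {}

    def recurse(i: int, acc_mass: float) -> None:
        if i == n:
            if lo_mass - 1e-9 <= acc_mass <= hi_mass + 1e-9:
                comp = ElementalComposition(counts)
                if constraint.dbr is not None:
                    d = double_bond_equivalents(comp)
                    if not constraint.dbr[0] - 1e-9 <= d <= constraint.dbr[1] + 1e-9:
                        return
                if charge != 0:
                    obs_err = ion_mz(comp, charge) - mz
                else:
                    obs_err = acc_mass - mz
                results.append((abs(obs_err), comp))
            return
        sym, lo, hi = order[i]
        m = ATOMIC_MASSES[sym]
        for k in range(lo, hi + 1):
            new_mass = acc_mass + k * m
            if new_mass + suffix_max[i + 1] < lo_mass - 1e-9:
                continue
            if new_mass + suffix_min[i + 1] > hi_mass + 1e-9:
                break
            counts[sym] = k
            recurse(i + 1, new_mass)
        counts.pop(sym, None)

    recurse(0, 0.0)
    results.sort(key=lambda t: (t[0], tuple(t[1].items())))
    return [comp for _, comp in results]


@dataclass(frozen=True)
class IsotopePattern:
    """Relative abundances of isotopologues M+0, M+1, ..., normalized to 1."""

    abundances: Tuple[float, ...]

    def __post_init__(self):
        if any(a < 0 for a in self.abundances):
            raise ValueError("isotopologue abundances must be nonnegative")

    def __getitem__(self, k: int) -> float:
        return self.abundances[k]

    def __len__(self) -> int:
        return len(self.abundances)

    def ratio_to_monoisotopic(self, k: int) -> float:
        """Abundance of M+k relative to M+0."""
        return self.abundances[k] / self.abundances[0]


def isotope_pattern(c: Mapping[str, int], n: int = 3) -> IsotopePattern:
    """Isotopologue distribution of a composition, truncated to ``n`` terms.

    Computed by convolving, per element, the ``count``-fold self-convolution
    of that element's natural isotope abundance vector (indexed by neutron
    excess).  The first ``n`` coefficients are exact; the retained vector is
    renormalized to sum to 1.
    """
    if n < 1:
        raise ValueError("need at least one isotopologue")
    pattern = np.zeros(n)
    pattern[0] = 1.0
    for sym, count in c.items():
        if sym not in ISOTOPE_ABUNDANCES:
            raise ValueError(f"unknown element symbol: {sym!r}")
        if count == 0:
            continue
        base = np.zeros(n)
        probs = ISOTOPE_ABUNDANCES[sym][:n]
        base[: len(probs)] = probs
        # count-fold self-convolution by squaring, truncated to n terms
        power = np.zeros(n)
        power[0] = 1.0
        k = count
        cur = base
        while k:
            if k & 1:
                power = np.convolve(power, cur)[:n]
            k >>= 1
            if k:
                cur = np.convolve(cur, cur)[:n]
        pattern = np.convolve(pattern, power)[:n]
    total = pattern.sum()
    if total <= 0:
        raise ValueError("degenerate isotope pattern")
    return IsotopePattern(tuple(pattern / total))
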