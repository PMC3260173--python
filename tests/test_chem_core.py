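"""Composition algebra: masses, m/z, DBE, enumeration, isotope patterns."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lipidquery.chem_core import (
    ATOMIC_MASSES,
    ELECTRON_MASS,
    ISOTOPE_ABUNDANCES,
    ElementalComposition,
    SumCompositionConstraint,
    Tolerance,
    double_bond_equivalents,
    enumerate_compositions,
    ion_mz,
    isotope_pattern,
    monoisotopic_mass,
)

EC = ElementalComposition.from_formula


# ----------------------------------------------------------------------
# composition container
# ----------------------------------------------------------------------

class TestElementalComposition:
    def test_parsing_equivalent_spellings(self):
        assert EC("C5 H11 O4 N1 P1") == EC("C5H11O4N1P1")
        assert EC("H2O")["H"] == 2 and EC("H2O")["O"] == 1

    def test_absent_element_reads_zero(self):
        assert EC("H2O")["C"] == 0

    def test_addition_is_elementwise(self):
        assert EC("C16H31O2") + EC("C17H31O2") == EC("C33H62O4")

    def test_subtraction_below_zero_is_error(self):
        with pytest.raises(ValueError):
            EC("H2O") - EC("H3")

    def test_unknown_element_named_in_error(self):
        with pytest.raises(ValueError, match="Xx"):
            ElementalComposition({"Xx": 1})


# ----------------------------------------------------------------------
# masses and m/z
# ----------------------------------------------------------------------

class TestMass:
    @pytest.mark.parametrize(
        "formula, expected",
        [
            ("", 0.0),
            ("H2O", 18.010565),  # 2 x 1.00782503 + 15.9949146
            ("C2H8NO4P", 141.0191),  # phosphoethanolamine head loss
        ],
    )
    def test_monoisotopic_examples(self, formula, expected):
        assert monoisotopic_mass(EC(formula)) == pytest.approx(expected, abs=5e-5)

    def test_head_group_losses_round_to_published_deltas(self):
        assert round(monoisotopic_mass(EC("C2H8NO4P")), 2) == 141.02
        assert round(monoisotopic_mass(EC("C3H12NO6P")), 2) == 189.04

    @pytest.mark.parametrize(
        "formula, charge, expected",
        [
            ("C16H31O2", -1, 255.2330),
            ("C17H31O2", -1, 267.2330),
            ("C38H73NO8P", -1, 702.5079),
            ("H", +1, 1.00728),
        ],
    )
    def test_ion_mz_examples(self, formula, charge, expected):
        assert ion_mz(EC(formula), charge) == pytest.approx(expected, abs=5e-5)

    def test_ion_mz_rejects_neutral(self):
        with pytest.raises(ValueError):
            ion_mz(EC("H2O"), 0)

    def test_charge_flip_differs_by_two_electrons(self):
        c = EC("C16H31O2")
        assert ion_mz(c, -1) - ion_mz(c, +1) == pytest.approx(
            2 * ELECTRON_MASS, abs=1e-12
        )

    @given(
        st.dictionaries(
            st.sampled_from(sorted(ATOMIC_MASSES)),
            st.integers(0, 60),
            max_size=6,
        ),
        st.dictionaries(
            st.sampled_from(sorted(ATOMIC_MASSES)),
            st.integers(0, 60),
            max_size=6,
        ),
    )
    @settings(max_examples=80, derandomize=True)
    def test_mass_additivity(self, a, b):
        ca, cb = ElementalComposition(a), ElementalComposition(b)
        assert monoisotopic_mass(ca + cb) == pytest.approx(
            monoisotopic_mass(ca) + monoisotopic_mass(cb), abs=1e-9
        )


# ----------------------------------------------------------------------
# double-bond equivalents
# ----------------------------------------------------------------------

@pytest.mark.parametrize(
    "formula, expected",
    [
        ("CH4", 0.0),
        ("C16H31O2", 1.5),  # saturated acyl anion
        ("C17H31O2", 2.5),  # 17:1 acyl anion
        ("C38H73NO8P", 3.5),  # PE 33:1 [M-H]-
    ],
)
def test_double_bond_equivalents(formula, expected):
    assert double_bond_equivalents(EC(formula)) == expected


# ----------------------------------------------------------------------
# enumeration, with brute-force oracle
# ----------------------------------------------------------------------

def brute_force_enumerate(mz, tol, constraint):
    """Naive reference: full product over the constraint box."""
    syms = [s for s, _, _ in constraint.element_ranges]
    ranges = [range(lo, hi + 1) for _, lo, hi in constraint.element_ranges]
    out = []
    for counts in itertools.product(*ranges):
        mass = sum(n * ATOMIC_MASSES[s] for s, n in zip(syms, counts))
        get = dict(zip(syms, counts)).get
        dbe = get("C", 0) + 1 - get("H", 0) / 2 + (get("N", 0) + get("P", 0)) / 2
        if constraint.dbr is not None and not (
            constraint.dbr[0] - 1e-9 <= dbe <= constraint.dbr[1] + 1e-9
        ):
            continue
        if constraint.charge != 0:
            obs = (mass - constraint.charge * ELECTRON_MASS) / abs(constraint.charge)
        else:
            obs = mass
        half = tol.window(mz)
        if mz - half - 1e-9 <= obs <= mz + half + 1e-9:
            out.append(ElementalComposition({s: n for s, n in zip(syms, counts)}))
    return sorted(out, key=lambda c: tuple(c.items()))


class TestEnumeration:
    def test_unique_acyl_anion_match(self):
        k = SumCompositionConstraint.from_string(
            "C[10..20] H[20..40] O[2..2]", dbr=(1.5, 7.5), charge=-1
        )
        assert enumerate_compositions(255.233, Tolerance(5, "ppm"), k) == [
            EC("C16H31O2")
        ]

    def test_empty_box_yields_nothing(self):
        k = SumCompositionConstraint.from_string(
            "C[2..4] H[2..4] O[2..2]", charge=-1
        )
        assert enumerate_compositions(255.233, Tolerance(5, "ppm"), k) == []

    def test_pe_precursor_box(self):
        k = SumCompositionConstraint.from_string(
            "C[30..50] H[40..100] N[1..1] O[8..8] P[1..1]", charge=-1
        )
        assert enumerate_compositions(702.508, Tolerance(5, "ppm"), k) == [
            EC("C38H73NO8P")
        ]

    def test_matches_brute_force_on_random_boxes(self):
        rng = np.random.default_rng(20240917)
        for _ in range(40):
            c_lo = int(rng.integers(0, 30))
            h_lo = int(rng.integers(0, 50))
            o_lo = int(rng.integers(0, 6))
            k = SumCompositionConstraint(
                (
                    ("C", c_lo, c_lo + int(rng.integers(0, 12))),
                    ("H", h_lo, h_lo + int(rng.integers(0, 25))),
                    ("O", o_lo, o_lo + int(rng.integers(0, 4))),
                ),
                dbr=(0.0, 12.0) if rng.random() < 0.5 else None,
                charge=int(rng.choice([-1, 1, 0])),
            )
            mz = float(rng.uniform(50, 900))
            tol = Tolerance(float(rng.uniform(2, 500)), "ppm")
            got = enumerate_compositions(mz, tol, k)
            expected = brute_force_enumerate(mz, tol, k)
            assert sorted(got, key=lambda c: tuple(c.items())) == expected

    def test_results_sorted_by_mass_error(self):
        k = SumCompositionConstraint.from_string(
            "C[1..40] H[1..80] O[0..4]", charge=-1
        )
        got = enumerate_compositions(400.0, Tolerance(0.2, "da"), k)
        errs = [abs(ion_mz(c, -1) - 400.0) for c in got]
        assert errs == sorted(errs)


# ----------------------------------------------------------------------
# isotope patterns, with per-atom brute-force oracle
# ----------------------------------------------------------------------

def brute_force_pattern(comp, n):
    """Expand every atom's isotope choice explicitly (tiny molecules only)."""
    dist = {0: 1.0}
    for sym, count in comp.items():
        probs = ISOTOPE_ABUNDANCES[sym]
        for _ in range(count):
            new = {}
            for shift, p in dist.items():
                for k, pk in enumerate(probs):
                    new[shift + k] = new.get(shift + k, 0.0) + p * pk
            dist = new
    vec = [dist.get(k, 0.0) for k in range(n)]
    total = sum(vec)
    return [v / total for v in vec]


class TestIsotopePattern:
    def test_single_carbon(self):
        assert isotope_pattern(EC("C"), 2).abundances == pytest.approx(
            (0.9893, 0.0107), abs=1e-12
        )

    def test_truncation_renormalizes(self):
        assert isotope_pattern(EC("H2O"), 1).abundances == (1.0,)

    def test_pe_precursor_m1_ratio(self):
        p = isotope_pattern(EC("C38H73NO8P"), 3)
        assert p.ratio_to_monoisotopic(1) == pytest.approx(0.427, abs=0.005)

    @pytest.mark.parametrize("formula", ["C2H2O", "CHNOPS", "C4S2", "H2O2"])
    def test_matches_per_atom_expansion(self, formula):
        comp = EC(formula)
        got = isotope_pattern(comp, 4).abundances
        expected = brute_force_pattern(comp, 4)
        assert got == pytest.approx(expected, abs=1e-12)

    def test_sums_to_one_and_m0_decreases_with_carbon(self):
        prev = 2.0
        for n_c in (1, 10, 20, 40, 80):
            p = isotope_pattern(ElementalComposition({"C": n_c, "H": 10}), 4)
            assert sum(p.abundances) == pytest.approx(1.0, abs=1e-12)
            assert p[0] < prev
            prev = p[0]

    def test_unknown_element_is_error(self):
        with pytest.raises(ValueError):
            isotope_pattern({"Zz": 1}, 2)
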