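"""Query language: parsing, evaluation, soundness and completeness."""

import itertools

import pytest

from lipidquery.chem_core import (
    ATOMIC_MASSES,
    ELECTRON_MASS,
    ElementalComposition,
    ion_mz,
)
from lipidquery.masterscan import MasterScanSettings, PrecursorEntry
from lipidquery.mfql import MfqlError, evaluate_query, parse_mfql, run_queries
from lipidquery.queries import PE_NEGATIVE, PE_NLS_POSITIVE, PG_NEGATIVE

from conftest import make_cluster, make_masterscan

EC = ElementalComposition.from_formula

FIG1_STYLE = """\
QUERYNAME = PE;
DEFINE prPE = 'C[30..50] H[40..100] N[1..1] O[8..8] P[1..1]' WITH DBR = (1.5,7.5), CHG = -1;
DEFINE FA1 = 'C[10..22] H[20..46] O[2..2]' WITH DBR = (1.5,7.5), CHG = -1;
DEFINE FA2 = 'C[10..22] H[20..46] O[2..2]' WITH DBR = (1.5,7.5), CHG = -1;
IDENTIFY prPE IN MS1-, FA1 IN MS2-, FA2 IN MS2-;
SUCHTHAT FA1.chemsc + FA2.chemsc + C5H11O4N1P1 == prPE.chemsc;
REPORT MASS = prPE.mass; CHEMSC = prPE.chemsc; INTENS = prPE.intensity;
"""


class TestParsing:
    def test_pe_query_structure(self):
        q = parse_mfql(FIG1_STYLE)
        assert q.name == "PE"
        assert set(q.defines) == {"prPE", "FA1", "FA2"}
        assert q.defines["prPE"].charge == -1
        assert q.defines["prPE"].dbr == (1.5, 7.5)
        assert q.identify == [("prPE", 1, -1), ("FA1", 2, -1), ("FA2", 2, -1)]
        assert q.suchthat[0] == "cmp" and q.suchthat[1] == "=="
        # left side is the additive chain of the two fragments plus the head
        assert q.suchthat[2][0] == "add"
        assert [c for c, _ in q.report] == ["MASS", "CHEMSC", "INTENS"]

    def test_undefined_variable_named_in_error(self):
        bad = FIG1_STYLE.replace("FA2.chemsc", "FA3.chemsc")
        with pytest.raises(MfqlError, match="FA3"):
            parse_mfql(bad)

    def test_minimal_query(self):
        q = parse_mfql(
            "QUERYNAME = X;\n"
            "DEFINE pr = 'C[1..10] H[1..20]' WITH CHG = -1;\n"
            "IDENTIFY pr IN MS1-;\n"
            "REPORT MASS = pr.mass;\n"
        )
        assert q.suchthat is None
        assert q.defines["pr"].dbr is None

    def test_and_form_of_identify(self):
        q = parse_mfql(
            FIG1_STYLE.replace(
                "IDENTIFY prPE IN MS1-, FA1 IN MS2-, FA2 IN MS2-;",
                "IDENTIFY prPE IN MS1-, FA1 AND FA2 IN MS2-;",
            )
        )
        assert q.identify == [("prPE", 1, -1), ("FA1", 2, -1), ("FA2", 2, -1)]

    def test_syntax_error_reports_location(self):
        with pytest.raises(MfqlError, match="line"):
            parse_mfql("QUERYNAME = ;\n")

    def test_exact_formula_define(self):
        q = parse_mfql(PE_NLS_POSITIVE)
        assert q.defines["nlPE"].is_exact
        assert q.defines["nlPE"].exact_composition() == EC("C2H8NO4P")
        assert q.defines["nlPE"].charge == 0

    def test_builtin_queries_parse(self):
        for text in (PE_NEGATIVE, PG_NEGATIVE, PE_NLS_POSITIVE):
            parse_mfql(text)

    def test_tolerance_override_extension(self):
        q = parse_mfql(
            FIG1_STYLE.replace("QUERYNAME = PE;", "QUERYNAME = PE;\nTOLERANCE = 3 PPM;")
        )
        assert q.tolerance.value == 3.0 and q.tolerance.unit == "ppm"


class TestEvaluation:
    def test_fig1_identification(self, pe_33_1_masterscan):
        q = parse_mfql(FIG1_STYLE)
        records = evaluate_query(q, pe_33_1_masterscan)
        assert len(records) == 1
        r = records[0]
        assert r.annotation == "PE 33:1"
        assert r.molecular_annotation == "PE 16:0/17:1"
        assert r.precursor_composition == EC("C38H73NO8P")
        assert abs(r.err_ppm) < 1e-6
        assert r.report["CHEMSC"] == EC("C38H73NO8P")

    def test_empty_masterscan(self):
        ms = make_masterscan([])
        assert evaluate_query(parse_mfql(FIG1_STYLE), ms) == []

    def test_suchthat_rejects_wrong_fragment_sum(self):
        # 16:0 + 17:0 anions sum to PE 33:0, ~2 Da away from the 33:1 precursor
        prec = make_cluster(ion_mz(EC("C38H73NO8P"), -1), {"S1": 1e5})
        f1 = make_cluster(ion_mz(EC("C16H31O2"), -1), {"S1": 4e4})
        f2 = make_cluster(ion_mz(EC("C17H33O2"), -1), {"S1": 3e4})
        ms = make_masterscan([PrecursorEntry(cluster=prec, fragments=[f1, f2])])
        assert evaluate_query(parse_mfql(FIG1_STYLE), ms) == []

    def test_symmetric_fragment_swap_reported_once(self, pe_33_1_masterscan):
        records = evaluate_query(parse_mfql(FIG1_STYLE), pe_33_1_masterscan)
        assert len(records) == 1

    def test_ms2_query_on_ms1_only_masterscan_warns_empty(self, caplog):
        ms = make_masterscan(
            [PrecursorEntry(cluster=make_cluster(702.5079, {"S1": 1.0}))]
        )
        with caplog.at_level("WARNING"):
            records = evaluate_query(parse_mfql(FIG1_STYLE), ms)
        assert records == []
        assert any("MS2" in m for m in caplog.messages)

    def test_polarity_mismatch_is_error(self, pe_33_1_masterscan):
        q = parse_mfql(FIG1_STYLE.replace("MS1-", "MS1+").replace("MS2-", "MS2+"))
        with pytest.raises(ValueError, match="polarity"):
            evaluate_query(q, pe_33_1_masterscan)

    def test_soundness_suchthat_holds_on_every_record(self, pe_33_1_masterscan):
        q = parse_mfql(FIG1_STYLE)
        head = EC("C5H11O4N1P1")
        for r in evaluate_query(q, pe_33_1_masterscan):
            fa = [r.assignment["FA1"], r.assignment["FA2"]]
            assert fa[0] + fa[1] + head == r.assignment["prPE"]


def brute_force_records(query, ms):
    """Independent oracle: naive product over all composition tuples.

    Enumerates every composition in each variable's constraint box with a
    plain itertools product, pairs MS1 variables with each precursor
    cluster and MS2 variables with every attached fragment cluster, and
    keeps the tuples whose compositions satisfy the additivity constraint
    re-implemented directly.  Returns canonical (precursor composition,
    sorted fragment compositions) pairs.
    """

    def box(constraint):
        syms = [s for s, _, _ in constraint.element_ranges]
        ranges = [range(lo, hi + 1) for _, lo, hi in constraint.element_ranges]
        for counts in itertools.product(*ranges):
            comp = dict(zip(syms, counts))
            dbe = (
                comp.get("C", 0)
                + 1
                - comp.get("H", 0) / 2
                + (comp.get("N", 0) + comp.get("P", 0)) / 2
            )
            if constraint.dbr and not (
                constraint.dbr[0] - 1e-9 <= dbe <= constraint.dbr[1] + 1e-9
            ):
                continue
            yield ElementalComposition(comp)

    def matches(comp, constraint, mz, tol):
        mass = sum(n * ATOMIC_MASSES[s] for s, n in comp.items())
        if constraint.charge:
            obs = (mass - constraint.charge * ELECTRON_MASS) / abs(constraint.charge)
        else:
            obs = mass
        return abs(obs - mz) <= tol.window(mz) + 1e-9

    head = EC("C5H11O4N1P1")
    found = set()
    tol1 = ms.settings.ms1_tolerance
    tol2 = ms.settings.ms2_tolerance
    for entry in ms.entries:
        pre_candidates = [
            c
            for c in box(query.defines["prPE"])
            if matches(c, query.defines["prPE"], entry.cluster.mz, tol1)
        ]
        frag_candidates = [
            c
            for frag in entry.fragments
            for c in box(query.defines["FA1"])
            if matches(c, query.defines["FA1"], frag.mz, tol2)
        ]
        for pre in pre_candidates:
            for fa1, fa2 in itertools.product(frag_candidates, repeat=2):
                if fa1 + fa2 + head == pre:
                    found.add(
                        (
                            tuple(pre.items()),
                            tuple(sorted(tuple(f.items()) for f in (fa1, fa2))),
                        )
                    )
    return found


class TestCompleteness:
    def test_equals_brute_force_on_small_masterscan(self):
        entries = []
        # three precursors: PE 33:1 with matching fragments, PE 34:1
        # (16:0/18:1), and a decoy with non-additive fragments
        for prec_formula, frag_formulas in [
            ("C38H73NO8P", ["C16H31O2", "C17H31O2"]),
            ("C39H75NO8P", ["C16H31O2", "C18H33O2"]),
            ("C38H71NO8P", ["C14H27O2", "C18H35O2"]),  # sums to 33:2's box? no
        ]:
            prec = make_cluster(ion_mz(EC(prec_formula), -1), {"S1": 1e4})
            frags = [
                make_cluster(ion_mz(EC(f), -1), {"S1": 1e3}) for f in frag_formulas
            ]
            entries.append(PrecursorEntry(cluster=prec, fragments=frags))
        ms = make_masterscan(entries)
        q = parse_mfql(FIG1_STYLE)
        got = {
            (
                tuple(r.assignment["prPE"].items()),
                tuple(
                    sorted(
                        tuple(r.assignment[v].items()) for v in ("FA1", "FA2")
                    )
                ),
            )
            for r in evaluate_query(q, ms)
        }
        assert got == brute_force_records(q, ms)
        assert len(got) == 2  # the decoy's fragments sum 2 Da short


class TestRunQueries:
    def test_mixed_classes_in_one_list(self, pe_query, pg_query):
        pe_prec = make_cluster(ion_mz(EC("C38H73NO8P"), -1), {"S1": 1e4})
        pe_frags = [
            make_cluster(ion_mz(EC("C16H31O2"), -1), {"S1": 1e3}),
            make_cluster(ion_mz(EC("C17H31O2"), -1), {"S1": 1e3}),
        ]
        pg_prec = make_cluster(ion_mz(EC("C40H76O10P"), -1), {"S1": 2e4})
        pg_frags = [
            make_cluster(ion_mz(EC("C16H31O2"), -1), {"S1": 1e3}),
            make_cluster(ion_mz(EC("C18H33O2"), -1), {"S1": 1e3}),
        ]
        ms = make_masterscan(
            [
                PrecursorEntry(cluster=pe_prec, fragments=pe_frags),
                PrecursorEntry(cluster=pg_prec, fragments=pg_frags),
            ]
        )
        records = run_queries([pe_query, pg_query], ms)
        assert {r.annotation for r in records} == {"PE 33:1", "PG 34:1"}

    def test_same_query_twice_reports_twice(self, pe_query, pe_33_1_masterscan):
        records = run_queries([pe_query, pe_query], pe_33_1_masterscan)
        assert len(records) == 2

    def test_zero_queries(self, pe_33_1_masterscan):
        assert run_queries([], pe_33_1_masterscan) == []

    def test_determinism(self, pe_query, pg_query, pe_33_1_masterscan):
        a = run_queries([pe_query, pg_query], pe_33_1_masterscan)
        b = run_queries([pe_query, pg_query], pe_33_1_masterscan)
        assert [(r.annotation, r.precursor_mz, r.intensities) for r in a] == [
            (r.annotation, r.precursor_mz, r.intensities) for r in b
        ]
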