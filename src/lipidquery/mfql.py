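"""Molecular-fragmentation query language (MFQL) dialect.

A query names a lipid class and declares, in four sections, how to
recognize it in the MasterScan::

    QUERYNAME = PE;
    DEFINE prPE = 'C[29..55] H[30..100] N[1..1] O[8..8] P[1..1]'
        WITH DBR = (2.0,15.0), CHG = -1;
    DEFINE FA1 = 'C[10..24] H[10..48] O[2..2]' WITH DBR = (1.0,8.0), CHG = -1;
    DEFINE FA2 = 'C[10..24] H[10..48] O[2..2]' WITH DBR = (1.0,8.0), CHG = -1;
    IDENTIFY prPE IN MS1-, FA1 IN MS2-, FA2 IN MS2-;
    SUCHTHAT FA1.chemsc + FA2.chemsc + C5H11O4N1P1 == prPE.chemsc;
    REPORT MASS = prPE.mass; CHEMSC = prPE.chemsc; INTENS = prPE.intensity;

``DEFINE`` binds a variable to a sum-composition constraint (element count
ranges, double-bond-equivalent range DBR, charge CHG; charge 0 declares a
*neutral loss*).  ``IDENTIFY`` places variables in a spectrum context
(MS1+/MS1-/MS2+/MS2-).  ``SUCHTHAT`` is an arithmetic/boolean expression
over variable attributes (``chemsc``, ``mass``, ``intensity``,
``errppm``); composition equality is exact element-wise equality.
``REPORT`` lists output columns.  An optional ``TOLERANCE = <x> PPM;`` (or
``DA``) right after ``QUERYNAME`` overrides the MasterScan tolerance for
that query — a dialect extension.

The grammar is a defined dialect: faithful to the published keyword set
and attribute names, but scripts written for other engines are not
guaranteed to parse.
"""

from __future__ import annotations

import itertools
import logging
import re
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

from . import lipids
from .chem_core import (
    ElementalComposition,
    SumCompositionConstraint,
    Tolerance,
    enumerate_compositions,
    ion_mz,
)
from .masterscan import MasterScan, PeakCluster, PrecursorEntry

logger = logging.getLogger(__name__)

__all__ = [
    "QueryAst",
    "IdentificationRecord",
    "MfqlError",
    "parse_mfql",
    "evaluate_query",
    "run_queries",
]

ATTRIBUTES = ("chemsc", "mass", "intensity", "errppm")


class MfqlError(ValueError):
    """Lexical, syntax or semantic error in a query script."""

    def __init__(self, message: str, line: int | None = None, col: int | None = None):
        loc = f" (line {line}, column {col})" if line is not None else ""
        super().__init__(message + loc)
        self.line = line
        self.col = col


# ----------------------------------------------------------------------
# AST
# ----------------------------------------------------------------------

@dataclass
class QueryAst:
    """Parsed query: DEFINE bindings, IDENTIFY contexts, SUCHTHAT, REPORT."""

    name: str
    defines: Dict[str, SumCompositionConstraint]
    identify: List[Tuple[str, int, int]]  # (variable, ms_level, polarity)
    suchthat: Optional[tuple] = None  # expression tree
    report: List[Tuple[str, tuple]] = field(default_factory=list)
    tolerance: Optional[Tolerance] = None

    def context_of(self, var: str) -> Tuple[int, int]:
        for v, level, pol in self.identify:
            if v == var:
                return level, pol
        raise KeyError(var)


@dataclass
class FragmentMatch:
    """One fragment variable's assignment within a record."""

    variable: str
    composition: ElementalComposition
    cluster: PeakCluster
    err_ppm: Optional[float]
    is_neutral_loss: bool = False


@dataclass
class IdentificationRecord:
    """One species matched by one query on one precursor cluster."""

    query: str
    lipid_class: str
    precursor_mz: float
    precursor_composition: ElementalComposition
    charge: int
    polarity: int
    err_ppm: Optional[float]
    annotation: str
    molecular_annotation: Optional[str]
    intensities: Dict[str, float]
    fragments: List[FragmentMatch] = field(default_factory=list)
    fragment_intensities: Dict[str, Dict[str, float]] = field(default_factory=dict)
    report: Dict[str, object] = field(default_factory=dict)
    flags: List[str] = field(default_factory=list)
    assignment: Dict[str, ElementalComposition] = field(default_factory=dict)


# ----------------------------------------------------------------------
# lexer
# ----------------------------------------------------------------------

_TOKEN_RE = re.compile(
    r"""
    (?P<ws>\s+)
  | (?P<comment>\#[^\n]*)
  | (?P<number>\d+\.\d+|\.\d+|\d+)
  | (?P<string>'[^']*')
  | (?P<ident>[A-Za-z_][A-Za-z0-9_]*)
  | (?P<op>==|!=|<=|>=|[=<>+\-*(),;.\[\]])
    """,
    re.VERBOSE,
)

KEYWORDS = {
    "QUERYNAME", "DEFINE", "WITH", "DBR", "CHG", "IDENTIFY", "IN",
    "SUCHTHAT", "REPORT", "AND", "OR", "NOT", "TOLERANCE", "PPM", "DA",
}


@dataclass(frozen=True)
class _Token:
    kind: str  # 'number' | 'string' | 'ident' | 'op' | 'kw' | 'eof'
    value: str
    line: int
    col: int


def _tokenize(text: str) -> List[_Token]:
    tokens: List[_Token] = []
    line, col, pos = 1, 1, 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if not m or m.start() != pos:
            raise MfqlError(f"unexpected character {text[pos]!r}", line, col)
        kind = m.lastgroup
        value = m.group()
        if kind not in ("ws", "comment"):
            if kind == "ident" and value.upper() in KEYWORDS:
                tokens.append(_Token("kw", value.upper(), line, col))
            else:
                tokens.append(_Token(kind, value, line, col))
        newlines = value.count("\n")
        if newlines:
            line += newlines
            col = len(value) - value.rfind("\n")
        else:
            col += len(value)
        pos = m.end()
    tokens.append(_Token("eof", "", line, col))
    return tokens


# ----------------------------------------------------------------------
# parser
# ----------------------------------------------------------------------

class _Parser:
    def __init__(self, text: str):
        self.tokens = _tokenize(text)
        self.pos = 0
        self.defines: Dict[str, SumCompositionConstraint] = {}

    # token helpers ------------------------------------------------------
    @property
    def cur(self) -> _Token:
        return self.tokens[self.pos]

    def _advance(self) -> _Token:
        tok = self.cur
        self.pos += 1
        return tok

    def _expect(self, kind: str, value: Optional[str] = None) -> _Token:
        tok = self.cur
        if tok.kind != kind or (value is not None and tok.value != value):
            want = value or kind
            raise MfqlError(f"expected {want!r}, found {tok.value!r}", tok.line, tok.col)
        return self._advance()

    def _accept(self, kind: str, value: Optional[str] = None) -> Optional[_Token]:
        tok = self.cur
        if tok.kind == kind and (value is None or tok.value == value):
            return self._advance()
        return None

    # grammar ------------------------------------------------------------
    def parse(self) -> QueryAst:
        self._expect("kw", "QUERYNAME")
        self._expect("op", "=")
        name = self._expect("ident").value
        self._expect("op", ";")

        tolerance = None
        if self._accept("kw", "TOLERANCE"):
            self._expect("op", "=")
            value = float(self._expect("number").value)
            unit_tok = self._expect("kw")
            if unit_tok.value not in ("PPM", "DA"):
                raise MfqlError(
                    f"tolerance unit must be PPM or DA, found {unit_tok.value!r}",
                    unit_tok.line, unit_tok.col,
                )
            tolerance = Tolerance(value, unit_tok.value.lower())
            self._expect("op", ";")

        if self.cur.kind != "kw" or self.cur.value != "DEFINE":
            raise MfqlError("query must contain at least one DEFINE",
                            self.cur.line, self.cur.col)
        while self._accept("kw", "DEFINE"):
            self._parse_define()

        self._expect("kw", "IDENTIFY")
        identify = self._parse_identify()

        suchthat = None
        if self._accept("kw", "SUCHTHAT"):
            suchthat = self._parse_or()
            self._expect("op", ";")

        self._expect("kw", "REPORT")
        report: List[Tuple[str, tuple]] = []
        while True:
            col = self._expect("ident").value
            self._expect("op", "=")
            expr = self._parse_or()
            self._expect("op", ";")
            report.append((col, expr))
            if self.cur.kind != "ident":
                break
        self._expect("eof")

        ast = QueryAst(
            name=name,
            defines=self.defines,
            identify=identify,
            suchthat=suchthat,
            report=report,
            tolerance=tolerance,
        )
        self._validate(ast)
        return ast

    def _parse_define(self) -> None:
        name_tok = self._expect("ident")
        if name_tok.value in self.defines:
            raise MfqlError(f"variable {name_tok.value!r} defined twice",
                            name_tok.line, name_tok.col)
        self._expect("op", "=")
        pat_tok = self._expect("string")
        pattern = pat_tok.value.strip("'")
        self._expect("kw", "WITH")
        dbr = None
        if self._accept("kw", "DBR"):
            self._expect("op", "=")
            self._expect("op", "(")
            lo = self._parse_signed_number()
            self._expect("op", ",")
            hi = self._parse_signed_number()
            self._expect("op", ")")
            dbr = (lo, hi)
            self._expect("op", ",")
        self._expect("kw", "CHG")
        self._expect("op", "=")
        charge = int(self._parse_signed_number())
        self._expect("op", ";")
        try:
            constraint = SumCompositionConstraint.from_string(
                pattern, dbr=dbr, charge=charge
            )
        except ValueError as exc:
            raise MfqlError(str(exc), pat_tok.line, pat_tok.col) from exc
        self.defines[name_tok.value] = constraint

    def _parse_signed_number(self) -> float:
        sign = 1.0
        if self._accept("op", "-"):
            sign = -1.0
        elif self._accept("op", "+"):
            pass
        return sign * float(self._expect("number").value)

    def _parse_identify(self) -> List[Tuple[str, int, int]]:
        clauses: List[Tuple[str, int, int]] = []
        while True:
            names = [self._expect("ident").value]
            while self._accept("kw", "AND"):
                names.append(self._expect("ident").value)
            self._expect("kw", "IN")
            level, pol = self._parse_context()
            for n in names:
                clauses.append((n, level, pol))
            if not self._accept("op", ","):
                break
        self._expect("op", ";")
        return clauses

    def _parse_context(self) -> Tuple[int, int]:
        tok = self._expect("ident")
        if tok.value not in ("MS1", "MS2"):
            raise MfqlError(f"expected spectrum context MS1/MS2, found {tok.value!r}",
                            tok.line, tok.col)
        level = 1 if tok.value == "MS1" else 2
        sign = self._accept("op", "+") or self._accept("op", "-")
        if not sign:
            raise MfqlError("spectrum context needs a polarity sign (+/-)",
                            tok.line, tok.col)
        return level, (1 if sign.value == "+" else -1)

    # expressions --------------------------------------------------------
    def _parse_or(self) -> tuple:
        node = self._parse_and()
        while self._accept("kw", "OR"):
            node = ("or", node, self._parse_and())
        return node

    def _parse_and(self) -> tuple:
        node = self._parse_not()
        while self._accept("kw", "AND"):
            node = ("and", node, self._parse_not())
        return node

    def _parse_not(self) -> tuple:
        if self._accept("kw", "NOT"):
            return ("not", self._parse_not())
        return self._parse_comparison()

    def _parse_comparison(self) -> tuple:
        left = self._parse_additive()
        tok = self.cur
        if tok.kind == "op" and tok.value in ("==", "=", "!=", "<=", ">=", "<", ">"):
            self._advance()
            op = "==" if tok.value == "=" else tok.value
            right = self._parse_additive()
            return ("cmp", op, left, right)
        if tok.kind == "kw" and tok.value == "IN":
            self._advance()
            self._expect("op", "(")
            members = [self._parse_additive()]
            while self._accept("op", ","):
                members.append(self._parse_additive())
            self._expect("op", ")")
            return ("member", left, members)
        return left

    def _parse_additive(self) -> tuple:
        node = self._parse_multiplicative()
        while True:
            if self._accept("op", "+"):
                node = ("add", node, self._parse_multiplicative())
            elif self._accept("op", "-"):
                node = ("sub", node, self._parse_multiplicative())
            else:
                return node

    def _parse_multiplicative(self) -> tuple:
        node = self._parse_unary()
        while self._accept("op", "*"):
            node = ("mul", node, self._parse_unary())
        return node

    def _parse_unary(self) -> tuple:
        if self._accept("op", "-"):
            return ("neg", self._parse_unary())
        return self._parse_primary()

    def _parse_primary(self) -> tuple:
        tok = self.cur
        if tok.kind == "number":
            self._advance()
            return ("num", float(tok.value))
        if self._accept("op", "("):
            node = self._parse_or()
            self._expect("op", ")")
            return node
        if tok.kind == "ident":
            self._advance()
            if self._accept("op", "."):
                attr = self._expect("ident").value
                if attr not in ATTRIBUTES:
                    raise MfqlError(
                        f"unknown attribute {attr!r}; expected one of {ATTRIBUTES}",
                        tok.line, tok.col,
                    )
                if tok.value not in self.defines:
                    raise MfqlError(f"undefined variable {tok.value!r}",
                                    tok.line, tok.col)
                return ("attr", tok.value, attr)
            if tok.value in self.defines:
                raise MfqlError(
                    f"variable {tok.value!r} needs an attribute (e.g. "
                    f"{tok.value}.chemsc)", tok.line, tok.col,
                )
            try:
                comp = ElementalComposition.from_formula(tok.value)
            except ValueError:
                raise MfqlError(f"undefined variable {tok.value!r}",
                                tok.line, tok.col) from None
            return ("comp", comp)
        raise MfqlError(f"unexpected token {tok.value!r}", tok.line, tok.col)

    def _validate(self, ast: QueryAst) -> None:
        identified = {v for v, _, _ in ast.identify}
        for v in identified:
            if v not in ast.defines:
                raise MfqlError(f"undefined variable {v!r} in IDENTIFY")
        ms1_vars = [v for v, lvl, _ in ast.identify if lvl == 1]
        if not ms1_vars:
            raise MfqlError("query must IDENTIFY at least one variable in MS1")
        pols = {pol for _, _, pol in ast.identify}
        if len(pols) > 1:
            raise MfqlError("cross-polarity joins within one query are not supported")

        def walk(node: tuple) -> None:
            if node[0] == "attr":
                if node[1] not in identified:
                    raise MfqlError(
                        f"variable {node[1]!r} used but not placed by IDENTIFY"
                    )
            for child in node[1:]:
                if isinstance(child, tuple):
                    walk(child)
                elif isinstance(child, list):
                    for c in child:
                        walk(c)

        if ast.suchthat:
            walk(ast.suchthat)
        for _, expr in ast.report:
            walk(expr)


def parse_mfql(text: str) -> QueryAst:
    """Parse one query script into a :class:`QueryAst`.

    Raises :class:`MfqlError` with line/column on lexical or syntax errors,
    on undefined variables and on malformed composition constraints.
    """
    return _Parser(text).parse()


# ----------------------------------------------------------------------
# evaluation
# ----------------------------------------------------------------------

@dataclass
class _Binding:
    composition: ElementalComposition
    cluster: PeakCluster
    err_ppm: Optional[float]
    is_neutral_loss: bool


def _eval(node: tuple, env: Dict[str, _Binding], sample: Optional[str] = None):
    kind = node[0]
    if kind == "num":
        return node[1]
    if kind == "comp":
        return node[1]
    if kind == "attr":
        b = env[node[1]]
        attr = node[2]
        if attr == "chemsc":
            return b.composition
        if attr == "mass":
            return b.cluster.mz
        if attr == "errppm":
            return b.err_ppm if b.err_ppm is not None else 0.0
        if attr == "intensity":
            if sample is not None:
                return b.cluster.per_sample_intensity.get(sample, 0.0)
            return b.cluster.total_intensity
        raise MfqlError(f"unknown attribute {attr!r}")
    if kind in ("add", "sub", "mul"):
        left = _eval(node[1], env, sample)
        right = _eval(node[2], env, sample)
        if isinstance(left, ElementalComposition) or isinstance(
            right, ElementalComposition
        ):
            if not (
                isinstance(left, ElementalComposition)
                and isinstance(right, ElementalComposition)
            ):
                raise MfqlError("cannot mix compositions and numbers in arithmetic")
            if kind == "add":
                return left + right
            if kind == "sub":
                return left - right
            raise MfqlError("compositions cannot be multiplied")
        return {"add": left + right, "sub": left - right, "mul": left * right}[kind]
    if kind == "neg":
        val = _eval(node[1], env, sample)
        if isinstance(val, ElementalComposition):
            raise MfqlError("cannot negate a composition")
        return -val
    if kind == "cmp":
        op = node[1]
        left = _eval(node[2], env, sample)
        right = _eval(node[3], env, sample)
        comp_left = isinstance(left, ElementalComposition)
        comp_right = isinstance(right, ElementalComposition)
        if comp_left or comp_right:
            if op not in ("==", "!="):
                raise MfqlError("compositions only support (in)equality comparison")
            if not (comp_left and comp_right):
                return op == "!="
            return (left == right) if op == "==" else (left != right)
        return {
            "==": left == right,
            "!=": left != right,
            "<": left < right,
            ">": left > right,
            "<=": left <= right,
            ">=": left >= right,
        }[op]
    if kind == "member":
        val = _eval(node[1], env, sample)
        return any(val == _eval(m, env, sample) for m in node[2])
    if kind == "and":
        return bool(_eval(node[1], env, sample)) and bool(_eval(node[2], env, sample))
    if kind == "or":
        return bool(_eval(node[1], env, sample)) or bool(_eval(node[2], env, sample))
    if kind == "not":
        return not bool(_eval(node[1], env, sample))
    raise MfqlError(f"unknown expression node {kind!r}")


def _expr_uses_intensity(node: tuple) -> bool:
    if node[0] == "attr" and node[2] == "intensity":
        return True
    for child in node[1:]:
        if isinstance(child, tuple) and _expr_uses_intensity(child):
            return True
        if isinstance(child, list) and any(_expr_uses_intensity(c) for c in child):
            return True
    return False


def _is_acyl_anion(comp: ElementalComposition, charge: int) -> Optional[Tuple[int, int]]:
    """(n, d) when the composition is an acyl (carboxylate) anion, else None."""
    if charge != -1 or set(comp) - {"C", "H", "O"}:
        return None
    if comp["O"] != 2:
        return None
    n = comp["C"]
    d2 = 2 * n - 1 - comp["H"]  # = 2 * double bonds
    if n < 2 or d2 < 0 or d2 % 2:
        return None
    return n, d2 // 2


def _fmt_fa(n: int, d: int) -> str:
    return f"{n}:{d}"


def _annotate(
    query_name: str,
    precursor: _Binding,
    charge: int,
    fragments: List[FragmentMatch],
) -> Tuple[str, Optional[str]]:
    cls = query_name
    fa_list = []
    for fm in fragments:
        if fm.is_neutral_loss:
            continue
        fa = _is_acyl_anion(fm.composition, -1)
        if fa is None:
            fa_list = None
            break
        fa_list.append(fa)
    molecular = None
    if fa_list:
        total_c = sum(n for n, _ in fa_list)
        total_d = sum(d for _, d in fa_list)
        annotation = f"{cls} {total_c}:{total_d}"
        molecular = f"{cls} " + "/".join(_fmt_fa(n, d) for n, d in sorted(fa_list))
        return annotation, molecular
    if cls in lipids.LIPID_CLASSES:
        try:
            return lipids.annotation_from_ion(cls, precursor.composition, charge), None
        except (ValueError, KeyError):
            pass
    return f"{cls} {precursor.composition}", None


def evaluate_query(query: QueryAst, ms: MasterScan) -> List[IdentificationRecord]:
    """Run one parsed query against a MasterScan.

    For every precursor cluster, the MS1 variables are assigned all
    compositions inside their constraint within tolerance of the cluster
    m/z; MS2 variables draw candidates from the fragment clusters attached
    to that precursor (charge-0 variables match the *neutral loss*
    precursor minus fragment).  One record is emitted per variable
    assignment that satisfies the SUCHTHAT expression, symmetric duplicate
    assignments (swapped equivalent fragment variables) collapsed to one.
    """
    pols = {pol for _, _, pol in query.identify}
    if pols and pols != {ms.polarity}:
        raise ValueError(
            f"query {query.name!r} expects polarity {sorted(pols)}, "
            f"MasterScan holds {ms.polarity}"
        )
    ms1_vars = [v for v, lvl, _ in query.identify if lvl == 1]
    ms2_vars = [v for v, lvl, _ in query.identify if lvl == 2]
    if ms2_vars and not ms.has_ms2:
        logger.warning(
            "query %s needs MS2 spectra but the MasterScan has none", query.name
        )
        return []

    tol1 = query.tolerance or ms.settings.ms1_tolerance
    tol2 = query.tolerance or ms.settings.ms2_tolerance
    tol1_virtual = ms.settings.virtual_precursor_tolerance
    tol_virtual = ms.settings.virtual_fragment_tolerance

    records: List[IdentificationRecord] = []
    seen: set = set()

    for entry in ms.entries:
        pcluster = entry.cluster
        candidates: Dict[str, List[_Binding]] = {}
        feasible = True
        for var in ms1_vars:
            constraint = query.defines[var]
            tol_p = tol1_virtual if pcluster.virtual else tol1
            comps = enumerate_compositions(pcluster.mz, tol_p, constraint)
            binds = []
            for comp in comps:
                theo = ion_mz(comp, constraint.charge) if constraint.charge else comp.mass
                err = (pcluster.mz - theo) / theo * 1e6
                binds.append(_Binding(comp, pcluster, err, False))
            if not binds:
                feasible = False
                break
            candidates[var] = binds
        if not feasible:
            continue
        for var in ms2_vars:
            constraint = query.defines[var]
            binds = []
            for frag in entry.fragments:
                tol = tol_virtual if frag.virtual else tol2
                if constraint.charge == 0:
                    loss = pcluster.mz - frag.mz
                    if loss <= 0:
                        continue
                    comps = enumerate_compositions(loss, tol, constraint)
                    for comp in comps:
                        binds.append(_Binding(comp, frag, None, True))
                else:
                    comps = enumerate_compositions(frag.mz, tol, constraint)
                    for comp in comps:
                        if frag.virtual:
                            err = None
                        else:
                            theo = ion_mz(comp, constraint.charge)
                            err = (frag.mz - theo) / theo * 1e6
                        binds.append(_Binding(comp, frag, err, False))
            if not binds:
                feasible = False
                break
            candidates[var] = binds
        if not feasible:
            continue

        var_order = ms1_vars + ms2_vars
        for combo in itertools.product(*(candidates[v] for v in var_order)):
            env = dict(zip(var_order, combo))
            if query.suchthat is not None and not _eval(query.suchthat, env):
                continue
            # canonical key: symmetric in variables sharing constraint+context
            key_parts = []
            groups: Dict[tuple, List[tuple]] = {}
            for v in var_order:
                b = env[v]
                sig = (str(query.defines[v]), query.defines[v].charge,
                       query.context_of(v))
                groups.setdefault(sig, []).append(
                    (tuple(b.composition.items()), round(b.cluster.mz, 9))
                )
            for sig in sorted(groups, key=str):
                key_parts.append((sig, tuple(sorted(groups[sig]))))
            key = (id(entry), tuple(key_parts))
            if key in seen:
                continue
            seen.add(key)

            prec_var = ms1_vars[0]
            prec = env[prec_var]
            charge = query.defines[prec_var].charge
            frag_matches = [
                FragmentMatch(
                    variable=v,
                    composition=env[v].composition,
                    cluster=env[v].cluster,
                    err_ppm=env[v].err_ppm,
                    is_neutral_loss=env[v].is_neutral_loss,
                )
                for v in ms2_vars
            ]
            annotation, molecular = _annotate(query.name, prec, charge, frag_matches)
            report: Dict[str, object] = {}
            for col, expr in query.report:
                if _expr_uses_intensity(expr):
                    report[col] = {
                        s: _eval(expr, env, sample=s) for s in ms.samples
                    }
                else:
                    report[col] = _eval(expr, env)
            # the species' per-sample intensities are the first intensity-
            # bearing REPORT expression (so e.g. a neutral-loss query can
            # quantify by its class-specific loss fragment); default is the
            # precursor cluster signal
            intensities = dict(pcluster.per_sample_intensity)
            for col, expr in query.report:
                if _expr_uses_intensity(expr):
                    intensities = dict(report[col])
                    break
            records.append(
                IdentificationRecord(
                    query=query.name,
                    lipid_class=query.name,
                    precursor_mz=pcluster.mz,
                    precursor_composition=prec.composition,
                    charge=charge,
                    polarity=ms.polarity,
                    err_ppm=prec.err_ppm,
                    annotation=annotation,
                    molecular_annotation=molecular,
                    intensities=intensities,
                    fragments=frag_matches,
                    fragment_intensities={
                        fm.variable: dict(fm.cluster.per_sample_intensity)
                        for fm in frag_matches
                    },
                    report=report,
                    flags=(["virtual_precursor"] if pcluster.virtual else []),
                    assignment={v: env[v].composition for v in var_order},
                )
            )

    records.sort(
        key=lambda r: (r.precursor_mz, abs(r.err_ppm or 0.0), r.annotation)
    )
    return records


def run_queries(
    queries: Sequence[QueryAst], ms: MasterScan
) -> List[IdentificationRecord]:
    """Execute queries in order and concatenate their records.

    Queries are independent: running the same query twice reports its
    records twice.  Within a query, duplicate variable assignments are
    already collapsed by :func:`evaluate_query`.
    """
    out: List[IdentificationRecord] = []
    for q in queries:
        out.extend(evaluate_query(q, ms))
    return out
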