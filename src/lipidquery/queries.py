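"""Built-in query scripts for the PE and PG classes.

Negative-mode queries identify the [M-H]- precursor together with the two
acyl-anion fragments and demand that the fragment sum compositions plus
the class's head-group/backbone residue add up to the precursor's sum
composition; they work unchanged on DDA MasterScans and on MasterScans
built from transposed precursor-ion scans.  Positive-mode queries identify
the protonated (PE) or ammoniated (PG) precursor by its characteristic
head-group neutral loss and are meant for transposed neutral-loss scans.

The constraint boxes cover diacyl species with chain lengths 24-44 total
carbons and up to 6 double bonds per fatty acid.
"""

from __future__ import annotations

from typing import Dict

__all__ = [
    "PE_NEGATIVE",
    "PG_NEGATIVE",
    "PE_NLS_POSITIVE",
    "PG_NLS_POSITIVE",
    "BUILTIN_QUERIES",
]

PE_NEGATIVE = """\
QUERYNAME = PE;
DEFINE prPE = 'C[29..55] H[30..100] N[1..1] O[8..8] P[1..1]' WITH DBR = (2.0,15.0), CHG = -1;
DEFINE FA1 = 'C[10..24] H[10..48] O[2..2]' WITH DBR = (1.0,8.0), CHG = -1;
DEFINE FA2 = 'C[10..24] H[10..48] O[2..2]' WITH DBR = (1.0,8.0), CHG = -1;
IDENTIFY prPE IN MS1-, FA1 IN MS2-, FA2 IN MS2-;
SUCHTHAT FA1.chemsc + FA2.chemsc + C5H11O4N1P1 == prPE.chemsc;
REPORT MASS = prPE.mass; CHEMSC = prPE.chemsc; INTENS = prPE.intensity;
"""

PG_NEGATIVE = """\
QUERYNAME = PG;
DEFINE prPG = 'C[30..52] H[30..100] O[10..10] P[1..1]' WITH DBR = (2.0,15.0), CHG = -1;
DEFINE FA1 = 'C[10..24] H[10..48] O[2..2]' WITH DBR = (1.0,8.0), CHG = -1;
DEFINE FA2 = 'C[10..24] H[10..48] O[2..2]' WITH DBR = (1.0,8.0), CHG = -1;
IDENTIFY prPG IN MS1-, FA1 IN MS2-, FA2 IN MS2-;
SUCHTHAT FA1.chemsc + FA2.chemsc + C6H12O6P1 == prPG.chemsc;
REPORT MASS = prPG.mass; CHEMSC = prPG.chemsc; INTENS = prPG.intensity;
"""

PE_NLS_POSITIVE = """\
QUERYNAME = PE;
DEFINE prPE = 'C[29..55] H[30..105] N[1..1] O[8..8] P[1..1]' WITH DBR = (1.0,14.0), CHG = 1;
DEFINE nlPE = 'C2 H8 N1 O4 P1' WITH CHG = 0;
IDENTIFY prPE IN MS1+, nlPE IN MS2+;
REPORT MASS = prPE.mass; CHEMSC = prPE.chemsc; INTENS = nlPE.intensity;
"""

PG_NLS_POSITIVE = """\
QUERYNAME = PG;
DEFINE prPG = 'C[30..52] H[30..110] N[1..1] O[10..10] P[1..1]' WITH DBR = (0.0,13.0), CHG = 1;
DEFINE nlPG = 'C3 H12 N1 O6 P1' WITH CHG = 0;
IDENTIFY prPG IN MS1+, nlPG IN MS2+;
REPORT MASS = prPG.mass; CHEMSC = prPG.chemsc; INTENS = nlPG.intensity;
"""

BUILTIN_QUERIES: Dict[str, str] = {
    "pe_negative": PE_NEGATIVE,
    "pg_negative": PG_NEGATIVE,
    "pe_nls_positive": PE_NLS_POSITIVE,
    "pg_nls_positive": PG_NLS_POSITIVE,
}
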