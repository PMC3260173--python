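"""Shared fixtures: hand-built MasterScans and parsed built-in queries."""

import pytest

from lipidquery.chem_core import ElementalComposition, Tolerance, ion_mz
from lipidquery.masterscan import (
    MasterScan,
    MasterScanSettings,
    PeakCluster,
    PrecursorEntry,
)
from lipidquery.mfql import parse_mfql
from lipidquery.queries import PE_NEGATIVE, PG_NEGATIVE


def make_cluster(mz, intensities, n_samples=None, virtual=False):
    n = n_samples or len(intensities)
    occ = sum(1 for v in intensities.values() if v > 0) / n
    return PeakCluster(
        mz=mz,
        per_sample_intensity=dict(intensities),
        occupancy=occ,
        member_count=len(intensities),
        virtual=virtual,
    )


def make_masterscan(entries, polarity=-1, samples=("S1",), settings=None):
    return MasterScan(
        settings=settings or MasterScanSettings(),
        polarity=polarity,
        samples=list(samples),
        entries=entries,
    )


@pytest.fixture
def pe_query():
    return parse_mfql(PE_NEGATIVE)


@pytest.fixture
def pg_query():
    return parse_mfql(PG_NEGATIVE)


@pytest.fixture
def pe_33_1_masterscan():
    """One PE 33:1 precursor (m/z 702.508) with its 16:0/17:1 acyl anions."""
    prec = make_cluster(
        ion_mz(ElementalComposition.from_formula("C38H73NO8P"), -1), {"S1": 1e5}
    )
    f1 = make_cluster(
        ion_mz(ElementalComposition.from_formula("C16H31O2"), -1), {"S1": 4e4}
    )
    f2 = make_cluster(
        ion_mz(ElementalComposition.from_formula("C17H31O2"), -1), {"S1": 3e4}
    )
    entry = PrecursorEntry(cluster=prec, fragments=[f1, f2])
    return make_masterscan([entry])
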