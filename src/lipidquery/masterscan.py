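"""Scan merging, cross-sample peak alignment and the MasterScan database.

The MasterScan is the experiment-wide flat database: repeated scans from
each sample are first merged into one representative spectrum, then peaks
are aligned across samples into clusters.  Each cluster keeps the single
intensity-weighted average m/z while the per-sample intensities are
preserved unchanged.  Two experiment-wide constraints prune the database:
a minimal intensity and an occupancy threshold (the fraction of samples in
which a peak must have been observed; 1.0 keeps only peaks seen in every
sample).

Grouping uses one deterministic greedy rule throughout: clusters are seeded
from peaks in descending intensity order; a peak joins the seed's cluster
when it lies within the resolution-dependent tolerance of the seed m/z; a
source (scan or sample) contributes at most one peak per cluster, the
nearest in m/z winning, and displaced peaks re-enter the pool.
"""

from __future__ import annotations

import json
from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Dict, Hashable, List, Optional, Sequence, Tuple

from .chem_core import Tolerance
from .spectra_io import Peak, Scan

__all__ = [
    "ResolutionModel",
    "PeakCluster",
    "PrecursorEntry",
    "MasterScanSettings",
    "MasterScan",
    "tolerance_at",
    "merge_scans",
    "align_across_samples",
    "apply_thresholds",
    "build_masterscan",
    "save_masterscan",
    "load_masterscan",
    "greedy_group",
]


@dataclass(frozen=True)
class ResolutionModel:
    """Linear FWHM resolution model R(m) = r0 + slope * (m - m_ref)."""

    r0: float
    slope: float = 0.0
    m_ref: float = 0.0

    def resolution(self, mz: float) -> float:
        return self.r0 + self.slope * (mz - self.m_ref)


def tolerance_at(model: ResolutionModel, mz: float) -> float:
    """Grouping tolerance Δm = mz / R(mz), in Th."""
    r = model.resolution(mz)
    if r <= 0:
        raise ValueError(f"nonpositive resolution {r} at m/z {mz}")
    return mz / r


@dataclass
class PeakCluster:
    """One aligned peak across samples.

    ``mz`` is the intensity-weighted average of the member peaks; the
    per-sample intensities are kept as acquired.  ``occupancy`` is the
    fraction of the experiment's samples contributing nonzero intensity.
    """

    mz: float
    per_sample_intensity: Dict[str, float]
    occupancy: float
    member_count: int
    virtual: bool = False

    @property
    def max_intensity(self) -> float:
        return max(self.per_sample_intensity.values(), default=0.0)

    @property
    def total_intensity(self) -> float:
        return sum(self.per_sample_intensity.values())


@dataclass
class PrecursorEntry:
    """One precursor-level cluster and its attached fragment clusters.

    ``virtual`` precursors have no matching survey-MS1 cluster: either the
    dataset contains no survey scans at all (transposed PIS/NLS data) or an
    MS/MS scan's isolation window matched no MS1 peak.
    """

    cluster: PeakCluster
    fragments: List[PeakCluster] = field(default_factory=list)

    @property
    def virtual(self) -> bool:
        return self.cluster.virtual


@dataclass
class MasterScanSettings:
    """Instrument and filtering settings baked into a MasterScan."""

    ms1_resolution: ResolutionModel = ResolutionModel(r0=7500.0, m_ref=700.0)
    ms2_resolution: ResolutionModel = ResolutionModel(r0=7500.0, m_ref=700.0)
    ms1_tolerance: Tolerance = Tolerance(10.0, "ppm")
    ms2_tolerance: Tolerance = Tolerance(15.0, "ppm")
    #: virtual precursor/fragment axes come from unit-resolution instruments,
    #: so identification against them uses absolute windows
    virtual_precursor_tolerance: Tolerance = Tolerance(0.05, "da")
    virtual_fragment_tolerance: Tolerance = Tolerance(0.1, "da")
    precursor_window: float = 0.5  # Th; unit-resolution isolation
    min_intensity: float = 0.0
    min_occupancy: float = 0.0
    occupancy_unit: str = "samples"  # or "scans"

    def __post_init__(self):
        if not 0.0 <= self.min_occupancy <= 1.0:
            raise ValueError("occupancy threshold must lie in [0, 1]")
        if self.occupancy_unit not in ("samples", "scans"):
            raise ValueError("occupancy_unit must be 'samples' or 'scans'")


@dataclass
class MasterScan:
    """Aligned precursor clusters with attached fragment clusters."""

    settings: MasterScanSettings
    polarity: int
    samples: List[str]
    entries: List[PrecursorEntry]
    version: int = 1

    @property
    def ms1_clusters(self) -> List[PeakCluster]:
        return [e.cluster for e in self.entries if not e.virtual]

    @property
    def has_ms2(self) -> bool:
        return any(e.fragments for e in self.entries)


# ----------------------------------------------------------------------
# greedy grouping primitive
# ----------------------------------------------------------------------

def greedy_group(
    items: Sequence[Tuple[float, float, Hashable, object]],
    tol_fn: Callable[[float], float],
    one_per_source: bool = True,
) -> List[List[Tuple[float, float, Hashable, object]]]:
    """Group (mz, intensity, source, payload) tuples by the greedy rule.

    Seeds are taken in descending intensity (ties: ascending m/z); every
    unassigned item within ``tol_fn(seed_mz)`` of the seed joins, except
    that with ``one_per_source`` a source keeps only its item nearest to
    the seed; displaced items stay in the pool for later seeds.
    """
    n = len(items)
    order_mz = sorted(range(n), key=lambda i: (items[i][0], i))
    mzs = [items[i][0] for i in order_mz]
    assigned = [False] * n
    groups: List[List[Tuple[float, float, Hashable, object]]] = []
    for seed in sorted(range(n), key=lambda i: (-items[i][1], items[i][0], i)):
        if assigned[seed]:
            continue
        seed_mz = items[seed][0]
        tol = tol_fn(seed_mz)
        lo = bisect_left(mzs, seed_mz - tol)
        hi = bisect_right(mzs, seed_mz + tol)
        members: Dict[Hashable, int] = {}
        free: List[int] = []
        for pos in range(lo, hi):
            idx = order_mz[pos]
            if assigned[idx]:
                continue
            src = items[idx][2]
            if not one_per_source:
                free.append(idx)
                continue
            prev = members.get(src)
            if prev is None:
                members[src] = idx
            else:
                # nearest to the seed wins; the displaced peak re-enters the pool
                if abs(items[idx][0] - seed_mz) < abs(items[prev][0] - seed_mz):
                    members[src] = idx
        chosen = free if not one_per_source else list(members.values())
        for idx in chosen:
            assigned[idx] = True
        groups.append([items[i] for i in sorted(chosen)])
    return groups


def _weighted_mz(pairs: Sequence[Tuple[float, float]]) -> float:
    total = sum(w for _, w in pairs)
    if total <= 0:
        return sum(m for m, _ in pairs) / len(pairs)
    return sum(m * w for m, w in pairs) / total


# ----------------------------------------------------------------------
# merging and alignment
# ----------------------------------------------------------------------

def merge_scans(scans: Sequence[Scan], model: ResolutionModel) -> Scan:
    """Merge repeated scans of one sample into a representative spectrum.

    Within each scan, peaks closer than the resolution tolerance are first
    combined (intensity-weighted m/z, summed intensity); matching peaks are
    then grouped across scans, each group becoming one peak at the
    intensity-weighted mean m/z with the arithmetic mean of the per-scan
    intensities over the scans in which it appears.  Intensity thresholds
    are applied later, at the MasterScan stage, not here.
    """
    if not scans:
        raise ValueError("no scans to merge")
    first = scans[0]
    for s in scans[1:]:
        same = (
            s.sample_id == first.sample_id
            and s.ms_level == first.ms_level
            and s.mode == first.mode
            and s.polarity == first.polarity
            and s.monitored_fragment_mz == first.monitored_fragment_mz
            and s.neutral_loss_delta == first.neutral_loss_delta
        )
        if not same:
            raise ValueError("cannot merge scans with mixed metadata")
    tol_fn = lambda m: tolerance_at(model, m)

    # stage 1: collapse near-coincident peaks within each scan
    per_scan: List[List[Tuple[float, float]]] = []
    for s in scans:
        items = [(p.mz, p.intensity, id(p), None) for p in s.peaks]
        groups = greedy_group(items, tol_fn, one_per_source=False)
        collapsed = [
            (_weighted_mz([(m, i) for m, i, _, _ in g]), sum(i for _, i, _, _ in g))
            for g in groups
            if g
        ]
        per_scan.append(collapsed)

    # stage 2: group across scans, one peak per scan per group
    items = [
        (m, i, scan_idx, None)
        for scan_idx, collapsed in enumerate(per_scan)
        for m, i in collapsed
    ]
    groups = greedy_group(items, tol_fn, one_per_source=True)
    merged = []
    for g in groups:
        if not g:
            continue
        mz = _weighted_mz([(m, i) for m, i, _, _ in g])
        intensity = sum(i for _, i, _, _ in g) / len(g)
        merged.append(Peak(mz, intensity))
    rep = replace(first, peaks=sorted(merged, key=lambda p: p.mz))
    return rep


def align_across_samples(
    per_sample: Dict[str, Scan],
    model: ResolutionModel,
    n_samples_experiment: Optional[int] = None,
    virtual: bool = False,
) -> List[PeakCluster]:
    """Align representative spectra of different samples into clusters.

    The cluster m/z is the intensity-weighted mean over all member peaks;
    per-sample intensities are preserved unchanged.  ``occupancy`` is
    computed against ``n_samples_experiment`` (default: the number of
    samples passed in).
    """
    if not per_sample:
        raise ValueError("need at least one sample")
    denom = n_samples_experiment or len(per_sample)
    tol_fn = lambda m: tolerance_at(model, m)
    items = [
        (p.mz, p.intensity, sid, None)
        for sid in sorted(per_sample)
        for p in per_sample[sid].peaks
    ]
    groups = greedy_group(items, tol_fn, one_per_source=True)
    clusters = []
    for g in groups:
        if not g:
            continue
        mz = _weighted_mz([(m, i) for m, i, _, _ in g])
        intensities = {src: i for _, i, src, _ in g}
        occ = sum(1 for v in intensities.values() if v > 0) / denom
        clusters.append(
            PeakCluster(
                mz=mz,
                per_sample_intensity=dict(sorted(intensities.items())),
                occupancy=occ,
                member_count=len(g),
                virtual=virtual,
            )
        )
    clusters.sort(key=lambda c: c.mz)
    return clusters


def apply_thresholds(
    clusters: Sequence[PeakCluster],
    min_intensity: float,
    min_occupancy: float,
) -> List[PeakCluster]:
    """Drop clusters below the intensity or occupancy constraint.

    A cluster survives when its maximal per-sample intensity reaches
    ``min_intensity`` and its occupancy reaches ``min_occupancy``; an
    occupancy threshold of 1.0 keeps only peaks observed in every sample.
    """
    if not 0.0 <= min_occupancy <= 1.0:
        raise ValueError("occupancy threshold must lie in [0, 1]")
    return [
        c
        for c in clusters
        if c.max_intensity >= min_intensity and c.occupancy >= min_occupancy - 1e-12
    ]


# ----------------------------------------------------------------------
# building
# ----------------------------------------------------------------------

def _merge_per_sample(
    scans: Sequence[Scan], model: ResolutionModel
) -> Dict[str, Scan]:
    by_sample: Dict[str, List[Scan]] = {}
    for s in scans:
        by_sample.setdefault(s.sample_id, []).append(s)
    return {sid: merge_scans(ss, model) for sid, ss in sorted(by_sample.items())}


def build_masterscan(
    scans: Sequence[Scan], settings: Optional[MasterScanSettings] = None
) -> MasterScan:
    """Assemble the MasterScan from all scans of an experiment.

    Survey MS1 scans are merged per sample and aligned into precursor
    clusters.  Full MS/MS scans (including virtual ones from PIS/NLS
    transposition) are grouped by precursor m/z within the isolation
    window, merged and aligned per group, and attached to the nearest MS1
    cluster; groups with no MS1 match become virtual precursors carrying
    the summed fragment signal (or the recorded precursor intensity) per
    sample.  Intensity/occupancy thresholds are applied per MS level.
    """
    if settings is None:
        settings = MasterScanSettings()
    scans = [s for s in scans if s.mode == "full"]
    if not scans:
        raise ValueError("no full-mode scans; transpose PIS/NLS data first")
    polarities = {s.polarity for s in scans}
    if len(polarities) != 1:
        raise ValueError("mixed polarities in one MasterScan")
    polarity = polarities.pop()
    samples = sorted({s.sample_id for s in scans})
    n_samples = len(samples)

    occupancy_denominator = n_samples
    if settings.occupancy_unit == "scans":
        occupancy_denominator = max(
            n_samples, len([s for s in scans if s.ms_level == 1]) or n_samples
        )

    ms1_scans = [s for s in scans if s.ms_level == 1]
    ms2_scans = [s for s in scans if s.ms_level == 2]

    ms1_clusters: List[PeakCluster] = []
    if ms1_scans:
        reps = _merge_per_sample(ms1_scans, settings.ms1_resolution)
        ms1_clusters = align_across_samples(
            reps, settings.ms1_resolution, occupancy_denominator
        )
        ms1_clusters = apply_thresholds(
            ms1_clusters, settings.min_intensity, settings.min_occupancy
        )

    entries = [PrecursorEntry(cluster=c) for c in ms1_clusters]
    ms1_mzs = [c.mz for c in ms1_clusters]

    # group MS2 scans by precursor m/z within the isolation window
    if ms2_scans:
        for s in ms2_scans:
            if s.precursor_mz is None:
                raise ValueError("full MS/MS scan without precursor m/z")
        items = [
            (s.precursor_mz, s.precursor_intensity or s.total_intensity, i, s)
            for i, s in enumerate(ms2_scans)
        ]
        groups = greedy_group(
            items, lambda m: settings.precursor_window, one_per_source=False
        )
        for g in sorted(groups, key=lambda g: min(t[0] for t in g) if g else 0.0):
            if not g:
                continue
            group_scans = [t[3] for t in g]
            group_mz = _weighted_mz([(m, w) for m, w, _, _ in g])
            any_virtual = any(s.virtual for s in group_scans)
            reps = _merge_per_sample(group_scans, settings.ms2_resolution)
            frags = align_across_samples(
                reps,
                settings.ms2_resolution,
                occupancy_denominator,
                virtual=any_virtual,
            )
            frags = apply_thresholds(
                frags, settings.min_intensity, settings.min_occupancy
            )
            if not frags:
                continue
            # attach to the nearest MS1 cluster within the isolation window
            target: Optional[PrecursorEntry] = None
            if ms1_mzs:
                pos = bisect_left(ms1_mzs, group_mz)
                best, best_d = None, settings.precursor_window
                for j in (pos - 1, pos):
                    if 0 <= j < len(ms1_mzs):
                        d = abs(ms1_mzs[j] - group_mz)
                        if d <= best_d:
                            best, best_d = j, d
                if best is not None:
                    target = entries[best]
            if target is None:
                # virtual precursor: per-sample intensity from the recorded
                # precursor signal, falling back to the summed fragment signal
                per_sample: Dict[str, float] = {}
                for s in group_scans:
                    val = (
                        s.precursor_intensity
                        if s.precursor_intensity is not None
                        else s.total_intensity
                    )
                    per_sample[s.sample_id] = per_sample.get(s.sample_id, 0.0) + val
                occ = sum(1 for v in per_sample.values() if v > 0) / occupancy_denominator
                cluster = PeakCluster(
                    mz=group_mz,
                    per_sample_intensity=dict(sorted(per_sample.items())),
                    occupancy=occ,
                    member_count=len(group_scans),
                    virtual=True,
                )
                target = PrecursorEntry(cluster=cluster)
                entries.append(target)
            target.fragments.extend(frags)

    for e in entries:
        e.fragments.sort(key=lambda c: c.mz)
    entries.sort(key=lambda e: e.cluster.mz)
    return MasterScan(
        settings=settings, polarity=polarity, samples=samples, entries=entries
    )


# ----------------------------------------------------------------------
# persistence (versioned JSON container)
# ----------------------------------------------------------------------

_FORMAT = "lipidquery-masterscan"
_VERSION = 1


def _cluster_to_dict(c: PeakCluster) -> dict:
    return {
        "mz": c.mz,
        "per_sample_intensity": c.per_sample_intensity,
        "occupancy": c.occupancy,
        "member_count": c.member_count,
        "virtual": c.virtual,
    }


def _cluster_from_dict(d: dict) -> PeakCluster:
    return PeakCluster(
        mz=d["mz"],
        per_sample_intensity=dict(d["per_sample_intensity"]),
        occupancy=d["occupancy"],
        member_count=d["member_count"],
        virtual=d["virtual"],
    )


def save_masterscan(ms: MasterScan, path: str | Path) -> None:
    s = ms.settings
    doc = {
        "format": _FORMAT,
        "version": _VERSION,
        "polarity": ms.polarity,
        "samples": ms.samples,
        "settings": {
            "ms1_resolution": [s.ms1_resolution.r0, s.ms1_resolution.slope, s.ms1_resolution.m_ref],
            "ms2_resolution": [s.ms2_resolution.r0, s.ms2_resolution.slope, s.ms2_resolution.m_ref],
            "ms1_tolerance": [s.ms1_tolerance.value, s.ms1_tolerance.unit],
            "ms2_tolerance": [s.ms2_tolerance.value, s.ms2_tolerance.unit],
            "virtual_precursor_tolerance": [
                s.virtual_precursor_tolerance.value,
                s.virtual_precursor_tolerance.unit,
            ],
            "virtual_fragment_tolerance": [
                s.virtual_fragment_tolerance.value,
                s.virtual_fragment_tolerance.unit,
            ],
            "precursor_window": s.precursor_window,
            "min_intensity": s.min_intensity,
            "min_occupancy": s.min_occupancy,
            "occupancy_unit": s.occupancy_unit,
        },
        "entries": [
            {
                "cluster": _cluster_to_dict(e.cluster),
                "fragments": [_cluster_to_dict(f) for f in e.fragments],
            }
            for e in ms.entries
        ],
    }
    Path(path).write_text(json.dumps(doc))


def load_masterscan(path: str | Path) -> MasterScan:
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ValueError(f"{path}: truncated or corrupt MasterScan file") from exc
    if doc.get("format") != _FORMAT:
        raise ValueError(f"{path}: not a MasterScan container")
    if doc.get("version") != _VERSION:
        raise ValueError(
            f"{path}: MasterScan format version {doc.get('version')} is not "
            f"supported (this build reads version {_VERSION})"
        )
    sd = doc["settings"]
    settings = MasterScanSettings(
        ms1_resolution=ResolutionModel(*sd["ms1_resolution"]),
        ms2_resolution=ResolutionModel(*sd["ms2_resolution"]),
        ms1_tolerance=Tolerance(*sd["ms1_tolerance"]),
        ms2_tolerance=Tolerance(*sd["ms2_tolerance"]),
        virtual_precursor_tolerance=Tolerance(*sd["virtual_precursor_tolerance"]),
        virtual_fragment_tolerance=Tolerance(*sd["virtual_fragment_tolerance"]),
        precursor_window=sd["precursor_window"],
        min_intensity=sd["min_intensity"],
        min_occupancy=sd["min_occupancy"],
        occupancy_unit=sd["occupancy_unit"],
    )
    entries = [
        PrecursorEntry(
            cluster=_cluster_from_dict(e["cluster"]),
            fragments=[_cluster_from_dict(f) for f in e["fragments"]],
        )
        for e in doc["entries"]
    ]
    return MasterScan(
        settings=settings,
        polarity=doc["polarity"],
        samples=list(doc["samples"]),
        entries=entries,
        version=doc["version"],
    )
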