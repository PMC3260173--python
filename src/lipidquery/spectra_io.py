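"""Reading and writing of shotgun spectra and results tables.

Supported inputs are centroided mzXML (read through pyteomics) and
two-column plain-text peak lists (.csv with sniffed delimiter, .dta with
the conventional "precursorMass charge" first line).  Outputs are the
results table (.csv) and a JSON scan container used by the CLI to pass
scan lists between pipeline stages.
"""

from __future__ import annotations

import base64
import csv
import json
import struct
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import pandas as pd
from pyteomics import mzxml as _mzxml

__all__ = [
    "Peak",
    "Scan",
    "read_mzxml",
    "write_mzxml",
    "read_peaklist",
    "write_results_csv",
    "save_scans",
    "load_scans",
]


@dataclass(frozen=True)
class Peak:
    """One centroided peak: m/z in Th, intensity in arbitrary units >= 0."""

    mz: float
    intensity: float

    def __post_init__(self):
        if self.mz <= 0:
            raise ValueError(f"peak m/z must be positive, got {self.mz}")
        if self.intensity < 0:
            raise ValueError(f"peak intensity must be >= 0, got {self.intensity}")


@dataclass
class Scan:
    """One acquisition event (MS1 survey, MS/MS, PIS or NLS scan).

    ``mode`` is ``full`` for survey and full MS/MS scans, ``pis`` for
    precursor-ion scans (``monitored_fragment_mz`` set) and ``nls`` for
    neutral-loss scans (``neutral_loss_delta`` set).  Virtual MS/MS scans
    produced by transposing PIS/NLS data carry ``virtual=True`` and a
    ``provenance`` note; NLS-derived fragments additionally record the loss
    Δ per peak in ``loss_deltas``.
    """

    sample_id: str
    ms_level: int
    polarity: int
    mode: str = "full"
    precursor_mz: Optional[float] = None
    precursor_intensity: Optional[float] = None
    monitored_fragment_mz: Optional[float] = None
    neutral_loss_delta: Optional[float] = None
    peaks: List[Peak] = field(default_factory=list)
    scan_index: int = 0
    virtual: bool = False
    provenance: Tuple[str, ...] = ()
    loss_deltas: Optional[Tuple[Optional[float], ...]] = None

    def __post_init__(self):
        if self.ms_level not in (1, 2):
            raise ValueError(f"ms_level must be 1 or 2, got {self.ms_level}")
        if self.polarity not in (1, -1):
            raise ValueError(f"polarity must be +1 or -1, got {self.polarity}")
        if self.mode not in ("full", "pis", "nls"):
            raise ValueError(f"unknown scan mode {self.mode!r}")
        if self.mode == "pis" and self.monitored_fragment_mz is None:
            raise ValueError("pis scan requires monitored_fragment_mz")
        if self.mode == "nls" and self.neutral_loss_delta is None:
            raise ValueError("nls scan requires neutral_loss_delta")
        if self.mode != "pis" and self.monitored_fragment_mz is not None:
            raise ValueError("monitored_fragment_mz only valid for mode='pis'")
        if self.mode != "nls" and self.neutral_loss_delta is not None:
            raise ValueError("neutral_loss_delta only valid for mode='nls'")
        self.peaks = sorted(self.peaks, key=lambda p: p.mz)

    @property
    def total_intensity(self) -> float:
        return sum(p.intensity for p in self.peaks)


# ----------------------------------------------------------------------
# mzXML
# ----------------------------------------------------------------------

def read_mzxml(path: str | Path, sample_id: Optional[str] = None) -> List[Scan]:
    """Read a centroided mzXML file into a list of :class:`Scan`.

    One Scan per ``<scan>`` element, ``mode='full'``.  ``sample_id``
    defaults to the file stem.  Profile-mode scans (``centroided="0"``) are
    rejected; data must be centroided upstream.
    """
    path = Path(path)
    sid = sample_id if sample_id is not None else path.stem
    scans: List[Scan] = []
    try:
        entries = list(_mzxml.read(str(path)))
    except Exception as exc:  # lxml/pyteomics parse failures
        raise ValueError(f"malformed mzXML {path}: {exc}") from exc
    for entry in entries:
        num = entry.get("num", "?")
        centroided = entry.get("centroided")
        if centroided is not None and not centroided:
            raise ValueError(
                f"scan {num} in {path} is profile-mode; centroid the data first"
            )
        pol = entry.get("polarity")
        polarity = -1 if pol == "-" else 1
        level = int(entry["msLevel"])
        prec_mz = None
        prec_int = None
        precs = entry.get("precursorMz")
        if precs:
            prec_mz = float(precs[0]["precursorMz"])
            pi = precs[0].get("precursorIntensity")
            prec_int = float(pi) if pi is not None else None
        peaks = [
            Peak(float(m), float(i))
            for m, i in zip(entry["m/z array"], entry["intensity array"])
        ]
        scans.append(
            Scan(
                sample_id=sid,
                ms_level=level,
                polarity=polarity,
                mode="full",
                precursor_mz=prec_mz if level == 2 else None,
                precursor_intensity=prec_int if level == 2 else None,
                peaks=peaks,
                scan_index=int(num) if str(num).isdigit() else len(scans),
            )
        )
    return scans


def write_mzxml(scans: Sequence[Scan], path: str | Path) -> None:
    """Write scans as minimal centroided mzXML 3.2 (64-bit network m/z-int)."""
    path = Path(path)
    lines = [
        '<?xml version="1.0" encoding="ISO-8859-1"?>',
        '<mzXML xmlns="http://sashimi.sourceforge.net/schema_revision/mzXML_3.2">',
        f' <msRun scanCount="{len(scans)}">',
    ]
    for idx, scan in enumerate(scans, start=1):
        payload = b"".join(
            struct.pack(">dd", p.mz, p.intensity) for p in scan.peaks
        )
        b64 = base64.b64encode(payload).decode("ascii")
        pol = "-" if scan.polarity < 0 else "+"
        attrs = (
            f'num="{idx}" msLevel="{scan.ms_level}" peaksCount="{len(scan.peaks)}" '
            f'polarity="{pol}" centroided="1"'
        )
        if scan.peaks:
            attrs += f' lowMz="{scan.peaks[0].mz:.6f}" highMz="{scan.peaks[-1].mz:.6f}"'
        lines.append(f'  <scan {attrs}>')
        if scan.ms_level == 2 and scan.precursor_mz is not None:
            pi = scan.precursor_intensity if scan.precursor_intensity is not None else 0.0
            lines.append(
                f'   <precursorMz precursorIntensity="{pi:.6f}">'
                f"{scan.precursor_mz:.6f}</precursorMz>"
            )
        lines.append(
            '   <peaks compressionType="none" compressedLen="0" precision="64" '
            f'byteOrder="network" contentType="m/z-int">{b64}</peaks>'
        )
        lines.append("  </scan>")
    lines += [" </msRun>", "</mzXML>", ""]
    path.write_text("\n".join(lines))


# ----------------------------------------------------------------------
# peak lists
# ----------------------------------------------------------------------

def read_peaklist(path: str | Path, dialect: str, meta: Scan) -> Scan:
    """Read a two-column peak list into a Scan carrying ``meta``'s metadata.

    ``dialect='csv'``: comma- or tab-delimited (sniffed from the first
    line), one optional header line (detected by a non-numeric first
    field).  ``dialect='dta'``: whitespace-delimited, first line
    "precursorMass charge" (recorded as the precursor m/z for MS2 scans),
    subsequent lines "mz intensity".
    """
    path = Path(path)
    if dialect not in ("csv", "dta"):
        raise ValueError(f"unknown peak-list dialect {dialect!r}")
    lines = [ln.strip() for ln in path.read_text().splitlines()]
    lines = [ln for ln in lines if ln]
    peaks: List[Peak] = []
    precursor_mz = meta.precursor_mz

    def parse_row(ln: str, lineno: int, sep: Optional[str]) -> Tuple[float, float]:
        parts = ln.split(sep) if sep else ln.split()
        parts = [p for p in parts if p != ""]
        try:
            return float(parts[0]), float(parts[1])
        except (ValueError, IndexError) as exc:
            raise ValueError(
                f"{path}:{lineno}: cannot parse peak row {ln!r}"
            ) from exc

    if dialect == "dta":
        if not lines:
            raise ValueError(f"{path}: empty .dta file")
        first = lines[0].split()
        try:
            precursor_mz = float(first[0])
        except (ValueError, IndexError) as exc:
            raise ValueError(f"{path}:1: bad .dta header {lines[0]!r}") from exc
        for lineno, ln in enumerate(lines[1:], start=2):
            mz, inten = parse_row(ln, lineno, None)
            peaks.append(Peak(mz, inten))
    else:
        sep = "\t" if lines and "\t" in lines[0] else ","
        start = 0
        if lines:
            head = lines[0].split(sep)[0].strip()
            try:
                float(head)
            except ValueError:
                start = 1  # header line
        for lineno, ln in enumerate(lines[start:], start=start + 1):
            mz, inten = parse_row(ln, lineno, sep)
            peaks.append(Peak(mz, inten))

    return replace(
        meta,
        peaks=peaks,
        precursor_mz=precursor_mz if meta.ms_level == 2 else None,
    )


# ----------------------------------------------------------------------
# results
# ----------------------------------------------------------------------

def write_results_csv(records: Iterable, path: str | Path) -> pd.DataFrame:
    """Write identification records as a flat .csv results table.

    One row per record, ordered by (query, precursor m/z); columns: query,
    species annotation, molecular species (when fatty acids were resolved),
    sum composition, m/z, mass error in ppm, then one intensity column per
    sample.  Returns the DataFrame that was written.
    """
    records = sorted(
        records, key=lambda r: (r.query, r.precursor_mz, abs(r.err_ppm or 0.0))
    )
    samples: List[str] = []
    for r in records:
        for s in r.intensities:
            if s not in samples:
                samples.append(s)
    samples.sort()
    rows = []
    for r in records:
        row = {
            "query": r.query,
            "species": r.annotation,
            "molecular_species": r.molecular_annotation or "",
            "sum_composition": str(r.precursor_composition),
            "mz": round(r.precursor_mz, 6),
            "err_ppm": round(r.err_ppm, 3) if r.err_ppm is not None else "",
        }
        for s in samples:
            row[f"intensity:{s}"] = r.intensities.get(s, 0.0)
        rows.append(row)
    columns = ["query", "species", "molecular_species", "sum_composition", "mz",
               "err_ppm"] + [f"intensity:{s}" for s in samples]
    frame = pd.DataFrame(rows, columns=columns)
    frame.to_csv(path, index=False)
    return frame


# ----------------------------------------------------------------------
# JSON scan container (CLI plumbing)
# ----------------------------------------------------------------------

_SCAN_FORMAT = "lipidquery-scans"
_SCAN_VERSION = 1


def save_scans(scans: Sequence[Scan], path: str | Path) -> None:
    doc = {
        "format": _SCAN_FORMAT,
        "version": _SCAN_VERSION,
        "scans": [
            {
                "sample_id": s.sample_id,
                "ms_level": s.ms_level,
                "polarity": s.polarity,
                "mode": s.mode,
                "precursor_mz": s.precursor_mz,
                "precursor_intensity": s.precursor_intensity,
                "monitored_fragment_mz": s.monitored_fragment_mz,
                "neutral_loss_delta": s.neutral_loss_delta,
                "scan_index": s.scan_index,
                "virtual": s.virtual,
                "provenance": list(s.provenance),
                "loss_deltas": list(s.loss_deltas) if s.loss_deltas else None,
                "peaks": [[p.mz, p.intensity] for p in s.peaks],
            }
            for s in scans
        ],
    }
    Path(path).write_text(json.dumps(doc))


def load_scans(path: str | Path) -> List[Scan]:
    doc = json.loads(Path(path).read_text())
    if doc.get("format") != _SCAN_FORMAT:
        raise ValueError(f"{path}: not a scan container")
    if doc.get("version") != _SCAN_VERSION:
        raise ValueError(f"{path}: unsupported scan container version {doc.get('version')}")
    scans = []
    for d in doc["scans"]:
        scans.append(
            Scan(
                sample_id=d["sample_id"],
                ms_level=d["ms_level"],
                polarity=d["polarity"],
                mode=d["mode"],
                precursor_mz=d["precursor_mz"],
                precursor_intensity=d["precursor_intensity"],
                monitored_fragment_mz=d["monitored_fragment_mz"],
                neutral_loss_delta=d["neutral_loss_delta"],
                scan_index=d["scan_index"],
                virtual=d["virtual"],
                provenance=tuple(d["provenance"]),
                loss_deltas=tuple(d["loss_deltas"]) if d.get("loss_deltas") else None,
                peaks=[Peak(m, i) for m, i in d["peaks"]],
            )
        )
    return scans
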