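"""Transposition of precursor-ion and neutral-loss scans to virtual MS/MS.

Triple-quadrupole shotgun experiments record, per analysis, the intensity
of one fixed fragment (precursor ion scanning, PIS) or of one fixed neutral
mass difference (neutral loss scanning, NLS) across the precursor m/z
range.  Aligning the precursor axes of all such scans from one sample and
reading the table the other way round yields, for every observed precursor
mass, the list "[fragment, abundance], ..." — a *virtual* MS/MS spectrum.
Downstream, virtual spectra flow through the same MasterScan and query
machinery as full MS/MS spectra; they are flagged so fragment mass-accuracy
scoring can be relaxed (the fragment m/z is the nominal monitored target,
not a measurement).
"""

from __future__ import annotations

from typing import Dict, List, Sequence, Tuple

from .masterscan import ResolutionModel, greedy_group, tolerance_at
from .spectra_io import Peak, Scan

__all__ = ["transpose_pis", "transpose_nls"]


def _transpose(
    scans: Sequence[Scan],
    model: ResolutionModel,
    mode: str,
) -> List[Scan]:
    if not scans:
        return []
    polarities = {s.polarity for s in scans}
    if len(polarities) != 1:
        raise ValueError("cannot transpose scans of mixed polarity")
    for s in scans:
        if s.mode != mode:
            raise ValueError(f"expected mode={mode!r} scans, got {s.mode!r}")
        if mode == "pis" and s.monitored_fragment_mz is None:
            raise ValueError("PIS scan without a monitored fragment m/z")
        if mode == "nls":
            if s.neutral_loss_delta is None:
                raise ValueError("NLS scan without a neutral-loss delta")
            if s.neutral_loss_delta <= 0:
                raise ValueError(
                    f"neutral-loss delta must be positive, got {s.neutral_loss_delta}"
                )

    tol_fn = lambda m: tolerance_at(model, m)
    virtual: List[Scan] = []
    by_sample: Dict[str, List[Scan]] = {}
    for s in scans:
        by_sample.setdefault(s.sample_id, []).append(s)

    for sample_id in sorted(by_sample):
        sample_scans = by_sample[sample_id]
        # one item per (precursor-axis peak, source scan)
        items: List[Tuple[float, float, int, Scan]] = [
            (p.mz, p.intensity, idx, s)
            for idx, s in enumerate(sample_scans)
            for p in s.peaks
        ]
        groups = greedy_group(items, tol_fn, one_per_source=True)
        clusters = []
        for g in groups:
            if not g:
                continue
            total = sum(i for _, i, _, _ in g)
            if total <= 0:
                continue
            mz = sum(m * i for m, i, _, _ in g) / total
            clusters.append((mz, g))
        clusters.sort(key=lambda t: t[0])

        for prec_mz, g in clusters:
            frags: List[Peak] = []
            deltas: List[float | None] = []
            prov: List[str] = []
            for _, intensity, _, src in sorted(
                g, key=lambda t: t[3].monitored_fragment_mz
                if mode == "pis"
                else t[3].neutral_loss_delta
            ):
                if mode == "pis":
                    fmz = src.monitored_fragment_mz
                    deltas.append(None)
                    prov.append(f"pis:{fmz:g}")
                else:
                    fmz = prec_mz - src.neutral_loss_delta
                    deltas.append(src.neutral_loss_delta)
                    prov.append(f"nls:{src.neutral_loss_delta:g}")
                frags.append(Peak(fmz, intensity))
            order = sorted(range(len(frags)), key=lambda i: frags[i].mz)
            virtual.append(
                Scan(
                    sample_id=sample_id,
                    ms_level=2,
                    polarity=scans[0].polarity,
                    mode="full",
                    precursor_mz=prec_mz,
                    precursor_intensity=sum(p.intensity for p in frags),
                    peaks=[frags[i] for i in order],
                    virtual=True,
                    provenance=tuple(prov[i] for i in order),
                    loss_deltas=tuple(deltas[i] for i in order),
                )
            )
    return virtual


def transpose_pis(pis_scans: Sequence[Scan], model: ResolutionModel) -> List[Scan]:
    """Transpose precursor-ion scans into virtual MS/MS scans.

    Per sample, the precursor axes of all PIS scans are aligned with the
    same greedy rule used for MasterScan building; each aligned precursor
    mass becomes a virtual MS/MS scan whose fragment peaks are the
    monitored fragment m/z values with the precursor's intensity in the
    corresponding scan.  Precursors with no signal produce nothing; the
    summed fragment signal is recorded as the virtual precursor intensity.
    """
    return _transpose(pis_scans, model, "pis")


def transpose_nls(nls_scans: Sequence[Scan], model: ResolutionModel) -> List[Scan]:
    """Transpose neutral-loss scans into virtual MS/MS scans.

    Same alignment as :func:`transpose_pis`; each virtual fragment peak is
    placed at (precursor m/z - Δ) and additionally annotated with Δ in
    ``Scan.loss_deltas`` so queries can match either the fragment mass or
    the loss itself.
    """
    return _transpose(nls_scans, model, "nls")
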