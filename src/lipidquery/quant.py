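"""Isotopic correction, per-class normalization and profile concordance.

Species of one lipid class that differ by one double bond are 2.0157 Da
apart, so the M+2 isotopologue of the more unsaturated species (at
+2.0067 Da) can fall on the less unsaturated species' monoisotopic peak on
unit-resolution instruments.  :func:`isotopic_correction` removes these
overlaps: processing records of one class in ascending precursor m/z, the
predicted isotopologue envelope of each species (scaled by its observed
monoisotopic intensity, per sample) is subtracted from any heavier record
whose precursor m/z matches an isotopologue position within the MS1
tolerance; fragment intensities are corrected analogously using the
fragment composition's own envelope.  Corrected intensities are clipped at
zero — correction never increases a signal.

:func:`class_normalize` turns corrected records into per-class relative
profiles (species abundances summing to 1 per sample), combining isobaric
species of the same class whose annotations collide.
:func:`profile_concordance` compares two such profiles by ordinary least
squares over the shared species, returning (r², slope) — the statistic
used to judge agreement between acquisition modes and instruments.
"""

from __future__ import annotations

import copy
import logging
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

from scipy import stats as _stats

from .chem_core import NEUTRON_MASS_SHIFT, ion_mz, isotope_pattern
from .masterscan import MasterScan
from .mfql import IdentificationRecord

logger = logging.getLogger(__name__)

__all__ = [
    "ClassProfile",
    "isotopic_correction",
    "class_normalize",
    "profile_concordance",
]


@dataclass
class ClassProfile:
    """Relative abundances of one class's species, per sample.

    ``entries`` maps species annotation -> {sample -> abundance}; per
    sample the abundances over the class sum to 1.  Samples whose class
    total was zero are listed in ``undefined_samples`` and carry NaN.
    """

    lipid_class: str
    entries: Dict[str, Dict[str, float]]
    undefined_samples: List[str] = field(default_factory=list)

    @property
    def species(self) -> List[str]:
        return list(self.entries)

    def mean_abundances(self) -> Dict[str, float]:
        """Across-sample mean relative abundance per species."""
        out = {}
        for sp, per_sample in self.entries.items():
            vals = [v for s, v in per_sample.items() if s not in self.undefined_samples]
            out[sp] = sum(vals) / len(vals) if vals else math.nan
        return out


def isotopic_correction(
    records: Sequence[IdentificationRecord],
    ms: MasterScan,
    n_isotopologues: int = 3,
) -> List[IdentificationRecord]:
    """Subtract predicted isotopologue overlaps between same-class species.

    Records are deep-copied; inputs are not mutated.  Records without an
    assigned composition are passed through with a warning flag.  The
    subtraction cascades: lighter species are corrected first and their
    *corrected* intensities scale the envelope subtracted from heavier
    ones.  Per-neutron spacing is ~1.00336 Da (13C); matching uses the
    MasterScan's MS1 tolerance (MS2 tolerance for fragments).
    """
    out = [copy.deepcopy(r) for r in records]
    by_class: Dict[str, List[IdentificationRecord]] = {}
    for r in out:
        if r.precursor_composition is None:
            logger.warning("record %s has no composition; passed through", r.annotation)
            r.flags.append("no_composition")
            continue
        by_class.setdefault(r.lipid_class, []).append(r)

    for cls, recs in by_class.items():
        recs.sort(key=lambda r: r.precursor_mz)
        for i, light in enumerate(recs):
            pattern = isotope_pattern(light.precursor_composition, n_isotopologues)
            z = abs(light.charge) or 1
            light_theo = ion_mz(light.precursor_composition, light.charge)
            for k in range(1, len(pattern)):
                # overlap is decided on the *theoretical* masses of the two
                # assigned compositions: whether envelopes collide is a
                # property of the species, not of measurement noise
                pos = light_theo + k * NEUTRON_MASS_SHIFT / z
                tol = ms.settings.ms1_tolerance.window(pos)
                ratio = pattern.ratio_to_monoisotopic(k)
                for heavy in recs[i + 1:]:
                    heavy_theo = ion_mz(heavy.precursor_composition, heavy.charge)
                    if abs(heavy_theo - pos) > tol:
                        continue
                    clipped = False
                    for sample, inten in light.intensities.items():
                        cur = heavy.intensities.get(sample, 0.0)
                        corrected = cur - ratio * inten
                        if corrected < 0:
                            corrected = 0.0
                            clipped = True
                        heavy.intensities[sample] = corrected
                    if clipped and "clipped_at_zero" not in heavy.flags:
                        heavy.flags.append("clipped_at_zero")
                    heavy.flags.append(f"isotope_corrected:M+{k}:{light.annotation}")
                    _correct_fragments(light, heavy, k, ms, n_isotopologues)
    return out


def _correct_fragments(
    light: IdentificationRecord,
    heavy: IdentificationRecord,
    k: int,
    ms: MasterScan,
    n_isotopologues: int,
) -> None:
    """Remove the light species' fragment isotopologues from the heavy record."""
    if not light.fragments or not heavy.fragments:
        return
    for lf in light.fragments:
        if lf.is_neutral_loss:
            continue
        fpattern = isotope_pattern(lf.composition, n_isotopologues)
        if k >= len(fpattern):
            continue
        ratio = fpattern.ratio_to_monoisotopic(k)
        pos = lf.composition.mass + k * NEUTRON_MASS_SHIFT
        tol = ms.settings.ms2_tolerance.window(pos)
        light_int = light.fragment_intensities.get(lf.variable, {})
        for hf in heavy.fragments:
            if hf.is_neutral_loss or abs(hf.composition.mass - pos) > tol:
                continue
            heavy_int = heavy.fragment_intensities.get(hf.variable)
            if heavy_int is None:
                continue
            for sample, inten in light_int.items():
                cur = heavy_int.get(sample, 0.0)
                heavy_int[sample] = max(0.0, cur - ratio * inten)


def class_normalize(
    records: Sequence[IdentificationRecord],
) -> List[ClassProfile]:
    """Per-class relative quantification.

    Species intensities are divided by the class total, per sample.
    Records of the same class whose (sum) annotation collides — isobaric
    species or the same species matched at molecular level more than once
    — are combined by summation before normalizing.
    """
    by_class: Dict[str, Dict[str, Dict[str, float]]] = {}
    samples_by_class: Dict[str, set] = {}
    for r in records:
        cls = r.lipid_class
        species = by_class.setdefault(cls, {})
        entry = species.setdefault(r.annotation, {})
        for sample, inten in r.intensities.items():
            entry[sample] = entry.get(sample, 0.0) + inten
            samples_by_class.setdefault(cls, set()).add(sample)

    profiles: List[ClassProfile] = []
    for cls in sorted(by_class):
        species = by_class[cls]
        samples = sorted(samples_by_class[cls])
        totals = {
            s: sum(entry.get(s, 0.0) for entry in species.values()) for s in samples
        }
        undefined = [s for s in samples if totals[s] <= 0]
        if undefined:
            logger.warning(
                "class %s has zero total intensity in samples %s", cls, undefined
            )
        entries: Dict[str, Dict[str, float]] = {}
        for annotation in sorted(species):
            per_sample = {}
            for s in samples:
                if s in undefined:
                    per_sample[s] = math.nan
                else:
                    per_sample[s] = species[annotation].get(s, 0.0) / totals[s]
            entries[annotation] = per_sample
        profiles.append(
            ClassProfile(lipid_class=cls, entries=entries, undefined_samples=undefined)
        )
    return profiles


def profile_concordance(
    a: ClassProfile, b: ClassProfile
) -> Tuple[float, float]:
    """(r², slope) of regressing ``b``'s abundances on ``a``'s.

    Species are matched by annotation; per species, the across-sample mean
    relative abundance is used.  Unweighted ordinary least squares with a
    free intercept.  Requires at least two shared species.
    """
    mean_a = a.mean_abundances()
    mean_b = b.mean_abundances()
    shared = [
        sp
        for sp in mean_a
        if sp in mean_b and not (math.isnan(mean_a[sp]) or math.isnan(mean_b[sp]))
    ]
    if len(shared) < 2:
        raise ValueError(
            f"profiles share {len(shared)} species; need at least 2 for regression"
        )
    x = [mean_a[sp] for sp in shared]
    y = [mean_b[sp] for sp in shared]
    fit = _stats.linregress(x, y)
    return fit.rvalue ** 2, fit.slope
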