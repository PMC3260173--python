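"""Synthetic lipidomes and simulated shotgun acquisitions.

This generator is the package's test bed: it builds a random (but
reproducible) PE/PG lipidome of known composition and simulates the three
acquisition modes the engine interprets —

* DDA:  per replicate one survey MS1 scan of [M-H]- precursors plus one
  full MS/MS scan per species containing its two acyl-anion fragments;
* PIS:  negative-mode precursor ion scans, one scan per monitored
  acyl-anion m/z, a species contributing a precursor-axis peak to every
  scan whose target matches one of its fatty acids;
* NLS:  positive-mode neutral loss scans ([M+H]+ for PE, [M+NH4]+ for PG),
  a species responding only to its class's head-group loss
  (Δ 141.02 / Δ 189.04).

The instrument model applies Gaussian relative mass error (ppm), Gaussian
relative intensity noise, optional uniform chemical-noise peaks with
exponential intensities, and a detection limit.  Peaks are monoisotopic;
isotopologue envelopes are not simulated.  The fragmentation model is
minimal: each diacyl species yields its two acyl anions with intensities
proportional to abundance, split by a configurable sn-position bias, and
nothing else.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from . import lipids
from .chem_core import ElementalComposition, ion_mz
from .masterscan import ResolutionModel
from .spectra_io import Peak, Scan

__all__ = [
    "LipidSpecies",
    "SyntheticLipidome",
    "InstrumentModel",
    "generate_lipidome",
    "simulate_dda",
    "simulate_pis",
    "simulate_nls",
    "pis_targets_for",
]


@dataclass(frozen=True)
class LipidSpecies:
    """One diacyl species: class, the two fatty acids, relative abundance."""

    lipid_class: str
    fa1: Tuple[int, int]
    fa2: Tuple[int, int]
    abundance: float

    @property
    def neutral(self) -> ElementalComposition:
        return lipids.species_neutral(self.lipid_class, self.fa1, self.fa2)

    @property
    def negative_ion(self) -> ElementalComposition:
        return self.neutral - ElementalComposition({"H": 1})

    @property
    def positive_ion(self) -> ElementalComposition:
        cls = lipids.LIPID_CLASSES[self.lipid_class]
        return self.neutral + cls.positive_adduct

    @property
    def negative_mz(self) -> float:
        return ion_mz(self.negative_ion, -1)

    @property
    def positive_mz(self) -> float:
        return ion_mz(self.positive_ion, +1)

    @property
    def sum_annotation(self) -> str:
        return lipids.sum_annotation(self.lipid_class, self.neutral)

    @property
    def molecular_annotation(self) -> str:
        fas = sorted([self.fa1, self.fa2])
        body = "/".join(f"{n}:{d}" for n, d in fas)
        return f"{self.lipid_class} {body}"

    def acyl_anions(self) -> List[Tuple[ElementalComposition, float]]:
        """The two acyl-anion compositions with their fractional shares."""
        return [
            (lipids.acyl_anion(*self.fa1), 0.5),
            (lipids.acyl_anion(*self.fa2), 0.5),
        ]


@dataclass(frozen=True)
class SyntheticLipidome:
    """A known species list plus the seed that produced it."""

    species: Tuple[LipidSpecies, ...]
    seed: int = 0

    def __len__(self) -> int:
        return len(self.species)

    @property
    def sum_annotations(self) -> List[str]:
        return [sp.sum_annotation for sp in self.species]

    @classmethod
    def from_species(
        cls,
        entries: Sequence[Tuple[str, Tuple[int, int], Tuple[int, int]]],
        abundances: Optional[Sequence[float]] = None,
        seed: int = 0,
    ) -> "SyntheticLipidome":
        """Build a lipidome from explicit (class, fa1, fa2) entries."""
        if abundances is None:
            abundances = [1.0] * len(entries)
        species = tuple(
            LipidSpecies(c, tuple(f1), tuple(f2), a)
            for (c, f1, f2), a in zip(entries, abundances)
        )
        return cls(species=species, seed=seed)


@dataclass(frozen=True)
class InstrumentModel:
    """Instrument imperfections applied by the simulators.

    ``mass_error_ppm`` is the standard deviation of the Gaussian relative
    m/z error; ``intensity_noise`` the relative s.d. of multiplicative
    intensity noise; ``chemical_noise_density`` the expected number of
    random background peaks per Th of the scan range; ``detection_limit``
    the absolute intensity floor below which peaks are dropped.
    """

    resolution: ResolutionModel = ResolutionModel(r0=7500.0, m_ref=700.0)
    mass_error_ppm: float = 0.0
    intensity_noise: float = 0.0
    chemical_noise_density: float = 0.0
    chemical_noise_scale: float = 100.0
    detection_limit: float = 0.0
    mz_range: Tuple[float, float] = (200.0, 950.0)

    def __post_init__(self):
        for name in ("mass_error_ppm", "intensity_noise",
                     "chemical_noise_density", "detection_limit"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")


def generate_lipidome(
    classes: Sequence[str] = ("PE", "PG"),
    n_species: int = 20,
    seed: int = 0,
    chain_range: Tuple[int, int] = (12, 22),
    max_double_bonds: int = 6,
    abundance_decades: Tuple[float, float] = (4.0, 6.0),
) -> SyntheticLipidome:
    """Draw a reproducible random lipidome.

    Fatty acids are drawn uniformly from the configured chain-length and
    double-bond pools (double bonds capped so the acyl chain stays
    chemically plausible); species abundances are log-uniform over the
    given decade range.  Sum annotations are unique within the lipidome so
    per-species abundances are well defined.
    """
    for c in classes:
        if c not in lipids.LIPID_CLASSES:
            raise ValueError(
                f"unsupported lipid class {c!r}; known: {sorted(lipids.LIPID_CLASSES)}"
            )
    rng = np.random.default_rng(seed)
    species: List[LipidSpecies] = []
    used: set = set()
    attempts = 0
    while len(species) < n_species and attempts < 10000:
        attempts += 1
        cls = classes[len(species) % len(classes)]

        def draw_fa() -> Tuple[int, int]:
            n = int(rng.integers(chain_range[0], chain_range[1] + 1))
            d = int(rng.integers(0, min(max_double_bonds, max(0, (n - 8) // 2)) + 1))
            return n, d

        fa1, fa2 = sorted([draw_fa(), draw_fa()])
        total = (fa1[0] + fa2[0], fa1[1] + fa2[1])
        if (cls, total) in used:
            continue
        used.add((cls, total))
        abundance = 10.0 ** rng.uniform(*abundance_decades)
        species.append(LipidSpecies(cls, fa1, fa2, abundance))
    if len(species) < n_species:
        raise ValueError(
            f"could not draw {n_species} species with unique annotations"
        )
    return SyntheticLipidome(species=tuple(species), seed=seed)


# ----------------------------------------------------------------------
# noise helpers
# ----------------------------------------------------------------------

def _noisy_mz(rng: np.random.Generator, mz: float, inst: InstrumentModel) -> float:
    if inst.mass_error_ppm <= 0:
        return mz
    return mz * (1.0 + rng.normal(0.0, inst.mass_error_ppm) * 1e-6)


def _noisy_intensity(rng: np.random.Generator, value: float, inst: InstrumentModel) -> float:
    if inst.intensity_noise <= 0:
        return value
    return max(0.0, value * (1.0 + rng.normal(0.0, inst.intensity_noise)))


def _chemical_noise(rng: np.random.Generator, inst: InstrumentModel) -> List[Peak]:
    if inst.chemical_noise_density <= 0:
        return []
    lo, hi = inst.mz_range
    n = rng.poisson(inst.chemical_noise_density * (hi - lo))
    peaks = []
    for _ in range(n):
        peaks.append(
            Peak(float(rng.uniform(lo, hi)),
                 float(rng.exponential(inst.chemical_noise_scale)))
        )
    return peaks


def _finalize(peaks: Iterable[Peak], inst: InstrumentModel) -> List[Peak]:
    kept = [p for p in peaks if p.intensity > inst.detection_limit]
    return sorted(kept, key=lambda p: p.mz)


# ----------------------------------------------------------------------
# simulators
# ----------------------------------------------------------------------

def simulate_dda(
    lipidome: SyntheticLipidome,
    inst: InstrumentModel,
    n_replicates: int = 4,
    seed: int = 0,
    sn_bias: float = 1.0,
    fragment_yield: float = 0.5,
) -> List[Scan]:
    """Simulate negative-mode data-dependent acquisition.

    Per replicate: one survey MS1 scan with one [M-H]- peak per species
    (intensity proportional to abundance), then one full MS/MS scan per
    species whose peaks are its two acyl anions.  The sn-1 fragment gets a
    ``sn_bias`` : 1 intensity advantage; the total fragment signal is
    ``fragment_yield`` x abundance.
    """
    rng = np.random.default_rng(seed)
    scans: List[Scan] = []
    index = 0
    for rep in range(n_replicates):
        sample = f"S{rep + 1}"
        ms1_peaks = [
            Peak(
                _noisy_mz(rng, sp.negative_mz, inst),
                _noisy_intensity(rng, sp.abundance, inst),
            )
            for sp in lipidome.species
        ] + _chemical_noise(rng, inst)
        scans.append(
            Scan(
                sample_id=sample,
                ms_level=1,
                polarity=-1,
                peaks=_finalize(ms1_peaks, inst),
                scan_index=index,
            )
        )
        index += 1
        for sp in lipidome.species:
            share1 = sn_bias / (1.0 + sn_bias)
            contributions: Dict[ElementalComposition, float] = {}
            for (comp, _), share in zip(
                sp.acyl_anions(), (share1, 1.0 - share1)
            ):
                contributions[comp] = contributions.get(comp, 0.0) + share
            frag_peaks = [
                Peak(
                    _noisy_mz(rng, ion_mz(comp, -1), inst),
                    _noisy_intensity(
                        rng, fragment_yield * sp.abundance * share, inst
                    ),
                )
                for comp, share in contributions.items()
            ]
            scans.append(
                Scan(
                    sample_id=sample,
                    ms_level=2,
                    polarity=-1,
                    precursor_mz=_noisy_mz(rng, sp.negative_mz, inst),
                    peaks=_finalize(frag_peaks, inst),
                    scan_index=index,
                )
            )
            index += 1
    return scans


def pis_targets_for(
    lipidome: SyntheticLipidome, decimals: int = 1
) -> List[float]:
    """Nominal monitored m/z list covering every acyl anion in the lipidome.

    Mirrors the bench practice of successively acquiring PIS scans for the
    acyl anions of all common fatty acids, rounded to the instrument's
    target precision.
    """
    targets = {
        round(ion_mz(comp, -1), decimals)
        for sp in lipidome.species
        for comp, _ in sp.acyl_anions()
    }
    return sorted(targets)


def simulate_pis(
    lipidome: SyntheticLipidome,
    fragment_mz_list: Sequence[float],
    inst: InstrumentModel,
    n_replicates: int = 3,
    seed: int = 0,
    q1_window: float = 0.3,
    sn_bias: float = 1.0,
) -> List[Scan]:
    """Simulate negative-mode precursor ion scanning.

    One scan per monitored fragment per replicate; a species contributes a
    precursor-axis peak to a scan iff one of its acyl anions lies within
    ``q1_window`` Th of the monitored target, with intensity proportional
    to abundance times that fatty acid's share.
    """
    if not fragment_mz_list:
        raise ValueError("monitored fragment list must be nonempty")
    rng = np.random.default_rng(seed)
    scans: List[Scan] = []
    index = 0
    share1 = sn_bias / (1.0 + sn_bias)
    for rep in range(n_replicates):
        sample = f"S{rep + 1}"
        for target in fragment_mz_list:
            peaks = []
            for sp in lipidome.species:
                signal = 0.0
                for (comp, _), share in zip(
                    sp.acyl_anions(), (share1, 1.0 - share1)
                ):
                    if abs(ion_mz(comp, -1) - target) <= q1_window:
                        signal += sp.abundance * share
                if signal > 0:
                    peaks.append(
                        Peak(
                            _noisy_mz(rng, sp.negative_mz, inst),
                            _noisy_intensity(rng, signal, inst),
                        )
                    )
            peaks += _chemical_noise(rng, inst)
            scans.append(
                Scan(
                    sample_id=sample,
                    ms_level=2,
                    polarity=-1,
                    mode="pis",
                    monitored_fragment_mz=float(target),
                    peaks=_finalize(peaks, inst),
                    scan_index=index,
                )
            )
            index += 1
    return scans


def simulate_nls(
    lipidome: SyntheticLipidome,
    delta_list: Sequence[float],
    inst: InstrumentModel,
    n_replicates: int = 3,
    seed: int = 0,
    delta_window: float = 0.1,
) -> List[Scan]:
    """Simulate positive-mode neutral loss scanning.

    One scan per monitored Δ per replicate; a species responds to a scan
    iff its class's head-group loss matches the scan's Δ within
    ``delta_window`` Da (PE: Δ 141.02 from [M+H]+; PG: Δ 189.04 from
    [M+NH4]+), contributing a peak at its positive-mode precursor m/z.
    """
    if not delta_list:
        raise ValueError("neutral-loss delta list must be nonempty")
    rng = np.random.default_rng(seed)
    scans: List[Scan] = []
    index = 0
    for rep in range(n_replicates):
        sample = f"S{rep + 1}"
        for delta in delta_list:
            if delta <= 0:
                raise ValueError(f"neutral-loss delta must be positive, got {delta}")
            peaks = []
            for sp in lipidome.species:
                cls = lipids.LIPID_CLASSES[sp.lipid_class]
                if abs(cls.positive_loss_mass - delta) > delta_window:
                    continue
                peaks.append(
                    Peak(
                        _noisy_mz(rng, sp.positive_mz, inst),
                        _noisy_intensity(rng, sp.abundance, inst),
                    )
                )
            peaks += _chemical_noise(rng, inst)
            scans.append(
                Scan(
                    sample_id=sample,
                    ms_level=2,
                    polarity=1,
                    mode="nls",
                    neutral_loss_delta=float(delta),
                    peaks=_finalize(peaks, inst),
                    scan_index=index,
                )
            )
            index += 1
    return scans
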