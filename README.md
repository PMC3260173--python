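# lipidquery

Cross-platform interpretation of shotgun lipidomics spectra: `lipidquery`
aligns direct-infusion MS and MS/MS spectra from many samples into a single
**MasterScan** database, identifies lipid species with a
molecular-fragmentation query language (an MFQL dialect) over
**sum-composition constraints**, and quantifies species consistently whether
the data were acquired by data-dependent acquisition (DDA) on a
high-resolution instrument or by precursor-ion scanning (PIS) / neutral-loss
scanning (NLS) on a triple quadrupole.

It is aimed at lipidomics practitioners who need one interpretation engine
for heterogeneous shotgun datasets — and at method developers who want a
fully synthetic, ground-truth test bed for such an engine.

## The approach

**Sum compositions instead of mass lists.** A diacyl glycerophospholipid of
class *X* with fatty-acid totals *C:D* (carbons : double bonds) has a fixed
elemental composition; a query therefore declares element-count *ranges*
plus a double-bond-equivalent window (DBE = C + 1 − H/2 + (N+P)/2) and a
charge, rather than enumerating expected masses. For phosphatidylethanolamine
(PE) in negative mode:

```text
QUERYNAME = PE;
DEFINE prPE = 'C[29..55] H[30..100] N[1..1] O[8..8] P[1..1]' WITH DBR = (2.0,15.0), CHG = -1;
DEFINE FA1  = 'C[10..24] H[10..48] O[2..2]' WITH DBR = (1.0,8.0), CHG = -1;
DEFINE FA2  = 'C[10..24] H[10..48] O[2..2]' WITH DBR = (1.0,8.0), CHG = -1;
IDENTIFY prPE IN MS1-, FA1 IN MS2-, FA2 IN MS2-;
SUCHTHAT FA1.chemsc + FA2.chemsc + C5H11O4N1P1 == prPE.chemsc;
REPORT MASS = prPE.mass; CHEMSC = prPE.chemsc; INTENS = prPE.intensity;
```

The `SUCHTHAT` clause is exact element-wise arithmetic: the two acyl-anion
compositions plus the phosphoethanolamine head group and glycerol backbone
(C5H11O4N1P1) must add up to the precursor's composition. For PE 16:0/17:1
that is C16H31O2 (m/z 255.2) + C17H31O2 (m/z 267.2) + C5H11O4N1P1 =
C38H73NO8P, the molecular anion at m/z 702.5.

**MasterScan.** Repeated scans are merged into representative spectra; peaks
are aligned across samples into clusters carrying the intensity-weighted
average m/z while per-sample intensities are preserved. Minimal-intensity
and occupancy thresholds (the fraction of samples in which a peak must
appear) prune chemical noise.

**PIS/NLS transposition.** Triple-quadrupole scans monitor one fragment (or
one neutral loss Δ) at a time. Aligning the precursor axes of all such scans
and reading the table the other way round yields a *virtual* MS/MS spectrum
per precursor mass — after which the very same queries apply. PE and PG are
profiled in positive mode through their head-group losses (Δ m/z 141.02 from
[M+H]⁺ and Δ m/z 189.04 from [M+NH4]⁺, respectively).

**Quantification.** Isotopic correction removes predicted isotopologue
overlaps between same-class species (the M+2 of a species falling on the
species with one fewer double bond), then species intensities are normalized
to the class total; profiles from different modes/instruments are compared
by ordinary least squares (r², slope).

No external data are required: `lipidquery.synthgen` generates PE/PG
lipidomes with known composition and simulates DDA, PIS and NLS acquisitions
with configurable mass error, intensity noise, chemical noise and detection
limit.

## Worked example

Simulate a six-species PE/PG lipidome (5 ppm mass error, 10% intensity
noise, two replicates) and interpret it:

```bash
lipidquery simulate --seed 7 --n-species 6 --mode dda --replicates 2 \
    --mass-error-ppm 5 --intensity-noise 0.1 --out-dir sim
python -c "from lipidquery.queries import PE_NEGATIVE, PG_NEGATIVE;
open('pe.mfql','w').write(PE_NEGATIVE); open('pg.mfql','w').write(PG_NEGATIVE)"
lipidquery run --config sim/experiment.toml --queries pe.mfql --queries pg.mfql --out results.csv
```

which prints `6 records -> results.csv`, the results table being

```text
query,species,molecular_species,sum_composition,mz,err_ppm,intensity:S1,intensity:S2
PE,PE 39:4,PE 17:4/22:0,C44 H79 N1 O8 P1,780.555817,1.203,353821.54535769776,397458.3703062284
PE,PE 41:9,PE 19:5/22:4,C46 H73 N1 O8 P1,798.505512,-3.026,366568.9775503046,358645.6630519262
PE,PE 41:4,PE 19:1/22:3,C46 H83 N1 O8 P1,808.586644,0.575,95780.55910671913,89869.9049781196
PG,PG 33:3,PG 13:1/20:2,C39 H70 O10 P1,729.470112,-1.503,40876.38886835626,43256.11839888518
PG,PG 33:1,PG 12:0/21:1,C39 H74 O10 P1,733.504386,2.559,508858.5224410497,472182.9775721357
PG,PG 35:7,PG 17:4/18:3,C41 H66 O10 P1,749.440958,1.4,398614.48538415803,407074.21758496785
```

Every simulated species is recovered with its fatty acids resolved
(`species` is the class + total C:D annotation, `molecular_species` the
per-fatty-acid assignment); `err_ppm` is the mass error of the aligned
precursor cluster against the matched composition, and the per-sample
intensity columns feed the relative class profiles written to
`sim/profiles.csv` (class, species, sample, abundance; abundances per class
and sample sum to 1). The ground truth the generator used is in
`sim/lipidome.txt`.

The same `run` command interprets PIS or NLS datasets (`--mode pis` /
`--mode nls` in `simulate`); the pipeline transposes them into virtual MS/MS
spectra automatically. The CLI stages (`import`, `transpose`, `build`,
`query`, `report`) expose the intermediate artifacts individually.

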