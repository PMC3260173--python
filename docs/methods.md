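# Methods

This note documents the models, algorithms and numerical choices behind
`lipidquery`, and what the synthetic test bed does and does not establish.

## Composition algebra

All identification reduces to arithmetic over elemental compositions.
Monoisotopic atomic masses (H 1.00782503207, C 12, N 14.0030740048,
O 15.9949146196, P 30.97376163, S 31.97207100 Da) are hard-coded from IUPAC
values; ion m/z accounts for the electron mass (0.00054858 Da):
m/z = (M − z·mₑ)/|z|. Double-bond equivalents use

    DBE = C + 1 − H/2 + (N + P)/2,

treating nitrogen and phosphorus as trivalent. This convention makes the
saturated acyl (carboxylate) anion CₙH₂ₙ₋₁O₂ come out at DBE 1.5 — the
natural lower bound of a fatty-acid DBE window — and a diacyl
glycerophospholipid's neutral species at DBE = (double bonds) + 2 (the two
ester carbonyls). Other conventions for P exist; this one is used
consistently throughout and in the query dialect's `DBR` ranges.

Constrained enumeration (`enumerate_compositions`) walks the element-range
box depth-first, heaviest element first, pruning on reachable mass bounds;
it is exhaustive (tested against a naive product over the box) and returns
candidates sorted by absolute mass error. Tolerances are relative (ppm) or
absolute (Th), selectable per setting.

Isotope patterns are computed by truncated convolution of per-element
natural-abundance vectors indexed by neutron excess (C 98.93/1.07,
H 99.9885/0.0115, N 99.636/0.364, O 99.757/0.038/0.205, S 94.99/0.75/4.25
percent; P mono-isotopic), using exponentiation-by-squaring under
convolution. The first *n* coefficients are exact; the retained vector is
renormalized to sum to 1.

## MasterScan construction

One deterministic greedy rule drives all grouping: seeds are taken in
descending intensity; peaks within the resolution-dependent window
Δm = m/R(m) of the seed join its cluster; a source (scan or sample)
contributes at most one peak per cluster, nearest m/z winning, displaced
peaks re-entering the pool. R(m) = r0 + slope·(m − m_ref) is the linear
FWHM resolution model (default r0 = 7500 at m/z 700, matching the
validation instruments' settings).

* **Merging** repeated scans of one sample first collapses near-coincident
  peaks within each scan (weighted-mean m/z, summed intensity), then groups
  across scans; the merged intensity is the arithmetic mean over the scans
  in which the peak appears, so it does not scale with scan count.
* **Alignment** across samples preserves per-sample intensities unchanged
  and stores the intensity-weighted average m/z per cluster, so alignment
  conserves total intensity exactly.
* **Thresholds**: a cluster survives when its *maximal* per-sample intensity
  reaches the minimal-intensity setting (so species present in a sample
  subset are kept) and its occupancy (fraction of samples with signal;
  denominator switchable to scans) reaches the occupancy threshold.
  Occupancy 1.0 keeps only peaks seen in every sample.
* **MS/MS attachment**: full MS/MS scans are grouped by precursor m/z within
  the isolation window (±0.5 Th default, unit-resolution precursor
  selection), merged/aligned per group, and attached to the nearest survey
  cluster; groups with no survey match become flagged *virtual* precursors —
  the normal situation for transposed PIS/NLS data, which have no survey
  scans at all.

The MasterScan persists as a versioned JSON container (settings, clusters,
per-sample intensities); loading verifies the format tag and version and
refuses partial or future-versioned files.

## PIS/NLS transposition

Per sample, the precursor axes of all precursor-ion (or neutral-loss) scans
are aligned with the same greedy rule; each aligned precursor mass becomes a
virtual MS/MS scan listing (fragment, intensity) pairs — the monitored
target m/z for PIS, (precursor − Δ) annotated with Δ for NLS. The summed
fragment signal is recorded as the virtual precursor intensity. Virtual
fragment m/z values are nominal targets, not measurements, so mass-error
bookkeeping is disabled for them and identification uses absolute windows:
0.1 Th for virtual fragments and 0.05 Th for virtual precursor clusters.
The latter value is deliberate: the precursor axis of a triple quadrupole is
unit-resolution, co-isolated near-isobars (e.g. a PE and a PG species ~0.02
Th apart in positive mode) shift the merged cluster mean beyond any ppm
window, while the nearest *wrong* composition in the query boxes lies
0.094 Th away (±1 C vs ∓7 H) — 0.05 Th accepts the former and excludes the
latter.

## Query evaluation

A query is parsed by a hand-written tokenizer and recursive-descent parser
into DEFINE bindings (sum-composition constraint, DBE range, charge),
IDENTIFY contexts (MS1±/MS2±), an optional SUCHTHAT expression and REPORT
columns. Charge 0 declares a *neutral loss*: the variable matches a fragment
cluster when the precursor-minus-fragment mass difference fits the
constraint. Evaluation enumerates, per precursor cluster, all compositions
per variable within tolerance, takes the product over variables, keeps
assignments satisfying SUCHTHAT (composition equality is exact element-wise
equality), and collapses symmetric duplicates (swapped equivalent fragment
variables). All precursor compositions within tolerance are emitted, ranked
by absolute ppm error — the engine deliberately applies no arbitration or
false-discovery control, and downstream consumers see every candidate.

Species are annotated "Class C:D" (total fatty-acid carbons and double
bonds); when all fragment variables resolve to acyl anions the molecular
species ("PE 16:0/17:1") is reported as well. sn-positions are never
assigned. A record's per-sample intensities come from the first
intensity-bearing REPORT expression; the built-in NLS queries report the
class-specific head-loss fragment intensity, which keeps co-isolated
positive-mode precursors from contaminating each other's quantification.

## Quantification

Isotopic correction processes same-class records in ascending precursor
m/z. Overlap is decided on the *theoretical* masses of the two assigned
compositions: species j is corrected by species i when
|m(j) − m(i) − k·1.00336/|z|| falls within the MS1 tolerance (k = 1, 2;
1.00336 Da is the ¹³C isotopologue spacing). The envelope of i — its
isotope pattern scaled by i's (already corrected) per-sample intensity — is
subtracted from j and clipped at zero; fragment intensities are corrected
analogously with the fragment composition's own pattern. Using theoretical
rather than observed masses makes the decision a property of the species
pair, not of measurement noise: at 10 ppm (high resolution) the 0.0089 Da
gap between M+2 and a one-double-bond-lighter species is resolved and
nothing is subtracted; at unit-resolution settings (absolute tolerance) the
correction engages. Cross-class overlaps are not corrected.

Class profiles divide species intensity by the class total per sample,
summing records whose sum annotation collides (isobaric species, multiple
molecular assignments). Concordance between two profiles is unweighted
ordinary least squares with free intercept over the shared species' across-
sample mean abundances, reported as (r², slope).

## Synthetic test bed

`synthgen` draws diacyl PE/PG lipidomes: fatty acids uniform over chains
12–22 with 0–6 double bonds (capped so short chains stay plausible),
abundances log-uniform over 10⁴–10⁶ (two decades, a realistic dynamic range
for a direct-infusion class profile), sum annotations unique per lipidome.
Default replicate counts are 4 (DDA) and 3 (PIS/NLS), matching the
validation experiment sizes; the fragmentation model yields exactly the two
acyl anions (intensity ∝ abundance, configurable sn-bias, default
symmetric), PIS responds when an acyl anion lies within the Q1 window of
the monitored target, and NLS responds only to the class's head-group loss
(PE: Δ141.02 from [M+H]⁺; PG: Δ189.04 from [M+NH4]⁺). Instrument
imperfections: Gaussian relative mass error (ppm), Gaussian multiplicative
intensity noise, Poisson-uniform chemical-noise peaks with exponential
intensities, and an absolute detection limit.

**What the simulator omits.** Peaks are monoisotopic only — isotopologue
envelopes are not emitted, so the pipeline's isotopic correction is
effectively idle on simulated data (it is exercised on constructed
envelopes in unit tests). There is no Q1/Q3 transmission model, no scan-
speed artifact, no ether/plasmalogen lipids, no cardiolipins (multiply
charged precursors are out of scope), and no LC dimension. Passing tests on
this test bed therefore demonstrate the correctness and cross-mode
consistency of the *interpretation engine*, not detection performance on
real spectra.

**Problem sizes.** The system-level checks run 20-species lipidomes; the
cross-mode concordance property samples 50 random lipidomes at 5 ppm mass
error and 10% intensity noise and compares per-class profiles across
DDA/PIS/NLS for every mode pair. Co-isolation of near-isobars (see above)
occasionally distorts individual regressions — a genuine consequence of the
"emit all candidates" design — so the concordance claim is distributional:
the median comparison and at least 90% of individual comparisons must reach
r² ≥ 0.98 with slope in [0.9, 1.1].

## Known limitations

* The MFQL grammar is a dialect: faithful to the published keyword set
  (DEFINE/IDENTIFY/SUCHTHAT/REPORT, `chemsc`/`mass`/`intensity`/`errppm`,
  constraint syntax, per-query TOLERANCE override as an extension), but
  scripts written for other engines are not guaranteed to parse.
* Identification confidence is not scored; every composition within
  tolerance is reported.
* Only centroided mzXML is read; profile data must be centroided upstream.
* The DBE convention for phosphorus and the occupancy denominator
  (samples vs scans) are choices exposed in settings, not claims about any
  other implementation.
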