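# Methods

`saffronms` implements a MALDI-TOF MS workflow for quality control of
saffron (*Crocus sativus* L.): theoretical fingerprinting of its marker
metabolome, structure-aware annotation of high-energy CID MS/MS spectra,
screening for plant-derived adulterants, and quantitation of the
adulteration level with curcumin as a non-isotopic isobaric internal
standard.  This note records the models, conventions, parameter choices
and known limitations.

## Mass arithmetic

All m/z values derive from a fixed internal table of IUPAC isotope masses
and abundances for C, H, N, O, Na, K and S, so results do not depend on
third-party library versions.  The electron mass (0.000548579909 u) is
subtracted once per positive elementary charge; this is what separates
the two m/z 369.13 isobars — protonated curcumin `[C21H21O6]+` at
369.1333 and the picrocrocin potassium adduct `[C16H26O7K]+` at
369.1310 — by only 0.0023 Th, below TOF resolving power.

Isotope patterns are aggregated isotopologue distributions: per-element
abundance vectors keyed by nucleon offset are convolved (binary
exponentiation for repeated atoms), and each aggregate's m/z is the
abundance-weighted mean of its isotopologues.  The untruncated
distribution is probability-normalized to 1 within 1e-9 (isotopologue
groups below 1e-15 are pruned).  The test suite checks the convolution
against exhaustive isotopologue enumeration on small formulas and the
monoisotopic masses against pyteomics as an independent oracle.

Double-bond equivalents use DBE = (2C + 2 + N − H − Na − K)/2, i.e.
alkali cations count as monovalent hydrogen-like substituents.  This is
the convention that yields the half-integer DBE values characteristic of
even-electron cationized species (3.5 for picrocrocin + K).  Reported
DBE values that contradict it (one IBF metabolite) are noted on the
compound record rather than matched.

## Compound registry

Crocins C-n are built compositionally: crocetin C20H24O4 plus n hexose
residues C6H10O5 (162.0528 Da each) distributed over two linear glycan
chains (r1 ≥ r2).  C-5 is stored as both observed chain topologies,
(3,2) and (4,1).  The registry also carries picrocrocin and eight
glycoconjugated carotenoid-breakdown metabolites (trimethylcyclohexene
"TMC" and hexahydro-isobenzofuranone "IBF" skeletons), the stigma
flavonols (kaempferol sophorosides, quercetin and its glucoside), the
turmeric curcuminoid triplet, three calendula flavonol di-O-glycosides,
and the gardenia iridoid geniposide — 30 records.

Where a published ion annotation conflicts with the compositional rule,
the registry stores the composition-derived formula and keeps the
published value in `reported_mz` with a `discrepancy` note.  This
affects the heavier crocin glycoforms (reported sodiated masses sit
0.01–0.03 Th above composition, e.g. 675.27 vs 675.26 for C-2 and
1161.45 vs 1161.42 for C-5), one metabolite whose published formula and
m/z disagree outright, and the geniposide K adduct (reported 427.00 vs
computed 427.10).  Matching against observed spectra can therefore use
either value at an explicit tolerance, but theoretical ground truth is
always the composition.  The calendula di-O-glycosides are stored by
reported precursor m/z (641.17 / 649.14 / 617.15) and their MS/MS
aglycone cascades only, because consistent full formulas cannot be
reconstructed from the published ions.

## Fragment model

Glycosidic cleavages follow the Domon–Costello nomenclature.  B/C ions
carry i hexose residues plus the ionizing cation (B1 with Na+ is the
sodiated hexose at 185.04); Y ions retain the aglycone and are
enumerated over combined removals from both chains, since sequential
hexose losses are routine in keV CID of oligosaccharides; Z = Y − H2O.
Some published Z assignments follow a nonstandard Y − O rule (497.2 for
C-7); these are deliberately not reproduced.

Cross-ring chemistry comprises the 0,2X ion (precursor − 120.0423,
the O-glycoside diagnostic) and charge-remote terminal-ring cleavages
emitted as 0,2A (−C2H4O2, 60.0211) and 0,3A (−C3H6O3, 90.0317) losses
from the precursor and from every Y ion.  The 0,4A2 and 3,5A2 candidates
are emitted with a `diagnostic_absent` flag: their absence from a
spectrum is the linearity argument for the glycan chains, and they never
count toward match scores.  Small neutral losses (CH3•, H2O, CO, CH2O,
CO2, C4H8; combinations to depth 2) are generated from the precursor and
from each B/Y ion.  TMC and IBF ring cleavages are fixed diagnostic
tables at the 1-decimal precision such ions are reported with.

**Scoring.**  `match_msms` matches at ±0.3 Th (product ions are reported
at 1 d.p.) and scores only *structure-specific* ions — glycosidic,
cross-ring, ring-cleavage and stored diagnostics.  Generic
small-neutral-loss products explain observed peaks but enter neither the
numerator nor the denominator: they carry almost no structural
information, and including them lets a candidate win simply by emitting
fewer predictions.  For the same reason, `rank_candidates` orders by
matched-ion count first (absolute evidence), then score, then summed
|Δm/z|.  A consequence worth knowing: when one topology's ion set is a
mass-subset of another's (C-7 as (4,3) vs (6,1)), the richer true
topology can only tie, never lose; it wins outright whenever any
chain-length-discriminating ion (B5/C5/B6/C6) is present.  Under 30%
simulated fragment dropout this happens in ≈99% of spectra; the
remaining ties are genuinely evidence-free.

Against the published high-energy CID product-ion lists for C-1..C-5,
the union of generated ions matches 72% of entries at ±0.3 Th (the
suite enforces ≥60%).  The unmatched remainder is dominated by
charge-remote fragments of the crocetin polyene core (e.g. 259.1,
335.2), which this model intentionally does not attempt.

## Peak processing

Peak lists are centroided, positive-mode, singly charged.  The S/N
filter mirrors the instrument-side automatic discard (threshold 200 by
default); peaks without an S/N estimate are kept with a warning.
Accurate-mass fingerprint matching uses a 10 ppm default tolerance —
the nominal instrument accuracy is 5 ppm, but reported high-mass crocin
values deviate by up to ~26 ppm, so the tolerance is configurable
per run.  A peak keeps every assignment within tolerance, ranked by
|Δppm|, so the 369.13 isobar pair yields two flagged assignments
rather than a forced choice; exact ties prefer crocins, then the
internal standard, then lexicographic name, making output deterministic.

Glycoform ladders are maximal arithmetic chains at 162.0528 ± 0.05 Th
(each peak links to its nearest successor); Na/K adduct pairs are peak
pairs at 15.9739 ± 0.02 Th.  Isotope-cluster areas (ICA) sum peak areas
at mono m/z + k·1.00336 for k = 0..3 within ±0.05 Th; four
isotopologues cover >99.9% of the envelope for all ions in range, and a
missing monoisotopic peak is an error rather than a zero.  Peaks without
an explicit area use intensity as a proxy.

mzML input is handled by a deliberately small internal reader for
centroided spectra (32/64-bit float arrays, optional zlib compression,
first MS1 scan); CSV peak lists (`mz,intensity[,area][,snr]`) are the
primary format.

## Quantitation

The measurement statistic is the molar ratio
MR_S = ΣICA_S / (ΣICA_S + ΣICA_T), with ICA_S the isotope-cluster areas
of the C-2, C-3 and C-4 sodiated crocins and ICA_T the area of the m/z
369.13 internal-standard cluster.  Because curcumin and the picrocrocin
K adduct are unresolvable, that cluster physically contains both; the
endogenous picrocrocin contribution is part of the blank signal.

Calibration is ordinary least squares of response on adulteration level
(% w/w), with standard errors from the residual variance, regression
ANOVA F on (1, n−2) degrees of freedom, 95% t-intervals, and a recorded
check of whether zero lies in the intercept CI.  MR_S decreases with
adulteration; the fit accepts either orientation (MR_S or 1−MR_S) and
records which was used.  Detection limits follow the IUPAC blank-based
formulas S_LOD = S_RB + 3σ_RB and S_LOQ = S_RB + 10σ_RB over ≥3
0%-adulteration replicates (sample SD, n−1); percent-domain limits
invert the calibration line anchored at the blank mean, which reduces to
kσ_RB/|slope| and is therefore orientation-agnostic.  The complementary
maximum quantifiable adulteration is 100 − LOD%.  Unknowns are
quantified by inverse prediction with the first-order standard error
(s/|b|)·sqrt(1/m + 1/n + (x̂−x̄)²/Sxx); estimates outside the calibrated
range are flagged as extrapolated.  Replicate summaries report
RSD% = 100·SD/mean and accuracy as 100·mean/true (the spiked-recovery
convention; a |bias|-based alternative is available).

## Synthetic-data generator

The simulator produces everything the pipeline consumes, with known
ground truth and full seed determinism (`numpy.random.default_rng`).

*MS1 spectra*: each compound × adduct emits its truncated isotope
envelope at the theoretical m/z perturbed by a systematic ppm bias plus
Gaussian ppm jitter (default 3 ppm, matching a MALDI-TOF accuracy of a
few ppm); the total envelope area equals moles × response factor ×
adduct weight exactly before noise.  Default adduct weights are
Na:K = 3:1 (sodium-dominant cationization); curcuminoids ionize
protonated.  Spurious noise peaks (default 50) are drawn uniformly over
the 200–2000 Th window with S/N below the 200 threshold, so the S/N
filter separates signal from noise by construction.

*MS/MS spectra*: the theoretical fragment list with per-ion dropout,
lognormal intensities and ppm jitter.

*Calibration series*: the default design is 8 levels spanning 0–30%
(w/w) in triplicate.  Crocin cluster areas scale with the saffron mass
fraction (1 − x/100); the 369.13 cluster is a picrocrocin baseline
(5% of the crocin signal) plus a curcumin response of
(total saffron signal)/100 per percent.  That response constant makes
the total integrated signal independent of x — an ion-competition
picture of MALDI in which the adulterant takes over the displaced
saffron's share of a fixed ion yield — and the noise-free MR_S exactly
linear in x (slope −0.00952/%, intercept 0.952).  All areas carry
multiplicative lognormal noise with σ = 0.015 (≈1.5% RSD, consistent
with replicate RSDs below 2%); the resulting calibrations have
R² ≈ 0.995–0.9995.  The ground-truth sidecar stores the generative
parameters, the noise-free responses, and the OLS line through them,
which a zero-noise fit recovers exactly.

What the simulator does *not* emulate: profile peak shapes, baseline and
matrix-cluster chemistry, detector saturation, suppression that varies
across the plate, and real relative MALDI response factors of crocins vs
curcumin (not publicly established; exposed as free parameters).
Passing tests therefore demonstrate correctness of the computational
pipeline under a controlled instrument model, not analytical validity on
any particular spectrometer — the published figures of merit (LOD 1.1%,
accuracy ≈98%) derive from raw instrument data that is not deposited and
are not reproduced here.

## Screening logic

Per-sample verdicts for three adulterant classes, each "positive",
"excluded" or "inconclusive" (never a guess when required MS/MS is
missing):

* **turmeric** — MS/MS of the m/z 369.13 precursor decides the isobar:
  ≥2 exclusive picrocrocin daughters (337/309/225/207) excludes
  turmeric, ≥2 exclusive curcuminoid daughters confirms it; the shared
  −H2O daughter at 351 is ignored.  Without MS/MS, the full MS1
  curcuminoid triplet 369.13/339.12/309.11 counts as positive; a bare
  369.13 is inconclusive.
* **calendula** — MS/MS of the 641.17 di-O-glycoside: the
  641 → 478 → 339 aglycone cascade confirms, its absence excludes;
  MS1 markers alone are inconclusive.
* **gardenia** — the geniposide Na/K adduct pair 411.13/427.10 at the
  15.974 Th spacing; a single adduct is inconclusive.

## Numerical conventions and degenerate inputs

m/z is carried at full double precision and printed at 4 d.p.; reported
reference comparisons use the precision the reference value is quoted
at.  Sample SDs use n−1 throughout.  A calibration slope below 1e-12 in
magnitude raises rather than producing absurd inversions.  Empty peak
lists, empty registries, unknown adducts/skeletons/compounds, negative
counts after adduct arithmetic, and single-level calibration designs are
all explicit errors.  Reports embed the resolved configuration and
registry version and contain no timestamps, so reruns are byte-identical.

## Problem sizes

The test suite runs the Monte-Carlo properties at the scales chosen for
the package's own verification: 100 seeded repetitions for slope-CI
coverage (n = 74 points per fit) and calibration linearity, 100 seeded
MS/MS topology classifications, and 50 end-to-end
calibrate-then-quantify runs plus one full spectrum-level pipeline at
11 calibration spectra.
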