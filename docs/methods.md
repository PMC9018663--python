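# Methods

## The screening problem

Oily injection preparations used for illicit growth promotion contain one
or more anabolic steroid esters at high concentration. The screening
instrument is an ASAP source on a single quadrupole: a 2 µL extract is
desorbed from a glass capillary in hot nitrogen, ionized by corona
discharge, and scanned in positive mode over *m/z* 50–600. There is no
chromatographic separation and only unit mass resolution, so specificity is
obtained by acquiring the same desorption event at four sampling-cone
voltages (channels at 12, 20, 30 and 40 V). At 12 V the protonated molecule
is essentially the only analyte ion; increasing cone voltage drives
in-source fragmentation, and the voltage-resolved fragment pattern is the
compound's fingerprint.

## Compound registry and mass arithmetic

The panel is 17 steroid esters. Masses are *nominal* (integer mass numbers
of the most abundant isotope, C=12, H=1, N=14, O=16, S=32; no electron-mass
correction), the regime in which a quadrupole reports centroids; a
monoisotopic variant is provided for future high-resolution use. Neutral
formulas are fixed from chemical identity and every [M+H]⁺ value is
validated against the registry's monitored SIR *m/z* list at import time.

One deliberate inconsistency is preserved: for testosterone isocaproate
(`T Iso`, C₂₅H₃₈O₃, [M+H]⁺ 387) the monitored SIR value on the instrument
method is 289 — protonated testosterone, not the ester. The record stores
both numbers and exposes `sir_mz_discrepant=True` rather than silently
correcting either; with the default synthetic profiles the consequence is
that a `T Iso` hit can never be SIR-confirmed (its *m/z* 289 trace is
baseline), which the confirmation layer reports honestly.

Fragment ions carry elemental formulas only where an assignment is
established (nine such assignments, each checked against its printed
nominal mass); fragments with unclear pathways (e.g. *m/z* 279 of the
trenbolone esters, *m/z* 159 of the estradiol esters) are stored without a
formula. Nortestosterone phenylpropionate and drostanolone enanthate have
no published assignments for this source; their registry fragments (257/155
/109 and 287) are this package's own choices, made so every panel member
has a usable fingerprint.

## Preprocessing

Applied identically at library build and query time, in this order:

1. restrict to the acquired range, 50 ≤ *m/z* ≤ 600 (boundaries inclusive);
2. bin centroids to nominal *m/z* (round-half-to-even; intensities in the
   same integer bin are summed — banker's rounding is stated explicitly
   because quadrupole centroids sit near half-integers often enough to
   matter);
3. normalize to relative intensity, base peak = 100;
4. discard peaks with relative intensity below 5%. The threshold is read
   *inclusively* (a peak at exactly 5.0% survives) and is configurable.

The chain is idempotent, never removes the base peak, and is applied with
the library's stored build parameters whenever a query is screened, so
query/library preprocessing cannot diverge.

No background subtraction or baseline correction is performed anywhere.

## Library and MSP serialization

A library entry is one compound's four preprocessed channel spectra. If
replicate acquisitions of a standard are supplied they are averaged
peak-wise *before* thresholding (variance reduction; a peak hovering around
5% is then kept or dropped by its mean, not by one replicate's luck).

Entries are serialized to NIST-style MSP text, one `Name: <abbr>@<V>V`
block per compound × voltage with machine-readable
`Comment: Compound=<abbr>; ConeVoltage=<V>V` fields, readable by generic
MSP tools. Relative intensities are quantized to 0.1% steps at build time
and written as integers on a 0–1000 scale, which makes the MSP round trip
*lossless*: a library rebuilt from its own file yields bit-identical match
scores. The reader tolerates Windows and Unix line endings and both `;`-
and whitespace-separated comment fields.

## Matching and the hit rule

The vendor score used on the instrument is proprietary. The open
replacement is the de-facto standard for unit-resolution library search:

    score(q, r) = round_half_up( 1000 · cos(√q, √r) )

with the square-root-transformed intensity vectors laid out on the union of
the two spectra's nominal bins. It is symmetric, exactly 1000 for identical
spectra, 0 for disjoint peak sets. Channel scores are fused as a weighted
arithmetic mean (equal weights by default, computed on the rounded channel
scores). A compound is a **hit** iff, jointly (all ≥, boundaries pass):

* channel 1 (12 V) score ≥ 850,
* each of the 20/30/40 V scores ≥ 825,
* fused average ≥ 800.

Because the conjunction can only remove hits relative to the average-only
rule, the panel false-positive rate under the full criteria is provably ≤
the rate under "average ≥ 800" on any data — the mechanism by which the
per-channel conditions suppress false positives. Result lists are sorted by
average score, ties broken lexicographically for determinism.

### Known limitation: cocktails under a symmetric score

The union-bin cosine penalizes *extra* query peaks. A cocktail of three
compounds at comparable levels has, at 12 V, three near-orthogonal [M+H]⁺
peaks; for any normalized-inner-product similarity the squared scores of
mutually orthogonal references against one query sum to ≤ 1, so three
constituents can never simultaneously reach 0.85 on channel 1 (that would
need 3 × 0.85² ≈ 2.17). Cocktail constituents therefore score ~550–700 at
12 V and are *not* hits under the default score, even noise-free. This is
intrinsic to symmetric scoring, not a bug: real multi-compound samples on
this kind of instrument are evidently scored by a presence-tolerant
(asymmetric) method. The package ships such a variant,
`channel_score(..., kind="reference")` (cosine restricted to the reference
entry's bins, insensitive to extra query ions), under which seeded
3-compound cocktails are recovered with zero false negatives; it is off by
default because the default score's symmetry, self-match and disjoint-set
properties are part of this package's contract. Its own weakness is the
converse one: a single-peak 12 V reference is "confirmed" by *any* ion at
that *m/z*, so it should be used together with SIR confirmation.

## SIR confirmation

All 17 monitored *m/z* values are recorded as 12 V chronograms. A hit is
confirmed iff its trace shows peak-to-peak S/N ≥ 3 (the conventional
detection limit; configurable): S/N = (apex − median of a noise window) /
(max − min of the window), the noise window defaulting to the leading 25%
of the trace. The apex is the global maximum (earliest sample on ties); the
peak region is the contiguous stretch above 5% of apex (harmonized with the
spectral threshold), integrated by trapezoid. Confirmation is monotone:
`sir_confirmed ⊆ hits`, a missing trace yields "unconfirmed" with a warning
rather than an error, and non-hits are left untouched.

## Performance statistics

* **ME%** = 100·(A_matrix − A_solvent)/A_solvent (negative = suppression).
* **RSD%** = 100·(sample SD)/mean over replicate responses.
* **Linearity**: OLS of response vs concentration; *r* is the Pearson
  correlation (working range 10–500 mg/L in the default scenarios).
* **MLOD**: OLS of peak-to-peak S/N vs concentration through the lowest
  (default 3) levels with finite S/N; MLOD is the concentration at
  S/N = 3, clipped to positive; flat or decreasing S/N is "not estimable".
* **FP%/FN%** are per-panel-compound: FP over the non-spiked library
  members of a sample, FN over the spiked ones.

## Synthetic acquisitions

The generator's defaults are the study conditions; they were chosen once:

| parameter | default | rationale |
|---|---|---|
| spike level / dilution | 100 mg/L, 100-fold | standard screening level; oily samples are diluted 100-fold in acetonitrile |
| detector response | 1e5 counts per mg/L (post-dilution) | puts a 100 mg/L spike at ~1e5 counts, well above noise, below saturation |
| intensity noise | lognormal, σ = 0.05 | few-percent run-to-run variation typical of probe loading |
| oil matrix | 80 seeded ions, exponential mean 1000 counts, *m/z* biased to 100–300 | dense low-mass interference visible in blanks yet small against a 100 mg/L spike, so spiked oily samples still screen positive — with occasional unlucky draws pushing interference above the 5% cut and costing a channel-1 hit (the realistic matrix false-negative mechanism) |
| saturation cap | 1e6 counts | detector ceiling; clipping distorts relative intensities exactly as saturation does |
| fragmentation | precursor 100/100/75/45 and fragment scale 4/28/60/90 (relative) at 12/20/30/40 V, geometric decay 0.85 across a compound's fragment list | reproduces the qualitative pattern: [M+H]⁺ base peak at 12 V with sub-threshold fragments, fragment-dominated spectra at 40 V, fragment-count monotone in voltage |
| SIR peak | Gaussian σ = 0.25 s, apex at 2 s of a 4 s trace, 10 Hz, baseline 200 ± 50 counts | the ±2.45σ span above 5% of apex is ~1.22 s, i.e. 12–13 samples at 10 Hz and ~3 at 2 Hz, matching the scan-rate trade-off the method is built around |

The SIR apex is proportional to the sample's noise-free 12 V signal at the
monitored *m/z*, times a lognormal run factor (desorption variability).

What the generator does **not** emulate: real relative fragment abundances
(unpublished — the decay model is structural only), ionization suppression
or enhancement by matrix (synthetic ME% ≈ 0), desorption-temperature
profiles, carry-over, and instrument-specific mass accuracy drift. Passing
tests therefore demonstrate the correctness of the *pipeline* (formats,
preprocessing, scoring, decision logic, statistics) under realistic signal
structure, not quantitative agreement with any instrument's measured
scores, MLODs or matrix effects.

## Numerical conventions

* Spectral binning: round-half-to-even; channel scores: round-half-up.
* 5% thresholds (spectral and chronogram-region) are inclusive.
* Apex ties → earliest time; rank ties → lexicographic by abbreviation.
* Library intensities quantized to 0.1% steps (lossless MSP round trip).
* Empty or all-zero spectra are rejected at normalization; a blank oily
  sample still screens (its matrix ions form the spectrum) and produces
  zero hits.
* Seeds: every stochastic routine takes or derives a `numpy` seed
  sequence; identical seeds give identical acquisitions on any platform.

## Problem sizes used in the shipped evaluations

The default end-to-end evaluation screens 100 seeded samples (singles and
3-compound cocktails, oil matrix on) against the 17-entry library, and the
performance statistics use 6-level calibrations and 6 replicates; the whole
evaluation runs in a few seconds on one CPU.
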