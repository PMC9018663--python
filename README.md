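# asapscreen

Screening of anabolic steroid esters in oily injection preparations by
spectral library matching of multi-cone-voltage ASAP–MS acquisitions.

Illicit veterinary preparations are typically oily cocktails of steroid
esters (testosterone, nortestosterone, boldenone, estradiol, trenbolone and
drostanolone esters). A compact atmospheric-solids-analysis-probe (ASAP)
source on a single-quadrupole instrument can flag these in about a minute,
but with no chromatography and unit mass resolution, specificity has to come
from **in-source fragmentation fingerprints**: the same sample is scanned in
one run at four sampling-cone voltages (12, 20, 30, 40 V). At 12 V the
protonated molecule [M+H]⁺ dominates; at higher voltages each compound
produces its characteristic fragment ions (e.g. ester cleavage of
testosterone esters to *m/z* 271 [C₁₉H₂₇O]⁺, B-ring cleavage to *m/z* 109
and 105). This package implements the full screening workflow for a
17-compound panel:

1. **Library build** — reference spectra of each standard at the four
   voltages, preprocessed identically to queries (*m/z* 50–600, nominal
   binning, relative intensities, 5% threshold, no background subtraction)
   and stored in NIST MSP text format.
2. **Matching** — per-channel similarity on a 0–1000 scale
   (`score = round(1000·cosθ)` between √intensity vectors on the union of
   nominal *m/z* bins), fused as a weighted average across channels.
3. **Hit decision** — a compound is a *hit* iff channel 1 (12 V) ≥ 850,
   each remaining channel ≥ 825 **and** the average ≥ 800. The per-channel
   conditions are what suppresses false positives relative to an
   average-only rule.
4. **SIR confirmation** — hits are cross-checked against selected-ion-
   recording chronograms of the 17 monitored [M+H]⁺ values at 12 V
   (peak-to-peak S/N ≥ 3); confirmation can only remove detections.
5. **Performance statistics** — matrix effect (ME%), intra-day precision
   (RSD%), calibration linearity (Pearson *r*), method limit of detection
   (MLOD, from S/N = 3 interpolation), and panel-wise FP/FN rates.

A seeded synthetic-acquisition module emulates the instrument (voltage-
dependent fragmentation, additive mixtures, oil-matrix interference,
detector saturation, ~2 s Gaussian desorption peaks at 10 Hz), so the whole
pipeline is testable without instrument data.

## Worked example

```python
from asapscreen import LibraryMatchScreener, screen
from asapscreen.synthetic import SampleDefinition, reference_library, simulate_acquisition

library = reference_library()                # 17 standards, 4 channels each
sample = SampleDefinition({"T Pr": 100.0},   # testosterone propionate, 100 mg/L
                          matrix="oil", seed=42)
acquisition, chronograms = simulate_acquisition(sample)

for r in screen(acquisition, library)[:3]:
    print(r.compound, r.channel_scores, r.average_score, r.hit)
```

prints

```
T Pr {12: 973, 20: 976, 30: 991, 40: 984} 981.0 True
T Ac {12: 0, 20: 410, 30: 673, 40: 825} 477.0 False
T Bz {12: 0, 20: 410, 30: 673, 40: 825} 477.0 False
```

The spiked compound scores ≥ 973 on every channel and is the only hit; the
other testosterone esters share their high-voltage fragments (so their 20–40
V scores are substantial) but have the wrong [M+H]⁺ at 12 V, which the
channel-1 criterion catches. The same pipeline is scriptable from the shell:

```bash
asapscreen simulate --out runs/sim --seed 7 --n-samples 5
asapscreen build-library --standards runs/standards --out runs/library.msp
asapscreen screen --library runs/library.msp --input runs/sim/sample_000.csv --out runs/report
asapscreen confirm --report runs/report/screening_report.csv \
    --sir runs/sim/sample_000_sir.csv --out runs/confirmed.csv
```

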