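# heflim

Quantitative fluorescence-lifetime (FLIM) analysis of H&E-stained tissue
sections, aimed at separating cancerous from adjacent peritumoral liver
tissue. Conventional H&E histopathology is morphological and qualitative;
time-correlated single photon counting (TCSPC) FLIM adds a per-pixel physical
observable — the eosin fluorescence lifetime — that differs markedly between
the two tissue classes. `heflim` provides the full computational chain for
this kind of study, plus a synthetic-data generator so every stage is testable
without microscope data.

## What it computes

**Biexponential lifetime fitting.** Each pixel's photon-arrival histogram is
modelled as

    I(t) = a₁ exp(−t/τ₁) + a₂ exp(−t/τ₂) + bg

fitted by weighted least squares, and summarised by the amplitude-weighted
mean lifetime

    τₘ = (a₁τ₁ + a₂τ₂) / (a₁ + a₂)

rendered as a pseudo-colored map (blue → green → red over 500–3500 ps).

**Phasor analysis.** Each decay maps to phasor coordinates

    G = Σ I(tᵢ) cos(nωtᵢ) / Σ I(tᵢ),   S = Σ I(tᵢ) sin(nωtᵢ) / Σ I(tᵢ)

with ω = 2πf the laser angular repetition frequency (f = 76 MHz) and harmonic
n = 1. Single-exponential decays fall on the universal semicircle of radius ½
centered at (½, 0); mixtures fall inside it on the chord joining their
components. Pixels are grouped by k-means on (G, S) and mapped back to the
image as a fit-free segmentation.

**Region statistics.** Lifetime images are split into four clockwise
quadrants; quadrant means feed a pooled-variance Student t-test between the
cancerous and peritumoral groups. Per sample, lifetimes are normalized so the
peritumoral mean is 1, giving a cancerous/peritumoral lifetime ratio that is
correlated (Pearson) against clinical liver-function indicators
(bilirubin fractions, transaminases, AFP, …). A 4-patient indicator table is
packaged for the correlation stage.

**Synthetic data.** TCSPC cubes (256 time bins over one 76 MHz period) are
simulated per region as Poisson counts around a mixture decay. The default
study uses a short/long component pair of 600/2600 ps with amplitude fractions
0.85/0.15 (peritumoral, mean 900 ps) and 0.20/0.80 (cancerous, mean 2200 ps),
inside the 500–1000 ps and 2000–2500 ps ranges reported for the two tissue
classes.

## Worked example

`examples/01_simulate_and_fit.py` simulates a 32×32 half-plane image (top
half peritumoral, bottom half cancerous, 5000 photons/pixel) and fits every
pixel:

```
fitted 1024 of 1024 pixels
peritumoral mean tau_m :   888.1 ps (design 900)
cancerous   mean tau_m :  2153.2 ps (design 2200)
median reduced chi^2   :    0.92
```

The fitted region means recover the generative design values within a few
percent and sit over 1200 ps apart — the separation the method exploits.
`examples/02_phasor_segmentation.py` shows k-means phasor clusters landing on
the theoretical universal-circle positions of their generating lifetimes;
`examples/03_clinical_correlation.py` prints the Pearson correlations of the
packaged patient table (total bilirubin: r = 0.79);
`examples/04_full_pipeline.py` runs the whole study end to end
(t = 475.5, p = 1.2e-45 for 12-vs-12 quadrant means at 24×24 pixels).

A thin CLI wraps the same stages:

```sh
heflim simulate --size 64 --photons 5000 --seed 7 --out cube.h5
heflim fit --in cube.h5 --out fit
heflim phasor --in cube.h5 --k 3 --seed 7 --out ph
heflim run --seed 7 --size 64   # full pipeline with manifest
```

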