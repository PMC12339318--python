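# Methods

## Generative model

A TCSPC acquisition is modelled as a cube of independent Poisson counts: for
pixel (i, j) in region ℓ with mixture {(aₖ, τₖ)} and photon budget N, the
expected count in the time bin centered at t is proportional to
Σₖ aₖ exp(−t/τₖ), rescaled so the expectation over the window sums to N.
Defaults: 256 bins spanning exactly one laser repetition period
(f = 76 MHz → 13.158 ns, bin width 51.4 ps). Fluorescence decays, so the
exponents are negative by construction.

Two options extend the model and are off by default, keeping closed-form
checks exact: a Gaussian instrument response (IRF) of configurable FWHM,
applied by circular convolution, and incomplete-decay wrap-around (photons
from preceding pulses, the geometric-series correction
1/(1 − e^{−T/τ})). The defaults amount to assuming an ideal delta IRF and a
window long enough that inter-pulse carryover is negligible — adequate for
the 600–2600 ps lifetimes simulated here, where e^{−T/τ} ≤ 0.6 % of a pulse
survives the 13.2 ns period.

The default tissue classes share the component pair τ = (600, 2600) ps and
differ only in amplitude fractions: peritumoral a = (0.85, 0.15), mean
900 ps; cancerous a = (0.20, 0.80), mean 2200 ps. These were chosen once so
the amplitude-weighted means sit inside the 500–1000 ps and 2000–2500 ps
ranges that distinguish the two tissue classes, with a shared component basis
(the biologically plausible reading: same fluorophores, different
microenvironment weighting). The photon budget of 5000 per pixel is a
realistic mid-range TCSPC dose; a "necrotic" label emits 2 % of it to
exercise masking, and "background" emits nothing.

Randomness uses one root seed; each pixel draws from a child stream keyed on
(seed, row, col), so a simulated cube is reproducible and independent of
pixel iteration order (a sub-window of a larger layout reproduces the same
draws).

### What the generator does not emulate

No spatial point-spread blur, detector afterpulsing, pile-up, dye-spectrum
structure, or spatial heterogeneity within a region. Passing tests therefore
demonstrate correctness of the estimators under the stated statistical model,
not robustness to every artifact of real acquisitions; in particular the
group-separation p-values on synthetic data are far smaller than tissue data
would give, because real regions are spatially heterogeneous.

## Lifetime fitting

Per pixel, the model A₁e^{−t/τ₁} + A₂e^{−t/τ₂} + bg is fitted by weighted
least squares with a trust-region reflective optimizer (scipy
`least_squares`) under bounds τ ∈ [50, 10000] ps, amplitudes and background
≥ 0. The weights are 1/σ̂ with σ̂² estimated from a 7-bin moving average of
the counts rather than the raw per-bin counts: raw Neyman weights
(var ≈ max(counts, 1)) correlate the weight with the noise in each bin and
bias lifetimes low by ~3–4 % at 5–10k photons, which smoothing reduces to
~1–2 %. Setting `weight_smoothing=1` restores raw-count weighting.

Initialization is moment-based — τ₁, τ₂ start at 0.5× and 1.5× the empirical
mean photon delay — followed by a linear least-squares solve for the
amplitudes and background at those lifetimes. Optimizer tolerances
(ftol = xtol = gtol = 1e-4) were chosen from accuracy/runtime benchmarks:
tightening to 1e-8 changes recovered τₘ by well under the Poisson scatter
while roughly doubling runtime. Components are reported in canonical order
τ₁ ≤ τ₂ (swap on construction), making the fit invariant to exchanging the
two components' initialization.

Pixels with fewer than 100 total photons are masked, not fitted (the
conventional threshold below which a four-parameter fit is meaningless).
An optional k×k spatial pre-binning pools neighborhoods for dim data.
Reduced χ² is reported per pixel from the weighted residuals. Display
histograms clamp τₘ into the 500–3500 ps range at the edge bins; exported
values stay unclamped.

## Phasor analysis

G and S are computed as rectangle-rule sums over bin centers. Discretization
biases the phasor by O(bin width/τ); with 51.4 ps bins this stays within the
10⁻³ fidelity checked by the tests for τ ≳ 150 ps, and can be removed
entirely by calibration — a rotation/scaling in the phasor plane determined
from a reference of known lifetime. Calibration is optional and off by
default because the synthetic data has a delta IRF and known timing.

Cluster identification uses k-means on (G, S) with k-means++ seeding and a
fixed random state (default k = 3). Clusters are relabelled by descending
mean lifetime, taken from the paired lifetime image when available and from
the cluster center's phase lifetime otherwise. Phase and modulation
lifetimes invert the phasor coordinates as τ_φ = S/(Gnω) and
τ_M = (1/nω)√(1/(G²+S²) − 1); they agree on the universal circle and bracket
mixtures (τ_φ < τ_M inside). Noisy phasors may scatter slightly outside the
semicircle; invariant checks on Poisson data use a 0.02 tolerance.

## Region statistics

Quadrants are numbered clockwise from the top-left (1 = top-left,
2 = top-right, 3 = bottom-right, 4 = bottom-left); odd dimensions floor-split
so the top/left blocks are the smaller ones. The quadrants partition the
image exactly. The group test is the classical pooled-variance two-sided
Student t-test; two constant equal groups return t = 0, p = 1 by convention.
Per-sample normalization divides every measurement by that sample's
peritumoral mean, which is therefore exactly 1 and makes all normalized
values scale-invariant.

Pearson correlations of the lifetime ratio against indicator columns are
reported to 2 decimals, matching the packaged table's precision. With n = 4
patients these correlations are descriptive; no p-values are attached.
Recomputing correlations from the packaged table's printed columns
reproduces the total-bilirubin entry (r = 0.79); the table's other published
correlation entries do not recompute from its printed columns and are left
as reported values, not assertions.

## Problem sizes

The test suite simulates and fits three 32×32 images per tissue class (the
statistical study), a 7-point τₘ recovery grid at 10⁴ photons × 60
replicates, and smaller unit fixtures; `scripts/acceptance.py` fits six
64×64 cubes at 5000 photons/pixel. These sizes give per-region standard
errors of a few ps — ample for the 1300 ps class separation — while keeping
a full run in tens of seconds to a few minutes.

## Known limitations

- Per-pixel independent fits only; no global (shared-τ) or maximum-likelihood
  fitting.
- Harmonic n = 1 analysis; no multi-harmonic unmixing or phasor denoising.
- The IRF model is Gaussian and shared across pixels.
- Clinical correlation with n = 4 cannot support inference; the synthetic
  clinical generator calibrates the population r, so small-sample scatter in
  the sample r is expected and tested only at n = 200.
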