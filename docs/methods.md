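# Methods

This note documents the models, parameter choices and numerical behavior
behind `dyadsync`, including the places where the design was genuinely
open and what the synthetic-data tests do and do not establish.

## Signal model of the synthetic dyads

Each subject's long-channel HbO signal is built from four parts, in μM:

* **Coupled neural fluctuations.** Per homologous channel pair, a common
  Gaussian process band-passed to the coupling band (default
  0.05–0.1 Hz, 4th-order Butterworth, unit variance) is mixed into both
  subjects with amplitude ratio `strength**(1/4)` against an independent
  band-limited residual of complementary variance. With unit-variance
  components, the magnitude-squared spectral coherence inside the band is
  `alpha⁴`, so this mixing makes the *true squared coherence equal the
  requested strength* — the quantity WTC estimates. (Using
  `sqrt(strength)` — the natural first guess — would give coherence
  `strength²`.)
* **Broadband hemodynamic background** (default amplitude 1.0 relative
  to the band component): white noise low-passed at 0.5 Hz, the
  approximate bandwidth of vascular dynamics. Its spectral floor is what
  keeps spectral leakage of the coupled band from masquerading as
  out-of-band coherence: coherence is scale-free, so without a floor even
  −40 dB leakage would read as strongly coherent.
* **Superficial (scalp) component**, shared between a subject's short
  and long channels and entering long channels scaled by `scalp_gain`
  (default 0.4): cardiac, respiratory and Mayer-wave sinusoids plus white
  noise. Oscillation frequencies are drawn **per subject**
  (cardiac N(1.2, 0.072) Hz, respiratory N(0.3, 0.03), Mayer
  N(0.1, 0.012)); two subjects sharing exactly the same deterministic
  frequency would be trivially phase-locked and show spurious coherence.
* **Chromophore model.** Neural activity moves HbR opposite to HbO
  (ratio −0.25); the blood-volume-driven scalp component moves them in
  phase (+0.3). The ratio −0.25 is also deliberate numerically: −0.4
  almost exactly cancels the 760 nm extinction combination
  (1486 − 0.4·3844 ≈ −51 cm⁻¹/M), which would hide all neural-signed
  content from one wavelength and floor the scalp coupling index.

Forward optics: `ΔOD = E · [HbO, HbR] · d · DPF` with the standard
extinction table, 3 cm long / 0.8 cm short separations, DPF 6.0 at both
wavelengths, then `I = I₀ · exp(−ΔOD)` plus 0.3% RMS per-wavelength
sensor noise — the sample-to-sample noise level that dominates temporal
derivatives, the operating regime robust motion correction assumes.
Motion events are Poisson in time (`artifact_rate` per minute per
channel): spikes of 1–3 samples at 5–20× the channel's OD SD (60%) and
step baseline shifts at 3–10× (40%), applied to both wavelengths and
recorded in the ground truth.

What the generator does **not** emulate: cortical geometry and optode
sensitivity profiles, 1/f spectral shape of real hemodynamics, nonlinear
or time-varying coupling, realistic conversational audio. Passing tests
therefore demonstrate correctness of the *pipeline* under a known
generative model, not clinical validity on real recordings.

## Preprocessing chain

Fixed order (enforced by `preprocess_dyad`): CV filter → OD → TDDR →
wavelet filter → SCI filter → Beer–Lambert → short-separation
regression.

* **CV filter.** Population SD / mean of raw intensity per wavelength,
  channel value = max over wavelengths, threshold 0.1.
* **TDDR** follows the published algorithm exactly (verified sample-level
  against an independent copy of the reference implementation): split at
  0.5 Hz, Tukey-biweight IRLS on the low-band derivative
  (c = 4.685, MAD scale), reconstruction by cumulative sum, high band and
  mean added back. Two properties matter for interpreting results. The
  biweight reweights **every** derivative sample (w(1σ) ≈ 0.91,
  w(2σ) ≈ 0.45), so even artifact-free signals are perturbed — a few
  percent for tone-like signals, tens of percent RMS when smooth
  narrowband hemodynamics dominate the low-band derivative. And the
  0.5 Hz split returns short spikes' high-frequency content untouched, so
  TDDR alone reduces a 1–3-sample spike by only ~30% at 7.81 Hz; the
  **wavelet step is what removes spikes** (>90% reduction for the pair,
  measured against the chain's clean-signal output).
* **Wavelet filter.** Orthogonal DWT (`db2`, periodization, full depth);
  detail coefficients outside `q1/q3 ± 3·IQR` (the boxplot far-outlier
  fence, ≈4.7σ for Gaussian data) are zeroed. The conservative factor
  leaves clean data essentially untouched while 10–20σ motion spikes are
  far outside the fence.
* **SCI**: cardiac band 0.5–2.5 Hz (3rd-order Butterworth, zero-phase),
  Pearson correlation between the two wavelengths' OD, threshold 0.8.
  The band is the conventional one; the source method names only the
  metric and threshold.
* **Beer–Lambert**: per-sample 2×2 solve; exact inverse of the forward
  model by construction.
* **Short-separation regression**: OLS with intercept of each long
  channel on all surviving same-subject short channels, per chromophore;
  residual returned. No short channel ⇒ pass-through with a warning.
* A channel pair enters the coherence stage only if **both** members
  survived QC.

Measured end-to-end fidelity on artifact-free data (0.01–0.2 Hz band):
per-channel correlation with the injected neural component 0.72–0.98,
median ≈ 0.90. The loss is almost entirely TDDR's nonlinear shrinkage;
it is the price of running the published motion correction, and the test
suite pins the achieved level rather than an aspirational one.

## Wavelet transform coherence

Analytic Morlet (ω₀ = 6), geometric frequency grid (default
0.01–0.7 Hz at 12 voices/octave; the heavy simulation studies use 8
voices over 0.02–0.7 Hz, and 0.03–0.35 Hz for 120 s blocks whose cone of
influence admits nothing slower than ~0.03 Hz). CWT via frequency-domain
multiplication on a zero-padded grid; cone of influence by the √2·s
e-folding rule. Smoothing per Torrence–Compo/Grinsted: Gaussian in time
with σ = s, boxcar over 0.6 octaves in scale, both renormalised at the
edges so self-coherence is exactly 1. An O(N²) explicit-convolution
oracle in the test suite reproduces the FFT implementation to 1e-6.

Two practical consequences of this standard estimator are worth stating.
Time-averaged null coherence is strongly biased upward (~0.33 for white
noise, up to ~0.45 for narrowband signals at 240 s) because the σ = s
smoothing window holds only a handful of independent wavelet samples —
absolute WTC values are therefore meaningless on their own, which is
precisely why task bins are selected *relative to the permutation null*.
And the frequency resolution (Morlet bandwidth ⊕ 0.3-octave scale
smoothing) smears a coupled band outward; in band-specificity studies,
bins within `resolution_guard_octaves` (≈0.79 octave: 5%-power Morlet
overlap + half the scale boxcar) of the injected band sense genuinely
coherent signal and are excluded from the false-selection count.

## Permutation null and bin selection

Null samples pair a child signal with a uniformly drawn non-partner
mother signal (the standard hyperscanning shuffle, preserving each
subject's autospectrum); distinct pairings are computed once with
multiplicities recorded (8 dyads have only 56 ordered non-partner
pairings for 200 draws). Per frequency bin, a one-sided Welch t-test
(real > null, two-sided available) at α = 0.05 selects task-related
bins; `n_perm = 0` skips selection and uses all bins. Selection masks
are computed per channel pair by default; a pooled-across-pairs mode
(one global mask per task) is available and is what the group-recovery
study uses — a single task-level frequency band is a common reading of
this selection step, and pooling all pairs' spectra reduces
mask-selection noise.

Because real and permuted means share the same subjects, the t statistic
is mildly conservative when spectra carry subject-specific signatures;
measured per-bin null selection rate is ≈0.037 at α = 0.05 through the
full chain (within two binomial SEs over 500 cohorts, the independent
unit being the cohort).

IBS: `z = atanh(mean coherence over selected bins)`, coherence clipped
at 1 − 10⁻⁶.

## Statistics

One-way ANOVA per channel pair, two-tailed post-hoc t-tests (Welch by
default — group sizes like 33/18/12 make pooled variance fragile),
BH-FDR across channel pairs within each task (the correction family is
configurable; applying it to the ANOVA p-values is the default, post-hoc
or both are options). Kendall tau-b with tie correction. Correlations
are computed only for channels flagged in the group stage and only
within the designated clinical group.

## Study conditions used by the validation studies

* Null calibration: 500 cohorts × 8 dyads, 120 s blocks, 200
  permutations, artifact-free; analysis 0.03–0.35 Hz, 8 voices.
* Band recovery: 20 seeds × 20 dyads, squared coherence 0.6 at
  0.05–0.1 Hz, 240 s, artifact rate 0.1/min; analysis 0.02–0.7 Hz.
* Group recovery: 20 seeds × (15/15/15) dyads, base coupling 0.2, +0.3
  delta on one of four channel pairs, 360 s blocks (the full cooperative-
  task duration), artifact rate 0.05/min, pooled masks, 200 permutations.
  The low artifact rate keeps QC attrition from silently shrinking the
  stated group sizes; artifact handling is exercised by its own tests.
* Association recovery: 50 seeds × 33 dyads (the clinical group size),
  symptom scores drawn from a Gaussian copula at Kendall τ = 0.4 against
  one pair's realised coupling strength.

## Known limitations

* The published TDDR perturbs clean narrowband signals (see above); a
  <5% clean-signal RMSE for the motion-correction stage is not
  achievable with the published algorithm and the corresponding check is
  expected to fail, documenting the fact rather than hiding it.
* Morpheme counting is a deterministic rule table (inflection suffixes,
  contraction splitting, an irregulars/exceptions lexicon); it
  approximates the conventional child-language counting rules and makes
  no claim of parity with any specific coding tool. Clause counting uses
  a surface subordinator list.
* TNW counts word tokens with fillers excluded (both choices exposed).
* Time-resolved (sliding-window) IBS, directed coupling measures, and
  optode-to-cortex registration are out of scope.
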