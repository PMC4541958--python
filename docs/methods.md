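# Methods

This note documents the models implemented in `etongue`, the choices made
where the published analysis chain leaves details open, and what the
synthetic data generator does and does not emulate.

## Signal model and acquisition geometry

A measurement excites the electrochemical cell with an isosceles triangle
potential wave (initial = low = final = −2 V, high = +2 V, scan rate
200 mV s⁻¹) sampled at 100 Hz, and records the current on four metallic
working electrodes simultaneously. One full cycle spans 4000 samples; the
reference acquisition reports 3986 points, which we model as the instrument
stopping acquisition slightly before cycle end (`make_excitation` emits
`n_points` samples of the periodic wave, default 3986). The canonical
channel order Pt, Ag, Au, Pd is fixed everywhere — feature indices are only
reproducible if the concatenation order never changes.

The full design is 4 varieties × 4 commercial samples × 5 replicate
measurements = 80 records per dilution level (0×, 5×, 10×, 100×), i.e. an
80 × (4 × 3986) data matrix. Class codes are fixed: 1 = JiaHe218,
2 = JiaHe66, 3 = XiuShui128, 4 = XiuShui134. The packaged reference
confusion matrices are printed in a different class order
(XiuShui134, XiuShui128, JiaHe218, JiaHe66); `ConfusionMatrix` therefore
carries its class order explicitly, and all indicator computations are
order-invariant.

## FFT compression and the fc fidelity score

`compress` keeps the first *k* one-sided DFT coefficients (index 0 = DC).
`reconstruct` zero-fills the rest and inverts with conjugate symmetry, so
output is real and exactly length-preserving. Numerical choices:

- **Features are coefficient magnitudes.** Whether the 16 retained
  "coefficients" should enter the model as magnitudes, real parts, or
  interleaved real/imaginary pairs is not specified anywhere; we use
  magnitudes because they are real, nonnegative, and give exactly the
  64-input topology. Discarding phase is a documented limitation: two
  time-shifted but otherwise identical traces produce identical features.
- **fc uses the union area.** fc is the ratio of the area shared by the raw
  and reconstructed curves to "the total area under both curves". Reading
  the denominator as the *sum* of areas would cap fc at 0.5 for identical
  curves, contradicting fc = 1 at perfect reconstruction, so the denominator
  is the area of the pointwise *union* (max). Signed traces have no
  well-defined "area under the curve", so both curves are shifted by their
  common minimum — but only when some value is negative; non-negative curves
  compare as-is (so constant curves 1 vs 2 score 0.5, not 0).
- **Rectangular sums,** not trapezoids: sampling is uniform and plain sums
  are bit-reproducible.
- **No windowing or detrending** before the transform.
- The compression ratio (1 − k/n) × 100 % is reported to two decimals by
  truncation (99.5986…% → 99.59 %), matching the convention of the reported
  value.

## Landmark features

The 18-value alternative feature set reads characteristic current values off
each electrode: 5 from Pt, 3 from Ag, 5 from Au, 5 from Pd. The original
points were circled by eye on current–time charts, so detection needed an
operationalization:

1. box smoothing (default window 25 samples, odd, reflect-padded);
2. candidates = extrema of the smoothed trace plus inflections (= extrema of
   its first difference), excluding one window at each record end so edge
   effects cannot spawn candidates;
3. ranking by prominence — inflection prominences (ampere/sample) are scaled
   by the window length onto the current scale; candidates below
   `min_prominence` (default 2 % of the channel's smoothed range) are
   dropped;
4. greedy selection of the top *m*, skipping candidates within one window of
   an already-selected stronger one; prominence ties break toward the lower
   index for determinism.

Features are the smoothed current *values* at the selected indices (not the
indices). Box smoothing biases sharp apex values low by a few percent; on
the generator's smooth Gaussian landmarks the bias is below 5 %.

## DFA

Implemented as multi-class canonical (Fisher) discriminant analysis: axes
solve S_b v = λ S_w v with at most min(g−1, p) informative axes. With 64
features and 80 samples S_w is singular, so it is ridge-regularized with
ε · trace/p · I, ε = 1e−6; the trace used is trace(S_w) + trace(S_b) so the
regularizer stays nonzero even in the fully degenerate zero-within-scatter
case (where the fit must still find the informative directions).
Contribution of axis *i* is λᵢ/Σλ; canonical correlation is √(λᵢ/(1+λᵢ)).
Axis signs follow the convention "first non-negligible loading positive" so
fits are reproducible. The distance classification rule uses all axes
(nearest class centroid, ties to the lowest class code); whether the original
rule used all axes or only two is unstated — we use all and document it.

The Discrimination Index has no published formula (it originates in
commercial e-tongue software). Our surrogate, DI = round(100 · SS_between /
SS_total) on the first two axes (half-up rounding to an integer), satisfies
the stated endpoints: DI = 100 exactly iff within-class scatter vanishes in
the 2-D map, and DI ≈ 0 for label-independent features at large n. Note that
with p ≫ n/g (64 FFT features, 20 samples per class) the regularized fit can
drive within-class scatter near zero even for weak class structure, so
in-sample DI saturates near 100; DI is a visualization summary here, not a
validated effect size — generalization is measured by the cross-validated
network instead.

## RBF network

Three layers, single linear output regressed on class codes 1–4
(kept as published, rather than one-hot outputs, despite the ordinal
artifact that confusing codes 1 and 4 costs more in the loss than confusing
neighbours):

- **Scaling:** features are z-scored with training-fold statistics (default).
  FFT magnitudes span orders of magnitude; without scaling, hidden-unit
  distances are dominated by the DC term.
- **Centers:** Lloyd's k-means with seeded deterministic maximin
  initialization (random first center from the fold seed, then repeated
  farthest-point selection); an empty cluster is repaired by moving its
  center to the point farthest from its assigned center. Hand-rolled (~40
  lines) because determinism and the exact variant matter more than library
  features. With n_hidden = n the centers are the training points (exact
  interpolation regime).
- **Spread:** σ = overlap coefficient (default 1.5) × mean distance over all
  distinct unordered center pairs. The Gaussian kernel uses the
  exp(−d²/2σ²) convention.
- **Weights:** least squares of [Φ | 1] against the codes (a bias column is
  added; codes 1–4 are not zero-centered). Prediction decodes the continuous
  output to the nearest code in {1,…,4}, ties toward the lower code,
  clipping outputs outside [1, 4].
- **LOOCV** retrains everything per fold — scaling, clustering (fold-derived
  seed), weights — on the 79-sample subset; clustering once on all 80
  samples would leak the held-out sample into the centers.

Default topologies: 64-32-1 (FFT features) and 18-13-1 (landmark features).

## Synthetic data generator

The generator emulates the *statistical* structure the analysis assumes, not
electrochemistry. Per channel, the noise-free class waveform is a small
capacitive baseline (0.05 × base amplitude per volt, following the triangle
potential) plus Gaussian bumps at fixed positions — the designed landmarks.
Signs alternate along the sweep so every interior extremum is a designed
landmark; each channel's dominant positive bump sits at/near the +2 V apex
and its deepest trough near a −2 V end, reproducing the peak/trough-at-the-
potential-extremes morphology. Pt/Au/Pd carry 5 designed landmarks, Ag 3.

Varieties differ by fixed multiplicative perturbations of bump amplitudes
(± `between_class_separation` × a per-class pattern). Stochastic layers, all
driven by one seed:

- **Sample offsets** (sd 4e−7 A per channel): constant shifts shared by a
  commercial sample's five replicates, emulating batch chemistry.
- **Replicate drift** (level + linear slope, sd = `drift_ratio` × noise_sd):
  slow electrode-polarization drift between measurements. Point-valued
  landmark features absorb drift in full, while FFT magnitudes confine it to
  the lowest coefficients — this is the mechanistic reason FFT features
  outperform landmark features here, mirroring the reported ordering.
- **White noise** (sd 8e−7 A i.i.d. per point): instrument sampling noise.

**Dilution** multiplies the deviation of each class waveform from the
grand-mean waveform by an attenuation factor (1.0 / 0.22 / 0.07 / 0.04 at
0×/5×/10×/100×), and scales the sample offsets by the same factor: diluting
the extract dilutes all sample-specific chemistry, while instrument noise
and drift are unaffected. This makes classes *converge* (producing genuine
confusion, not merely higher variance) and leaves the common waveform — and
hence landmark detectability — intact at every dilution.

Magnitudes (tens of µA) and all noise scales are pattern-scale choices, not
claims about rice solutions; no published quantitative noise or amplitude
figures exist. The defaults were calibrated once and frozen so that the
shipped-seed (1234) study reproduces the qualitative reference behaviour,
and they are ordinary config fields for anyone wanting other regimes. With
the shipped seed the FFT-mode LOOCV accuracies are 100 / 91.3 / 45.0 / 36.3 %
across 0×/5×/10×/100× (strictly decreasing; DI = 100 at 0×), and landmark-
mode accuracies (100 / 56.3 / 11.3 / 27.5 %) never exceed the FFT-mode value
at any dilution.

What passing tests on this generator do **not** show: robustness to real
electrode fouling, drift that correlates across channels, non-Gaussian
interferents, peak *position* shifts between varieties, or the reported
sub-chance collapse at 100× (real confusion matrices show systematic
misassignment below the 25 % chance floor; the synthetic floor sits at or
slightly above chance). Reproductions of the published fc table and DFA
eigenvalue table are out of reach without the original measurements; only
their qualitative trends (fc monotone in k; leading axes dominating the
contribution) are property-tested.

## Problem sizes and determinism

All shipped analyses use the full 80-record design; a complete two-mode,
four-dilution LOOCV study (640 network fits) runs in a few seconds. Every
random draw — generator noise, k-means initialization per LOOCV fold — is
derived from the top-level seed, so experiment summaries are byte-identical
across reruns; fold seeds are `seed + 1000003·fold (mod 2³¹)` and
per-dilution RBF seeds `seed + 97·dilution (mod 2³¹)`.
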