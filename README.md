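# etongue

Chemometrics toolkit for a **voltammetric electronic tongue** — a taste-sensing
system that records cyclic-voltammetry current responses of a liquid sample on
an array of four metallic working electrodes (Pt, Ag, Au, Pd) and classifies
the sample with multivariate pattern recognition. The reference application is
discriminating four rice varieties (JiaHe218, JiaHe66, XiuShui128, XiuShui134)
from their water-soluble extracts at several dilution levels; the same
machinery applies to any 4-channel voltammetric classification problem.

The package is aimed at food-chemometrics and sensor-array researchers who
want the full analysis chain as tested, scriptable Python rather than
instrument-vendor software.

## What it computes

A measurement is a 4 × 3986 block of currents from one triangle-wave potential
sweep (−2 V → +2 V → −2 V at 200 mV s⁻¹, sampled at 100 Hz). The analysis
chain is:

- **FFT compression.** Each 3986-point trace is reduced to its first
  *k* = 16 one-sided DFT coefficients (compression ratio
  (1 − k/n) × 100 % = 99.59 %). Reconstruction fidelity is scored with
  *fc* = Σᵢ min(f̃ᵢ, g̃ᵢ) / Σᵢ max(f̃ᵢ, g̃ᵢ) ∈ [0, 1] — the shared area of the
  raw and reconstructed curves over their union; fc = 1 iff reconstruction is
  perfect. The 16 coefficient magnitudes per electrode give a 64-value
  feature vector; alternatively, 18 **landmark features** (5/3/5/5
  characteristic peak/trough/inflection currents from Pt/Ag/Au/Pd) can be
  extracted.
- **DFA (Discriminant Factorial Analysis).** Canonical discriminant axes
  solve S_b v = λ S_w v (between- vs within-class scatter, ridge-regularized
  when singular), with per-axis eigenvalue contributions and canonical
  correlations √(λ/(1+λ)). Samples are classified by nearest class centroid
  in discriminant space, and separation is summarized by a
  **Discrimination Index** DI = round(100 · SS_between / SS_total) on the
  first two axes (100 = perfect discrimination).
- **RBF network.** A radial-basis-function net (64-32-1 for FFT features,
  18-13-1 for landmarks) with k-means cluster centers, Gaussian spread
  σ = 1.5 × mean inter-center distance (the *overlap coefficient*), and a
  single linear output fitted by least squares onto the class codes 1–4.
  Performance is estimated by leave-one-out cross-validation and reported as
  accuracy, macro specificity and macro sensitivity of the 4 × 4 confusion
  matrix.
- **Synthetic voltammograms.** Because the original rice measurements are not
  deposited, a seeded generator produces class-structured synthetic datasets
  (80 records = 4 varieties × 4 samples × 5 replicates) in which dilution
  shrinks class differences toward a common mean — so the whole pipeline is
  testable end to end.

## Worked example

Score one of the packaged reference confusion matrices (the published
leave-one-out predictions at 0× dilution):

```bash
$ etongue score --fixture dil0
{
  "accuracy": 95.0,
  "classes": ["XiuShui134", "XiuShui128", "JiaHe218", "JiaHe66"],
  "macro_sensitivity": 95.0,
  "macro_specificity": 98.3,
  "n_correct": 76,
  ...
}
```

76 of 80 samples on the diagonal give 95 % accuracy; averaging the four
per-class rejection rates gives 98.3 % specificity.

Run the full synthetic study in Python:

```python
from etongue import GeneratorConfig, RBFConfig, generate_dataset, loocv, score
from etongue.pipeline import feature_matrix

cfg = GeneratorConfig(seed=1234)
for dilution in (0, 5, 10, 100):
    ds = generate_dataset(cfg, dilution)          # 80 labelled records
    X, y = feature_matrix(ds, "fft")              # 80 x 64 features
    cm, _ = loocv(X, y, RBFConfig(n_hidden=32, seed=(1234 + 97 * dilution)))
    print(dilution, score(cm).accuracy)
```

```
0 100.0
5 91.3
10 45.0
100 36.3
```

Classification degrades monotonically as dilution erases the class-specific
chemistry: near-perfect at 0×, to chance-level at 100× — the behaviour the
instrument shows on real rice extracts. The `etongue` CLI exposes the same
steps (`simulate`, `features`, `dfa`, `rbf`, `score`, `run`); see
`etongue --help`.

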