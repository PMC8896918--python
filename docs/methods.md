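# Methods

## Signal model and decomposition

An EEG segment is a finite real series x[0..N−1] at sampling frequency
fs.  The pipeline makes no stationarity assumption; the discrete
wavelet transform is used precisely because ictal EEG is nonstationary
and needs joint time–frequency resolution.  Decomposition uses the
Daubechies-4 analysis pair (quadrature-mirror low/high-pass filters)
applied recursively to the approximation branch for 5 levels.  Signals
enter the filter bank raw — no detrending, normalization or artifact
removal — because the feature set is deliberately amplitude-sensitive
(ictal EEG is distinguished partly by amplitude) and any rescaling
would have to be declared as part of the protocol.

**Boundary handling** is periodization.  Among the standard extension
modes it is the only one under which (a) each level's coefficient
count is exactly half its input length, matching the
halving-by-downsampling description of the filter bank, and (b) the
transform is orthonormal, so Parseval's identity Σx² = Σ(coefficients²)
holds and perfect reconstruction is exact to rounding.  Both
properties are asserted in the test suite (relative 1e−8 over lengths
2⁶…2¹²) and one analysis level is checked against an explicit
periodized-convolution oracle at 1e−10.  Published subband analyses of
this kind rarely state their extension mode; results obtained with
other modes can differ slightly near segment edges.

**Band bookkeeping**: Dj ↔ (fs/2^(j+1), fs/2^j), A_L ↔ (0, fs/2^(L+1)).
Edges are kept at full precision internally and rounded only for
display.  At fs = 173.61 Hz the 2-dp edges are 86.81/43.40/21.70/10.85/
5.43/2.71 Hz; note fs/2 = 86.805 is a decimal tie, conventionally
printed as 86.8 at 1 dp.

## Features

Per subband: MAV, max, min, sample SD (N−1), average power, Shannon
entropy, approximate entropy.  Two estimator decisions were genuinely
open and are resolved as follows.

* **Shannon entropy.**  The estimator of the distribution p_i is not
  dictated by the formula −Σ p_i log₂ p_i.  Default: normalized
  coefficient energies p_i = x_i²/Σx_j² ("wavelet Shannon entropy"),
  chosen because it needs no binning parameter and is the common
  convention for wavelet subbands.  An equal-width amplitude histogram
  (default 16 bins) is available via ``estimator="histogram"`` for
  users who read the entropy as an amplitude-distribution measure.
  H ∈ [0, log₂ N] (energy form) or [0, log₂ n_bins] (histogram).

* **Approximate entropy.**  ApEn(m, r, N) = Φᵐ(r) − Φᵐ⁺¹(r), Φᵐ(r) =
  (N−m+1)⁻¹ Σᵢ ln Cᵢᵐ(r), Cᵢᵐ(r) counting m-templates within Chebyshev
  distance r, self-match included (hence ApEn ≥ 0 and a constant
  series gives exactly 0).  Defaults m = 2, r = 0.2 × sample SD of the
  subband being measured — the standard Pincus settings; no published
  (m, r) exists for this protocol, so cross-study ApEn values are not
  directly comparable.  The implementation is vectorized
  (O(N²) distance matrix); the test suite pins it to a literal
  loop-based transcription of the definition at 1e−12.

MAV is computed with the absolute value |x_i|; the name and standard
usage require it even though the defining formula is sometimes printed
without the modulus.

Column ordering of the feature table is fixed (subband-major, features
in the order MAV, MAXC, MINC, STD, AVP, SHEN, APEN) so feature matrices
are byte-reproducible.

## Classification protocol

Seventeen problems: 16 two-class groupings of the Bonn sets against
the ictal set E (plus AB-CD), and the three-class AB-CD-E.  The last
group of a case is its positive class.  Class imbalance in pooled
cases (e.g. 400 vs 100 in ABCD-E) is left as-is; no resampling.

Cross-validation is stratified 10-fold with a seeded shuffle; metrics
are computed on each held-out fold and averaged across folds
(fold-undefined ratios are skipped in the average).  A pooled mode —
one confusion matrix accumulated over all folds — is available behind
a flag for users who prefer a single-table summary.

Classifier adapters delegate to scikit-learn: SVC(kernel="linear",
C=1), Gaussian NB, DecisionTreeClassifier(criterion="gini", no depth
limit, seeded), and a kNN built on sklearn's neighbour search with
k = 3 and Euclidean distance.  kNN vote ties (possible only in the
three-class problem with k = 3) are broken by the distance of the
nearest neighbour among the tied classes, then by the lowest class
index — a documented deterministic rule rather than an incidental one.
The default grid mode evaluates one (subband, feature) column at a
time, mirroring per-feature results tables; an "all" mode trains on
the full 28-column matrix.

Metrics: accuracy = 100·CCP/TPT (CCP = correctly classified patterns,
also valid for the 3-class table), sensitivity, specificity, PPV, NPV
as the usual one-vs-rest ratios for the positive class, and MCC with
the four-term denominator computed as one integer product under a
single square root (this keeps MCC exactly within [−1, 1]).  A 0/0
ratio is reported as NaN and printed ``NA``; MCC with a zero
denominator is defined as 0.  For the three-class problem the binary
metrics are one-vs-rest with the seizure group positive — the
clinically meaningful contrast — and no macro-averaging is attempted.

## Synthetic data generator

The generator emulates the *class structure* of a seizure benchmark,
not the physiology of EEG:

* background class "H": a sinusoid at a frequency drawn uniformly from
  8–13 Hz (posterior alpha), amplitude 50 µV, random phase, plus
  pink (1/f-amplitude) noise at 15 µV RMS;
* seizure class "S": the same background plus a periodic biphasic
  spike-wave train — sharp positive Gaussian spike (σ = 25 ms)
  followed 90 ms later by a slower negative wave (σ = 120 ms) —
  repeating at a frequency drawn from 2.5–5 Hz with amplitude 300 µV;
* optional interictal class "I": background plus sparse isolated
  spikes (Poisson, 1 event/s) at intermediate amplitude, for
  three-class tests.

Defaults follow the Bonn geometry: 100 segments per class, 4096
samples, fs = 173.61 Hz.  The 2.5–5 Hz discharge fundamental falls
inside the D5 band (2.71–5.43 Hz), so the D5 mean absolute value
separates the classes — the property the end-to-end benchmark tests
(every classifier ≥ 95% ten-fold accuracy on the single D5-MAV
feature, label-permutation control at 50% ± 10).  The amplitude ratio
(6×) is far above clinical ambiguity, deliberately: the benchmark
validates the pipeline's plumbing and determinism, not clinical
difficulty.  What passing it does **not** show: performance on real
EEG with artifacts, electrode noise, inter-patient variability,
subtler ictal morphologies, or class overlap; no neural-mass modelling
or fitted 1/f exponents are attempted.

Randomness is keyed by SeedSequence([seed, class, index]), so each
segment is reproducible in isolation and classes/indices are
independent streams.

## Numerical and degenerate-input choices

* Decomposition of a signal shorter than 2^levels raises with the
  maximum feasible depth in the message.
* Signal requires ≥ 2 finite samples and fs > 0; datasets must share
  one fs and carry labels.
* std requires N ≥ 2 (N−1 denominator); mav/avg_power accept N ≥ 1.
* ApEn requires N ≥ m + 2 and r > 0; for a constant series the
  relative tolerance degenerates to 0, which still yields the correct
  ApEn of 0 because self-matches keep every count positive.
* Stratified folding refuses classes smaller than the fold count
  rather than silently degrading.
* Results CSV prints percentages to 2 decimals, MCC to 3, ``NA`` for
  undefined ratios; files are written atomically (tmp + rename).

## Problem sizes

The default test and benchmark sizes — 100 segments per class at 4096
samples for the end-to-end check, 30 per class at 512 samples for unit
tests, ApEn oracle comparisons at N ≤ 300 — were chosen as the
smallest sizes at which the asserted statistical properties are stable
across seeds.

## Known limitations

* The Bonn and clinical headline accuracies of the protocol this
  package operationalises depend on unstated choices (ApEn parameters,
  entropy estimator, SVM kernel, boundary mode); the package exposes
  all of them explicitly instead of guessing a single configuration.
* EDF reading is a thin mne adapter (one Signal per channel); montage,
  referencing and artifact handling are out of scope.
* Only the Daubechies family as shipped by PyWavelets is exercised;
  wavelet-packet and undecimated transforms are out of scope.
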