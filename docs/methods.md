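# Methods

This note records the model, the numerical conventions, the synthetic-data
design and the open choices made while building the package.

## Transform model

The 1D-DTCWT decomposes a real signal with two parallel critically-sampled
two-channel filter banks (trees a and b). Level j halves the sequence
length; after J levels the transform keeps complex details d_j (real part
tree a, imaginary part tree b) for j = 1…J and a complex approximation a_J.
Each tree alone is an orthogonal (level ≥ 2) or biorthogonal (level 1)
wavelet transform and inverts exactly; the dual-tree inverse averages the
two trees' reconstructions. The representation is 2× redundant, which is
what buys approximate shift invariance within a critically-sampled-per-tree
scheme.

### Filters

* **Level 1**: LeGall 5/3 biorthogonal pair, scaled so both lowpass filters
  have DC gain √2. The taps are dyadic rationals, so stage perfect
  reconstruction is exact. Tree b uses the same taps delayed by one sample
  (stored as a leading zero in its tap files): at the first level a full
  one-sample offset between trees is what makes the level-1 complex
  coefficients approximately analytic after downsampling by 2.
* **Levels ≥ 2**: a length-14 orthonormal "Q-shift" lowpass whose passband
  group delay approximates (L−1)/2 − 1/4 = 6.25 samples; tree b is its
  exact time reverse (delay 6.75), so the trees differ by half a sample at
  the halved rate — the condition for near-analyticity at all deeper
  levels. The highpass is the standard quadrature companion
  h1[n] = (−1)ⁿ h0[L−1−n].

The Q-shift filter is designed inside the package
(`filters.design_qshift_lowpass`) rather than copied from published tables:
the filter is parameterised on a paraunitary lattice, so *any* angle vector
yields an exactly orthonormal bank — perfect reconstruction never depends
on optimiser convergence — and the angles are optimised (Nelder–Mead,
multi-start, fixed seed) for the delay target, stopband energy and a zero
at ω = π. The Nyquist zero is then made exact by a one-dimensional
root-find on the last angle (residual ~1e−17), so constant inputs produce
detail coefficients at machine-precision zero. Published Q-shift tables are
printed to ~8 decimals, which would cap reconstruction accuracy near 1e−8;
the designed taps are stored to full double precision as plain-text files
(one tap per line) under `src/gaitdtcwt/filter_data/default/` and can be
regenerated with `scripts/design_filters.py`. Measured diagnostics of the
shipped set: inter-tree cross-correlation peak offset 0.51 samples
(parabolic interpolation), stopband attenuation consistent with the length,
one exact vanishing moment.

### Boundary handling and length policy

Stages operate on circular (periodic) extensions. This is a deliberate
design choice: with non-symmetric orthonormal filters, a critically sampled
stage with symmetric reflection is not invertible, whereas the circular
stage is exactly orthogonal for every even length — including lengths
shorter than the filter, where taps wrap and fold. Reconstruction error of
the full transform is ~1e−15 for all tested lengths (16–128) and depths
(1–5).

Odd intermediate lengths are padded to even by repeating the last sample
before decimation; per-level input lengths are recorded in the coefficient
object so the inverse trims exactly. For the default 46-frame window the
schedule is 46 → 23 → (pad 24) → 12 → 6 → 3 → (pad 4) → 2: five levels end
with 2 approximation coefficients per tree. Validity requires
signal length ≥ 2^levels and an even original length.

### Envelopes and the shift-invariance diagnostic

Two distinct envelope notions are used, on purpose:

* The **coefficient-domain magnitude** |d_j^Re + i d_j^Im| is where
  near-analyticity lives: on an off-grid test tone its total variation is
  ~100× smaller than that of rectified single-tree details. The smoothness
  test asserts this inequality.
* The **shift-invariance metric** compares full-length per-level detail
  reconstructions: for each level, the level's contribution to the signal
  is reconstructed per tree and the pointwise magnitude taken; the metric
  is the relative L2 difference between "shift then analyse" and "analyse
  then shift" (circular shifts, consistent with the boundary rule). This
  definition is exact under integer shifts at full length, avoiding the
  fractional-shift ambiguity of decimated coefficient sequences. The
  single-tree baseline uses the rectified tree-a contribution alone; the
  dual-tree metric is strictly smaller on tones, noise and synthetic gait
  channels (typically 2–4×).

## Pipeline parameters

| parameter | default | meaning |
|---|---|---|
| sample_rate | 96 Hz | IMU frame rate the defaults assume |
| smooth_width | 5 frames (~52 ms) | centred moving average; truncated-window mean at edges (zero padding would bias edge accelerations) |
| window_len | 46 frames (~0.48 s) | swing-phase window starting at each toe-off; must be even |
| levels | 5 | decomposition depth; leaves 2 approximation coefficients per tree for 46 frames |
| C grid | {1, 10, 100} | SVM regularisation, inner 3-fold CV |
| gamma factors | {0.5, 1, 2} / 72 | RBF width around the scale heuristic (features are standardised first, so variance ≈ 1 per dimension) |

Features are the level-5 approximation coefficients of both trees, channel
by channel (layout: channel-major, tree a then tree b), 72 values for the
default configuration. Both trees' coefficients are used directly (not
their magnitudes): the real/imaginary pair carries the phase information
that separates waveforms of similar energy. Per-feature z-scoring is fitted
on training folds only; the SVM is scikit-learn's `SVC` (pairwise
multi-class voting) inside the standardise + grid-search pipeline, seeded
for determinism. `fit_curve` (approximation-only reconstruction) is
provided for visualising the smooth low-frequency fit but is not on the
classification path.

Reported accuracy is the pooled fraction correct, trace(confusion)/total,
which equals the test-count-weighted fold mean exactly (asserted to 1e−12);
the fold standard deviation is reported alongside, mirroring the mean ± std
convention for cross-validated recognisers.

## Synthetic cohort

Each state's 18 channels are sums of 4 harmonics of the gait cycle with
complex coefficients drawn once per state from a fixed seed; transitional
states interpolate their two steady endpoints' coefficients linearly across
the cycle, emulating a transitional step that starts in one mode's waveform
and ends in the other's. The ramp-descent template is a perturbation of
stair descent so the hardest pairs (SD/RD and, by construction, LW-SD/LW-RD
and SD-LW/SD) are the closest templates, mirroring the confusions reported
for real recognisers. The nominal cycle is 104 frames with a 0.5 swing
fraction, so every cycle holds a full 46-frame window; contact is 1 during
stance and 0 during swing, making the scheduled toe-off frames exact ground
truth for the segmenter. Subjects scale amplitude (lognormal, σ = 0.08) and
cycle length (σ = 0.04, clipped), perturb the state templates
(`coeff_sd`, default 0.15 — the subject effect), and add Gaussian noise at
the sensor floors (0.03 g accelerometer, 2 deg/s gyroscope, scaled by
`noise_sd`). The default cohort is 10 subjects × 13 states × 6 windows
(780 windows), a size comparable to a single-session wearable study.

What the generator does **not** emulate: biomechanically valid joint
kinematics, stride-to-stride autocorrelation, fatigue or speed drift,
asymmetric amputee gait, sensor mounting error, or contact-sequence noise.
Consequently, passing end-to-end tests demonstrates that the pipeline's
machinery is correct and that its accuracy ordering behaves as expected
(noise degrades it monotonically; subject variance hurts the
user-independent protocol specifically); it does not certify accuracy
levels on real recordings. On the default cohort the states are cleanly
separable (pooled 10-fold accuracy saturates at 1.0; leave-one-subject-out
≈ 0.99, dropping to ≈ 0.83 when the subject effect is quadrupled), and the
permuted-label control sits at chance (1/13 within binomial error).

## Numerical and degenerate-input conventions

* Reconstruction tolerance 1e−10 absolute on unit-scale signals (measured
  ~1e−15); linearity asserted to 1e−11 relative.
* Odd-length signals, odd window lengths, excessive depths, non-binary
  contact sequences, unknown labels, NaN features, single-class or
  single-subject datasets are rejected with messages naming the violated
  requirement.
* Toe-offs without room for a full window are skipped and logged, never
  padded (padding would fabricate swing content that feeds the level-5
  coefficients).
* Windows are cut one per toe-off, non-overlapping; steady and transitional
  recordings are treated identically.
* All randomness (templates, subjects, noise, fold shuffles, SVM seeds)
  flows through explicit integer seeds; no global RNG state is used.

## Known limitations

* Circular boundary handling wraps window edges; for 46-frame windows cut
  at toe-off the edge frames are genuinely informative, so no window
  apodisation is applied. Alternative tap sets can be supplied as
  directories of text files (`--filters-dir`), but they must satisfy the
  stage perfect-reconstruction invariants under the circular convention.
* The one-window-per-stride design does not use overlapping windows or
  sequence models; each window is classified independently.
* The user-independent protocol rotates over all subjects
  (leave-one-subject-out), the stricter reading of a 9-train/1-test
  subject split.
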