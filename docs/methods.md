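# Methods

## Signal model and feature

Each channel of a scalp EEG frame is modelled as the output of a causal,
stable, linear time-invariant autoregressive system of order p driven by
white Gaussian noise:

    x(n) = -Σ_{k=1}^{p} a_k x(n-k) + u(n),      u(n) ~ N(0, σ_u²).

The stationary autocorrelation function (ACF) r_x(m) of such a process and
its AR coefficients are linked by the Yule–Walker equations, a Toeplitz
linear system. Instead of solving that system for the a_k — whose values are
unbounded and whose estimation needs a matrix solve — the feature used here
is the sequence of **reflection coefficients** k_1..k_p, obtained directly
from the ACF estimate by the Levinson–Durbin recursion:

    k_m       = ( r_x(m) - Σ_{j=1}^{m-1} d_j^{(m-1)} r_x(m-j) ) / E^{(m-1)}
    d_j^{(m)} = d_j^{(m-1)} - k_m d_{m-j}^{(m-1)},   d_m^{(m)} = k_m
    E^{(m)}   = (1 - k_m²) E^{(m-1)},                E^{(0)} = r_x(0)

In particular k_1 = r_x(1)/r_x(0) and
k_2 = (r_x(2)/r_x(0) - k_1²) / (1 - k_1²). The m-th reflection coefficient
is the partial correlation between x(n) and x(n-m) after the linear
influence of the intermediate samples is removed. Three properties make it a
good classification feature:

* **boundedness** — for any stable system |k_m| < 1, so features live in a
  fixed box, unlike raw AR coefficients;
* **cheapness** — computing p coefficients needs only p ACF lags and O(p²)
  arithmetic, no matrix inversion (the final-stage predictor weights
  d_j^{(p)} nevertheless equal the Yule–Walker solution, with d_j = -a_j at
  full order — the property the test suite verifies against an independent
  Toeplitz solve);
* **order robustness** — raising the order from p to p+1 changes only the
  new highest coefficient, so truncating the feature at p = 2 is
  well-defined.

The ACF estimator is the **biased** one (divisor N at every lag). This is a
deliberate choice: the biased estimate is positive semidefinite, which
guarantees |k_m| ≤ 1 and a monotone nonincreasing residual-energy ladder;
the unbiased 1/(N-m) variant does not. Frames are not re-centred before the
ACF: normalization is per channel over the whole session, so frame means
are near but not exactly zero, and the ACF is taken on the frames as they
are.

A frame is declared *degenerate* when its residual energy falls below
1e-12 × r_x(0) during the recursion (a perfectly predictable or all-zero
frame); extraction raises an error naming the frame and channel rather than
emitting a silent ±1.

## Pipeline

1. **Notch.** A second-order IIR notch at the 60 Hz line frequency, applied
   forward-backward (zero phase). Default quality factor Q = 15 (≈ 4 Hz
   width). A much narrower notch (Q = 30) leaves a longer edge transient
   after forward-backward filtering, and on a 10 s session that ringing —
   not the steady-state response — dominates the residual power in the line
   bin; Q = 15 keeps the session-level periodogram suppression above 40 dB
   while leaving a 10 Hz tone's RMS intact to 0.02%. Q is a parameter.
2. **Normalization.** Each channel is z-scored over the full session
   (mean 0, variance 1), after the notch and before framing.
3. **Framing.** 1 s frames with 0.5 s shift (50% overlap), starting at
   sample 0, trailing partial frame dropped: a 10 s session at 250 Hz gives
   19 frames of 250 samples.
4. **Features.** Two reflection coefficients per channel by default
   (order-2 model), channel-major columns; 2l features for l channels, i.e.
   12 for the six-channel montage C3, P3, O1 (left), C4, P4, O2 (right).
   The full band is used — no band-pass before feature extraction — since
   the coefficients summarise the entire spectral shape and mental-task
   information extends above 40 Hz.
5. **Classification.** Pairwise (two tasks at a time) soft-margin SVM,
   quadratic kernel (x·x' + 1)² by default, C = 1, under frame-level
   leave-one-out cross-validation; accuracy is the percentage of held-out
   frames classified correctly.

### LOOCV caveat

Frame-level LOOCV is optimistic: 50%-overlapping frames from one session
share half their samples, so each test frame has near-duplicates in the
training folds. It is retained as the default because it is the protocol
the feature is evaluated under; `group_by_session=True` switches to
leave-one-session-out for an uncontaminated estimate.

A second, subtler property of LOOCV: on *label-permuted* data with tightly
clustered features it degenerates to leave-one-out majority voting and
lands far **below** 50% (removing the test point tips its cluster's
training majority to the other class). Chance-level behaviour should
therefore be checked with overlapping class distributions, which is what
the null (identical class models) check does; it lands at 50–60% with
380 frames.

## Baseline features (PAR4/PAR5/PAR6)

The comparison features combine per-band spectral power with
inter-hemispheric asymmetry ratios A(i,j) = (P(i) - P(j)) / (P(i) + P(j))
over every (left i, right j) electrode pair. Band table: delta 0.1–4 Hz
(the lower edge matching a 0.1–100 Hz acquisition passband), theta 4–7,
alpha 8–13, beta 14–20, gamma 24–37 (a deliberately narrow gamma, following
the baseline methods' convention), high 40–100 Hz. PAR4 uses the first
four bands, PAR5 adds gamma, PAR6 adds the high band. With N_b bands,
N_i = N_j = 3 electrodes per hemisphere and l = 6 channels the dimension is
N_b·N_i·N_j + N_b·l: 60, 75 and 90 columns.

Band power is the raw (boxcar) periodogram of the frame summed over in-band
bins, edges inclusive, normalised so that a disjoint partition of
[0, fs/2] sums exactly to the frame's mean-square power. The original
baseline publications do not fully specify their estimators, so this
periodogram is a deterministic stand-in; parity with those papers' absolute
accuracies is not claimed. Band-limited variants for the band-selection
experiment use a 4th-order Butterworth filter applied forward-backward
(a band reaching 0 Hz degrades to a low-pass, one reaching Nyquist to a
high-pass).

## Synthetic data

The simulator generates what the estimator assumes: each channel an
independent stationary AR process with white Gaussian excitation, class
identity encoded in the per-channel dynamics, optionally a coherent 60 Hz
sinusoid on all channels. Class models are specified in
reflection-coefficient space and converted by the step-up recursion, so
stability holds by construction. 1000 samples are generated and discarded
before the retained window to remove the zero-initial-condition transient.
All outputs are pure functions of (parameters, seed); per-session seeds are
spawned from one root `SeedSequence`.

Defaults mirror the acquisition geometry the method targets: 6 channels,
250 Hz, 10 s sessions, ten sessions per class. The reference two-class
setting uses opposite signatures k = (0.6, -0.4) vs (-0.6, 0.4) on every
channel — a strong, well-separated pair — and the null setting uses
identical models.

What the simulator does **not** emulate: 1/f background spectra, ocular and
muscle artifacts, cross-channel correlation, within-session
nonstationarity, or any physiological difference between actual mental
tasks. Passing tests therefore demonstrate that the pipeline recovers known
AR structure and separates classes that differ in it — not that any given
accuracy transfers to recorded EEG.

## Numerical choices

* Degeneracy threshold 1e-12 relative to r_x(0); ACF lags computed = number
  of coefficients requested (no extras).
* Sign conventions: a_k on the left-hand side of the difference equation;
  d_j are forward-predictor weights, so d_j = -a_j at full order and k_m
  equals the (sign-unflipped) partial autocorrelation at lag m. Users
  relating k to other toolkits' PACF should note some define the recursion
  with the opposite sign.
* Step-up/step-down round trips are exact to ~1e-12 for |k| ≤ 0.9 but the
  step-down divides by (1 - k_m²) per order, so near-unit coefficients at
  order 6 lose a few digits (~1e-9 worst case at |k| = 0.95).
* SVM: C = 1; quadratic kernel (x·x' + 1)²; polynomial default degree 3
  with +1 offset; RBF scale 1/(n_features · var(X)). A decision value of
  exactly zero predicts the lexicographically smaller label
  (deterministic tie-break).
* PCA components are scores of the mean-centred matrix, decreasing
  explained variance, computed with a full SVD.
* EDF files are written as single-record 16-bit EDF with per-channel
  physical scaling, exact on round trip to ~1.5e-5 of each channel's range;
  reading goes through `mne` and returns microvolt amplitudes.

## Problem sizes

The test suite and the acceptance script run entirely on synthetic data:
1000 random stable ACF sequences for the oracle-equivalence and
order-extension checks, 1e5-sample realizations for parameter recovery
(worst-case error ≈ 0.006, well inside the ±0.02 acceptance band), and
ten 10 s sessions per class (380 frames) for the end-to-end LOOCV checks.
These sizes were chosen to hold the sampling error of each check an order
of magnitude below its tolerance.

## Known limitations

* Accuracy figures on synthetic pairs are not comparable to results on
  recorded EEG; the separable pair is constructed to be easy.
* The baselines' band powers use a single-frame periodogram (variance ~100%
  per bin); Welch or multitaper estimates would be less noisy but are out
  of scope.
* Only pairwise (two-class) classification is implemented; no multiclass
  scheme, no hyperparameter search, no artifact rejection.
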