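# Methods

This note records the modelling choices behind `dstrf`: the encoding models,
how the dynamic spectrotemporal receptive fields (DSTRFs) are extracted and
summarized, what the synthetic ground-truth neurons emulate, and the
numerical decisions made where the underlying procedure left room.

## Stimulus representation

Audio is converted to an auditory spectrogram by a simplified cochlear
model: a bank of constant-Q fourth-order gammatone filters with log-spaced
centre frequencies, a hair-cell stage (half-wave rectification, 400 Hz
low-pass smoothing, cube-root compression), a lateral-inhibition stage
(first-order difference across adjacent bands, half-wave rectified), and
integration into 10 ms frames (100 Hz frame rate). The native resolution is
128 bands; models consume a 32-band version obtained by averaging groups of
4 adjacent bands (centre frequencies combine geometrically, preserving log
spacing). The default frequency range is 180 Hz to min(7 kHz, 0.45 × the
audio sampling rate), so the bank always fits under Nyquist. The exact
filter constants are not critical: every downstream algorithm consumes the
time × frequency matrix, whatever produced it.

Models see the stimulus through causal sliding windows of 40 frames
(400 ms) × 32 bands with stride 1: the window ending at frame *t* predicts
the response at *t*. Lag index 0 is the oldest frame, lag 39 the current
one. Windows never straddle split boundaries; the first 39 frames of each
contiguous segment are not predicted (no zero-padded history is invented).

## Encoding models

Four model families share one predict contract (prediction *k* targets
response frame `first_valid_frame + k`):

* **Linear STRF** — ridge regression of the response on the flattened
  window. The penalty is selected from a grid (log-spaced, scaled by the
  mean eigenvalue of the stimulus covariance) by Pearson correlation on the
  validation split, averaged over 4 contiguous validation sub-blocks.
  Sub-block averaging matters: slow shared stimulus structure can make a
  single whole-segment correlation prefer pathologically under-regularized
  fits.
* **LN cascade** — rank-4 time-frequency separable model: four Gaussian
  spectral kernels (centre, width, amplitude each), a 40-tap FIR filter per
  channel, channels summed, then a double-exponential output nonlinearity
  σ(x) = b + a·exp(−exp(−e^κ (x − c))).
* **STP cascade** — the LN model with a Tsodyks–Markram adaptation stage
  between the spectral kernels and the FIR filters. Per channel, the gain
  state follows d(t) = d(t−1) + u·x(t−1)·(1 − d(t−1)) − d(t−1)/τ with
  d(0) = 0, and the stage outputs d(t)·x(t). u ∈ [0,1] is the release
  probability, τ > 0 the recovery constant in frames. Channel drives are
  rectified before the stage (the adaptation input must be nonnegative).
  Both cascades are fitted by full-batch Adam with analytic gradients
  (backpropagation through time for the adaptation recursion; verified
  against finite differences in the test suite), in unconstrained
  parameterizations (u through a sigmoid, τ = 1 + e^θ). On divergence the
  fit restarts with a threefold smaller step.
* **CNN** — three 3×3 convolutional layers with 8 kernels each, 1×1
  convolutions with 4 and then 1 kernel, a 32-unit dense layer, and a
  single linear output. All hidden layers are ReLU and bias-free; only the
  output node has a bias. Stride 1, zero 'same' padding. The bias-free
  constraint is what makes the locally-linear reading below exact.

The training loss for the cascades and the CNN is MSE minus Pearson
correlation (unit weights; the correlation term is defined as 0 when the
prediction has zero variance, keeping early training finite). CNN training
uses Adam (default learning rate 1e-4), minibatches of 128, L2 of 0.001 on
all weights, dropout 0.3 after convolutional layers and 0.4 after the dense
hidden layer, at most 30 epochs, and early stopping when validation loss
has not improved for 5 epochs; the best-validation weights are returned,
with the initialization itself counting as a candidate. All randomness
(initialization, shuffling, dropout) derives from one seed. Degenerate
initializations — a draw for which the single-kernel bottleneck layer is
inactive for every probe stimulus, so the network outputs a constant and
receives no gradient — are rejected and redrawn deterministically.

### Short-recording training protocol

The defaults above suit half-hour recordings. The synthetic studies in this
package run on minutes of stimulus, a regime in which two changes are
needed (these apply to the study drivers in `dstrf.experiments`, not to the
`train_cnn` defaults):

* **Dropout off.** With a few hundred optimizer steps, dropout's
  regularization prevents any useful convergence; L2 and best-validation
  selection remain.
* **Ridge-guided initialization with routing.** A bias-free ReLU network
  can represent a linear map exactly — relu(w·x) − relu(−w·x) = w·x — and
  the nonnegative spectrogram passes unchanged through an identity channel
  of the rectified convolutional stack. `ridge_guided_weights` therefore
  builds a network that *starts* at the fitted ridge STRF, with He-scaled
  side channels free to learn nonlinear corrections. Each site is routed:
  if the ridge baseline is informative (validation correlation ≥ 0.45) the
  network starts from it and takes small steps (1e-4) that refine rather
  than destroy the inherited structure; if the linear baseline is weak
  there is nothing worth inheriting, and the network trains from He
  initialization with larger steps (1e-3). Trained from scratch at
  desk scale, DSTRFs remain dominated by the random initialization rather
  than by learned structure; the guided start is what makes the
  linearization analysis meaningful on short recordings.

## Evaluation

Test stimuli are presented repeatedly (6 trials by default). Trials are
split by 1-based odd/even numbering into mean responses Ro and Re, and the
noise-corrected correlation of a prediction P is
ρc = (ρ(P,Re) + ρ(P,Ro)) / (2·√ρ(Ro,Re)); reported accuracy is ρc².
Sites with non-positive odd/even reliability cannot be corrected and are
flagged invalid rather than clipped. The training-data-duration analysis
fits 1 − ρ² against log2(duration) by least squares and reports the slope,
plus the relative error reduction per doubling (slope divided by the fitted
error at the mean log-duration).

## DSTRF extraction

Within one ReLU activation region the network applies one exact linear
function of the input; its lag × frequency weighting is the DSTRF. Two
independent routes compute it: a backward pass through the convolutional
network (dropout disabled, float64), and the product of masked weight
matrices after converting each convolutional layer to its sparse locally
connected equivalent. Units with exactly zero pre-activation count as
inactive (their occurrence is logged); the identity
ŷ(x) = ⟨DSTRF(x), x⟩ + output bias then holds to float precision, and both
routes are cross-checked against central finite differences in the tests.

Coefficient significance uses a jackknife: the training range is cut into
*n* contiguous segments (lengths within one frame of each other) and one
model is trained per left-out segment. Members share the training seed —
the ensemble spread measures sensitivity to the resampled data, not to
re-initialization, which is what the jackknife standard error
SE = √((n−1)/n · Σ(θᵢ − θ̄)²) quantifies; initialization robustness is a
separate protocol. When the guided initialization is in use, each member
derives its own ridge fit from its reduced training data, so the held-out
segment never leaks in through the init. A coefficient is kept when at
least ⌈0.95·n⌉ members agree on a strict sign (19 of 20 at full scale;
5 of 5 at the test scale n = 5); masked coefficients are set to zero and
kept ones take the jackknife mean. Metrics are computed on the masked mean
series per time slice; the unmasked series is available alongside.

## Nonlinearity metrics

* **Complexity** — sum of max-normalized singular values of the
  (lag·frequency) × time matrix of DSTRF slices; 1 for a purely linear
  model, larger as the network applies a more diverse set of linear
  functions.
* **State switches** — mean number of hidden units changing active/inactive
  state between consecutive stimulus windows.
* **Gain change** — each slice's magnitude is the standard deviation of its
  coefficients (denominator F·T − 1); the metric is the standard deviation
  of these magnitudes over time (denominator N − 1).
* **Temporal hold** — for each shift n from 1 to 30 (300 ms), the
  correlation of slice t with slice t+n is compared against the same
  correlation after displacing slice t+n by n lag steps toward older lags —
  the direction a stimulus-locked feature travels as time advances under
  this package's lag convention (the constructed-drift fixture in the test
  suite pins this direction to behaviour). A one-tailed Wilcoxon
  signed-rank test over all t decides significance per n; the hold is the
  largest significant n (0 if none). Correlations are Pearson over
  vectorized slices with zero-filled shifting; zero-variance slices are
  excluded pairwise.
* **Shape change** — complexity of the lag-aligned series. Alignment
  iteratively shifts every slice (±30 lags, zero-filled) to maximize
  correlation with the running mean, recomputing the mean each iteration,
  until the shifts stabilize or 50 iterations pass; on oscillation the
  best-seen configuration is returned and flagged. Aligned slices differing
  only in amplitude share singular vectors, so gain variation does not
  inflate shape change.
* **Receptive-field subtypes** — k-means (10 seeded restarts) on centred,
  unit-normalized vectorized aligned slices (correlation distance), k
  chosen over 1..6 by the gap statistic with 10 reference draws and the
  first-local-optimum rule. The reference is uniform in the bounding box of
  the data expressed in its principal axes. An axis-aligned box was tried
  first and overestimates k badly for spatially smooth receptive fields
  (the gap curve rises monotonically); the principal-axis reference
  recovers planted one- and two-cluster fixtures correctly.

## Synthetic ground truth

The generator produces a nonnegative, spectrotemporally correlated
spectrogram (random moving ripples over a smoothed noise floor, with an
overall amplitude modulation at the ~300 ms scale) and five neuron kinds
with planted nonlinearities: `linear`; `static_nl` (double-exponential
output nonlinearity, default slope e, inflection 0.5 SD above the mean
drive); `gain_adaptive` (drive divided by 1 + η·E with E the rectified,
normalized upward fluctuation of a 300 ms leaky energy integral; η = 3
swings the gain over roughly an order of magnitude); `temporal_hold` (the
response holds the largest recent rectified template match for 5 frames);
and `multi_template` (two orthogonal Gabor templates switched by a
band-energy statistic of the current window). Clean responses are z-scored;
the training trace and each of the 6 test repeats add independent Gaussian
noise (0.4 SD in the studies). Splits are contiguous
train/validation/test; studies use fractions (0.78, 0.12, 0.10) — the
3 % validation share used on half-hour recordings is far too short at
desk scale for penalty selection or early stopping.

What the generator does *not* emulate: phonetic or any natural-sound
statistical structure beyond second-order ripple correlations,
multi-electrode covariance, non-Gaussian or temporally correlated trial
noise, and nonstationary neural states. Passing the dissociation study
therefore shows that the pipeline recovers planted nonlinearities of these
functional forms at these noise levels — not that cortical recordings would
yield the same metric values.

## Problem sizes

The study protocols default to 90–120 s stimuli per neuron, 6 training
epochs for the scored model, a jackknife of n = 5 with 3 epochs per member,
and 4 initializations (2 vs 2) for the robustness protocol. These sizes run
the full five-neuron study on one desktop core in tens of minutes; every
size is an argument, and the half-hour-scale defaults remain in the
configuration objects.

## Known limitations

* The exact-linearization machinery requires bias-free hidden layers,
  stride-1 'same'-padded convolutions, and ReLU; other architectures are
  rejected rather than approximated.
* The Tsodyks–Markram update is implemented exactly as specified
  (facilitation-like sign, d(0) = 0); the update lives in one function so a
  depression-style convention is a one-line change.
* Temporal hold is an aggregate over the whole test stimulus; it is not
  conditioned on stimulus content.
* At desk scale the CNN's advantage over the linear model is bounded by the
  few hundred optimizer steps a study can afford; absolute metric values
  are not comparable to half-hour-recording values, only their ordering
  across planted nonlinearities is.
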