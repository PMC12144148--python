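# Methods

## The modeling problem

Eye-gaze position at 1000 Hz alternates between fixations (hundreds of
milliseconds of near-stationary jitter) and saccades (tens of milliseconds of
ballistic movement with a smooth speed bell).  The per-millisecond speed
series — Euclidean displacement divided by the 1 ms sampling interval — is
therefore a strongly heavy-tailed, temporally structured signal: most samples
sit near zero, rare samples are orders of magnitude larger.  `gazegan` builds
generative models of this speed series: adversarially trained neural
generators with a frequency-domain regularizer, and a Gaussian hidden Markov
baseline, plus the metrics to compare them against data.

## Preprocessing

`gaze_preprocess` converts a timestamped (time in ms, x/y in screen pixels)
gaze table into training currency:

1. speed `v_i = ||p_{i+1} - p_i|| / (t_{i+1} - t_i)` (px/ms),
2. min-max scaling to [0, 1] (`(v - min) / (max - min)`; the parameters are
   kept for inversion and are fitted on the training split only — a holdout
   transformed with training-split parameters is clipped into [0, 1]),
3. segmentation into non-overlapping windows of length L = 200 (the full-scale
   default), remainder discarded and counted.

Non-overlapping windows avoid duplicated content across mini-batch rows.
Left/right eyes are treated as separate series; their segment sets can be
pooled with `pool_datasets` when desired.

## Synthetic scanpaths

The recordings such models are normally fitted to are rarely shareable, so
`synthetic_gaze` generates speed series (and matching 2-D scanpaths) with the
same distributional signature:

* epoch durations are gamma distributed — fixations with mean 250 ms
  (shape 4), saccades with mean 30 ms (shape 8); gamma is positive and
  right-skewed, and only the first two moments matter for the statistics we
  target;
* fixation samples are |N(0, 1)| x `fixation_speed_scale` (default
  0.02 px/ms);
* each saccade follows a raised half-sine speed bell, zero at the endpoints,
  scaled by a log-normal peak (median 2 px/ms, log-spread 0.45), plus
  half-normal noise (scale 0.005 px/ms);
* every epoch draws from its own seed-derived substream keyed by epoch index
  (extending the duration never changes earlier epochs), with speed and
  direction draws on separate channels so the 1-D series and the 2-D scanpath
  are consistent views of one process (saccades move in one uniformly random
  direction; fixation jitter re-draws its direction every millisecond).

The log-normal spread 0.45 was calibrated once so that the min-max-normalized
speed distribution has skewness ~4.7 and excess kurtosis ~28 (population
moments), the heavy-tailed regime reported for visual-search gaze speeds.
What the simulator does *not* emulate: main-sequence amplitude/duration
coupling, smooth pursuit, blink artifacts, tracker measurement noise, and the
extreme max-to-mean ratios that artifact spikes produce in real recordings
(a normalized mean of ~2e-3 together with kurtosis ~31 is unreachable at
feasible sample sizes, since a single sample at 300+ standard deviations
dominates the fourth moment).  Tests passing on this generator therefore
demonstrate correct mechanics and the claimed directional effects on a
realistic heavy-tailed signal, not performance on any particular tracker's
recordings.

## Architectures

Four generator/discriminator pairings cross {CNN, LSTM} x {CNN, LSTM}; all
operate on [0, 1]-scaled speed sequences.

* **LSTM generator** — an independent uniform[0, 1) noise vector (default
  dimension 256) per time step feeds a 16-unit LSTM; a dense tanh head maps
  each hidden state to per-step horizontal/vertical displacements, and the
  emitted speed is their Euclidean norm divided by sqrt(2) (so it lies in
  [0, 1]).  A direct 1-channel speed head (`output_head="speed1d"`,
  (tanh+1)/2) is available; only speed magnitudes are ever scored.
* **CNN generator** — a noise vector is densely projected to
  (64 channels x L/8), then grown by three fractional-strided convolutions
  (kernel 4, stride 2, padding 1; batch-norm + ReLU), ending in tanh.
  tanh outputs are mapped from [-1, 1] to [0, 1], preserving the activation
  while matching the data range.
* **CNN discriminator** — mirrored strided convolutions (16-32-64 channels,
  batch-norm after all but the first, LeakyReLU 0.2), flattened into a dense
  sigmoid probability.
* **LSTM discriminator** — per-step dense sigmoid scores on 16-unit hidden
  states, averaged over the sequence.

The channel schedule and kernel geometry follow the standard deep
convolutional GAN convention; they are package choices, not reported facts.
Batch-norm layers use running statistics in inference mode, so metric
evaluation is deterministic and batch-independent.

The networks run on a compact numpy reverse-mode autodiff engine
(`gazegan.nn`) written for this package: broadcasting arithmetic, 2-D matmul,
pointwise nonlinearities, reductions/slicing, and fused
convolution/transposed-convolution/LSTM nodes with hand-written backward
passes.  Every backward pass is verified against central finite differences
in the test suite.

## Losses and training

With discriminator output D(.) in (0, 1) (probabilities clamped to
[1e-7, 1-1e-7] inside every log):

* generator (non-saturating): `L_G = -mean_i log D(G(z_i))`;
* discriminator (negated objective, minimized):
  `L_D = -mean_i log D(x_i) - mean_i log(1 - D(G(z_i)))` (independent means,
  so real/fake batch sizes may differ);
* spectral loss: with `m[k]` the batch mean of `|F(x)_k|` (unnormalized DFT,
  magnitudes computed as sqrt(Re^2 + Im^2 + 1e-24) so gradients stay finite
  at exact zeros),

      L_spectral = sum_k [ log(m_real[k] + eps) - log(m_fake[k] + eps) ]^2,

  with eps = 1e-8 and natural logarithms (a different base rescales the loss
  by a constant that the weight lambda absorbs).  Real and generated batches
  carry no pairing, so the comparison is between population mean spectra
  rather than per-pair — per-pair assignment would be arbitrary, and the
  population spectrum is what the regularizer is meant to match.

Training alternates one discriminator and one generator Adam step
(lr 2e-4, betas 0.5/0.999) per mini-batch.  The generator objective is
`L_final = L_G + lambda * L_spectral / N` — the spectral term enters as its
per-frequency mean (the mean squared log-spectrum error).  This
normalization is deliberate: the raw sum grows linearly with sequence
length, so a fixed lambda would regularize a length-200 model and a
length-64 model with very different strengths; in the normalized form
lambda = 0.1 balances the adversarial term at any length.  (In pilots with
the un-normalized sum at length 64, the spectral direction exceeded the
adversarial gradient ~30-fold and the generator collapsed to a single
mean-spectrum waveform.)  `EpochRecord.L_spectral` logs the normalized term,
so `L_final = L_G + lambda * L_spectral` holds exactly on every logged epoch;
the un-normalized sum remains available as `losses.spectral_loss`.

Per epoch, metrics are computed on a fixed holdout against a freshly
generated sample of equal size: the histogram Jensen-Shannon divergence of
pooled values and the spectral score (mean squared log-spectrum error of
batch-mean spectra).  All weight initialization, shuffling and noise derive
from one seed; runs are bit-reproducible single-threaded.  A non-finite loss
aborts with the epoch/batch named rather than continuing silently; epoch
records are flushed to CSV as they are produced, so interrupted runs keep
their completed epochs.

## HMM baseline

The baseline is a Gaussian hidden Markov model on the normalized speed
series.  Fitting is Baum-Welch EM (scaled forward-backward E-step via
hmmlearn, closed-form M-step) under package-controlled initialization:
emission means at evenly spaced sample quantiles, pooled-variance emissions,
uniform transitions perturbed by seed-controlled noise, 5 restarts keeping
the best final log-likelihood.  Stopping uses relative log-likelihood change
below 1e-4 (max 500 iterations); collapsed emission variances are floored at
1e-10 with a warning.  Gaussian emissions are the standard continuous choice;
since speeds are heavy-tailed, fitting on log-transformed series is possible
by preprocessing, but the shipped baseline operates on the normalized scale.
Sampling truncates emissions to [0, 1] by resampling, respecting the
normalized scale.  The forward log-likelihood used for scoring is an
independent log-space recursion implemented here and tested against both
brute-force path enumeration and hmmlearn's scorer.

State-count selection fits each candidate (default 2..5), samples a series,
and scores the histogram divergence against the input series, returning the
table and the argmin.  Note a structural caveat: when the data really are a
K-state HMM, a (K+1)-state fit reproduces the same marginal (the extra
component duplicates a mode), so the divergence difference between K and K+1
sits at the sampling-noise floor and the argmin between them is effectively
a tie — the informative signature is the steep decline up to K followed by a
plateau.

## Metrics

* **D_JS** — both sample sets are binned into 100 equal-width bins spanning
  their pooled range; `D_JS = KL(P||M)/2 + KL(Q||M)/2`, `M = (P+Q)/2`, with
  base-2 logarithms so the value is bounded by [0, 1] exactly (0 log 0 = 0).
* **ACF** — `ACF(h) = sum_{t<=T-h}(X_t - Xbar)(X_{t+h} - Xbar) /
  sum_t (X_t - Xbar)^2`.
* **Moments** — population (divisor n) mean, SD, skewness m3/m2^1.5 and
  kurtosis m4/m2^2; the kurtosis convention (excess vs Pearson) is
  configurable, defaulting to excess.
* **Efficiency scores** — trapezoidal integrals of the spectral-loss and
  D_JS curves over an epoch window (default 100-500) plus mean wall time per
  epoch; the "volume" is their product.  Wall time is recorded for reporting
  but never asserted on (hardware-dependent).

## Scaled benchmark

The shipped end-to-end benchmark (`gazegan.benchmarks`) trains the LSTM-CNN
variant on 2,000 simulated sequences of length 64 (batch 64, noise dimension
64, 50 epochs) for lambda in {0, 0.1} across 3 seeds, with a 256-sequence
holdout; min-max parameters come from the training portion.  These sizes
preserve the full pipeline and the two directional claims of interest —
D_JS falls over training, and the spectral regularizer improves the final
spectral score — at workstation scale.  Full-scale defaults (length 200,
batch 128, 500 epochs, noise 256) remain the package defaults for real use.

## Numerical choices and degenerate inputs

* eps = 1e-8 inside spectral logs; probability clamp 1e-7; magnitude guard
  1e-24 inside the DFT magnitude square root.
* Constant series raise explicit degenerate-range errors in normalization,
  histogramming and the ACF rather than emitting NaNs.
* Zero time gaps raise with the offending index; non-finite gaze rows are
  dropped and counted.
* Histogram ties: `select_state_count` resolves equal divergences to the
  first (smallest) candidate.
* Adam state, shuffling and noise are all derived from the run seed through
  named SeedSequence spawn keys, keeping every stream independent.

## Known limitations

* The simulator's tails are lighter than artifact-laden tracker data (see
  above); absolute metric values on real recordings will differ.
* Adversarial training at the benchmark scale is short (50 epochs); the
  generator matches the bulk and mid-range of the speed distribution but not
  the extreme tail quantiles.
* The HMM baseline assumes Gaussian emissions on the normalized scale.
* Wall-clock comparisons across architectures (the efficiency "volume") are
  hardware-dependent and reported, not asserted.
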