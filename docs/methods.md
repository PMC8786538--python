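# Methods

This note documents the models implemented in `ocuclean`, the defaults and
the reasoning behind the genuinely open design choices. Nothing here states
an empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Semi-simulated data

Quantifying artifact removal requires a clean reference, which real
contaminated recordings cannot provide. The generator therefore builds the
dataset in two stages.

*Clean EEG* (`semisim.generate_clean_eeg`): each channel/epoch is a mixture
of three band-limited rhythms — theta (4–8 Hz), alpha (8–13 Hz, dominant)
and beta (13–30 Hz) — each realized as three sinusoids with seeded random
frequency, phase and amplitude, plus 1/f-shaped Gaussian background noise.
Signals are zero-mean and scaled to a 10 µV RMS, a typical scalp amplitude.
The default geometry is 25 channels (22 EEG + 3 EOG), 288 epochs of 6 s at
250 Hz (1500 samples), matching a standard motor-imagery recording block.

*Contamination* (`semisim.contaminate`): a seeded subset of epochs
(`artifact_fraction`, default 0.5) receives a blink train — squared
half-sine pulses of 200–400 ms width at Poisson-random onsets (default rate
0.5/s, at least one pulse per contaminated epoch), peak-normalized. EEG
channels receive the train scaled so that the epoch's clean-power /
artifact-power ratio equals `snr` exactly (default 1.0; the evaluation sweep
uses 0.5–1.5). EOG reference channels carry the unscaled train at
`amplitude_ratio` (default 50, physiological range 10–100) times the
clean-EEG RMS. The leak is uniform across EEG channels — no volume-conduction
model — and the contamination is strictly additive, with the clean tensor and
the artifact component retained for scoring.

The SNR sweep rescales the *artifact* against a fixed clean signal; since
only the ratio is controlled, rescaling the EEG instead would change the
absolute error scale but not any of the qualitative comparisons.

What the generator does **not** emulate: spatially structured propagation of
the ocular source across the scalp, non-ocular artifact classes (muscle,
cardiac, electrode), inter-subject variability, and the nonstationarity of
real background EEG. Passing tests therefore demonstrate correctness of the
mechanics and recoverability under the stated additive model, not clinical
performance on real recordings.

All randomness descends from one integer seed through spawned
`numpy.random.SeedSequence` streams, so every fixture is bit-reproducible.

## Detection-phase decomposition

Each level of the cascade applies one low/high analysis split to the current
band and then splits each output again, producing the four named subbands
LFLF/LFHF/HFLF/HFHF; the recursion continues on LFLF for five levels (20
subbands total). A plain dyadic wavelet transform yields two bands per
level; the four-band naming is only consistent with this depth-2
wavelet-packet arrangement.

Splits use the analysis filters of an orthogonal wavelet (default
Daubechies-4, configurable) with **zero extension and full convolution**,
decimated at the even phase, so each output has length
`ceil((n + L − 1)/2)`. For orthogonal filters this evaluates an expansion in
an orthonormal family: energy is conserved exactly and the inverse
(upsample, convolve with the synthesis filters, trim `L − 1` leading
samples) reconstructs to machine precision. The price is boundary
coefficients at each end (filter half-width); the vanishing-moment property
holds for interior coefficients. The inverse transform exists for
verification only — the detection path never reconstructs.

A level "counts" only while the recursed band keeps strictly shrinking;
below that the error message names the maximum feasible depth. A 1500-sample
epoch yields five levels with band lengths 381/101/31/13/9.

*Pisarenko analysis*: for each subband, the order-M (default 8) Toeplitz
matrix of unbiased sample autocorrelations is eigendecomposed; the
pseudospectrum `1/|e(f)ᴴ v_min|²` is evaluated on a 256-point grid over
[0, 0.5) cycles/sample. Dominant frequencies are local maxima above
median + 3·MAD of the pseudospectrum, strongest first. Subbands shorter than
2M samples (the deepest levels) or identically zero carry a `None` marker
instead. How the two decompositions combine downstream is a design choice
here: both are carried forward jointly into the feature summary.

## Features

Each decomposed channel-epoch is flattened to five statistics per subband in
fixed order (mean, variance, energy, dominant Pisarenko frequency, spectral
entropy of the pseudospectrum; zero for marked subbands) — 100 variables.
The observation matrix for feature extraction has one row per epoch
(detection is per-epoch classification), averaging the statistics over EEG
channels.

PCA is the covariance eigenproblem on the centered matrix (divisor n − 1),
components sorted by descending eigenvalue, each eigenvector's
largest-magnitude entry made positive for reproducibility. ICA wraps
scikit-learn's FastICA (log-cosh contrast, PCA whitening, 500 iterations at
tolerance 1e-6, seeded); the overall unmixing rows are unit-normalized with
the same sign rule. Non-convergence keeps the best iterate and flags the
model; all-Gaussian inputs (every source with |excess kurtosis| < 0.25) are
flagged non-identifiable. The default of 83 components per method is a
configuration value; requesting more components than
`min(n_epochs − 1, n_vars)` raises instead of silently truncating, so the
default applies to datasets with at least 84 epochs and 83 variables.

## Deformable convolutional network

All layers are one-dimensional and implemented in numpy with hand-derived
gradients (float64).

* Deformable convolution: a zero-initialized regular convolution (kernel 3)
  over the input predicts one fractional offset per tap and output position;
  taps are read at `t + n − k/2 + δ` by linear interpolation with zero
  contribution outside the signal. Zero initialization makes the untrained
  layer exactly a standard convolution (no bias).
* Deformable pooling: window-2 average pooling whose in-window samples are
  shifted by offsets from a strided zero-initialized convolution. Mean
  aggregation (rather than a raw sum) keeps the activation scale stable
  across layers.
* Heads: the detector flattens and applies an affine map with a sigmoid —
  a differentiable surrogate for the signum decision; the hard label is
  `p > 0.5`, a tie counting as the negative (clean) class. The denoiser head
  is a per-position affine map (1×1 convolution), identity activation.
* Offsets are trained: the interpolation kernel's subgradient `sign(v − it)`
  propagates the loss into the offset generators.

Default trunks (the architecture is not otherwise constrained): detector
`dconv(16,k3) → dpool(2) → dconv(32,k3) → dpool(2) → dense(1)`; denoiser
`dconv(8,k5) → dconv(8,k5) → conv(1,k1)`, with ReLU after each deformable
convolution. Both are small enough to train in seconds on one CPU.

Training is plain mini-batch SGD (batch 16) so the learning-rate search box
[0.1, 0.9] retains its printed meaning; the detector minimizes binary
cross-entropy, the denoiser mean absolute error. A non-finite loss aborts
with a diagnostic. Inputs are scaled by the caller: detection features are
divided by the global training std times √(feature count), which keeps the
observation-vector norm — and hence the logit scale — independent of the
feature count; per-column standardization was rejected because it inflates
low-variance tail components to the scale of the leading discriminative ones
and invites overfitting.

The tuner searches (epochs, learning rate) over {10..20} × [0.1, 0.9] with
DS-EFO, rounding the epoch coordinate; detection fitness is
`fr1 = 1/(accuracy + precision)` on the validation split (a vanished
denominator maps to a large sentinel, never a division error; since both
rates are ≤ 1, fr1 ≥ 0.5 always), denoising fitness is the validation MAE.
Training divergence during a trial maps to the sentinel.

## DS-EFO

The optimizer state per individual is a position (box-constrained), its
objective value (minimized), a frequency and an amplitude. Frequencies map
fitness linearly to [fr_min, fr_max] = [0, 1] (best → 1); when all fitness
values coincide, every frequency is 1. Amplitudes follow
`amp ← β·amp + (1−β)·fr`, initialized at the frequency; β defaults to 0.5
(unstated in the model's description; convergence on pilot quadratics is
insensitive across [0.25, 0.75]). The active range is the mean box width
times the amplitude.

*Active move*: a neighbor within the active range is chosen uniformly and
each coordinate steps by `U(−2, 2)` times the separation along that
coordinate — the fish probes the region up to twice the sensed separation on
either side, so the step length adapts to the local population spread. This
neighbor-relative reading is what gives the method a vanishing step size as
the population converges; a position-only random step of radius equal to
the active range (used as the fallback when no neighbor is sensed) has a
fixed O(box) scale and stalls near 1e-1 on the 5-D sphere benchmark.
*Passive move*: up to 3 active individuals are drawn with probability
proportional to amplitude/distance (ε = 1e-12 guards coincident positions);
the move interpolates toward their amplitude-weighted mean with
per-coordinate U(0, 1) weights. An empty active set falls back to the
no-neighbor active step. With probability 0.1 one uniformly chosen
coordinate of the candidate is resampled from the box.

Mode selection: plain EFO draws active mode with probability equal to the
frequency; DS-EFO is active iff the individual's distance to the current
best is strictly below the population mean of those distances *and* at least
one neighbor lies within its active range (so a fully collapsed population
is all-passive). Candidates are clipped to the box and accepted only if they
improve (greedy); the best-so-far is never lost, making the trace monotone.
One candidate per individual per iteration bounds the evaluation budget at
`pop + pop × iterations`. Non-finite objective values reject the candidate
with a warning.

## EMCD and the mitigation path

`find_extrema` takes strict interior extrema, collapsing plateaus to their
midpoint (mode counts depend on this convention). Envelopes are cubic
B-splines through the maxima (superior) or minima (inferior), degree reduced
when fewer than four knots exist, constant-extended beyond the outermost
extrema; fewer than two extrema raises `NEEDS_EXTREMA`. The mean curve is
the envelope average. Iterating `mode = current − mean_curve(current)`
extracts modes until `max_levels` (module default 5) or until the trend has
fewer than two maxima or minima; the final trend is the leftover, making
`Σ modes + leftover` the exact inverse by construction. Spline overshoot
between sparse knots means the extrema count is not strictly monotone across
the deepest levels, only strongly decreasing overall.

The EWF statistics count oscillation: mode count `(T_ma + T_kb)/2`,
empirical period `T/md` and frequency `md/T` (NaN when no extrema exist).

*Which part is denoised.* Blink deflections are slow (200–400 ms) relative
to the EEG rhythms, so EMCD places them almost entirely in the leftover
trend while the modes carry the oscillatory brain signal. The denoiser
therefore receives the **leftover** by default, with the modes passed
through untouched and re-added at reconstruction — a denoiser that only saw
the modes could never remove an artifact living in the part it cannot touch.
A config switch (`denoiser.component: modes`) flips the roles. For the same
reason the pipeline decomposes with `max_levels = 2` by default: deeper
iteration drains blink energy into the later modes, where it is out of the
denoiser's reach.

The training target for a flagged channel-epoch is the clean signal minus
the untouched part, so that `untouched + denoised ≈ clean`; inputs and
targets share one global scale (the training-input std). Because the
leftover is band-limited, it is decimated by 8 before the network and the
output linearly interpolated back, which widens the effective receptive
field to cover a whole blink and cuts the compute by the same factor.
Training uses three annealed SGD stages at lr, lr/3 and lr/10 (the MAE
loss has constant-magnitude gradients, so its error floor scales with the
learning rate), on a seeded subset of at most 512 channel-epochs; all
flagged epochs are then denoised with the trained network. Scores
(MAE/RMSE/Pearson r against the clean target, per epoch over the EEG
channels) are reported alongside the contaminated-baseline scores. With
`denoiser.passthrough` the network is skipped and reconstruction returns the
contaminated input exactly — the conservation baseline.

## Pipeline conventions

Epochs split 60/10/30 into train/validation/test by a seeded permutation;
feature models (PCA/ICA) and the detector are fitted on the training split
only, and the reported detection metrics come from the held-out test split.
Hyperparameter tuning by DS-EFO is off by default (the default network
config is 15 epochs at rate 0.3); enabling it uses a scaled-down budget of
population 6 × 10 iterations, with the full population-10 × 100-iteration
budget available in the config. Mitigation operates on ground-truth labels
when called directly and on predicted-positive epochs in `run_full`; epochs
predicted clean are never modified. Provenance (config hash, seed,
timestamps) accompanies every run and fixed seed + config reproduce results
bit-identically.

Scaled problem sizes used by the test suite are the package's own choices:
unit and pipeline tests use 7 EEG + 1 EOG channels, 60 epochs of 2 s
(500 samples — the shortest epoch supporting all five decomposition
levels); the acceptance checks run the full default geometry for detection
and mitigation and 96-epoch fixtures for the SNR sweep (0.5/1.0/1.5).

## Known limitations

* The additive, spatially uniform contamination model makes detection easy
  at snr ≈ 1; real recordings have correlated, nonstationary artifacts and
  the reported fixture accuracies will not transfer.
* The denoiser is transductive in spirit: it trains on a subset of the same
  flagged pool it cleans (with a clean target available). Cross-recording
  generalization is untested.
* Pisarenko assumes sinusoids in white noise; on broadband subbands the
  dominant-frequency feature is a coarse summary, which is acceptable here
  because it only feeds a classifier.
* The EDF reader segments fixed-length epochs and ignores annotations; real
  label sets must be supplied separately.
* MAE-trained networks with plain SGD need the documented annealing to reach
  a tight error floor; single-stage training at a boxed learning rate leaves
  a visibly higher floor.
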