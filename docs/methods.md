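# Methods

This note documents the models implemented in `statecomp`, the choices made
where the design was genuinely open, and what the synthetic validation does
and does not establish.

## Synthetic data generator

The generator emulates the statistical structure that both state models
feed on, not the biophysics of a head. Per subject:

1. A hidden K-state Markov chain with sticky transitions (diagonal
   `stay_prob`, uniform off-diagonal) is simulated **at the envelope
   analysis rate** (40 Hz) and upsampled to the acquisition rate (1 kHz) by
   sample-and-hold. Planted lifetimes — geometric with mean
   `1/(1 - stay_prob)` state samples, 250 ms at the defaults — are
   therefore exactly representable after envelope downsampling. The chain
   starts from its stationary distribution, so occupancy estimates carry no
   burn-in bias.
2. Each source is an independent band-limited Gaussian process (white noise
   through a zero-phase 4th-order Butterworth band-pass, unit variance):
   alpha/beta-like irregular oscillations without committing to a
   parametric oscillator.
3. Source `k`'s amplitude is `1 + burst_gain * pattern[z(t), k]` with
   one-hot patterns: each state boosts one dedicated source, the remaining
   sources form a stationary background. Amplitude steps are smoothed by a
   25 ms raised-cosine ramp; downstream envelopes are effectively low-passed
   near 10 Hz, so sharper edges would be unobservable anyway.
4. Sources mix to sensors through a toy leadfield with **orthonormal
   columns** (QR of a seeded Gaussian matrix). This idealization makes the
   planted sensor topographies mutually well separated by construction and
   the minimum-norm inverse well posed; it deliberately removes the
   leadfield collinearity of real head models (see Limitations).
   Gradiometer-pair recordings are two independent mixture rows per sensor
   location, exercising the Euclidean-norm combination path.
5. Additive i.i.d. Gaussian sensor noise (`noise_sd`).

Defaults (3 states, stay 0.9 at 40 Hz, burst gain 2, noise SD 0.5, 60 s per
subject at 1 kHz, 32 channels, 8 sources) are the reference conditions used
across the tests. Burst gain 2 means a 3x amplitude (9x power) elevation of
one source during its state — a strong but transient modulation; noise SD
0.5 is half the per-source signal scale.

What the generator does **not** emulate: 1/f background spectra,
physiological artifacts (ECG/EOG), inter-subject leadfield variability,
spatially correlated sensor noise, within-state non-stationarity. Passing
recovery tests on this data validates the algorithms' correctness and their
behaviour under the stated SNR, not their performance on real recordings.

## Preprocessing

* **Band-pass**: 4th-order Butterworth applied forward-backward
  (`sosfiltfilt`): zero phase (GFP peak timing is untouched) and maximally
  flat passband (< 1% ripple after squaring).
* **Moving-window downsampling**: means of non-overlapping windows of
  length `fs/target_fs` (integer-ratio only, trailing partial window
  dropped, output length `floor(n/w)`). The boxcar's frequency response is
  the implicit anti-alias filter — a deliberately *soft* low-pass; no sharp
  filter is added. Nested downsampling (1000→200→40) is exactly equal to
  direct 1000→40 because boxcar means nest.
* **Average reference** subtracts each sample's spatial mean (electrodes
  only; it is a projection, hence idempotent, and commutes with linear
  filtering).
* **Hilbert envelopes** are analytic-signal magnitudes per channel, FFT
  length padded to a fast composite size. The first and last second are
  filter/Hilbert transient zones; analyses in this package either use long
  segments (≥ 20 s) where the edge contribution is negligible or exclude
  edge-truncated runs explicitly (see lifetimes).
* **Normalization**: per subject, channel means removed, then all channels
  divided by one pooled SD over all sensors and samples. "Normalize by the
  global variance" is implemented as division by the pooled *SD* so that
  pooled variance is exactly 1 and units stay interpretable; dividing by
  the variance itself would only rescale the PCA basis and leave every
  correlation-based statistic unchanged.
* **PCA** loadings are the leading eigenvectors of the channel covariance
  of the concatenated set, with a deterministic sign convention (largest-
  magnitude coefficient positive).
* **Minimum-norm inverse**: `L^T (L L^T + λ tr(LL^T)/C · I)^{-1}` — a
  scalar-λ Tikhonov inverse. No noise-covariance whitening or data-driven
  regularization is attempted; λ defaults to 1e-2.

## Microstates

AAHC is deterministic by construction; the open details were fixed as
follows:

* **Cluster GFP** (the atomization criterion) is the cluster's contribution
  to explained GFP, `Σ_i (gfp_i |r(v_i, u_c)|)²`, which equals the top
  eigenvalue of the member scatter matrix divided by the channel count.
  Atomization therefore always dissolves the weakest cluster in
  explained-variance terms, and the final model's GEV is the ratio of the
  summed top eigenvalues to total squared GFP.
* **Spatial correlation** removes each map's spatial mean first (a no-op
  for average-referenced electrodes; it makes non-negative combined-
  gradiometer maps comparable).
* **Polarity invariance** is on for electrodes (oscillatory maps flip sign
  within a state) and off for combined gradiometers (amplitude maps carry
  no sign); the flag is exposed.
* Ties (argmax/argmin) break to the lowest index; GFP plateaus peak at
  their first sample; principal components carry a fixed sign. Repeated
  runs are bit-identical.
* **Group models** come either from pooled AAHC over all subjects' peak
  maps (the default here: one model, directly comparable to the group HMM)
  or from per-subject AAHC followed by iterated permutation alignment:
  exhaustive search over template permutations (and sign flips) against
  current group templates, group templates re-estimated as per-slot first
  principal components, iterated to convergence of the mean |correlation|.
* **Backfitting** is per-sample argmax of |spatial correlation|; the
  smoothed variant labels GFP-peak samples only and extends them by
  nearest-peak interpolation (midpoint ties to the earlier peak). "Raw"
  lifetimes in this package always refer to the continuous per-sample
  labelling without smoothing.

## Envelope HMM

* **Inference**: variational Bayes with conjugate priors — symmetric
  Dirichlet(1) on the initial distribution and each transition row, and a
  Gaussian–Wishart prior per state centred on the pooled data statistics
  with minimal strength (β₀ = 1, ν₀ = d + 2, prior mean precision =
  inverse pooled covariance). The E-step runs scaled forward–backward with
  sub-normalized expected parameters exp(E[log π]), exp(E[log A]); the
  objective is the evidence lower bound (log normalizer minus the KL of
  every parameter factor), which is monotone per restart and is the
  negative free energy used for restart selection (10 restarts by default,
  lowest free energy kept). An EM route (maximum likelihood, log-likelihood
  objective) shares the same recursions behind a flag; both pass the same
  parameter-recovery tests. Exact prior hyperparameters are package
  choices validated by recovery, not literature values.
* **Initialization** per restart: means at K random data points,
  covariances at the pooled covariance, sticky transitions (0.9 diagonal).
  Covariances are regularized each iteration by adding `1e-6 · tr(Σ)/d` to
  the diagonal.
* **Decoding**: Viterbi in the log domain on the point estimates (Dirichlet
  means for π/A, posterior means for the Gaussians); ties to the lowest
  index. The decoded labelling is exclusive and complete by construction.
  Sample-and-hold upsampling (e.g. 40→200 Hz for cross-rate comparisons)
  preserves occupancies exactly.
* Forward–backward and Viterbi inner loops are numba-compiled; group-level
  fits run at T ≈ 2–3·10⁴ samples in seconds.

### Known bias: decoded lifetimes under emission overlap

With the default conditions the fitted transition diagonals come out near
0.83–0.88 for a planted 0.9. This is not an implementation artifact — an
independent EM implementation (hmmlearn) reproduces the same estimates on
identical input, and decoding with the *true* parameters still yields
lifetimes below the planted mean — but a property of maximum-likelihood/VB
estimation when state-conditional envelope distributions overlap: soft
responsibilities spread over states, inflating off-diagonal transition
counts, and isolated decoding errors fragment long runs. The effect
shrinks as the envelope representation gets cleaner; with the pipeline's
default reduction to N = 8 components, decoded lifetimes sit within ~15% of
the planted 250 ms, while at N = channels they are ~40% short. The
qualitative ordering that the comparison framework relies on — raw
microstate lifetimes (tens of ms) ≪ HMM lifetimes (≥ 100 ms) — is robust
across all of these settings.

## State statistics

* **Lifetimes/occupancies**: maximal constant-label runs over half-open
  sample intervals. Runs truncated by the series edges are *excluded* from
  mean lifetimes by default (truncation biases them downward) but counted
  in visit counts and occupancies; a state observed only in edge runs falls
  back to the edge-included mean and is flagged. With edge exclusion off,
  the accounting identity Σ_k n_visits_k · mean_lifetime_k = duration holds
  exactly.
* **Partial-correlation maps**: for state k, the other states' series plus
  an intercept are regressed out of both sides and the residuals are
  Pearson-correlated. Exclusive-complete activations sum to one, so this
  control set is rank deficient; the last-indexed control series is then
  dropped (logged at INFO), leaving K−1 regression degrees of freedom —
  consistent with the ν correction below. Per-subject maps are the same
  regression restricted to the subject's segment.
* **Thresholding**: N_tdof = ⌊T/4⌋ temporal degrees of freedom for 40 Hz
  envelopes (the boxcar's ~10 Hz bandwidth leaves roughly one independent
  sample in four), ν = N_tdof − (K−1); Fisher-transformed correlations are
  N(0, 1/√(ν−3)) under the null, tested two-tailed at α divided by
  (K−1) × spatial_df. The spatial degrees of freedom are a config input
  (default: the number of synthetic sources; real studies would derive
  them from the forward-model rank).
* **Comparisons**: per subject, Pearson correlations of unthresholded power
  maps (spatial) and Spearman correlations of binary activations
  (temporal; on binary series Spearman coincides with the phi coefficient,
  asserted in tests). Group inference is a one-sided one-sample t-test per
  state pair against zero mean correlation, Bonferroni-corrected over
  pairs; zero-variance maps or constant series exclude the affected pair.
  Correlations are computed per subject and then tested, rather than on
  concatenated series, so between-subject variance enters the test.

## Problem sizes in the validation suite

Test and acceptance runs use 2–10 pseudo-subjects at 15–60 s, 16–32
channels, and multi-restart HMM fits with 2–5 restarts; the brute-force
decoding oracle enumerates all K^T paths for K ≤ 3, T ≤ 8, and the
threshold formula is checked against a 5·10⁵-draw Monte-Carlo null. These
sizes make every property measurable with comfortable margins while the
whole suite stays in the minutes range on one CPU.

## Limitations

* The orthonormal toy leadfield removes source cross-talk; real MEG/EEG
  inverse problems are far more collinear, and template recovery and map
  localization on real data will be correspondingly harder.
* The Fisher-null temporal-dof rule (⌊T/4⌋) is a convention tied to the
  40 Hz/10 Hz envelope pipeline, not an estimate from the data's actual
  autocorrelation.
* The VB implementation targets full-covariance Gaussian emissions on
  reduced envelopes; time-delay embeddings, semi-Markov durations and
  spectral state characterizations are out of scope.
* EDF input is read through `mne` when available; only the container
  formats written by the package itself are guaranteed lossless.
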