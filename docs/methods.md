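# Methods

## Problem and model

`speechdx` screens single-channel speech recordings for depression with a
fully interpretable generative pipeline. Each recording is reduced to a
frame-level feature sequence, and two class-conditional hidden Markov models
— Healthy (M_h) and Depressed (M_p) — score the sequence; the larger
log-likelihood wins. Both class models descend from a single *universal*
ergodic GMM-HMM M trained on a balanced pool of the most "centric"
recordings of both classes; class identity enters only through
maximum-a-posteriori (MAP) adaptation of the Gaussian means. The design
assumption is that healthy and depressed speech share most of their
acoustic support (hence a shared universal model estimated on more data)
and differ in where within that support the probability mass sits (hence
means-only adaptation) and in how long spectral patterns persist (hence an
ergodic topology with informative self-transition probabilities).

## Feature extraction

Framing is 30 ms windows with a 10 ms hop at 16 kHz (480/160 samples);
frame count for N samples is `floor((N-480)/160)+1`. Three families share
this framing so they concatenate frame-aligned:

* **MFCC.** Hamming window, 480-point power spectrum, 26 triangular mel
  filters spanning 0–8 kHz, log with floor 1e-10 (so silence is
  well-defined), orthonormal DCT-II, coefficients 1–13 kept (the 0th, a
  log-energy proxy, is dropped). Velocity/acceleration are least-squares
  slopes over ±2 frames with edge replication. These choices are the
  standard speech-recognition recipe; all are configurable.
* **TEO-CB-Auto-Env.** The signal is passed through 16 critical-band
  4th-order Butterworth bandpass filters (zero-phase, bands spanning
  100–7400 Hz), the Teager energy operator
  Ψ[x](n) = x(n)² − x(n+1)x(n−1) is applied per band, and per frame the
  rectified normalized autocorrelation of the TEO profile is integrated
  over lags 0..L/2 and divided by L/2. The per-frame normalization makes
  the descriptor amplitude-invariant; an all-zero frame scores 0 by
  definition. The lag range and rectification convention follow the
  "area under the autocorrelation envelope" construction for
  stressed-speech analysis; both are configurable.
* **F0 / harmonic ratio.** Per mean-removed frame, the normalized
  autocorrelation is searched over lags for 50–500 Hz; HR is its maximum
  and F0 the rate over the chosen lag. Because periodic signals peak at
  every multiple of the period, the smallest near-maximal lag (within 0.01
  of the maximum) is chosen and then hill-climbed to its local peak,
  which suppresses octave-down errors. Frames with HR below 0.3 are
  treated as unvoiced (F0 = 0).

Presets: *reading* = MFCC+velocity+acceleration (d = 39); *interview* =
MFCC+velocity+TEO+F0/HR (d = 44). No voice-activity trimming or
per-recording normalization is applied; feature ops own their scaling.

## Data selection

Within each class, recordings are compared by a canonical-correlation
distance: both sequences are truncated to their common length (centered,
to avoid onset-silence bias), and d(i,j) = 1 − ρ, with ρ the first
canonical correlation computed by the whitened-cross-covariance SVD with a
ridge ε = 1e-6·trace/d on the auto-covariances (frame counts close to d
make them ill-conditioned; the ridge perturbs ρ at the 1e-6 scale, so
"identical ⇒ distance 0" holds to ~1e-5 rather than exactly). A
zero-variance recording is defined maximally dissimilar (distance 1).
Classic PAM (greedy BUILD, then SWAP to a local optimum, deterministic
with lowest-index tie-breaks) clusters each class (default k = 2);
recordings are ranked by distance to their medoid, the most centric half
(default fraction 0.5) is marked for universal training, and the larger
class's training set is trimmed so both classes contribute equally. The
clustering ablation swaps the CCA distance for Euclidean distance between
per-recording mean vectors (rescaled to [0,1]).

k and the centric fraction are not dictated by the approach; k = 2 and 0.5
are exposed as configuration.

## HMM engine

Diagonal-covariance Gaussian mixtures per state (full covariance would be
poorly estimated at these data sizes; the variance floor is
1e-5 × the global per-dimension data variance). All recursions —
forward, backward, Viterbi, Baum-Welch — run in log space; Viterbi ties
break toward the lower state index. Initialization pools all frames,
k-means clusters them into S states (≤50 iterations), and fits each
state's K-component mixture by EM (≤25 iterations); A and π start uniform
over the topology mask. Baum-Welch caps at 25 iterations or a relative
log-likelihood gain below 1e-6; topology-forbidden transitions stay
exactly zero, and a state that receives no transition mass keeps its
previous row. Every stochastic step takes an explicit seed.

## MAP adaptation

With occupation likelihoods N_sk (summed forward-backward posteriors of
state s, component k over the class's adaptation sequences) and
occupancy-weighted data means μ̄_sk,

    μ̂_sk = N_sk/(N_sk+τ) · μ̄_sk + τ/(N_sk+τ) · μ_sk.

Only means are updated — weights, variances, transitions and π are shared
with the parent structurally (the adapted model is a copy whose means are
overwritten), so the "only means differ" invariant cannot be violated by
construction. Components with N_sk = 0 keep the universal mean exactly.
τ defaults to 16, the conventional relevance factor in MAP speaker-model
adaptation; the limits τ=0 (data means) and τ→∞ (prior means) are tested.

## Classification and interpretation

pv = [LL(M_h), LL(M_p)] via the forward algorithm; ζ = max pv; exact ties
go to Healthy (deterministic, and conservative in a screening setting).
The confidence score is c = 1/(1+exp(−(ℓ_win−ℓ_lose)/T)): a per-frame
averaged log-likelihood ratio through a logistic, i.e. the equal-prior
posterior of the winner; it is bounded in [0.5, 1], reduces to 0.5 at
ties, and is invariant to duplicating the recording. The posterior time
series scores sliding windows (default 3 s window, 1 s hop) by
length-normalized log-likelihood softmax; with the window spanning the
whole recording its single row reproduces `classify`'s decision.
Segment ranking keeps the top-n windows by posterior, merging adjacent
same-class windows. Viterbi paths under both models are exported for
audit, and model cards print the transition matrix with the per-state
self-transition diagnostic (depressed-speech states are expected to
persist longer).

## Evaluation protocol

Folds partition *subjects*, stratified by label; the invariant that no
subject straddles train/test is asserted on every run. Metrics are
accuracy, precision, recall, F1 in percent with Depressed as the positive
class. The grid search scans S ∈ {3..7} × K ∈ {2,4,...,128} against a 10%
subject-held-out validation split (subject-level, preserving
independence); ties prefer the smaller model. Ablation flags: `no_ubm`
(class-specific HMMs trained directly), `topology=left_right`,
`selection=clustering`, and feature subsets via `FeatureConfig`.

## Synthetic study conditions

The feature-mode generator samples from known class GMM-HMMs with d = 8,
2 states, unit variances and two knobs: *separation* (mean shift of the
depressed generator along a fixed random direction) and *persistence*
(self-transitions: Healthy 0.7, Depressed 0.9 by default, mirroring the
finding that depressed-speech states dwell longer). The default corpus is
10 subjects per class × 3 recordings × 150 frames — small enough that the
full 5-fold protocol runs in minutes on one CPU while leaving ~60 test
decisions per protocol run. The *separable* scenario (separation 3.0) is
solvable exactly; the *null* scenario (separation 0, equal persistence)
is a permutation control whose accuracy should sit in a chance band.
Audio mode renders sampled state paths as phase-continuous
harmonic-plus-noise signals (state-dependent F0 and noise level) so the
full WAV → features → decision path is exercised; it is a controllable
abstraction, not realistic speech. Consequently, passing synthetic tests
demonstrates correctness of the machinery and the expected qualitative
behavior (emphasis, persistence, chance-level nulls), not clinical
performance on real depressed speech.

## Known limitations

* CCA distance need not satisfy the triangle inequality; PAM treats it as
  a generic dissimilarity.
* The confidence score is a calibrated-looking logistic but is not
  calibrated against outcome frequencies.
* The synthetic audio renderer produces stationary-per-state timbre;
  features like MFCC deltas are far better behaved on it than on real
  speech.
* No voice-activity detection: long silences dilute likelihoods on real
  recordings.
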