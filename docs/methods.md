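# Methods

This note documents the models implemented in `statedyn`, their
assumptions, the synthetic data used to validate them, and the numerical
choices a user may want to revisit.

## Generative models

### Gaussian hidden Markov model (`statedyn.hmm`)

The joint distribution factorizes as a first-order Markov chain over a
discrete latent state with a multivariate-normal observation model:

    p(x_{1:T}, θ_{1:T}) = p(x_1|θ_1) p(θ_1) ∏_t p(x_t|θ_t) p(θ_t|θ_{t-1}),
    x_t | θ_t = k  ~  N(μ_k, D_k),      A_ij = p(θ_t = j | θ_{t-1} = i).

Assumptions: states are mutually exclusive; within a state the data are
i.i.d. Gaussian; state durations are implicitly geometric.  Subjects are
modeled as independent chains sharing one parameter set (group model);
inference on concatenated subjects restarts the chain at each boundary.

*Inference* is exact: scaled forward-backward for the smoothed marginals
γ and pairwise marginals ξ, Viterbi for the MAP path (ties broken toward
the lowest state index).  Log-space emission likelihoods plus per-step
scaling keep T ≥ 10⁵ stable.

*Training* modes:

- `em` (default): maximum-likelihood Baum-Welch.  The reported free
  energy is exactly the negative log evidence, so the trace is
  non-increasing — a property the tests assert.  An optional
  `stay_prior` adds Dirichlet pseudo-counts to the transition-matrix
  diagonal (MAP M-step) for analyses that expect persistent states.
- `vb`: variational Bayes with conjugate priors — symmetric Dirichlet
  (concentration 1) on transition rows and the initial distribution, a
  Gaussian-Wishart on each state's mean/precision (data-scaled scale
  matrix, ν₀ = C + 2, κ₀ = 10⁻³).  The reported free energy is the
  negative ELBO.

Free energies are comparable only between runs on the same data with
the same hyperparameters.  Run-to-run variability from random
initialization is handled by training N independent runs and keeping
the lowest-free-energy one (`fit_ensemble` / `select_best_run`);
`align_states` matches states across runs by maximal covariance
correlation (linear assignment) for reproducibility checks.

Defaults: random-gamma (Dirichlet) initialization; covariance ridge
10⁻⁶ × trace/C; stopping at relative objective change < 10⁻⁶ or 200
iterations; collapsed states (occupancy < C+1) are re-seeded from a
random data segment.  Mean pinning — fixing μ_k ≡ 0 so that all dynamic
structure is carried by the covariances — is resolved automatically
from the preparation record: on for time-delay embedded data, off for
amplitude-envelope data.

### Dynamic mode mixture (`statedyn.dynemo`)

At every sample the observation distribution is a convex mixture of J
mode means and covariances:

    x_t ~ N(Σ_j α_jt μ_j, Σ_j α_jt D_j),   α_t = softmax(θ_t),

with a strictly causal Gaussian prior on the logits,
p(θ_t | θ_{1:t-1}) = N(m_t, σ_t²).  The causal map is implemented as a
learned linear recurrence per mode (m_t = a·θ_{t-1} + b, constant
learned variance) — the minimal parameterization of the contract that a
prior predicts the next logits from their history.

*Inference* is amortized variational.  The posterior over θ_t is a
factorized Gaussian whose means are a learned linear read-out of
multi-scale local covariance features of the data (moving-average
second moments over windows of 10/50/200 samples, z-scored), with one
learned standard deviation per mode.  Two observations motivate this
design:

- a *free-form* per-sample posterior can overfit: wiggling the logits
  sample-by-sample raises the likelihood while the learned prior
  variance adapts to the wiggle, destroying recovery.  Sharing the
  encoder across all samples removes that degeneracy;
- for Gaussian observations the log-likelihood ratio between modes is
  *linear* in windowed second moments, so the feature class can in
  principle express the exact posterior-mean map.

The ELBO (reparameterized likelihood term, one sample per step, minus
the analytic KL to the causal prior) is maximized with Adam on
hand-derived gradients; the KL term is annealed in linearly over the
first 40% of iterations (a guard against posterior collapse), and the
learning rate decays linearly to 10%.  Convex mixtures carry a scale
degeneracy — inflating the mode covariances while contracting the
mixing toward the simplex interior leaves the likelihood unchanged — so
a weak inverse-Wishart prior on each mode covariance, centred on the
global data covariance (strength 0.05·T pseudo-samples), selects the
minimal basis; this is what makes the inferred mixing collapse to
near-binary on genuinely mutually exclusive data.  Initialization
(default `init="hmm"`) anchors the mode covariances and the encoder
with a short HMM fit, the standard hard-clustering initializer for
mixtures.

The reported free energy is the posterior-mean plug-in likelihood minus
the exact KL term — a deterministic quantity suitable for ranking runs.

Post-processing: `renormalize_mixing` reweights α by each mode
covariance's trace (so modes of different overall variance contribute
comparably) and re-projects to the simplex; `binarize_mixing` fits a
two-component univariate GMM per mode and labels the higher-mean
component "on".

## Data preparation (`statedyn.prepare`)

- *Amplitude envelope*: zero-phase Butterworth bandpass (order 5,
  forward-backward) then the modulus of the analytic signal.  The first
  and last ~1 cycle of each recording are edge-affected; no padding is
  applied.
- *Time-delay embedding*: each channel is augmented with lagged copies
  at lags −(n−1)/2 … +(n−1)/2 (always one-sample shifts).  Column order
  is channel-major, lag-minor; the first and last (n−1)/2 rows are
  dropped, and the index map from prepared rows to original samples is
  carried through every later stage so that inferred state time courses
  can be re-aligned with the source data (dual estimation, spectra).
- *PCA*: fitted on the subject-concatenated data by default (models are
  trained on concatenated data), economy SVD with a deterministic sign
  convention; components and explained-variance ratios are stored in the
  preparation record.  Required for multichannel TDE data, where the
  embedded dimension is C × n_embeddings.
- *Standardization*: per subject by default (removes inter-subject scale
  differences before concatenation).  The default order is
  TDE → PCA → standardize; both orders are available.

## Spectral estimation (`statedyn.spectra`)

State-conditioned spectra use DPSS multitapers (defaults: 2 s windows,
time-half-bandwidth 4, 7 tapers, 50% overlap; all parameter-stamped in
the output).  Windows are weighted by the mean state probability within
the window and normalized by total weight; a hard Viterbi assignment is
the special case of a one-hot course.  PSDs are one-sided densities, so
integrating over (0, Nyquist] recovers the variance (Parseval — tested
at 5%).  States with total weight under one window are flagged missing
rather than silently zero.  Note the resolution bandwidth (±NW/window
length): spectra that change quickly need longer windows, e.g. the
AR(1) validation uses 4 s windows.

Mode spectra for soft mixtures use the GLM approach: a sliding-window
multitaper (cross-)spectrogram is regressed on the window-averaged,
demeaned mixing coefficients plus an intercept; the reported mode
spectrum is intercept + coefficient, so a zero-effect mode equals the
mean spectrum.  Degenerate designs (J = 1, constant α) fall back to the
intercept with a warning.

Coherence is |S_xy|/√(S_xx S_yy) (magnitude, not magnitude-squared —
configurable by squaring; common electrophysiology practice).
Data-driven frequency bands come from non-negative matrix factorization
of stacked coherence spectra (nndsvd initialization, fixed seed),
components ordered by peak frequency so "the first band" is always the
low-frequency one.  Amplitude-envelope correlation is bandpass →
envelope → Pearson correlation.  Static analyses reuse the same
machinery with a single all-on state.

## Summary statistics (`statedyn.summary`)

Fractional occupancy, mean lifetime, mean interval (end of one visit to
start of the next; edge gaps excluded), switching rate (= "burst count"
in the single-region setting) and mean amplitude.  Conventions:
boundary-truncated runs count toward lifetimes; a state needs ≥ 2
visits for an interval; statistics are computed per subject, never
across subject boundaries.  The identity FO = switching rate × mean
lifetime holds within edge effects (tested at 2% for T = 10⁵).

## Group inference (`statedyn.group`)

Evoked responses: the state time course (Viterbi by default) is epoched
around events, baseline-corrected by the pre-event mean, and tested
with a one-sample t per state × time point; the null sign-flips each
unit's deviations and pools the maximum |t| (family-wise error
control).  Sign-flip validity requires symmetric exchangeable units:
subject-level trial-averaged responses satisfy this; raw single-trial
binary indicators do not (their skew inflates the FWER — averaged units
are calibrated at FWER 4–6% in the acceptance tests).

Two-group contrasts use a standardized mean difference per element
(unit-free, so states × metrics or bands × edges pool directly), group
labels are permuted (exact enumeration when ≤ n_perm distinct
assignments exist), and the maximum over all pooled elements forms the
null.  p-values are (1 + #{null ≥ obs}) / (n_perm + 1), floored at
1/(n_perm+1).

Display thresholding: a two-component GMM on the connection
distribution (keep posterior-probability > 0.5 of the higher-mean,
"atypically strong", component; affine-invariant; unimodal input warns
and returns an empty mask), or top-k% of edges (ties at the cut all
kept).

## Synthetic data (`statedyn.simulate`)

The generators define the study conditions under which every stage is
validated:

- *State-switching Gaussian data*: Markov path (scalar stay
  probabilities expand to uniform-off-diagonal matrices) + per-state
  Gaussian draws; optional per-subject jitter of means/covariance
  scales so dual estimation is testable.  `distinct_covariances`
  produces the well-separated regime (orthogonal rank-one variance
  boosts, strength 5) used in recovery tests; `random_covariances`
  (near-identity Wishart draws) provides generic SPD matrices for
  oracle tests.
- *Soft-mixture data*: logits are Gaussian-smoothed white noise
  (σ = 200 samples, marginal SD 2 — slow, partial mixing), α = softmax,
  draws from the instantaneous mixture moments.
- *Bursts*: per type, a renewal process of activations (rate 0.25/s,
  gamma-distributed durations with shape 2 and mean 0.4 s ⇒ ~10%
  occupancy per type, typical of the electrophysiological burst
  literature), a sinusoidal carrier with random phase per burst, a
  tapered-cosine (Tukey, 10% taper) envelope — smooth onset/offset with
  a flat plateau so the nominal mask remains recoverable from signal
  amplitude — and additive white noise (sd 0.316, i.e. variance 0.1).
  Sampling frequency defaults to 100 Hz, the conventional rate for
  burst analyses.  Overlapping bursts of different types are summed;
  the mask records each type independently.

What these simulations do *not* emulate: 1/f background spectra,
volume-conduction/leakage structure, forward-modelled sensor noise,
non-Gaussian heavy tails, or non-stationary artifacts.  Passing the
recovery tests therefore demonstrates correctness of the machinery
under its own assumptions, not performance on real recordings.

Two limits of the mutually-exclusive-state description show up
quantitatively in the burst validation and are worth knowing about:
overlapping bursts of different types cannot be co-assigned (the
overlap, ~duty of the other type, is missing from one type's recovered
mask), and time-delay-embedded windows mix regimes within
(n_embeddings − 1) samples of every burst boundary, so visits are
systematically trimmed/smeared at edges.  Together these cap the
per-type mask dice near 0.8–0.9 at the default conditions even though
state spectra and lifetimes are recovered accurately.

## Numerical choices

- Covariance ridge 10⁻⁶·trace/C everywhere a covariance is estimated.
- Viterbi ties → lowest state index.
- Permutation defaults: 5,000 permutations, exact enumeration when the
  group-label space is at most that large.
- NMF: nndsvda init, tolerance 10⁻⁸, seed exposed.
- The mixture trainer aborts with diagnostics on non-finite loss rather
  than continuing from a poisoned state.
- Problem sizes in the validation suite (T = 5·10⁴ for recovery tests,
  10⁵ for law checks, 500 replicates for FWER calibration) were chosen
  as the smallest sizes at which the targeted tolerances are clearly
  resolvable.

## Known limitations

- The HMM's `vb` mode uses fixed, weakly informative priors; no
  empirical-Bayes updating of hyperparameters.
- The mixture model's encoder is linear in its features; strongly
  nonlinear posterior-mean maps (e.g. very low SNR regimes) may need a
  richer encoder.
- No HSMM-style explicit duration modeling; state dwell times are
  geometric under the prior.
- Sign-flip evoked inference assumes symmetric units (see above).
- `run_pipeline` covers the three standard workflows; bespoke analyses
  are expected to compose the library functions directly.
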