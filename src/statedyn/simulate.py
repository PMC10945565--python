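"""Synthetic multichannel time series with known latent structure.

Three generators cover the study conditions every downstream stage is
validated against:

* :func:`sample_hmm` — state-switching multivariate Gaussian data.  A
  hidden Markov chain selects, at every sample, one of K states, each with
  its own mean vector and covariance matrix.
* :func:`sample_soft_mixture` — data whose instantaneous mean and
  covariance are convex combinations of J mode means/covariances, with
  mixing coefficients ``alpha_t = softmax(theta_t)`` driven by a slowly
  varying logit process.
* :func:`sample_bursts` — a single channel containing transient
  amplitude-modulated sinusoids ("bursts") at one or more carrier
  frequencies, embedded in white Gaussian noise, with the exact on/off
  mask of every burst type returned as ground truth.

All generators are deterministic given their spec's ``seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import TimeSeriesSet

__all__ = [
    "HMMSimSpec",
    "MixtureSimSpec",
    "BurstSimSpec",
    "sample_hmm",
    "sample_soft_mixture",
    "sample_bursts",
    "random_covariances",
    "distinct_covariances",
    "expand_transition_matrix",
]


# ---------------------------------------------------------------------------
# validation helpers


def _check_spd(covs: np.ndarray, name: str) -> np.ndarray:
    covs = np.asarray(covs, dtype=float)
    if covs.ndim == 2:
        covs = covs[None]
    for i, c in enumerate(covs):
        if not np.allclose(c, c.T, atol=1e-10):
            raise ValueError(f"{name}[{i}] is not symmetric")
        eigvals = np.linalg.eigvalsh(c)
        if eigvals.min() <= 0:
            raise ValueError(
                f"{name}[{i}] is not positive definite "
                f"(smallest eigenvalue {eigvals.min():.3g})"
            )
    return covs


def _check_stochastic(A: np.ndarray) -> np.ndarray:
    A = np.asarray(A, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("transition matrix must be square")
    if (A < 0).any() or not np.allclose(A.sum(axis=1), 1.0, atol=1e-12):
        raise ValueError("transition matrix rows must be non-negative and sum to 1")
    return A


def expand_transition_matrix(stay_probability: float, n_states: int) -> np.ndarray:
    """Uniform-off-diagonal transition matrix with the given stay probability."""
    if not 0 <= stay_probability <= 1:
        raise ValueError("stay_probability must lie in [0, 1]")
    if n_states == 1:
        return np.ones((1, 1))
    off = (1.0 - stay_probability) / (n_states - 1)
    A = np.full((n_states, n_states), off)
    np.fill_diagonal(A, stay_probability)
    return A


def distinct_covariances(
    n: int,
    n_channels: int,
    rng: np.random.Generator,
    strength: float = 5.0,
) -> np.ndarray:
    """Draw ``n`` well-separated SPD matrices.

    Each matrix is the identity plus a strong rank-one boost along its
    own member of a random orthonormal frame, with mild random Wishart
    texture.  This is the canonical construction for state/mode
    covariances that are individually well-conditioned yet mutually
    discriminable — each state concentrates variance along a different
    direction.
    """
    if n > n_channels:
        raise ValueError("need n <= n_channels for orthogonal boost directions")
    q, _ = np.linalg.qr(rng.standard_normal((n_channels, n_channels)))
    covs = np.empty((n, n_channels, n_channels))
    for i in range(n):
        w = rng.standard_normal((4 * n_channels, n_channels)) / np.sqrt(4 * n_channels)
        texture = w.T @ w
        texture /= np.trace(texture) / n_channels
        covs[i] = (
            0.8 * np.eye(n_channels)
            + 0.2 * texture
            + strength * np.outer(q[:, i], q[:, i])
        )
    return covs


def random_covariances(
    n: int,
    n_channels: int,
    rng: np.random.Generator,
    df_scale: float = 4.0,
) -> np.ndarray:
    """Draw ``n`` well-conditioned, mutually distinct SPD matrices.

    Wishart-style draws with ``df_scale * n_channels`` degrees of freedom,
    normalized to unit mean variance, plus a small ridge for conditioning.
    """
    df = max(int(df_scale * n_channels), n_channels + 2)
    covs = np.empty((n, n_channels, n_channels))
    for i in range(n):
        w = rng.standard_normal((df, n_channels))
        c = w.T @ w / df
        c /= np.trace(c) / n_channels
        covs[i] = c + 0.05 * np.eye(n_channels)
    return covs


# ---------------------------------------------------------------------------
# specs


@dataclass
class HMMSimSpec:
    """Conditions for state-switching multivariate Gaussian data."""

    n_samples: int
    n_channels: int
    state_means: np.ndarray  # (K, C)
    state_covariances: np.ndarray  # (K, C, C)
    transition_matrix: np.ndarray | float  # (K, K) or scalar stay probability
    sampling_frequency: float = 250.0
    n_subjects: int = 1
    initial_distribution: np.ndarray | None = None
    subject_jitter: float = 0.0  # per-subject heterogeneity scale (0 = none)
    seed: int = 0

    def __post_init__(self):
        if self.n_samples <= 0 or self.n_subjects <= 0 or self.n_channels <= 0:
            raise ValueError("counts must be positive")
        self.state_means = np.atleast_2d(np.asarray(self.state_means, dtype=float))
        self.state_covariances = _check_spd(self.state_covariances, "state_covariances")
        K = self.state_means.shape[0]
        if self.state_covariances.shape != (K, self.n_channels, self.n_channels):
            raise ValueError("state_covariances shape mismatch")
        if self.state_means.shape[1] != self.n_channels:
            raise ValueError("state_means shape mismatch")
        if np.isscalar(self.transition_matrix):
            self.transition_matrix = expand_transition_matrix(
                float(self.transition_matrix), K
            )
        self.transition_matrix = _check_stochastic(self.transition_matrix)
        if self.transition_matrix.shape[0] != K:
            raise ValueError("transition matrix size must match number of states")
        if self.initial_distribution is None:
            self.initial_distribution = np.full(K, 1.0 / K)
        self.initial_distribution = np.asarray(self.initial_distribution, dtype=float)
        if not np.isclose(self.initial_distribution.sum(), 1.0, atol=1e-12):
            raise ValueError("initial distribution must sum to 1")

    @property
    def n_states(self) -> int:
        return self.state_means.shape[0]


@dataclass
class MixtureSimSpec:
    """Conditions for soft-mixture data with a smoothed-random-walk logit process.

    The logit process is white Gaussian noise per mode smoothed with a
    Gaussian kernel of width ``logit_smoothing`` samples and rescaled to
    marginal standard deviation ``logit_scale``; mixing coefficients are
    its softmax.
    """

    n_samples: int
    n_channels: int
    mode_means: np.ndarray  # (J, C)
    mode_covariances: np.ndarray  # (J, C, C)
    sampling_frequency: float = 250.0
    logit_smoothing: float = 200.0  # Gaussian kernel sigma, samples
    logit_scale: float = 2.0  # marginal SD of each logit
    seed: int = 0

    def __post_init__(self):
        if self.n_samples <= 0 or self.n_channels <= 0:
            raise ValueError("counts must be positive")
        self.mode_means = np.atleast_2d(np.asarray(self.mode_means, dtype=float))
        self.mode_covariances = _check_spd(self.mode_covariances, "mode_covariances")
        J = self.mode_means.shape[0]
        if self.mode_covariances.shape != (J, self.n_channels, self.n_channels):
            raise ValueError("mode_covariances shape mismatch")
        if self.mode_means.shape[1] != self.n_channels:
            raise ValueError("mode_means shape mismatch")
        if self.logit_smoothing <= 0 or self.logit_scale < 0:
            raise ValueError("logit process parameters must be positive")

    @property
    def n_modes(self) -> int:
        return self.mode_means.shape[0]


@dataclass
class BurstSimSpec:
    """Conditions for transient oscillations (bursts) in white noise.

    Each burst type is a Poisson process of activations (rate
    ``burst_rate`` per second); each activation is a sinusoid at the
    type's carrier frequency, amplitude-modulated by a tapered-cosine
    (Tukey, 10% taper) envelope — smooth raised-cosine onset and offset
    with a flat plateau, so the burst mask remains recoverable from the
    signal amplitude.  Durations are gamma distributed (shape 2) with
    mean ``burst_duration_mean``.  Bursts of different types may overlap
    and are summed; the returned mask records each type independently.
    """

    n_samples: int
    sampling_frequency: float = 100.0  # burst analyses conventionally run at 100 Hz
    carrier_frequencies: tuple[float, ...] = (10.0, 25.0)
    burst_rate: float = 0.25  # activations per second per type (~10% occupancy)
    burst_duration_mean: float = 0.4  # seconds
    burst_amplitude: float = 1.0  # peak envelope amplitude
    noise_sd: float = 0.316  # N(0, 0.1)-variance background noise
    seed: int = 0

    def __post_init__(self):
        if self.n_samples <= 0:
            raise ValueError("n_samples must be positive")
        nyq = self.sampling_frequency / 2.0
        for f in self.carrier_frequencies:
            if not 0 < f < nyq:
                raise ValueError(f"carrier frequency {f} Hz not below Nyquist {nyq} Hz")
        if self.burst_duration_mean <= 0:
            raise ValueError("burst durations must be positive")
        if self.burst_rate < 0 or self.noise_sd < 0:
            raise ValueError("burst_rate and noise_sd must be non-negative")


# ---------------------------------------------------------------------------
# samplers


def _sample_markov_chain(
    A: np.ndarray, pi: np.ndarray, n_samples: int, rng: np.random.Generator
) -> np.ndarray:
    K = A.shape[0]
    cdf = np.cumsum(A, axis=1)
    u = rng.random(n_samples)
    path = np.empty(n_samples, dtype=np.int64)
    path[0] = np.searchsorted(np.cumsum(pi), u[0], side="right")
    for t in range(1, n_samples):
        path[t] = np.searchsorted(cdf[path[t - 1]], u[t], side="right")
    return np.minimum(path, K - 1)


def _jitter_params(
    means: np.ndarray,
    covs: np.ndarray,
    scale: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-subject heterogeneity: additive mean jitter, multiplicative
    covariance scale jitter (kept SPD by construction)."""
    means = means + scale * rng.standard_normal(means.shape)
    factors = np.exp(scale * rng.standard_normal(covs.shape[0]))
    covs = covs * factors[:, None, None]
    return means, covs


def sample_hmm(spec: HMMSimSpec) -> tuple[TimeSeriesSet, list[np.ndarray]]:
    """Draw state-switching Gaussian data; returns (data, state paths).

    Each subject's path is an independent draw from the Markov chain and
    ``x_t | path_t = k ~ N(mu_k, D_k)``.
    """
    rng = np.random.default_rng(spec.seed)
    chols = np.linalg.cholesky(spec.state_covariances)
    arrays, paths = [], []
    for _ in range(spec.n_subjects):
        means, covs = spec.state_means, spec.state_covariances
        ch = chols
        if spec.subject_jitter > 0:
            means, covs = _jitter_params(means, covs, spec.subject_jitter, rng)
            ch = np.linalg.cholesky(covs)
        path = _sample_markov_chain(
            spec.transition_matrix, spec.initial_distribution, spec.n_samples, rng
        )
        z = rng.standard_normal((spec.n_samples, spec.n_channels))
        x = np.empty_like(z)
        for k in range(spec.n_states):
            idx = np.where(path == k)[0]
            if len(idx):
                x[idx] = means[k] + z[idx] @ ch[k].T
        arrays.append(x)
        paths.append(path)
    ts = TimeSeriesSet(arrays=arrays, sampling_frequency=spec.sampling_frequency)
    return ts, paths


def _smoothed_logits(
    n_samples: int, n_modes: int, sigma: float, scale: float, rng: np.random.Generator
) -> np.ndarray:
    from scipy.ndimage import gaussian_filter1d

    white = rng.standard_normal((n_samples, n_modes))
    theta = gaussian_filter1d(white, sigma=sigma, axis=0, mode="reflect")
    sd = theta.std(axis=0)
    sd[sd == 0] = 1.0
    return theta / sd * scale


def sample_soft_mixture(spec: MixtureSimSpec) -> tuple[TimeSeriesSet, np.ndarray]:
    """Draw soft-mixture data; returns (data, ground-truth alpha (T, J)).

    ``x_t ~ N(sum_j alpha_jt mu_j, sum_j alpha_jt D_j)`` with
    ``alpha_t = softmax(theta_t)`` and theta the smoothed logit process.
    """
    rng = np.random.default_rng(spec.seed)
    theta = _smoothed_logits(
        spec.n_samples, spec.n_modes, spec.logit_smoothing, spec.logit_scale, rng
    )
    theta -= theta.max(axis=1, keepdims=True)
    alpha = np.exp(theta)
    alpha /= alpha.sum(axis=1, keepdims=True)

    m = alpha @ spec.mode_means  # (T, C)
    C_t = np.einsum("tj,jcd->tcd", alpha, spec.mode_covariances)
    L = np.linalg.cholesky(C_t)
    z = rng.standard_normal((spec.n_samples, spec.n_channels))
    x = m + np.einsum("tcd,td->tc", L, z)
    ts = TimeSeriesSet(arrays=[x], sampling_frequency=spec.sampling_frequency)
    return ts, alpha


def sample_bursts(spec: BurstSimSpec) -> tuple[TimeSeriesSet, np.ndarray]:
    """Draw a single-channel burst signal; returns (data, mask (T, n_types)).

    signal = sum_types mask_type(t) * tukey_envelope(t) * sin(2 pi f t + phase)
             + N(0, noise_sd^2) noise.
    """
    from scipy.signal import windows as sp_windows

    rng = np.random.default_rng(spec.seed)
    fs = spec.sampling_frequency
    T = spec.n_samples
    t_axis = np.arange(T) / fs
    n_types = len(spec.carrier_frequencies)
    signal = np.zeros(T)
    mask = np.zeros((T, n_types), dtype=bool)

    for j, f in enumerate(spec.carrier_frequencies):
        t = 0.0
        while True:
            gap = rng.exponential(1.0 / spec.burst_rate) if spec.burst_rate > 0 else np.inf
            t += gap
            if t >= T / fs:
                break
            duration = rng.gamma(shape=2.0, scale=spec.burst_duration_mean / 2.0)
            start = int(round(t * fs))
            length = max(int(round(duration * fs)), 2)
            stop = min(start + length, T)
            if stop <= start:
                continue
            env = sp_windows.tukey(length, alpha=0.1)[: stop - start] * spec.burst_amplitude
            phase = rng.uniform(0, 2 * np.pi)
            signal[start:stop] += env * np.sin(
                2 * np.pi * f * t_axis[start:stop] + phase
            )
            mask[start:stop, j] = True
            t += duration

    signal = signal + spec.noise_sd * rng.standard_normal(T)
    ts = TimeSeriesSet(arrays=[signal[:, None]], sampling_frequency=fs)
    return ts, mask
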