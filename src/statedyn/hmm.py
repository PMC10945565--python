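"""Hidden Markov model with multivariate-normal observations.

The generative model: a latent state ``theta_t`` in ``{1..K}`` follows a
first-order Markov chain with transition matrix ``A`` and initial
distribution ``pi``; observations are drawn from the active state's
Gaussian, ``x_t | theta_t = k ~ N(mu_k, D_k)``.  Training on time-delay
embedded data conventionally pins the means to zero so that all dynamic
structure is carried by the state covariances.

Inference is exact (scaled forward-backward; Viterbi decoding).  Two
training modes are provided:

* ``"em"`` (default) — maximum-likelihood Baum-Welch.  The reported free
  energy is the exact negative log evidence, so the objective trace is
  non-increasing, which the tests exploit.
* ``"vb"`` — variational Bayes with conjugate priors (Dirichlet rows on
  the transition matrix and initial distribution, Gaussian-Wishart on the
  observation parameters); the reported free energy is the negative ELBO.

Free energies are comparable only across runs on the same data with the
same hyperparameters; the run with the lowest value is conventionally
kept for analysis.

The model/results surface follows the statsmodels convention:
``GaussianHMM(data, n_states).fit()`` returns an :class:`HMMResults`
holding parameters, posteriors, the free-energy trace, a ``viterbi()``
decoder, ``dual_estimate()`` and a ``summary()`` table.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy.linalg import solve_triangular
from scipy.special import digamma, gammaln

from .data import PreparedData, TimeSeriesSet, as_time_series_set

__all__ = [
    "HMMParams",
    "Posterior",
    "GaussianHMM",
    "HMMResults",
    "forward_backward",
    "viterbi",
    "free_energy",
    "dual_estimate",
]

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# parameter / posterior containers


@dataclass
class HMMParams:
    """State means/covariances, transition matrix and initial distribution."""

    means: np.ndarray  # (K, C)
    covariances: np.ndarray  # (K, C, C)
    transition_matrix: np.ndarray  # (K, K) row-stochastic
    initial_distribution: np.ndarray  # (K,)

    def __post_init__(self):
        self.means = np.atleast_2d(np.asarray(self.means, dtype=float))
        self.covariances = np.asarray(self.covariances, dtype=float)
        if self.covariances.ndim == 2:
            self.covariances = self.covariances[None]
        self.transition_matrix = np.atleast_2d(
            np.asarray(self.transition_matrix, dtype=float)
        )
        self.initial_distribution = np.asarray(self.initial_distribution, dtype=float)
        K = self.n_states
        if not np.allclose(self.transition_matrix.sum(axis=1), 1.0, atol=1e-10):
            raise ValueError("transition matrix rows must sum to 1")
        if (self.transition_matrix < 0).any():
            raise ValueError("transition matrix must be non-negative")
        if self.covariances.shape[0] != K or self.initial_distribution.shape != (K,):
            raise ValueError("inconsistent state counts across parameters")

    @property
    def n_states(self) -> int:
        return self.means.shape[0]

    @property
    def n_channels(self) -> int:
        return self.means.shape[1]

    def stay_probabilities(self) -> np.ndarray:
        return np.diag(self.transition_matrix)


@dataclass
class Posterior:
    """Smoothed marginals and pairwise transition expectations.

    ``gamma`` rows are per-sample state probabilities (concatenated over
    subjects); ``xi`` stacks the (T_s - 1, K, K) pairwise marginals of
    each subject in order.  ``log_evidence`` is the exact data
    log-likelihood under the parameters used for inference;
    ``free_energy`` is its negative (or the negative ELBO in VB mode).
    """

    gamma: np.ndarray
    xi: np.ndarray
    log_evidence: float
    free_energy: float
    segment_lengths: list[int] = field(default_factory=list)

    def split_gamma(self) -> list[np.ndarray]:
        out, start = [], 0
        for n in self.segment_lengths:
            out.append(self.gamma[start : start + n])
            start += n
        return out


# ---------------------------------------------------------------------------
# numerical kernels


@njit(cache=False)
def _fb_kernel(B, A, pi):
    """Scaled forward-backward.  B is the (T, K) emission likelihood
    matrix rescaled so each row's maximum is 1."""
    T, K = B.shape
    alpha = np.empty((T, K))
    c = np.empty(T)
    a = pi * B[0]
    c[0] = a.sum()
    alpha[0] = a / c[0]
    for t in range(1, T):
        a = (alpha[t - 1] @ A) * B[t]
        c[t] = a.sum()
        alpha[t] = a / c[t]
    beta = np.empty((T, K))
    beta[T - 1] = 1.0
    gamma = np.empty((T, K))
    gamma[T - 1] = alpha[T - 1]
    xi = np.empty((T - 1, K, K))
    for t in range(T - 2, -1, -1):
        bb = B[t + 1] * beta[t + 1]
        beta[t] = (A @ bb) / c[t + 1]
        g = alpha[t] * beta[t]
        gamma[t] = g / g.sum()
        for i in range(K):
            for j in range(K):
                xi[t, i, j] = alpha[t, i] * A[i, j] * bb[j] / c[t + 1]
        xi[t] /= xi[t].sum()
    return gamma, xi, np.log(c).sum()


@njit(cache=False)
def _viterbi_kernel(logB, logA, logpi):
    T, K = logB.shape
    delta = logpi + logB[0]
    psi = np.zeros((T, K), dtype=np.int64)
    for t in range(1, T):
        new = np.empty(K)
        for j in range(K):
            best, arg = -np.inf, 0
            for i in range(K):
                v = delta[i] + logA[i, j]
                if v > best:  # strict: lowest index wins ties
                    best, arg = v, i
            new[j] = best + logB[t, j]
            psi[t, j] = arg
        delta = new
    path = np.empty(T, dtype=np.int64)
    best, arg = -np.inf, 0
    for i in range(K):
        if delta[i] > best:
            best, arg = delta[i], i
    path[T - 1] = arg
    for t in range(T - 2, -1, -1):
        path[t] = psi[t + 1, path[t + 1]]
    return path


def _log_emission(x: np.ndarray, params: HMMParams) -> np.ndarray:
    """(T, K) log N(x_t; mu_k, D_k)."""
    T, C = x.shape
    K = params.n_states
    logB = np.empty((T, K))
    for k in range(K):
        try:
            L = np.linalg.cholesky(params.covariances[k])
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(
                f"state {k} covariance is singular; increase the covariance "
                "regularization (covariance_reg) or reduce the model size"
            ) from exc
        logdet = 2.0 * np.log(np.diag(L)).sum()
        z = solve_triangular(L, (x - params.means[k]).T, lower=True)
        logB[:, k] = -0.5 * (C * np.log(2 * np.pi) + logdet + (z**2).sum(axis=0))
    return logB


def _segments(data) -> tuple[list[np.ndarray], object]:
    """Normalize input to a list of per-subject matrices."""
    if isinstance(data, PreparedData):
        return data.arrays, data
    if isinstance(data, TimeSeriesSet):
        return data.arrays, data
    if isinstance(data, np.ndarray):
        return [np.atleast_2d(data.T).T if data.ndim == 1 else data], None
    return list(data), None


# ---------------------------------------------------------------------------
# exact inference (module-level operations)


def forward_backward(params: HMMParams, data) -> Posterior:
    """Exact smoothed marginals; per-subject segments are independent chains."""
    arrays, _ = _segments(data)
    gammas, xis, loglik = [], [], 0.0
    for x in arrays:
        logB = _log_emission(np.asarray(x, dtype=float), params)
        rowmax = logB.max(axis=1)
        B = np.exp(logB - rowmax[:, None])
        g, xi, logc = _fb_kernel(B, params.transition_matrix, params.initial_distribution)
        gammas.append(g)
        xis.append(xi)
        loglik += logc + rowmax.sum()
    gamma = np.concatenate(gammas, axis=0)
    xi = (
        np.concatenate(xis, axis=0)
        if xis and xis[0].size
        else np.empty((0, params.n_states, params.n_states))
    )
    return Posterior(
        gamma=gamma,
        xi=xi,
        log_evidence=loglik,
        free_energy=-loglik,
        segment_lengths=[len(x) for x in arrays],
    )


def viterbi(params: HMMParams, data) -> list[np.ndarray]:
    """Maximum-a-posteriori state sequence per subject (0-based labels)."""
    arrays, _ = _segments(data)
    with np.errstate(divide="ignore"):
        logA = np.log(params.transition_matrix)
        logpi = np.log(params.initial_distribution)
    paths = []
    for x in arrays:
        logB = _log_emission(np.asarray(x, dtype=float), params)
        paths.append(_viterbi_kernel(logB, logA, logpi))
    return paths


def free_energy(params: HMMParams, data) -> float:
    """Negative log evidence under exact inference (lower is better)."""
    return forward_backward(params, data).free_energy


# ---------------------------------------------------------------------------
# dual estimation


def dual_estimate(
    gamma_or_paths,
    source_data: TimeSeriesSet,
    prepared: PreparedData | None = None,
    n_states: int | None = None,
) -> dict:
    """Subject-specific observation statistics from a group state time course.

    Re-estimates each subject's per-state means and covariances by
    gamma-weighted averaging of that subject's *source* data.  When the
    state time course was inferred on prepared (e.g. time-delay embedded)
    data, pass ``prepared`` so its index maps re-align the rows to source
    samples.  A hard path is accepted in place of gamma.

    Returns a dict with ``means (S, K, C)``, ``covariances (S, K, C, C)``
    and a boolean ``missing (S, K)`` mask flagging subject/state pairs
    with (near) zero occupancy; their statistics are NaN, never silently
    zero.
    """
    if isinstance(gamma_or_paths, np.ndarray):
        gamma_or_paths = [gamma_or_paths]
    gammas = []
    for g in gamma_or_paths:
        g = np.asarray(g)
        if g.ndim == 1:  # hard path -> one-hot
            if n_states is None:
                n_states_local = int(g.max()) + 1
            else:
                n_states_local = n_states
            onehot = np.zeros((len(g), n_states_local))
            onehot[np.arange(len(g)), g.astype(int)] = 1.0
            g = onehot
        gammas.append(g)
    K = gammas[0].shape[1]
    S = source_data.n_subjects
    C = source_data.n_channels
    if len(gammas) != S:
        raise ValueError("need one state time course per subject")

    means = np.full((S, K, C), np.nan)
    covs = np.full((S, K, C, C), np.nan)
    missing = np.zeros((S, K), dtype=bool)
    for s in range(S):
        x = source_data.arrays[s]
        g = gammas[s]
        if prepared is not None:
            x = x[prepared.index_maps[s]]
        if len(x) != len(g):
            raise ValueError(
                "state time course not aligned with source samples; "
                "pass the PreparedData used for inference"
            )
        occ = g.sum(axis=0)
        for k in range(K):
            if occ[k] < C + 1:  # too few effective samples for a covariance
                missing[s, k] = True
                continue
            w = g[:, k] / occ[k]
            mu = w @ x
            xc = x - mu
            means[s, k] = mu
            covs[s, k] = (xc * w[:, None]).T @ xc
    return {"means": means, "covariances": covs, "missing": missing}


# ---------------------------------------------------------------------------
# training


def _regularized(cov: np.ndarray, eps: float) -> np.ndarray:
    C = cov.shape[-1]
    tr = np.trace(cov, axis1=-2, axis2=-1)
    return cov + (eps * np.maximum(tr, 1e-300) / C)[..., None, None] * np.eye(C)


def _random_segment_stats(x, rng, min_len):
    T = len(x)
    length = min(T, min_len)
    start = rng.integers(0, T - length + 1)
    seg = x[start : start + length]
    return seg.mean(axis=0), np.cov(seg.T, bias=True).reshape(x.shape[1], x.shape[1])


class GaussianHMM:
    """Hidden Markov model with Gaussian observations.

    Parameters
    ----------
    data : TimeSeriesSet, PreparedData, ndarray or list of ndarray
        Per-subject (T, C) matrices; subjects are independent chains
        sharing one set of parameters.
    n_states : int
        Number of latent states K.
    pin_means : bool or None
        Fix state means at zero.  ``None`` (default) resolves from the
        preparation record: on for time-delay embedded data, off
        otherwise.
    covariance_reg : float
        Trace-scaled ridge added to every estimated covariance.
    """

    def __init__(
        self,
        data,
        n_states: int,
        pin_means: bool | None = None,
        covariance_reg: float = 1e-6,
        sampling_frequency: float | None = None,
    ):
        if n_states < 1:
            raise ValueError("n_states must be >= 1")
        arrays, container = _segments(data)
        self.arrays = [np.asarray(a, dtype=float) for a in arrays]
        self.data = data if container is not None else None
        self.n_states = n_states
        self.n_channels = self.arrays[0].shape[1]
        self.covariance_reg = covariance_reg
        self.sampling_frequency = sampling_frequency or getattr(
            data, "sampling_frequency", None
        )
        if pin_means is None:
            steps = getattr(data, "record", {}).get("steps", [])
            pin_means = any(s.get("step") == "tde" for s in steps)
        self.pin_means = bool(pin_means)
        self._x = np.concatenate(self.arrays, axis=0)

    # -- M-step -------------------------------------------------------------

    def _m_step(self, gamma, xi_sum, first_rows, rng, stay_prior=0.0) -> HMMParams:
        x = self._x
        K, C = self.n_states, self.n_channels
        occ = gamma.sum(axis=0)
        collapsed = np.where(occ < C + 1)[0]
        occ_safe = np.maximum(occ, 1e-300)
        means = (gamma.T @ x) / occ_safe[:, None]
        if self.pin_means:
            means = np.zeros((K, C))
        covs = np.empty((K, C, C))
        for k in range(K):
            xc = x - means[k]
            covs[k] = (xc * gamma[:, k : k + 1]).T @ xc / occ_safe[k]
        # empty-state collapse: reinitialize from a random data segment
        for k in collapsed:
            logger.warning("state %d collapsed; reinitializing from data segment", k)
            seg = self.arrays[rng.integers(len(self.arrays))]
            mu, cov = _random_segment_stats(seg, rng, max(10 * C, 50))
            if not self.pin_means:
                means[k] = mu
            covs[k] = cov
        covs = _regularized(covs, self.covariance_reg)
        if stay_prior > 0:  # MAP with a sticky Dirichlet transition prior
            xi_sum = xi_sum + stay_prior * np.eye(K)
        A = xi_sum / np.maximum(xi_sum.sum(axis=1, keepdims=True), 1e-300)
        pi = first_rows.mean(axis=0)
        pi = pi / pi.sum()
        return HMMParams(means, covs, A, pi)

    def _initial_params(self, rng) -> HMMParams:
        T = len(self._x)
        gamma = rng.dirichlet(np.ones(self.n_states), size=T)
        xi_sum = gamma[:-1].T @ gamma[1:]
        first = gamma[[0]]
        return self._m_step(gamma, xi_sum, first, rng)

    # -- fitting ------------------------------------------------------------

    def fit(
        self,
        n_iter: int = 200,
        tol: float = 1e-6,
        seed: int | None = 0,
        algorithm: str = "em",
        initial_params: HMMParams | None = None,
        stay_prior: float = 0.0,
        verbose: bool = False,
    ) -> "HMMResults":
        """Alternate exact E-steps with closed-form M-steps.

        Stops when the relative change of the objective falls below
        ``tol`` or after ``n_iter`` iterations.  With ``algorithm="em"``
        the objective (negative log evidence) is non-increasing; with
        ``algorithm="vb"`` it is the negative ELBO under conjugate
        priors.

        ``stay_prior`` adds Dirichlet pseudo-counts to the diagonal of
        the transition matrix (MAP M-step), expressing a prior belief in
        temporally persistent states; useful to suppress spurious
        few-sample state visits, e.g. at burst boundaries where
        time-delay-embedded windows mix regimes.  With a nonzero prior
        the reported objective is the data term of a penalized
        likelihood, so strict monotonicity is no longer guaranteed.
        """
        if algorithm not in ("em", "vb"):
            raise ValueError("algorithm must be 'em' or 'vb'")
        rng = np.random.default_rng(seed)
        if algorithm == "vb":
            return self._fit_vb(n_iter, tol, rng, verbose)
        params = initial_params or self._initial_params(rng)
        trace = []
        posterior = forward_backward(params, self.arrays)
        trace.append(posterior.free_energy)
        for it in range(n_iter):
            gsplit = posterior.split_gamma()
            first_rows = np.stack([g[0] for g in gsplit])
            xi_sum = posterior.xi.sum(axis=0)
            params = self._m_step(
                posterior.gamma, xi_sum, first_rows, rng, stay_prior=stay_prior
            )
            posterior = forward_backward(params, self.arrays)
            trace.append(posterior.free_energy)
            if verbose:
                logger.info("iter %d free energy %.6f", it, trace[-1])
            if abs(trace[-2] - trace[-1]) < tol * abs(trace[-2]):
                break
        return HMMResults(self, params, posterior, np.array(trace), algorithm="em")

    # -- variational Bayes ----------------------------------------------------

    def _fit_vb(self, n_iter, tol, rng, verbose) -> "HMMResults":
        """VB-EM with Dirichlet priors on transition/initial rows and a
        Gaussian-Wishart prior on each state's (mean, precision)."""
        x = self._x
        T, C = x.shape
        K = self.n_states
        # priors
        a0 = 1.0  # Dirichlet concentration
        beta0 = 1e-3
        nu0 = C + 2.0
        m0 = np.zeros(C)
        W0_inv = np.eye(C) * np.var(x, axis=0).mean() * nu0
        W0 = np.linalg.inv(W0_inv)

        # init from a short ML fit
        init = self.fit(n_iter=5, seed=rng.integers(2**31), algorithm="em")
        gamma = init.posterior.gamma
        xi_sum = init.posterior.xi.sum(axis=0)
        first = np.stack([g[0] for g in init.posterior.split_gamma()])

        trace = []
        posterior = None
        for it in range(n_iter):
            # ---- variational M-step
            Nk = gamma.sum(axis=0)
            xbar = (gamma.T @ x) / np.maximum(Nk, 1e-300)[:, None]
            a_A = a0 + xi_sum
            a_pi = a0 + first.sum(axis=0)
            beta_k = beta0 + Nk
            nu_k = nu0 + Nk
            m_k = (beta0 * m0 + Nk[:, None] * xbar) / beta_k[:, None]
            if self.pin_means:
                m_k = np.zeros((K, C))
            W_k_inv = np.empty((K, C, C))
            for k in range(K):
                xc = x - xbar[k]
                Sk = (xc * gamma[:, k : k + 1]).T @ xc
                dm = (xbar[k] - m0)[:, None]
                W_k_inv[k] = W0_inv + Sk + (beta0 * Nk[k] / beta_k[k]) * (dm @ dm.T)

            # ---- variational E-step quantities
            ElogA = digamma(a_A) - digamma(a_A.sum(axis=1, keepdims=True))
            Elogpi = digamma(a_pi) - digamma(a_pi.sum())
            logB = np.empty((T, K))
            Elogdet = np.empty(K)
            for k in range(K):
                L = np.linalg.cholesky(W_k_inv[k])
                logdet_Winv = 2 * np.log(np.diag(L)).sum()
                Elogdet[k] = (
                    digamma((nu_k[k] - np.arange(C)) / 2).sum()
                    + C * np.log(2)
                    - logdet_Winv
                )
                z = solve_triangular(L, (x - m_k[k]).T, lower=True)
                quad = nu_k[k] * (z**2).sum(axis=0)
                logB[:, k] = 0.5 * (
                    Elogdet[k] - C / beta_k[k] - quad - C * np.log(2 * np.pi)
                )
            A_tilde = np.exp(ElogA)
            pi_tilde = np.exp(Elogpi)
            gammas, xis, logZ = [], [], 0.0
            start = 0
            first_rows = []
            for arr in self.arrays:
                n = len(arr)
                lb = logB[start : start + n]
                rowmax = lb.max(axis=1)
                B = np.exp(lb - rowmax[:, None])
                g, xi, logc = _fb_kernel(B, A_tilde, pi_tilde / pi_tilde.sum())
                # correct for using a normalized pi_tilde inside the kernel
                logZ += logc + rowmax.sum() + np.log(pi_tilde.sum())
                gammas.append(g)
                xis.append(xi)
                first_rows.append(g[0])
                start += n
            gamma = np.concatenate(gammas)
            xi_sum = np.sum([xi.sum(axis=0) for xi in xis], axis=0)
            first = np.stack(first_rows)

            # ---- ELBO = log Z~ - KL(q||p) for A, pi and Gaussian-Wishart
            kl = _kl_dirichlet_rows(a_A, a0) + _kl_dirichlet_rows(a_pi[None], a0)
            for k in range(K):
                kl += _kl_gauss_wishart(
                    m_k[k], beta_k[k], W_k_inv[k], nu_k[k], m0, beta0, W0_inv, nu0
                )
            elbo = logZ - kl
            trace.append(-elbo)
            if verbose:
                logger.info("VB iter %d free energy %.6f", it, trace[-1])
            if it > 0 and abs(trace[-2] - trace[-1]) < tol * abs(trace[-2]):
                break

        # posterior-expected parameters for reporting
        covs = np.empty((K, C, C))
        for k in range(K):
            covs[k] = W_k_inv[k] / (nu_k[k] - C - 1)
        covs = _regularized(covs, self.covariance_reg)
        A = a_A / a_A.sum(axis=1, keepdims=True)
        pi = a_pi / a_pi.sum()
        params = HMMParams(m_k, covs, A, pi)
        xi_full = (
            np.concatenate(xis, axis=0) if xis and xis[0].size else np.empty((0, K, K))
        )
        posterior = Posterior(
            gamma=gamma,
            xi=xi_full,
            log_evidence=elbo,
            free_energy=-elbo,
            segment_lengths=[len(a) for a in self.arrays],
        )
        return HMMResults(self, params, posterior, np.array(trace), algorithm="vb")


def _kl_dirichlet_rows(a: np.ndarray, a0: float) -> float:
    """Sum of KL(Dir(a_row) || Dir(a0 * ones)) over rows."""
    a = np.atleast_2d(a)
    K = a.shape[1]
    ahat = a.sum(axis=1)
    kl = (
        gammaln(ahat)
        - gammaln(a).sum(axis=1)
        - gammaln(K * a0)
        + K * gammaln(a0)
        + ((a - a0) * (digamma(a) - digamma(ahat)[:, None])).sum(axis=1)
    )
    return float(kl.sum())


def _kl_gauss_wishart(m, beta, W_inv, nu, m0, beta0, W0_inv, nu0) -> float:
    """KL( N(m, (beta Lam)^-1) W(W, nu) || N(m0, (beta0 Lam)^-1) W(W0, nu0) )."""
    C = len(m)
    L = np.linalg.cholesky(W_inv)
    logdet_Winv = 2 * np.log(np.diag(L)).sum()
    L0 = np.linalg.cholesky(W0_inv)
    logdet_W0inv = 2 * np.log(np.diag(L0)).sum()
    Elogdet = digamma((nu - np.arange(C)) / 2).sum() + C * np.log(2) - logdet_Winv
    W = np.linalg.inv(W_inv)
    # Gaussian part: E_q(Lam)[ KL(N(m, (beta Lam)^-1) || N(m0, (beta0 Lam)^-1)) ]
    dm = m - m0
    kl_gauss = 0.5 * (
        C * np.log(beta / beta0)
        + C * (beta0 / beta - 1)
        + beta0 * nu * dm @ W @ dm
    )
    # Wishart part
    def log_B(logdet_w_inv, nu_):
        return -0.5 * nu_ * (-logdet_w_inv) - 0.5 * nu_ * C * np.log(2) - (
            C * (C - 1) / 4
        ) * np.log(np.pi) - gammaln((nu_ - np.arange(C)) / 2).sum()

    kl_wish = (
        log_B(logdet_Winv, nu)
        - log_B(logdet_W0inv, nu0)
        + 0.5 * (nu - nu0) * Elogdet
        + 0.5 * nu * (np.trace(W0_inv @ W) - C)
    )
    return float(kl_gauss + kl_wish)


# ---------------------------------------------------------------------------
# results


class HMMResults:
    """Fitted HMM: parameters, posteriors, diagnostics."""

    def __init__(self, model, params, posterior, free_energy_trace, algorithm):
        self.model = model
        self.params: HMMParams = params
        self.posterior: Posterior = posterior
        self.free_energy_trace = free_energy_trace
        self.algorithm = algorithm
        self._paths = None

    @property
    def free_energy(self) -> float:
        return self.posterior.free_energy

    @property
    def n_states(self) -> int:
        return self.params.n_states

    def state_probabilities(self) -> list[np.ndarray]:
        """Per-subject (T_s, K) posterior state probabilities."""
        return self.posterior.split_gamma()

    def viterbi(self) -> list[np.ndarray]:
        if self._paths is None:
            self._paths = viterbi(self.params, self.model.arrays)
        return self._paths

    def dual_estimate(self, source_data: TimeSeriesSet, use_gamma: bool = True) -> dict:
        prepared = self.model.data if isinstance(self.model.data, PreparedData) else None
        courses = self.state_probabilities() if use_gamma else self.viterbi()
        return dual_estimate(
            courses, source_data, prepared=prepared, n_states=self.n_states
        )

    def fractional_occupancies(self) -> np.ndarray:
        return self.posterior.gamma.mean(axis=0)

    def plot_free_energy(self, ax=None):
        from .plotting import plot_free_energy_trace

        return plot_free_energy_trace(self, ax=ax)

    def plot_state_probabilities(self, subject: int = 0, t_max: int = 2000, ax=None):
        from .plotting import plot_state_probabilities

        return plot_state_probabilities(self, subject=subject, t_max=t_max, ax=ax)

    def summary(self) -> str:
        lines = [
            "Gaussian hidden Markov model",
            "=" * 46,
            f"states:             {self.n_states}",
            f"channels:           {self.model.n_channels}",
            f"subjects:           {len(self.model.arrays)}",
            f"samples:            {sum(len(a) for a in self.model.arrays)}",
            f"algorithm:          {self.algorithm}",
            f"means pinned:       {self.model.pin_means}",
            f"free energy:        {self.free_energy:.4f}",
            f"iterations:         {len(self.free_energy_trace)}",
            "",
            "state  frac. occupancy  stay prob.",
        ]
        fo = self.fractional_occupancies()
        stay = self.params.stay_probabilities()
        for k in range(self.n_states):
            lines.append(f"{k:>5}  {fo[k]:>15.4f}  {stay[k]:>10.4f}")
        return "\n".join(lines)

    def save(self, directory) -> None:
        """Archive: JSON metadata + binary arrays."""
        import json
        from pathlib import Path

        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        np.savez(
            d / "model.npz",
            means=self.params.means,
            covariances=self.params.covariances,
            transition_matrix=self.params.transition_matrix,
            initial_distribution=self.params.initial_distribution,
            gamma=self.posterior.gamma,
            free_energy_trace=self.free_energy_trace,
        )
        meta = {
            "model": "hmm",
            "n_states": self.n_states,
            "algorithm": self.algorithm,
            "free_energy": self.free_energy,
            "pin_means": self.model.pin_means,
            "segment_lengths": self.posterior.segment_lengths,
        }
        (d / "model.json").write_text(json.dumps(meta, indent=2))
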