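"""Soft mode mixtures with a learned causal sequence prior.

The generative model relaxes the HMM's mutually exclusive states: at
every sample the observation distribution is a *convex mixture* of J
mode means and covariances,

    x_t ~ N( sum_j alpha_jt mu_j ,  sum_j alpha_jt D_j ),
    alpha_t = softmax(theta_t),

with the latent logits theta_t given a strictly causal Gaussian prior
p(theta_t | theta_{1:t-1}) = N(m_theta_t, sigma_theta_t^2) whose mean and
variance are a learned function of the past.  Here that causal map is a
single-layer linear recurrence per mode, m_theta_t = a * theta_{t-1} + b
with learned variance — the minimal parameterization of the contract —
and the variational posterior over the logits is a free-form factorized
Gaussian q(theta_t) = N(m_t, diag(s_t^2)), one per sample, optimized
jointly with the mode parameters by stochastic gradient ascent on the
evidence lower bound (reparameterized sampling, one draw per step,
hand-derived analytic gradients, Adam updates).  KL annealing (the KL
term is ramped in linearly over the first part of training) guards
against posterior collapse.

``DyNeMo(data, n_modes).fit()`` returns a :class:`DyNeMoResults` with
the mode parameters, the inferred mixing time course, its trace-
renormalized version and a two-component-GMM binarizer.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .data import PreparedData, TimeSeriesSet

__all__ = [
    "DyNeMoParams",
    "MixingTimeCourse",
    "DyNeMo",
    "DyNeMoResults",
    "softmax_mixing",
    "mix_parameters",
    "renormalize_mixing",
    "binarize_mixing",
]

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# elementary operations


def softmax_mixing(logits: np.ndarray) -> np.ndarray:
    """Row-wise softmax; invariant to additive constants per row."""
    logits = np.asarray(logits, dtype=float)
    if not np.isfinite(logits).all():
        raise ValueError("logits must be finite")
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def mix_parameters(
    alpha: np.ndarray, mode_means: np.ndarray, mode_covariances: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Instantaneous (m_t, C_t) = (sum_j a_jt mu_j, sum_j a_jt D_j)."""
    alpha = np.atleast_2d(alpha)
    if alpha.shape[1] != mode_means.shape[0]:
        raise ValueError("alpha and mode parameters disagree on the mode count")
    m = alpha @ mode_means
    C = np.einsum("tj,jcd->tcd", alpha, mode_covariances)
    return m, C


def renormalize_mixing(alpha: np.ndarray, mode_covariances: np.ndarray) -> np.ndarray:
    """Reweight mixing coefficients by each mode covariance's trace.

    alpha~_jt = alpha_jt tr(D_j) / sum_k alpha_kt tr(D_k); rows stay on
    the simplex.  This makes mode contributions to the instantaneous
    covariance comparable across modes of different overall variance.
    """
    alpha = np.atleast_2d(alpha)
    traces = np.trace(mode_covariances, axis1=-2, axis2=-1)
    if (traces <= 0).any():
        raise ValueError("mode covariance traces must be positive")
    w = alpha * traces
    return w / w.sum(axis=1, keepdims=True)


def binarize_mixing(values: np.ndarray, seed: int = 0) -> tuple[np.ndarray, float]:
    """On/off series from one mode's (renormalized) mixing coefficients.

    Fits a two-component univariate Gaussian mixture; the higher-mean
    component is "on".  Returns (boolean series, threshold).  Degenerate
    (effectively unimodal) inputs warn and return all-off.
    """
    from sklearn.mixture import GaussianMixture

    values = np.asarray(values, dtype=float).ravel()
    rng_range = values.max() - values.min()
    if rng_range <= 1e-12:
        warnings.warn("constant mixing series; returning all-off")
        return np.zeros(len(values), dtype=bool), np.inf
    gmm = GaussianMixture(n_components=2, random_state=seed, n_init=3)
    gmm.fit(values[:, None])
    means = gmm.means_.ravel()
    sds = np.sqrt(gmm.covariances_.ravel())
    hi, lo = np.argmax(means), np.argmin(means)
    separation = (means[hi] - means[lo]) / max(sds.mean(), 1e-12)
    if separation < 1.0:
        warnings.warn("mixing distribution looks unimodal; returning all-off")
        return np.zeros(len(values), dtype=bool), np.inf
    on = gmm.predict(values[:, None]) == hi
    if on.any() and (~on).any():
        threshold = 0.5 * (values[on].min() + values[~on].max())
    else:
        threshold = means.mean()
    return on, float(threshold)


# ---------------------------------------------------------------------------
# containers


@dataclass
class DyNeMoParams:
    """Mode means/covariances plus the learned sequence-prior parameters."""

    mode_means: np.ndarray  # (J, C)
    mode_covariances: np.ndarray  # (J, C, C)
    prior_decay: np.ndarray | None = None  # (J,) recurrence coefficient a
    prior_bias: np.ndarray | None = None  # (J,) recurrence bias b
    prior_sd: np.ndarray | None = None  # (J,) innovation sd

    @property
    def n_modes(self) -> int:
        return self.mode_means.shape[0]

    @property
    def n_channels(self) -> int:
        return self.mode_means.shape[1]


@dataclass
class MixingTimeCourse:
    """Posterior-mean logits and the derived mixing coefficients."""

    logits: np.ndarray  # (T, J)
    alpha: np.ndarray  # (T, J), softmax of logits
    renormalized_alpha: np.ndarray  # (T, J), trace-renormalized

    def __post_init__(self):
        for a in (self.alpha, self.renormalized_alpha):
            if not np.allclose(a.sum(axis=1), 1.0, atol=1e-8):
                raise ValueError("mixing coefficient rows must sum to 1")


# ---------------------------------------------------------------------------
# model


def _chol_params(covs: np.ndarray) -> np.ndarray:
    """Raw parameterization of SPD matrices: lower triangle with the
    diagonal stored in log space."""
    L = np.linalg.cholesky(covs)
    raw = np.tril(L, -1)
    idx = np.arange(L.shape[-1])
    raw[:, idx, idx] = np.log(L[:, idx, idx])
    return raw


def _chol_from_params(raw: np.ndarray) -> np.ndarray:
    L = np.tril(raw, -1)
    idx = np.arange(raw.shape[-1])
    L[:, idx, idx] = np.exp(raw[:, idx, idx])
    return L


class _Adam:
    def __init__(self, shapes, lr):
        self.lr = lr
        self.m = [np.zeros(s) for s in shapes]
        self.v = [np.zeros(s) for s in shapes]
        self.t = 0

    def step(self, params, grads):
        self.t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        out = []
        for i, (p, g) in enumerate(zip(params, grads)):
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g**2
            mhat = self.m[i] / (1 - b1**self.t)
            vhat = self.v[i] / (1 - b2**self.t)
            out.append(p + self.lr * mhat / (np.sqrt(vhat) + eps))
        return out


class DyNeMo:
    """Soft-mixture latent dynamics model (maximizes the ELBO).

    Parameters
    ----------
    data : TimeSeriesSet, PreparedData, ndarray or list of ndarray
        Per-subject (T, C) matrices.  The sequence prior restarts at
        subject boundaries.
    n_modes : int
        Number of modes J.
    pin_means : bool or None
        Fix mode means at zero; ``None`` resolves from the preparation
        record (on for time-delay embedded data).
    """

    def __init__(
        self,
        data,
        n_modes: int,
        pin_means: bool | None = None,
        covariance_reg: float = 1e-6,
    ):
        from .hmm import _segments

        if n_modes < 1:
            raise ValueError("n_modes must be >= 1")
        arrays, container = _segments(data)
        self.arrays = [np.asarray(a, dtype=float) for a in arrays]
        self.data = data if container is not None else None
        self.n_modes = n_modes
        self.n_channels = self.arrays[0].shape[1]
        self.covariance_reg = covariance_reg
        self.sampling_frequency = getattr(data, "sampling_frequency", None)
        if pin_means is None:
            steps = getattr(data, "record", {}).get("steps", [])
            pin_means = any(s.get("step") == "tde" for s in steps)
        self.pin_means = bool(pin_means)
        self._x = np.concatenate(self.arrays, axis=0)
        self._seg_starts = np.cumsum([0] + [len(a) for a in self.arrays])[:-1]

    # -- initialization -------------------------------------------------------

    def _init_covs(self, rng) -> np.ndarray:
        """Covariances of J disjoint random contiguous windows of the data."""
        x = self._x
        T, C = x.shape
        J = self.n_modes
        win = max(min(T // max(J, 1), 2000), 5 * C)
        covs = np.empty((J, C, C))
        starts = rng.permutation(max(T - win, 1))[:J]
        for j in range(J):
            seg = x[starts[j % len(starts)] : starts[j % len(starts)] + win]
            covs[j] = np.cov(seg.T, bias=True).reshape(C, C)
            covs[j] += (0.01 + 1e-6) * np.trace(covs[j]) / C * np.eye(C)
            # small random SPD perturbation to break symmetry between modes
            w = rng.standard_normal((C, 2 * C)) / np.sqrt(2 * C)
            covs[j] = 0.9 * covs[j] + 0.1 * np.trace(covs[j]) / C * (w @ w.T)
        return covs

    # -- training -------------------------------------------------------------

    def _encoder_features(self, scales) -> np.ndarray:
        """Amortization features: moving-average local second moments.

        For every channel pair (i <= j) and every smoothing scale, the
        centred moving average of x_i x_j over that scale, computed per
        subject (no bleed across boundaries) and z-scored.  These are the
        sufficient-statistic analogues the encoder reads the mixing
        ratio from.
        """
        from scipy.ndimage import uniform_filter1d

        C = self.n_channels
        iu = np.triu_indices(C)
        feats = []
        for arr in self.arrays:
            prod = arr[:, iu[0]] * arr[:, iu[1]]  # (T_s, n_pairs)
            feats.append(
                np.concatenate(
                    [
                        uniform_filter1d(prod, size=int(w), axis=0, mode="nearest")
                        for w in scales
                    ],
                    axis=1,
                )
            )
        Z = np.concatenate(feats, axis=0)
        Z -= Z.mean(axis=0)
        sd = Z.std(axis=0)
        sd[sd == 0] = 1.0
        return Z / sd

    def fit(
        self,
        n_iter: int = 500,
        learning_rate: float = 0.03,
        seed: int | None = 0,
        kl_annealing_frac: float = 0.4,
        init: str = "hmm",
        feature_scales: tuple[int, ...] = (10, 50, 200),
        covariance_prior_strength: float = 0.05,
        verbose: bool = False,
    ) -> "DyNeMoResults":
        """Maximize the ELBO: expected mixture log likelihood minus the KL
        between the amortized posterior over the logits and the learned
        causal prior.  Deterministic given ``seed``.

        The posterior is amortized: the logit means are a learned linear
        read-out of multi-scale local covariance features of the data
        (``feature_scales``, in samples), with one posterior sd per
        mode.  Sharing the encoder across all samples regularizes the
        mixing time course — per-sample free logits could trivially
        overfit the likelihood.  ``init="hmm"`` (default) anchors the
        mode covariances and the encoder with a short HMM fit (hard
        clustering is a standard initializer for mixture models and
        resolves the basis degeneracy of convex mixtures);
        ``init="random"`` starts from random data-window covariances.
        The learning rate decays linearly to 10% of its initial value.

        A convex mixture has a scale degeneracy: inflating the mode
        covariances while pulling the mixing coefficients toward the
        simplex interior leaves the likelihood unchanged.  A weak
        inverse-Wishart prior on each mode covariance, centred on the
        global data covariance with ``covariance_prior_strength * T``
        pseudo-samples, selects the minimal basis — mode covariances as
        close to the data as possible, mixing coefficients reaching the
        simplex vertices when the data are truly single-mode.
        """
        rng = np.random.default_rng(seed)
        x = self._x
        T, C = x.shape
        J = self.n_modes
        Z = self._encoder_features(feature_scales)
        F = Z.shape[1]

        # parameters: encoder (W, c), posterior sd log_s (per mode),
        # observation (mu, Lraw), prior (a_raw, b, log_sp, log_s0)
        W = np.zeros((J, F))
        c = np.zeros(J)
        mu = np.zeros((J, C)) if self.pin_means else np.tile(x.mean(axis=0), (J, 1))
        if init == "hmm" and J > 1:
            from .hmm import GaussianHMM

            hmm_fit = GaussianHMM(self.arrays, J, pin_means=self.pin_means).fit(
                n_iter=15, seed=None if seed is None else seed + 101
            )
            gamma = np.clip(hmm_fit.posterior.gamma, 1e-3, None)
            target = np.log(gamma)
            target -= target.mean(axis=1, keepdims=True)
            # ridge least-squares fit of the encoder to the HMM logits
            lam = 1e-3 * T
            A_ = Z.T @ Z + lam * np.eye(F)
            W = np.linalg.solve(A_, Z.T @ target).T
            c = target.mean(axis=0) - W @ Z.mean(axis=0)
            if not self.pin_means:
                mu = hmm_fit.params.means.copy()
            Lraw = _chol_params(hmm_fit.params.covariances)
        elif init == "random" or J == 1:
            Lraw = _chol_params(self._init_covs(rng))
        else:
            raise ValueError("init must be 'hmm' or 'random'")
        log_s = np.full(J, np.log(0.5))
        a_raw = np.full(J, 4.0)  # sigmoid(4) ~ 0.98
        b = np.zeros(J)
        log_sp = np.full(J, np.log(0.2))
        log_s0 = np.full(J, 0.0)

        params = [W, c, log_s, mu, Lraw, a_raw, b, log_sp, log_s0]
        opt = _Adam([p.shape for p in params], learning_rate)
        seg_mask = np.zeros(T, dtype=bool)
        seg_mask[self._seg_starts] = True
        inner = ~seg_mask  # samples whose prior chains from t-1
        prev_idx = np.flatnonzero(inner) - 1

        trace = np.empty(n_iter)
        anneal_iters = max(int(n_iter * kl_annealing_frac), 1)
        eyeC = np.eye(C)
        n0 = covariance_prior_strength * T  # pseudo-samples of the IW prior
        S_bar = (x.T @ x) / T if self.pin_means else np.cov(x.T, bias=True)

        for it in range(n_iter):
            W, c, log_s, mu, Lraw, a_raw, b, log_sp, log_s0 = params
            a = 1.0 / (1.0 + np.exp(-a_raw))
            m = Z @ W.T + c
            s = np.exp(log_s)[None, :]
            eps = rng.standard_normal((T, J))
            theta = m + s * eps
            alpha = softmax_mixing(theta)

            L = _chol_from_params(Lraw)
            D = L @ np.swapaxes(L, 1, 2)
            Ct = np.einsum("tj,jcd->tcd", alpha, D)
            P = np.linalg.inv(Ct)
            sign, logdet = np.linalg.slogdet(Ct)
            r = x - alpha @ mu
            q = np.einsum("tcd,td->tc", P, r)
            ll = -0.5 * (C * np.log(2 * np.pi) + logdet + np.einsum("tc,tc->t", r, q))

            # gradients of the likelihood
            g_alpha = (
                np.einsum("jc,tc->tj", mu, q)
                - 0.5 * np.einsum("tcd,jdc->tj", P, D)
                + 0.5 * np.einsum("tc,jcd,td->tj", q, D, q)
            )
            g_theta = alpha * (g_alpha - (g_alpha * alpha).sum(axis=1, keepdims=True))
            g_mu = (
                np.zeros_like(mu)
                if self.pin_means
                else np.einsum("tj,tc->jc", alpha, q)
            )
            G = 0.5 * (np.einsum("tc,td->tcd", q, q) - P)
            g_D = np.einsum("tj,tcd->jcd", alpha, G)
            if n0 > 0:  # inverse-Wishart shrinkage toward the data covariance
                Dinv = np.linalg.inv(D)
                g_D -= 0.5 * n0 * (Dinv - Dinv @ S_bar @ Dinv)
            g_L = 2.0 * g_D @ L
            g_Lraw = np.tril(g_L)
            idx = np.arange(C)
            g_Lraw[:, idx, idx] = g_L[:, idx, idx] * L[:, idx, idx]

            # KL(q || prior) and its gradients
            sp2 = np.exp(2 * log_sp)
            s0_2 = np.exp(2 * log_s0)
            pm = np.zeros((T, J))
            pv = np.empty((T, J))
            pm[inner] = a * m[prev_idx] + b
            pv[inner] = sp2
            pv[seg_mask] = s0_2
            diff = m - pm
            s2 = s**2
            kl = 0.5 * (np.log(pv) - 2 * log_s[None, :] + (s2 + diff**2) / pv - 1.0)
            kl_total = kl.sum()

            g_m_kl = diff / pv
            np.add.at(g_m_kl, prev_idx, -(a * diff[inner] / pv[inner]))
            g_logs_kl = (s2 / pv - 1.0).sum(axis=0)
            g_a = -np.einsum("tj,tj->j", diff[inner] / pv[inner], m[prev_idx])
            g_b = -(diff[inner] / pv[inner]).sum(axis=0)
            var_term = 1.0 - (s2 + diff**2) / pv
            g_logsp = var_term[inner].sum(axis=0)
            g_logs0 = var_term[seg_mask].sum(axis=0)

            kappa = min(1.0, (it + 1) / anneal_iters)
            elbo = ll.sum() - kappa * kl_total
            if not np.isfinite(elbo):
                raise FloatingPointError(
                    f"training diverged at iteration {it}: non-finite loss "
                    f"(ll={ll.sum():.3g}, kl={kl_total:.3g}); "
                    "lower the learning rate"
                )
            trace[it] = -elbo

            g_m = g_theta - kappa * g_m_kl
            g_W = g_m.T @ Z
            g_c = g_m.sum(axis=0)
            g_log_s = (g_theta * s * eps).sum(axis=0) - kappa * g_logs_kl
            grads = [
                g_W,
                g_c,
                g_log_s,
                g_mu,
                g_Lraw,
                -kappa * g_a * a * (1.0 - a),  # chain through the sigmoid
                -kappa * g_b,
                -kappa * g_logsp,
                -kappa * g_logs0,
            ]
            opt.lr = learning_rate * (1.0 - 0.9 * it / max(n_iter - 1, 1))
            params = opt.step(params, grads)
            if verbose and it % 50 == 0:
                logger.info("iter %d loss %.2f", it, trace[it])

        W, c, log_s, mu, Lraw, a_raw, b, log_sp, log_s0 = params
        a = 1.0 / (1.0 + np.exp(-a_raw))
        m = Z @ W.T + c
        L = _chol_from_params(Lraw)
        D = L @ np.swapaxes(L, 1, 2)
        D += (
            self.covariance_reg
            * np.trace(D, axis1=1, axis2=2)[:, None, None]
            / C
            * eyeC
        )
        fitted = DyNeMoParams(
            mode_means=mu,
            mode_covariances=D,
            prior_decay=a,
            prior_bias=b,
            prior_sd=np.exp(log_sp),
        )
        # deterministic free energy for run ranking: posterior-mean plug-in
        # likelihood minus the exact KL term
        alpha_hat = softmax_mixing(m)
        _, Ct = mix_parameters(alpha_hat, mu, D)
        sign, logdet = np.linalg.slogdet(Ct)
        r = x - alpha_hat @ mu
        q = np.einsum("tcd,td->tc", np.linalg.inv(Ct), r)
        ll_det = -0.5 * (C * np.log(2 * np.pi) + logdet + np.einsum("tc,tc->t", r, q))
        s = np.exp(log_s)[None, :]
        pm = np.zeros((T, J))
        pv = np.empty((T, J))
        pm[inner] = a * m[prev_idx] + b
        pv[inner] = np.exp(2 * log_sp)
        pv[seg_mask] = np.exp(2 * log_s0)
        kl = 0.5 * (np.log(pv) - 2 * log_s[None, :] + (s**2 + (m - pm) ** 2) / pv - 1.0)
        free_energy = float(-(ll_det.sum() - kl.sum()))

        course = MixingTimeCourse(
            logits=m,
            alpha=alpha_hat,
            renormalized_alpha=renormalize_mixing(alpha_hat, D),
        )
        return DyNeMoResults(self, fitted, course, trace, free_energy)


# ---------------------------------------------------------------------------
# results


class DyNeMoResults:
    """Fitted soft-mixture model: parameters, mixing time course, loss."""

    def __init__(self, model, params, mixing, loss_trace, free_energy):
        self.model = model
        self.params: DyNeMoParams = params
        self.mixing: MixingTimeCourse = mixing
        self.loss_trace = loss_trace
        self.free_energy = float(free_energy)

    @property
    def n_modes(self) -> int:
        return self.params.n_modes

    @property
    def alpha(self) -> np.ndarray:
        return self.mixing.alpha

    @property
    def renormalized_alpha(self) -> np.ndarray:
        return self.mixing.renormalized_alpha

    def split_alpha(self, renormalized: bool = False) -> list[np.ndarray]:
        """Per-subject mixing coefficient series."""
        al = self.renormalized_alpha if renormalized else self.alpha
        out, start = [], 0
        for arr in self.model.arrays:
            out.append(al[start : start + len(arr)])
            start += len(arr)
        return out

    def binarize(self, seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
        """Per-mode on/off series from the renormalized mixing coefficients
        via a two-component GMM.  Returns (on (T, J) bool, thresholds (J,))."""
        T, J = self.renormalized_alpha.shape
        on = np.zeros((T, J), dtype=bool)
        thresholds = np.empty(J)
        for j in range(J):
            on[:, j], thresholds[j] = binarize_mixing(
                self.renormalized_alpha[:, j], seed=seed
            )
        return on, thresholds

    def plot_loss(self, ax=None):
        from .plotting import plot_free_energy_trace

        return plot_free_energy_trace(self, ax=ax)

    def plot_mixing(self, renormalized: bool = True, t_max: int = 2000, ax=None):
        from .plotting import plot_mixing

        return plot_mixing(self, renormalized=renormalized, t_max=t_max, ax=ax)

    def summary(self) -> str:
        ra = self.renormalized_alpha
        lines = [
            "Dynamic mode mixture model",
            "=" * 46,
            f"modes:              {self.n_modes}",
            f"channels:           {self.model.n_channels}",
            f"samples:            {len(self.alpha)}",
            f"means pinned:       {self.model.pin_means}",
            f"free energy:        {self.free_energy:.4f}",
            f"iterations:         {len(self.loss_trace)}",
            "",
            "mode   mean alpha~   sd alpha~   cov trace",
        ]
        traces = np.trace(self.params.mode_covariances, axis1=1, axis2=2)
        for j in range(self.n_modes):
            lines.append(
                f"{j:>4}  {ra[:, j].mean():>11.4f}  {ra[:, j].std():>9.4f}"
                f"  {traces[j]:>9.4f}"
            )
        return "\n".join(lines)

    def save(self, directory) -> None:
        import json
        from pathlib import Path

        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        np.savez(
            d / "model.npz",
            mode_means=self.params.mode_means,
            mode_covariances=self.params.mode_covariances,
            logits=self.mixing.logits,
            alpha=self.alpha,
            renormalized_alpha=self.renormalized_alpha,
            loss_trace=self.loss_trace,
        )
        meta = {
            "model": "dynemo",
            "n_modes": self.n_modes,
            "free_energy": self.free_energy,
            "pin_means": self.model.pin_means,
        }
        (d / "model.json").write_text(json.dumps(meta, indent=2))
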