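"""Post-hoc spectral estimation conditioned on latent time courses.

Once an HMM state time course (or a soft mode time course) has been
inferred, the spectral content of each state/mode is estimated from the
*source* data rather than the prepared training data:

* :func:`multitaper_state_spectra` — DPSS multitaper PSD and cross-PSD
  per subject/state, with windows weighted by the state probability
  (or hard-assigned from a Viterbi path).
* :func:`glm_mode_spectra` — for soft mixtures, regress the
  window-averaged mixing coefficients onto a sliding-window multitaper
  (cross-)spectrogram; a mode's spectrum is the regression intercept
  (mean spectrum) plus its coefficient, so a zero-effect mode equals the
  mean spectrum.
* :func:`coherence_from_cpsd`, :func:`nnmf_bands`, :func:`power_map`,
  :func:`aec`, :func:`static_spectra` — coherence networks, data-driven
  frequency bands by non-negative matrix factorization, band power maps,
  amplitude envelope correlation, and the static (single all-on state)
  versions of all of the above.

PSDs are one-sided densities: integrating over (0, Nyquist] recovers the
signal variance (Parseval).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.signal import windows as sp_windows

from .data import TimeSeriesSet

__all__ = [
    "SpectralEstimate",
    "multitaper_state_spectra",
    "glm_mode_spectra",
    "coherence_from_cpsd",
    "nnmf_bands",
    "power_map",
    "aec",
    "static_spectra",
]


@dataclass
class SpectralEstimate:
    """Subject x state(/mode) x channel(-pair) x frequency spectra.

    ``psd``: (S, K, C, F) real, non-negative.  ``cpsd``: (S, K, C, C, F)
    complex, conjugate-symmetric in the channel indices.  States flagged
    in ``missing`` had too little occupancy for a stable estimate and
    hold NaN.
    """

    frequencies: np.ndarray
    psd: np.ndarray
    cpsd: np.ndarray | None = None
    missing: np.ndarray | None = None  # (S, K) bool
    metadata: dict = field(default_factory=dict)

    def save(self, directory: str | Path) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        arrays = {"frequencies": self.frequencies, "psd": self.psd}
        if self.cpsd is not None:
            arrays["cpsd"] = self.cpsd
        if self.missing is not None:
            arrays["missing"] = self.missing
        np.savez(d / "spectra.npz", **arrays)
        (d / "spectra.json").write_text(json.dumps(self.metadata, indent=2))

    def plot(self, subject: int = 0, channel: int = 0, ax=None):
        from .plotting import plot_psd

        return plot_psd(self, subject=subject, channel=channel, ax=ax)

    @classmethod
    def load(cls, directory: str | Path) -> "SpectralEstimate":
        d = Path(directory)
        z = np.load(d / "spectra.npz")
        return cls(
            frequencies=z["frequencies"],
            psd=z["psd"],
            cpsd=z["cpsd"] if "cpsd" in z else None,
            missing=z["missing"] if "missing" in z else None,
            metadata=json.loads((d / "spectra.json").read_text()),
        )


# ---------------------------------------------------------------------------
# multitaper machinery


def _window_plan(T, fs, window_length, overlap):
    n_win = int(round(window_length * fs))
    step = max(int(round(n_win * (1 - overlap))), 1)
    starts = np.arange(0, T - n_win + 1, step)
    return n_win, starts


def _taper_ffts(x, starts, n_win, tapers):
    """(n_windows, n_tapers, C, F) tapered FFTs of windowed segments."""
    segs = np.stack([x[s : s + n_win] for s in starts])  # (W, n_win, C)
    segs = segs - segs.mean(axis=1, keepdims=True)
    # (W, K_tap, n_win, C) -> rfft over samples
    tapered = segs[:, None] * tapers[None, :, :, None]
    return np.fft.rfft(tapered, axis=2).transpose(0, 1, 3, 2)


def _window_weights(course, starts, n_win, n_states):
    course = np.asarray(course)
    if course.ndim == 1:  # hard path -> one-hot
        onehot = np.zeros((len(course), n_states))
        onehot[np.arange(len(course)), course.astype(int)] = 1.0
        course = onehot
    return np.stack(
        [course[s : s + n_win].mean(axis=0) for s in starts]
    )  # (W, K)


def multitaper_state_spectra(
    source_data: TimeSeriesSet,
    state_courses,
    sample_offsets=None,
    window_length: float = 2.0,
    time_half_bandwidth: float = 4.0,
    n_tapers: int = 7,
    overlap: float = 0.5,
    frequency_range: tuple[float, float] | None = None,
    min_weight_windows: float = 1.0,
) -> SpectralEstimate:
    """State-conditioned multitaper PSD and cross-PSD.

    Each window's contribution to state k is weighted by the mean state
    probability over the window (hard Viterbi assignment falls out when a
    path is passed), normalized by the total weight (state occupancy).
    States with total weight below ``min_weight_windows`` windows are
    flagged missing.

    ``state_courses``: per-subject (T', K) probabilities or (T',) paths,
    aligned to source samples starting at ``sample_offsets[s]`` (default
    0) — pass the time-delay-embedding trim when applicable.
    """
    fs = source_data.sampling_frequency
    if isinstance(state_courses, np.ndarray):
        state_courses = [state_courses]
    S = source_data.n_subjects
    if len(state_courses) != S:
        raise ValueError("need one state time course per subject")
    sc0 = np.asarray(state_courses[0])
    K = 1 if sc0.ndim == 1 else sc0.shape[1]
    if sc0.ndim == 1:
        K = int(max(np.asarray(c).max() for c in state_courses)) + 1
    if sample_offsets is None:
        sample_offsets = [0] * S
    C = source_data.n_channels
    n_win = int(round(window_length * fs))
    tapers = sp_windows.dpss(n_win, time_half_bandwidth, Kmax=n_tapers)
    tapers /= np.sqrt((tapers**2).sum(axis=1, keepdims=True))
    freqs = np.fft.rfftfreq(n_win, 1 / fs)

    psd = np.full((S, K, C, len(freqs)), np.nan)
    cpsd = np.full((S, K, C, C, len(freqs)), np.nan, dtype=complex)
    missing = np.zeros((S, K), dtype=bool)
    for s in range(S):
        x = source_data.arrays[s]
        off = sample_offsets[s]
        course = np.asarray(state_courses[s])
        x = x[off : off + len(course)]
        if len(x) != len(course):
            raise ValueError("state time course longer than available source samples")
        _, starts = _window_plan(len(x), fs, window_length, overlap)
        if len(starts) == 0:
            raise ValueError("recording shorter than one spectral window")
        Y = _taper_ffts(x, starts, n_win, tapers)  # (W, tap, C, F)
        # per-window cross-spectra averaged over tapers, scaled to density
        Xw = np.einsum("wkcf,wkdf->wcdf", Y, np.conj(Y)) * (2.0 / (fs * n_tapers))
        w = _window_weights(course, starts, n_win, K)  # (W, K)
        wsum = w.sum(axis=0)
        for k in range(K):
            if wsum[k] < min_weight_windows:
                missing[s, k] = True
                continue
            cp = np.einsum("w,wcdf->cdf", w[:, k], Xw) / wsum[k]
            cpsd[s, k] = cp
            psd[s, k] = np.real(np.einsum("ccf->cf", cp))
    if frequency_range is not None:
        sel = (freqs >= frequency_range[0]) & (freqs <= frequency_range[1])
        freqs, psd, cpsd = freqs[sel], psd[..., sel], cpsd[..., sel]
    return SpectralEstimate(
        frequencies=freqs,
        psd=psd,
        cpsd=cpsd,
        missing=missing,
        metadata={
            "estimator": "multitaper",
            "window_length_s": window_length,
            "time_half_bandwidth": time_half_bandwidth,
            "n_tapers": n_tapers,
            "overlap": overlap,
            "sampling_frequency": fs,
        },
    )


def static_spectra(ts: TimeSeriesSet, **kwargs) -> SpectralEstimate:
    """Multitaper spectra of the full recording (single all-on state)."""
    courses = [np.ones((n, 1)) for n in ts.n_samples]
    return multitaper_state_spectra(ts, courses, **kwargs)


# ---------------------------------------------------------------------------
# GLM mode spectra


def glm_mode_spectra(
    source_data: TimeSeriesSet,
    alphas,
    sample_offsets=None,
    window_length: float = 2.0,
    time_half_bandwidth: float = 4.0,
    n_tapers: int = 7,
    overlap: float = 0.5,
    frequency_range: tuple[float, float] | None = None,
) -> SpectralEstimate:
    """Mode-specific spectra by regression on a sliding-window spectrogram.

    Per subject: compute a multitaper (cross-)spectrogram; regress the
    window-averaged, demeaned mixing coefficients (plus an intercept)
    onto it at every frequency and channel pair.  The reported mode
    spectrum is ``intercept + coefficient``, so a mode uncorrelated with
    the spectrogram reduces to the mean spectrum.  With J = 1 (or
    degenerate designs) the intercept alone is reported.
    """
    fs = source_data.sampling_frequency
    if isinstance(alphas, np.ndarray):
        alphas = [alphas]
    S = source_data.n_subjects
    if sample_offsets is None:
        sample_offsets = [0] * S
    C = source_data.n_channels
    J = np.asarray(alphas[0]).shape[1]
    n_win = int(round(window_length * fs))
    tapers = sp_windows.dpss(n_win, time_half_bandwidth, Kmax=n_tapers)
    tapers /= np.sqrt((tapers**2).sum(axis=1, keepdims=True))
    freqs = np.fft.rfftfreq(n_win, 1 / fs)
    F = len(freqs)

    psd = np.full((S, J, C, F), np.nan)
    cpsd = np.full((S, J, C, C, F), np.nan, dtype=complex)
    for s in range(S):
        x = source_data.arrays[s]
        off = sample_offsets[s]
        alpha = np.asarray(alphas[s])
        x = x[off : off + len(alpha)]
        _, starts = _window_plan(len(x), fs, window_length, overlap)
        Y = _taper_ffts(x, starts, n_win, tapers)
        Xw = np.einsum("wkcf,wkdf->wcdf", Y, np.conj(Y)) * (2.0 / (fs * n_tapers))
        a_win = np.stack([alpha[w : w + n_win].mean(axis=0) for w in starts])  # (W,J)
        a_dm = a_win - a_win.mean(axis=0)
        keep = a_dm.std(axis=0) > 1e-12
        design = np.column_stack([a_dm[:, keep], np.ones(len(starts))])
        target = Xw.reshape(len(starts), -1)
        coef, *_ = np.linalg.lstsq(design, target, rcond=None)
        coef = coef.reshape(-1, C, C, F)
        intercept = coef[-1]
        betas = np.zeros((J, C, C, F), dtype=complex)
        betas[keep] = coef[:-1]
        if not keep.any():
            warnings.warn("degenerate mixing design; reporting intercept-only spectra")
        for j in range(J):
            cp = intercept + betas[j]
            cpsd[s, j] = cp
            psd[s, j] = np.maximum(np.real(np.einsum("ccf->cf", cp)), 0.0)
    if frequency_range is not None:
        sel = (freqs >= frequency_range[0]) & (freqs <= frequency_range[1])
        freqs, psd, cpsd = freqs[sel], psd[..., sel], cpsd[..., sel]
    return SpectralEstimate(
        frequencies=freqs,
        psd=psd,
        cpsd=cpsd,
        metadata={
            "estimator": "glm-multitaper",
            "window_length_s": window_length,
            "time_half_bandwidth": time_half_bandwidth,
            "n_tapers": n_tapers,
            "overlap": overlap,
            "sampling_frequency": fs,
            "convention": "mode spectrum = intercept + coefficient",
        },
    )


# ---------------------------------------------------------------------------
# derived network quantities


def coherence_from_cpsd(se: SpectralEstimate) -> np.ndarray:
    """Coherence |S_xy| / sqrt(S_xx S_yy) per subject/state/pair/frequency.

    Returns (S, K, C, C, F) in [0, 1]; entries with a vanishing
    auto-spectrum are NaN.
    """
    if se.cpsd is None:
        raise ValueError("SpectralEstimate has no cross-spectra")
    auto = np.real(np.einsum("skccf->skcf", se.cpsd))
    denom = np.sqrt(auto[:, :, :, None, :] * auto[:, :, None, :, :])
    with np.errstate(invalid="ignore", divide="ignore"):
        coh = np.abs(se.cpsd) / denom
    coh[~np.isfinite(coh)] = np.nan
    return np.clip(coh, 0.0, 1.0, out=coh)


def nnmf_bands(coherence_spectra: np.ndarray, n_components: int, seed: int = 0):
    """Data-driven frequency bands by non-negative matrix factorization.

    ``coherence_spectra``: any array whose last axis is frequency; all
    leading axes (subjects, states, channel pairs) are stacked into
    observations.  Returns ``(components, weights)`` with components
    (n_components, F) ordered by the frequency of their weight maximum
    ascending, so the first component is the low-frequency band.
    All-zero observations are tolerated and receive zero loadings.
    """
    from sklearn.decomposition import NMF

    X = np.asarray(coherence_spectra)
    F = X.shape[-1]
    X = X.reshape(-1, F)
    X = X[np.isfinite(X).all(axis=1)]
    if (X < 0).any():
        raise ValueError("coherence spectra must be non-negative")
    if n_components > min(X.shape):
        raise ValueError("n_components exceeds the rank of the stacked spectra")
    model = NMF(
        n_components=n_components,
        init="nndsvda",
        max_iter=2000,
        random_state=seed,
        tol=1e-8,
    )
    W = model.fit_transform(X)
    H = model.components_  # (n_components, F)
    order = np.argsort(H.argmax(axis=1))
    return H[order], W[:, order]


def power_map(
    se: SpectralEstimate,
    band: tuple[float, float] | None = None,
    component_weights: np.ndarray | None = None,
    relative_to_mean: bool = False,
) -> np.ndarray:
    """Per-channel power per subject/state: integrate the PSD over a band,
    or weight it by an NNMF spectral component.  ``relative_to_mean``
    subtracts the across-state mean map."""
    freqs = se.frequencies
    if (band is None) == (component_weights is None):
        raise ValueError("give exactly one of band or component_weights")
    if band is not None:
        lo, hi = band
        sel = (freqs >= lo) & (freqs <= hi)
        if not sel.any():
            raise ValueError(f"band {band} contains no frequency bins")
        df = freqs[1] - freqs[0]
        power = se.psd[..., sel].sum(axis=-1) * df
    else:
        w = np.asarray(component_weights, dtype=float)
        if w.shape != freqs.shape:
            raise ValueError("component weights must match the frequency grid")
        power = np.einsum("skcf,f->skc", se.psd, w) * (freqs[1] - freqs[0])
    if relative_to_mean:
        power = power - np.nanmean(power, axis=1, keepdims=True)
    return power


def aec(
    ts: TimeSeriesSet, band: tuple[float, float]
) -> np.ndarray:
    """Amplitude envelope correlation networks per subject: (S, C, C).

    bandpass -> amplitude envelope -> Pearson correlation between channel
    envelopes.  Constant envelopes give NaN entries.
    """
    from .prepare import amplitude_envelope, bandpass

    env = amplitude_envelope(bandpass(ts, band[0], band[1]))
    S, C = ts.n_subjects, ts.n_channels
    out = np.full((S, C, C), np.nan)
    for s in range(S):
        e = env.arrays[s]
        sd = e.std(axis=0)
        ok = sd > 0
        if ok.sum() >= 2:
            c = np.corrcoef(e[:, ok].T)
            out[s][np.ix_(np.where(ok)[0], np.where(ok)[0])] = c
        out[s][np.diag_indices(C)] = np.where(ok, 1.0, np.nan)
    return out
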