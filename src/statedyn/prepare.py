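"""Transform source time series into training data.

The two preparation routes mirror the two things a latent-dynamics model
can be asked to track:

* **Amplitude envelope (AE)** — bandpass a frequency range of interest,
  then take the modulus of the analytic (Hilbert) signal.  Models trained
  on AE data see amplitude dynamics only.
* **Time-delay embedding (TDE)** — augment each channel with time-lagged
  copies (always shifted by one sample), so the covariance matrix of the
  embedded data encodes the auto- and cross-correlation, hence spectral,
  structure of the original channels.  Models trained on TDE data see
  oscillatory frequency and phase-coupling dynamics.

TDE typically inflates the channel count, so group PCA (`pca_reduce`) and
per-subject standardization follow.  Every step records its provenance
and keeps the map from prepared rows back to original samples.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import signal as sp_signal

from .data import PreparedData, TimeSeriesSet

__all__ = [
    "bandpass",
    "amplitude_envelope",
    "time_delay_embed",
    "pca_reduce",
    "standardize",
    "prepare_tde_pipeline",
    "prepare_ae_pipeline",
]


def bandpass(
    ts: TimeSeriesSet, low: float, high: float, order: int = 5
) -> TimeSeriesSet:
    """Zero-phase band-limit each channel to ``(low, high)`` Hz.

    Forward-backward Butterworth (order ``order``); ``low = 0`` gives a
    low-pass filter.  Length is preserved.
    """
    nyq = ts.nyquist
    if not (0 <= low < high):
        raise ValueError("need 0 <= low < high")
    if high >= nyq:
        raise ValueError(f"high cutoff {high} Hz must be below Nyquist {nyq} Hz")
    if low == 0:
        sos = sp_signal.butter(order, high, btype="lowpass", fs=ts.sampling_frequency, output="sos")
    else:
        sos = sp_signal.butter(
            order, [low, high], btype="bandpass", fs=ts.sampling_frequency, output="sos"
        )
    arrays = [sp_signal.sosfiltfilt(sos, a, axis=0) for a in ts.arrays]
    return TimeSeriesSet(
        arrays=arrays,
        sampling_frequency=ts.sampling_frequency,
        channel_names=list(ts.channel_names),
        subject_ids=list(ts.subject_ids),
    )


def amplitude_envelope(ts: TimeSeriesSet) -> TimeSeriesSet:
    """Modulus of the analytic signal, per channel and contiguous recording.

    The first and last ~1 oscillation cycle of each recording are edge
    affected; no padding is applied.
    """
    arrays = [np.abs(sp_signal.hilbert(a, axis=0)) for a in ts.arrays]
    return TimeSeriesSet(
        arrays=arrays,
        sampling_frequency=ts.sampling_frequency,
        channel_names=list(ts.channel_names),
        subject_ids=list(ts.subject_ids),
    )


def time_delay_embed(
    data: TimeSeriesSet | PreparedData, n_embeddings: int
) -> PreparedData:
    """Augment channels with lagged copies (lags -(n-1)/2 .. +(n-1)/2).

    Column order is channel-major, lag-minor: for channel c the columns
    ``c*n .. c*n + n - 1`` hold ``x_c(t + lag)`` for lag ascending from
    ``-(n-1)/2`` to ``+(n-1)/2``.  The first and last ``(n-1)/2`` rows,
    where some lag is unavailable, are dropped.
    """
    if n_embeddings < 1 or n_embeddings % 2 == 0:
        raise ValueError("n_embeddings must be an odd positive integer")
    if isinstance(data, TimeSeriesSet):
        data = PreparedData.from_time_series(data)
    half = (n_embeddings - 1) // 2
    arrays, index_maps = [], []
    for a, imap in zip(data.arrays, data.index_maps):
        T, C = a.shape
        if n_embeddings >= T:
            raise ValueError(f"series of length {T} too short for {n_embeddings} embeddings")
        T_out = T - n_embeddings + 1
        out = np.empty((T_out, C * n_embeddings))
        for c in range(C):
            for i, lag in enumerate(range(-half, half + 1)):
                out[:, c * n_embeddings + i] = a[half + lag : half + lag + T_out, c]
        arrays.append(out)
        index_maps.append(imap[half : half + T_out])
    record = dict(data.record)
    record["steps"] = record.get("steps", []) + [
        {"step": "tde", "n_embeddings": n_embeddings}
    ]
    return PreparedData(
        arrays=arrays,
        sampling_frequency=data.sampling_frequency,
        index_maps=index_maps,
        record=record,
        subject_ids=list(data.subject_ids),
    )


def pca_reduce(
    pd: PreparedData, n_components: int, per_subject: bool = False
) -> PreparedData:
    """Project onto the top principal directions.

    By default the PCA basis is fitted on the subject-concatenated data
    (group PCA) and applied to every subject, since models are trained on
    concatenated data; ``per_subject=True`` fits one basis per subject.
    """
    if n_components > pd.n_channels:
        raise ValueError(
            f"n_components={n_components} exceeds dimension {pd.n_channels}"
        )

    def _fit(x):
        mean = x.mean(axis=0)
        xc = x - mean
        # economy SVD of the centred data; deterministic sign convention
        _, s, vt = np.linalg.svd(xc, full_matrices=False)
        signs = np.sign(vt[np.arange(len(vt)), np.abs(vt).argmax(axis=1)])
        vt = vt * signs[:, None]
        var = s**2 / (len(x) - 1)
        total = var.sum()
        rank = int((s > s[0] * 1e-10).sum()) if len(s) else 0
        k = n_components
        if k > rank:
            warnings.warn(
                f"requested {n_components} components but data rank is {rank}; "
                f"retaining {rank}"
            )
            k = rank
        return mean, vt[:k], var[:k] / total

    if per_subject:
        fits = [_fit(a) for a in pd.arrays]
    else:
        fit = _fit(pd.concatenated())
        fits = [fit] * pd.n_subjects

    arrays = [(a - mean) @ comps.T for a, (mean, comps, _) in zip(pd.arrays, fits)]
    record = dict(pd.record)
    record["steps"] = record.get("steps", []) + [
        {
            "step": "pca",
            "n_components": arrays[0].shape[1],
            "per_subject": per_subject,
            "components": fits[0][1],
            "explained_variance_ratio": fits[0][2],
        }
    ]
    return PreparedData(
        arrays=arrays,
        sampling_frequency=pd.sampling_frequency,
        index_maps=[m.copy() for m in pd.index_maps],
        record=record,
        subject_ids=list(pd.subject_ids),
    )


def standardize(pd: PreparedData, per_subject: bool = True) -> PreparedData:
    """Z-transform each column to zero mean, unit variance (per subject by
    default, removing inter-subject scale differences before concatenation)."""
    groups = pd.arrays if per_subject else [pd.concatenated()]
    moments = []
    for g in groups:
        mean = g.mean(axis=0)
        sd = g.std(axis=0)
        zero = np.where(sd == 0)[0]
        if len(zero):
            raise ValueError(f"zero-variance column(s) {zero.tolist()}; cannot standardize")
        moments.append((mean, sd))
    if per_subject:
        arrays = [(a - m) / s for a, (m, s) in zip(pd.arrays, moments)]
    else:
        m, s = moments[0]
        arrays = [(a - m) / s for a in pd.arrays]
    record = dict(pd.record)
    record["steps"] = record.get("steps", []) + [
        {"step": "standardize", "per_subject": per_subject}
    ]
    return PreparedData(
        arrays=arrays,
        sampling_frequency=pd.sampling_frequency,
        index_maps=[m.copy() for m in pd.index_maps],
        record=record,
        subject_ids=list(pd.subject_ids),
    )


def prepare_tde_pipeline(
    ts: TimeSeriesSet,
    n_embeddings: int = 15,
    n_components: int | None = None,
) -> PreparedData:
    """TDE -> (group PCA) -> per-subject standardization."""
    pd = time_delay_embed(ts, n_embeddings)
    if n_components is None and ts.n_channels > 1:
        raise ValueError("n_components is required for multichannel TDE data")
    if n_components is not None:
        pd = pca_reduce(pd, n_components)
    return standardize(pd)


def prepare_ae_pipeline(
    ts: TimeSeriesSet, low: float | None = None, high: float | None = None
) -> PreparedData:
    """(bandpass) -> amplitude envelope -> per-subject standardization."""
    if (low is None) != (high is None):
        raise ValueError("give both low and high, or neither")
    if low is not None:
        ts = bandpass(ts, low, high)
    env = amplitude_envelope(ts)
    pd = PreparedData.from_time_series(env)
    pd.record["steps"] = [{"step": "amplitude_envelope", "band": (low, high)}]
    return standardize(pd)
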