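"""Quick-look plots for fitted models and spectra (matplotlib)."""

from __future__ import annotations

import numpy as np

__all__ = [
    "plot_free_energy_trace",
    "plot_state_probabilities",
    "plot_mixing",
    "plot_psd",
]


def _axes(ax):
    if ax is None:
        import matplotlib.pyplot as plt

        _, ax = plt.subplots()
    return ax


def plot_free_energy_trace(results, ax=None):
    """Objective trace of a fit (HMM free energy or mixture loss)."""
    ax = _axes(ax)
    trace = getattr(results, "free_energy_trace", None)
    if trace is None:
        trace = results.loss_trace
    ax.plot(trace)
    ax.set_xlabel("iteration")
    ax.set_ylabel("free energy")
    return ax


def plot_state_probabilities(results, subject: int = 0, t_max: int = 2000, ax=None):
    """Stacked per-state posterior probabilities for one subject."""
    ax = _axes(ax)
    gamma = results.state_probabilities()[subject][:t_max]
    fs = results.model.sampling_frequency or 1.0
    t = np.arange(len(gamma)) / fs
    ax.stackplot(t, gamma.T)
    ax.set_xlabel("time (s)" if fs != 1.0 else "sample")
    ax.set_ylabel("state probability")
    ax.set_ylim(0, 1)
    return ax


def plot_mixing(results, renormalized: bool = True, t_max: int = 2000, ax=None):
    """Mode mixing coefficients over time."""
    ax = _axes(ax)
    alpha = results.renormalized_alpha if renormalized else results.alpha
    alpha = alpha[:t_max]
    fs = results.model.sampling_frequency or 1.0
    t = np.arange(len(alpha)) / fs
    for j in range(alpha.shape[1]):
        ax.plot(t, alpha[:, j], label=f"mode {j}")
    ax.set_xlabel("time (s)" if fs != 1.0 else "sample")
    ax.set_ylabel("renormalized alpha" if renormalized else "alpha")
    ax.legend()
    return ax


def plot_psd(se, subject: int = 0, channel: int = 0, ax=None):
    """Per-state/mode PSD of one channel of a SpectralEstimate."""
    ax = _axes(ax)
    for k in range(se.psd.shape[1]):
        ax.plot(se.frequencies, se.psd[subject, k, channel], label=f"state {k}")
    ax.set_xlabel("frequency (Hz)")
    ax.set_ylabel("PSD")
    ax.legend()
    return ax
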