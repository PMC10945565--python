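"""Summary statistics of latent dynamics.

For hard state time courses (HMM Viterbi paths or binarized mode time
courses) the statistics are: fractional occupancy, mean lifetime
("dwell time"), mean interval, switching rate ("burst count" in the
single-region burst setting — the same quantity under two names) and
mean amplitude.  For soft mode time courses: the time-mean, time-SD and
pairwise Pearson correlation of the (renormalized) mixing coefficients.

Conventions (fixed and relied on by the tests):

* Runs truncated by a recording boundary count toward lifetimes.
* An interval is the gap from the *end* of one visit to the *start* of
  the next; edge gaps (before the first / after the last visit) are
  excluded.  A state needs >= 2 visits for a defined interval.
* Statistics are computed per subject on that subject's own recording,
  never across subject boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import TimeSeriesSet

__all__ = [
    "SummaryTable",
    "state_runs",
    "fractional_occupancy",
    "mean_lifetime",
    "mean_interval",
    "switching_rate",
    "mean_amplitude",
    "mixing_stats",
    "state_envelope_correlation",
    "summary_table",
]


@dataclass
class SummaryTable:
    """(subjects, states) matrix of one named summary statistic."""

    values: np.ndarray  # (S, K), NaN = undefined
    statistic: str
    units: str
    subject_ids: list[str] | None = None

    def to_tidy(self) -> pd.DataFrame:
        S, K = self.values.shape
        ids = self.subject_ids or [f"subject{i}" for i in range(S)]
        rows = [
            {
                "subject_id": ids[s],
                "state": k,
                "statistic": self.statistic,
                "value": self.values[s, k],
                "units": self.units,
            }
            for s in range(S)
            for k in range(K)
        ]
        return pd.DataFrame(rows)


def _as_paths(path) -> list[np.ndarray]:
    if isinstance(path, np.ndarray):
        return [path]
    return [np.asarray(p) for p in path]


def _infer_n_states(paths, n_states):
    if n_states is not None:
        return n_states
    return int(max(p.max() for p in paths)) + 1


def state_runs(path: np.ndarray, n_states: int) -> list[list[tuple[int, int]]]:
    """Contiguous visits per state as (onset, length) pairs."""
    path = np.asarray(path)
    if len(path) == 0:
        raise ValueError("empty state path")
    change = np.flatnonzero(np.diff(path)) + 1
    onsets = np.concatenate([[0], change])
    lengths = np.diff(np.concatenate([onsets, [len(path)]]))
    runs: list[list[tuple[int, int]]] = [[] for _ in range(n_states)]
    for onset, length in zip(onsets, lengths):
        runs[path[onset]].append((int(onset), int(length)))
    return runs


def fractional_occupancy(path, n_states: int | None = None) -> np.ndarray:
    """Fraction of total time each state is active; rows sum to 1."""
    paths = _as_paths(path)
    K = _infer_n_states(paths, n_states)
    return np.stack([np.bincount(p, minlength=K) / len(p) for p in paths])


def mean_lifetime(path, fs: float, n_states: int | None = None) -> np.ndarray:
    """Average visit duration per state, seconds.  NaN if never visited."""
    if fs <= 0:
        raise ValueError("sampling frequency must be positive")
    paths = _as_paths(path)
    K = _infer_n_states(paths, n_states)
    out = np.full((len(paths), K), np.nan)
    for s, p in enumerate(paths):
        for k, runs in enumerate(state_runs(p, K)):
            if runs:
                out[s, k] = np.mean([l for _, l in runs]) / fs
    return out


def mean_interval(path, fs: float, n_states: int | None = None) -> np.ndarray:
    """Average end-to-next-start gap per state, seconds.  NaN if < 2 visits."""
    if fs <= 0:
        raise ValueError("sampling frequency must be positive")
    paths = _as_paths(path)
    K = _infer_n_states(paths, n_states)
    out = np.full((len(paths), K), np.nan)
    for s, p in enumerate(paths):
        for k, runs in enumerate(state_runs(p, K)):
            if len(runs) >= 2:
                gaps = [
                    runs[i + 1][0] - (runs[i][0] + runs[i][1])
                    for i in range(len(runs) - 1)
                ]
                out[s, k] = np.mean(gaps) / fs
    return out


def switching_rate(path, fs: float, n_states: int | None = None) -> np.ndarray:
    """Visit onsets per second, per state ("burst count" in the burst
    pipeline).  A constant path has one onset, giving rate fs / T."""
    if fs <= 0:
        raise ValueError("sampling frequency must be positive")
    paths = _as_paths(path)
    K = _infer_n_states(paths, n_states)
    out = np.zeros((len(paths), K))
    for s, p in enumerate(paths):
        duration = len(p) / fs
        for k, runs in enumerate(state_runs(p, K)):
            out[s, k] = len(runs) / duration
    return out


def mean_amplitude(
    path, envelope_data: TimeSeriesSet, n_states: int | None = None
) -> np.ndarray:
    """Average amplitude envelope (averaged over channels) while each state
    is active.  NaN for states never visited."""
    paths = _as_paths(path)
    K = _infer_n_states(paths, n_states)
    out = np.full((len(paths), K), np.nan)
    for s, p in enumerate(paths):
        env = envelope_data.arrays[s].mean(axis=1)
        if len(env) != len(p):
            raise ValueError("envelope not aligned with state path")
        for k in range(K):
            sel = p == k
            if sel.any():
                out[s, k] = env[sel].mean()
    return out


def mixing_stats(alpha) -> dict:
    """Time-mean and time-SD per mode plus the pairwise Pearson correlation
    of the mode time courses.  Constant modes get NaN correlations."""
    alphas = [np.atleast_2d(a) for a in ([alpha] if isinstance(alpha, np.ndarray) else alpha)]
    S = len(alphas)
    J = alphas[0].shape[1]
    means = np.stack([a.mean(axis=0) for a in alphas])
    sds = np.stack([a.std(axis=0) for a in alphas])
    corr = np.full((S, J, J), np.nan)
    for s, a in enumerate(alphas):
        sd = a.std(axis=0)
        ok = sd > 0
        if ok.sum() >= 2:
            c = np.corrcoef(a[:, ok].T)
            idx = np.ix_(np.where(ok)[0], np.where(ok)[0])
            corr[s][idx] = c
        corr[s][np.diag_indices(J)] = np.where(ok, 1.0, np.nan)
    return {"mean": means, "sd": sds, "correlation": corr}


def state_envelope_correlation(
    gamma: np.ndarray,
    ts: TimeSeriesSet,
    bands: list[tuple[float, float]],
    subject: int = 0,
    sample_offset: int = 0,
) -> np.ndarray:
    """Pearson correlation of each state's probability time course with the
    band-limited amplitude envelope, per frequency band: (K, n_bands).

    ``sample_offset`` shifts the envelope to the source samples the state
    probabilities are aligned to (e.g. the trim of a time-delay
    embedding).
    """
    from .prepare import amplitude_envelope, bandpass

    gamma = np.atleast_2d(gamma)
    K = gamma.shape[1]
    out = np.full((K, len(bands)), np.nan)
    for b, (lo, hi) in enumerate(bands):
        env_ts = amplitude_envelope(bandpass(ts, lo, hi))
        env = env_ts.arrays[subject].mean(axis=1)
        env = env[sample_offset : sample_offset + len(gamma)]
        if len(env) != len(gamma):
            raise ValueError("gamma not aligned with envelope samples")
        for k in range(K):
            g = gamma[:, k]
            if g.std() == 0 or env.std() == 0:
                continue
            out[k, b] = np.corrcoef(g, env)[0, 1]
    return out


_STAT_FUNCS = {
    "fractional_occupancy": (fractional_occupancy, "dimensionless", False),
    "mean_lifetime": (mean_lifetime, "s", True),
    "mean_interval": (mean_interval, "s", True),
    "switching_rate": (switching_rate, "Hz", True),
}


def summary_table(
    paths, fs: float, statistic: str, n_states: int | None = None
) -> SummaryTable:
    """Compute one named statistic for all subjects as a SummaryTable."""
    if statistic not in _STAT_FUNCS:
        raise ValueError(
            f"unknown statistic {statistic!r}; choose from {sorted(_STAT_FUNCS)}"
        )
    func, units, needs_fs = _STAT_FUNCS[statistic]
    values = func(paths, fs, n_states=n_states) if needs_fs else func(paths, n_states=n_states)
    return SummaryTable(values=np.atleast_2d(values), statistic=statistic, units=units)
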