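"""Group-level inference with family-wise error control.

Two permutation procedures, both using the *maximum statistic* over all
pooled comparisons to control the family-wise error rate (FWER):

* :func:`evoked_maxstat` — epoched state time courses around events; the
  null is built by randomly sign-flipping each trial's deviation from
  its pre-event baseline (or by permuting trial labels), pooling the
  maximum |t| over states and time points.
* :func:`twogroup_maxstat` — subject-level summary tables compared
  between two groups with a standardized mean difference, pooling the
  maximum over states x metrics (or bands x parcels / edges).

Plus the two network-thresholding rules used for display: a
two-component GMM separating "background" from "atypically strong"
connections, and a top-k% rule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from math import comb

import numpy as np

__all__ = [
    "EpochedStateCourse",
    "PermutationResult",
    "epoch_states",
    "evoked_maxstat",
    "twogroup_maxstat",
    "threshold_gmm",
    "threshold_topk",
]


@dataclass
class EpochedStateCourse:
    """(trials, time, states) state indicators around events."""

    trials: np.ndarray
    window: tuple[int, int]  # samples relative to event, [pre, post)
    sampling_frequency: float | None = None
    n_dropped: int = 0

    @property
    def times(self) -> np.ndarray:
        t = np.arange(self.window[0], self.window[1])
        if self.sampling_frequency:
            return t / self.sampling_frequency
        return t.astype(float)

    def average(self) -> np.ndarray:
        """Trial-average activation probability: the network response."""
        return self.trials.mean(axis=0)


@dataclass
class PermutationResult:
    observed: np.ndarray
    null_max: np.ndarray
    p_values: np.ndarray
    alpha: float
    mask: np.ndarray = field(init=False)
    settings: dict = field(default_factory=dict)

    def __post_init__(self):
        self.mask = self.p_values < self.alpha


def _to_indicator(course, n_states=None):
    course = np.asarray(course)
    if course.ndim == 1:
        K = n_states or int(course.max()) + 1
        onehot = np.zeros((len(course), K))
        onehot[np.arange(len(course)), course.astype(int)] = 1.0
        return onehot
    return course


def epoch_states(
    course,
    event_samples,
    window: tuple[int, int],
    sampling_frequency: float | None = None,
    n_states: int | None = None,
) -> EpochedStateCourse:
    """Epoch a state time course around events.

    ``window = (pre, post)`` in samples relative to each event (pre is
    usually negative).  Out-of-bounds trials are dropped and counted.
    """
    ind = _to_indicator(course, n_states)
    T = len(ind)
    pre, post = window
    if post <= pre:
        raise ValueError("window must satisfy post > pre")
    trials, dropped = [], 0
    for e in np.asarray(event_samples, dtype=int):
        lo, hi = e + pre, e + post
        if lo < 0 or hi > T:
            dropped += 1
            continue
        trials.append(ind[lo:hi])
    if not trials:
        raise ValueError("no usable trials: all events fall outside the recording")
    return EpochedStateCourse(
        trials=np.stack(trials),
        window=window,
        sampling_frequency=sampling_frequency,
        n_dropped=dropped,
    )


def _sign_flip_tmax(dev, n_perm, rng):
    """Null max |t| distribution under random per-trial sign flips.

    dev: (n_trials, n_elements) baseline-corrected deviations.  The sum
    of squares is flip-invariant, so per-permutation t statistics are
    cheap.
    """
    n, m = dev.shape
    ss = (dev**2).sum(axis=0)
    tiny = 1e-10 * (ss.max() / n + 1e-300)  # zero-variance guard
    signs = rng.choice([-1.0, 1.0], size=(n_perm, n))
    sums = signs @ dev  # (n_perm, m)
    mean = sums / n
    var = (ss[None, :] - n * mean**2) / (n - 1)
    se = np.sqrt(np.maximum(var, 0) / n)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.abs(mean) / se
    t[~np.isfinite(t) | (var <= tiny)] = 0.0
    return t.max(axis=1)


def evoked_maxstat(
    epoched: EpochedStateCourse,
    baseline: tuple[int, int] | None = None,
    n_perm: int = 5000,
    alpha: float = 0.05,
    seed: int | None = 0,
    method: str = "sign_flip",
) -> PermutationResult:
    """FWER-controlled test of the evoked network response.

    Each trial's course is baseline-corrected by its mean over the
    ``baseline`` window (samples relative to the event; default the full
    pre-event part of the window).  The observed statistic is the
    one-sample t over trials per (time, state); the null pools the
    maximum |t| over all states and time points.

    Validity rests on the exchangeable units having a symmetric
    deviation distribution under the null.  That holds for continuous
    responses — in particular subject-level trial-averaged state
    courses, the usual group-level input — but not for raw single-trial
    binary state indicators, whose skew inflates the family-wise error
    rate; average trials (per subject or in blocks) before testing.
    ``method="label_flip"`` (exchanging the roles of baseline and epoch
    within a trial) is algebraically the same sign flip and is provided
    for nomenclature only.
    """
    if method not in ("sign_flip", "label_flip"):
        raise ValueError("method must be 'sign_flip' or 'label_flip'")
    rng = np.random.default_rng(seed)
    trials = epoched.trials  # (n, T, K)
    n, T, K = trials.shape
    if n < 8:
        warnings.warn(f"only {n} trials; permutation p-values will be coarse")
    pre = epoched.window[0]
    if baseline is None:
        baseline = (pre, 0)
    b0, b1 = baseline[0] - pre, baseline[1] - pre
    if not (0 <= b0 < b1 <= T):
        raise ValueError("baseline window outside the epoch")
    base = trials[:, b0:b1].mean(axis=1, keepdims=True)
    dev = (trials - base).reshape(n, T * K)

    ss = (dev**2).sum(axis=0)
    tiny = 1e-10 * (ss.max() / n + 1e-300)
    mean = dev.mean(axis=0)
    var = (ss - n * mean**2) / (n - 1)
    se = np.sqrt(np.maximum(var, 0) / n)
    with np.errstate(invalid="ignore", divide="ignore"):
        t_obs = mean / se
    t_obs[~np.isfinite(t_obs) | (var <= tiny)] = 0.0

    if method == "sign_flip":
        null = _sign_flip_tmax(dev, n_perm, rng)
    else:  # label_flip: permute which samples count as baseline vs epoch
        null = np.empty(n_perm)
        for i in range(n_perm):
            flip = rng.random(n) < 0.5
            d = dev.copy()
            d[flip] *= -1
            null[i] = _sign_flip_tmax(d, 1, np.random.default_rng(rng.integers(2**31)))
    p = (1 + (null[:, None] >= np.abs(t_obs)[None, :]).sum(axis=0)) / (n_perm + 1)
    return PermutationResult(
        observed=t_obs.reshape(T, K),
        null_max=null,
        p_values=p.reshape(T, K),
        alpha=alpha,
        settings={"n_perm": n_perm, "method": method, "baseline": baseline},
    )


def _standardized_diff(data, labels):
    """Per-element (mean_1 - mean_2) / pooled SD."""
    g1, g2 = data[labels == 0], data[labels == 1]
    n1, n2 = len(g1), len(g2)
    pooled = np.sqrt(
        ((n1 - 1) * g1.var(axis=0, ddof=1) + (n2 - 1) * g2.var(axis=0, ddof=1))
        / (n1 + n2 - 2)
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        d = (g1.mean(axis=0) - g2.mean(axis=0)) / pooled
    d[~np.isfinite(d)] = 0.0
    return d


def twogroup_maxstat(
    tables,
    group_labels,
    n_perm: int = 5000,
    alpha: float = 0.05,
    seed: int | None = 0,
    standardize_metrics: bool = True,
) -> PermutationResult:
    """Two-group contrast with max-statistic pooling over all elements.

    ``tables``: one (subjects, elements) array, or a list of them (one
    per metric) that is pooled — e.g. states x metrics, bands x parcels,
    bands x edges.  When pooling metrics with heterogeneous units each
    metric is standardized by its pooled SD (enforced by the statistic
    itself, which is a standardized mean difference).  The null permutes
    group labels; when the number of distinct assignments is at most
    ``n_perm`` the permutation distribution is enumerated exactly.
    """
    if isinstance(tables, np.ndarray):
        tables = [tables]
    mats = [np.atleast_2d(np.asarray(t, dtype=float)) for t in tables]
    n_subjects = mats[0].shape[0]
    for t in mats:
        if t.shape[0] != n_subjects:
            raise ValueError("all tables must have one row per subject")
    shapes = [t.shape[1] for t in mats]
    data = np.concatenate(mats, axis=1)  # (subjects, total elements)
    labels = np.asarray(group_labels)
    uniq = np.unique(labels)
    if len(uniq) != 2:
        raise ValueError("exactly two groups required")
    labels = (labels == uniq[1]).astype(int)
    n1 = int((labels == 0).sum())
    if n1 < 2 or (n_subjects - n1) < 2:
        raise ValueError("each group needs at least 2 subjects")
    if standardize_metrics:
        # the standardized-difference statistic is already unit-free per
        # element; additionally scale each metric block to unit pooled SD
        # so absolute values are comparable across metrics
        col = 0
        for w in shapes:
            block = data[:, col : col + w]
            sd = block.std(axis=0, ddof=1)
            sd[sd == 0] = 1.0
            data[:, col : col + w] = block / sd
            col += w

    obs = _standardized_diff(data, labels)

    n_distinct = comb(n_subjects, n1)
    rng = np.random.default_rng(seed)
    if n_distinct <= n_perm:
        perms = []
        for idx in combinations(range(n_subjects), n1):
            lab = np.ones(n_subjects, dtype=int)
            lab[list(idx)] = 0
            perms.append(lab)
        exhaustive = True
    else:
        perms = [rng.permutation(labels) for _ in range(n_perm)]
        exhaustive = False
    null = np.empty(len(perms))
    for i, lab in enumerate(perms):
        null[i] = np.abs(_standardized_diff(data, lab)).max()
    p = (1 + (null[:, None] >= np.abs(obs)[None, :]).sum(axis=0)) / (len(perms) + 1)

    def unstack(v):
        out, col = [], 0
        for w in shapes:
            out.append(v[col : col + w])
            col += w
        return out if len(out) > 1 else out[0]

    return PermutationResult(
        observed=obs,
        null_max=null,
        p_values=p,
        alpha=alpha,
        settings={
            "n_perm": len(perms),
            "exhaustive": exhaustive,
            "blocks": shapes,
        },
    )


def threshold_gmm(
    values: np.ndarray, seed: int = 0
) -> tuple[np.ndarray, float]:
    """Keep "atypically strong" connections via a two-component GMM.

    Fits a two-component univariate Gaussian mixture to the connection
    values; values whose posterior probability of belonging to the
    higher-mean component exceeds 0.5 are kept.  Affine rescaling of the
    inputs leaves the mask unchanged.  Effectively unimodal input warns
    and returns an empty mask.
    """
    from sklearn.mixture import GaussianMixture

    values = np.asarray(values, dtype=float).ravel()
    if len(values) < 10:
        raise ValueError("need at least 10 values to fit the mixture")
    if values.max() - values.min() <= 1e-12:
        warnings.warn("all connection values equal; empty mask")
        return np.zeros(len(values), dtype=bool), np.inf
    scale = values.std()
    v = (values - values.mean()) / scale  # affine-invariant fit
    gmm = GaussianMixture(n_components=2, random_state=seed, n_init=5)
    gmm.fit(v[:, None])
    means = gmm.means_.ravel()
    sds = np.sqrt(gmm.covariances_.ravel())
    hi = int(np.argmax(means))
    if (means.max() - means.min()) / max(sds.mean(), 1e-12) < 1.0:
        warnings.warn("connection distribution looks unimodal; empty mask")
        return np.zeros(len(values), dtype=bool), np.inf
    post = gmm.predict_proba(v[:, None])[:, hi]
    mask = post > 0.5
    if mask.any() and (~mask).any():
        threshold = 0.5 * (values[mask].min() + values[~mask].max())
    else:
        threshold = float(values.mean())
    return mask, float(threshold)


def threshold_topk(matrix: np.ndarray, fraction: float) -> np.ndarray:
    """Keep the ceil(fraction * n_edges) largest-|value| unique edges of a
    symmetric matrix (diagonal excluded).  Ties at the cut are all kept."""
    matrix = np.asarray(matrix, dtype=float)
    if not (0 < fraction < 1):
        raise ValueError("fraction must be in (0, 1)")
    if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
        raise ValueError("matrix must be square")
    if not np.allclose(matrix, matrix.T, atol=1e-8, equal_nan=True):
        raise ValueError("matrix must be symmetric")
    n = matrix.shape[0]
    iu = np.triu_indices(n, k=1)
    edges = np.abs(matrix[iu])
    n_keep = int(np.ceil(fraction * len(edges)))
    cut = np.sort(edges)[::-1][n_keep - 1]
    keep = edges >= cut
    if keep.sum() > n_keep:
        warnings.warn(
            f"ties at the threshold: keeping {int(keep.sum())} edges "
            f"instead of {n_keep}"
        )
    mask = np.zeros_like(matrix, dtype=bool)
    mask[iu] = keep
    return mask | mask.T
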