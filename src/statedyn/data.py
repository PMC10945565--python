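"""Containers for multichannel time series and prepared training data.

A :class:`TimeSeriesSet` is the universal input: one real-valued
``(T_s, C)`` matrix per subject, a shared sampling frequency, channel
labels and subject IDs.  A :class:`PreparedData` is what the models are
trained on; it additionally carries the preparation record (filter band,
embedding lags, PCA basis, standardization moments) and, crucially, the
index map from each prepared row back to the sample of the original
recording it is centred on, so that inferred state/mode time courses can
be re-aligned with the source data for dual estimation and spectral
estimation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["TimeSeriesSet", "PreparedData", "as_time_series_set"]


def _validate_matrix(x: np.ndarray, name: str) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    if x.ndim != 2:
        raise ValueError(f"{name} must be a (T, C) matrix, got shape {x.shape}")
    if not np.isfinite(x).all():
        raise ValueError(f"{name} contains NaN or Inf")
    return x


@dataclass
class TimeSeriesSet:
    """Per-subject ``(T_s, C)`` matrices with a shared sampling frequency."""

    arrays: list[np.ndarray]
    sampling_frequency: float
    channel_names: list[str] | None = None
    subject_ids: list[str] | None = None

    def __post_init__(self):
        if self.sampling_frequency <= 0:
            raise ValueError("sampling_frequency must be positive")
        self.arrays = [
            _validate_matrix(a, f"subject {i} data") for i, a in enumerate(self.arrays)
        ]
        channels = {a.shape[1] for a in self.arrays}
        if len(channels) != 1:
            raise ValueError(f"all subjects must share a channel count, got {channels}")
        if self.channel_names is None:
            self.channel_names = [f"ch{i}" for i in range(self.n_channels)]
        if self.subject_ids is None:
            self.subject_ids = [f"subject{i}" for i in range(self.n_subjects)]
        if len(self.channel_names) != self.n_channels:
            raise ValueError("channel_names length mismatch")
        if len(self.subject_ids) != self.n_subjects:
            raise ValueError("subject_ids length mismatch")

    @property
    def n_subjects(self) -> int:
        return len(self.arrays)

    @property
    def n_channels(self) -> int:
        return self.arrays[0].shape[1]

    @property
    def n_samples(self) -> list[int]:
        return [a.shape[0] for a in self.arrays]

    @property
    def nyquist(self) -> float:
        return self.sampling_frequency / 2.0

    def concatenated(self) -> np.ndarray:
        return np.concatenate(self.arrays, axis=0)

    def save(self, directory: str | Path) -> None:
        """Write one binary float array per subject plus a JSON sidecar."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for sid, arr in zip(self.subject_ids, self.arrays):
            np.save(directory / f"{sid}.npy", arr)
        sidecar = {
            "sampling_frequency": self.sampling_frequency,
            "channel_names": self.channel_names,
            "subject_ids": self.subject_ids,
        }
        (directory / "timeseries.json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def load(cls, directory: str | Path) -> "TimeSeriesSet":
        directory = Path(directory)
        sidecar = json.loads((directory / "timeseries.json").read_text())
        arrays = [np.load(directory / f"{sid}.npy") for sid in sidecar["subject_ids"]]
        return cls(
            arrays=arrays,
            sampling_frequency=sidecar["sampling_frequency"],
            channel_names=sidecar["channel_names"],
            subject_ids=sidecar["subject_ids"],
        )


@dataclass
class PreparedData:
    """Training matrices plus provenance and sample-alignment metadata.

    ``index_maps[s][i]`` is the sample index in the *original* recording of
    subject ``s`` that prepared row ``i`` is centred on.  For purely
    pointwise transforms this is the identity; time-delay embedding trims
    ``(n_embeddings - 1) / 2`` samples at each end.
    """

    arrays: list[np.ndarray]
    sampling_frequency: float
    index_maps: list[np.ndarray]
    record: dict = field(default_factory=dict)
    subject_ids: list[str] | None = None

    def __post_init__(self):
        self.arrays = [
            _validate_matrix(a, f"subject {i} prepared data")
            for i, a in enumerate(self.arrays)
        ]
        if len(self.index_maps) != len(self.arrays):
            raise ValueError("index_maps must have one entry per subject")
        for a, m in zip(self.arrays, self.index_maps):
            if len(m) != a.shape[0]:
                raise ValueError("index map length must match prepared length")
        if self.subject_ids is None:
            self.subject_ids = [f"subject{i}" for i in range(len(self.arrays))]

    @property
    def n_subjects(self) -> int:
        return len(self.arrays)

    @property
    def n_channels(self) -> int:
        return self.arrays[0].shape[1]

    @property
    def n_samples(self) -> list[int]:
        return [a.shape[0] for a in self.arrays]

    def concatenated(self) -> np.ndarray:
        return np.concatenate(self.arrays, axis=0)

    def split(self, concatenated: np.ndarray) -> list[np.ndarray]:
        """Split a concatenated per-row quantity back into subjects."""
        lengths = self.n_samples
        if len(concatenated) != sum(lengths):
            raise ValueError("length mismatch when splitting concatenated array")
        out, start = [], 0
        for n in lengths:
            out.append(concatenated[start : start + n])
            start += n
        return out

    def save_record(self, path: str | Path) -> None:
        def default(o):
            if isinstance(o, np.ndarray):
                return o.tolist()
            if isinstance(o, (np.integer, np.floating)):
                return o.item()
            raise TypeError(type(o))

        Path(path).write_text(json.dumps(self.record, indent=2, default=default))

    @classmethod
    def from_time_series(cls, ts: TimeSeriesSet) -> "PreparedData":
        """Wrap a raw time series as trivially prepared data (identity map)."""
        return cls(
            arrays=[a.copy() for a in ts.arrays],
            sampling_frequency=ts.sampling_frequency,
            index_maps=[np.arange(a.shape[0]) for a in ts.arrays],
            record={"steps": []},
            subject_ids=list(ts.subject_ids),
        )


def as_time_series_set(data, sampling_frequency: float | None = None) -> TimeSeriesSet:
    """Coerce an array, list of arrays or TimeSeriesSet to a TimeSeriesSet."""
    if isinstance(data, TimeSeriesSet):
        return data
    if isinstance(data, np.ndarray):
        data = [data]
    if sampling_frequency is None:
        raise ValueError("sampling_frequency required when passing raw arrays")
    return TimeSeriesSet(arrays=list(data), sampling_frequency=sampling_frequency)
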