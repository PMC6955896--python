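"""Epoched trial containers shared by every pipeline stage.

A :class:`TrialSet` holds labeled, epoched multichannel time series in one of
three spaces: raw scalp channels (``sensor``), standardized cortical sources
(``source``), or aggregated region time courses (``roi``).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = ["HAND", "FOOT", "LABELS", "TrialSet"]

HAND = "hand"
FOOT = "foot"
LABELS = (HAND, FOOT)

_SPACES = ("sensor", "source", "roi")


@dataclass
class TrialSet:
    """Labeled epoched multichannel recordings.

    Parameters
    ----------
    data : ndarray, shape (n_trials, n_channels, n_samples)
    labels : array of str, one of {"hand", "foot"} per trial
    fs : sampling rate in Hz
    space : one of {"sensor", "source", "roi"}
    channel_names : channel identifiers (electrode labels or ROI ids)
    """

    data: np.ndarray
    labels: np.ndarray
    fs: float
    space: str = "sensor"
    channel_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.labels = np.asarray(self.labels, dtype=object)
        if self.data.ndim != 3:
            raise ValueError(f"data must be (n_trials, n_channels, n_samples), got {self.data.shape}")
        if len(self.labels) != self.data.shape[0]:
            raise ValueError("labels length must equal number of trials")
        unknown = set(self.labels) - set(LABELS)
        if unknown:
            raise ValueError(f"unknown labels: {sorted(unknown)}")
        if not np.isfinite(self.data).all():
            raise ValueError("trial data contains non-finite values")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.space not in _SPACES:
            raise ValueError(f"space must be one of {_SPACES}")
        if self.channel_names and len(self.channel_names) != self.data.shape[1]:
            raise ValueError("channel_names length must equal number of channels")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    def select_channels(self, names: list[str]) -> "TrialSet":
        """Return a copy restricted to ``names``, in the given order."""
        if not self.channel_names:
            raise ValueError("trial set has no channel names to select by")
        idx = [self.channel_names.index(n) for n in names]
        return TrialSet(self.data[:, idx, :].copy(), self.labels.copy(), self.fs,
                        self.space, list(names))

    def save(self, path: str, **metadata: object) -> None:
        """Write to an NPZ archive with a JSON metadata sidecar entry."""
        meta = {"fs": self.fs, "space": self.space,
                "channel_names": list(self.channel_names), **metadata}
        np.savez(path, data=self.data, labels=self.labels.astype(str),
                 meta=np.array(json.dumps(meta)))

    @classmethod
    def load(cls, path: str) -> "TrialSet":
        with np.load(path, allow_pickle=False) as archive:
            meta = json.loads(str(archive["meta"]))
            return cls(archive["data"], archive["labels"].astype(object), meta["fs"],
                       meta["space"], list(meta["channel_names"]))
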