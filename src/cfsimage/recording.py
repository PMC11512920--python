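"""The core in-memory EEG container."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np


@dataclass
class Recording:
    """A multichannel EEG recording (channels x samples).

    Data are in arbitrary microvolt-scale units; after the standardisation
    pass each channel has zero mean and unit variance, mirroring common
    preprocessing of reference-subtracted EEG.
    """

    data: np.ndarray
    sfreq: float
    channel_names: tuple[str, ...]
    subject_id: str = "unknown"
    label: str = "unknown"

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        self.channel_names = tuple(self.channel_names)
        if self.sfreq <= 0:
            raise ValueError("sfreq must be positive")
        if self.data.shape[0] != len(self.channel_names):
            raise ValueError(
                f"{self.data.shape[0]} rows but {len(self.channel_names)} channel names"
            )

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sfreq

    def standardized(self) -> "Recording":
        """Per-channel z-score (zero mean, unit variance)."""
        mu = self.data.mean(axis=1, keepdims=True)
        sd = self.data.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        return replace(self, data=(self.data - mu) / sd)
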