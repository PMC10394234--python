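"""The raw multichannel EEG recording container."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import DomainError
from .montage import ElectrodeMontage

SFREQ = 500.0  # Hz, fixed acquisition rate of the paradigm


@dataclass
class RawRecording:
    """Multichannel EEG time series (µV) with stimulus markers.

    ``data`` is channels x samples at 500 Hz.  ``marker_samples`` holds
    the 0-based sample index of each stimulus onset and ``marker_kinds``
    the stimulus kind (standard/duration/frequency/intensity).
    ``reference`` names the recording reference ("FCz" as acquired,
    "average" after re-referencing).
    """

    data: np.ndarray
    sfreq: float
    channel_names: tuple[str, ...]
    marker_samples: np.ndarray
    marker_kinds: np.ndarray
    montage: ElectrodeMontage | None = None
    subject_id: str = ""
    reference: str = "FCz"
    eog_channel: str = "EOG"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.marker_samples = np.asarray(self.marker_samples, dtype=np.int64)
        self.marker_kinds = np.asarray(self.marker_kinds)
        if self.data.ndim != 2 or self.data.shape[0] != len(self.channel_names):
            raise DomainError("data must be (n_channels, n_samples)")
        if not np.isfinite(self.data).all():
            raise DomainError("recording contains non-finite samples")
        if len(self.marker_samples) != len(self.marker_kinds):
            raise DomainError("marker samples/kinds length mismatch")
        if len(self.marker_samples):
            needed = self.marker_samples.max() + int(round(0.4 * self.sfreq))
            if self.data.shape[1] < needed:
                raise DomainError(
                    "recording too short: must extend at least 400 ms past "
                    "the last marker"
                )

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def eeg_mask(self) -> np.ndarray:
        return np.array([c != self.eog_channel for c in self.channel_names])

    def index(self, channel: str) -> int:
        try:
            return self.channel_names.index(channel)
        except ValueError:
            raise KeyError(f"channel {channel!r} not in recording") from None

    def copy_with(self, **kwargs) -> "RawRecording":
        return replace(self, **kwargs)
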