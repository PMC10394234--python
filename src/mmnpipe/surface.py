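"""Sensor-level MMN measures: difference waves and windowed peak detection."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DomainError
from .montage import ANALYSIS_CHANNELS
from .preprocess import EvokedResponse

PEAK_WINDOW_MS = (150.0, 250.0)


@dataclass(frozen=True)
class DifferenceWaveform:
    """Deviant-minus-standard MMN waveform (µV), channel x sample."""

    condition: str
    waveform: np.ndarray
    time_ms: np.ndarray
    channel_names: tuple[str, ...]

    def __post_init__(self) -> None:
        if not np.isfinite(self.waveform).all():
            raise DomainError("difference waveform contains non-finite values")

    def channel(self, name: str) -> np.ndarray:
        try:
            return self.waveform[self.channel_names.index(name)]
        except ValueError:
            raise KeyError(f"channel {name!r} not present") from None


@dataclass(frozen=True)
class PeakMeasure:
    channel: str
    amplitude_uv: float
    latency_ms: float


def compute_difference(
    deviant: EvokedResponse, standard: EvokedResponse
) -> DifferenceWaveform:
    """Pointwise deviant − standard."""
    if deviant.channel_names != standard.channel_names:
        raise DomainError("deviant and standard have different channel orders")
    if deviant.mean_waveform.shape != standard.mean_waveform.shape or not np.array_equal(
        deviant.time_ms, standard.time_ms
    ):
        raise DomainError("deviant and standard have mismatched time axes")
    return DifferenceWaveform(
        condition=deviant.condition,
        waveform=deviant.mean_waveform - standard.mean_waveform,
        time_ms=deviant.time_ms,
        channel_names=deviant.channel_names,
    )


def detect_peak(
    diff: DifferenceWaveform,
    channel: str,
    window_ms: tuple[float, float] = PEAK_WINDOW_MS,
    mode: str = "peak",
    mean_halfwidth_ms: float = 20.0,
) -> PeakMeasure:
    """Most negative sample in the closed window; ties -> earliest latency.

    ``mode="mean-around-peak"`` instead reports the mean amplitude within
    ±``mean_halfwidth_ms`` of the detected peak (latency unchanged);
    the default is the single-sample peak.
    """
    w = diff.channel(channel)
    lo, hi = window_ms
    sel = (diff.time_ms >= lo) & (diff.time_ms <= hi)
    if not sel.any():
        raise DomainError(f"window {window_ms} outside the epoch time axis")
    vals = w[sel]
    times = diff.time_ms[sel]
    i = int(np.argmin(vals))  # argmin returns the first minimum: earliest tie
    amplitude = float(vals[i])
    latency = float(times[i])
    if mode == "mean-around-peak":
        around = np.abs(diff.time_ms - latency) <= mean_halfwidth_ms
        amplitude = float(w[around].mean())
    elif mode != "peak":
        raise DomainError(f"unknown peak mode {mode!r}")
    return PeakMeasure(channel=channel, amplitude_uv=amplitude, latency_ms=latency)


def surface_measures(
    diffs: dict[str, DifferenceWaveform],
    channels: tuple[str, ...] = ANALYSIS_CHANNELS,
    window_ms: tuple[float, float] = PEAK_WINDOW_MS,
) -> pd.DataFrame:
    """Peak amplitude/latency table for the analysis electrodes.

    One row per condition x channel with columns condition, channel,
    amplitude_uv, latency_ms.
    """
    rows = []
    for cond, diff in diffs.items():
        for ch in channels:
            pk = detect_peak(diff, ch, window_ms)
            rows.append(
                {
                    "condition": cond,
                    "channel": ch,
                    "amplitude_uv": pk.amplitude_uv,
                    "latency_ms": pk.latency_ms,
                }
            )
    return pd.DataFrame(rows)


def plot_difference(diff: DifferenceWaveform, channels=ANALYSIS_CHANNELS, ax=None):
    """Quick-look plot of the MMN difference wave at selected channels."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for ch in channels:
        ax.plot(diff.time_ms, diff.channel(ch), label=ch)
    ax.axvspan(*PEAK_WINDOW_MS, alpha=0.15, color="gray")
    ax.set_xlabel("time (ms)")
    ax.set_ylabel("amplitude (µV)")
    ax.set_title(f"MMN difference wave — {diff.condition}")
    ax.legend(fontsize="small")
    return ax
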