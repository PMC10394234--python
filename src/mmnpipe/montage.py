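"""Electrode montage geometry.

The analysis uses a 32-channel cap: 31 scalp electrodes on an extended
10-20 layout plus one EOG electrode below the right eye, recorded
against an FCz reference.  Positions are idealized: the canonical 10-20
angular positions are taken from MNE's ``standard_1020`` montage,
re-centred on a best-fit sphere, projected onto the scalp-shell radius
of the spherical head model, and made exactly left-right symmetric so
that mirror-symmetry properties of the forward model hold to machine
precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError

#: scalp electrodes of the default cap, in recording order
SCALP_CHANNELS: tuple[str, ...] = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "FC5", "FC1", "FC2", "FC6",
    "T7", "C3", "Cz", "C4", "T8",
    "TP9", "CP5", "CP1", "CP2", "CP6", "TP10",
    "P7", "P3", "Pz", "P4", "P8",
    "POz", "O1", "O2", "Oz",
)

#: left/right homologue pairs used to symmetrize the layout
_LR_PAIRS: tuple[tuple[str, str], ...] = (
    ("Fp1", "Fp2"), ("F7", "F8"), ("F3", "F4"), ("FC5", "FC6"),
    ("FC1", "FC2"), ("T7", "T8"), ("C3", "C4"), ("TP9", "TP10"),
    ("CP5", "CP6"), ("CP1", "CP2"), ("P7", "P8"), ("P3", "P4"),
    ("O1", "O2"),
)

_MIDLINE: tuple[str, ...] = ("Fz", "Cz", "Pz", "POz", "Oz", "FCz")

#: the six fronto-central electrodes entering the sensor-level analysis
ANALYSIS_CHANNELS: tuple[str, ...] = ("Fz", "F3", "F4", "Cz", "C3", "C4")

EOG_CHANNEL = "EOG"

#: unit direction of the EOG electrode (below the right eye): anterior,
#: slightly right and below the equatorial plane of the head sphere
_EOG_DIRECTION = np.array([0.32, 0.87, -0.38])


@dataclass(frozen=True)
class ElectrodeMontage:
    """Electrode labels and Cartesian scalp positions (meters, head frame).

    Head frame: +x through the right pre-auricular point, +y through the
    nasion, +z through the vertex; origin at the centre of the spherical
    head model.  All scalp electrodes lie exactly on ``scalp_radius``.
    """

    channel_names: tuple[str, ...]
    positions: np.ndarray  # (n_channels, 3) in meters
    recording_reference: str = "FCz"
    reference_position: np.ndarray = field(default=None)  # type: ignore[assignment]
    eog_channel: str = EOG_CHANNEL
    scalp_radius: float = 0.085

    def __post_init__(self) -> None:
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ConfigurationError("channel names must be unique")
        if self.positions.shape != (len(self.channel_names), 3):
            raise ConfigurationError("positions must be (n_channels, 3)")

    @property
    def n_channels(self) -> int:
        return len(self.channel_names)

    @property
    def eeg_channels(self) -> tuple[str, ...]:
        """Scalp EEG channels (everything except the EOG channel)."""
        return tuple(c for c in self.channel_names if c != self.eog_channel)

    @property
    def eeg_mask(self) -> np.ndarray:
        return np.array([c != self.eog_channel for c in self.channel_names])

    def index(self, channel: str) -> int:
        try:
            return self.channel_names.index(channel)
        except ValueError:
            raise KeyError(f"channel {channel!r} not in montage") from None

    def position(self, channel: str) -> np.ndarray:
        return self.positions[self.index(channel)]

    def to_table(self) -> str:
        """Plain-text electrode table: label, x, y, z in meters."""
        lines = ["label\tx\ty\tz"]
        for name, pos in zip(self.channel_names, self.positions):
            lines.append(f"{name}\t{pos[0]:.9f}\t{pos[1]:.9f}\t{pos[2]:.9f}")
        ref = self.reference_position
        lines.append(
            f"#ref:{self.recording_reference}\t{ref[0]:.9f}\t{ref[1]:.9f}\t{ref[2]:.9f}"
        )
        return "\n".join(lines) + "\n"

    @classmethod
    def from_table(cls, text: str, scalp_radius: float = 0.085) -> "ElectrodeMontage":
        names: list[str] = []
        rows: list[list[float]] = []
        ref_name, ref_pos = "FCz", None
        for line in text.strip().splitlines()[1:]:
            parts = line.split("\t")
            if parts[0].startswith("#ref:"):
                ref_name = parts[0].split(":", 1)[1]
                ref_pos = np.array([float(v) for v in parts[1:4]])
                continue
            names.append(parts[0])
            rows.append([float(v) for v in parts[1:4]])
        return cls(
            channel_names=tuple(names),
            positions=np.array(rows),
            recording_reference=ref_name,
            reference_position=ref_pos,
            scalp_radius=scalp_radius,
        )


def _fit_sphere_center(points: np.ndarray) -> np.ndarray:
    """Least-squares centre of a sphere through ``points`` (linearized fit)."""
    A = np.c_[2.0 * points, np.ones(len(points))]
    b = (points**2).sum(axis=1)
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    return sol[:3]


def _idealized_1020_directions() -> dict[str, np.ndarray]:
    """Unit directions of the 10-20 labels on a centred sphere.

    Starts from MNE's ``standard_1020`` idealized positions, re-centres
    them on a least-squares sphere, normalizes, and enforces exact
    left-right symmetry (x -> -x) between homologue pairs as well as
    x = 0 on midline sites.
    """
    import warnings

    import mne

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # montage naming deprecations
        std = mne.channels.make_standard_montage("standard_1020")
    pos_map = std.get_positions()["ch_pos"]
    wanted = set(SCALP_CHANNELS) | set(_MIDLINE)
    labels = [name for name in pos_map if name in wanted]
    pts = np.array([pos_map[name] for name in labels])
    center = _fit_sphere_center(pts)
    dirs = {}
    for name, p in zip(labels, pts):
        v = p - center
        dirs[name] = v / np.linalg.norm(v)
    # exact symmetrization
    for name in _MIDLINE:
        v = dirs[name].copy()
        v[0] = 0.0
        dirs[name] = v / np.linalg.norm(v)
    mirror = np.array([-1.0, 1.0, 1.0])
    for left, right in _LR_PAIRS:
        u = dirs[left] + dirs[right] * mirror
        u = u / np.linalg.norm(u)
        dirs[left] = u
        dirs[right] = u * mirror
    return dirs


def build_montage(layout_name: str = "standard-32") -> ElectrodeMontage:
    """Build the named electrode layout.

    Only ``"standard-32"`` is supported: 31 scalp channels of the
    extended 10-20 system plus an EOG channel below the right eye,
    FCz recording reference.  Deterministic for a given layout.
    """
    if layout_name != "standard-32":
        raise ConfigurationError(
            f"unknown montage layout {layout_name!r}; supported: 'standard-32'"
        )
    radius = 0.085
    dirs = _idealized_1020_directions()
    names = SCALP_CHANNELS + (EOG_CHANNEL,)
    positions = np.empty((len(names), 3))
    for i, name in enumerate(SCALP_CHANNELS):
        positions[i] = dirs[name] * radius
    positions[-1] = _EOG_DIRECTION / np.linalg.norm(_EOG_DIRECTION) * radius
    return ElectrodeMontage(
        channel_names=names,
        positions=positions,
        recording_reference="FCz",
        reference_position=dirs["FCz"] * radius,
        eog_channel=EOG_CHANNEL,
        scalp_radius=radius,
    )
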