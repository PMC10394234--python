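"""Run configuration: every pipeline constant as a named, serializable field."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .errors import ConfigurationError


@dataclass
class RunConfig:
    """Workflow configuration with the paradigm's published defaults.

    Round-trips losslessly through YAML.  Unknown keys in a config file
    are rejected with an error naming them.
    """

    # cohort design
    group_sizes: dict = field(default_factory=lambda: {
        "CON": 50, "BS": 74, "UHR&BS": 74, "UHR": 13})
    transition_counts: dict = field(default_factory=lambda: {
        "BS": 3, "UHR&BS": 10, "UHR": 2})
    noise_rms_uv: float = 8.0
    blink_rate_hz: float = 0.1
    measurement_calibrated: bool = True
    # head model
    shell_radii_mm: list = field(default_factory=lambda: [71.0, 79.0, 85.0])
    conductivities: list = field(default_factory=lambda: [0.33, 0.0042, 0.33])
    series_truncation: int = 60
    source_coords_mm: dict = field(default_factory=lambda: {
        "RS1": [-41.0, -26.0, 11.0],
        "RS2": [41.0, -26.0, 11.0],
        "RS3": [0.0, 25.0, 25.0]})
    inverse_ridge: float = 0.0
    # paradigm / preprocessing
    n_stimuli: int = 2400
    soa_ms: int = 500
    filter_low_hz: float = 1.0
    filter_high_hz: float = 20.0
    amplitude_threshold_uv: float = 120.0
    eog_threshold_uv: float = 60.0
    gate_ratio: float = 0.60
    peak_window_ms: list = field(default_factory=lambda: [150.0, 250.0])
    # run control
    master_seed: int = 0
    outdir: str = "mmnpipe-out"

    def design(self):
        from .cohort import CohortDesign

        return CohortDesign(
            group_sizes=dict(self.group_sizes),
            transition_counts=dict(self.transition_counts),
            noise_rms_uv=self.noise_rms_uv,
            blink_rate_hz=self.blink_rate_hz,
            measurement_calibrated=self.measurement_calibrated,
            master_seed=self.master_seed,
        )

    def head_model(self):
        from .forward import HeadModel

        return HeadModel(
            shell_radii=tuple(r / 1000.0 for r in self.shell_radii_mm),
            conductivities=tuple(self.conductivities),
            series_truncation=self.series_truncation,
        )

    def source_coords(self) -> dict:
        return {
            k: tuple(v / 1000.0 for v in xyz)
            for k, xyz in self.source_coords_mm.items()
        }

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(asdict(self), sort_keys=False), encoding="utf-8"
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = sorted(set(raw) - known)
        if unknown:
            raise ConfigurationError(
                f"unknown configuration keys: {', '.join(unknown)}"
            )
        return cls(**raw)
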