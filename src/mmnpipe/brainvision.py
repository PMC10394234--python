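"""BrainVision Core format I/O (.vhdr/.vmrk/.eeg triplets).

Recordings are written as IEEE float-32, multiplexed, µV, with stimulus
markers S1–S4 encoding standard/duration/frequency/intensity events.
Writing is implemented directly (the format's text headers are simple
INI files); reading goes through MNE's BrainVision reader and converts
back into the package's :class:`~mmnpipe.recording.RawRecording`.
"""

from __future__ import annotations

import os
import warnings
from pathlib import Path

import numpy as np

from .errors import FormatError
from .paradigm import MARKER_CODES
from .recording import RawRecording

_KIND_BY_CODE = {v.replace(" ", ""): k for k, v in MARKER_CODES.items()}

_VHDR_TEMPLATE = """\
Brain Vision Data Exchange Header File Version 1.0
; Written by mmnpipe

[Common Infos]
Codepage=UTF-8
DataFile={stem}.eeg
MarkerFile={stem}.vmrk
DataFormat=BINARY
DataOrientation=MULTIPLEXED
NumberOfChannels={n_channels}
SamplingInterval={sampling_interval_us}

[Binary Infos]
BinaryFormat=IEEE_FLOAT_32

[Channel Infos]
{channel_lines}
"""

_VMRK_TEMPLATE = """\
Brain Vision Data Exchange Marker File, Version 1.0

[Common Infos]
Codepage=UTF-8
DataFile={stem}.eeg

[Marker Infos]
Mk1=New Segment,,1,1,0,19700101000000000000
{marker_lines}
"""


def write_brainvision(rec: RawRecording, path: str | os.PathLike) -> Path:
    """Write a recording as a BrainVision triplet; returns the .vhdr path.

    ``path`` may point at the .vhdr file or at the basename without
    extension.
    """
    base = Path(path)
    if base.suffix == ".vhdr":
        base = base.with_suffix("")
    base.parent.mkdir(parents=True, exist_ok=True)
    stem = base.name

    ch_lines = "\n".join(
        f"Ch{i + 1}={name},,1,µV" for i, name in enumerate(rec.channel_names)
    )
    vhdr = _VHDR_TEMPLATE.format(
        stem=stem,
        n_channels=rec.n_channels,
        sampling_interval_us=int(round(1e6 / rec.sfreq)),
        channel_lines=ch_lines,
    )
    base.with_suffix(".vhdr").write_text(vhdr, encoding="utf-8")

    mk_lines = []
    for i, (sample, kind) in enumerate(
        zip(rec.marker_samples, rec.marker_kinds), start=2
    ):
        mk_lines.append(
            f"Mk{i}=Stimulus,{MARKER_CODES[str(kind)]},{int(sample) + 1},1,0"
        )
    vmrk = _VMRK_TEMPLATE.format(stem=stem, marker_lines="\n".join(mk_lines))
    base.with_suffix(".vmrk").write_text(vmrk, encoding="utf-8")

    rec.data.T.astype("<f4").tofile(base.with_suffix(".eeg"))
    return base.with_suffix(".vhdr")


def read_brainvision(path: str | os.PathLike) -> RawRecording:
    """Read a BrainVision triplet into a :class:`RawRecording` (µV).

    Uses MNE's reader; header/data inconsistencies (truncated binary
    file, wrong channel count) raise :class:`FormatError`.
    """
    import mne

    path = Path(path)
    if path.suffix != ".vhdr":
        path = path.with_suffix(".vhdr")
    if not path.exists():
        raise FormatError(f"header file not found: {path}")
    _check_sizes(path)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            raw = mne.io.read_raw_brainvision(path, preload=True, verbose="error")
    except FormatError:
        raise
    except Exception as exc:
        raise FormatError(f"cannot read BrainVision file {path}: {exc}") from exc

    data = raw.get_data() * 1e6  # V -> µV
    samples, kinds = [], []
    for ann in raw.annotations:
        desc = ann["description"]  # e.g. "Stimulus/S  1"
        code = desc.split("/")[-1].replace(" ", "")
        if code in _KIND_BY_CODE:
            samples.append(int(round(ann["onset"] * raw.info["sfreq"])))
            kinds.append(_KIND_BY_CODE[code])
    return RawRecording(
        data=data,
        sfreq=float(raw.info["sfreq"]),
        channel_names=tuple(raw.ch_names),
        marker_samples=np.asarray(samples, dtype=np.int64),
        marker_kinds=np.asarray(kinds, dtype=object),
        subject_id=path.stem,
        reference="FCz",
    )


def _check_sizes(vhdr_path: Path) -> None:
    """Verify that the .eeg payload matches the header geometry."""
    text = vhdr_path.read_text(encoding="utf-8", errors="replace")
    n_ch = fmt = None
    for line in text.splitlines():
        if line.startswith("NumberOfChannels="):
            n_ch = int(line.split("=", 1)[1])
        elif line.startswith("BinaryFormat="):
            fmt = line.split("=", 1)[1].strip()
    if n_ch is None:
        raise FormatError(f"{vhdr_path}: missing NumberOfChannels")
    if fmt != "IEEE_FLOAT_32":
        raise FormatError(f"{vhdr_path}: unsupported binary format {fmt!r}")
    eeg = vhdr_path.with_suffix(".eeg")
    if not eeg.exists():
        raise FormatError(f"data file not found: {eeg}")
    size = eeg.stat().st_size
    frame = 4 * n_ch
    if size == 0 or size % frame != 0:
        raise FormatError(
            f"{eeg}: size {size} is not a multiple of the "
            f"{n_ch}-channel float32 frame"
        )
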