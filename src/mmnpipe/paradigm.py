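"""Constrained pseudo-random auditory oddball stimulus sequence.

One continuous block of 2,400 tones at a fixed 500 ms onset asynchrony:
79 % standards (1000 Hz, 100 ms, 80 dB) and 7 % each of duration
(50 ms), frequency (1200 Hz) and intensity (70 dB) deviants, with at
least two standards between any two deviants and the first two events
forced to standards.  Deviant slots are drawn uniformly at random from
all placements satisfying the gap constraint (a direct combinatorial
bijection, so generation never needs retries), then deviant kinds are
randomly permuted over the chosen slots.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DesignError

SOA_MS = 500
N_EVENTS = 2400
N_STANDARD = 1896
N_PER_DEVIANT = 168
MIN_STANDARD_GAP = 2  # standards required between consecutive deviants

KINDS = ("standard", "duration", "frequency", "intensity")
DEVIANT_KINDS = ("duration", "frequency", "intensity")

#: tone parameters: (frequency Hz, duration ms, level dB SPL)
TONE_PARAMETERS: dict[str, tuple[int, int, int]] = {
    "standard": (1000, 100, 80),
    "duration": (1000, 50, 80),
    "frequency": (1200, 100, 80),
    "intensity": (1000, 100, 70),
}

#: BrainVision marker description per stimulus kind
MARKER_CODES = {"standard": "S  1", "duration": "S  2",
                "frequency": "S  3", "intensity": "S  4"}


@dataclass(frozen=True)
class StimulusEvent:
    kind: str
    onset_ms: int

    @property
    def tone_freq_hz(self) -> int:
        return TONE_PARAMETERS[self.kind][0]

    @property
    def tone_dur_ms(self) -> int:
        return TONE_PARAMETERS[self.kind][1]

    @property
    def tone_level_db(self) -> int:
        return TONE_PARAMETERS[self.kind][2]


@dataclass(frozen=True)
class ParadigmSequence:
    events: tuple[StimulusEvent, ...]
    soa_ms: int = SOA_MS
    seed: int | None = None

    @property
    def kinds(self) -> np.ndarray:
        return np.array([e.kind for e in self.events])

    @property
    def onsets_ms(self) -> np.ndarray:
        return np.array([e.onset_ms for e in self.events])

    def counts(self) -> dict[str, int]:
        kinds = self.kinds
        return {k: int((kinds == k).sum()) for k in KINDS}

    def to_tsv(self) -> str:
        lines = ["kind\tonset_ms"]
        lines += [f"{e.kind}\t{e.onset_ms}" for e in self.events]
        return "\n".join(lines) + "\n"

    @classmethod
    def from_tsv(cls, text: str, seed: int | None = None) -> "ParadigmSequence":
        events = []
        for line in text.strip().splitlines()[1:]:
            kind, onset = line.split("\t")
            events.append(StimulusEvent(kind, int(onset)))
        return cls(events=tuple(events), seed=seed)


def generate_sequence(
    seed: int, avoid_same_kind_succession: bool = False
) -> ParadigmSequence:
    """Generate one oddball block.

    Identical seeds give identical sequences.  With
    ``avoid_same_kind_succession`` the kind assignment is resampled until
    no two consecutive deviants (in deviant order) share a kind — a
    stricter reading of "without recurring order", off by default.
    """
    rng = np.random.default_rng(seed)
    n_dev = 3 * N_PER_DEVIANT
    step = MIN_STANDARD_GAP + 1
    # deviant slot indices: i_1 < ... < i_k in [2, 2399] with gaps >= 3.
    # Bijection: y_j = i_j - 3 (j-1) maps valid placements one-to-one to
    # increasing sequences in [2, hi]; sample y without replacement.
    lo = MIN_STANDARD_GAP
    hi = N_EVENTS - 1 - step * (n_dev - 1)
    if hi < lo + n_dev - 1:
        raise DesignError("gap constraint infeasible for the requested counts")
    y = np.sort(rng.choice(np.arange(lo, hi + 1), size=n_dev, replace=False))
    slots = y + step * np.arange(n_dev)

    if avoid_same_kind_succession:
        labels = _succession_free_labels(rng, n_dev)
    else:
        labels = rng.permutation(np.repeat(DEVIANT_KINDS, N_PER_DEVIANT))

    kinds = np.array(["standard"] * N_EVENTS, dtype=object)
    kinds[slots] = labels
    events = tuple(
        StimulusEvent(kind=str(k), onset_ms=i * SOA_MS)
        for i, k in enumerate(kinds)
    )
    return ParadigmSequence(events=events, seed=seed)


def _succession_free_labels(rng, n_dev: int, max_restarts: int = 1000) -> np.ndarray:
    """Random kind assignment with no two consecutive deviants alike.

    Sequentially draws kinds proportional to their remaining counts,
    excluding the previous kind; restarts on the rare dead end."""
    kinds = np.array(DEVIANT_KINDS, dtype=object)
    for _ in range(max_restarts):
        remaining = np.full(3, N_PER_DEVIANT)
        out: list[str] = []
        prev = -1
        for _ in range(n_dev):
            weights = remaining.astype(float)
            if prev >= 0:
                weights[prev] = 0.0
            total = weights.sum()
            if total == 0:
                break
            prev = int(rng.choice(3, p=weights / total))
            remaining[prev] -= 1
            out.append(kinds[prev])
        if len(out) == n_dev:
            return np.array(out, dtype=object)
    raise DesignError("could not find a succession-free kind assignment")


@dataclass(frozen=True)
class SequenceValidationReport:
    counts_ok: bool
    gap_ok: bool
    onsets_ok: bool
    details: dict[str, str] = field(default_factory=dict)

    @property
    def all_ok(self) -> bool:
        return self.counts_ok and self.gap_ok and self.onsets_ok


def validate_sequence(seq: ParadigmSequence) -> SequenceValidationReport:
    """Check every sequence invariant independently; never raises."""
    details: dict[str, str] = {}
    counts = seq.counts()
    expected = {"standard": N_STANDARD, **{k: N_PER_DEVIANT for k in DEVIANT_KINDS}}
    counts_ok = len(seq.events) == N_EVENTS and counts == expected
    if not counts_ok:
        details["counts"] = f"got {counts} over {len(seq.events)} events"

    kinds = seq.kinds
    dev_idx = np.flatnonzero(kinds != "standard")
    gap_ok = True
    if dev_idx.size and dev_idx[0] < MIN_STANDARD_GAP:
        gap_ok = False
        details["gap"] = f"first deviant at slot {dev_idx[0]}"
    if dev_idx.size > 1 and (np.diff(dev_idx) < MIN_STANDARD_GAP + 1).any():
        gap_ok = False
        details["gap"] = "fewer than 2 standards between deviants"

    onsets = seq.onsets_ms
    onsets_ok = bool(
        len(onsets) > 0
        and onsets[0] == 0
        and (np.diff(onsets) == seq.soa_ms).all()
    )
    if not onsets_ok:
        details["onsets"] = "onsets are not a 0-based lattice at the SOA"
    return SequenceValidationReport(counts_ok, gap_ok, onsets_ok, details)


def to_vmrk_entries(
    seq: ParadigmSequence, sfreq: float, offset_samples: int = 0
) -> list[str]:
    """BrainVision stimulus marker lines for the sequence.

    Marker numbering starts at Mk2 (Mk1 is conventionally the segment
    marker written by the recorder); positions are 1-based samples.
    """
    lines = []
    for i, ev in enumerate(seq.events, start=1):
        sample = int(round(ev.onset_ms * sfreq / 1000.0)) + offset_samples
        lines.append(f"Mk{i + 1}=Stimulus,{MARKER_CODES[ev.kind]},{sample + 1},1,0")
    return lines
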