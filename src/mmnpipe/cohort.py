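"""Synthetic EEG cohort generator.

Generates whole-cohort raw EEG with the statistical structure the
analysis assumes: event-locked regional-source activity whose
deviant-minus-standard MMN component carries group-specific amplitudes,
plus coloured sensor noise and blink artifacts, recorded against an FCz
reference.

Group structure (duration condition, nAm mean ± SD) follows the
published clinical moments: healthy controls keep a strong frontal
(RS3) MMN source (13.95 ± 7.17) while the three risk groups are
markedly reduced there; temporal sources (RS1/RS2) do not differ much
between groups.  Subjects who later transition to psychosis draw their
frontal amplitude from a lower distribution (5.21 ± 2.89 versus
8.29 ± 4.68 for non-transitioning subjects meeting UHR criteria).

Amplitude calibration: the MMN component injected into the recording is
scaled so that its deviant-minus-standard source peak, *as measured by
the standard analysis chain* (1–20 Hz zero-phase band-pass, baseline
correction, 150–250 ms peak window), equals the subject's nominal
amplitude.  The published amplitudes are themselves measurements taken
through such a chain, so the generator treats them as measured units;
the deterministic scale factor is computed from the filter response of
the chain, never fitted to data.  Set ``measurement_calibrated=False``
on the design to inject raw template peaks at nominal amplitude
instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import signal

from .errors import DesignError, DomainError
from .forward import DipoleSource, HeadModel, potentials_at
from .montage import ElectrodeMontage, build_montage
from .paradigm import DEVIANT_KINDS, ParadigmSequence, generate_sequence
from .preprocess import BASELINE_MS, design_bandpass
from .recording import SFREQ, RawRecording

GROUPS = ("CON", "BS", "UHR&BS", "UHR")
RISK_GROUPS = ("BS", "UHR&BS", "UHR")
UHR_CRITERIA_GROUPS = ("UHR&BS", "UHR")
SOURCES = ("RS1", "RS2", "RS3")

#: duration-condition source amplitude moments per group (nAm mean, SD)
GROUP_SOURCE_MOMENTS: dict[str, dict[str, tuple[float, float]]] = {
    "CON":    {"RS1": (14.71, 8.51), "RS2": (13.08, 5.54), "RS3": (13.95, 7.17)},
    "BS":     {"RS1": (14.86, 7.48), "RS2": (13.66, 6.38), "RS3": (7.72, 4.16)},
    "UHR&BS": {"RS1": (16.96, 7.13), "RS2": (15.74, 7.79), "RS3": (8.80, 4.42)},
    "UHR":    {"RS1": (18.33, 8.47), "RS2": (14.56, 9.51), "RS3": (9.23, 5.65)},
}

#: amplitude moments for subjects meeting UHR criteria, split by
#: later transition status (signs restored from the inverse coding of
#: the regression table)
TRANSITION_SOURCE_MOMENTS: dict[bool, dict[str, tuple[float, float]]] = {
    False: {"RS1": (16.62, 7.55), "RS2": (14.38, 7.87), "RS3": (8.29, 4.68)},
    True:  {"RS1": (13.34, 4.92), "RS2": (15.66, 9.20), "RS3": (5.21, 2.89)},
}

#: demographic / clinical covariate moments per group (mean, SD)
COVARIATE_MOMENTS: dict[str, dict[str, tuple[float, float]]] = {
    "CON":    {"age": (21.00, 5.55), "sips_pos": (0.0, 0.0),
               "sips_neg": (0.0, 0.0), "gaf": (85.0, 5.0)},
    "BS":     {"age": (23.11, 5.69), "sips_pos": (4.58, 3.29),
               "sips_neg": (10.46, 5.95), "gaf": (58.92, 14.75)},
    "UHR&BS": {"age": (18.91, 4.86), "sips_pos": (10.86, 3.68),
               "sips_neg": (13.32, 6.01), "gaf": (52.01, 12.19)},
    "UHR":    {"age": (17.15, 3.98), "sips_pos": (10.44, 2.68),
               "sips_neg": (12.46, 6.36), "gaf": (57.67, 10.51)},
}

#: number of male subjects per group (matching the reported counts)
MALE_COUNTS = {"CON": 27, "BS": 46, "UHR&BS": 41, "UHR": 10}

AMPLITUDE_FLOOR_NAM = 0.5

#: fixed dipole orientation of the MMN component per source (unit
#: vectors, head frame).  Inferior-pointing moments produce the classic
#: fronto-central negativity with polarity inversion at the mastoids;
#: the frontal source is tilted posteriorly to load midline frontal
#: channels.
MMN_ORIENTATIONS: dict[str, np.ndarray] = {
    "RS1": np.array([0.0, 0.0, -1.0]),
    "RS2": np.array([0.0, 0.0, -1.0]),
    "RS3": np.array([0.0, -0.5, -0.8660254037844386]),
}

MMN_WIDTH_MS = 100.0  # full width of the raised-cosine MMN bump


@dataclass(frozen=True)
class SubjectProfile:
    """Generative parameters of one simulated subject."""

    subject_id: str
    group: str
    transition: bool
    source_mmn_amp: dict  # condition -> (3,) nAm for RS1/RS2/RS3
    mmn_peak_latency_ms: float
    standard_response_amp: float  # nAm, obligatory auditory response
    noise_rms_uv: float
    blink_rate_hz: float
    age: float
    sex: str
    sips_pos: float
    sips_neg: float
    gaf: float
    seed: int = 0

    def __post_init__(self) -> None:
        for cond, amps in self.source_mmn_amp.items():
            if np.any(np.asarray(amps) <= 0):
                raise DomainError(f"{cond} amplitudes must be positive")
        if not 150.0 <= self.mmn_peak_latency_ms <= 250.0:
            raise DomainError("MMN latency must lie in the 150–250 ms window")


@dataclass(frozen=True)
class CohortDesign:
    """Cohort composition and generative moments."""

    group_sizes: dict = field(default_factory=lambda: dict(
        CON=50, BS=74, **{"UHR&BS": 74}, UHR=13))
    transition_counts: dict = field(default_factory=lambda: dict(
        BS=3, **{"UHR&BS": 10}, UHR=2))
    group_mean_sd: dict = field(
        default_factory=lambda: {g: dict(v) for g, v in GROUP_SOURCE_MOMENTS.items()})
    transition_effect: dict = field(
        default_factory=lambda: {k: dict(v) for k, v in TRANSITION_SOURCE_MOMENTS.items()})
    covariate_moments: dict = field(
        default_factory=lambda: {g: dict(v) for g, v in COVARIATE_MOMENTS.items()})
    noise_rms_uv: float = 8.0
    blink_rate_hz: float = 0.1
    amplitude_floor_nam: float = AMPLITUDE_FLOOR_NAM
    measurement_calibrated: bool = True
    master_seed: int = 0

    def __post_init__(self) -> None:
        for g, n in self.group_sizes.items():
            if n < 0:
                raise DesignError(f"group size of {g} must be >= 0")
        for g, k in self.transition_counts.items():
            if k > self.group_sizes.get(g, 0):
                raise DesignError(
                    f"transition count of {g} exceeds the group size")
        for g, mom in self.group_mean_sd.items():
            for src, (m, sd) in mom.items():
                if sd < 0:
                    raise DesignError(f"SD of {g}/{src} must be >= 0")

    @property
    def n_subjects(self) -> int:
        return sum(self.group_sizes.values())


def default_study_design(master_seed: int = 0) -> CohortDesign:
    """The default cohort: 50 controls and 161 at-risk subjects
    (BS 74, UHR&BS 74, UHR 13) with 3/10/2 transitions."""
    return CohortDesign(master_seed=master_seed)


def _draw_amplitude(rng, mean: float, sd: float, floor: float) -> float:
    """Normal draw winsorized at the positive floor.

    Clipping (rather than resampling) keeps the sample mean within a
    fraction of a percent of the nominal mean for the moments used here.
    """
    return float(np.clip(rng.normal(mean, sd), floor, None))


def sample_profiles(design: CohortDesign, seed: int | None = None) -> list[SubjectProfile]:
    """Draw per-subject generative parameters for the whole cohort.

    Deterministic given the seed (defaults to the design's master seed).
    Group counts and transition counts are matched exactly; amplitudes
    are winsorized-normal draws at the design moments.
    """
    seed = design.master_seed if seed is None else seed
    rng = np.random.default_rng(seed)
    floor = design.amplitude_floor_nam
    for g, mom in design.group_mean_sd.items():
        for src, (m, sd) in mom.items():
            if m <= floor:
                raise DesignError(
                    f"mean amplitude of {g}/{src} ({m}) is at or below the "
                    f"truncation floor ({floor})")
    profiles: list[SubjectProfile] = []
    counter = 0
    for group in GROUPS:
        n = design.group_sizes.get(group, 0)
        n_trans = design.transition_counts.get(group, 0)
        trans_flags = np.zeros(n, dtype=bool)
        if n_trans:
            trans_flags[rng.choice(n, size=n_trans, replace=False)] = True
        n_male = min(MALE_COUNTS.get(group, round(n / 2)), n)
        sexes = np.array(["M"] * n_male + ["F"] * (n - n_male), dtype=object)
        rng.shuffle(sexes)
        cov = design.covariate_moments[group]
        for i in range(n):
            transition = bool(trans_flags[i])
            uhr_criteria = group in UHR_CRITERIA_GROUPS
            amps: dict[str, np.ndarray] = {}
            dur = np.empty(3)
            for k, src in enumerate(SOURCES):
                if group == "CON":
                    m, sd = design.group_mean_sd[group][src]
                elif src == "RS3" and transition:
                    m, sd = design.transition_effect[True][src]
                elif src == "RS3" and uhr_criteria:
                    m, sd = design.transition_effect[False][src]
                elif uhr_criteria:
                    m, sd = design.transition_effect[transition][src]
                else:
                    m, sd = design.group_mean_sd[group][src]
                dur[k] = _draw_amplitude(rng, m, sd, floor)
            amps["duration"] = dur
            # frequency/intensity deviants showed no group structure:
            # default all groups to control-level moments there
            for cond in ("frequency", "intensity"):
                a = np.empty(3)
                for k, src in enumerate(SOURCES):
                    m, sd = design.group_mean_sd["CON"][src]
                    a[k] = _draw_amplitude(rng, m, sd, floor)
                amps[cond] = a
            age_m, age_sd = cov["age"]
            profiles.append(
                SubjectProfile(
                    subject_id=f"S{counter:03d}",
                    group=group,
                    transition=transition,
                    source_mmn_amp=amps,
                    # snapped to the 2 ms sample grid of the recording
                    mmn_peak_latency_ms=float(
                        2.0 * round(np.clip(rng.normal(200.0, 15.0), 160.0, 240.0) / 2.0)),
                    standard_response_amp=float(
                        np.clip(rng.normal(20.0, 4.0), 5.0, None)),
                    noise_rms_uv=design.noise_rms_uv,
                    blink_rate_hz=design.blink_rate_hz,
                    age=float(max(13.0, rng.normal(age_m, age_sd))),
                    sex=str(sexes[i]),
                    sips_pos=float(max(0.0, rng.normal(*cov["sips_pos"]))),
                    sips_neg=float(max(0.0, rng.normal(*cov["sips_neg"]))),
                    gaf=float(np.clip(rng.normal(*cov["gaf"]), 1.0, 100.0)),
                    seed=int(rng.integers(0, 2**31 - 1)),
                )
            )
            counter += 1
    return profiles


def _raised_cosine(t_ms: np.ndarray, center_ms: float, width_ms: float) -> np.ndarray:
    out = np.zeros_like(t_ms)
    m = np.abs(t_ms - center_ms) < width_ms / 2.0
    out[m] = 0.5 * (1.0 + np.cos(2.0 * np.pi * (t_ms[m] - center_ms) / width_ms))
    return out


def _standard_waveform(t_ms: np.ndarray) -> np.ndarray:
    """Unit-peak biphasic obligatory auditory response (N1-like at
    100 ms with a smaller opposite lobe)."""
    return _raised_cosine(t_ms, 100.0, 80.0) - 0.5 * _raised_cosine(t_ms, 190.0, 140.0)


def source_response_templates(
    profile: SubjectProfile, kind: str, sfreq: float = SFREQ
) -> np.ndarray:
    """Source moment time courses for one stimulus kind.

    Returns (3 sources, 3 orientations, samples) nAm on a 0–400 ms
    axis.  Standards evoke the obligatory response at the temporal
    sources only; deviants add a raised-cosine MMN component at all
    three sources whose deviant-minus-standard peak magnitude equals the
    profile amplitude, peaking at the profile latency.
    """
    n_t = int(round(0.4 * sfreq))
    t_ms = np.arange(n_t) * 1000.0 / sfreq
    out = np.zeros((3, 3, n_t))
    std = profile.standard_response_amp * _standard_waveform(t_ms)
    for k, src in enumerate(("RS1", "RS2")):
        out[k] += MMN_ORIENTATIONS[src][:, None] * std[None, :]
    if kind != "standard":
        amps = np.asarray(profile.source_mmn_amp[kind])
        bump = _raised_cosine(t_ms, profile.mmn_peak_latency_ms, MMN_WIDTH_MS)
        for k, src in enumerate(SOURCES):
            out[k] += amps[k] * MMN_ORIENTATIONS[src][:, None] * bump[None, :]
    return out


@lru_cache(maxsize=256)
def measurement_gain(latency_ms: float, sfreq: float = SFREQ,
                     width_ms: float = MMN_WIDTH_MS) -> float:
    """Peak gain of the analysis chain on a unit MMN bump.

    Passes a unit raised-cosine bump at the given post-stimulus latency
    through the 1–20 Hz zero-phase band-pass, epoch baseline correction
    and the 150–250 ms peak search, and returns the measured
    deviant-minus-standard peak.  The standard average is not clean
    either: every deviant is flanked by standards at lags ±1/±2 whose
    baseline-corrected epochs pick up the filter tails of the deviant's
    MMN, and each lag holds exactly (deviants/standards) of the standard
    trials; those four expected contributions are subtracted here.
    Deterministic; used to express generative amplitudes in measured
    units, never fitted to pipeline output.
    """
    from .paradigm import N_PER_DEVIANT, N_STANDARD, SOA_MS

    pad = 2.5  # seconds of context on both sides
    n = int(round((2 * pad + 0.5) * sfreq))
    t_ms = (np.arange(n) - pad * sfreq) * 1000.0 / sfreq  # 0 = stimulus onset
    x = _raised_cosine(t_ms, latency_ms, width_ms)
    y = signal.sosfiltfilt(design_bandpass(sfreq=sfreq), x)
    onset = int(pad * sfreq)
    n_pre = int(round(BASELINE_MS * sfreq / 1000.0))
    n_post = int(0.4 * sfreq)
    soa = int(round(SOA_MS * sfreq / 1000.0))

    def epoch(shift: int) -> np.ndarray:
        s = onset + shift
        ep = y[s - n_pre : s + n_post]
        return ep - ep[:n_pre].mean()

    diff = epoch(0)
    lag_fraction = 3 * N_PER_DEVIANT / N_STANDARD
    for k in (-2, -1, 1, 2):
        diff = diff - lag_fraction * epoch(k * soa)
    tt = (np.arange(diff.size) - n_pre) * 1000.0 / sfreq
    win = (tt >= 150.0) & (tt <= 250.0)
    return float(diff[win].max())


@lru_cache(maxsize=8)
def _smooth_mixing_cached(positions_bytes: bytes, n_ch: int, corr_len: float):
    positions = np.frombuffer(positions_bytes).reshape(n_ch, 3)
    d2 = ((positions[:, None, :] - positions[None, :, :]) ** 2).sum(-1)
    K = np.exp(-d2 / (2.0 * corr_len**2))
    return K / np.linalg.norm(K, axis=1, keepdims=True)


def _smooth_mixing(montage: ElectrodeMontage, corr_len: float = 0.04) -> np.ndarray:
    """Row-normalized smooth spatial mixing kernel (Gaussian in scalp
    distance) turning independent channel streams into spatially
    correlated noise with unit per-channel variance."""
    return _smooth_mixing_cached(
        montage.positions.tobytes(), montage.n_channels, corr_len
    )


@lru_cache(maxsize=8)
def _spatial_color_cached(positions_bytes: bytes, n_ch: int, corr_len: float):
    K = _smooth_mixing_cached(positions_bytes, n_ch, corr_len)
    C = 0.5 * np.eye(n_ch) + 0.5 * (K @ K.T)
    return np.linalg.cholesky(C)


def _spatial_color(montage: ElectrodeMontage, corr_len: float = 0.04) -> np.ndarray:
    """Cholesky factor of the noise spatial covariance
    (half independent, half kernel-smoothed; unit channel variance)."""
    return _spatial_color_cached(
        montage.positions.tobytes(), montage.n_channels, corr_len
    )


def _blink_topography(montage: ElectrodeMontage) -> np.ndarray:
    """Per-channel blink amplitude (µV), FCz-referenced.

    Frontal-dominant positive deflection on the scalp, mirrored with
    opposite sign and larger amplitude on the infraorbital EOG channel.
    """
    toward_eyes = np.array([0.0, 1.0, -0.2])
    toward_eyes /= np.linalg.norm(toward_eyes)
    u = montage.positions / np.linalg.norm(montage.positions, axis=1, keepdims=True)
    w = np.maximum(0.0, u @ toward_eyes)
    topo = 70.0 * w
    topo[montage.index(montage.eog_channel)] = -80.0
    ref_u = montage.reference_position / np.linalg.norm(montage.reference_position)
    topo -= 70.0 * max(0.0, float(ref_u @ toward_eyes))
    return topo


def _shaped_noise(rng, n_rows: int, n_samples: int, sfreq: float) -> tuple[np.ndarray, float]:
    """Rows of unit-variance coloured noise (1/f tilt, 1–45 Hz band).

    Returns the noise and the factor by which the analysis band-pass
    (1–20 Hz zero-phase) would scale its RMS, computed from the filter's
    power response so that callers can calibrate post-filter RMS without
    filtering anything.
    """
    from scipy import fft as sfft

    n_fft = sfft.next_fast_len(n_samples, real=True)
    white = rng.standard_normal((n_rows, n_fft))
    freqs = sfft.rfftfreq(n_fft, 1.0 / sfreq)
    shape = np.zeros_like(freqs)
    band = (freqs >= 0.5) & (freqs <= 45.0)
    shape[band] = 1.0 / np.sqrt(np.maximum(freqs[band], 1.0))
    spec = sfft.rfft(white, axis=1) * shape
    noise = sfft.irfft(spec, n=n_fft, axis=1)[:, :n_samples]
    # Parseval: E[var] per row given unit-variance white input
    w = np.full(freqs.size, 2.0)
    w[0] = 1.0
    if n_fft % 2 == 0:
        w[-1] = 1.0
    var = float((w * shape**2).sum()) / n_fft
    noise /= np.sqrt(var)
    # post-analysis-filter RMS factor (zero-phase -> |H|^2 power gain)
    _, h = signal.sosfreqz(design_bandpass(sfreq=sfreq), worN=freqs * 2 * np.pi / sfreq)
    var_filt = float((w * shape**2 * np.abs(h) ** 4).sum()) / n_samples
    return noise, float(np.sqrt(var_filt / var))


def simulate_subject(
    profile: SubjectProfile,
    seq: ParadigmSequence,
    montage: ElectrodeMontage | None = None,
    head: HeadModel | None = None,
    seed: int | None = None,
    lead_in_s: float = 1.0,
    measurement_calibrated: bool = True,
    _gains: np.ndarray | None = None,
) -> RawRecording:
    """Simulate one raw 32-channel recording (µV, FCz reference).

    recording = lead-field-projected source templates at the event
    onsets + coloured background noise (RMS calibrated so the 1–20 Hz
    band-passed noise has the profile's RMS) + stereotyped blink
    transients (Poisson arrivals, frontal-dominant, mirrored on EOG).
    Deterministic under the seed (defaults to the profile seed).
    """
    montage = montage or build_montage()
    head = head or HeadModel()
    seed = profile.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    sfreq = SFREQ
    gains = _recording_gains(montage, head) if _gains is None else _gains

    lead_in = int(round(lead_in_s * sfreq))
    n_t = int(round(0.4 * sfreq))
    onsets = (seq.onsets_ms * sfreq / 1000.0).round().astype(int) + lead_in
    n_samples = int(onsets[-1] + n_t + lead_in)
    n_ch = montage.n_channels

    cal = 1.0
    if measurement_calibrated:
        cal = 1.0 / measurement_gain(round(profile.mmn_peak_latency_ms, 3), sfreq)

    # per-kind scalp templates (channels x samples), FCz-referenced
    std_tpl = source_response_templates(profile, "standard", sfreq)
    scalp: dict[str, np.ndarray] = {}
    for kind in ("standard",) + DEVIANT_KINDS:
        tpl = source_response_templates(profile, kind, sfreq)
        mmn_part = tpl - std_tpl  # zero for standards
        moments = (std_tpl + cal * mmn_part).reshape(9, n_t)
        scalp[kind] = gains @ moments

    data = np.zeros((n_ch, n_samples))
    for onset, kind in zip(onsets, seq.kinds):
        data[:, onset : onset + n_t] += scalp[kind]

    if profile.noise_rms_uv > 0:
        noise, filt_factor = _shaped_noise(rng, n_ch, n_samples, sfreq)
        # half the variance is spatially correlated: independent channel
        # streams mixed through a smooth spatial kernel over the cap,
        # emulating volume-conducted background activity (applied via the
        # Cholesky factor of the mixed covariance)
        L = _spatial_color(montage)
        target_raw_rms = profile.noise_rms_uv / filt_factor
        data += target_raw_rms * (L @ noise)

    if profile.blink_rate_hz > 0:
        duration_s = n_samples / sfreq
        n_blinks = rng.poisson(profile.blink_rate_hz * duration_s)
        blink_len = int(round(0.4 * sfreq))
        t_ms = np.arange(blink_len) * 1000.0 / sfreq
        blink_wave = _raised_cosine(t_ms, 200.0, 400.0)
        topo = _blink_topography(montage)
        starts = rng.integers(0, n_samples - blink_len, size=n_blinks)
        for s in np.sort(starts):
            data[:, s : s + blink_len] += topo[:, None] * blink_wave[None, :]

    return RawRecording(
        data=data,
        sfreq=sfreq,
        channel_names=montage.channel_names,
        marker_samples=onsets,
        marker_kinds=seq.kinds,
        montage=montage,
        subject_id=profile.subject_id,
        reference=montage.recording_reference,
        meta={"seed": seed, "group": profile.group},
    )


def _recording_gains(montage: ElectrodeMontage, head: HeadModel) -> np.ndarray:
    """Lead field (channels x 9, µV/nAm) in the FCz recording reference."""
    from .inverse import DEFAULT_SOURCE_COORDS

    sites = np.vstack([montage.positions, montage.reference_position])
    cols = []
    for loc in DEFAULT_SOURCE_COORDS.values():
        for ori in np.eye(3):
            v = potentials_at(head, DipoleSource(np.asarray(loc), ori), sites)
            cols.append(v[:-1] - v[-1])
    return np.column_stack(cols)


def simulate_cohort(
    design: CohortDesign,
    montage: ElectrodeMontage | None = None,
    head: HeadModel | None = None,
):
    """Simulate a whole cohort, streaming one recording at a time.

    Returns ``(profiles, recordings, metadata)``: the subject profiles,
    a generator yielding one :class:`RawRecording` per subject (in
    profile order, so recordings never need to be held simultaneously),
    and the cohort metadata table.
    """
    montage = montage or build_montage()
    head = head or HeadModel()
    profiles = sample_profiles(design)
    gains = _recording_gains(montage, head)
    seq_seeds = np.random.default_rng(design.master_seed + 1).integers(
        0, 2**31 - 1, size=len(profiles))

    def recordings():
        for p, s in zip(profiles, seq_seeds):
            seq = generate_sequence(int(s))
            yield simulate_subject(
                p, seq, montage, head,
                measurement_calibrated=design.measurement_calibrated,
                _gains=gains,
            )

    metadata = cohort_metadata(profiles)
    return profiles, recordings(), metadata


def cohort_metadata(profiles: list[SubjectProfile]) -> pd.DataFrame:
    rows = []
    for p in profiles:
        rows.append(
            {
                "subject_id": p.subject_id,
                "group": p.group,
                "transition": p.transition,
                "age": p.age,
                "sex": p.sex,
                "sips_pos": p.sips_pos,
                "sips_neg": p.sips_neg,
                "gaf": p.gaf,
                "seed": p.seed,
                "true_rs1_duration": p.source_mmn_amp["duration"][0],
                "true_rs2_duration": p.source_mmn_amp["duration"][1],
                "true_rs3_duration": p.source_mmn_amp["duration"][2],
            }
        )
    return pd.DataFrame(rows)
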