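import numpy as np
import pytest
from scipy import signal

from mmnpipe.errors import ConfigurationError, DomainError
from mmnpipe.montage import build_montage
from mmnpipe.preprocess import (
    EpochSet,
    average_by_condition,
    bandpass,
    design_bandpass,
    reject_artifacts,
    rereference_average,
    segment,
    subject_gate,
)
from mmnpipe.recording import RawRecording


def make_raw(data, markers=(), kinds=(), montage=None):
    montage = montage or build_montage()
    return RawRecording(
        data=data,
        sfreq=500.0,
        channel_names=montage.channel_names,
        marker_samples=np.asarray(markers, dtype=np.int64),
        marker_kinds=np.asarray(kinds, dtype=object),
        montage=montage,
    )


def make_epochs(trials, labels, accepted=None, reasons=None):
    """Hand-built EpochSet on the standard −100…398 ms axis."""
    trials = np.asarray(trials, float)
    n = trials.shape[0]
    montage = build_montage()
    return EpochSet(
        trials=trials,
        condition_labels=np.asarray(labels, dtype=object),
        time_ms=(np.arange(250) - 50) * 2.0,
        accepted=np.ones(n, bool) if accepted is None else np.asarray(accepted),
        rejection_reason=(
            np.full(n, "none", dtype=object) if reasons is None
            else np.asarray(reasons, dtype=object)
        ),
        channel_names=montage.channel_names,
    )


class TestRereference:
    def test_three_channel_arithmetic(self):
        mont = build_montage()
        data = np.zeros((32, 1500))
        data[0], data[1], data[2] = 1.0, 2.0, 3.0
        raw = make_raw(data)
        out = rereference_average(raw)
        mean = (1.0 + 2.0 + 3.0) / 31  # other EEG channels are zero
        assert np.allclose(out.data[0], 1.0 - mean)
        assert np.allclose(out.data[1], 2.0 - mean)
        assert np.allclose(out.data[2], 3.0 - mean)

    def test_zero_mean_and_idempotence(self):
        rng = np.random.default_rng(0)
        raw = make_raw(rng.normal(size=(32, 2000)))
        once = rereference_average(raw)
        eeg = once.data[once.eeg_mask]
        assert np.abs(eeg.mean(axis=0)).max() < 1e-9
        twice = rereference_average(once)
        assert np.abs(twice.data - once.data).max() < 1e-9

    def test_common_offset_removed(self):
        rng = np.random.default_rng(1)
        base = rng.normal(size=(32, 1000))
        raw_a = make_raw(base)
        raw_b = make_raw(base + 42.0)
        a = rereference_average(raw_a)
        b = rereference_average(raw_b)
        eeg = a.eeg_mask
        assert np.allclose(a.data[eeg], b.data[eeg], atol=1e-9)

    def test_eog_excluded_from_reference(self):
        mont = build_montage()
        data = np.zeros((32, 100))
        data[mont.index("EOG")] = 100.0  # huge EOG must not shift EEG
        out = rereference_average(make_raw(data))
        assert np.allclose(out.data[out.eeg_mask], 0.0)


class TestBandpass:
    def test_frequency_response(self):
        sos = design_bandpass(1.0, 20.0, 500.0)
        w, h = signal.sosfreqz(sos, worN=[10.0, 100.0], fs=500.0)
        # zero-phase application squares the magnitude response
        assert np.abs(h[0]) ** 2 >= 0.9
        assert -20 * np.log10(np.abs(h[1]) ** 2) >= 20.0

    def test_invalid_cutoffs(self):
        with pytest.raises(ConfigurationError):
            design_bandpass(1.0, 300.0, 500.0)
        with pytest.raises(ConfigurationError):
            design_bandpass(30.0, 20.0, 500.0)

    def test_dc_removed_and_tone_preserved(self):
        t = np.arange(10_000) / 500.0
        tone = np.sin(2 * np.pi * 10.0 * t)
        data = np.tile(5.0 + tone, (32, 1))
        out = bandpass(make_raw(data))
        mid = out.data[0, 2000:8000]
        assert abs(mid.mean()) < 0.01
        amp = np.abs(mid).max()
        assert 0.9 <= amp <= 1.1

    def test_high_frequency_power_suppressed(self):
        rng = np.random.default_rng(2)
        data = rng.normal(size=(32, 20_000))
        out = bandpass(make_raw(data))
        f, pxx = signal.periodogram(out.data[5], fs=500.0)
        assert pxx[f > 40].sum() / pxx.sum() < 0.01


class TestSegment:
    def test_epoch_geometry(self):
        rng = np.random.default_rng(3)
        markers = np.arange(100, 4100, 250)
        raw = make_raw(rng.normal(size=(32, 4600)), markers,
                       ["standard"] * len(markers))
        ep = segment(raw)
        assert ep.trials.shape == (len(markers), 32, 250)
        assert ep.time_ms[0] == -100.0 and ep.time_ms[-1] == 398.0
        assert ep.accepted.all()
        # baseline mean is zero per channel and trial
        base = ep.trials[:, :, :50].mean(axis=2)
        assert np.abs(base).max() < 1e-12

    def test_constant_channel_becomes_zero(self):
        data = np.full((32, 2000), 7.0)
        raw = make_raw(data, [500, 900], ["standard", "duration"])
        ep = segment(raw)
        assert np.abs(ep.trials).max() < 1e-12

    def test_edge_markers_flagged_not_dropped(self):
        rng = np.random.default_rng(4)
        raw = make_raw(rng.normal(size=(32, 1000)), [20, 500],
                       ["standard", "standard"])
        ep = segment(raw)
        assert ep.n_trials == 2
        assert list(ep.accepted) == [False, True]
        assert list(ep.rejection_reason) == ["edge", "none"]


class TestRejection:
    def test_amplitude_threshold_boundaries(self):
        trials = np.zeros((3, 32, 250))
        trials[0, 4, 120] = 130.0  # over on an EEG channel
        trials[1, 4, 120] = 119.0  # under
        trials[2, 4, 120] = -130.0  # negative excursions count too
        ep = reject_artifacts(make_epochs(trials, ["standard"] * 3))
        assert list(ep.accepted) == [False, True, False]
        assert ep.rejection_reason[0] == "amplitude"
        assert ep.rejection_reason[1] == "none"

    def test_eog_blink_rejected(self):
        mont = build_montage()
        trials = np.zeros((2, 32, 250))
        eog = mont.index("EOG")
        trials[0, eog, 100:150] = 80.0  # 80 µV peak-to-peak blink
        trials[1, eog, 100:150] = 20.0
        ep = reject_artifacts(make_epochs(trials, ["standard"] * 2))
        assert list(ep.accepted) == [False, True]
        assert ep.rejection_reason[0] == "eog"

    def test_big_eog_alone_does_not_trip_amplitude_rule(self):
        mont = build_montage()
        trials = np.zeros((1, 32, 250))
        trials[0, mont.index("EOG"), :] = 200.0  # constant: no p-p, not EEG
        ep = reject_artifacts(make_epochs(trials, ["standard"]))
        assert ep.accepted[0]

    def test_idempotent_and_preserves_edge(self):
        trials = np.zeros((2, 32, 250))
        trials[0, 0, 0] = 500.0
        ep0 = make_epochs(trials, ["standard"] * 2,
                          accepted=[False, False], reasons=["edge", "edge"])
        ep1 = reject_artifacts(ep0)
        ep2 = reject_artifacts(ep1)
        assert list(ep1.rejection_reason) == ["edge", "edge"]
        assert list(ep1.accepted) == list(ep2.accepted)
        assert list(ep1.rejection_reason) == list(ep2.rejection_reason)

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(5)
        trials = rng.normal(0, 50, size=(40, 32, 250))
        ep = make_epochs(trials, ["standard"] * 40)
        accepted = [
            reject_artifacts(ep, amplitude_threshold_uv=th).accepted.sum()
            for th in (200.0, 150.0, 120.0, 90.0, 60.0)
        ]
        assert all(a >= b for a, b in zip(accepted, accepted[1:]))


class TestGate:
    @pytest.mark.parametrize(
        "n_accepted,included", [(1440, True), (1439, False), (2400, True)]
    )
    def test_sixty_percent_boundary(self, n_accepted, included):
        trials = np.zeros((2400, 2, 250))
        accepted = np.zeros(2400, bool)
        accepted[:n_accepted] = True
        mont = build_montage()
        ep = EpochSet(
            trials=trials,
            condition_labels=np.full(2400, "standard", dtype=object),
            time_ms=(np.arange(250) - 50) * 2.0,
            accepted=accepted,
            rejection_reason=np.full(2400, "none", dtype=object),
            channel_names=mont.channel_names[:2],
        )
        gate = subject_gate(ep)
        assert gate.included is included
        assert gate.acceptance_ratio == pytest.approx(n_accepted / 2400)

    def test_zero_trials_error(self):
        ep = make_epochs(np.zeros((0, 32, 250)), [])
        with pytest.raises(DomainError):
            subject_gate(ep)


class TestAveraging:
    def test_mean_over_accepted_only(self):
        rng = np.random.default_rng(6)
        trials = rng.normal(size=(10, 32, 250))
        labels = ["standard"] * 6 + ["duration"] * 4
        accepted = np.array([True] * 5 + [False] + [True, True, False, True])
        ep = make_epochs(trials, labels, accepted=accepted)
        ev = average_by_condition(ep)
        # brute force: mean over the accepted subset only
        want_std = trials[:5].mean(axis=0)
        want_dev = trials[[6, 7, 9]].mean(axis=0)
        assert np.allclose(ev["standard"].mean_waveform, want_std)
        assert np.allclose(ev["duration"].mean_waveform, want_dev)
        assert ev["standard"].n_trials_accepted == 5
        assert ev["duration"].n_trials_accepted == 3

    def test_symmetric_trials_average_to_zero(self):
        w = np.random.default_rng(7).normal(size=(32, 250))
        ep = make_epochs(np.stack([w, -w]), ["standard", "standard"])
        ev = average_by_condition(ep)
        assert np.abs(ev["standard"].mean_waveform).max() < 1e-12

    def test_order_invariance(self):
        rng = np.random.default_rng(8)
        trials = rng.normal(size=(12, 32, 250))
        labels = np.array(["standard", "duration"] * 6, dtype=object)
        ep = make_epochs(trials, labels)
        ev1 = average_by_condition(ep)
        perm = rng.permutation(12)
        ep2 = make_epochs(trials[perm], labels[perm])
        ev2 = average_by_condition(reject_artifacts(ep2))
        for k in ev1:
            assert np.allclose(ev1[k].mean_waveform, ev2[k].mean_waveform)

    def test_empty_condition_raises(self):
        trials = np.zeros((4, 32, 250))
        labels = ["standard"] * 2 + ["duration"] * 2
        accepted = [True, True, False, False]
        ep = make_epochs(trials, labels, accepted=accepted)
        with pytest.raises(DomainError, match="duration"):
            average_by_condition(ep)
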