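from dataclasses import replace

import numpy as np
import pytest

from mmnpipe.cohort import (
    CohortDesign,
    GROUP_SOURCE_MOMENTS,
    MMN_ORIENTATIONS,
    SOURCES,
    cohort_metadata,
    default_study_design,
    measurement_gain,
    sample_profiles,
    simulate_cohort,
    simulate_subject,
    source_response_templates,
)
from mmnpipe.errors import DesignError
from mmnpipe.paradigm import generate_sequence


class TestDesign:
    def test_default_counts_match_study(self, design):
        assert design.group_sizes == {"CON": 50, "BS": 74, "UHR&BS": 74, "UHR": 13}
        at_risk = sum(v for k, v in design.group_sizes.items() if k != "CON")
        assert at_risk == 161
        assert sum(design.transition_counts.values()) == 15
        assert design.n_subjects == 211

    def test_default_moments(self, design):
        assert design.group_mean_sd["CON"]["RS3"] == (13.95, 7.17)
        assert design.group_mean_sd["BS"]["RS3"] == (7.72, 4.16)
        assert design.group_mean_sd["UHR&BS"]["RS3"] == (8.80, 4.42)
        assert design.group_mean_sd["UHR"]["RS3"] == (9.23, 5.65)
        assert design.transition_effect[True]["RS3"] == (5.21, 2.89)
        assert design.transition_effect[False]["RS3"] == (8.29, 4.68)

    def test_invalid_designs_rejected(self):
        with pytest.raises(DesignError):
            CohortDesign(group_sizes={"CON": -1})
        with pytest.raises(DesignError):
            CohortDesign(transition_counts={"BS": 99})


class TestProfiles:
    def test_counts_and_transitions(self, design):
        profiles = sample_profiles(design)
        assert len(profiles) == 211
        at_risk = [p for p in profiles if p.group != "CON"]
        assert len(at_risk) == 161
        assert sum(p.transition for p in profiles) == 15
        assert sum(p.transition for p in profiles if p.group == "UHR&BS") == 10
        meta = cohort_metadata(profiles)
        assert meta.transition.sum() == 15
        assert meta.groupby("group").size().to_dict() == design.group_sizes

    def test_reproducible_under_seed(self, design):
        a = sample_profiles(design, seed=5)
        b = sample_profiles(design, seed=5)
        c = sample_profiles(design, seed=6)
        amps = lambda ps: np.array([p.source_mmn_amp["duration"] for p in ps])
        assert np.array_equal(amps(a), amps(b))
        assert [p.seed for p in a] == [p.seed for p in b]
        assert not np.array_equal(amps(a), amps(c))

    def test_degenerate_zero_sd(self):
        moments = {g: {s: (10.0, 0.0) for s in SOURCES}
                   for g in GROUP_SOURCE_MOMENTS}
        design = CohortDesign(
            group_sizes={"CON": 5, "BS": 0, "UHR&BS": 0, "UHR": 0},
            transition_counts={},
            group_mean_sd=moments,
        )
        for p in sample_profiles(design, seed=0):
            assert np.allclose(p.source_mmn_amp["duration"], 10.0)

    def test_large_sample_mean_recovers_moments(self):
        """Winsorized-normal draws keep the sample mean within 2 % of
        the nominal control frontal-source mean."""
        design = CohortDesign(
            group_sizes={"CON": 10_000, "BS": 0, "UHR&BS": 0, "UHR": 0},
            transition_counts={},
        )
        profiles = sample_profiles(design, seed=1)
        rs3 = np.array([p.source_mmn_amp["duration"][2] for p in profiles])
        assert abs(rs3.mean() - 13.95) / 13.95 < 0.02

    def test_floor_infeasibility(self):
        moments = {g: {s: (0.4, 0.01) for s in SOURCES}
                   for g in GROUP_SOURCE_MOMENTS}
        design = CohortDesign(group_mean_sd=moments)
        with pytest.raises(DesignError):
            sample_profiles(design)

    def test_latency_within_window(self, design):
        for p in sample_profiles(design)[:50]:
            assert 150.0 <= p.mmn_peak_latency_ms <= 250.0


class TestTemplates:
    def profile(self, design):
        return sample_profiles(design)[0]

    def test_standard_has_no_frontal_component(self, design):
        tpl = source_response_templates(self.profile(design), "standard")
        assert np.abs(tpl[2]).max() == 0.0  # RS3 silent for standards
        assert np.abs(tpl[0]).max() > 0.0  # temporal sources respond

    def test_deviant_minus_standard_peak_calibration(self, design):
        p = self.profile(design)
        std = source_response_templates(p, "standard")
        for kind in ("duration", "frequency", "intensity"):
            dev = source_response_templates(p, kind)
            mmn = dev - std
            mag = np.linalg.norm(mmn, axis=1)  # source x time
            t_ms = np.arange(mag.shape[1]) * 2.0
            for k in range(3):
                peak = mag[k].max()
                assert peak == pytest.approx(p.source_mmn_amp[kind][k], abs=1e-12)
                assert t_ms[np.argmax(mag[k])] == pytest.approx(
                    p.mmn_peak_latency_ms, abs=1.0)

    def test_support_confined_to_epoch(self, design):
        tpl = source_response_templates(self.profile(design), "duration")
        assert tpl.shape[-1] == 200  # 0..398 ms at 500 Hz

    def test_orientations_unit_norm(self):
        for v in MMN_ORIENTATIONS.values():
            assert np.linalg.norm(v) == pytest.approx(1.0, abs=1e-12)


class TestMeasurementGain:
    def test_gain_below_unity_and_smooth(self):
        g200 = measurement_gain(200.0)
        g220 = measurement_gain(220.0)
        assert 0.8 < g200 < 1.0
        assert 0.8 < g220 < 1.0
        assert abs(g200 - g220) < 0.05


class TestSimulateSubject:
    def test_markers_and_determinism(self, design, montage, head):
        p = sample_profiles(design)[3]
        seq = generate_sequence(0)
        a = simulate_subject(p, seq, montage, head, seed=11)
        b = simulate_subject(p, seq, montage, head, seed=11)
        assert len(a.marker_samples) == 2400
        assert np.array_equal(a.data, b.data)
        c = simulate_subject(p, seq, montage, head, seed=12)
        assert not np.array_equal(a.data, c.data)

    def test_noiseless_projection_roundtrip(self, design, montage, head):
        """With zero noise/blinks and no measurement calibration, epochs
        at deviant onsets minus the standard projection reproduce the
        projected MMN template to 1e-9 µV."""
        from mmnpipe.cohort import _recording_gains

        p = replace(sample_profiles(design)[0], noise_rms_uv=0.0,
                    blink_rate_hz=0.0)
        seq = generate_sequence(1)
        raw = simulate_subject(p, seq, montage, head,
                               measurement_calibrated=False)
        gains = _recording_gains(montage, head)
        std = source_response_templates(p, "standard")
        dev = source_response_templates(p, "duration")
        want = gains @ (dev - std).reshape(9, -1)
        kinds = raw.marker_kinds
        dev_onsets = raw.marker_samples[kinds == "duration"]
        std_proj = gains @ std.reshape(9, -1)
        for onset in dev_onsets[:5]:
            got = raw.data[:, onset : onset + 200] - std_proj
            assert np.abs(got - want).max() < 1e-9

    def test_monotone_scalp_response_in_rs3(self, design, montage, head):
        """Raising the frontal amplitude strictly raises the noiseless
        frontal-channel MMN magnitude."""
        from mmnpipe.cohort import _recording_gains

        base = sample_profiles(design)[0]
        gains = _recording_gains(montage, head)
        fz = montage.index("Fz")
        mags = []
        for amp in (5.0, 10.0, 20.0):
            amps = dict(base.source_mmn_amp)
            amps["duration"] = np.array([10.0, 10.0, amp])
            p = replace(base, source_mmn_amp=amps, noise_rms_uv=0.0,
                        blink_rate_hz=0.0)
            std = source_response_templates(p, "standard")
            dev = source_response_templates(p, "duration")
            scalp = gains @ (dev - std).reshape(9, -1)
            mags.append(np.abs(scalp[fz]).max())
        assert mags[0] < mags[1] < mags[2]

    def test_noise_rms_calibration(self, design, montage, head):
        """In-band noise RMS lands near the configured 8 µV."""
        from mmnpipe.preprocess import bandpass

        p = replace(sample_profiles(design)[0], blink_rate_hz=0.0)
        amps = {k: np.array([1e-6, 1e-6, 1e-6]) for k in p.source_mmn_amp}
        p = replace(p, source_mmn_amp=amps, standard_response_amp=1e-6)
        seq = generate_sequence(2)
        raw = simulate_subject(p, seq, montage, head, seed=0)
        filt = bandpass(raw)
        rms = filt.data[:, 5000:-5000].std(axis=1)
        assert abs(np.median(rms) - 8.0) / 8.0 < 0.05


class TestSimulateCohort:
    def test_streaming_and_metadata(self, montage, head):
        design = CohortDesign(
            group_sizes={"CON": 2, "BS": 1, "UHR&BS": 1, "UHR": 0},
            transition_counts={"UHR&BS": 1},
            master_seed=3,
        )
        profiles, recordings, meta = simulate_cohort(design, montage, head)
        assert len(profiles) == 4
        assert len(meta) == 4
        first = next(recordings)
        assert first.subject_id == profiles[0].subject_id
        assert first.data.shape[0] == 32
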