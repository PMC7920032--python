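"""Synthetic recording generator: construction contracts, determinism,
murmur confinement / calibration, and the ground-truth SNR oracle."""

import logging

import numpy as np
import pytest
from scipy.signal import hilbert, periodogram

import neopcg as n
from neopcg import SimConfig, levine_to_ratio


def oracle_snr_sys(truth):
    """Ground-truth systole/diastole SNR from the component tracks:
    envelope of the pure murmur track over true systole vs envelope of
    the noise track over true diastole (the noise-free murmur/floor
    ratio the generator calibrates)."""
    env_sig = np.abs(hilbert(truth.murmur_track))
    env_noise = np.abs(hilbert(truth.noise_track))
    sys_samples = np.concatenate(
        [env_sig[a:b] for a, b in truth.phase_sample_intervals("SYS")])
    dia_samples = np.concatenate(
        [env_noise[a:b] for a, b in truth.phase_sample_intervals("DIA")])
    return 20 * np.log10(sys_samples.mean() / dia_samples.mean())


class TestConfig:
    def test_nyquist_guard(self):
        with pytest.raises(ValueError):
            SimConfig(murmur_band=(60.0, 2100.0))

    def test_negative_ratio_and_bad_attenuation(self):
        with pytest.raises(ValueError):
            SimConfig(murmur_ratio=-1)
        with pytest.raises(ValueError):
            SimConfig(ps_attenuation=0.0)
        with pytest.raises(ValueError):
            SimConfig(ps_attenuation=1.5)

    def test_noise_floor_must_be_positive(self):
        with pytest.raises(ValueError):
            SimConfig(broadband_noise_amplitude=0.0)

    def test_levine_mapping_doubles_per_grade(self):
        assert levine_to_ratio(0) == 0.0
        assert levine_to_ratio(2) == 4.0
        assert levine_to_ratio(3) == 8.0
        assert levine_to_ratio(4) == 2 * levine_to_ratio(3)
        cfg = SimConfig.from_levine(2)
        assert cfg.murmur_ratio == 4.0


class TestEcg:
    def test_beat_count_at_fixed_rate(self):
        cfg = SimConfig(duration=30.0, heart_rate=140.0, rr_jitter=0.0)
        _, r = n.simulate_ecg(cfg)
        assert abs(len(r) - 70) <= 1

    def test_seeded_determinism(self):
        cfg = SimConfig(seed=42)
        s1, r1 = n.simulate_ecg(cfg)
        s2, r2 = n.simulate_ecg(cfg)
        assert np.array_equal(s1, s2) and np.array_equal(r1, r2)

    def test_zero_jitter_gives_constant_rr(self):
        cfg = SimConfig(rr_jitter=0.0)
        _, r = n.simulate_ecg(cfg)
        rr = np.diff(r)
        assert np.max(np.abs(rr - 60.0 / 140.0)) < 1.0 / cfg.sampling_rate

    def test_too_short_duration_errors(self):
        with pytest.raises(ValueError):
            n.simulate_ecg(SimConfig(duration=0.3))


class TestHeartSounds:
    def test_no_murmur_means_silent_systole(self):
        cfg = SimConfig(murmur_ratio=0.0)
        _, r = n.simulate_ecg(cfg)
        clean, truth = n.simulate_heart_sounds(cfg, r)
        assert np.all(truth.murmur_track == 0)
        for a, b in truth.phase_sample_intervals("SYS"):
            assert np.all(clean[a:b] == 0)

    def test_phase_order_within_each_beat(self, murmur_recording):
        for beat in murmur_recording.ground_truth.phase_intervals:
            assert beat.s1[1] <= beat.systole[0]
            assert beat.systole[1] <= beat.s2[0]
            assert beat.s2[1] <= beat.diastole[0]

    def test_phases_tile_between_consecutive_s1_onsets(self, murmur_recording):
        beats = murmur_recording.ground_truth.phase_intervals
        for prev, nxt in zip(beats, beats[1:]):
            assert prev.diastole[1] == pytest.approx(nxt.s1[0], abs=1e-9)

    @pytest.mark.parametrize("ratio", [2.0, 5.0, 10.0])
    def test_truth_oracle_snr_matches_nominal(self, ratio):
        cfg = SimConfig(seed=21, murmur_ratio=ratio)
        rec = n.simulate_recording(cfg, group="CHD")
        snr = oracle_snr_sys(rec.ground_truth)
        assert snr == pytest.approx(20 * np.log10(ratio), abs=1.0)

    def test_murmur_band_outside_nyquist_errors(self):
        cfg = SimConfig()
        _, r = n.simulate_ecg(cfg)
        object.__setattr__(cfg, "murmur_band", (60.0, 2500.0))
        with pytest.raises(ValueError):
            n.simulate_heart_sounds(cfg, r)


class TestRecording:
    def test_channel_lengths(self, murmur_recording):
        cfg = murmur_recording.config
        expected = round(cfg.duration * cfg.sampling_rate)
        for x in murmur_recording.channels.values():
            assert len(x) == expected

    def test_ps_equals_steth_up_to_lowpass_when_not_attenuated(self):
        cfg = SimConfig(seed=2, ps_attenuation=1.0, motion_noise_amplitude=0.0)
        rec = n.simulate_recording(cfg)
        from neopcg import lowpass
        # channels share the clean PCG; with unit gain and no motion
        # noise they differ only by the 1 kHz low-pass and by their
        # independent broadband noise realizations
        clean = rec.ground_truth.s1_track + rec.ground_truth.s2_track
        steth_noise = rec.channels["stethoscope"] - clean
        assert np.allclose(steth_noise.std(), cfg.broadband_noise_amplitude, rtol=0.1)
        recon = lowpass(clean, cfg.sampling_rate, 1000.0).samples
        resid = rec.channels["ps"] - recon
        assert resid.std() < 1.5 * cfg.broadband_noise_amplitude

    def test_control_group_forces_zero_murmur(self, caplog):
        cfg = SimConfig(seed=3, murmur_ratio=6.0)
        with caplog.at_level(logging.WARNING, logger="neopcg.simulate"):
            rec = n.simulate_recording(cfg, group="control")
        assert rec.ground_truth.true_murmur_ratio == 0.0
        assert any("overriding murmur_ratio" in m for m in caplog.messages)

    def test_bitwise_determinism(self):
        cfg = SimConfig(seed=9, murmur_ratio=4.0)
        r1 = n.simulate_recording(cfg, group="CHD")
        r2 = n.simulate_recording(cfg, group="CHD")
        for name in r1.channels:
            assert np.array_equal(r1.channels[name], r2.channels[name])

    def test_murmur_energy_confined_to_systole(self, murmur_recording):
        truth = murmur_recording.ground_truth
        mask = np.zeros(len(truth.murmur_track), dtype=bool)
        for a, b in truth.phase_sample_intervals("SYS"):
            mask[a:b] = True
        assert np.all(truth.murmur_track[~mask] == 0)

    def test_murmur_spectrally_confined(self, murmur_recording):
        truth = murmur_recording.ground_truth
        cfg = murmur_recording.config
        f, p = periodogram(truth.murmur_track, fs=cfg.sampling_rate)
        lo, hi = cfg.murmur_band
        in_band = p[(f >= lo) & (f <= hi)].sum() / p.sum()
        assert in_band >= 0.95

    @pytest.mark.parametrize("ratio", [1.0, 4.0, 12.0])
    def test_envelope_calibration(self, ratio):
        rec = n.simulate_recording(SimConfig(seed=17, murmur_ratio=ratio), group="CHD")
        truth = rec.ground_truth
        em = np.abs(hilbert(truth.murmur_track))
        en = np.abs(hilbert(truth.noise_track))
        m = np.concatenate([em[a:b] for a, b in truth.phase_sample_intervals("SYS")]).mean()
        d = np.concatenate([en[a:b] for a, b in truth.phase_sample_intervals("DIA")]).mean()
        assert m / d == pytest.approx(ratio, rel=0.10)


class TestCohort:
    def test_cohort_composition(self):
        recs = n.simulate_cohort(9, 9, seed=1)
        assert len(recs) == 18
        assert sum(r.group == "CHD" for r in recs) == 9
        assert sum(r.group == "control" for r in recs) == 9

    def test_controls_have_no_murmur(self, small_cohort):
        for rec in small_cohort:
            if rec.group == "control":
                assert rec.ground_truth.true_murmur_ratio == 0.0

    def test_cohort_determinism(self):
        a = n.simulate_cohort(2, 2, seed=4)
        b = n.simulate_cohort(2, 2, seed=4)
        for ra, rb in zip(a, b):
            assert ra.subject_id == rb.subject_id
            for name in ra.channels:
                assert np.array_equal(ra.channels[name], rb.channels[name])

    def test_empty_range_errors(self):
        with pytest.raises(ValueError):
            n.simulate_cohort(2, 2, murmur_ratio_range=(5.0, 5.0), seed=0)
        with pytest.raises(ValueError):
            n.simulate_cohort(0, 2, seed=0)
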