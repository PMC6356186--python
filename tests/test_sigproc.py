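"""Beat detection, interval filtering, quality gating, ensembles, fiducials."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from seatvitals import (
    Artifact,
    BeatSeries,
    EnsembleWaveform,
    NoiseSpec,
    Recording,
    SignalQualityError,
    TrueVitals,
    assess_recording,
    detect_r_peaks,
    ensemble_average,
    filter_abnormal_beats,
    generate_recording,
    inject_artifacts,
    locate_bcg_fiducials,
    locate_ppg_foot,
    measure_ppg_ac_dc,
)
from seatvitals import sigproc as sp
from seatvitals import synthcardio as sc


def make_beats(rr_list, t0=0.5):
    times = np.concatenate([[t0], t0 + np.cumsum(rr_list)])
    return BeatSeries(times, np.ones(times.size, bool), [None] * times.size)


class TestDetectRPeaks:
    def test_clean_recording_every_beat_within_10_ms_no_extras(self, clean_recording, config):
        beats = detect_r_peaks(clean_recording.ecg, clean_recording.fs, config)
        truth = clean_recording.event_times("r_peak")
        assert beats.n_beats == truth.size
        assert np.max(np.abs(beats.r_times - truth)) < 0.010

    def test_flat_signal_yields_empty_flagged_series(self, config):
        beats = detect_r_peaks(np.zeros(5000), 1000.0, config)
        assert beats.n_beats == 0 and "flat_or_nan_input" in beats.flags

    def test_all_nan_yields_empty_flagged_series(self, config):
        beats = detect_r_peaks(np.full(5000, np.nan), 1000.0, config)
        assert beats.n_beats == 0 and beats.flags

    def test_too_short_input_rejected(self, config):
        with pytest.raises(ValueError):
            detect_r_peaks(np.zeros(500), 1000.0, config)

    def test_sensitivity_and_ppv_at_default_noise(self, subject, config):
        """Detection against annotations across seeded noisy recordings."""
        tp = fp = fn = 0
        for seed in range(10):
            v = TrueVitals(sbp=120, dbp=80, sv=70, spo2=97,
                           hr=60.0 + 4 * seed, hrv_sd=0.03)
            rec = generate_recording(subject, v, 30.0, 1000.0, NoiseSpec(), seed=seed)
            beats = detect_r_peaks(rec.ecg, rec.fs, config)
            truth = rec.event_times("r_peak")
            matched = np.zeros(truth.size, bool)
            for t in beats.r_times:
                i = np.argmin(np.abs(truth - t))
                if abs(truth[i] - t) < 0.05 and not matched[i]:
                    matched[i] = True
                    tp += 1
                else:
                    fp += 1
            fn += int((~matched).sum())
        assert tp / (tp + fn) >= 0.99      # sensitivity
        assert tp / (tp + fp) >= 0.99      # positive predictive value


class TestFilterAbnormalBeats:
    def test_constant_rr_keeps_everything(self):
        out = filter_abnormal_beats(make_beats([0.8] * 12))
        assert out.accepted.all()

    def test_printed_sequence_rejects_the_two_bounding_beats(self):
        # RR = [0.8 x6, 1.3, 0.8 x6]: only the beats bounding the 1.3 s
        # interval (indices 6 and 7) deviate from the running median rule
        out = filter_abnormal_beats(make_beats([0.8] * 6 + [1.3] + [0.8] * 6), tolerance=0.20)
        rejected = np.where(~out.accepted)[0].tolist()
        assert rejected == [6, 7]
        assert out.rejection_reason[6] == "abnormal_interval"

    def test_timing_untouched_and_idempotent(self):
        beats = make_beats([0.8, 0.82, 1.4, 0.8, 0.79, 0.81, 0.8])
        once = filter_abnormal_beats(beats)
        twice = filter_abnormal_beats(once)
        assert np.array_equal(once.r_times, beats.r_times)
        assert np.array_equal(once.accepted, twice.accepted)

    def test_fewer_than_three_beats_all_rejected(self):
        out = filter_abnormal_beats(make_beats([0.8]))
        assert not out.accepted.any()
        assert all(r == "too_few" for r in out.rejection_reason)

    @given(st.lists(st.floats(0.4, 1.6), min_size=3, max_size=40))
    @settings(derandomize=True, max_examples=60)
    def test_idempotence_property(self, rrs):
        beats = make_beats(rrs)
        once = filter_abnormal_beats(beats)
        twice = filter_abnormal_beats(once)
        assert np.array_equal(once.accepted, twice.accepted)
        assert once.rejection_reason == twice.rejection_reason

    def test_ectopic_adjacent_beats_rejected(self, clean_recording, config):
        rt = clean_recording.event_times("r_peak")
        onset = float(rt[30] + 0.4 * (rt[31] - rt[30]))
        rec = inject_artifacts(clean_recording, [Artifact("ectopic_beat", onset, 0.0, 1.0)])
        beats = detect_r_peaks(rec.ecg, rec.fs, config)
        beats = filter_abnormal_beats(beats, config.rr_tolerance, config.rr_median_window)
        near = np.where(np.abs(beats.r_times - onset) < 0.6)[0]
        assert near.size and not beats.accepted[near].any()


class TestAssessRecording:
    def test_clean_recording_accepted(self, clean_recording, config):
        beats = filter_abnormal_beats(detect_r_peaks(clean_recording.ecg, clean_recording.fs, config))
        report = assess_recording(clean_recording, beats, config)
        assert report.recording_accepted and report.n_beats_accepted >= 20

    def test_short_recording_rejected_too_short(self, config):
        fs, dur = 500.0, 5.0
        rec = Recording(fs=fs, ecg=np.zeros(int(fs * dur)), bcg=np.zeros(int(fs * dur)),
                        ppg_red=np.ones(int(fs * dur)), ppg_ir=np.ones(int(fs * dur)),
                        duration=dur, subject_id="x")
        beats = filter_abnormal_beats(detect_r_peaks(rec.ecg, fs, config))
        report = assess_recording(rec, beats, config)
        assert not report.recording_accepted and "too_short" in report.reasons

    def test_full_dropout_rejected(self, clean_recording, config):
        rec = inject_artifacts(clean_recording,
                               [Artifact("dropout", 0.0, clean_recording.duration, 0.0)])
        beats = filter_abnormal_beats(detect_r_peaks(rec.ecg, rec.fs, config))
        assert not assess_recording(rec, beats, config).recording_accepted

    def test_motion_burst_raises_motion_reason(self, clean_recording, config):
        rec = inject_artifacts(clean_recording,
                               [Artifact("motion_burst", 5.0, 20.0, 8.0)], seed=0)
        beats = filter_abnormal_beats(detect_r_peaks(rec.ecg, rec.fs, config))
        report = assess_recording(rec, beats, config)
        assert "motion" in report.reasons


class TestEnsembleAverage:
    def test_identical_beats_reproduce_single_beat(self, subject, config):
        # RR of exactly 0.8 s keeps every beat on the same sample grid
        v = TrueVitals(sbp=120, dbp=80, sv=70, spo2=97, hr=75.0)
        rec = generate_recording(subject, v, 60.0, 1000.0, NoiseSpec.zero(), seed=0)
        beats = detect_r_peaks(rec.ecg, rec.fs, config)
        ens = ensemble_average(rec, beats, "bcg", config=config)
        filt = sp.filter_channel(rec, "bcg", config)
        i = int(round(beats.r_times[30] * rec.fs))
        npre = int(round(config.ensemble_pre_s * rec.fs))
        seg = filt[i - npre: i - npre + ens.amplitude.size]
        # residual slow high-pass transients bound the agreement at ~1e-3 N
        assert np.allclose(ens.amplitude, seg, atol=2e-3)
        # the averaging operator itself is an exact pointwise mean
        guard = int(round(config.edge_guard_s * rec.fs))
        npost = ens.amplitude.size - npre
        segs = [filt[k - npre: k + npost]
                for k in (np.round(beats.r_times * rec.fs)).astype(int)
                if k - npre >= guard and k + npost <= filt.size - guard]
        assert np.allclose(ens.amplitude, np.mean(segs, axis=0), atol=1e-12)

    def test_rejected_beats_do_not_contribute(self, clean_recording, config):
        beats = detect_r_peaks(clean_recording.ecg, clean_recording.fs, config)
        acc = beats.accepted.copy()
        acc[::3] = False
        marked = BeatSeries(beats.r_times, acc, [None] * beats.n_beats)
        removed = BeatSeries(beats.r_times[acc], np.ones(acc.sum(), bool), [None] * int(acc.sum()))
        a = ensemble_average(clean_recording, marked, "bcg", config=config)
        b = ensemble_average(clean_recording, removed, "bcg", config=config)
        assert np.array_equal(a.amplitude, b.amplitude)
        assert a.n_beats == b.n_beats

    def test_zero_accepted_beats_raises(self, clean_recording, config):
        beats = detect_r_peaks(clean_recording.ecg, clean_recording.fs, config)
        none = BeatSeries(beats.r_times, np.zeros(beats.n_beats, bool),
                          ["x"] * beats.n_beats)
        with pytest.raises(SignalQualityError):
            ensemble_average(clean_recording, none, "bcg", config=config)

    def test_noise_suppression_follows_sqrt_n(self, subject, config):
        """Residual ensemble noise ~ sigma_filtered / sqrt(N) across seeds."""
        v = TrueVitals(sbp=120, dbp=80, sv=70, spo2=97, hr=74.3)
        clean = generate_recording(subject, v, 60.0, 500.0, NoiseSpec.zero(), seed=0)
        beats = detect_r_peaks(clean.ecg, clean.fs, config)
        ref = ensemble_average(clean, beats, "bcg", config=config)
        sigma = 0.5
        resid = []
        for seed in range(12):
            rng = np.random.default_rng(seed)
            noisy = clean.copy()
            noisy.bcg = noisy.bcg + rng.normal(0, sigma, noisy.bcg.size)
            ens = ensemble_average(noisy, beats, "bcg", config=config)
            resid.append(np.std(ens.amplitude - ref.amplitude))
        measured = np.mean(resid)
        # white noise through the BCG band-pass then averaged over N beats
        filt_factor = np.std(sp.bandpass(np.random.default_rng(99).normal(0, 1, 200_000),
                                         clean.fs, config.bcg_band, config.filter_order))
        expected = sigma * filt_factor / np.sqrt(ref.n_beats)
        assert measured == pytest.approx(expected, rel=0.2)


@pytest.fixture(scope="module")
def bcg_ens(clean_recording, config):
    beats = detect_r_peaks(clean_recording.ecg, clean_recording.fs, config)
    return ensemble_average(clean_recording, beats, "bcg", config=config)


@pytest.fixture(scope="module")
def ppg_ens(clean_recording, config):
    beats = detect_r_peaks(clean_recording.ecg, clean_recording.fs, config)
    return ensemble_average(clean_recording, beats, "ppg_ir", config=config)


class TestBcgFiducials:
    def test_j_time_matches_pep_within_one_sample(self, bcg_ens, subject, config):
        fid = locate_bcg_fiducials(bcg_ens, config)
        assert fid.bcg_j.time == pytest.approx(subject.pep, abs=1.0 / 1000.0)

    def test_i_j_k_ordering_and_jk_amplitude(self, bcg_ens, subject, vitals, config):
        fid = locate_bcg_fiducials(bcg_ens, config)
        assert fid.bcg_i.time < fid.bcg_j.time < fid.bcg_k.time
        truth = sc.true_jk_amplitude(subject, vitals.sv)
        assert fid.jk_amplitude == pytest.approx(truth, rel=0.02)

    def test_positive_scaling_equivariance(self, bcg_ens, config):
        fid1 = locate_bcg_fiducials(bcg_ens, config)
        doubled = dataclasses.replace(bcg_ens, amplitude=2.0 * bcg_ens.amplitude)
        fid2 = locate_bcg_fiducials(doubled, config)
        assert fid2.jk_amplitude == pytest.approx(2.0 * fid1.jk_amplitude, rel=1e-9)
        assert fid2.bcg_j.time == pytest.approx(fid1.bcg_j.time, abs=1e-9)

    def test_low_amplitude_waveform_same_times(self, bcg_ens, config):
        # a weak-heart-like 0.3x complex keeps its fiducial timing
        fid1 = locate_bcg_fiducials(bcg_ens, config)
        small = dataclasses.replace(bcg_ens, amplitude=0.3 * bcg_ens.amplitude)
        fid2 = locate_bcg_fiducials(small, config)
        assert fid2.bcg_j.time == pytest.approx(fid1.bcg_j.time, abs=1e-9)

    def test_featureless_ensemble_flagged(self, config):
        t = np.arange(-200, 600) / 1000.0
        flat = EnsembleWaveform("bcg", t, np.linspace(0, 1, t.size), n_beats=5)
        fid = locate_bcg_fiducials(flat, config)
        assert "bcg_fiducials_undefined" in fid.flags


class TestPpgFoot:
    def test_foot_within_5_ms_of_annotation(self, ppg_ens, clean_recording, config):
        foot = locate_ppg_foot(ppg_ens, config)
        truth = clean_recording.event_times("ppg_foot")[0] - clean_recording.event_times("r_peak")[0]
        assert foot == pytest.approx(truth, abs=0.005)

    def test_foot_precedes_pulse_peak(self, ppg_ens, config):
        foot = locate_ppg_foot(ppg_ens, config)
        t, y = ppg_ens.rel_time, ppg_ens.amplitude
        win = (t >= config.foot_search_s[0]) & (t <= config.foot_search_s[1])
        peak_t = t[win][np.argmax(y[win])]
        assert foot < peak_t

    def test_vertical_offset_invariance(self, ppg_ens, config):
        foot1 = locate_ppg_foot(ppg_ens, config)
        shifted = dataclasses.replace(ppg_ens, amplitude=ppg_ens.amplitude + 3.7)
        assert locate_ppg_foot(shifted, config) == pytest.approx(foot1, abs=1e-12)

    def test_non_pulsatile_ensemble_flagged(self, config):
        t = np.arange(-200, 600) / 1000.0
        flat = EnsembleWaveform("ppg_ir", t, np.zeros(t.size), n_beats=5, dc_level=2.0)
        with pytest.raises(SignalQualityError):
            locate_ppg_foot(flat, config)


class TestPpgAcDc:
    def test_known_amplitude_recovered_within_2_percent(self, clean_recording, config):
        beats = detect_r_peaks(clean_recording.ecg, clean_recording.fs, config)
        ens = ensemble_average(clean_recording, beats, "ppg_ir", config=config)
        ac, dc = measure_ppg_ac_dc(ens, config)
        assert ac == pytest.approx(sc.PPG_AC_RATIO_IR * sc.PPG_DC["ir"], rel=0.02)
        assert dc == pytest.approx(sc.PPG_DC["ir"], rel=0.02)

    def test_constant_signal_gives_zero_ac(self, config):
        t = np.arange(-200, 600) / 1000.0
        ens = EnsembleWaveform("ppg_ir", t, np.zeros(t.size), n_beats=3, dc_level=2.0)
        ac, dc = measure_ppg_ac_dc(ens, config)
        assert ac == 0.0 and dc == 2.0

    def test_gain_change_preserves_ac_over_dc(self, clean_recording, config):
        beats = detect_r_peaks(clean_recording.ecg, clean_recording.fs, config)
        ens = ensemble_average(clean_recording, beats, "ppg_ir", config=config)
        ac1, dc1 = measure_ppg_ac_dc(ens, config)
        doubled = dataclasses.replace(ens, amplitude=2 * ens.amplitude, dc_level=2 * ens.dc_level)
        ac2, dc2 = measure_ppg_ac_dc(doubled, config)
        assert ac2 / dc2 == pytest.approx(ac1 / dc1, rel=1e-9)

    def test_nonpositive_dc_rejected(self, config):
        t = np.arange(-200, 600) / 1000.0
        ens = EnsembleWaveform("ppg_ir", t, np.zeros(t.size), n_beats=3, dc_level=0.0)
        with pytest.raises(ValueError):
            measure_ppg_ac_dc(ens, config)
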