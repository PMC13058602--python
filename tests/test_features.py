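"""Windowing, beat detection, PTT/PWV, HR/HRV and feature composition."""

import numpy as np
import pytest

from padbp import (
    compute_hr_hrv,
    compute_mean_dc,
    compute_ptt,
    compute_pwv,
    detect_beats,
    extract_features,
    features_to_frame,
    iter_windows,
    process_pair,
)
from padbp.features import BeatAnnotations
from padbp.synthcap import _BCG_LOBES, _gauss_train

FS = 100.0


class TestWindows:
    def test_continuous_20s_enumerates_three(self):
        assert iter_windows(20.0, "continuous") == [(0.0, 10.0), (5.0, 15.0), (10.0, 20.0)]

    def test_continuous_boundary_single_window(self):
        assert iter_windows(10.0, "continuous") == [(0.0, 10.0)]

    def test_continuous_60s_gives_eleven(self):
        assert len(iter_windows(60.0, "continuous")) == 11

    def test_intermittent_tiling_and_anchors(self):
        assert iter_windows(80.0, "intermittent") == [(0.0, 40.0), (40.0, 80.0)]
        assert iter_windows(100.0, "intermittent", anchors=[5.0, 50.0]) == [
            (5.0, 45.0),
            (50.0, 90.0),
        ]

    def test_too_short_returns_empty(self):
        assert iter_windows(5.0, "continuous") == []

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            iter_windows(60.0, "weekly")


class TestBeatDetection:
    def test_recovers_every_simulated_beat(self, clean_processed):
        cfg, pc, pl, truth = clean_processed
        ann = detect_beats(pc.bcg, pl.bcg, cfg.sample_rate, hr_prior=cfg.hr_baseline)
        # edge beats can fall outside filter settling; interior must match 1:1
        interior = truth.beat_times[(truth.beat_times > 2) & (truth.beat_times < 118)]
        found = ann.j_peaks[(ann.j_peaks > 2) & (ann.j_peaks < 118)]
        assert len(found) == len(interior)

    def test_j_peak_alignment_within_one_sample(self, clean_processed):
        cfg, pc, pl, truth = clean_processed
        ann = detect_beats(pc.bcg, None, cfg.sample_rate, hr_prior=cfg.hr_baseline)
        errs = []
        for tb in truth.beat_times[2:-2]:
            errs.append(np.min(np.abs(ann.j_peaks - tb)))
        assert np.median(errs) <= 1.0 / cfg.sample_rate

    def test_i_trough_precedes_each_j(self, clean_processed):
        cfg, pc, _, _ = clean_processed
        ann = detect_beats(pc.bcg, None, cfg.sample_rate, hr_prior=cfg.hr_baseline)
        for ti in ann.i_troughs:
            after = ann.j_peaks[ann.j_peaks > ti]
            assert len(after) and 0.01 <= after[0] - ti <= 0.15

    def test_halved_beat_still_detected(self):
        t = np.arange(int(30 * FS)) / FS
        beats = np.arange(1.0, 29.0, 1.0)
        amps = np.ones(len(beats))
        amps[10] = 0.5  # one weak beat, still above the prominence floor
        x = np.zeros_like(t)
        for b, a in zip(beats, amps):
            x += a * _gauss_train(t, np.array([b]), _BCG_LOBES, FS)
        ann = detect_beats(x, None, FS)
        assert len(ann.j_peaks) == len(beats)
        assert np.min(np.abs(ann.j_peaks - beats[10])) < 0.05

    def test_too_short_signal_raises(self):
        with pytest.raises(ValueError):
            detect_beats(np.zeros(100), None, FS)


class TestPTT:
    def test_shifted_copy_recovers_exact_lag(self):
        t = np.arange(int(30 * FS)) / FS
        beats = np.arange(1.0, 29.0, 0.9)
        x = _gauss_train(t, beats, _BCG_LOBES, FS)
        d = 20  # samples
        y = np.roll(x, d)
        ann = detect_beats(x, y, FS)
        ptt = compute_ptt(x, y, ann, FS)
        assert abs(ptt - d / FS) < 0.5 / FS

    def test_noise_only_leg_is_invalid(self, rng):
        t = np.arange(int(30 * FS)) / FS
        x = _gauss_train(t, np.arange(1.0, 29.0, 1.0), _BCG_LOBES, FS)
        y = 0.1 * rng.standard_normal(len(t))
        ann = detect_beats(x, y, FS)
        assert np.isnan(compute_ptt(x, y, ann, FS))

    def test_too_few_beats_invalid(self):
        ann = BeatAnnotations(
            j_peaks=np.array([1.0, 2.0]), i_troughs=np.array([]), leg_peaks=np.array([])
        )
        assert np.isnan(compute_ptt(np.zeros(1000), np.zeros(1000), ann, FS))

    @pytest.mark.parametrize(
        "spacing,ptt,expected", [(1.0, 0.2, 5.0), (0.8, 0.16, 5.0), (0.9, 0.3, 3.0)]
    )
    def test_pwv_arithmetic(self, spacing, ptt, expected):
        assert np.isclose(compute_pwv(ptt, spacing), expected)

    def test_pwv_inverse_proportionality_and_errors(self):
        assert np.isclose(compute_pwv(0.1, 1.0), 2 * compute_pwv(0.2, 1.0))
        with pytest.raises(ValueError):
            compute_pwv(0.0, 1.0)


class TestHRHRV:
    def test_metronomic_beats(self):
        j = np.arange(0.0, 60.0, 1.0)
        hr, lf = compute_hr_hrv(j)
        assert np.isclose(hr, 60.0)
        assert lf == pytest.approx(0.0, abs=1e-9)

    def test_80_bpm(self):
        j = np.arange(0.0, 45.0, 0.75)
        hr, _ = compute_hr_hrv(j)
        assert np.isclose(hr, 80.0)

    def test_lf_modulation_captured_in_band(self):
        # intervals = 1 s + 10 ms sine at 0.1 Hz; build beat times iteratively
        times = [0.0]
        for _ in range(300):
            times.append(times[-1] + 1.0 + 0.010 * np.sin(2 * np.pi * 0.1 * times[-1]))
        hr, lf = compute_hr_hrv(np.array(times))
        var = np.var(np.diff(times)) * 1e6  # ms^2
        assert lf >= 0.9 * var  # >=90% of interval power in the LF band
        assert lf == pytest.approx(50.0, rel=0.35)  # ~A^2/2 for A = 10 ms

    def test_short_window_carries_no_lf(self):
        j = np.arange(0.0, 10.0, 0.8)
        hr, lf = compute_hr_hrv(j)
        assert np.isfinite(hr) and np.isnan(lf)

    def test_too_few_beats(self):
        hr, lf = compute_hr_hrv(np.array([0.0, 1.0]))
        assert np.isnan(hr) and np.isnan(lf)


class TestMeanDC:
    def test_constant_at_baseline_is_zero(self):
        x = np.full(3000, 5.0)
        assert compute_mean_dc(x, (10.0, 20.0), FS) == pytest.approx(0.0)

    def test_offset_recovered(self):
        x = np.full(6000, 2.0)
        x[2000:] += 0.2
        assert compute_mean_dc(x, (30.0, 50.0), FS) == pytest.approx(0.2)

    def test_tracks_map_during_maneuvers(self, maneuver_run):
        """Window-level mean dC follows mean arterial pressure (volume coupling)."""
        cfg, chest, leg, truth = maneuver_run
        pc, pl = process_pair(chest, leg)
        df = features_to_frame(
            extract_features(pc, pl, mode="continuous", hr_prior=cfg.hr_baseline)
        )
        map_t = truth.bp.map
        win_map = [
            np.mean(map_t[(truth.bp.times >= t0) & (truth.bp.times < t1)])
            for t0, t1 in zip(df.t_start, df.t_end)
        ]
        ok = np.isfinite(df.mean_dc.values)
        r = np.corrcoef(df.mean_dc.values[ok], np.asarray(win_map)[ok])[0, 1]
        assert r > 0.5


class TestExtractFeatures:
    def test_clean_run_all_windows_valid(self, clean_processed):
        cfg, pc, pl, truth = clean_processed
        out = extract_features(pc, pl, mode="continuous", hr_prior=cfg.hr_baseline)
        assert len(out) == len(iter_windows(cfg.duration, "continuous"))
        assert all(f.valid for f in out)

    def test_pwv_times_ptt_is_pad_spacing(self, clean_processed):
        cfg, pc, pl, _ = clean_processed
        out = extract_features(pc, pl, mode="continuous", hr_prior=cfg.hr_baseline)
        for f in out:
            if f.valid:
                assert f.pwv * f.ptt == pytest.approx(cfg.pad_spacing, rel=1e-12)

    def test_hr_matches_truth_within_2bpm(self, clean_processed):
        cfg, pc, pl, truth = clean_processed
        out = extract_features(pc, pl, mode="continuous", hr_prior=cfg.hr_baseline)
        for f, true_hr in zip(out, truth.true_hr):
            if f.valid and np.isfinite(true_hr):
                assert abs(f.hr - true_hr) < 2.0

    def test_artifact_invalidates_overlapping_windows(self, clean_run):
        cfg, chest, leg, _ = clean_run
        sig = chest.signal.copy()
        i0 = int(60.0 * cfg.sample_rate)
        sig[:, i0:] += 1.0  # 1 pF body-shift step at t = 60 s
        from padbp import SensorRecording

        chest2 = SensorRecording(
            signal=sig, sample_rate=cfg.sample_rate, pad_id="chest", pad_spacing=chest.pad_spacing
        )
        pc, pl = process_pair(chest2, leg)
        out = extract_features(pc, pl, mode="continuous", hr_prior=cfg.hr_baseline)
        # windows overlapping the rejected span by more than 20% must drop out
        fs = cfg.sample_rate
        hit = [
            f
            for f in out
            if np.mean(~pc.valid_mask[int(f.t_start * fs) : int(f.t_end * fs)]) > 0.2
        ]
        assert hit and all(not f.valid for f in hit)
        assert any(f.valid for f in out if f.t_end < 55.0)

    def test_missing_leg_degrades_gracefully(self, clean_processed):
        cfg, pc, _, _ = clean_processed
        out = extract_features(pc, None, mode="continuous", hr_prior=cfg.hr_baseline)
        assert all(not f.valid for f in out)
        assert all(np.isnan(f.ptt) for f in out)
        assert any(np.isfinite(f.hr) for f in out)

    def test_reference_bp_window_averaging(self, clean_processed):
        cfg, pc, pl, truth = clean_processed
        out = extract_features(
            pc,
            pl,
            mode="continuous",
            ref_bp=(truth.bp.times, truth.bp.sbp, truth.bp.dbp),
            hr_prior=cfg.hr_baseline,
        )
        assert out[0].ref_sbp == pytest.approx(cfg.sbp_baseline, abs=0.5)
        assert out[0].ref_dbp == pytest.approx(cfg.dbp_baseline, abs=0.5)

    def test_deterministic(self, clean_processed):
        cfg, pc, pl, _ = clean_processed
        a = features_to_frame(extract_features(pc, pl, hr_prior=cfg.hr_baseline))
        b = features_to_frame(extract_features(pc, pl, hr_prior=cfg.hr_baseline))
        assert a.equals(b)
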