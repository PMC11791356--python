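"""Hotspot detection: scoring, seeds, ROI growth, FWHM, filters, end-to-end."""

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from nirspot import (DetectionParams, MovieGeometry, ReleaseSite, SimConfig,
                     StimulusProtocol, compute_dff, detect_hotspots,
                     filter_hotspots, find_seeds, grow_roi, score_map,
                     simulate_movie, temporal_fwhm)
from nirspot.hotspots import Hotspot, evaluation_window
from nirspot.simulate import amplitude_for_hotspot_peak

from reference_detection import reference_detect


PROTO = StimulusProtocol(stim_start_s=10.0)


def _site_movie(sites, h=64, w=64, n=150, noise=False, seed=0):
    cfg = SimConfig(geometry=MovieGeometry(height=h, width=w, n_frames=n),
                    protocol=PROTO, sites=sites, seed=seed,
                    shot_noise=noise, read_noise_sd=10.0 if noise else 0.0)
    return simulate_movie(cfg)


class TestScoreMap:
    def test_constant_traces_score_zero(self, dff_factory):
        stack = dff_factory(np.zeros((30, 8, 8)))
        params = DetectionParams(derivative_smoothing=1, score_smoothing_px=1)
        s = score_map(stack, params, window=(10, 25))
        assert np.all(s == 0.0)

    def test_unit_step_scores_frame_rate(self, dff_factory):
        dff = np.zeros((30, 8, 8))
        dff[15:, 3, 4] = 1.0   # +1 step between frames 14 and 15 at 5 fps
        stack = dff_factory(dff)
        params = DetectionParams(derivative_smoothing=1, score_smoothing_px=1)
        s = score_map(stack, params, window=(15, 25))
        assert s[3, 4] == pytest.approx(5.0)

    def test_missing_window_and_protocol_rejected(self, dff_factory):
        stack = dff_factory(np.zeros((30, 8, 8)))
        with pytest.raises(ValueError):
            score_map(stack, DetectionParams())

    def test_argmax_at_injected_site_center(self):
        site = ReleaseSite(30, 20, 1.0, 2.0, 10.0, 2.0)
        stack, _ = _site_movie([site])
        d = compute_dff(stack)
        s = score_map(d, DetectionParams())
        r, c = np.unravel_index(np.argmax(s), s.shape)
        assert abs(r - 30) <= 1 and abs(c - 20) <= 1


class TestFindSeeds:
    def test_all_zero_score_gives_no_seeds(self):
        assert find_seeds(np.zeros((8, 8)), DetectionParams()) == []

    def test_two_sites_two_seeds(self):
        s1 = ReleaseSite(20, 20, 1.0, 1.6, 10.0, 2.0)
        s2 = ReleaseSite(20, 40, 1.0, 1.6, 10.0, 2.0)
        stack, _ = _site_movie([s1, s2])
        d = compute_dff(stack)
        from nirspot.hotspots import peak_map
        params = DetectionParams()
        seeds = find_seeds(score_map(d, params), params,
                           peak=peak_map(d, params))
        assert len(seeds) == 2
        assert {tuple(s) for s in seeds} == {(20, 20), (20, 40)}

    def test_close_maxima_suppressed_by_separation(self):
        score = np.zeros((10, 10))
        score[5, 5] = 1.0
        score[6, 5] = 1.0   # plateau tie, 1 px apart
        seeds = find_seeds(score, DetectionParams(min_separation_px=3.0))
        assert seeds == [(5, 5)]   # tie resolved to the smaller row

    def test_amplitude_floor_excludes_faint_maxima(self):
        score = np.zeros((10, 10))
        score[4, 4] = 1.0
        peak = np.full((10, 10), 0.01)   # below the 0.05 dF/F0 floor
        assert find_seeds(score, DetectionParams(), peak=peak) == []

    def test_ordering_is_deterministic(self):
        score = np.zeros((20, 20))
        score[3, 3] = 2.0
        score[15, 15] = 1.0
        seeds = find_seeds(score, DetectionParams())
        assert seeds == [(3, 3), (15, 15)]


class TestGrowRoi:
    def test_isolated_pixel_roi_is_single_pixel(self, dff_factory):
        dff = np.zeros((30, 8, 8))
        dff[15, 4, 4] = 1.0
        stack = dff_factory(dff)
        params = DetectionParams(derivative_smoothing=1)
        roi = grow_roi(stack, (4, 4), params, window=(10, 25))
        assert roi == [(4, 4)]
        area = len(roi) * stack.geometry.pixel_area_um2
        assert area == pytest.approx(0.5476)

    def test_gaussian_spot_area_matches_analytic_halfmax(self):
        from nirspot.simulate import gaussian_halfmax_area_um2
        site = ReleaseSite(32, 32, 0.5, 3.0, 10.0, 2.0)
        stack, _ = _site_movie([site])
        d = compute_dff(stack)
        roi = grow_roi(d, (32, 32), DetectionParams())
        area = len(roi) * stack.geometry.pixel_area_um2
        expected = gaussian_halfmax_area_um2(3.0)
        assert abs(area - expected) / expected < 0.15

    def test_disjoint_spots_stay_disjoint(self):
        s1 = ReleaseSite(16, 16, 1.0, 2.0, 10.0, 2.0)
        s2 = ReleaseSite(48, 48, 1.0, 2.0, 10.0, 2.0)
        stack, _ = _site_movie([s1, s2])
        d = compute_dff(stack)
        roi = grow_roi(d, (16, 16), DetectionParams())
        assert all(abs(r - 48) > 8 or abs(c - 48) > 8 for r, c in roi)


class TestTemporalFwhm:
    def test_symmetric_triangle(self):
        # 4 s base at 5 fps: rises 10 frames, falls 10 frames
        up = np.linspace(0, 1, 11)
        trace = np.r_[np.zeros(20), up, up[-2::-1], np.zeros(20)]
        fwhm, one_sided = temporal_fwhm(trace, 5.0)
        assert not one_sided
        assert fwhm == pytest.approx(2.0, abs=1e-9)

    def test_gaussian_pulse_width(self):
        t = np.arange(0, 30, 0.2)
        trace = np.exp(-0.5 * ((t - 15.0) / 1.0) ** 2)
        fwhm, one_sided = temporal_fwhm(trace, 5.0)
        assert not one_sided
        assert fwhm == pytest.approx(2.3548, abs=0.2)

    def test_monotone_rise_is_flagged_one_sided(self):
        trace = np.linspace(0, 1, 50)
        fwhm, one_sided = temporal_fwhm(trace, 5.0)
        assert one_sided and fwhm > 0

    def test_flat_trace_rejected(self):
        with pytest.raises(ValueError):
            temporal_fwhm(np.zeros(20), 5.0)


def _mk_hotspot(n_px=4, peak=0.5, repeat_peaks=(), trace=None):
    if trace is None:
        trace = np.zeros(100)
        trace[55:70] = peak * np.exp(-np.arange(15) / 10.0)
    roi = [(0, c) for c in range(n_px)]
    return Hotspot(id=0, seed=(0, 0), roi=roi, area_um2=n_px * 0.74 ** 2,
                   trace=np.asarray(trace), peak_dff=peak, peak_time_s=11.0,
                   fwhm_s=1.0, fwhm_one_sided=False,
                   repeat_peaks=list(repeat_peaks))


class TestFilters:
    def test_two_pixel_hotspot_fails_size(self):
        hs = _mk_hotspot(n_px=2)
        accepted, rejected = filter_hotspots([hs], DetectionParams(),
                                             eval_window=(50, 86))
        assert not accepted and rejected[0].qc["size_ok"] is False

    def test_three_pixels_pass_size_inclusively(self):
        hs = _mk_hotspot(n_px=3)   # 1.6428 um2 >= 1.6428 threshold
        accepted, _ = filter_hotspots([hs], DetectionParams(),
                                      eval_window=(50, 86))
        assert accepted and accepted[0].qc["size_ok"] is True

    def test_600pct_repeat_variation_rejected(self):
        hs = _mk_hotspot(repeat_peaks=[0.1, 0.7])
        _, rejected = filter_hotspots([hs], DetectionParams(), n_repeats=2,
                                      eval_window=(50, 86))
        assert rejected and rejected[0].qc["variation_ok"] is False

    def test_variation_below_limit_accepted(self):
        hs = _mk_hotspot(repeat_peaks=[0.2, 0.7])   # 250 % < 500 %
        accepted, _ = filter_hotspots([hs], DetectionParams(), n_repeats=2,
                                      eval_window=(50, 86))
        assert accepted

    def test_white_noise_trace_rejected_as_highfreq(self):
        rng = np.random.default_rng(0)
        hs = _mk_hotspot(trace=rng.normal(0, 1, 100))
        _, rejected = filter_hotspots([hs], DetectionParams(),
                                      frame_rate_hz=5.0)
        assert rejected and "highfreq_noise" in rejected[0].rejection_reasons

    def test_peak_outside_window_rejected(self):
        trace = np.zeros(100)
        trace[5:20] = 0.5   # transient before the stimulus
        hs = _mk_hotspot(trace=trace)
        _, rejected = filter_hotspots([hs], DetectionParams(),
                                      eval_window=(50, 86))
        assert rejected and "no_peak_in_window" in rejected[0].rejection_reasons

    def test_candidates_conserved(self):
        rng = np.random.default_rng(1)
        cands = [_mk_hotspot(n_px=2), _mk_hotspot(n_px=5),
                 _mk_hotspot(trace=rng.normal(0, 1, 100))]
        accepted, rejected = filter_hotspots(cands, DetectionParams(),
                                             eval_window=(50, 86))
        assert len(accepted) + len(rejected) == len(cands)


class TestDetectEndToEnd:
    def test_null_noiseless_movie_yields_no_hotspots(self):
        stack, _ = _site_movie([])
        d = compute_dff(stack)
        result = detect_hotspots(d)
        assert result.accepted == [] and result.rejected == []

    def test_planted_sites_recovered(self, sensor):
        # 10 well-separated sites at hotspot-level peak 0.5, moderate noise
        rng_pos = [(r, c) for r in (16, 48, 80, 112) for c in (16, 48, 80)][:10]
        amp = amplitude_for_hotspot_peak(0.5, 2.0 / 0.74, sensor)
        sites = [ReleaseSite(r, c, amp, 2.0, 10.5, 2.0) for r, c in rng_pos]
        cfg = SimConfig(geometry=MovieGeometry(height=128, width=128, n_frames=150),
                        protocol=PROTO, sites=sites, seed=5,
                        shot_noise=True, read_noise_sd=10.0)
        stack, truth = simulate_movie(cfg)
        d = compute_dff(stack)
        result = detect_hotspots(d)
        centers = np.array(rng_pos)
        seeds = np.array([h.seed for h in result.accepted])
        dist = cdist(seeds, centers)
        tp = sum(dist[:, j].min() <= 3 for j in range(len(centers)))
        recall = tp / len(centers)
        precision = sum(dist[i, :].min() <= 3 for i in range(len(seeds))) / len(seeds)
        assert recall >= 0.9 and precision >= 0.9
        mean_peak = np.mean([h.peak_dff for h in result.accepted])
        assert abs(mean_peak - 0.5) / 0.5 < 0.10

    def test_determinism_identical_inputs_identical_output(self):
        stack, _ = _site_movie([ReleaseSite(30, 30, 1.0, 2.0, 10.0, 2.0)],
                               noise=True, seed=3)
        d = compute_dff(stack)
        r1 = detect_hotspots(d)
        r2 = detect_hotspots(d)
        assert [h.seed for h in r1.accepted] == [h.seed for h in r2.accepted]
        assert [h.roi for h in r1.accepted] == [h.roi for h in r2.accepted]
        np.testing.assert_array_equal(r1.accepted[0].trace, r2.accepted[0].trace)

    def test_filter_monotonicity_in_min_area_and_snr(self):
        stack, _ = _site_movie([ReleaseSite(20, 20, 0.6, 1.5, 10.0, 2.0),
                                ReleaseSite(44, 44, 1.2, 2.5, 10.0, 2.0)],
                               noise=True, seed=9)
        d = compute_dff(stack)
        base = len(detect_hotspots(d, DetectionParams()).accepted)
        stricter = len(detect_hotspots(d, DetectionParams(min_area_um2=10.0)).accepted)
        assert stricter <= base
        lenient = len(detect_hotspots(d, DetectionParams(snr_min=1.0)).accepted)
        assert lenient >= base

    def test_brute_force_oracle_equivalence_on_small_movies(self):
        """Vectorised pipeline vs exhaustive per-pixel reference, 16x16."""
        proto = StimulusProtocol(stim_start_s=4.0, stim_duration_s=2.0)
        for seed in (0, 1, 2):
            cfg = SimConfig(
                geometry=MovieGeometry(height=16, width=16, n_frames=50),
                protocol=proto,
                sites=[ReleaseSite(5, 5, 1.0, 1.2, 4.2, 2.0),
                       ReleaseSite(11, 11, 0.6, 1.0, 4.6, 2.0)],
                seed=seed, shot_noise=True, read_noise_sd=5.0)
            stack, _ = simulate_movie(cfg)
            d = compute_dff(stack)
            params = DetectionParams()
            result = detect_hotspots(d, params)
            ref = reference_detect(d.dff, 5.0, 0.74, 4.0, 6.0, params)
            assert [tuple(h.seed) for h in result.candidates] == ref["seeds"]
            for h in result.candidates:
                r = ref["by_seed"][tuple(h.seed)]
                assert h.roi == r["roi"]
                assert h.peak_dff == pytest.approx(r["peak"], abs=1e-9)
                assert h.area_um2 == pytest.approx(r["area"], abs=1e-9)
                assert h.accepted == r["accepted"]


def test_evaluation_window_covers_stimulus_plus_pad(dff_factory):
    stack = dff_factory(np.zeros((150, 4, 4)), protocol=PROTO)
    f0, f1 = evaluation_window(stack, DetectionParams())
    assert f0 == 50                      # 10 s at 5 fps
    assert f1 == int(np.ceil(17.0 * 5)) + 1   # stim end 15 s + 2 s pad
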