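"""FOV summaries, size categories, clearance fits, group comparisons."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from nirspot import (MovieGeometry, ReleaseSite, SimConfig,
                     StimulusProtocol, compute_dff, detect_hotspots,
                     compare_groups, fit_clearance, simulate_clearance_trace,
                     simulate_movie, size_categories, summarize_fov)
from nirspot.simulate import PRESETS, amplitude_for_hotspot_peak
from nirspot.stats import stars


class TestSizeCategories:
    def test_direct_binning(self):
        assert size_categories([1.64, 10.0, 40.0]) == \
            {"small": 1, "middle": 1, "large": 1}

    def test_empty(self):
        assert size_categories([]) == {"small": 0, "middle": 0, "large": 0}

    @pytest.mark.parametrize("area,cat", [(9.0, "middle"), (36.0, "middle"),
                                          (8.999, "small"), (36.001, "large")])
    def test_boundaries_are_middle_inclusive(self, area, cat):
        counts = size_categories([area])
        assert counts[cat] == 1

    @given(st.lists(st.floats(0.0, 200.0), max_size=50))
    @settings(max_examples=50, derandomize=True)
    def test_count_conservation_and_order_invariance(self, areas):
        counts = size_categories(areas)
        assert sum(counts.values()) == len(areas)
        assert size_categories(list(reversed(areas))) == counts


class _FakeHotspot:
    def __init__(self, peak, area):
        self.peak_dff = peak
        self.area_um2 = area


class TestSummarizeFov:
    def test_single_hotspot_sd_flagged(self):
        s = summarize_fov([_FakeHotspot(0.5, 10.0)])
        assert s.n_hotspots == 1 and s.mean_peak_dff == 0.5
        assert s.sd_peak_dff == 0.0 and not s.sd_defined

    def test_two_peaks_unbiased_sd(self):
        s = summarize_fov([_FakeHotspot(0.1, 5.0), _FakeHotspot(0.3, 15.0)])
        assert s.mean_peak_dff == pytest.approx(0.2)
        assert s.sd_peak_dff == pytest.approx(0.1414, abs=1e-4)

    def test_fractions_sum_to_one(self):
        s = summarize_fov([_FakeHotspot(0.2, a) for a in (1.0, 10.0, 50.0, 8.0)])
        assert sum(s.size_fractions.values()) == pytest.approx(1.0)
        assert sum(s.size_counts.values()) == s.n_hotspots

    def test_45_planted_sites_counted_on_clean_movie(self, sensor):
        # 45 well-separated identical sites, noiseless: detector finds all
        positions = [(r, c) for r in range(10, 128, 17) for c in range(10, 128, 17)]
        positions = positions[:45]
        amp = amplitude_for_hotspot_peak(0.3, 2.0 / 0.74, sensor)
        sites = [ReleaseSite(r, c, amp, 2.0, 10.2, 2.0) for r, c in positions]
        cfg = SimConfig(geometry=MovieGeometry(height=128, width=128, n_frames=150),
                        protocol=StimulusProtocol(stim_start_s=10.0),
                        sites=sites, shot_noise=False, read_noise_sd=0.0)
        stack, _ = simulate_movie(cfg)
        result = detect_hotspots(compute_dff(stack))
        summary = summarize_fov(result.accepted, stack.geometry)
        assert summary.n_hotspots == 45


class TestFitClearance:
    @pytest.mark.parametrize("tau", [0.5, 1.0, 2.0, 5.0, 10.0])
    def test_noiseless_recovery_below_0p1pct(self, tau):
        trace = simulate_clearance_trace(tau, peak_dff=1.0, duration_s=30.0)
        fit = fit_clearance(trace, 5.0)
        assert fit.converged
        assert abs(fit.tau_s - tau) / tau < 1e-3

    def test_control_vs_pd_ratio_is_3p5(self):
        ctrl = fit_clearance(simulate_clearance_trace(
            PRESETS["control_early"].clearance_tau_s, duration_s=30.0), 5.0)
        pd = fit_clearance(simulate_clearance_trace(
            PRESETS["pd_early"].clearance_tau_s, duration_s=30.0), 5.0)
        assert pd.tau_s / ctrl.tau_s == pytest.approx(3.5, rel=1e-4)

    def test_white_noise_not_converged(self):
        rng = np.random.default_rng(4)
        fit = fit_clearance(rng.normal(0, 1, 150), 5.0)
        assert not fit.converged

    def test_noisy_median_bias_under_5pct(self):
        # SNR 10 traces over 200 seeds: median fitted tau within 5 % of truth
        taus = []
        for seed in range(200):
            trace = simulate_clearance_trace(2.0, peak_dff=1.0, noise_sd=0.1,
                                             duration_s=30.0, seed=seed)
            fit = fit_clearance(trace, 5.0)
            if fit.converged:
                taus.append(fit.tau_s)
        assert len(taus) > 190
        assert abs(np.median(taus) - 2.0) / 2.0 < 0.05

    def test_too_short_tail_rejected(self):
        with pytest.raises(ValueError):
            fit_clearance(np.array([1.0, 0.5, 0.2]), 5.0)


class TestCompareGroups:
    def test_identical_groups_t0_p1(self):
        r = compare_groups([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.statistic == 0.0 and r.p_value == 1.0

    def test_large_shift_highly_significant(self):
        r = compare_groups([1.0, 2.0, 3.0], [11.0, 12.0, 13.0])
        assert r.p_value < 0.001 and r.stars == "****"

    def test_pooled_t_matches_hand_calculation(self):
        # s_p^2 = 0.04, se = sqrt(0.04 * 2/3), t = -1 / se
        r = compare_groups([2.1, 2.5, 2.3], [3.1, 3.5, 3.3])
        assert r.statistic == pytest.approx(-1.0 / np.sqrt(0.04 * 2.0 / 3.0),
                                            rel=1e-12)
        assert r.df == (4.0,)

    def test_matches_scipy_reference_to_1e10(self):
        rng = np.random.default_rng(5)
        a, b = rng.normal(0, 1, 12), rng.normal(0.4, 1.3, 15)
        r = compare_groups(a, b)
        t_ref, p_ref = sps.ttest_ind(a, b, equal_var=True)
        assert abs(r.statistic - t_ref) < 1e-10
        assert abs(r.p_value - p_ref) < 1e-10
        rw = compare_groups(a, b, welch=True)
        t_w, p_w = sps.ttest_ind(a, b, equal_var=False)
        assert abs(rw.statistic - t_w) < 1e-10 and abs(rw.p_value - p_w) < 1e-10

    def test_anova_matches_scipy_and_tukey_matches_statsmodels(self):
        rng = np.random.default_rng(6)
        groups = [rng.normal(m, 1.0, 10) for m in (0.0, 0.5, 1.5)]
        r = compare_groups(*groups, labels=["a", "b", "c"])
        f_ref, p_ref = sps.f_oneway(*groups)
        assert abs(r.statistic - f_ref) < 1e-10
        assert abs(r.p_value - p_ref) < 1e-10

        from statsmodels.stats.multicomp import pairwise_tukeyhsd
        values = np.concatenate(groups)
        labels = np.repeat(["a", "b", "c"], [len(g) for g in groups])
        ref = pairwise_tukeyhsd(values, labels)
        ref_p = {(g1, g2): p for g1, g2, p in
                 zip(ref.groupsunique[ref._multicomp.pairindices[0]],
                     ref.groupsunique[ref._multicomp.pairindices[1]],
                     ref.pvalues)}
        for row in r.posthoc:
            key = (row["a"], row["b"])
            expected = ref_p.get(key, ref_p.get(key[::-1]))
            assert abs(row["p"] - expected) < 1e-8

    def test_zero_variance_equal_means_flagged(self):
        r = compare_groups([2.0, 2.0], [2.0, 2.0])
        assert r.p_value == 1.0 and "zero variance" in r.flag

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError):
            compare_groups([1.0], [2.0, 3.0])

    def test_star_coding_thresholds(self):
        assert stars(0.04) == "*"
        assert stars(0.009) == "**"
        assert stars(0.004) == "***"
        assert stars(0.0009) == "****"
        assert stars(0.2) == "ns"
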