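"""Spline trajectory fitting, condition comparison, peak and resumption analysis."""

import numpy as np
import pandas as pd
import pytest

from coldclock.profiles import ClockGeneProfile, ColdResponseSpec, diurnal_mean
from coldclock.simulate import simulate_amplicon
from coldclock.trajectory import (
    AMPLICON_TIMEPOINTS,
    compare_trajectories,
    find_peak,
    fit_spline,
    relative_expression,
    time_to_peak_after_release,
)

TIMES = np.array(AMPLICON_TIMEPOINTS, dtype=float)


class TestRelativeExpression:
    def test_simple_ratio(self):
        np.testing.assert_allclose(relative_expression([100], [1000]), [0.1])

    def test_depth_scaling_invariance(self):
        g = np.array([10, 40, 90.0])
        r = np.array([100, 200, 300.0])
        np.testing.assert_allclose(relative_expression(g, r),
                                   relative_expression(2 * g, 2 * r))

    def test_zero_gene_reads_valid(self):
        assert relative_expression([0], [500])[0] == 0.0

    def test_zero_reference_names_sample(self):
        with pytest.raises(ValueError, match=r"sample\(s\) \[1\]"):
            relative_expression([5, 5], [10, 0])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            relative_expression([1, 2], [1, 2, 3])


class TestFitSpline:
    def test_exact_on_cubic_log_trajectory(self):
        # ratios whose log1p is exactly cubic lie in the basis span
        coefs = [0.3, 0.05, -0.004, 0.0001]
        y_log = sum(c * TIMES**i for i, c in enumerate(coefs))
        fit = fit_spline(TIMES, np.expm1(y_log), df=4)
        np.testing.assert_allclose(fit.fitted, y_log, atol=1e-8)

    def test_constant_series_fits_flat(self):
        fit = fit_spline(TIMES, np.full_like(TIMES, 0.7))
        np.testing.assert_allclose(fit.fitted, np.log1p(0.7), atol=1e-10)
        assert fit.resid_var == pytest.approx(0.0, abs=1e-16)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_spline([0, 1, 2, 3], [1, 2, 3, 4], df=4)

    def test_noise_free_cca1_trajectory_recovered(self, shoot_panel):
        # CCA1 is the hardest default trajectory (peak/trough ratio ~7e6);
        # a df=4 cubic spline tracks it to r ~ 0.99 on the 13-point grid
        cca1 = shoot_panel["CCA1"]
        values = diurnal_mean(cca1, TIMES + 2.5) / 3000.0
        fit = fit_spline(TIMES, values, df=4)
        r = np.corrcoef(fit.fitted, np.log1p(values))[0, 1]
        assert r > 0.985


def null_long_frame(rng, n_genes, noise_sd=0.08):
    # noise is additive on the log1p fitting scale, matching the error
    # model of the least-squares trajectory comparison
    rows = []
    for g in range(n_genes):
        base = np.exp(rng.normal(0.0, 0.3))
        traj = base * np.exp(0.5 * np.cos(2 * np.pi * (TIMES - 6) / 24))
        for cond in ("ambient", "cold"):
            log_vals = np.log1p(traj) + rng.normal(0, noise_sd, len(TIMES))
            vals = np.expm1(np.maximum(log_vals, 1e-9))
            for t, v in zip(TIMES, vals):
                rows.append({"gene_id": f"g{g:03d}", "condition": cond,
                             "time": t, "ratio": v})
    return pd.DataFrame(rows)


class TestCompareTrajectories:
    def test_null_pvalues_uniform(self):
        from scipy import stats
        rng = np.random.default_rng(8)
        res = compare_trajectories(null_long_frame(rng, 200))
        ks = stats.kstest(res["pvalue"], "uniform")
        assert ks.pvalue > 0.01

    def test_power_dampened_vs_ambient(self, shoot_panel):
        # flat cold vs 10-fold ambient oscillation at amplicon noise levels
        panel = {"CCA1": shoot_panel["CCA1"], "EF1a": shoot_panel["EF1a"]}
        hits = 0
        for seed in range(100):
            counts, design = simulate_amplicon(panel, TIMES + 2.5, seed=seed)
            ratio = relative_expression(counts.loc["CCA1"].to_numpy(),
                                        counts.loc["EF1a"].to_numpy())
            frame = pd.DataFrame({"gene_id": "CCA1",
                                  "condition": design["condition"],
                                  "time": design["zt"] - 2.5, "ratio": ratio})
            res = compare_trajectories(frame)
            hits += int(res["pvalue"].iloc[0] < 0.01)
        assert hits >= 95

    def test_condition_label_swap_symmetry(self):
        rng = np.random.default_rng(3)
        frame = null_long_frame(rng, 6)
        res1 = compare_trajectories(frame)
        swapped = frame.copy()
        swapped["condition"] = swapped["condition"].map(
            {"ambient": "cold", "cold": "ambient"})
        res2 = compare_trajectories(swapped)
        np.testing.assert_allclose(res1["pvalue"], res2["pvalue"], rtol=1e-9)

    def test_single_condition_rejected(self):
        rng = np.random.default_rng(0)
        frame = null_long_frame(rng, 3)
        with pytest.raises(ValueError):
            compare_trajectories(frame[frame["condition"] == "cold"])


class TestFindPeak:
    def test_cosine_peak_at_phase(self):
        t = np.round(np.arange(0, 24.01, 0.1), 10)
        v = np.cos(2 * np.pi * (t - 6.0) / 24.0)
        peak = find_peak(t, v)
        assert peak.found and peak.time == pytest.approx(6.0, abs=0.1)

    def test_constant_trajectory_has_no_peak(self):
        t = np.linspace(0, 24, 100)
        assert not find_peak(t, np.full_like(t, 3.3)).found

    def test_tie_breaks_to_earliest(self):
        peak = find_peak([0, 1, 2, 3], [0, 5, 5, 0])
        assert peak.time == 1

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            find_peak([], [])

    def test_prr7_ambient_peak(self, shoot_panel):
        prr7 = shoot_panel["PRR7"]
        t = np.round(np.arange(0, 24.01, 0.1), 10)
        peak = find_peak(t, diurnal_mean(prr7, t))
        assert peak.time == pytest.approx(14.5, abs=0.1)


class TestResumption:
    @pytest.mark.parametrize("duration", [3.0, 6.0, 9.0])
    def test_cca1_peaks_three_hours_after_release(self, shoot_panel, duration):
        assert time_to_peak_after_release(shoot_panel["CCA1"], duration) == \
            pytest.approx(3.0, abs=1e-9)

    def test_independent_of_duration(self, shoot_panel):
        values = {time_to_peak_after_release(shoot_panel["CCA1"], d)
                  for d in np.arange(1.0, 13.0, 1.5)}
        assert len(values) == 1

    def test_zero_duration_peaks_at_ambient_phase(self, shoot_panel):
        cca1 = shoot_panel["CCA1"]
        delta = time_to_peak_after_release(cca1, 0.0)
        peak_zt = (2.5 + delta) % 24.0
        assert peak_zt == pytest.approx(cca1.phase, abs=0.1)

    def test_negative_duration_rejected(self, shoot_panel):
        with pytest.raises(ValueError):
            time_to_peak_after_release(shoot_panel["CCA1"], -1.0)
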