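"""Sensitivity stage: event pooling, binned quantiles, model selection, S0."""

import numpy as np
import pandas as pd
import pytest

import rootzone as rz
from rootzone import sensitivity as sens
from rootzone.cwd import compute_cwd, mask_post_rewetting


def make_profile(x, y):
    return sens.BinnedProfile(
        bin_center=np.asarray(x, float),
        q_value=np.asarray(y, float),
        n_in_bin=np.full(len(x), 10),
    )


class TestSelectLargestEvents:
    def test_only_largest_event_of_year_retained(self):
        # two events in one 365-day year with maxima 50 and 80
        et = np.zeros(365)
        p_in = np.zeros(365)
        et[10:60] = 1.0
        p_in[60] = 100.0
        et[100:180] = 1.0
        p_in[180] = 100.0
        series, events = compute_cwd(et, p_in)
        series = mask_post_rewetting(series, events)
        activity = np.ones(365)
        pairs = sens.select_largest_events(series, events, activity)
        assert len(events) == 2
        big = max(events, key=lambda e: e.max_cwd)
        # all retained days belong to the larger event's span
        assert pairs["cwd"].max() <= big.max_cwd
        assert len(pairs) >= big.length - 1

    def test_masked_days_excluded_from_pairs(self):
        et = np.zeros(365)
        p_in = np.zeros(365)
        et[0:50] = 1.0       # rises to 50
        p_in[50:60] = 0.9    # decline below 90% of max -> masked tail
        et[50:60] = 0.0
        p_in[60] = 100.0
        series, events = compute_cwd(et, p_in)
        masked_series = mask_post_rewetting(series, events)
        pairs = sens.select_largest_events(masked_series, events, np.ones(365))
        n_masked = int(masked_series.masked.sum())
        assert n_masked > 0
        assert len(pairs) == events[0].length - n_masked

    def test_no_events_gives_empty_frame(self):
        series, events = compute_cwd(np.zeros(365), np.ones(365))
        pairs = sens.select_largest_events(series, events, np.ones(365))
        assert len(pairs) == 0


class TestBinQuantiles:
    def test_constant_activity_gives_constant_bins(self, rng):
        pairs = pd.DataFrame({"cwd": rng.random(500) * 100, "x_norm": 0.5})
        prof = sens.bin_quantiles(pairs)
        assert np.allclose(prof.q_value[prof.valid], 0.5)

    def test_points_on_line_reproduce_line_at_member_quantile(self, rng):
        cwd = rng.random(5000) * 200
        pairs = pd.DataFrame({"cwd": cwd, "x_norm": 0.8 - 0.002 * cwd})
        prof = sens.bin_quantiles(pairs)
        ok = prof.valid
        # the q-th within-bin quantile of an affine decreasing function is
        # the function at the (1-q)-th quantile of member positions: within
        # half a bin width of the center
        bin_w = prof.bin_center[1] - prof.bin_center[0]
        expected = 0.8 - 0.002 * prof.bin_center[ok]
        assert np.max(np.abs(prof.q_value[ok] - expected)) < 0.002 * bin_w

    def test_default_bin_count_is_fifty(self):
        pairs = pd.DataFrame({"cwd": np.linspace(0, 99, 1000), "x_norm": 1.0})
        prof = sens.bin_quantiles(pairs)
        assert len(prof.bin_center) == 50

    def test_too_few_bins_rejected(self):
        pairs = pd.DataFrame({"cwd": [1.0], "x_norm": [1.0]})
        with pytest.raises(ValueError):
            sens.bin_quantiles(pairs, n_bins=2)

    def test_thin_bins_yield_missing(self):
        pairs = pd.DataFrame({"cwd": [0.0, 1.0, 50.0], "x_norm": [1.0, 1.0, 0.5]})
        prof = sens.bin_quantiles(pairs, n_bins=5, min_count=3)
        assert np.isnan(prof.q_value).sum() >= 4


class TestFitCandidateModels:
    def test_noise_free_line_recovered_exactly(self):
        x = np.linspace(1, 200, 50)
        fits = sens.fit_candidate_models(make_profile(x, 0.9 - 0.003 * x))
        lin = fits["linear"]
        assert lin.intercept == pytest.approx(0.9, abs=1e-10)
        assert lin.slope1 == pytest.approx(-0.003, abs=1e-12)

    def test_two_segment_break_recovered_within_bin_width(self):
        x = np.linspace(1, 300, 50)
        brk = 150.0
        y = 0.8 - 0.004 * np.minimum(x, brk) - 0.001 * np.maximum(x - brk, 0.0)
        fits = sens.fit_candidate_models(make_profile(x, y))
        got = fits["segmented-1"].breakpoints[0]
        assert abs(got - brk) <= (x[1] - x[0]) + 1e-9

    def test_segmented_bic_exceeds_linear_on_pure_line(self, rng):
        # with zero RSS gain the breakpoint penalty must dominate
        x = np.linspace(1, 100, 40)
        y = 1.0 - 0.005 * x + rng.normal(0, 1e-4, 40)
        fits = sens.fit_candidate_models(make_profile(x, y))
        assert fits["linear"].bic < fits["segmented-2"].bic

    def test_too_few_points_rejected(self):
        x = np.arange(5.0)
        with pytest.raises(ValueError):
            sens.fit_candidate_models(make_profile(x, x))

    def test_model_selection_specificity_on_noisy_lines(self):
        # linear truth + Gaussian noise: linear must win BIC >= 90% of runs
        rng = np.random.default_rng(7)
        wins = 0
        n_rep = 200
        for _ in range(n_rep):
            x = np.linspace(1, 200, 50)
            y = 1.0 - 0.004 * x + rng.normal(0, 0.03, 50)
            fits = sens.fit_candidate_models(make_profile(x, y))
            winner = min(fits.values(), key=lambda f: f.bic)
            wins += winner.model_class == "linear"
        assert wins / n_rep >= 0.90


class TestClassifyAndEstimate:
    def test_s0_arithmetic(self):
        x = np.linspace(1, 300, 50)
        fits = sens.fit_candidate_models(make_profile(x, 0.8 - 0.002 * x))
        res = sens.classify_and_estimate(fits)
        assert res.classification == "estimate"
        assert res.s0_estimate == pytest.approx(400.0, rel=1e-9)

    def test_insignificant_slope_rejected(self, rng):
        x = np.linspace(1, 100, 50)
        y = 0.5 + rng.normal(0, 0.05, 50)  # flat: no water-stress signal
        fits = sens.fit_candidate_models(make_profile(x, y))
        res = sens.classify_and_estimate(fits)
        assert res.classification in ("rejected", "flattening")
        assert res.s0_estimate is None

    def test_scale_equivariance_of_estimate(self):
        x = np.linspace(1, 300, 50)
        y = 0.8 - 0.002 * x
        res1 = sens.classify_and_estimate(sens.fit_candidate_models(make_profile(x, y)))
        res2 = sens.classify_and_estimate(
            sens.fit_candidate_models(make_profile(x, 3.7 * y))
        )
        assert res2.intercept_a == pytest.approx(3.7 * res1.intercept_a)
        assert res2.slope_b == pytest.approx(3.7 * res1.slope_b)
        assert res2.s0_estimate == pytest.approx(res1.s0_estimate, rel=1e-9)

    def test_missing_linear_fit_rejected(self):
        with pytest.raises(ValueError):
            sens.classify_and_estimate({})


class TestEndToEnd:
    def test_noise_free_drydown_recovery(self):
        # constant-PET drydowns: profile exactly linear, S0 recovered closely
        cfg = rz.SimConfig(
            s0_true=200.0, years=30, seed=5, sif_noise_sd=0.0,
            rain_p01=0.1, rain_p11=0.6, rain_mean_depth=12.0,
            rain_seasonal_amp=0.9, pet_mean=3.5, pet_seasonal_amp=0.0,
            temp_mean=15.0, temp_seasonal_amp=0.0,
        )
        f = rz.generate_forcing(cfg)
        rec = rz.run_location(f, rz.PipelineConfig(activity="ef"))
        assert rec["classification"] == "estimate"
        assert rec["s0_estimate"] == pytest.approx(200.0, rel=0.10)

    def test_estimate_always_exceeds_observed_max_cwd(self):
        # censored humid regime: extrapolated S0 must exceed the largest CWD
        for seed in range(5):
            cfg = rz.SimConfig(s0_true=300.0, years=30, seed=seed, **rz.HUMID)
            f = rz.generate_forcing(cfg)
            rec = rz.run_location(f, rz.PipelineConfig(activity="sif"))
            if rec.get("s0_estimate"):
                assert rec["s0_estimate"] > rec["max_cwd"]
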