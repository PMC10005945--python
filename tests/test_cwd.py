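"""CWD engine: snow balance, unit conversion, events, masking, annual maxima."""

import numpy as np
import pytest

from oracle_cwd import brute_force_cwd, brute_force_mask
from rootzone import (
    CwdSeries,
    SnowState,
    annual_max_cwd,
    compute_cwd,
    latent_heat_to_mass,
    mask_post_rewetting,
    snow_water_balance,
)


class TestSnowWaterBalance:
    def test_no_melt_below_one_degree(self):
        state = SnowState(snowpack=10.0)
        p_in, pack = snow_water_balance([4.0], [0.0], [0.5], state)
        assert p_in[0] == 4.0 and pack[0] == 10.0

    def test_degree_day_melt_rate(self):
        # 3 degC with threshold 1 and rate 1 -> melt 2 mm
        state = SnowState(snowpack=10.0)
        p_in, pack = snow_water_balance([0.0], [0.0], [3.0], state)
        assert p_in[0] == pytest.approx(2.0)
        assert pack[0] == pytest.approx(8.0)

    def test_melt_capped_by_available_snow(self):
        state = SnowState(snowpack=5.0)
        p_in, pack = snow_water_balance([0.0], [0.0], [50.0], state)
        assert p_in[0] == pytest.approx(5.0) and pack[0] == 0.0

    def test_snow_conservation(self, rng):
        n = 400
        rain = rng.exponential(2.0, n)
        snowfall = rng.exponential(1.0, n) * (rng.random(n) < 0.3)
        temp = rng.normal(0.0, 6.0, n)
        state = SnowState()
        p_in, pack = snow_water_balance(rain, snowfall, temp, state)
        melt = p_in - rain
        assert abs(snowfall.sum() - (pack[-1] + melt.sum())) < 1e-9

    def test_negative_precip_rejected(self):
        with pytest.raises(ValueError):
            snow_water_balance([-1.0], [0.0], [0.0])


class TestLatentHeatToMass:
    def test_zero_flux_gives_zero_et(self):
        assert latent_heat_to_mass(0.0) == 0.0

    def test_unit_conversion_with_constant_lambda(self):
        # 2.501e6 / 86400 = 28.947 W m-2 per mm/day
        et = latent_heat_to_mass(
            2.501e6 / 86400.0, latent_heat_fn=lambda t, p: 2.501e6
        )
        assert et == pytest.approx(1.0, abs=1e-12)

    def test_et_increasing_in_temperature(self):
        et_cold = latent_heat_to_mass(30.0, temp=0.0)
        et_warm = latent_heat_to_mass(30.0, temp=30.0)
        assert et_warm > et_cold


class TestComputeCwd:
    def test_pure_accumulation(self):
        series, events = compute_cwd([1.0, 1.0, 1.0], [0.0, 0.0, 0.0])
        np.testing.assert_allclose(series.cwd, [1, 2, 3])
        assert len(events) == 1
        assert events[0].max_cwd == 3 and events[0].end_day == 3

    def test_event_closes_when_rain_zeroes_the_sum(self):
        series, events = compute_cwd([1.0, 1.0, 0.0], [0.0, 0.0, 5.0])
        np.testing.assert_allclose(series.cwd, [1, 2, 0])
        assert len(events) == 1
        assert events[0].start_day == 0 and events[0].end_day == 3
        assert events[0].max_cwd == pytest.approx(2.0)

    def test_no_event_without_net_loss(self):
        series, events = compute_cwd([0.0, 0.0], [5.0, 5.0])
        assert np.all(series.cwd == 0) and events == []

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            compute_cwd([1.0], [0.0])

    def test_runaway_event_flagged_and_discarded(self):
        n = 6 * 365
        series, events = compute_cwd(np.ones(n), np.zeros(n))
        assert len(events) == 1 and events[0].discarded_runaway
        assert series.discarded.all()

    def test_oracle_equivalence_on_random_series(self, rng):
        for _ in range(200):
            n = int(rng.integers(10, 400))
            et = rng.exponential(2.0, n)
            p_in = rng.exponential(2.5, n) * (rng.random(n) < 0.4)
            series, events = compute_cwd(et, p_in)
            cwd_ref, eid_ref, ev_ref = brute_force_cwd(et, p_in)
            np.testing.assert_allclose(series.cwd, cwd_ref, atol=1e-9)
            np.testing.assert_array_equal(series.event_id, eid_ref)
            assert len(events) == len(ev_ref)
            for ev, (s, e, m, dm, run) in zip(events, ev_ref):
                assert (ev.start_day, ev.end_day, ev.day_of_max) == (s, e, dm)
                assert ev.max_cwd == pytest.approx(m, abs=1e-9)
                assert ev.discarded_runaway == run

    def test_idempotence(self, rng):
        et = rng.exponential(2.0, 300)
        p_in = rng.exponential(2.0, 300) * (rng.random(300) < 0.5)
        a = compute_cwd(et, p_in)
        b = compute_cwd(et, p_in)
        np.testing.assert_array_equal(a[0].cwd, b[0].cwd)
        assert [vars(e) for e in a[1]] == [vars(e) for e in b[1]]


class TestMaskPostRewetting:
    def test_strictly_increasing_event_unmasked(self):
        series, events = compute_cwd([1.0, 1.0, 1.0, 1.0], [0.0] * 4)
        masked = mask_post_rewetting(series, events).masked
        assert not masked.any()

    def test_post_peak_drop_below_fraction_masks_remainder(self):
        # peak 4 on day 3, rain drops CWD to 3.0 (< 0.9*4) on day 4
        et = [1.0, 1.0, 1.0, 1.0, 0.0, 1.0]
        p_in = [0.0, 0.0, 0.0, 0.0, 1.0, 0.5]
        series, events = compute_cwd(et, p_in)
        out = mask_post_rewetting(series, events, fraction=0.9)
        np.testing.assert_array_equal(out.masked, [0, 0, 0, 0, 1, 1])
        # CWD values themselves unchanged
        np.testing.assert_allclose(out.cwd, series.cwd)

    def test_fraction_one_masks_any_post_peak_decline(self):
        # cwd = [1, 2, 3, 2.9]: the slightest decline after the peak masks
        et = [1.0, 1.0, 1.0, 0.5]
        p_in = [0.0, 0.0, 0.0, 0.6]
        series, events = compute_cwd(et, p_in)
        out = mask_post_rewetting(series, events, fraction=1.0)
        np.testing.assert_array_equal(out.masked, [0, 0, 0, 1])

    def test_rising_limb_dip_before_peak_not_masked(self):
        # dip on day 2 while the deficit is still building to its max
        et = [1.0, 1.0, 0.0, 2.0, 2.0, 2.0]
        p_in = [0.0, 0.0, 0.5, 0.0, 0.0, 0.0]
        series, events = compute_cwd(et, p_in)
        out = mask_post_rewetting(series, events, fraction=0.9)
        assert not out.masked[:5].any()

    def test_invalid_fraction_rejected(self):
        series, events = compute_cwd([1.0, 1.0], [0.0, 0.0])
        with pytest.raises(ValueError):
            mask_post_rewetting(series, events, fraction=0.0)

    def test_oracle_equivalence_on_random_series(self, rng):
        for _ in range(100):
            n = int(rng.integers(20, 300))
            et = rng.exponential(2.0, n)
            p_in = rng.exponential(2.0, n) * (rng.random(n) < 0.5)
            series, events = compute_cwd(et, p_in)
            out = mask_post_rewetting(series, events)
            cwd_ref, _, ev_ref = brute_force_cwd(et, p_in)
            np.testing.assert_array_equal(out.masked, brute_force_mask(cwd_ref, ev_ref))


class TestAnnualMaxCwd:
    def test_all_zero_year(self):
        n = 365
        series = CwdSeries(
            day_index=np.arange(n), cwd=np.zeros(n), event_id=np.full(n, -1)
        )
        maxima = annual_max_cwd(series)
        assert maxima.loc[0] == 0.0

    def test_triangular_event_peak(self):
        n = 365
        cwd = np.zeros(n)
        cwd[100:121] = np.concatenate([np.linspace(6, 120, 10), np.linspace(110, 0, 11)])
        series = CwdSeries(day_index=np.arange(n), cwd=cwd, event_id=np.full(n, -1))
        assert annual_max_cwd(series).loc[0] == pytest.approx(120.0)

    def test_event_spanning_year_boundary_split_by_day(self):
        n = 2 * 365
        et = np.zeros(n)
        et[360:375] = 2.0  # event crosses the year boundary
        series, _ = compute_cwd(et, np.zeros(n))
        maxima = annual_max_cwd(series)
        assert maxima.loc[0] == pytest.approx(2.0 * 5)  # days 360..364
        assert maxima.loc[1] == pytest.approx(2.0 * 15)  # peak in year 1

    def test_runaway_year_yields_nan(self):
        n = 7 * 365
        series, _ = compute_cwd(np.ones(n), np.zeros(n))
        maxima = annual_max_cwd(series)
        assert maxima.isna().all()

    def test_empty_series_rejected(self):
        series = CwdSeries(day_index=np.array([]), cwd=np.array([]), event_id=np.array([]))
        with pytest.raises(ValueError):
            annual_max_cwd(series)
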