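import numpy as np
import pytest

from grasstrend import (
    DegenerateSeriesError,
    EstimationFailedError,
    GrasstrendError,
    RasterStack,
    StackConfig,
    SustainClass,
    classify_sustainability,
    default_tau_grid,
    hurst_exponent,
    hurst_map,
    rescaled_range,
    simulate_fgn,
    simulate_stack,
)


class TestRescaledRange:
    def test_hand_computed_two_point_window(self):
        # {1, 2}: deviations {-0.5, +0.5}, cumsum {-0.5, 0}, R = 0.5,
        # S = 0.5 (population), R/S = 1
        p = rescaled_range([1.0, 2.0], 2)
        assert p.rs == pytest.approx(1.0)
        assert p.n_windows == 1

    def test_constant_series_degenerate(self):
        with pytest.raises(DegenerateSeriesError):
            rescaled_range([3.0] * 12, 4)

    def test_tau_equal_n_gives_one_window(self, rng):
        series = rng.normal(size=16)
        assert rescaled_range(series, 16).n_windows == 1

    def test_window_count_and_leftover_discarded(self, rng):
        series = rng.normal(size=13)
        assert rescaled_range(series, 4).n_windows == 3

    def test_affine_invariance(self, rng):
        series = rng.normal(size=64)
        base = rescaled_range(series, 8).rs
        assert rescaled_range(series * 7.5 + 100, 8).rs == pytest.approx(base)

    def test_tau_out_of_range(self, rng):
        with pytest.raises(GrasstrendError):
            rescaled_range(rng.normal(size=10), 11)


class TestHurstExponent:
    def test_white_noise_near_half(self):
        # classical R/S carries a small positive bias at finite n
        rng = np.random.default_rng(77)
        ests = [hurst_exponent(rng.standard_normal(4096))[0] for _ in range(50)]
        assert 0.45 <= np.mean(ests) <= 0.62

    def test_fgn_recovery_at_0p8(self):
        rng = np.random.default_rng(88)
        ests = [
            hurst_exponent(simulate_fgn(2048, 0.8, rng))[0] for _ in range(50)
        ]
        assert abs(np.mean(ests) - 0.8) <= 0.1

    def test_trending_series_near_one(self):
        h, _ = hurst_exponent(np.arange(256, dtype=float))
        assert h >= 0.9

    def test_monotone_in_true_h(self):
        rng = np.random.default_rng(99)
        means = []
        for h_true in (0.3, 0.5, 0.7, 0.9):
            ests = [
                hurst_exponent(simulate_fgn(1024, h_true, rng))[0]
                for _ in range(50)
            ]
            means.append(np.mean(ests))
        assert means == sorted(means)

    def test_log_rs_grows_with_tau_in_expectation(self):
        rng = np.random.default_rng(5)
        taus = [8, 16, 32, 64]
        mean_rs = np.zeros(len(taus))
        for _ in range(30):
            s = simulate_fgn(256, 0.5, rng)
            mean_rs += [rescaled_range(s, t).rs for t in taus]
        assert np.all(np.diff(np.log(mean_rs)) > 0)

    def test_too_few_points_rejected(self, rng):
        with pytest.raises(EstimationFailedError):
            hurst_exponent(rng.normal(size=20), tau_grid=[4, 5])

    def test_anis_lloyd_correction_reduces_short_series_bias(self):
        rng = np.random.default_rng(42)
        raw, corrected = [], []
        for _ in range(200):
            s = rng.standard_normal(13)
            raw.append(hurst_exponent(s)[0])
            corrected.append(hurst_exponent(s, correction="anis-lloyd")[0])
        assert abs(np.mean(corrected) - 0.5) < abs(np.mean(raw) - 0.5)

    def test_default_grid_shapes(self):
        assert default_tau_grid(13) == [3, 4, 6, 12, 13]
        grid = default_tau_grid(100)
        assert grid[0] == 4 and grid[-1] == 100 and 50 in grid


class TestClassifySustainability:
    @pytest.mark.parametrize("h, expected", [
        (0.68, SustainClass.SUSTAINABLE),
        (0.5, SustainClass.RANDOM),
        (0.3, SustainClass.ANTI_SUSTAINABLE),
        (0.500001, SustainClass.SUSTAINABLE),
    ])
    def test_threshold_rule(self, h, expected):
        assert classify_sustainability(h) == expected

    def test_tolerance_band(self):
        assert classify_sustainability(0.52, tol=0.05) == SustainClass.RANDOM
        assert classify_sustainability(0.56, tol=0.05) == SustainClass.SUSTAINABLE


class TestHurstMap:
    def test_persistent_and_antipersistent_fields(self):
        for h_true, expect in ((0.7, SustainClass.SUSTAINABLE),
                               (0.3, SustainClass.ANTI_SUSTAINABLE)):
            data = simulate_stack(StackConfig(
                n_rows=15, n_cols=15, n_years=256, trend_mean=0.0,
                trend_sd=0.0, hurst_target=h_true, innovation_sd=1.0,
                baseline=0.0, seed=21,
            ))
            res = hurst_map(data.stack)
            frac = np.mean(res.sustainability == expect)
            assert frac >= 0.8, f"H*={h_true}: only {frac:.2f} classified"

    def test_fractions_partition(self, annual_stack_data):
        res = hurst_map(annual_stack_data.stack)
        codes = res.sustainability
        total = np.sum(codes > 0)
        parts = sum(int(np.sum(codes == c)) for c in SustainClass)
        assert parts == total == codes.size

    def test_map_matches_per_pixel_estimates(self, annual_stack_data):
        res = hurst_map(annual_stack_data.stack)
        v = annual_stack_data.stack.values
        for (i, j) in [(0, 0), (3, 7), (9, 9)]:
            h, a = hurst_exponent(v[:, i, j])
            assert res.h[i, j] == pytest.approx(h, abs=1e-10)
            assert res.fit_intercept[i, j] == pytest.approx(a, abs=1e-10)

    def test_nodata_year_masks_pixel(self, annual_stack_data):
        vals = annual_stack_data.stack.values.copy()
        vals[2, 0, 0] = np.nan
        stack = RasterStack(vals, annual_stack_data.stack.times)
        res = hurst_map(stack)
        assert np.isnan(res.h[0, 0])
        assert res.sustainability[0, 0] == 0
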