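import numpy as np
import pytest

from grasstrend import (
    Family,
    GrasslandType,
    GrasstrendError,
    GridMismatchError,
    PlotRecord,
    RasterStack,
    TypeCode,
    estimate_agb,
    fit_agb_models,
    flower_sensitivity,
    predict,
)
from grasstrend.agb import QA_EXTRAPOLATED, QA_FLOORED, AgbModelSet
from grasstrend.synthetic import SurveyConfig, generator_model, simulate_survey


def make_plots(gt, ndvis, agbs, flower=0.0):
    return [
        PlotRecord(f"{gt.value}{i}", gt, a, v, flower_coverage=flower)
        for i, (v, a) in enumerate(zip(ndvis, agbs))
    ]


linear = generator_model(Family.LINEAR, 200.0, 900.0)
power = generator_model(Family.POWER, 1200.0, 1.8)


class TestFitAgbModels:
    def test_exact_generating_laws_recovered(self, rng):
        m_ndvi = rng.uniform(0.52, 0.78, 20)
        s_ndvi = rng.uniform(0.1, 0.48, 20)
        plots = make_plots(GrasslandType.MEADOW, m_ndvi, predict(linear, m_ndvi))
        plots += make_plots(GrasslandType.STEPPE, s_ndvi, predict(power, s_ndvi))
        models = fit_agb_models(plots)
        assert models.meadow.family == Family.LINEAR
        assert models.meadow.a == pytest.approx(200.0, rel=1e-6)
        assert models.meadow.b == pytest.approx(900.0, rel=1e-6)
        assert models.meadow.r_squared == pytest.approx(1.0)
        assert models.steppe.family == Family.POWER
        assert models.steppe.a == pytest.approx(1200.0, rel=1e-5)
        assert models.steppe.b == pytest.approx(1.8, rel=1e-5)

    def test_steppe_power_monte_carlo_recovery(self):
        # AGB = 1200 * NDVI^1.8 + N(0, 30), n = 33 plots per replicate
        rng = np.random.default_rng(2024)
        wins, bs = 0, []
        for _ in range(100):
            ndvi = rng.uniform(0.05, 0.5, 33)
            agb = np.maximum(predict(power, ndvi) + rng.normal(0, 30, 33), 0.0)
            plots = make_plots(GrasslandType.STEPPE, ndvi, agb)
            plots += make_plots(
                GrasslandType.MEADOW, [0.6, 0.65, 0.7], [700, 750, 800]
            )
            models = fit_agb_models(plots)
            if models.steppe.family == Family.POWER:
                wins += 1
                bs.append(models.steppe.b)
        assert wins >= 90
        assert abs(np.median(bs) - 1.8) <= 0.2

    def test_type_with_too_few_plots_rejected(self):
        plots = make_plots(GrasslandType.MEADOW, [0.6, 0.7], [740, 830])
        plots += make_plots(GrasslandType.STEPPE, [0.2, 0.3, 0.4],
                            [100, 200, 300])
        with pytest.raises(GrasstrendError, match="meadow"):
            fit_agb_models(plots)

    def test_survey_means_reproduced_at_mean_ndvi(self, survey):
        # the generator laws are scaled so type-mean AGB matches the reported
        # plot averages; the fitted model evaluated at the mean NDVI must land
        # near the type-mean AGB
        models = fit_agb_models(survey.plots)
        for gt, model in ((GrasslandType.MEADOW, models.meadow),
                          (GrasslandType.STEPPE, models.steppe)):
            sub = [p for p in survey.plots if p.grassland_type == gt]
            mean_ndvi = np.mean([p.mean_field_ndvi for p in sub])
            mean_agb = np.mean([p.mean_agb_kg_per_hm2 for p in sub])
            assert predict(model, mean_ndvi) == pytest.approx(
                mean_agb, rel=0.10
            )


class TestEstimateAgb:
    def _stack(self, values):
        values = np.asarray(values, dtype=float)
        return RasterStack(values, list(range(2000, 2000 + values.shape[0])))

    def _models(self):
        return AgbModelSet(meadow=linear, steppe=power)

    def test_uniform_meadow(self):
        stack = self._stack(np.full((1, 3, 3), 0.6))
        tm = np.full((3, 3), TypeCode.MEADOW, dtype=np.uint8)
        est = estimate_agb(stack, tm, self._models())
        np.testing.assert_allclose(est.agb.values, 740.0)

    def test_non_grassland_masked(self):
        stack = self._stack(np.full((1, 2, 2), 0.6))
        tm = np.array([[1, 0], [2, 0]], dtype=np.uint8)
        est = estimate_agb(stack, tm, self._models())
        assert np.isnan(est.agb.values[0, :, 1]).all()
        assert not np.isnan(est.agb.values[0, :, 0]).any()

    def test_mixed_map_matches_per_type_mosaic(self, rng):
        ndvi = rng.uniform(0.05, 0.8, (2, 6, 6))
        stack = self._stack(ndvi)
        tm = rng.integers(0, 3, (6, 6)).astype(np.uint8)
        est = estimate_agb(stack, tm, self._models())
        # two-pass oracle: apply each model over the full grid, then mosaic
        all_meadow = estimate_agb(
            stack, np.full((6, 6), 1, np.uint8), self._models()
        ).agb.values
        all_steppe = estimate_agb(
            stack, np.full((6, 6), 2, np.uint8), self._models()
        ).agb.values
        expected = np.where((tm == 1)[None], all_meadow,
                            np.where((tm == 2)[None], all_steppe, np.nan))
        np.testing.assert_allclose(est.agb.values, expected)

    def test_output_non_negative_and_qa_flags(self):
        down = generator_model(Family.LINEAR, -100.0, 900.0)  # negative at low NDVI
        models = AgbModelSet(meadow=down, steppe=power)
        stack = self._stack(np.array([[[0.05, 0.85]]]))
        tm = np.full((1, 2), TypeCode.MEADOW, np.uint8)
        est = estimate_agb(stack, tm, models)
        assert est.agb.values[0, 0, 0] == 0.0  # floored
        assert est.qa[0, 0, 0] & QA_FLOORED
        assert est.qa[0, 0, 1] & QA_EXTRAPOLATED
        assert np.nanmin(est.agb.values) >= 0.0

    def test_monotone_models_preserve_pixel_order(self, rng):
        ndvi = np.sort(rng.uniform(0.1, 0.75, 16)).reshape(1, 4, 4)
        tm = np.full((4, 4), TypeCode.STEPPE, np.uint8)
        est = estimate_agb(self._stack(ndvi), tm, self._models())
        flat = est.agb.values.ravel()
        assert np.all(np.diff(flat) >= 0)

    def test_grid_mismatch_rejected(self):
        stack = self._stack(np.full((1, 3, 3), 0.5))
        with pytest.raises(GridMismatchError):
            estimate_agb(stack, np.ones((2, 2), np.uint8), self._models())


class TestFlowerSensitivity:
    def test_no_contamination_refit_identical(self, rng):
        ndvi = rng.uniform(0.52, 0.78, 10)
        plots = make_plots(GrasslandType.MEADOW, ndvi, predict(linear, ndvi))
        ndvi_s = rng.uniform(0.1, 0.48, 10)
        plots += make_plots(GrasslandType.STEPPE, ndvi_s, predict(power, ndvi_s))
        orig, refit, excluded = flower_sensitivity(plots)
        assert excluded == {"meadow": 0, "steppe": 0}
        assert orig == refit

    def test_zero_threshold_excludes_any_flowers(self, rng):
        ndvi = rng.uniform(0.52, 0.78, 8)
        plots = make_plots(GrasslandType.MEADOW, ndvi[:4],
                           predict(linear, ndvi[:4]), flower=0.0)
        plots += make_plots(GrasslandType.STEPPE, ndvi[4:] - 0.3,
                            predict(power, ndvi[4:] - 0.3), flower=0.0)
        flowered = make_plots(GrasslandType.MEADOW, [0.6, 0.7],
                              [740, 830], flower=0.05)
        flowered = [PlotRecord(f"F{i}", p.grassland_type,
                               p.mean_agb_kg_per_hm2, p.mean_field_ndvi,
                               flower_coverage=p.flower_coverage)
                    for i, p in enumerate(flowered)]
        _, _, excluded = flower_sensitivity(plots + flowered,
                                            coverage_threshold=0.0)
        assert excluded == {"meadow": 2, "steppe": 0}

    def test_contamination_direction(self):
        # contaminated meadow plots have measured NDVI inflated by +0.05 and
        # carry the flowers' clipped biomass; the flower-free refit must
        # predict lower AGB at a fixed mid-range NDVI than the original model
        data = simulate_survey(SurveyConfig(seed=11))
        orig, refit, excluded = flower_sensitivity(data.plots)
        assert excluded["meadow"] > 0
        assert predict(refit.meadow, 0.65) < predict(orig.meadow, 0.65)

    def test_exclusion_leaving_too_few_plots_rejected(self, rng):
        ndvi = rng.uniform(0.52, 0.78, 4)
        plots = make_plots(GrasslandType.MEADOW, ndvi, predict(linear, ndvi),
                           flower=0.5)
        ndvi_s = rng.uniform(0.1, 0.48, 5)
        plots += make_plots(GrasslandType.STEPPE, ndvi_s, predict(power, ndvi_s))
        with pytest.raises(GrasstrendError, match="meadow"):
            flower_sensitivity(plots)
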