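"""IRLS Poisson core: closed forms, invariances, oracle agreement."""

import math

import numpy as np
import pandas as pd
import pytest

from portmort.regression import (
    DesignMatrix,
    ModelSpec,
    PercentChange,
    build_design,
    fit_poisson,
    percent_change,
    run_association_suite,
)
from portmort.stratify import classify_harbour

from conftest import small_config
from portmort.synth import generate_city


def design_from_arrays(X, y, offset, columns):
    return DesignMatrix(X=np.asarray(X, dtype=float),
                        y=np.asarray(y, dtype=float),
                        offset=np.asarray(offset, dtype=float),
                        columns=columns,
                        index=pd.DataFrame(index=range(len(y))))


class TestClosedForms:
    def test_intercept_only_mle(self):
        d = design_from_arrays([[1.0], [1.0]], [3.0, 7.0],
                               np.log([10.0, 10.0]), ["intercept"])
        fit = fit_poisson(d)
        assert fit.converged
        assert fit.params["intercept"] == pytest.approx(math.log(0.5),
                                                        abs=1e-10)

    def test_two_group_rate_ratio_exact(self):
        # aggregated two-group data: exp(beta) is the ratio of crude rates;
        # counts and denominators follow the harbour/rest population split
        y = np.array([5003.0, 581.0])
        py = np.array([90_085.0 * 5, 10_258.0 * 5])
        d = design_from_arrays([[1.0, 0.0], [1.0, 1.0]], y, np.log(py),
                               ["intercept", "harbour"])
        fit = fit_poisson(d)
        rr_closed = (y[1] / py[1]) / (y[0] / py[0])
        assert math.exp(fit.params["harbour"]) == pytest.approx(rr_closed,
                                                                abs=1e-10)
        assert rr_closed == pytest.approx(1.0198, abs=5e-5)

    def test_matches_statsmodels_on_random_data(self):
        """20 seeded designs: coefficient agreement to 1e-6."""
        import statsmodels.api as sm

        rng = np.random.default_rng(404)
        for _ in range(20):
            n, p = 150, 4
            X = np.column_stack([np.ones(n), rng.normal(size=(n, p - 1))])
            offset = np.log(rng.uniform(50, 500, size=n))
            beta = rng.normal(scale=0.3, size=p)
            y = rng.poisson(np.exp(X @ beta + offset) * 0.01)
            d = design_from_arrays(X, y, offset + math.log(0.01),
                                   [f"b{i}" for i in range(p)])
            fit = fit_poisson(d)
            ref = sm.GLM(y, X, family=sm.families.Poisson(),
                         offset=d.offset).fit()
            assert fit.converged
            assert np.abs(fit.params.to_numpy() - ref.params).max() < 1e-6


class TestPercentChange:
    @staticmethod
    def _fit(beta, se=0.01):
        params = pd.Series({"intercept": 0.0, "pm25": beta})
        cov = pd.DataFrame(np.diag([1e-4, se ** 2]),
                           index=params.index, columns=params.index)
        from portmort.regression import RegressionFit
        return RegressionFit(params=params, cov=cov, deviance=0.0,
                             iterations=1, converged=True, drift_flags=[])

    def test_null_beta_gives_zero(self):
        pc = percent_change(self._fit(0.0), "pm25", 5.0)
        assert pc.estimate == 0.0
        assert pc.lower < 0.0 < pc.upper

    def test_rr_per_10_rescales_to_per_5(self):
        beta = math.log(1.08) / 10.0
        pc = percent_change(self._fit(beta), "pm25", 5.0)
        assert pc.estimate == pytest.approx((math.sqrt(1.08) - 1) * 100,
                                            abs=1e-9)
        assert pc.estimate == pytest.approx(3.923, abs=5e-4)

    def test_increment_consistency_identity(self):
        fit = self._fit(0.0123)
        per5 = percent_change(fit, "pm25", 5.0).estimate
        per10 = percent_change(fit, "pm25", 10.0).estimate
        assert (1 + per10 / 100) == pytest.approx((1 + per5 / 100) ** 2,
                                                  abs=1e-12)


class TestInvariances:
    @staticmethod
    def _simple_design(rng, x=None):
        n = 80
        if x is None:
            x = rng.uniform(10, 30, size=n)
        X = np.column_stack([np.ones(n), x])
        offset = np.log(rng.uniform(100, 1000, size=n))
        y = rng.poisson(np.exp(offset - 6 + 0.02 * x))
        return x, y, offset

    def test_exposure_shift_changes_only_intercept(self, rng):
        x, y, offset = self._simple_design(rng)
        d0 = design_from_arrays(np.column_stack([np.ones(len(x)), x]), y,
                                offset, ["intercept", "x"])
        d1 = design_from_arrays(np.column_stack([np.ones(len(x)), x + 7.0]),
                                y, offset, ["intercept", "x"])
        f0, f1 = fit_poisson(d0), fit_poisson(d1)
        assert f1.params["x"] == pytest.approx(f0.params["x"], abs=1e-10)
        assert f1.params["intercept"] == pytest.approx(
            f0.params["intercept"] - 7.0 * f0.params["x"], abs=1e-8)

    def test_exposure_rescaling_rescales_beta(self, rng):
        x, y, offset = self._simple_design(rng)
        k = 5.0
        d0 = design_from_arrays(np.column_stack([np.ones(len(x)), x]), y,
                                offset, ["intercept", "x"])
        dk = design_from_arrays(np.column_stack([np.ones(len(x)), x * k]),
                                y, offset, ["intercept", "x"])
        f0, fk = fit_poisson(d0), fit_poisson(dk)
        assert fk.params["x"] == pytest.approx(f0.params["x"] / k, abs=1e-10)

    def test_reference_categories_do_not_move_exposure_estimate(self):
        b = math.log(1.2) / 5
        cfg = small_config(n_tracts=4, total_population=4000,
                           flat_rate=2e-2, amplitude=8.0,
                           true_beta={"natural": {"pm25": b},
                                      "cardiovascular": {"pm25": b}})
        city = generate_city(cfg)
        stratum = classify_harbour(city.tracts, cfg.harbour_centroid, 800.0)
        spec = ModelSpec("cardiovascular", "pm25", 3)
        fits = []
        for ref_s, ref_ses in [(("35-64", "m"), "very_high"),
                               (("75+", "f"), "low")]:
            d = build_design(city.tracts, city.deaths, city.exposures,
                             stratum, spec, ref_stratum=ref_s, ref_ses=ref_ses)
            fits.append(fit_poisson(d).params["pm25"])
        assert fits[0] == pytest.approx(fits[1], abs=1e-8)


class TestDesignConstruction:
    def test_level1_has_intercept_and_exposure_only(self, toy_city):
        stratum = classify_harbour(toy_city.tracts, toy_city.config.harbour_centroid, 800.0)
        d = build_design(toy_city.tracts, toy_city.deaths, toy_city.exposures,
                         stratum, ModelSpec("natural", "pm25", 1))
        assert d.columns == ["intercept", "pm25"]

    def test_row_per_populated_stratum(self):
        cfg = small_config(n_tracts=2, total_population=4000)
        city = generate_city(cfg)
        stratum = classify_harbour(city.tracts, cfg.harbour_centroid, 800.0)
        d = build_design(city.tracts, city.deaths, city.exposures, stratum,
                         ModelSpec("natural", "pm25", 2))
        assert len(d.y) == 20  # 2 tracts x 10 strata, all populated
        assert d.n_dropped == 0

    def test_level3_column_count(self, preset_city, preset_stratum):
        d = build_design(preset_city.tracts, preset_city.deaths,
                         preset_city.exposures, preset_stratum,
                         ModelSpec("natural", "pm25", 3))
        # intercept + exposure + 9 stratum dummies + 5 SES dummies
        assert len(d.columns) == 16

    def test_all_zero_outcome_refused(self, toy_city):
        stratum = classify_harbour(toy_city.tracts, toy_city.config.harbour_centroid, 800.0)
        deaths = toy_city.deaths.copy()
        deaths["deaths"] = 0
        with pytest.raises(ValueError, match="zero"):
            build_design(toy_city.tracts, deaths, toy_city.exposures, stratum,
                         ModelSpec("natural", "pm25", 1))

    def test_rank_deficiency_names_column(self):
        X = np.column_stack([np.ones(10), np.arange(10.0), np.arange(10.0)])
        d = design_from_arrays(X, np.ones(10), np.zeros(10),
                               ["intercept", "x", "x_copy"])
        with pytest.raises(ValueError, match="x"):
            fit_poisson(d)

    def test_separation_drift_is_flagged(self):
        # indicator group with zero events: MLE at -infinity
        X = np.column_stack([np.ones(6), [0, 0, 0, 1, 1, 1]])
        y = np.array([5.0, 7.0, 6.0, 0.0, 0.0, 0.0])
        d = design_from_arrays(X, y, np.zeros(6), ["intercept", "g"])
        fit = fit_poisson(d)
        assert "g" in (fit.drift_flags or [])
        with pytest.raises(ValueError, match="drift"):
            percent_change(fit, "g", 1.0)


class TestAssociationSuite:
    def test_single_cause_grid_shape(self, toy_city):
        stratum = classify_harbour(toy_city.tracts, toy_city.config.harbour_centroid, 800.0)
        out = run_association_suite(toy_city.tracts, toy_city.deaths,
                                    toy_city.exposures, stratum,
                                    causes=["natural"], pollutants=["pm25"])
        # 1 cause x (1 pollutant + harbour) x 3 levels
        assert len(out) == 6
        assert out["converged"].all()

    def test_failed_cell_does_not_abort(self, toy_city):
        stratum = classify_harbour(toy_city.tracts, toy_city.config.harbour_centroid, 800.0)
        deaths = toy_city.deaths.copy()
        deaths.loc[deaths["cause"] == "respiratory", "deaths"] = 0
        out = run_association_suite(toy_city.tracts, deaths,
                                    toy_city.exposures, stratum,
                                    causes=["respiratory", "natural"],
                                    pollutants=["pm25"])
        resp = out[out["cause"] == "respiratory"]
        assert (~resp["converged"]).all()
        assert out[out["cause"] == "natural"]["converged"].all()
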