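"""Landscape projection, optimum intervals, OA/OAE scenarios and thresholds."""

import math

import numpy as np
import pytest

from carbscape import (
    CANONICAL_PROFILES,
    GridSpec,
    KineticParams,
    ScenarioSpec,
    alkalinity_threshold,
    eq1_rate,
    oa_threshold,
    oae_scenario,
    optimum_interval,
    predict_landscape,
)
from carbscape.kinetics import derive_kinetics, FitResult
from carbscape.speciation import speciate_from_ta_dic


def _fit_from_params(params: KineticParams) -> FitResult:
    return FitResult(params=params, derived=derive_kinetics(params),
                     r_squared=1.0, n_points=0,
                     model_id="eq1" if params.S > 0 else "eq2")


@pytest.fixture(scope="module")
def cusp_fit():
    return _fit_from_params(CANONICAL_PROFILES["P_cuspidata"].params)


@pytest.fixture(scope="module")
def melo_fit():
    return _fit_from_params(CANONICAL_PROFILES["Melosira_sp"].params)


class TestPredictLandscape:
    def test_rate_depends_on_co2_only(self, cusp_fit):
        """Cells sharing CO2 share the predicted rate (iso-CO2 contours)."""
        ls = predict_landscape(cusp_fit, GridSpec())
        tab = ls.table
        # check via direct reconstruction: rate must equal the curve at co2
        np.testing.assert_allclose(
            tab["rate"], eq1_rate(tab["co2"].to_numpy(), cusp_fit.params),
            rtol=1e-12)
        # two different (TA, DIC) cells engineered onto the same CO2 contour
        a = speciate_from_ta_dic(2400.0, 2100.0, 15.0, 33.06)
        from scipy.optimize import brentq

        dic_b = brentq(
            lambda d: speciate_from_ta_dic(3000.0, d, 15.0, 33.06).CO2 - a.CO2,
            2100.0, 3600.0)
        b = speciate_from_ta_dic(3000.0, dic_b, 15.0, 33.06)
        assert eq1_rate(a.CO2, cusp_fit.params) == pytest.approx(
            eq1_rate(b.CO2, cusp_fit.params), rel=1e-9)

    def test_grid_max_relative_rate_is_one(self, cusp_fit):
        ls = predict_landscape(cusp_fit, GridSpec())
        assert ls.table["rel_rate"].max() == pytest.approx(1.0)
        assert (ls.table["rel_rate"] >= 0.0).all()
        assert ls.table.loc[ls.table["optimum"], "rel_rate"].min() >= 0.9

    def test_broad_niche_flat_at_standard_dic(self, melo_fit):
        """A broad-niche species holds near-constant relative growth across
        TA 2000–3000 at DIC ≈ 2000 μmol kg⁻¹."""
        ls = predict_landscape(melo_fit, GridSpec())
        tab = ls.table
        band = tab[(np.isclose(tab["dic"], 2066.667, atol=1.0))
                   & (tab["ta"].between(2000.0, 3000.0))]
        assert len(band) >= 5
        assert band["rel_rate"].max() - band["rel_rate"].min() < 0.25

    def test_landscape_bit_reproducible(self, cusp_fit):
        a = predict_landscape(cusp_fit, GridSpec()).table
        b = predict_landscape(cusp_fit, GridSpec()).table
        assert a.equals(b)

    def test_high_ph_inhibition_representable(self, cusp_fit):
        """The grid contains cells beyond the pH ≈ 9.2 inhibition isobar."""
        ls = predict_landscape(cusp_fit, GridSpec())
        tab = ls.table
        assert tab["ph_t"].max() > 9.2
        hi_ph = tab[tab["ph_t"] > 9.2]
        assert (hi_ph["rel_rate"] < 0.9).all()


class TestOptimumInterval:
    def test_interval_collapses_toward_c_opt(self, cusp_fit):
        c_opt = cusp_fit.derived.c_opt
        (lo, hi), _ = optimum_interval(cusp_fit, 1.0 - 1e-8)
        assert lo == pytest.approx(c_opt, rel=1e-2)
        assert hi == pytest.approx(c_opt, rel=1e-2)
        w99 = np.subtract(*optimum_interval(cusp_fit, 0.99)[0][::-1])
        w90 = np.subtract(*optimum_interval(cusp_fit, 0.90)[0][::-1])
        assert hi - lo < w99 < w90

    def test_nested_in_fraction(self, cusp_fit):
        (lo_a, hi_a), _ = optimum_interval(cusp_fit, 0.95)
        (lo_b, hi_b), _ = optimum_interval(cusp_fit, 0.80)
        assert lo_b < lo_a < hi_a < hi_b

    def test_stenocarb_narrower_than_eurycarb(self, cusp_fit, melo_fit):
        (lo_s, hi_s), (hls, hhs) = optimum_interval(cusp_fit, 0.90)
        (lo_e, hi_e), (hle, hhe) = optimum_interval(melo_fit, 0.90)
        assert hi_s - lo_s < hi_e - lo_e
        assert hhs - hls < hhe - hle

    def test_saturating_fit_upper_edge_infinite(self):
        fit = _fit_from_params(KineticParams(1.0, 2.0, 0.0))
        (lo, hi), (hlo, hhi) = optimum_interval(fit, 0.9)
        assert lo == pytest.approx(18.0)  # f·Y/(1−f)
        assert math.isinf(hi) and math.isinf(hhi)

    def test_bad_fraction_rejected(self, cusp_fit):
        with pytest.raises(ValueError):
            optimum_interval(cusp_fit, 1.5)


class TestOaeScenario:
    def test_unequilibrated_endpoint_low_pco2(self):
        states = oae_scenario(ScenarioSpec(ta=2300.0, pco2_atm=423.0,
                                           delta_ta=300.0, fractions=(0.0,)))
        baseline, unequil = states[0], states[1]
        assert baseline.pCO2 == pytest.approx(423.0, abs=1e-3)
        # alkalinity addition at constant DIC pulls CO2 down sharply
        assert unequil.DIC == pytest.approx(baseline.DIC, abs=1e-6)
        assert unequil.pCO2 == pytest.approx(139.3, abs=0.5)

    def test_zero_delta_ta_leaves_baseline(self):
        states = oae_scenario(ScenarioSpec(delta_ta=0.0,
                                           fractions=(0.0, 0.5, 1.0)))
        base = states[0]
        for st in states[1:]:
            assert st.pCO2 == pytest.approx(base.pCO2, abs=1e-6)
            assert st.DIC == pytest.approx(base.DIC, abs=1e-3)

    def test_full_equilibration_restores_atmospheric_pco2(self):
        states = oae_scenario(ScenarioSpec(delta_ta=300.0, fractions=(1.0,)))
        base, eq = states[0], states[1]
        assert eq.pCO2 == pytest.approx(423.0, abs=1e-3)
        assert eq.DIC > base.DIC  # CO2 influx raises DIC at the new TA

    def test_fraction_bridge_monotone(self):
        fr = (0.0, 0.25, 0.5, 0.75, 1.0)
        states = oae_scenario(ScenarioSpec(delta_ta=300.0, fractions=fr))[1:]
        pco2 = [s.pCO2 for s in states]
        assert all(np.diff(pco2) > 0)

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            ScenarioSpec(fractions=(1.2,))


class TestThresholds:
    def test_bisection_matches_brute_force_sweep(self, cusp_fit):
        spec = ScenarioSpec(ta=2300.0, dic=2030.0)
        res = alkalinity_threshold(cusp_fit, spec, 0.90)
        # 1 μmol kg⁻¹ brute-force sweep oracle
        target = 0.90 * cusp_fit.derived.vmax
        sweep = None
        for dta in np.arange(0.0, 2000.0, 1.0):
            st = speciate_from_ta_dic(2300.0 + dta, 2030.0, 15.0, 33.06,
                                      silicate=0.0, phosphate=0.0)
            if eq1_rate(st.CO2, cusp_fit.params) < target:
                sweep = dta
                break
        assert sweep is not None
        assert abs(res["delta_ta"] - sweep) <= 1.0

    def test_higher_low_edge_gives_smaller_threshold(self, melo_fit):
        """Comparative statics: species needing more CO2 exit the optimum at
        smaller alkalinity additions."""
        rotula = _fit_from_params(CANONICAL_PROFILES["T_rotula"].params)
        spec = ScenarioSpec(ta=2300.0, dic=2030.0)
        thr_rot = alkalinity_threshold(rotula, spec, 0.90)
        thr_melo = alkalinity_threshold(melo_fit, spec, 0.90)
        (lo_r, _), _ = optimum_interval(rotula, 0.90)
        (lo_m, _), _ = optimum_interval(melo_fit, 0.90)
        assert lo_r > lo_m
        assert (thr_rot["delta_ta"] or 0.0) < thr_melo["delta_ta"]

    def test_discussion_baseline_accepted(self, cusp_fit):
        spec = ScenarioSpec(ta=2300.0, dic=2030.0, temperature=15.0,
                            salinity=33.06)
        res = alkalinity_threshold(cusp_fit, spec, 0.90)
        assert res["delta_ta"] is not None
        assert 0.0 < res["delta_ta"] < 2000.0
        assert res["ph_t"] > 8.17  # added alkalinity raises pH

    def test_no_threshold_sentinel(self):
        # an extremely CO2-affine, weakly inhibited curve never leaves its
        # optimum within +2000 TA
        fit = _fit_from_params(KineticParams(1.0, 0.01, 1e-5))
        spec = ScenarioSpec(ta=2300.0, dic=2030.0)
        assert alkalinity_threshold(fit, spec, 0.5)["delta_ta"] is None

    def test_oa_threshold_eq2_sentinel(self):
        fit = _fit_from_params(KineticParams(1.0, 2.0, 0.0))
        assert oa_threshold(fit, 0.9)["pco2"] is None

    def test_oa_threshold_decreases_with_fraction(self, cusp_fit):
        hi_90 = oa_threshold(cusp_fit, 0.90)["pco2"]
        hi_95 = oa_threshold(cusp_fit, 0.95)["pco2"]
        assert hi_95 < hi_90
        assert oa_threshold(cusp_fit, 0.90)["h_nmol"] > 0
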