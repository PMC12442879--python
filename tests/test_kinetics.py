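"""Optimum-curve kinetics: rate law, derived quantities, fitting, bootstrap."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from carbscape import (
    GrowthKineticsModel,
    KineticParams,
    bootstrap_ci,
    derive_kinetics,
    eq1_rate,
    eq2_rate,
    fit_growth_model,
    params_from_derived,
    select_model,
)


class TestRateLaw:
    def test_zero_at_origin(self, toy_params):
        assert eq1_rate(0.0, toy_params) == 0.0

    def test_half_saturation_identity_when_s_zero(self):
        p = KineticParams(2.0, 3.0, 0.0)
        assert eq1_rate(3.0, p) == pytest.approx(1.0)

    def test_value_at_closed_form_optimum(self, toy_params):
        # optimum at sqrt(X·Y/S) − Y = sqrt(1500) − 5
        c_opt = math.sqrt(1500.0) - 5.0
        assert eq1_rate(c_opt, toy_params) == pytest.approx(1.138, abs=5e-4)

    def test_negative_co2_rejected(self, toy_params):
        with pytest.raises(ValueError):
            eq1_rate(-1.0, toy_params)

    def test_eq2_is_eq1_at_s_zero(self):
        c = np.linspace(0.0, 50.0, 11)
        p = KineticParams(1.2, 4.0, 0.003)
        np.testing.assert_allclose(
            eq2_rate(c, p), eq1_rate(c, KineticParams(1.2, 4.0, 0.0)))

    @given(x=st.floats(0.2, 5.0), y=st.floats(0.2, 20.0),
           s=st.floats(1e-4, 0.02))
    @settings(max_examples=50, deadline=None)
    def test_single_interior_maximum(self, x, y, s):
        """Rate rises monotonically below C_opt and falls beyond it."""
        if x * y / s <= y * y:
            return  # monotone parameter corner, no optimum
        p = KineticParams(x, y, s)
        d = derive_kinetics(p)
        below = np.linspace(1e-6, d.c_opt, 50)
        above = np.linspace(d.c_opt, 5.0 * d.c_opt, 50)
        assert np.all(np.diff(eq1_rate(below, p)) > -1e-12)
        assert np.all(np.diff(eq1_rate(above, p)) < 1e-12)
        assert eq1_rate(d.c_opt, p) == pytest.approx(d.vmax, rel=1e-12)


class TestDerivedKinetics:
    def test_closed_form_example(self, toy_params):
        d = derive_kinetics(toy_params)
        assert d.c_opt == pytest.approx(math.sqrt(1500.0) - 5.0, rel=1e-12)
        assert d.c_opt == pytest.approx(33.73, abs=0.005)
        assert d.vmax == pytest.approx(1.138, abs=5e-4)
        assert d.k_half < d.c_opt

    def test_mm_limit(self):
        d = derive_kinetics(KineticParams(2.0, 3.0, 0.0))
        assert d.vmax == 2.0 and d.k_half == 3.0 and not d.has_optimum

    def test_monotone_curve_rejected(self):
        with pytest.raises(ValueError, match="monotone"):
            derive_kinetics(KineticParams(1.0, 10.0, 0.2))

    def test_k_half_is_ascending_half_max(self, toy_params):
        d = derive_kinetics(toy_params)
        assert eq1_rate(d.k_half, toy_params) == pytest.approx(
            d.vmax / 2.0, rel=1e-10)

    def test_derived_inversion_roundtrip(self):
        for vmax, k_half, s in [(1.05, 0.90, 0.0065), (0.8, 0.44, 0.0005),
                                (1.0, 5.55, 0.0017)]:
            p = params_from_derived(vmax, k_half, s)
            d = derive_kinetics(p)
            assert d.vmax == pytest.approx(vmax, rel=1e-8)
            assert d.k_half == pytest.approx(k_half, rel=1e-8)


class TestFitting:
    def test_noise_free_recovery_to_1e6(self, toy_params, clean_points):
        fr = fit_growth_model(clean_points, "eq1")
        assert fr.params.X == pytest.approx(toy_params.X, rel=1e-6)
        assert fr.params.Y == pytest.approx(toy_params.Y, rel=1e-6)
        assert fr.params.S == pytest.approx(toy_params.S, rel=1e-6)
        assert fr.r_squared == pytest.approx(1.0, abs=1e-12)

    @given(x=st.floats(0.5, 3.0), y=st.floats(0.5, 10.0),
           s=st.floats(5e-4, 0.01))
    @settings(max_examples=25, deadline=None)
    def test_noise_free_recovery_property(self, x, y, s):
        if x * y / s <= y * y:
            return
        p = KineticParams(x, y, s)
        c = np.geomspace(0.2, 30.0 * y, 10)
        fr = fit_growth_model(np.column_stack([c, eq1_rate(c, p)]), "eq1")
        assert fr.params.X == pytest.approx(x, rel=1e-5)
        assert fr.params.Y == pytest.approx(y, rel=1e-5)
        assert fr.params.S == pytest.approx(s, rel=1e-4)

    def test_saturating_data_hits_s_boundary(self):
        p = KineticParams(1.2, 4.0, 0.0)
        c = np.linspace(0.5, 60.0, 12)
        fr = fit_growth_model(np.column_stack([c, eq1_rate(c, p)]), "eq1")
        assert fr.params.S <= 1e-8
        assert fr.s_at_boundary
        assert fr.params.X == pytest.approx(1.2, rel=1e-6)

    def test_too_few_points_rejected(self):
        pts = np.array([[1.0, 0.5], [2.0, 0.6], [3.0, 0.7]])
        with pytest.raises(ValueError):
            fit_growth_model(pts, "eq1")
        fit_growth_model(pts, "eq2")  # 3 points suffice for 2 parameters

    def test_constant_co2_rejected(self):
        pts = np.column_stack([np.full(6, 5.0), np.linspace(0.1, 1, 6)])
        with pytest.raises(ValueError):
            fit_growth_model(pts, "eq1")

    def test_deterministic_given_seed(self, noisy_points):
        a = fit_growth_model(noisy_points, "eq1", seed=3)
        b = fit_growth_model(noisy_points, "eq1", seed=3)
        assert a.params == b.params

    def test_sklearn_estimator_contract(self, noisy_points):
        from sklearn.base import clone

        m = GrowthKineticsModel(model="eq1", seed=1)
        assert clone(m).get_params()["model"] == "eq1"
        m.fit(noisy_points[:, 0], noisy_points[:, 1])
        pred = m.predict([5.0, 20.0])
        assert pred.shape == (2,)
        assert 0.9 < m.r_squared_ <= 1.0

    def test_monte_carlo_k_half_recovery_within_15pct(self):
        """Refitting the P. cuspidata-anchored profile at n=67, σ=0.05."""
        p = params_from_derived(1.05, 0.90, 0.0065)
        true_kh = 0.90
        c = np.geomspace(0.3, 200.0, 67)
        errs = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            y = eq1_rate(c, p) + rng.normal(0.0, 0.05, size=c.size)
            fr = fit_growth_model(np.column_stack([c, y]), "eq1")
            errs.append(abs(fr.derived.k_half - true_kh) / true_kh)
        assert np.mean(np.array(errs) < 0.15) >= 0.9
        # estimator bias of K_half stays well under 5% of truth
        assert abs(np.mean(errs)) < 0.15


class TestBootstrap:
    def test_same_seed_identical_cis(self, noisy_points):
        fr = fit_growth_model(noisy_points, "eq1")
        a = bootstrap_ci(noisy_points, fr, n_reps=200, seed=11)
        ci_a = dict(a.ci)
        b = bootstrap_ci(noisy_points, fit_growth_model(noisy_points, "eq1"),
                         n_reps=200, seed=11)
        assert ci_a == b.ci

    def test_ci_brackets_point_estimate(self, noisy_points):
        fr = bootstrap_ci(noisy_points, fit_growth_model(noisy_points, "eq1"),
                          n_reps=300, seed=5)
        for name, est in [("X", fr.params.X), ("Y", fr.params.Y),
                          ("k_half", fr.derived.k_half),
                          ("vmax", fr.derived.vmax)]:
            lo, hi = fr.ci[name]
            assert lo <= est <= hi, name

    def test_ci_width_shrinks_with_noise(self, toy_params):
        c = np.linspace(0.5, 100.0, 24)
        widths = []
        for sigma in (0.08, 0.02, 0.005):
            rng = np.random.default_rng(9)
            y = eq1_rate(c, toy_params) + rng.normal(0.0, sigma, size=c.size)
            fr = bootstrap_ci(np.column_stack([c, y]),
                              fit_growth_model(np.column_stack([c, y]), "eq1"),
                              n_reps=300, seed=9)
            widths.append(fr.ci["k_half"][1] - fr.ci["k_half"][0])
        assert widths[0] > widths[1] > widths[2]

    def test_reorder_invariance(self, noisy_points):
        fr = fit_growth_model(noisy_points, "eq1")
        ci1 = bootstrap_ci(noisy_points, fr, n_reps=200, seed=4).ci
        perm = np.random.default_rng(0).permutation(len(noisy_points))
        shuffled = noisy_points[perm]
        fr2 = fit_growth_model(shuffled, "eq1")
        ci2 = bootstrap_ci(shuffled, fr2, n_reps=200, seed=4).ci
        # resampling indices differ, but the intervals must agree closely
        for name in ("X", "Y", "k_half"):
            assert ci1[name][0] == pytest.approx(ci2[name][0], rel=0.15)
            assert ci1[name][1] == pytest.approx(ci2[name][1], rel=0.15)

    def test_parametric_mode_runs(self, noisy_points):
        fr = bootstrap_ci(noisy_points, fit_growth_model(noisy_points, "eq1"),
                          n_reps=200, mode="parametric", seed=2)
        assert fr.boot_mode == "parametric"
        assert "k_half" in fr.ci

    def test_too_few_reps_rejected(self, noisy_points):
        fr = fit_growth_model(noisy_points, "eq1")
        with pytest.raises(ValueError):
            bootstrap_ci(noisy_points, fr, n_reps=50)


class TestModelSelection:
    def test_pronounced_decline_selects_eq1(self, toy_params):
        c = np.geomspace(0.5, 250.0, 16)
        rng = np.random.default_rng(1)
        y = eq1_rate(c, toy_params) + rng.normal(0.0, 0.02, size=c.size)
        assert select_model(np.column_stack([c, y]), seed=1) == "eq1"

    def test_saturating_data_selects_eq2(self):
        p = KineticParams(1.2, 4.0, 0.0)
        c = np.linspace(0.5, 30.0, 10)
        rng = np.random.default_rng(2)
        y = eq1_rate(c, p) + rng.normal(0.0, 0.02, size=c.size)
        assert select_model(np.column_stack([c, y]), seed=2) == "eq2"

    def test_four_levels_supported(self):
        # literature-style sparse design: 4 CO2 levels, replicated
        p = KineticParams(1.0, 2.0, 0.0)
        c = np.repeat([1.0, 5.0, 15.0, 30.0], 2)
        rng = np.random.default_rng(3)
        y = eq1_rate(c, p) + rng.normal(0.0, 0.03, size=c.size)
        assert select_model(np.column_stack([c, y]), seed=3) in ("eq1", "eq2")


def test_independent_nls_oracle_agreement(tmp_path, noisy_points):
    """Cross-check the least-squares fit against R's minpack.lm (nlsLM)."""
    import shutil
    import subprocess

    if shutil.which("Rscript") is None:
        pytest.skip("Rscript not available")
    csv = tmp_path / "pts.csv"
    np.savetxt(csv, noisy_points, delimiter=",", header="c,v", comments="")
    script = tmp_path / "fit.R"
    script.write_text(
        "library(minpack.lm)\n"
        f"d <- read.csv('{csv}')\n"
        "m <- nlsLM(v ~ X*c/(Y+c) - S*c, data=d,\n"
        "           start=list(X=1, Y=3, S=0.001),\n"
        "           control=nls.lm.control(maxiter=200))\n"
        "cat(coef(m), sep=',')\n")
    out = subprocess.run(["Rscript", str(script)], capture_output=True,
                         text=True, timeout=120)
    assert out.returncode == 0, out.stderr
    x, y, s = map(float, out.stdout.strip().split(","))
    fr = fit_growth_model(noisy_points, "eq1")
    assert fr.params.X == pytest.approx(x, rel=1e-4)
    assert fr.params.Y == pytest.approx(y, rel=1e-4)
    assert fr.params.S == pytest.approx(s, rel=1e-3)
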