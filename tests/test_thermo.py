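import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from torpormeter import (
    fit_conductance,
    fit_tb_regression,
    fit_vo2_regression,
    derive_H,
    derive_TR,
    derive_thermo,
    hpdi,
    line_params_from_state,
    o2_to_energy,
    predictive_check_low_ta,
    q10,
    simulate_minimal_table,
    state_from_line_params,
    steady_state_tb,
    summarize_state_shift,
)
from torpormeter.thermo import LinearFitPosterior, q10_by_ta, q10_per_animal

FAST = dict(n_warmup=200, n_samples=150)


def brute_hpdi(draws, mass):
    x = np.sort(draws)
    n = len(x)
    m = int(np.ceil(mass * n))
    best = None
    for i in range(n - m + 1):
        w = x[i + m - 1] - x[i]
        if best is None or w < best[0]:
            best = (w, x[i], x[i + m - 1])
    return best[1], best[2]


class TestHPDI:
    def test_integer_ramp_shortest_window(self):
        lo, hi = hpdi(np.arange(1, 101), 0.89)
        assert hi - lo == 88  # 89 consecutive values span 88 units
        assert lo == 1.0  # earliest of the equally-short windows

    @settings(max_examples=25, deadline=None, database=None)
    @given(seed=st.integers(0, 10_000), mass=st.sampled_from([0.5, 0.89, 0.95]))
    def test_matches_bruteforce_all_windows_oracle(self, seed, mass):
        rng = np.random.default_rng(seed)
        draws = rng.gamma(2.0, 1.0, size=150)
        assert hpdi(draws, mass) == pytest.approx(brute_hpdi(draws, mass))

    def test_symmetric_sample_close_to_equal_tailed(self):
        rng = np.random.default_rng(0)
        draws = rng.standard_normal(50_000)
        lo, hi = hpdi(draws, 0.89)
        eq = np.quantile(draws, [0.055, 0.945])
        assert lo == pytest.approx(eq[0], abs=0.05)
        assert hi == pytest.approx(eq[1], abs=0.05)

    def test_point_mass_gives_zero_width(self):
        lo, hi = hpdi(np.full(500, 3.3), 0.89)
        assert lo == hi == 3.3

    def test_invalid_mass_rejected(self):
        with pytest.raises(ValueError):
            hpdi(np.arange(200), 1.5)


class TestClosedForms:
    def test_steady_state_limits_and_value(self):
        assert steady_state_tb(0.0, 1.0, 36.6, 8.0) == 36.6
        assert steady_state_tb(0.2, 0.0, 36.6, 8.0) == 8.0
        assert steady_state_tb(0.144, 0.437, 32.8, 12.0) == pytest.approx(
            27.645, abs=0.001
        )

    @settings(max_examples=50, deadline=None, database=None)
    @given(
        G=st.floats(0.01, 2.0), H=st.floats(0.01, 10.0),
        tr=st.floats(25, 40), ta=st.floats(-5, 39),
    )
    def test_steady_state_between_ambient_and_setpoint(self, G, H, tr, ta):
        tb = steady_state_tb(G, H, tr, ta)
        lo, hi = sorted((ta, tr))
        assert lo - 1e-9 <= tb <= hi + 1e-9

    def test_q10_definition_and_value(self):
        assert q10(4.0, 2.0, 36.0, 26.0).q10 == pytest.approx(2.0)
        assert q10(5.0, 2.0, 36.0, 28.0).q10 == pytest.approx(2.5**1.25, rel=1e-12)

    @settings(max_examples=30, deadline=None, database=None)
    @given(c=st.floats(0.01, 100))
    def test_q10_scale_invariance(self, c):
        a = q10(5.0, 2.0, 36.0, 28.0).q10
        b = q10(c * 5.0, c * 2.0, 36.0, 28.0).q10
        assert b == pytest.approx(a, rel=1e-9)

    def test_q10_domain_errors(self):
        with pytest.raises(ValueError):
            q10(5.0, 2.0, 36.0, 36.0)
        with pytest.raises(ValueError):
            q10(-1.0, 2.0, 36.0, 28.0)

    def test_oxygen_energy_conversion(self):
        assert o2_to_energy(1.0) == (5.3, pytest.approx(22.1752))
        assert o2_to_energy(0.0) == (0.0, 0.0)
        cal2, j2 = o2_to_energy(2.0)
        assert cal2 == 2 * 5.3 and j2 == pytest.approx(2 * 22.1752)
        with pytest.raises(ValueError):
            o2_to_energy(-0.1)

    @settings(max_examples=40, deadline=None, database=None)
    @given(G=st.floats(0.05, 1.0), H=st.floats(0.05, 8.0), tr=st.floats(28, 40))
    def test_state_line_params_round_trip(self, G, H, tr):
        a1, b1, a2, b2 = line_params_from_state(G, H, tr)
        G2, H2, tr2 = state_from_line_params(a1, b1, a2, b2)
        assert (G2, H2, tr2) == (
            pytest.approx(G), pytest.approx(H), pytest.approx(tr)
        )


class TestDerived:
    @staticmethod
    def fake_fit(slope, intercept, sign, n=200):
        return LinearFitPosterior(
            slope_draws=np.full(n, float(slope)),
            intercept_draws=np.full(n, float(intercept)),
            residual_sd_draws=np.full(n, 0.1),
            sign_convention=sign,
        )

    def test_direct_substitution(self):
        ft = self.fake_fit(1.0, 0.0, "+slope*TA")
        fv = self.fake_fit(2.0, 36.0, "-slope*TA")
        assert np.all(derive_H(ft, fv) == 2.0)
        ft2 = self.fake_fit(1.0, 0.0, "+slope*TA")
        fv2 = self.fake_fit(1.0, 36.0, "-slope*TA")
        assert np.all(derive_TR(ft2, fv2) == 36.0)

    def test_point_values_inside_printed_interval(self):
        # torpid-state slope means: H = 0.103 / 0.257 = 0.4008, which lies in
        # the reported torpid-gain interval [0.233, 0.624] ml/g/hr/degC
        h = 0.103 / 0.257
        assert h == pytest.approx(0.4008, abs=1e-4)
        assert 0.233 < h < 0.624

    def test_draw_count_mismatch_rejected(self):
        with pytest.raises(ValueError):
            derive_H(self.fake_fit(1, 0, "+slope*TA", n=100),
                     self.fake_fit(1, 0, "-slope*TA", n=200))

    def test_thermogenesis_line_at_setpoint_is_zero(self):
        ft = self.fake_fit(0.25, 24.7, "+slope*TA")
        fv = self.fake_fit(0.11, 3.6, "-slope*TA")
        h, tr = derive_H(ft, fv), derive_TR(ft, fv)
        np.testing.assert_allclose(h * (tr - tr), 0.0)

    def test_elimination_identity_drawwise(self):
        # eliminating T_A from the two fitted lines must give exactly the
        # thermogenesis line H (T_R - T_B) with the derived (H, T_R)
        rng = np.random.default_rng(42)
        n = 100
        ft = LinearFitPosterior(
            slope_draws=rng.uniform(0.02, 0.4, n),
            intercept_draws=rng.uniform(20, 36, n),
            residual_sd_draws=np.full(n, 0.1),
            sign_convention="+slope*TA",
        )
        fv = LinearFitPosterior(
            slope_draws=rng.uniform(0.05, 0.3, n),
            intercept_draws=rng.uniform(2, 10, n),
            residual_sd_draws=np.full(n, 0.1),
            sign_convention="-slope*TA",
        )
        h, tr = derive_H(ft, fv), derive_TR(ft, fv)
        tb = rng.uniform(20, 40, 100)
        for i in range(n):
            a1, b1 = ft.slope_draws[i], ft.intercept_draws[i]
            a2, b2 = fv.slope_draws[i], fv.intercept_draws[i]
            eliminated = -(a2 / a1) * tb + (a2 * b1 / a1 + b2)
            np.testing.assert_allclose(
                eliminated, h[i] * (tr[i] - tb), rtol=1e-9, atol=1e-9
            )


class TestRegressions:
    def test_near_noise_free_line_recovery(self):
        table = simulate_minimal_table((0.25, 24.0, 0.11, 3.6), n_per_ta=2,
                                       residual_sd=1e-3, seed=1)
        ft = fit_tb_regression(table, random_state=0, **FAST)
        assert np.mean(ft.slope_draws) == pytest.approx(0.25, abs=0.01)
        assert np.mean(ft.intercept_draws) == pytest.approx(24.0, abs=0.15)
        fv = fit_vo2_regression(table, random_state=1, **FAST)
        assert np.mean(fv.slope_draws) == pytest.approx(0.11, abs=0.01)
        assert np.all(fv.slope_draws > 0)

    def test_shifting_ta_shifts_intercept_not_slope(self):
        table = simulate_minimal_table((0.25, 24.0, 0.11, 3.6), n_per_ta=3,
                                       residual_sd=0.05, seed=2)
        shifted = table.copy()
        shifted["ta"] += 5.0
        f0 = fit_tb_regression(table, random_state=3, **FAST)
        f5 = fit_tb_regression(shifted, random_state=3, **FAST)
        a0 = np.mean(f0.slope_draws)
        assert np.mean(f5.slope_draws) == pytest.approx(a0, abs=0.02)
        assert np.mean(f5.intercept_draws) == pytest.approx(
            np.mean(f0.intercept_draws) - 5 * a0, abs=0.1
        )

    def test_torpid_scale_slope_flatter_than_normal(self):
        torpid = simulate_minimal_table((0.25, 24.0, 0.103, 3.55), n_per_ta=3,
                                        residual_sd=0.05, seed=4)
        normal = simulate_minimal_table((0.043, 35.0, 0.203, 8.0), n_per_ta=3,
                                        residual_sd=0.05, seed=5)
        ft = fit_vo2_regression(torpid, random_state=6, **FAST)
        fn = fit_vo2_regression(normal, random_state=7, **FAST)
        assert np.mean(ft.slope_draws) < np.mean(fn.slope_draws)

    def test_insufficient_ta_spread_rejected(self):
        table = simulate_minimal_table((0.25, 24.0, 0.11, 3.6), n_per_ta=3,
                                       residual_sd=0.1, ta_grid=(12.0, 16.0))
        with pytest.raises(ValueError, match="distinct"):
            fit_tb_regression(table)


class TestConductance:
    def make_table(self, G=0.228, noise=1e-3, seed=0, n=12):
        rng = np.random.default_rng(seed)
        grad = rng.uniform(10, 25, n)
        return pd.DataFrame({
            "animal_id": [f"a{i}" for i in range(n)],
            "ta": 16.0,
            "state": "normal",
            "min_tb": 16.0 + grad,
            "vo2_at_min": np.clip(G * grad + noise * rng.standard_normal(n), 0, None),
        })

    def test_near_noise_free_recovery(self):
        post = fit_conductance(self.make_table(), random_state=0, **FAST)
        assert post.g_mean == pytest.approx(0.228, abs=0.002)

    def test_doubling_gradient_halves_conductance(self):
        table = self.make_table(noise=0.05)
        doubled = table.copy()
        doubled["min_tb"] = 16.0 + 2 * (table["min_tb"] - 16.0)
        g1 = fit_conductance(table, random_state=1, **FAST).g_mean
        g2 = fit_conductance(doubled, random_state=1, **FAST).g_mean
        assert g2 == pytest.approx(g1 / 2, rel=0.05)

    def test_nonpositive_gradient_rows_warned_and_dropped(self):
        table = self.make_table(noise=0.05)
        table.loc[0, "min_tb"] = 10.0  # below ambient
        with pytest.warns(UserWarning, match="non-positive"):
            post = fit_conductance(table, random_state=2, **FAST)
        assert post.g_mean == pytest.approx(0.228, rel=0.1)


class TestPredictiveCheck:
    def fitted(self, seed=0):
        table = simulate_minimal_table((0.25, 24.0, 0.103, 3.55), n_per_ta=3,
                                       residual_sd=0.3, seed=seed)
        return fit_tb_regression(table, random_state=seed, **FAST)

    def test_mean_prediction_is_not_an_exceedance(self):
        fit = self.fitted()
        rep = predictive_check_low_ta(fit, 8.0, 6, fit.predict_mean(8.0))
        assert not rep.exceeds_upper and not rep.below_lower

    def test_constructed_extra_thermogenesis_is_flagged(self):
        fit = self.fitted()
        inflated = fit.predict_mean(8.0) + 2.5  # additive warm offset at 8 degC
        rep = predictive_check_low_ta(fit, 8.0, 6, inflated)
        assert rep.exceeds_upper

    def test_hpdi_narrows_with_more_new_observations(self):
        fit = self.fitted()
        widths = []
        for n_new in (1, 6, 1000):
            rep = predictive_check_low_ta(fit, 8.0, n_new, 26.0, random_state=1)
            widths.append(rep.hpdi_high - rep.hpdi_low)
        assert widths[0] > widths[1] > widths[2]

    def test_invalid_n_new(self):
        with pytest.raises(ValueError):
            predictive_check_low_ta(self.fitted(), 8.0, 0, 26.0)


class TestStateShift:
    @staticmethod
    def derived(h, tr, n=200):
        from torpormeter.thermo import ThermoDerived

        return ThermoDerived(h_draws=np.full(n, float(h)),
                             tr_draws=np.full(n, float(tr)))

    @staticmethod
    def cond(g, n=200):
        from torpormeter.thermo import ConductancePosterior

        return ConductancePosterior(g_draws=np.full(n, float(g)),
                                    residual_sd_draws=np.full(n, 0.1))

    def test_printed_reduction_arithmetic(self):
        shift = summarize_state_shift(
            self.derived(5.1, 36.6), self.derived(0.437, 32.8),
            self.cond(0.228), self.cond(0.144),
        )
        assert round(shift["g_reduction_pct"]) == 37
        assert shift["gh_normal"] == pytest.approx(0.0447, abs=1e-3)
        assert shift["gh_torpid"] == pytest.approx(0.330, abs=1e-3)

    def test_identical_states_give_zero_shift(self):
        shift = summarize_state_shift(
            self.derived(5.1, 36.6), self.derived(5.1, 36.6),
            self.cond(0.228), self.cond(0.228),
        )
        assert shift["g_reduction_pct"] == 0.0
        assert shift["h_reduction_pct"] == 0.0
        assert shift["tr_difference"] == 0.0
        assert shift["h_ratio_geometric"] == pytest.approx(1.0)


class TestQ10Tables:
    def table(self):
        rows = []
        for ta, (vn, vt, tn, tt) in {
            12.0: (5.0, 2.0, 35.4, 27.4), 24.0: (2.8, 0.9, 36.0, 30.4),
        }.items():
            for a in range(2):
                rows.append({"animal_id": f"ta{ta}_a{a}", "ta": ta,
                             "state": "normal", "min_tb": tn, "vo2_at_min": vn})
                rows.append({"animal_id": f"ta{ta}_a{a}", "ta": ta,
                             "state": "torpid", "min_tb": tt, "vo2_at_min": vt})
        return pd.DataFrame(rows)

    def test_group_level_q10_per_ta(self):
        results = q10_by_ta(self.table())
        assert [r.ta for r in results] == [12.0, 24.0]
        assert results[0].q10 == pytest.approx(
            (5.0 / 2.0) ** (10 / (35.4 - 27.4))
        )
        # lower ambient temperature gives the smaller Q10, as observed
        assert results[0].q10 < results[1].q10

    def test_per_animal_matches_group_when_homogeneous(self):
        by_animal = q10_per_animal(self.table())
        assert len(by_animal) == 4
        group = {r.ta: r.q10 for r in q10_by_ta(self.table())}
        for r in by_animal:
            assert r.q10 == pytest.approx(group[r.ta])
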