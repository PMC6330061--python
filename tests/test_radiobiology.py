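"""LQ survival, Lea-Catcheside factor, population SF/TCP, histograms."""

import numpy as np
import pytest

from celldose.radiobiology import (
    DoseRateProfile,
    PerCellDose,
    RadiosensitivityParams,
    dose_histogram_report,
    lea_catcheside_g,
    population_outcomes,
    survival_probability,
    tcp_vs_time,
)

MU = np.log(2) / 1.5  # repair rate for 1.5 h half-time, 1/h


def make_dose(total, nuclear_frac=0.6):
    total = np.asarray(total, dtype=float)
    return PerCellDose(from_N=nuclear_frac * total,
                       from_Cy=0.25 * total, from_Cs=0.1 * total,
                       cross=0.05 * total)


class TestLeaCatcheside:
    def test_acute_limit_is_one(self):
        assert lea_catcheside_g(DoseRateProfile.constant(1e-5), MU) == \
            pytest.approx(1.0, abs=1e-4)

    def test_constant_rate_closed_form_vs_numeric(self):
        for T in (0.5, 1.0, 6.0, 24.0):
            p = DoseRateProfile.constant(T)
            closed = lea_catcheside_g(p, MU)
            numeric = lea_catcheside_g(p, MU, method="numeric")
            x = MU * T
            assert closed == pytest.approx(2 * (x - 1 + np.exp(-x)) / x**2)
            assert closed == pytest.approx(numeric, abs=1e-4)

    def test_linear_uptake_closed_form_vs_numeric(self):
        for T in (1.0, 4.0, 24.0):
            p = DoseRateProfile.linear_uptake(T)
            closed = lea_catcheside_g(p, MU)
            numeric = lea_catcheside_g(p, MU, method="numeric")
            assert closed == pytest.approx(numeric, abs=1e-4)

    def test_bounded_and_decreasing_with_duration(self):
        gs = [lea_catcheside_g(DoseRateProfile.linear_uptake(T), MU)
              for T in (0.1, 1.0, 4.0, 12.0, 48.0)]
        assert all(0 < g <= 1 for g in gs)
        assert np.all(np.diff(gs) < 0)

    def test_approaches_one_for_slow_repair(self):
        p = DoseRateProfile.constant(1.0)
        g = lea_catcheside_g(p, np.log(2) / 1e6)
        assert g == pytest.approx(1.0, abs=1e-5)

    def test_decay_only_infinite_horizon_closed_form(self):
        # R ~ exp(-lam t): G -> lam / (lam + mu) as T -> inf
        lam = np.log(2) / 2.8047 / 24.0  # 1/h
        p = DoseRateProfile.decay_only(2.8047, 60.0)
        assert lea_catcheside_g(p, MU) == pytest.approx(lam / (lam + MU),
                                                        rel=1e-3)

    def test_zero_dose_profile_rejected(self):
        p = DoseRateProfile.piecewise_linear([0.0, 1.0], [0.0, 0.0])
        with pytest.raises(ValueError, match="zero total dose"):
            lea_catcheside_g(p, MU)


class TestSurvival:
    params = RadiosensitivityParams(alpha=0.46, beta=0.003)

    def test_zero_dose_survives(self):
        sp = survival_probability(make_dose([0.0]), self.params, 1)
        assert sp[0] == 1.0

    def test_one_gray_direct_evaluation(self):
        dose = make_dose([1.0])
        sp = survival_probability(dose, self.params, 1)
        assert sp[0] == pytest.approx(np.exp(-0.463), rel=1e-12)

    def test_model_ordering(self):
        dose = make_dose(np.linspace(0.5, 8.0, 10))
        sp1 = survival_probability(dose, self.params, 1)
        sp2 = survival_probability(dose, self.params, 2)
        sp3 = survival_probability(dose, self.params, 3, G=0.5)
        assert np.all(sp2 < sp1)          # RBE-boosted nuclear dose kills more
        assert np.all(sp3 >= sp2)         # G < 1 relieves the quadratic term

    def test_rbe_applies_to_nuclear_self_dose_only(self):
        no_nuc = PerCellDose(from_N=np.array([0.0]), from_Cy=np.array([2.0]),
                             from_Cs=np.array([0.0]), cross=np.array([0.0]))
        sp1 = survival_probability(no_nuc, self.params, 1)
        sp2 = survival_probability(no_nuc, self.params, 2)
        assert sp1[0] == sp2[0]

    def test_invalid_g_rejected(self):
        with pytest.raises(ValueError):
            survival_probability(make_dose([1.0]), self.params, 3, G=1.5)
        with pytest.raises(ValueError):
            survival_probability(make_dose([1.0]), self.params, 4)

    def test_params_validation(self):
        with pytest.raises(ValueError):
            RadiosensitivityParams(alpha=-0.1, beta=0.0)
        with pytest.raises(ValueError):
            RadiosensitivityParams(alpha=0.1, beta=0.0, rbe_nucleus=0.5)


class TestPopulationOutcomes:
    def test_all_killed(self):
        res = population_outcomes(np.zeros(10))
        assert res.surviving_fraction == 0.0 and res.tcp == 1.0

    def test_any_certain_survivor_kills_tcp(self):
        res = population_outcomes(np.array([0.2, 1.0, 0.3]))
        assert res.tcp == 0.0

    def test_two_cells_half(self):
        res = population_outcomes(np.array([0.5, 0.5]))
        assert res.surviving_fraction == pytest.approx(0.5)
        assert res.tcp == pytest.approx(0.25)

    def test_bounds_and_relabeling_invariance(self):
        rng = np.random.default_rng(0)
        sp = rng.uniform(0, 0.99, 500)
        res = population_outcomes(sp)
        perm = population_outcomes(rng.permutation(sp))
        assert 0 <= res.tcp <= 1 and 0 <= res.surviving_fraction <= 1
        assert res.tcp <= 1 - sp.max() + 1e-12
        assert perm.surviving_fraction == pytest.approx(res.surviving_fraction)
        assert perm.tcp == pytest.approx(res.tcp)

    def test_empty_population_rejected(self):
        with pytest.raises(ValueError):
            population_outcomes(np.array([]))

    def test_jensen_population_sf_exceeds_mean_dose_sf(self):
        rng = np.random.default_rng(1)
        doses = rng.gamma(2.0, 2.0, 1000)
        params = RadiosensitivityParams(0.46, 0.003)
        sp = survival_probability(make_dose(doses), params, 1)
        sp_mean = survival_probability(make_dose([doses.mean()]), params, 1)
        assert sp.mean() > sp_mean[0]


class TestHistogram:
    def test_single_bin_collects_everyone(self):
        doses = np.full(20, 0.3)
        sp = np.full(20, 0.5)
        rep = dose_histogram_report(doses, sp, 0.5)
        assert rep.n_cells.sum() == 20
        assert len(rep) == 1

    def test_empty_bins_carry_unit_factor(self):
        doses = np.array([0.1, 2.3])
        sp = np.array([0.5, 0.5])
        rep = dose_histogram_report(doses, sp, 0.5)
        inner = rep.iloc[1:-1]
        assert np.allclose(inner.tcp_bin, 1.0)

    def test_bin_product_equals_population_tcp(self):
        rng = np.random.default_rng(4)
        doses = rng.gamma(2.0, 1.5, 300)
        sp = np.exp(-0.4 * doses)
        rep = dose_histogram_report(doses, sp, 0.5)
        assert np.prod(rep.tcp_bin) == pytest.approx(
            population_outcomes(sp).tcp, rel=1e-9)


class TestTcpVsTime:
    def test_monotone_tcp_and_crossing(self, small_cluster):
        from celldose.kinetics import assign_activity

        model, asm = small_cluster
        # scaled-down nuclear uptake that crosses TCP 50% within the horizon
        amap = assign_activity(model, {"N": 2000.0, "Cy": 4000.0, "Cs": 4000.0},
                               "uniform", exposure_h=24.0)
        params = RadiosensitivityParams(0.46, 0.003)
        frame = tcp_vs_time(asm, amap, {"N": 0.03, "Cy": 0.06, "Cs": 0.06},
                            params, 2, [0.0, 1.0, 3.0, 8.0], 2.8047)
        assert np.all(np.diff(frame.TCP) >= -1e-12)
        assert np.all((frame.TCP >= 0) & (frame.TCP <= 1))
        if frame.attrs["t_tcp50_days"] is not None:
            assert frame.loc[frame.t_days == frame.attrs["t_tcp50_days"],
                             "TCP"].iloc[0] >= 0.5

    def test_zero_activity_never_controls(self, small_cluster):
        from celldose.kinetics import assign_activity

        model, asm = small_cluster
        amap = assign_activity(model, {"N": 0.0, "Cy": 0.0, "Cs": 0.0},
                               "uniform", exposure_h=24.0)
        params = RadiosensitivityParams(0.46, 0.003)
        frame = tcp_vs_time(asm, amap, {"N": 0.0}, params, 1, [0.0, 5.0], 2.8047)
        assert np.all(frame.TCP == 0.0)
        assert frame.attrs["t_tcp50_days"] is None
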