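"""Two-site SPR kinetics: closed form vs ODE oracle, fitting round trips,
free energies and fold changes."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from hsascreen.spr import (
    DEFAULT_TEMPERATURE,
    GAS_CONSTANT_KJ,
    WATER_MOLARITY,
    KineticParams,
    Sensorgram,
    baseline_correct,
    delta_delta_g,
    equilibrium_kd,
    fit_heterogeneous,
    fold_change,
    free_energy,
    round_fold,
    simulate_sensorgram,
)
from hsascreen.synthetic import gen_sensorgram

from conftest import ASSAY_CONCS


def ode_sensorgram(kp, rmax1, rmax2, conc, times, t_assoc):
    """Independent oracle: numerically integrate the two-site rate equations
    dR_i/dt = ka_i*C*(Rmax_i - R_i) - kd_i*R_i with C switched off after
    t_assoc."""

    def rhs(t, r, conc_now):
        r1, r2 = r
        return [
            kp.ka1 * conc_now * (rmax1 - r1) - kp.kd1 * r1,
            kp.ka2 * conc_now * (rmax2 - r2) - kp.kd2 * r2,
        ]

    t_a = times[times <= t_assoc]
    sol_a = solve_ivp(
        rhs, (0.0, t_assoc), [0.0, 0.0], t_eval=t_a, args=(conc,),
        rtol=1e-11, atol=1e-13, method="LSODA",
    )
    t_d = times[times > t_assoc]
    resp_a = sol_a.y.sum(axis=0)
    if t_d.size:
        sol_d = solve_ivp(
            rhs, (t_assoc, times[-1]), sol_a.y[:, -1], t_eval=t_d, args=(0.0,),
            rtol=1e-11, atol=1e-13, method="LSODA",
        )
        return np.concatenate([resp_a, sol_d.y.sum(axis=0)])
    return resp_a


class TestSimulate:
    def test_zero_concentration_gives_zero_trace(self, baseline_params):
        times = np.arange(0.0, 601.0, 1.0)
        sg = simulate_sensorgram(baseline_params, 100, 100, 0.0, times, 300.0)
        assert np.all(sg.response == 0.0)

    def test_single_site_association_plateau_hand_value(self):
        """Rmax=100, ka=1e3, kd=1e-3, C=1e-5: plateau 100*0.01/0.011."""
        kp = KineticParams(ka1=1e3, kd1=1e-3, ka2=1e3, kd2=1e-3)
        times = np.linspace(0.0, 50000.0, 200)
        sg = simulate_sensorgram(kp, 100, 0, 1e-5, times, 50000.0)
        assert sg.response[-1] == pytest.approx(100 * 0.01 / 0.011, rel=1e-6)

    def test_full_decay_in_dissociation(self, baseline_params):
        times = np.array([0.0, 300.0, 1e7])
        sg = simulate_sensorgram(baseline_params, 100, 100, 1e-5, times, 300.0)
        assert sg.response[-1] == pytest.approx(0.0, abs=1e-6)

    @pytest.mark.parametrize("conc", [2.5e-6, 40e-6])
    def test_matches_ode_integration(self, baseline_params, conc):
        times = np.arange(0.0, 2701.0, 5.0)
        sg = simulate_sensorgram(baseline_params, 100, 60, conc, times, 300.0)
        oracle = ode_sensorgram(baseline_params, 100, 60, conc, times, 300.0)
        scale = np.max(np.abs(oracle))
        assert np.max(np.abs(sg.response - oracle)) / scale < 1e-6

    def test_association_plateau_formula(self, baseline_params):
        conc = 40e-6
        times = np.linspace(0.0, 5e5, 100)
        sg = simulate_sensorgram(baseline_params, 80, 120, conc, times, 5e5)
        expected = sum(
            rmax * ka * conc / (ka * conc + kd)
            for rmax, ka, kd in (
                (80, baseline_params.ka1, baseline_params.kd1),
                (120, baseline_params.ka2, baseline_params.kd2),
            )
        )
        assert sg.response[-1] == pytest.approx(expected, rel=1e-6)

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            KineticParams(ka1=-1.0, kd1=1e-3, ka2=1e3, kd2=1e-3)


class TestFit:
    def test_noiseless_single_concentration_round_trip(self, baseline_params):
        sg = gen_sensorgram(baseline_params, 100, 100, 10e-6, dt=2.0)
        avg, per = fit_heterogeneous([sg])
        for name in ("ka1", "kd1", "ka2", "kd2"):
            assert getattr(avg, name) == pytest.approx(
                getattr(baseline_params, name), rel=1e-3
            )

    def test_noiseless_five_concentration_average(self, baseline_params):
        """Averaged KD estimates equal the generating ratios kd_i/ka_i."""
        sgs = [gen_sensorgram(baseline_params, 100, 100, c) for c in ASSAY_CONCS]
        avg, per = fit_heterogeneous(sgs)
        assert len(per) == 5
        assert avg.KD1 == pytest.approx(baseline_params.kd1 / baseline_params.ka1, rel=1e-3)
        assert avg.KD2 == pytest.approx(baseline_params.kd2 / baseline_params.ka2, rel=1e-3)
        # per-fit consistency KD_i = kd_i / ka_i
        for p in per:
            assert p.KD1 == pytest.approx(p.kd1 / p.ka1, rel=1e-12)

    def test_fit_invariant_to_initial_site_labelling(self, baseline_params):
        sg = gen_sensorgram(baseline_params, 100, 100, 10e-6, dt=2.0)
        swapped_init = KineticParams(
            ka1=baseline_params.ka2, kd1=baseline_params.kd2,
            ka2=baseline_params.ka1, kd2=baseline_params.kd1,
        )
        avg_a, _ = fit_heterogeneous([sg], init=baseline_params)
        avg_b, _ = fit_heterogeneous([sg], init=swapped_init)
        assert avg_a.KD1 == pytest.approx(avg_b.KD1, rel=1e-6)
        assert avg_a.KD1 <= avg_a.KD2

    def test_zero_concentration_sensorgram_rejected(self, baseline_params):
        sg = gen_sensorgram(baseline_params, 100, 100, 0.0, dt=10.0)
        with pytest.raises(ValueError):
            fit_heterogeneous([sg])


class TestDerivedQuantities:
    def test_equilibrium_kd_definition(self):
        assert equilibrium_kd(1.0, 1.0) == 1.0
        assert equilibrium_kd(2.73e2, 0.11e-4) == pytest.approx(4.03e-8, rel=1e-2)
        with pytest.raises(ValueError):
            equilibrium_kd(0.0, 1e-3)

    def test_free_energy_standard_state_zero(self):
        assert free_energy(WATER_MOLARITY) == pytest.approx(0.0, abs=1e-12)

    def test_free_energy_closed_form_value(self):
        assert free_energy(0.64e-7) == pytest.approx(-51.0, abs=0.05)

    def test_halving_kd_shifts_by_rtln2(self):
        rt_ln2 = GAS_CONSTANT_KJ * DEFAULT_TEMPERATURE * np.log(2.0)
        assert free_energy(1e-6) - free_energy(2e-6) == pytest.approx(-rt_ln2)

    def test_free_energy_strictly_increasing_in_kd(self):
        kds = np.logspace(-9, -3, 10)
        dgs = [free_energy(k) for k in kds]
        assert all(a < b for a, b in zip(dgs, dgs[1:]))

    def test_ddg_zero_for_identical_params(self, baseline_params):
        assert delta_delta_g(baseline_params, baseline_params) == (0.0, 0.0)

    def test_ddg_antisymmetric(self, baseline_params):
        other = KineticParams(ka1=5e2, kd1=1e-4, ka2=1e3, kd2=1e-3)
        d12 = delta_delta_g(other, baseline_params)
        d21 = delta_delta_g(baseline_params, other)
        assert d12[0] == pytest.approx(-d21[0])
        assert d12[1] == pytest.approx(-d21[1])

    def test_prednisone_ddg2_negative(self):
        """Prednisone lowers KD2 vs the DMSO baseline: favors binding."""
        base = KineticParams(ka1=2.7e2, kd1=0.216e-4, ka2=8.9e2, kd2=26e-4,
                             KD1=0.64e-7, KD2=5.0e-6)
        pred = KineticParams(ka1=2.73e2, kd1=0.11e-4, ka2=36e2, kd2=13.6e-4,
                             KD1=0.38e-7, KD2=0.38e-6)
        _, ddg2 = delta_delta_g(pred, base)
        expected = GAS_CONSTANT_KJ * DEFAULT_TEMPERATURE * np.log(0.38 / 5.0)
        assert ddg2 == pytest.approx(expected)
        assert ddg2 < 0

    def test_fold_change_directions(self):
        base = KineticParams(ka1=1e3, kd1=1e-4, ka2=1e3, kd2=1e-2)
        stronger = KineticParams(ka1=1e3, kd1=0.5e-4, ka2=1e3, kd2=2e-2)
        (r1, d1), (r2, d2) = fold_change(stronger, base)
        assert (r1, d1) == (2.0, "decrease")
        assert (r2, d2) == (2.0, "increase")
        (r1, d1), _ = fold_change(base, base)
        assert (r1, d1) == (1.0, "unchanged")

    def test_round_fold_half_away(self):
        assert round_fold(12.5) == 13
        assert round_fold(4.06) == 4
        assert round_fold(2.97) == 3


class TestBaselineCorrect:
    def test_zero_blank_is_identity(self, baseline_params):
        sg = gen_sensorgram(baseline_params, 100, 100, 1e-5, dt=10.0)
        blank = Sensorgram(sg.times, np.zeros_like(sg.response), 0.0, sg.t_assoc)
        assert np.array_equal(baseline_correct(sg, blank).response, sg.response)

    def test_self_subtraction_gives_zeros(self, baseline_params):
        sg = gen_sensorgram(baseline_params, 100, 100, 1e-5, dt=10.0)
        assert np.all(baseline_correct(sg, sg).response == 0.0)

    def test_linear_drift_round_trip_with_interpolation(self, baseline_params):
        sg = gen_sensorgram(baseline_params, 100, 100, 1e-5, dt=10.0)
        drift = 0.002 * sg.times + 1.5
        drifted = Sensorgram(sg.times, sg.response + drift, sg.analyte_conc, sg.t_assoc)
        # blank sampled on a different (coarser) grid
        blank_t = np.arange(0.0, sg.times[-1] + 1, 45.0)
        blank = Sensorgram(blank_t, 0.002 * blank_t + 1.5, 0.0, sg.t_assoc)
        recovered = baseline_correct(drifted, blank, interpolate=True)
        assert np.allclose(recovered.response, sg.response, atol=1e-9)

    def test_grid_mismatch_without_interpolation_raises(self, baseline_params):
        sg = gen_sensorgram(baseline_params, 100, 100, 1e-5, dt=10.0)
        blank = Sensorgram(sg.times[:-1], sg.response[:-1], 0.0, sg.t_assoc)
        with pytest.raises(ValueError):
            baseline_correct(sg, blank)
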