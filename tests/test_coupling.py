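"""Coupled system: believing feedback, decoupling limits, scenario behavior."""

import math

import numpy as np
import pytest

from socioclimate import radiative_forcing
from socioclimate.config import set_param
from socioclimate.coupling import (
    believing_prob,
    coupled_rhs,
    run_climate_only,
    run_rumor_only,
    run_scenario,
)
from socioclimate.rumor_dynamics import RumorState, find_equilibrium, rumor_rhs


class TestBelievingProb:
    def test_identity_at_zero_anomaly(self):
        assert believing_prob(0.37, 0.5, 0.0) == 0.37

    def test_insensitive_when_v_zero(self):
        assert believing_prob(0.37, 0.0, 5.0) == 0.37

    def test_halves_at_analytic_halflife(self):
        v = 0.25
        assert believing_prob(0.8, v, math.log(2) / v) == pytest.approx(0.4)

    def test_cooling_caps_at_one(self):
        assert believing_prob(0.9, 1.0, -3.0) == 1.0

    def test_invalid_base_raises(self):
        with pytest.raises(ValueError, match="base"):
            believing_prob(1.2, 0.1, 0.0)


class TestCoupledRhs:
    def test_decoupled_rumor_matches_uncoupled_field(self, baseline):
        """v = 0 and Psi = 0 sever both coupling directions: the rumor block
        equals the uncoupled vector field and the carbon flow ignores i_R."""
        cfg = baseline.with_updates(
            rumor=baseline.rumor.with_updates(v=0.0),
            climate=baseline.climate.with_updates(Psi=0.0),
        )
        n = cfg.degree.n_classes
        rng = np.random.default_rng(7)
        rumor = rng.random(4 * n) * 0.25
        y = np.concatenate([rumor, [900.0, 1.1]])
        full = coupled_rhs(y, 2050.0, cfg, None)
        alone = rumor_rhs(
            RumorState.unpack(rumor, n), cfg.rumor, cfg.degree,
            cfg.rumor.eta0, cfg.rumor.omega0,
        ).pack()
        np.testing.assert_array_equal(full[: 4 * n], alone)
        assert full[-2] == pytest.approx(cfg.climate.E2021 - cfg.climate.delta * 900.0)

    def test_no_believers_leaves_only_turnover(self, baseline):
        n = baseline.degree.n_classes
        s = np.full(n, 0.6)
        y = np.concatenate([s, np.zeros(3 * n), [500.0, 0.5]])
        deriv = coupled_rhs(y, 2050.0, baseline, None)
        rp, cp = baseline.rumor, baseline.climate
        np.testing.assert_allclose(deriv[:n], rp.B - rp.mu * 0.6, atol=1e-15)
        np.testing.assert_allclose(deriv[n : 4 * n], 0.0, atol=1e-15)
        assert deriv[-2] == pytest.approx(cp.E2021 * 1.0 - cp.delta * 500.0)

    def test_joint_equilibrium_has_tiny_derivative(self, baseline, single_class_dd):
        """Composing a rumor fixed point (at the equilibrium temperature's
        believing probabilities) with the carbon/temperature fixed points
        zeroes the coupled field."""
        cfg = baseline.with_updates(degree=single_class_dd)
        rp, cp = cfg.rumor, cfg.climate

        # self-consistent iteration on (rumor eq, C*, T*)
        T = 0.5
        for _ in range(60):
            eta = believing_prob(rp.eta0, rp.v, T)
            omega = believing_prob(rp.omega0, rp.v, T)
            times, ys = run_rumor_only(cfg, 3000.0, eta=eta, omega=omega,
                                       initial=RumorState.seeded(1, 0.01))
            eq = find_equilibrium(rp, single_class_dd, eta, omega,
                                  RumorState.unpack(np.clip(ys[-1], 0, None), 1))
            iR = float(eq.state.iR[0])
            C = cp.E2021 * math.exp(-cp.Psi * iR) / cp.delta
            T_new = cp.q * radiative_forcing(C, cp)
            if abs(T_new - T) < 1e-12:
                T = T_new
                break
            T = T_new
        y = np.concatenate([eq.state.pack(), [C, T]])
        deriv = coupled_rhs(y, 2100.0, cfg, None)
        assert np.abs(deriv).max() < 1e-9


class TestRunScenario:
    def test_deterministic_csv_output(self, baseline, emissions, spinup, tmp_path):
        cfg = baseline.with_updates(horizon_end=2060)
        paths = []
        for name in ("a.csv", "b.csv"):
            result = run_scenario(cfg, emissions, spinup_state=spinup)
            p = tmp_path / name
            result.to_csv(p, sidecar=False)
            paths.append(p.read_bytes())
        assert paths[0] == paths[1]

    def test_annual_grid_and_bounded_fractions(self, baseline, emissions, spinup):
        result = run_scenario(baseline, emissions, spinup_state=spinup)
        np.testing.assert_array_equal(result.times, np.arange(2021.0, 2201.0))
        for series in (result.s, result.h, result.iB, result.iR):
            assert series.min() > -1e-9
            assert series.max() < 1 + 1e-9

    def test_strong_suppression_freezes_rumor(self, baseline, emissions, spinup):
        """Huge v suppresses believing so the seeded believers decay and
        rejectors never appear in appreciable numbers; emissions stay near
        the unmitigated baseline."""
        cfg = baseline.with_updates(
            rumor=baseline.rumor.with_updates(
                v=50.0, beta=0.0, varsigma=0.0
            ),
            horizon_end=2120,
        )
        result = run_scenario(cfg, emissions, spinup_state=spinup)
        assert result.iR.max() < 1e-6
        assert result.h.max() < 1e-6
        np.testing.assert_allclose(result.emissions, cfg.climate.E2021, rtol=1e-5)

    def test_psi_zero_temperature_is_rumor_free(self, baseline, emissions, spinup):
        """Without the mitigation channel the temperature path is identical
        to a run whose rumor never ignites."""
        cfg = set_param(baseline, "Psi", 0.0).with_updates(horizon_end=2100)
        with_rumor = run_scenario(cfg, emissions, spinup_state=spinup)
        frozen = run_scenario(
            cfg, emissions, spinup_state=spinup,
            initial=RumorState.all_susceptible(cfg.degree.n_classes),
        )
        np.testing.assert_allclose(with_rumor.T, frozen.T, atol=1e-7)
        assert with_rumor.iR.max() > 0.3  # the rumor did run

    def test_monotone_in_psi_pointwise(self, baseline, emissions, spinup):
        cfg = baseline.with_updates(horizon_end=2120)
        temps = []
        for psi in (0.1, 1.0, 3.0, 11.0):
            r = run_scenario(set_param(cfg, "Psi", psi), emissions, spinup_state=spinup)
            temps.append(r.T[r.times > 2030])
        temps = np.asarray(temps)
        assert np.all(np.diff(temps, axis=0) <= 1e-10)

    def test_raising_v_never_raises_believers(self, baseline, emissions, spinup):
        cfg = baseline.with_updates(horizon_end=2120)
        finals = []
        for v in (0.0, 0.2, 1.0, 3.0):
            r = run_scenario(
                cfg.with_updates(rumor=cfg.rumor.with_updates(v=v)),
                emissions, spinup_state=spinup,
            )
            finals.append(r.iB[-1])
        assert all(a >= b - 1e-9 for a, b in zip(finals, finals[1:]))

    def test_annual_samples_match_dense_solution(self, baseline, emissions, spinup):
        """The annual grid comes from the solver's interpolant; halving the
        tolerances moves the annual values by < 1e-6 relative."""
        cfg = baseline.with_updates(horizon_end=2060)
        a = run_scenario(cfg, emissions, spinup_state=spinup)
        b = run_scenario(cfg, emissions, spinup_state=spinup, rtol=1e-10, atol=1e-12)
        scale = np.abs(b.T).max()
        assert np.abs(a.T - b.T).max() / scale < 1e-6

    def test_bad_horizon_raises(self, baseline, emissions):
        with pytest.raises(ValueError, match="horizon"):
            run_scenario(baseline.with_updates(horizon_end=2021), emissions)


class TestComponentDecomposition:
    def test_fixed_step_run_is_bitwise_composition(self, baseline, emissions, spinup):
        """With v = 0 and Psi = 0 the coupled system is block-diagonal, so a
        fixed-step integration equals integrating the rumor and climate
        components separately, bit for bit."""
        cfg = baseline.with_updates(
            rumor=baseline.rumor.with_updates(v=0.0),
            climate=baseline.climate.with_updates(Psi=0.0),
            horizon_end=2050,
        )
        n = cfg.degree.n_classes
        res = run_scenario(cfg, emissions, spinup_state=spinup, method="rk4", n_per_year=200)
        _, rumor_alone = run_rumor_only(
            cfg, 2050.0, t_start=2021.0,
            initial=RumorState.seeded(n, cfg.rumor_seed),
            method="rk4", n_per_year=200,
        )
        _, climate_alone = run_climate_only(
            cfg.with_updates(horizon_end=2050), emissions, iR_total=0.0,
            spinup_state=spinup, method="rk4", n_per_year=200,
        )
        assert np.array_equal(
            res.rumor_per_class.reshape(len(res.times), -1), rumor_alone
        )
        assert np.array_equal(np.column_stack([res.C, res.T]), climate_alone)
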