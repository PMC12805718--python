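"""Unit and property tests of the chemostat core dynamics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from phagedefense.chemostat_core import (
    ChemostatState,
    StepSizeError,
    burst_modes,
    burst_size_distribution,
    expected_progeny,
    lysis_rate,
    run_to_equilibrium,
    step,
    virus_concentration,
)
from phagedefense.params import EcologyParams, StrategyParams

from .conftest import random_small_state
from .oracles import (
    literal_step,
    progeny_monte_carlo,
    progeny_pure_birth,
    virus_free_fixed_point,
)


class TestVirusConcentration:
    def test_newborn_at_cap_has_concentration_one(self, tiny_eco):
        assert virus_concentration(tiny_eco.P0, tiny_eco.Q, tiny_eco) == 1.0

    def test_empty_cell_has_zero(self, tiny_eco):
        assert virus_concentration(tiny_eco.P0, 0, tiny_eco) == 0.0

    def test_largest_cell_formula(self):
        eco = EcologyParams(A=1, B=0.1, C=1e-6, E=0.05, F=1, G=1, T=1,
                            psi0=1e7, Q=1000, P0=10)
        assert virus_concentration(19, 1000, eco) == pytest.approx(10 / 19)

    def test_monotone_in_q_and_p(self, tiny_eco):
        rhos_q = [virus_concentration(tiny_eco.P0, q, tiny_eco)
                  for q in range(tiny_eco.Q + 1)]
        assert np.all(np.diff(rhos_q) > 0)
        rhos_p = [virus_concentration(p, 2, tiny_eco)
                  for p in range(tiny_eco.P0, 2 * tiny_eco.P0)]
        assert np.all(np.diff(rhos_p) < 0)

    def test_out_of_range_rejected(self, tiny_eco):
        with pytest.raises(ValueError):
            virus_concentration(tiny_eco.P0 - 1, 0, tiny_eco)
        with pytest.raises(ValueError):
            virus_concentration(tiny_eco.P0, tiny_eco.Q + 1, tiny_eco)


class TestLysisRate:
    def test_zero_at_zero_concentration(self):
        eco = EcologyParams(A=1, B=0.1, C=1e-6, E=0.05, F=1, G=1, T=1, psi0=1e7)
        assert lysis_rate(0.0, eco, dt=0.01) == 0.0

    def test_below_threshold_formula(self):
        eco = EcologyParams(A=1, B=0.1, C=1e-6, E=0.05, F=1, G=1, T=1, psi0=1e7)
        assert lysis_rate(0.1, eco, dt=0.01) == pytest.approx(0.1 / 0.9)

    def test_at_threshold_caps_to_one_per_step(self):
        eco = EcologyParams(A=1, B=0.1, C=1e-6, E=0.05, F=1, G=2, T=0.5, psi0=1e7)
        assert lysis_rate(0.5, eco, dt=0.01) == pytest.approx(100.0)

    def test_monotone_in_rho_and_T(self):
        eco = EcologyParams(A=1, B=0.1, C=1e-6, E=0.05, F=1, G=1.5, T=0.9, psi0=1e7)
        rhos = np.linspace(0, 0.89, 50)
        vals = [lysis_rate(r, eco, 0.01) for r in rhos]
        assert np.all(np.diff(vals) >= 0)
        eco_hi_T = eco.replace(T=1.0)
        assert all(lysis_rate(r, eco_hi_T, 0.01) <= lysis_rate(r, eco, 0.01)
                   for r in rhos)


class TestStepOracleEquivalence:
    """The optimized kernel must reproduce a literal transcription of the
    update equations on arbitrary small states."""

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), p0=st.integers(2, 4),
           qmax=st.integers(1, 5), a=st.floats(0, 1), rfrac=st.floats(0, 1))
    def test_matches_literal_equations(self, seed, p0, qmax, a, rfrac):
        rng = np.random.default_rng(seed)
        eco = EcologyParams(A=2.0, B=0.1, C=1e-3, E=0.05, F=0.5,
                            G=1.0 + rng.random(), T=0.3 + 0.7 * rng.random(),
                            psi0=50.0, Q=qmax, P0=p0)
        strat = StrategyParams(a=a, r=rfrac * eco.E)
        n = random_small_state(rng, eco)
        phi, psi = float(rng.random()), float(50 * rng.random())
        state = ChemostatState(n=n.copy(), phi=phi, psi=psi)
        dt = 1e-3
        got = step(state, eco, strat, dt)
        exp_n, exp_phi, exp_psi = literal_step(n, phi, psi, eco, strat, dt)
        scale = max(n.max(), 1.0)
        assert np.allclose(got.n, exp_n, rtol=0, atol=1e-12 * scale)
        assert got.phi == pytest.approx(exp_phi, abs=1e-14)
        assert got.psi == pytest.approx(exp_psi, abs=1e-9 * max(psi, 1.0))

    def test_thousand_random_states(self, tiny_eco, rng):
        """Bulk oracle-equivalence sweep over 1000 random small states."""
        worst = 0.0
        for _ in range(1000):
            p0 = int(rng.integers(2, 5))
            qmax = int(rng.integers(1, 6))
            eco = EcologyParams(A=2.0, B=0.1, C=1e-3, E=0.05, F=0.5, G=1.0,
                                T=float(0.3 + 0.7 * rng.random()),
                                psi0=50.0, Q=qmax, P0=p0)
            strat = StrategyParams(a=float(rng.random()),
                                   r=float(rng.random()) * eco.E)
            n = random_small_state(rng, eco)
            phi, psi = float(rng.random()), float(50 * rng.random())
            got = step(ChemostatState(n=n.copy(), phi=phi, psi=psi),
                       eco, strat, 1e-3)
            exp_n, _, _ = literal_step(n, phi, psi, eco, strat, 1e-3)
            scale = max(n.max(), 1.0)
            worst = max(worst, np.abs(got.n - exp_n).max() / scale)
        assert worst <= 1e-12


class TestStepInvariants:
    def test_null_dynamics_unchanged(self, rng):
        """No virus, no nutrient, (near-)no dilution: nothing moves."""
        eco = EcologyParams(A=2.0, B=1e-12, C=1e-3, E=0.05, F=0.5, G=1.0,
                            T=0.8, phi0=0.0, psi0=0.0, Q=4, P0=3)
        n = np.zeros((eco.P0, eco.Q + 1))
        n[:, 0] = rng.random(eco.P0) * 5
        st0 = ChemostatState(n=n.copy(), phi=0.0, psi=0.0)
        out = step(st0, eco, StrategyParams(a=0.0, r=0.0), 0.01)
        assert np.allclose(out.n, n, rtol=0, atol=1e-12)

    def test_virus_bookkeeping_infections_equal_psi_decrement(self, rng):
        """With dilution off and no lysis, psi drops by exactly the count of
        newly infected cells."""
        eco = EcologyParams(A=1.0, B=1e-12, C=1e-3, E=0.05, F=1e-12, G=1.0,
                            T=1.0, psi0=0.0, phi0=0.0, Q=4, P0=3)
        n = np.zeros((3, 5))
        n[:, 0] = [7.0, 3.0, 2.0]
        psi = 40.0
        st0 = ChemostatState(n=n.copy(), phi=0.0, psi=psi)
        out = step(st0, eco, StrategyParams(a=0.0, r=0.0), 0.01)
        newly_infected = out.n[:, 1].sum()
        assert psi - out.psi == pytest.approx(newly_infected, rel=1e-12)

    def test_cell_conservation_without_sinks(self, rng):
        """No dilution, lysis, PCD or division: total cell count constant."""
        eco = EcologyParams(A=1.0, B=1e-12, C=1e-3, E=0.05, F=0.3, G=1.0,
                            T=1.0, psi0=10.0, Q=6, P0=3)
        n = np.zeros((3, 7))
        n[:2, :3] = rng.random((2, 3)) * 4  # keep top volume bin empty
        st0 = ChemostatState(n=n.copy(), phi=0.5, psi=10.0)
        strat = StrategyParams(a=0.0, r=0.01)
        total = n.sum()
        for _ in range(20):
            st0 = step(st0, eco, strat, 1e-3)
            # cells may reach the top bin eventually; stop before they do
            if st0.n[-1].sum() > 0:
                break
            assert st0.total == pytest.approx(total, rel=1e-12)

    def test_full_pcd_removes_every_infected_cell(self, tiny_eco):
        """At a=1, no infected cell survives a step and no lysis happens."""
        strat = StrategyParams(a=1.0, r=0.0)
        n = np.zeros((tiny_eco.P0, tiny_eco.Q + 1))
        n[:, 0] = 5.0
        st0 = ChemostatState(n=n, phi=1.0, psi=100.0)
        for _ in range(50):
            st0 = step(st0, tiny_eco, strat, 5e-3)
            assert st0.n[:, 1:].sum() == 0.0

    def test_oversized_step_rejected(self, tiny_eco):
        n = np.zeros((tiny_eco.P0, tiny_eco.Q + 1))
        n[0, 0] = 1.0
        st0 = ChemostatState(n=n, phi=1.0, psi=0.0)
        with pytest.raises(StepSizeError):
            step(st0, tiny_eco, StrategyParams(a=0.0, r=0.0), 10.0)


class TestEquilibrium:
    def test_no_nutrient_means_washout(self, tiny_eco):
        eco = tiny_eco.replace(phi0=0.0)
        res = run_to_equilibrium(eco, StrategyParams(a=0.0, r=0.0), t_max=200.0)
        assert res.N_star == 0.0
        assert res.extinct

    def test_full_immunity_cost_means_washout(self, tiny_eco):
        """r = E zeroes growth, so even without virus the population dies."""
        eco = tiny_eco.replace(psi0=0.0)
        res = run_to_equilibrium(eco, StrategyParams(a=0.0, r=eco.E),
                                 t_max=300.0)
        assert res.N_star == 0.0

    def test_virus_free_equilibrium_matches_fixed_point_solver(self, fig5_reduced):
        """Independent eigenvalue/root-finding solution of the stationary
        conditions agrees with forward integration within 1%."""
        eco = fig5_reduced.replace(psi0=0.0)
        strat = StrategyParams(a=0.0, r=0.0)
        res = run_to_equilibrium(eco, strat, tol=1e-6, t_max=2000.0)
        N_fp, phi_fp, _ = virus_free_fixed_point(eco, strat)
        assert res.converged
        assert res.N_star == pytest.approx(N_fp, rel=0.01)
        assert res.phi_star == pytest.approx(phi_fp, rel=0.01)

    def test_reference_habitat_optimum_is_viable(self, fig5_reduced,
                                                 caption_strategy):
        res = run_to_equilibrium(fig5_reduced, caption_strategy, t_max=700.0)
        assert res.converged
        assert res.N_star > 0
        assert res.pcd_count_rate > 0


class TestBurstSize:
    def test_full_pcd_means_no_lysis_events(self, fig5_reduced):
        res = run_to_equilibrium(fig5_reduced, StrategyParams(a=1.0, r=0.0),
                                 t_max=400.0)
        hist = burst_size_distribution(res)
        assert res.lysis_count_rate == 0.0
        assert hist.sum() == 0.0

    def test_histogram_sums_to_lysis_rate(self):
        from phagedefense.synthetic_data import fixture_ecologies

        fx = fixture_ecologies()["burst_bimodal"]
        res = run_to_equilibrium(fx["eco"], fx["strategy"], t_max=300.0)
        hist = burst_size_distribution(res)
        assert res.lysis_count_rate > 0
        assert hist.sum() == pytest.approx(res.lysis_count_rate, rel=1e-6)
        assert hist[0] == 0.0


class TestExpectedProgeny:
    def test_immediate_lysis_state_has_no_progeny(self, tiny_eco):
        # rho(P0, Q) = 1 >= T
        v = expected_progeny(tiny_eco.P0, tiny_eco.Q, tiny_eco,
                             StrategyParams(a=0.0, r=0.0), phi=0.5, psi=10.0)
        assert v == pytest.approx(0.0, abs=1e-12)

    def test_uninfected_cell_matches_pure_birth_closed_form(self, tiny_eco):
        """Without virus the chain is a birth ladder with uniform killing."""
        strat = StrategyParams(a=0.0, r=0.0)
        for p in range(tiny_eco.P0, 2 * tiny_eco.P0):
            got = expected_progeny(p, 0, tiny_eco, strat, phi=0.7, psi=0.0)
            want = progeny_pure_birth(p, tiny_eco, strat, phi=0.7)
            assert got == pytest.approx(want, abs=1e-9)

    def test_agrees_with_monte_carlo(self, tiny_eco, rng):
        strat = StrategyParams(a=0.0, r=0.02)
        p, q = tiny_eco.P0 + 1, 1
        got = expected_progeny(p, q, tiny_eco, strat, phi=0.6, psi=30.0)
        mc, se = progeny_monte_carlo(p, q, tiny_eco, strat, 0.6, 30.0,
                                     20000, rng)
        assert abs(got - mc) < 3 * max(se, 1e-3)

    def test_decreasing_in_viral_load(self, tiny_eco):
        strat = StrategyParams(a=0.0, r=0.01)
        vals = [expected_progeny(tiny_eco.P0 + 1, q, tiny_eco, strat,
                                 phi=0.6, psi=10.0)
                for q in range(tiny_eco.Q + 1)]
        assert np.all(np.diff(vals) <= 1e-12)

    def test_out_of_range_state_rejected(self, tiny_eco):
        with pytest.raises(ValueError):
            expected_progeny(2 * tiny_eco.P0, 0, tiny_eco,
                             StrategyParams(a=0.0, r=0.0), phi=1.0, psi=1.0)


class TestBurstModes:
    def test_empty_histogram_has_no_modes(self):
        assert burst_modes(np.zeros(50)) == 0

    def test_detects_two_separated_peaks(self):
        h = np.zeros(200)
        h[2:8] = [5, 9, 12, 9, 5, 2]
        h[150:156] = [3, 6, 8, 6, 3, 1]
        assert burst_modes(h) == 2

    def test_single_peak_counted_once(self):
        x = np.arange(100)
        h = np.exp(-0.5 * ((x - 40) / 8.0) ** 2)
        assert burst_modes(h) == 1
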