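import math

import numpy as np
import pytest

from qcewater import (ConvergenceError, QCEParameters, converge_state,
                      equilibrium_state, gibbs_energy, solve_populations,
                      volume_roots)
from qcewater.constants import ATM, AVOGADRO, GAS_CONSTANT

LN_A = math.log(AVOGADRO)


def brute_force_populations(ln_q, n, N_total=1.0):
    """Independent oracle: dense scan over ln N_1, refined to 1e-10.

    Uses only the mass-action relation and plain Python arithmetic; no part
    of the solver under test is reused.
    """
    ln_ntot = math.log(N_total * AVOGADRO)

    def mass(x):
        return sum(
            ni * math.exp(qi + ni * (x - ln_q[0]) - ln_ntot)
            for qi, ni in zip(ln_q, n)
        )  # Σ n_i N_i / N_total

    lo, hi = ln_ntot - 500.0, ln_ntot
    for _ in range(13):  # decimate the bracket: 500 / 10^13 < 1e-10
        step = (hi - lo) / 10.0
        for k in range(1, 11):
            point = hi if k == 10 else lo + k * step  # keep endpoint exact
            if mass(point) >= 1.0:
                lo, hi = point - step, point
                break
    x = 0.5 * (lo + hi)
    return [math.exp(qi + ni * (x - ln_q[0]) - LN_A) for qi, ni in zip(ln_q, n)]


class TestPopulations:
    def test_monomer_only(self):
        N = solve_populations(np.array([LN_A + 3.0]), np.array([1]), 0.7)
        assert N[0] == pytest.approx(0.7, rel=1e-12)

    def test_monomer_dimer_closed_form(self):
        # q chosen so the mole-scale equilibrium constant K = 1, i.e.
        # N_2 = N_1²; mass conservation N_1 + 2 N_1² = 1 gives N_1 = 1/2.
        ln_q1 = LN_A + 5.0
        ln_q = np.array([ln_q1, 2 * ln_q1 - LN_A])
        N = solve_populations(ln_q, np.array([1, 2]), 1.0)
        assert N[0] == pytest.approx(0.5, rel=1e-10)
        assert N[1] == pytest.approx(0.25, rel=1e-10)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_three_cluster_sets_match_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        ln_q = LN_A + rng.uniform(-5.0, 30.0, size=3)
        n = np.array([1, 2, 3])
        got = solve_populations(ln_q, n, 1.0)
        ref = brute_force_populations(list(ln_q), list(n), 1.0)
        np.testing.assert_allclose(got, ref, rtol=1e-9)

    def test_mass_conservation_and_positivity(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            k = rng.integers(2, 8)
            n = np.concatenate([[1], rng.integers(2, 12, size=k - 1)])
            ln_q = LN_A + rng.uniform(-50.0, 80.0, size=k)
            N = solve_populations(ln_q, n, 1.0)
            # extreme q spreads may underflow a population to exactly 0.0;
            # physical fixtures are checked for strict positivity elsewhere
            assert (N >= 0).all() and N[0] > 0
            assert float(n @ N) == pytest.approx(1.0, rel=1e-10)

    def test_requires_monomer_first(self):
        with pytest.raises(ValueError):
            solve_populations(np.array([1.0, 2.0]), np.array([2, 3]))


class TestVolumeRoots:
    def test_ideal_gas_monomer(self):
        v = volume_roots(np.array([1.0]), np.array([20.0]), np.array([1]),
                         QCEParameters(0.0, 0.0), 298.15, ATM)
        assert v.shape == (1,)
        assert v[0] == pytest.approx(24.4654, abs=2e-4)

    def test_excluded_volume_ideal_gas_exact(self):
        pops = np.array([0.4, 0.3])
        vols = np.array([20.0, 40.0])
        n = np.array([1, 2])
        params = QCEParameters(0.0, 1.5)
        v = volume_roots(pops, vols, n, params, 350.0, ATM)
        vex = 1.5 * float(pops @ (vols * AVOGADRO * 1e-27))
        expected = GAS_CONSTANT * 350.0 * pops.sum() / (ATM * 1e-3) + vex
        assert v[-1] == pytest.approx(expected, rel=1e-14)

    def test_generic_roots_satisfy_cubic(self):
        pops = np.array([0.05, 0.02, 0.08])
        vols = np.array([20.0, 41.0, 102.0])
        n = np.array([1, 2, 5])
        params = QCEParameters(300.0, 1.4)
        roots = volume_roots(pops, vols, n, params, 298.15, ATM)
        p_L = ATM * 1e-3
        vex = params.b_xv * float(pops @ (vols * AVOGADRO * 1e-27))
        n_mono = float(n @ pops)
        for v in roots:
            assert v > vex
            resid = (p_L * v ** 2 * (v - vex)
                     - GAS_CONSTANT * 298.15 * pops.sum() * v ** 2
                     + params.a_mf * n_mono * v - params.a_mf * n_mono * vex)
            assert abs(resid) <= 1e-8 * p_L * v ** 3


class TestParameters:
    def test_negative_values_rejected(self):
        with pytest.raises(ValueError):
            QCEParameters(-1.0, 0.5)
        with pytest.raises(ValueError):
            QCEParameters(1.0, -0.5)


class TestConvergeState:
    def test_ideal_gas_equivalence(self, synthetic18):
        mono = synthetic18.with_clusters(synthetic18.clusters[:1], "monomer")
        for T in (200.0, 298.15, 500.0):
            st = converge_state(mono, QCEParameters(0.0, 0.0), T, ATM, "gas")
            ratio = st.p * 1e-3 * st.molar_volume / (GAS_CONSTANT * T)
            assert abs(ratio - 1.0) <= 1e-10

    def test_reentering_fixed_point_converges_immediately(
            self, synthetic18, water_params, atm):
        st = converge_state(synthetic18, water_params, 298.15, atm, "liquid")
        again = converge_state(synthetic18, water_params, 298.15, atm,
                               st.molar_volume, populations0=st.populations)
        assert again.iterations <= 2
        assert again.molar_volume == pytest.approx(st.molar_volume, rel=1e-9)

    def test_mass_conserved_on_six_cluster_set(self, atm):
        from qcewater import synthetic_cluster_set
        cs = synthetic_cluster_set(5, 5)
        sub = cs.with_clusters(cs.clusters[:6], "six")
        st = converge_state(sub, QCEParameters(100.0, 1.0), 298.0, atm, "gas")
        total = float(st.stoichiometries @ st.populations)
        assert total == pytest.approx(1.0, rel=1e-10)
        assert (st.populations > 0).all()

    def test_warm_start_agrees_with_cold_start(self, synthetic18, water_params, atm):
        cold = converge_state(synthetic18, water_params, 300.0, atm, "liquid")
        prev = converge_state(synthetic18, water_params, 299.0, atm, "liquid")
        warm = converge_state(synthetic18, water_params, 300.0, atm,
                              prev.molar_volume, populations0=prev.populations)
        assert warm.molar_volume == pytest.approx(cold.molar_volume, rel=1e-8)
        np.testing.assert_allclose(warm.populations, cold.populations, rtol=1e-6)

    def test_nonconvergence_is_reported(self, synthetic18, water_params, atm):
        with pytest.raises(ConvergenceError, match="fixed point"):
            converge_state(synthetic18, water_params, 298.15, atm, "liquid",
                           max_iter=2)


class TestFreeEnergies:
    def test_pressure_derivative_of_g_is_volume(self, synthetic18):
        mono = synthetic18.with_clusters(synthetic18.clusters[:1], "monomer")
        params = QCEParameters(0.0, 0.0)
        dp = ATM * 1e-6
        g = []
        for p in (ATM - dp, ATM + dp):
            st = converge_state(mono, params, 298.15, p, "gas")
            g.append(st.gibbs_energy)
        v_mid = converge_state(mono, params, 298.15, ATM, "gas").molar_volume
        deriv = (g[1] - g[0]) / (2 * dp)     # kJ/(mol Pa)
        assert deriv == pytest.approx(v_mid * 1e-6, rel=1e-6)

    def test_gibbs_recompute_matches_stored(self, synthetic18, water_params, atm):
        st = converge_state(synthetic18, water_params, 298.15, atm, "liquid")
        assert gibbs_energy(st, synthetic18, water_params) == pytest.approx(
            st.gibbs_energy, rel=1e-12)

    def test_phase_selection_minimizes_g(self, synthetic18, water_params, atm):
        # liquid is the stable phase at ambient T, gas near 400 K
        low = equilibrium_state(synthetic18, water_params, 298.15, atm)
        high = equilibrium_state(synthetic18, water_params, 399.15, atm)
        assert low.phase == "liquid-like"
        assert high.phase == "gas-like"
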