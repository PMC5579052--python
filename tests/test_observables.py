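import math

import numpy as np
import pytest

from qcewater import (QCEParameters, StateResult, compute_isobar, ion_product,
                      kw_curve, kw_table, monomer_normalized_populations,
                      transition_temperature)
from qcewater.observables import Isobar, KwPoint
from qcewater.constants import ATM


def make_state(cs, populations, V=0.018, T=298.15, phase="liquid-like"):
    populations = np.asarray(populations, dtype=float)
    return StateResult(
        T=T, p=ATM, molar_volume=V, populations=populations,
        labels=cs.labels,
        stoichiometries=np.array([c.n_monomers for c in cs.clusters], float),
        phase=phase, gibbs_energy=0.0, helmholtz_energy=0.0,
        converged=True, iterations=1,
    )


class TestIonProduct:
    def test_single_ip_cluster_at_1e7_molar(self, toy):
        # toy order: W1, W3c, W5c, W5ip
        V = 0.018
        pops = [0.5, 0.01, 0.05, 1e-7 * V]
        pt = ion_product(make_state(toy, pops, V=V), toy)
        assert pt.Kw == pytest.approx(1e-14, rel=1e-12)
        assert pt.pKw == pytest.approx(14.0, abs=1e-10)

    def test_no_ip_clusters_gives_sentinel(self, toy):
        neutral = toy.with_clusters(toy.clusters[:3], "neutral")
        pt = ion_product(make_state(neutral, [0.5, 0.01, 0.05]), neutral)
        assert pt.Kw == 0.0
        assert math.isinf(pt.pKw)

    def test_two_ip_clusters_diagonal_sum(self, synthetic18):
        V = 0.018
        pops = np.zeros(len(synthetic18))
        pops[0] = 0.5
        ip_idx = [synthetic18.labels.index(l)
                  for l in synthetic18.ion_pair_labels[:2]]
        pops[ip_idx] = 1e-7 * V
        pt = ion_product(make_state(synthetic18, pops, V=V), synthetic18)
        assert pt.Kw == pytest.approx(2e-14, rel=1e-12)

    def test_product_mode_counts_cross_terms(self, synthetic18):
        V = 0.018
        pops = np.zeros(len(synthetic18))
        pops[0] = 0.5
        ip_idx = [synthetic18.labels.index(l)
                  for l in synthetic18.ion_pair_labels[:2]]
        pops[ip_idx] = 1e-7 * V
        st = make_state(synthetic18, pops, V=V)
        diag = ion_product(st, synthetic18, mode="diagonal").Kw
        prod = ion_product(st, synthetic18, mode="product").Kw
        assert prod == pytest.approx(2 * diag, rel=1e-12)

    def test_modes_coincide_for_single_dominant_ip(self, toy):
        V = 0.018
        st = make_state(toy, [0.5, 0.01, 0.05, 1e-7 * V], V=V)
        assert ion_product(st, toy, mode="diagonal").Kw == pytest.approx(
            ion_product(st, toy, mode="product").Kw, rel=1e-12)

    def test_unknown_mode_rejected(self, toy):
        with pytest.raises(ValueError):
            ion_product(make_state(toy, [1, 0, 0, 0]), toy, mode="geometric")


class TestNormalizedPopulations:
    def test_monomer_only(self, toy):
        mono = toy.with_clusters(toy.clusters[:1], "monomer")
        pops = monomer_normalized_populations(make_state(mono, [0.7]))
        assert pops == {"W1": 1.0}

    def test_sums_to_one(self, toy):
        pops = monomer_normalized_populations(
            make_state(toy, [0.3, 0.05, 0.06, 1e-9]))
        assert sum(pops.values()) == pytest.approx(1.0, abs=1e-12)

    def test_invariant_under_total_rescale(self, toy):
        a = monomer_normalized_populations(make_state(toy, [0.3, 0.05, 0.06, 1e-9]))
        b = monomer_normalized_populations(
            make_state(toy, np.array([0.3, 0.05, 0.06, 1e-9]) * 3.0))
        for k in a:
            assert a[k] == pytest.approx(b[k], rel=1e-12)


class TestIsobar:
    def test_monomer_ideal_density_inverse_in_t(self, synthetic18):
        mono = synthetic18.with_clusters(synthetic18.clusters[:1], "monomer")
        iso = compute_isobar(mono, QCEParameters(0.0, 0.0),
                             np.arange(300.0, 311.0, 5.0), ATM)
        rho = iso.densities(synthetic18.monomer.molar_mass)
        T = iso.temperatures
        np.testing.assert_allclose(rho * T, rho[0] * T[0], rtol=1e-10)

    def test_single_point_isobar(self, synthetic18):
        mono = synthetic18.with_clusters(synthetic18.clusters[:1], "monomer")
        iso = compute_isobar(mono, QCEParameters(0.0, 0.0), [298.15], ATM)
        assert len(iso.entries) == 1
        assert iso.transition_temperature is None

    def test_entries_must_ascend(self, toy):
        states = [make_state(toy, [1, 0, 0, 0], T=t) for t in (300.0, 300.0)]
        with pytest.raises(ValueError):
            Isobar(pressure=ATM, entries=states)

    def test_frame_has_population_columns(self, synthetic18, water_params, atm):
        iso = compute_isobar(synthetic18, water_params, [298.15], atm)
        frame = iso.to_frame(synthetic18.monomer.molar_mass)
        assert "N[W10ip]" in frame.columns
        assert frame["phase"].iloc[0] == "liquid-like"
        assert frame["density_g_per_cm3"].iloc[0] == pytest.approx(1.0, abs=0.05)


class TestTransitionDetection:
    def _isobar(self, toy, volumes, temps):
        states = [make_state(toy, [1, 0, 0, 0], V=v, T=t)
                  for v, t in zip(volumes, temps)]
        return Isobar(pressure=ATM, entries=states)

    def test_large_jump_found(self, toy):
        iso = self._isobar(toy, [0.019, 0.020, 0.021, 24.0, 25.0],
                           [371.0, 372.0, 373.0, 374.0, 375.0])
        assert transition_temperature(iso) == pytest.approx(373.5)

    def test_smooth_curve_has_no_transition(self, toy):
        iso = self._isobar(toy, [20.0, 21.0, 22.0, 23.0],
                           [300.0, 310.0, 320.0, 330.0])
        assert transition_temperature(iso) is None

    def test_equal_jumps_pick_lower_temperature(self, toy, caplog):
        import logging
        iso = self._isobar(toy, [1.0, 9.0, 81.0], [300.0, 310.0, 320.0])
        with caplog.at_level(logging.WARNING, logger="qcewater.observables"):
            t = transition_temperature(iso)
        assert t == pytest.approx(305.0)
        assert any("equal volume jumps" in r.message for r in caplog.records)


class TestKwCurve:
    def test_ip_free_set_is_all_zero(self, synthetic18):
        mono = synthetic18.with_clusters(synthetic18.clusters[:1], "monomer")
        iso = compute_isobar(mono, QCEParameters(0.0, 0.0),
                             [300.0, 320.0], ATM)
        pts = kw_curve(iso, mono)
        assert all(pt.Kw == 0.0 and math.isinf(pt.pKw) for pt in pts)

    def test_single_entry_curve(self, synthetic18, water_params, atm):
        iso = compute_isobar(synthetic18, water_params, [298.15], atm)
        pts = kw_curve(iso, synthetic18)
        assert len(pts) == 1
        assert 0.0 < pts[0].Kw < 1.0

    def test_table_columns(self, synthetic18, water_params, atm):
        iso = compute_isobar(synthetic18, water_params, [298.15], atm)
        frame = kw_table(iso, synthetic18)
        assert list(frame.columns) == ["T_K", "Kw_mol2_L2", "pKw",
                                       "pKw_experimental"]

    def test_kwpoint_consistency(self):
        pt = KwPoint.from_kw(298.15, 1e-14)
        assert pt.pKw == pytest.approx(-math.log10(pt.Kw))
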