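"""Encounter probability, 2D constants, bond kinetics, adhesion."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from synapse_sim import (BindingConstants, ContactEvent, EncounterParams,
                         adhesion_probability, bond_counts_batch,
                         derive_2d_constants, encounter_probability,
                         simulate_bond_formation, surface_density)
from synapse_sim.contact import bond_count_fast

from oracles import brownian_hit_fraction, gillespie_bond_mean


class TestEncounterProbability:
    def test_zero_density_zero_probability(self):
        assert encounter_probability(0.0, EncounterParams()) == 0.0

    def test_probability_bounds_and_monotonicity(self):
        params = EncounterParams()
        probs = [encounter_probability(d, params)
                 for d in (1e4, 1e5, 1e6, 1e7, 1e9)]
        assert all(0.0 <= p <= 1.0 for p in probs)
        assert probs == sorted(probs)

    def test_short_round_limit(self):
        fast = EncounterParams(round_duration=1e-6)
        assert encounter_probability(1e6, fast) < 1e-6

    def test_density_not_counts_drives_probability(self):
        # rescaling volume and counts together leaves the density unchanged,
        # so the probability is identical by construction of the interface
        params = EncounterParams()
        assert encounter_probability(5e6, params) == \
            encounter_probability(50e6 / 10.0, params)

    def test_unknown_entity_class_is_a_config_error(self):
        with pytest.raises(KeyError, match="bystander"):
            encounter_probability(1e6, EncounterParams(), "bystander")

    def test_matches_brownian_walk_oracle_within_three_se(self):
        """Formula vs empirical hit frequency of random walkers among
        immotile absorbing spheres at matched density."""
        params = EncounterParams()  # D = 0.2 um^2/s, radii 5.5 + 5.0 um
        density = 6e6  # spheres/mL, a realistic co-incubation density
        n_walkers = 6000
        p_formula = encounter_probability(density, params)
        p_sim = brownian_hit_fraction(density, params, params.round_duration,
                                      n_walkers, seed=42)
        se = math.sqrt(p_sim * (1 - p_sim) / n_walkers)
        assert abs(p_sim - p_formula) < 3 * se


class TestDerive2DConstants:
    def test_confinement_scaling_law(self, binding_default):
        k1 = derive_2d_constants(binding_default, 10.0)
        k2 = derive_2d_constants(binding_default, 20.0)
        assert k2.kon2D_A == pytest.approx(k1.kon2D_A / 2)
        assert k2.kon2D_B == pytest.approx(k1.kon2D_B / 2)
        assert k2.koff2D_A == k1.koff2D_A == binding_default.koff_A

    def test_dimensional_round_trip(self, binding_default):
        """kon2D carries (molecules/um^2)^-1 s^-1: multiplying back by
        N_A * sigma recovers the 3D on-rate in M^-1 s^-1."""
        sigma_nm = 15.0
        k2d = derive_2d_constants(binding_default, sigma_nm)
        avogadro = 6.02214076e23
        kon3d = k2d.kon2D_A * avogadro * (sigma_nm * 1e-3) / 1e15
        assert kon3d == pytest.approx(binding_default.kon_A, rel=1e-12)

    def test_2d_affinity_scales_inversely_with_confinement(self, binding_default):
        k2d = derive_2d_constants(binding_default, 20.0)
        kd_2d = k2d.koff2D_B / k2d.kon2D_B          # molecules/um^2
        kd_3d_um3 = binding_default.KD_B * 6.02214076e23 / 1e15
        assert kd_2d == pytest.approx(kd_3d_um3 * 0.020, rel=1e-12)


class TestBondFormation:
    def test_no_reactants_no_bonds(self, k2d_default):
        ev = ContactEvent(0.0, 0.0, 0.0, 0.0, contact_area=1.0, duration=2.0)
        assert simulate_bond_formation(ev, k2d_default) == 0.0

    def test_single_channel_linear_closed_form_at_small_time(self, binding_default):
        # no dissociation, AY + B channel only, depletion negligible at
        # vanishing time: N(t) = A_c * kon2D_B * rho_AY * rho_B * t
        bc = BindingConstants(kon_A=binding_default.kon_A, koff_A=1e-12,
                              kon_B=binding_default.kon_B, koff_B=1e-12)
        k2d = derive_2d_constants(bc, 20.0)
        rho_ay, rho_b, area, t = 5.0, 50.0, 1.0, 1e-5
        n = bond_counts_batch(np.array([0.0]), np.array([rho_ay]),
                              np.array([rho_b]), np.array([0.0]),
                              np.array([area]), np.array([t]), k2d)[0]
        expected = area * k2d.kon2D_B * rho_ay * rho_b * t
        assert n == pytest.approx(expected, rel=1e-6)

    def test_matches_gillespie_oracle_within_three_se(self, k2d_default):
        rho = (120.0, 15.0, 150.0, 40.0)
        area, duration = 2.0, 1.5
        n_ode = bond_counts_batch(*[np.array([r]) for r in rho],
                                  np.array([area]), np.array([duration]),
                                  k2d_default)[0]
        mean, se = gillespie_bond_mean(rho, area, duration, k2d_default,
                                       n_runs=1000, seed=7)
        assert abs(n_ode - mean) < 3 * se

    def test_bond_count_never_exceeds_lesser_side(self, k2d_default):
        rng = np.random.default_rng(5)
        rho = rng.uniform(0, 400, size=(200, 4))
        area = rng.uniform(0.5, 3.0, size=200)
        dur = rng.uniform(0.1, 5.0, size=200)
        n = bond_counts_batch(rho[:, 0], rho[:, 1], rho[:, 2], rho[:, 3],
                              area, dur, k2d_default)
        effector_side = (rho[:, 0] + rho[:, 1]) * area
        target_side = (rho[:, 2] + rho[:, 3]) * area
        assert (n >= 0).all()
        assert (n <= np.minimum(effector_side, target_side) * (1 + 1e-9)).all()

    def test_fast_path_agrees_with_batch_integrator(self, k2d_default):
        rng = np.random.default_rng(11)
        for _ in range(200):
            rho = rng.uniform(0, 300, size=4)
            area, dur = rng.uniform(0.5, 3.0), rng.uniform(0.1, 5.0)
            fast = bond_count_fast(*rho, area, dur, k2d_default)
            ref = bond_counts_batch(*[np.array([x]) for x in rho],
                                    np.array([area]), np.array([dur]),
                                    k2d_default)[0]
            assert fast == pytest.approx(ref, rel=0.02, abs=1e-9)

    def test_contact_event_validation(self):
        with pytest.raises(ValueError):
            ContactEvent(1.0, 1.0, 1.0, 1.0, contact_area=1.0, duration=10.0)
        with pytest.raises(ValueError):
            ContactEvent(-1.0, 1.0, 1.0, 1.0, contact_area=1.0, duration=1.0)


class TestAdhesionProbability:
    def test_zero_bonds_zero_probability(self):
        assert adhesion_probability(0.0, 0.05) == 0.0

    def test_half_probability_at_log_two(self):
        alpha = 0.05
        assert adhesion_probability(math.log(2) / alpha, alpha) == \
            pytest.approx(0.5, rel=1e-12)

    def test_saturation_and_monotonicity(self):
        assert adhesion_probability(1e9, 0.05) == pytest.approx(1.0)
        probs = [adhesion_probability(n, 0.05) for n in (0, 1, 5, 20, 100)]
        assert probs == sorted(probs)
        assert adhesion_probability(10, 0.1) > adhesion_probability(10, 0.01)

    @given(st.floats(min_value=0, max_value=1e6),
           st.floats(min_value=1e-6, max_value=10))
    def test_always_a_probability(self, bonds, alpha):
        assert 0.0 <= adhesion_probability(bonds, alpha) <= 1.0


class TestCD19DrivesAdhesion:
    def test_lower_cd19_gives_stochastically_lower_adhesion(self, k2d_default):
        """First-order stochastic dominance of P_a over sampled contacts —
        the mechanism behind antigen escape."""
        rng = np.random.default_rng(21)
        n = 400
        alpha = 0.01
        dur = rng.uniform(0.1, 5.0, size=n)

        def sample_pa(cd19_mean):
            rho_b = surface_density(cd19_mean * 0.9, 5.0)
            rho_yb = surface_density(cd19_mean * 0.1, 5.0)
            out = []
            for d in dur:
                bonds = bond_count_fast(130.0, 1.0, rho_b, rho_yb, 1.0, d,
                                        k2d_default)
                out.append(adhesion_probability(bonds, alpha))
            return np.sort(out)

        low = sample_pa(4.0e4)
        high = sample_pa(1.45e5)
        assert (low <= high + 1e-12).all()
        assert low.mean() < high.mean()
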