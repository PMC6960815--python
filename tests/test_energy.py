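"""Individual free-energy terms and their exact printed values."""

import math

import numpy as np
import pytest

from sbris import chain, energy, units
from sbris.chain import (Conformation, Coordinates, all_trans_conformation,
                         build_coordinates, build_topology)
from sbris.energy import (ElectrostaticEnvironment, SingularityError,
                          elastic_energy, long_range_energy, mechanical_work,
                          protonation_energy, rotational_energy,
                          sev_overlap, short_range_energy, site_charges,
                          total_free_energy)

LN10 = math.log(10.0)


def _conf(states, topo=None):
    topo = topo or build_topology(len(states) + 1)
    return all_trans_conformation(topo, states), topo


class TestRotational:
    def test_default_zero_for_any_conformation(self):
        conf, _ = _conf([0, 1, 2, 1])
        assert rotational_energy(conf) == 0.0

    def test_counts_gauche_bonds(self):
        conf, _ = _conf([1, 2, 1, 0])
        assert rotational_energy(conf, (0.0, 1.0, 1.0)) == pytest.approx(3.0)

    def test_empty_rotatable_set(self):
        conf = Conformation(np.empty(0, dtype=np.int8),
                            np.full(3, 0.15), np.full(2, 120.0))
        assert rotational_energy(conf, (0.0, 1.0, 1.0)) == 0.0

    def test_asymmetric_gauche_energies_rejected(self):
        conf, _ = _conf([0])
        with pytest.raises(ValueError):
            rotational_energy(conf, (0.0, 1.0, 2.0))


class TestProtonation:
    @pytest.mark.parametrize("s, pH, pK, expected", [
        (np.zeros(5), 12.0, 9.0, 0.0),
        (np.array([1, 0, 1, 1]), 9.0, 9.0, 0.0),
        (np.array([1, 1]), 10.0, 9.0, 2 * LN10),
    ])
    def test_values(self, s, pH, pK, expected):
        assert protonation_energy(s, pH, pK) == pytest.approx(expected)


class TestLongRange:
    def test_zero_charges(self):
        pos = np.array([[0, 0, 0], [0, 0, 1.0], [0, 0, 2.0]])
        env = ElectrostaticEnvironment(1.0)
        assert long_range_energy(np.zeros(3), pos, env) == 0.0

    def test_unscreened_pair_at_bjerrum_length(self):
        pos = np.array([[0, 0, 0], [0, 0, 0.35], [0, 0, 0.7]])
        env = ElectrostaticEnvironment(0.0)  # kappa = 0
        q = np.array([1.0, 0.0, 1.0])
        assert long_range_energy(q, pos, env) == pytest.approx(1.0)

    def test_screened_pair_at_debye_length(self):
        # kappa d = 1 at d = 0.304 nm, I = 1 M
        pos = np.array([[0, 0, 0], [0, 0, 0.15], [0, 0, 0.304]])
        env = ElectrostaticEnvironment(1.0)
        q = np.array([1.0, 0.0, 1.0])
        expected = 0.7 / 0.304 * math.exp(-1.0)
        assert long_range_energy(q, pos, env) == pytest.approx(expected)
        assert expected == pytest.approx(0.8471, abs=1e-4)

    def test_nearest_neighbour_sites_excluded(self):
        pos = np.array([[0, 0, 0], [0, 0, 0.3], [0, 0, 0.6]])
        env = ElectrostaticEnvironment(1.0)
        # only the (0, 2) pair enters: the (i, i+1) pairs are short-range
        q = np.array([1.0, 1.0, 0.0])
        assert long_range_energy(q, pos, env) == 0.0

    def test_coincident_charges_rejected(self):
        pos = np.zeros((3, 3))
        env = ElectrostaticEnvironment(1.0)
        with pytest.raises(SingularityError):
            long_range_energy(np.ones(3), pos, env)

    def test_monotonically_screened_by_ionic_strength(self, rng):
        topo = build_topology(6)
        states = rng.integers(0, 3, 5).astype(np.int8)
        coords = build_coordinates(topo, all_trans_conformation(topo, states))
        pos = coords.positions[topo.site_nodes]
        q = np.ones(6)
        values = [long_range_energy(q, pos, ElectrostaticEnvironment(I))
                  for I in (0.0, 0.001, 0.01, 0.1, 1.0)]
        assert all(a > b for a, b in zip(values, values[1:]))


class TestShortRange:
    def test_trans_and_gauche_pair_energies(self):
        conf, _ = _conf([0])
        q = np.ones(2)
        assert short_range_energy(q, conf) == pytest.approx(LN10)
        conf_g, _ = _conf([1])
        assert short_range_energy(q, conf_g) == pytest.approx(3 * LN10)

    def test_deprotonated_neighbour_contributes_nothing(self):
        conf, _ = _conf([0, 1])
        q = np.array([1.0, 0.0, 1.0])
        assert short_range_energy(q, conf) == 0.0


class TestElastic:
    def test_equilibrium_geometry_is_zero(self, topo50):
        conf = all_trans_conformation(topo50)
        assert elastic_energy(conf, topo50) == 0.0

    def test_stretched_bond_printed_value(self):
        topo = build_topology(2)
        conf = all_trans_conformation(topo)
        conf.bond_lengths[0] += 0.01  # 0.1 A in nm
        # 0.5 * 300 * 0.1^2 = 1.5 kcal/mol
        assert elastic_energy(conf, topo) == pytest.approx(
            1.5 * units.KCAL_MOL_TO_KT, rel=1e-6)
        assert elastic_energy(conf, topo) == pytest.approx(2.532, abs=2e-3)

    def test_bent_angle_printed_value(self):
        topo = build_topology(2)
        conf = all_trans_conformation(topo)
        conf.bond_angles[0] += 10.0
        # 0.5 * 0.01 * 10^2 = 0.5 kcal/mol
        assert elastic_energy(conf, topo) == pytest.approx(
            0.5 * units.KCAL_MOL_TO_KT, rel=1e-6)
        assert elastic_energy(conf, topo) == pytest.approx(0.844, abs=1e-3)


class TestMechanicalWork:
    def test_values(self):
        pos = np.zeros((2, 3))
        pos[1, 2] = units.KT_PN_NM  # r_z = kBT/pN
        coords = Coordinates(pos)
        assert mechanical_work(coords, 0.0) == 0.0
        assert mechanical_work(coords, 1.0) == pytest.approx(-1.0)
        flat = Coordinates(np.array([[0, 0, 0], [1.0, 0, 0]]))
        assert mechanical_work(flat, 5.0) == 0.0


class TestExcludedVolume:
    def test_extended_chain_has_no_clash(self, topo50):
        coords = build_coordinates(topo50, all_trans_conformation(topo50))
        assert not sev_overlap(coords, topo50)

    def test_point_charges_never_clash(self):
        topo = build_topology(3, radius_ionizable=0.0, radius_inert=0.0)
        pos = np.zeros((7, 3))  # all coincident, still no overlap
        assert not sev_overlap(Coordinates(pos), topo)

    def test_close_pair_four_bonds_apart_clashes(self):
        topo = build_topology(3)  # radii 0.17/0.155 nm, sum 0.325-0.34
        coords = build_coordinates(topo, all_trans_conformation(topo))
        pos = coords.positions.copy()
        pos[4] = pos[0] + [0.2, 0.0, 0.0]  # nodes 0 and 4: 4 bonds apart
        assert sev_overlap(Coordinates(pos), topo)


class TestTotalFreeEnergy:
    def test_uncharged_extended_rigid_chain_is_zero(self, topo50):
        conf = all_trans_conformation(topo50)
        coords = build_coordinates(topo50, conf)
        e = total_free_energy(topo50, conf, coords,
                              ElectrostaticEnvironment(1.0),
                              protonation=np.zeros(50), pH=7.0)
        assert e == 0.0

    def test_additivity_against_term_by_term_sum(self, rng):
        topo = build_topology(6, eps_rot=(0.0, 0.4, 0.4))
        states = rng.integers(0, 3, 5).astype(np.int8)
        conf = all_trans_conformation(topo, states)
        conf.bond_lengths += rng.normal(0, 0.004, conf.bond_lengths.size)
        conf.bond_angles += rng.normal(0, 4.0, conf.bond_angles.size)
        coords = build_coordinates(topo, conf)
        s = rng.integers(0, 2, 6).astype(float)
        env = ElectrostaticEnvironment(0.1)
        total = total_free_energy(topo, conf, coords, env, protonation=s,
                                  pH=8.0, force_pN=0.7)
        parts = (rotational_energy(conf, topo.eps_rot)
                 + protonation_energy(s, 8.0, topo.pK)
                 + long_range_energy(s, coords.positions[topo.site_nodes],
                                     env)
                 + short_range_energy(s, conf, topo.eps_int)
                 + elastic_energy(conf, topo)
                 + mechanical_work(coords, 0.7))
        assert total == pytest.approx(parts, abs=1e-12)

    @pytest.mark.parametrize("theta, fill", [(0.0, 0.0), (1.0, 1.0)])
    def test_smeared_limits_match_fluctuating(self, rng, theta, fill):
        """theta in {0, 1} reproduces the frozen all-0/all-1 occupations."""
        topo = build_topology(5)
        states = rng.integers(0, 3, 4).astype(np.int8)
        conf = all_trans_conformation(topo, states)
        coords = build_coordinates(topo, conf)
        env = ElectrostaticEnvironment(0.01)
        smeared = total_free_energy(topo, conf, coords, env, mode="smeared",
                                    theta=theta, force_pN=0.2)
        s = np.full(5, fill)
        fluct = total_free_energy(topo, conf, coords, env, protonation=s,
                                  pH=topo.pK, force_pN=0.2)
        # at pH = pK the one-body proton term vanishes: pair terms must agree
        assert smeared == pytest.approx(fluct, abs=1e-12)

    def test_rigid_motion_invariance(self, rng):
        topo = build_topology(5)
        states = rng.integers(0, 3, 4).astype(np.int8)
        conf = all_trans_conformation(topo, states)
        coords = build_coordinates(topo, conf)
        env = ElectrostaticEnvironment(0.1)
        s = np.ones(5)
        # rotation about z preserves r_z, hence every term incl. work
        ang = rng.uniform(0, 2 * math.pi)
        Rz = np.array([[math.cos(ang), -math.sin(ang), 0],
                       [math.sin(ang), math.cos(ang), 0], [0, 0, 1]])
        moved = Coordinates(coords.positions @ Rz.T + [1.0, -2.0, 0.0])
        e1 = total_free_energy(topo, conf, coords, env, protonation=s,
                               pH=7.0, force_pN=0.4)
        e2 = total_free_energy(topo, conf, moved, env, protonation=s,
                               pH=7.0, force_pN=0.4)
        assert e1 == pytest.approx(e2, abs=1e-10)


def test_site_charges_validation():
    with pytest.raises(ValueError):
        site_charges("smeared", theta=1.5, n_sites=3)
    with pytest.raises(ValueError):
        site_charges("fluctuating")
    assert np.allclose(site_charges("smeared", theta=0.25, n_sites=4), 0.25)


def test_debye_length_closed_form():
    assert units.debye_length_nm(1.0) == pytest.approx(0.304)
    assert units.debye_length_nm(0.01) == pytest.approx(3.04)
    assert math.isinf(units.debye_length_nm(0.0))
    with pytest.raises(ValueError):
        units.debye_length_nm(-1.0)
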