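import numpy as np
import pytest

from gbion import build_system
from gbion.born import effective_radii
from gbion.constants import EPS_OUT_DEFAULT, KE_COULOMB
from gbion.dynamics import _ForceField
from gbion.energy import (EnergyError, canonical_total_energy, energy_scan,
                          f_gb, gbion_pair_energy, lj_energy, self_energy,
                          total_energy_forces)
from tests.conftest import make_random_system


class TestFgb:
    def test_contact_limit_geometric_mean(self):
        assert f_gb(0.0, 2.0, 2.0, 4.0) == pytest.approx(2.0)
        assert f_gb(0.0, 1.0, 4.0, 4.0) == pytest.approx(2.0)

    def test_closed_form_value(self):
        assert f_gb(1.0, 1.0, 1.0, 4.0) == pytest.approx(1.33372, abs=1e-5)

    def test_gamma_to_zero_limit_is_distance(self):
        assert f_gb(5.0, 2.0, 2.0, 1e-12) == pytest.approx(5.0, abs=1e-9)
        assert f_gb(5.0, 2.0, 2.0, 0.0) == pytest.approx(5.0, abs=0)

    def test_f_at_least_d(self, rng):
        d = rng.uniform(0, 20, 200)
        R = rng.uniform(0.5, 4.0, 200)
        for gamma in (1e-6, 0.1, 1.0, 4.0, 8.0):
            assert np.all(f_gb(d, R, R[::-1], gamma) >= d - 1e-12)

    def test_negative_inputs_rejected(self):
        with pytest.raises(EnergyError):
            f_gb(-1.0, 1.0, 1.0, 4.0)
        with pytest.raises(EnergyError):
            f_gb(1.0, 1.0, 1.0, -0.5)


class TestPairEnergy:
    def test_canonical_unit_pair_value(self):
        e = gbion_pair_energy(1.0, 1.0, -1.0, 1.0, 1.0, 4.0, 1.0)
        assert e == pytest.approx(-86.259, abs=2e-3)

    def test_gamma_zero_is_coulomb_in_water(self):
        e = gbion_pair_energy(1.0, 1.0, -1.0, 1.0, 1.0, 1e-12, 1.0)
        assert e == pytest.approx(-KE_COULOMB / EPS_OUT_DEFAULT, rel=1e-9)

    def test_eps_in_equal_eps_out_is_coulomb_for_any_gamma(self):
        d = np.linspace(0.5, 20, 50)
        ref = KE_COULOMB * -1.0 / (EPS_OUT_DEFAULT * d)
        for gamma in (1e-6, 0.5, 4.0):
            e = gbion_pair_energy(d, 1.0, -1.0, 1.5, 2.0, gamma,
                                  EPS_OUT_DEFAULT)
            assert np.allclose(e, ref, rtol=1e-12)

    def test_monotone_approach_to_coulomb(self):
        """|E - E_coulomb| shrinks as eps_in grows and as gamma drops."""
        d = np.linspace(0.5, 20.0, 40)
        coulomb = KE_COULOMB * -1.0 / (EPS_OUT_DEFAULT * d)
        prev = None
        for eps_in in (1.0, 8.0, 36.0, 54.0, 78.5):
            dev = np.abs(gbion_pair_energy(d, 1, -1, 1.5, 1.5, 4.0, eps_in)
                         - coulomb)
            if prev is not None:
                assert np.all(dev <= prev + 1e-12)
            prev = dev
        prev = None
        for gamma in (4.0, 1.0, 0.1, 1e-6):
            dev = np.abs(gbion_pair_energy(d, 1, -1, 1.5, 1.5, gamma, 1.0)
                         - coulomb)
            if prev is not None:
                assert np.all(dev <= prev + 1e-12)
            prev = dev

    def test_zero_distance_rejected(self):
        with pytest.raises(EnergyError):
            gbion_pair_energy(0.0, 1, -1, 1, 1, 4.0, 1.0)


class TestSelfEnergy:
    def test_born_ion_value(self):
        assert self_energy(1.0, 2.0, 1.0) == pytest.approx(-81.958, abs=1e-3)

    def test_zero_charge(self):
        assert self_energy(0.0, 2.0, 1.0) == 0.0

    def test_matched_dielectrics(self):
        assert self_energy(1.0, 2.0, EPS_OUT_DEFAULT) == 0.0


class TestLennardJones:
    def test_minimum_depth_and_zero_crossing(self):
        sigma, eps = 3.0, 0.25
        d_min = 2 ** (1 / 6) * sigma
        assert lj_energy(d_min, sigma, sigma, eps, eps) == pytest.approx(-eps)
        assert lj_energy(sigma, sigma, sigma, eps, eps) == pytest.approx(0.0)
        assert lj_energy(50.0, sigma, sigma, eps, eps) == pytest.approx(
            0.0, abs=1e-6)
        assert lj_energy(50.0, sigma, sigma, eps, eps) < 0.0


class TestTotalEnergyForces:
    def test_breakdown_sums_exactly(self, rng, nacl_table):
        s = make_random_system(rng, 12, spread=8.0)
        radii = effective_radii(s)
        bd, _ = total_energy_forces(s, radii, nacl_table)
        parts = bd.coulomb + bd.gb_cross + bd.gb_self + bd.lj + bd.restraint
        assert bd.total == pytest.approx(parts, rel=1e-10)
        assert sum(bd.by_class_pair.values()) == pytest.approx(
            bd.coulomb + bd.gb_cross, rel=1e-9)

    def test_net_force_vanishes(self, rng, nacl_table):
        s = make_random_system(rng, 15, spread=8.0)
        _, F = total_energy_forces(s, effective_radii(s), nacl_table)
        assert np.allclose(F.sum(axis=0), 0.0, atol=1e-10)

    def test_newtons_third_law_two_particles(self, nacl_table):
        s = build_system([
            {"position": [0, 0, 0], "species": "NA"},
            {"position": [3, 1, 0], "species": "CL"}])
        _, F = total_energy_forces(s, effective_radii(s), nacl_table)
        assert np.allclose(F[0], -F[1])

    def test_forces_match_finite_differences(self, rng, nacl_table):
        s = make_random_system(rng, 20, spread=6.0)
        radii = effective_radii(s)
        _, F = total_energy_forces(s, radii, nacl_table)
        h = 1e-5
        fmax = np.abs(F).max()
        for i in range(0, s.n_particles, 3):
            for dim in range(3):
                es = []
                for sgn in (1, -1):
                    pos = s.positions.copy()
                    pos[i, dim] += sgn * h
                    s2 = s.with_positions(pos)
                    bd, _ = total_energy_forces(
                        s2, effective_radii(s2), nacl_table,
                        compute_forces=False)
                    es.append(bd.total)
                fd = -(es[0] - es[1]) / (2 * h)
                assert abs(fd - F[i, dim]) / fmax < 1e-6

    def test_stale_radii_rejected(self, rng, nacl_table):
        s = make_random_system(rng, 5, spread=6.0)
        radii = effective_radii(s)
        moved = s.with_positions(s.positions + 1.0)
        with pytest.raises(Exception, match="stale"):
            total_energy_forces(moved, radii, nacl_table)

    def test_canonical_reduction_is_bitwise(self, rng, canonical_table):
        for _ in range(50):
            s = make_random_system(rng, int(rng.integers(2, 9)), spread=8.0)
            radii = effective_radii(s)
            bd, _ = total_energy_forces(s, radii, canonical_table,
                                        compute_forces=False)
            electro = bd.coulomb + bd.gb_cross + bd.gb_self
            assert electro == canonical_total_energy(s, radii)

    def test_compiled_kernels_agree_with_reference(self, rng, nacl_table):
        for n in (4, 17, 40):
            s = make_random_system(rng, n, spread=10.0)
            ff = _ForceField(s, nacl_table, frozen_solute=False)
            bd_k, F_k = ff.evaluate(s.positions)
            bd_n, F_n = total_energy_forces(s, effective_radii(s), nacl_table)
            assert bd_k.total == pytest.approx(bd_n.total, rel=1e-12)
            assert np.allclose(F_k, F_n, rtol=1e-9, atol=1e-12)


class TestEnergyScan:
    def test_unit_pair_value_in_reduced_units(self):
        scan = energy_scan(1.0, -1.0, 4.0, 1.0, np.array([1.0]))
        assert scan["energy"][0] == pytest.approx(-0.2598, abs=1e-4)

    def test_intermediate_eps_in_lies_between_canonical_and_coulomb(self):
        d = np.linspace(0.5, 10.0, 100)
        canon = energy_scan(1.0, -1.0, 4.0, 1.0, d)["energy"]
        mid = energy_scan(1.0, -1.0, 4.0, 36.0, d)["energy"]
        coulomb = energy_scan(1.0, -1.0, 4.0, 36.0, d)["coulomb"]
        assert np.all(mid < coulomb)
        assert np.all(mid > canon)

    def test_curves_decay_to_zero(self):
        d = np.array([200.0, 500.0])
        scan = energy_scan(1.0, -1.0, 4.0, 8.0, d)
        assert np.allclose(scan["energy"], 0.0, atol=1e-4)
        assert np.allclose(scan["coulomb"], 0.0, atol=1e-4)
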