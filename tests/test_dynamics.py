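import numpy as np
import pytest

from gbion import build_system
from gbion.constants import KB
from gbion.dynamics import (SimConfig, SimulationError, mc_sample, minimize,
                            run_simulation)
from gbion.params import PairClassTable
from gbion.restraints import FlatBottomSphere, flat_bottom_energy_force


def free_ions(positions, charge=0.0):
    return build_system([
        {"position": p, "species": "NA", "charge": charge, "mobility": "free"}
        for p in positions])


class TestFlatBottomRestraint:
    def test_zero_inside_and_at_boundary(self):
        u, f = flat_bottom_energy_force(np.array([0.0, 5.0, 10.0]), 10.0, 20.0)
        assert np.allclose(u, 0.0)
        assert np.allclose(f, 0.0)

    def test_harmonic_beyond(self):
        u, f = flat_bottom_energy_force(11.0, 10.0, 20.0)
        assert u == pytest.approx(20.0)
        assert f == pytest.approx(-40.0)

    def test_continuity_at_r3(self):
        eps = 1e-9
        u_in, f_in = flat_bottom_energy_force(10.0 - eps, 10.0, 20.0)
        u_out, f_out = flat_bottom_energy_force(10.0 + eps, 10.0, 20.0)
        assert abs(u_out - u_in) < 1e-12
        assert abs(f_out - f_in) < 1e-6

    def test_restraint_forces_point_inward(self):
        s = free_ions([[15.0, 0, 0]])
        rest = FlatBottomSphere(r3=10.0, k=20.0, anchor=np.zeros(3))
        e, F = rest.energy_forces(s)
        assert e == pytest.approx(20.0 * 25.0)
        assert F[0, 0] < 0

    def test_com_anchor(self):
        s = build_system([
            {"position": [0, 0, 0], "species": "PHO", "mobility": "fixed"},
            {"position": [2, 0, 0], "species": "PHO", "mobility": "fixed"},
            {"position": [20, 0, 0], "species": "NA"}])
        rest = FlatBottomSphere(r3=10.0, k=20.0, anchor=[0, 1])
        e, _ = rest.energy_forces(s)
        # distance from COM at (1,0,0) is 19 -> 9 Å excess
        assert e == pytest.approx(20.0 * 81.0)


class TestLangevin:
    def test_same_seed_identical_trajectories(self):
        s = free_ions([[0, 0, 0], [5, 0, 0]], charge=0.0)
        table = PairClassTable()
        cfg = SimConfig(n_steps=500, snapshot_stride=50, seed=11)
        t1 = run_simulation(s, table, None, cfg)
        t2 = run_simulation(s, table, None, cfg)
        assert np.array_equal(t1.positions, t2.positions)

    def test_zero_temperature_zero_force_is_ballistic(self):
        s = free_ions([[0, 0, 0]])
        table = PairClassTable()
        cfg = SimConfig(temperature=0.0, friction_ps=0.0, n_steps=100,
                        snapshot_stride=100, seed=0)
        v0 = np.array([[0.01, 0.0, 0.0]])
        traj = run_simulation(s, table, None, cfg, velocities=v0)
        assert traj.positions[-1][0, 0] == pytest.approx(
            100 * cfg.dt_fs * 0.01, rel=1e-9)

    def test_fixed_particles_do_not_move(self, nacl_table):
        s = build_system([
            {"position": [0, 0, 0], "species": "PHO", "mobility": "fixed"},
            {"position": [6, 0, 0], "species": "NA"}])
        cfg = SimConfig(n_steps=300, snapshot_stride=50, seed=2)
        traj = run_simulation(s, nacl_table, None, cfg)
        assert np.array_equal(traj.positions[-1][0], s.positions[0])
        assert not np.array_equal(traj.positions[-1][1], s.positions[1])

    def test_kinetic_temperature_within_two_percent(self):
        """Thermostat accuracy over 1e5 steps of a 25-ion ideal gas."""
        rng = np.random.default_rng(5)
        s = free_ions(rng.uniform(-20, 20, (25, 3)))
        s.lj_eps[:] = 0.0
        table = PairClassTable()
        cfg = SimConfig(n_steps=100_000, friction_ps=5.0, snapshot_stride=25,
                        seed=8)
        traj = run_simulation(s, table, None, cfg)
        assert traj.temperatures.mean() == pytest.approx(300.0, rel=0.02)

    def test_equipartition_in_harmonic_well(self):
        """Velocity variance of a tethered bead matches k_B T / m."""
        s = build_system([{"position": [0.0, 0, 0], "species": "NA",
                           "charge": 0.0, "mobility": "restrained"}])
        table = PairClassTable()
        cfg = SimConfig(n_steps=60_000, friction_ps=2.0, snapshot_stride=25,
                        seed=13, solute_restraint_k=5.0)
        traj = run_simulation(s, table, None, cfg)
        # snapshot temperatures average the velocity variance over dof
        t_mean = traj.temperatures.mean()
        n_eff = len(traj.temperatures) / 20
        assert abs(t_mean - 300.0) < 3 * 300.0 * np.sqrt(2 / (3 * n_eff))

    def test_energy_blowup_halts_with_diagnostic(self, nacl_table):
        # a stiff tether integrated far beyond its stability limit diverges
        s = build_system([{"position": [1.0, 0, 0], "species": "NA",
                           "charge": 0.0, "mobility": "restrained"}])
        cfg = SimConfig(n_steps=2000, dt_fs=50.0, friction_ps=0.0,
                        snapshot_stride=10, seed=1,
                        solute_restraint_k=1.0e4)
        with pytest.raises(SimulationError, match="blow-up"):
            run_simulation(s, nacl_table, None, cfg)

    def test_volume_contract(self, nacl_table):
        """Ions essentially never stray past r3 + 2 sqrt(kT/k)."""
        from gbion import place_ions
        s = place_ions(None, {"NA": 6, "CL": 6}, radius=10.0, seed=9)
        rest = FlatBottomSphere(r3=12.0, k=20.0, anchor=np.zeros(3))
        cfg = SimConfig(n_steps=20_000, friction_ps=1.0, snapshot_stride=10,
                        seed=3, n_equil_steps=2000)
        traj = run_simulation(s, nacl_table, rest, cfg)
        r = np.linalg.norm(traj.positions, axis=2)
        slack = 2 * np.sqrt(KB * 300 / 20.0)
        frac = (r > 12.0 + slack).mean()
        assert frac < 1e-3


class TestMonteCarlo:
    def test_acceptance_approaches_one_for_tiny_steps(self):
        s = free_ions([[0, 0, 0], [5, 5, 5]])
        table = PairClassTable()
        rest = FlatBottomSphere(r3=20.0, k=20.0, anchor=np.zeros(3))
        acc = []
        for step in (4.0, 0.5, 0.05):
            t = mc_sample(s, table, rest, n_moves=2000, seed=4,
                          step_size=step)
            acc.append(t.meta["acceptance"])
        assert acc[-1] > 0.99
        assert acc[0] <= acc[1] <= acc[2] + 1e-9

    def test_requires_mobile_ions(self, nacl_table):
        s = build_system([{"position": [0, 0, 0], "species": "PHO",
                           "mobility": "fixed"}])
        with pytest.raises(SimulationError):
            mc_sample(s, nacl_table, n_moves=10)

    def test_opposite_ions_mean_separation_matches_langevin(self, nacl_table):
        recs = [{"position": [3, 0, 0], "species": "NA"},
                {"position": [-3, 0, 0], "species": "CL"}]
        s = build_system(recs)
        rest = FlatBottomSphere(r3=10.0, k=20.0, anchor=np.zeros(3))
        tl = run_simulation(s, nacl_table, rest,
                            SimConfig(n_steps=120_000, friction_ps=0.5,
                                      snapshot_stride=100, seed=1))
        tm = mc_sample(s, nacl_table, rest, n_moves=60_000, seed=2,
                       step_size=3.0)
        dl = np.linalg.norm(tl.positions[:, 0] - tl.positions[:, 1], axis=1)
        dm = np.linalg.norm(tm.positions[:, 0] - tm.positions[:, 1], axis=1)
        # 3 sigma on blocked standard errors of both estimates
        se = np.hypot(_block_se(dl), _block_se(dm))
        assert abs(dl.mean() - dm.mean()) < 3 * se


def _block_se(x, n_blocks=10):
    blocks = np.array_split(x, n_blocks)
    means = np.array([b.mean() for b in blocks])
    return means.std(ddof=1) / np.sqrt(n_blocks)


def test_minimize_reduces_energy(nacl_table, rng):
    from tests.conftest import make_random_system
    s = make_random_system(rng, 10, spread=3.0)
    from gbion.dynamics import _ForceField
    ff = _ForceField(s, nacl_table, frozen_solute=False)
    e0 = ff.evaluate(s.positions, compute_forces=False)[0].total
    x = minimize(s, nacl_table, n_steps=100, frozen_solute=False)
    e1 = ff.evaluate(x, compute_forces=False)[0].total
    assert e1 <= e0
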