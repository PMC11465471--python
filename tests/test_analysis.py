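import numpy as np
import pytest

from gbion import build_system
from gbion.analysis import (AnalysisError, IonProfile, block_profiles,
                            cylindrical_profile, ions_associated,
                            neutralization_degree, pmf_profile,
                            profile_compare, profile_window_variance,
                            radial_angle_map)
from gbion.constants import CONC_MOLAR_TO_PER_A3
from gbion.dynamics import Trajectory


def make_traj(positions, species="NA", charge=1.0, extra_records=None):
    """Trajectory with frames of identical topology from raw coordinates."""
    positions = np.asarray(positions, dtype=float)
    n = positions.shape[1]
    records = [{"position": positions[0, i], "species": species,
                "charge": charge, "mobility": "free"} for i in range(n)]
    if extra_records:
        records = extra_records + records
        pad = np.array([r["position"] for r in extra_records])
        positions = np.concatenate(
            [np.repeat(pad[None], positions.shape[0], axis=0), positions],
            axis=1)
    system = build_system(records)
    return Trajectory(positions=positions, energies=[{}] * len(positions),
                      temperatures=np.zeros(len(positions)), config=None,
                      system=system)


def uniform_cylinder_frames(rng, n_frames, n_ions, r_max, h):
    u = rng.random((n_frames, n_ions))
    r = r_max * np.sqrt(u)
    th = 2 * np.pi * rng.random((n_frames, n_ions))
    z = h * (rng.random((n_frames, n_ions)) - 0.5)
    return np.stack([r * np.cos(th), r * np.sin(th), z], axis=2)


class TestCylindricalProfile:
    def test_uniform_ions_give_flat_profile(self, rng):
        frames = uniform_cylinder_frames(rng, 1200, 120, 30.0, 40.0)
        traj = make_traj(frames)
        prof = cylindrical_profile(traj, bins=10, r_max=30.0, h=40.0)
        density = 120 / (np.pi * 30.0**2 * 40.0) / CONC_MOLAR_TO_PER_A3
        assert np.allclose(prof.conc, density, rtol=0.1)
        assert prof.c_inf == pytest.approx(density, rel=0.05)

    def test_single_fixed_ion_lands_in_its_bin(self):
        frames = np.tile(np.array([[[5.0, 0.0, 1.0]]]), (10, 1, 1))
        traj = make_traj(frames)
        prof = cylindrical_profile(traj, bins=30, r_max=30.0, h=20.0)
        idx = np.digitize(5.0, prof.bin_edges) - 1
        assert prof.conc[idx] > 0
        assert np.count_nonzero(prof.conc) == 1

    def test_count_consistency(self, rng):
        frames = uniform_cylinder_frames(rng, 50, 80, 30.0, 40.0)
        traj = make_traj(frames)
        prof = cylindrical_profile(traj, bins=15, r_max=30.0, h=40.0)
        r = np.linalg.norm(frames[..., :2], axis=2)
        in_cyl = (r < 30.0).sum() / 50
        assert prof.mean_counts() == pytest.approx(in_cyl, rel=1e-6)

    def test_empty_trajectory_rejected(self, rng):
        frames = uniform_cylinder_frames(rng, 1, 5, 20.0, 20.0)
        traj = make_traj(frames)
        traj.positions = traj.positions[:0]
        with pytest.raises(AnalysisError):
            cylindrical_profile(traj)


class TestIonsAssociated:
    def _flat_profile(self, c, n_bins=60, r_max=30.0, h=85.0):
        edges = np.linspace(0, r_max, n_bins + 1)
        return IonProfile(bin_edges=edges, conc=np.full(n_bins, c),
                          c_inf=c, h=h, species="NA", n_frames=1)

    def test_flat_profile_zero_excess(self):
        assert ions_associated(self._flat_profile(0.145)) == pytest.approx(0.0)

    def test_exponential_excess_matches_closed_form(self):
        edges = np.linspace(0, 30.0, 1200)
        r = 0.5 * (edges[:-1] + edges[1:])
        c_inf, A, lam, h = 0.145, 2.0, 4.0, 85.0
        prof = IonProfile(bin_edges=edges, conc=c_inf + A * np.exp(-r / lam),
                          c_inf=c_inf, h=h, species="NA", n_frames=1)
        r_max = 28.0
        # closed form of ∫ A e^{-r/lam} 2 pi r h dr from 0 to r_max
        integral = A * 2 * np.pi * h * lam * (
            lam - np.exp(-r_max / lam) * (r_max + lam))
        expected = integral * CONC_MOLAR_TO_PER_A3
        assert ions_associated(prof, r_max=r_max) == pytest.approx(
            expected, rel=1e-3)

    def test_flat_shell_recovered_exactly(self):
        edges = np.linspace(0, 30.0, 31)
        conc = np.full(30, 0.1)
        conc[8:12] += 0.75  # excess shell aligned with bins
        prof = IonProfile(bin_edges=edges, conc=conc, c_inf=0.1, h=50.0,
                          species="NA", n_frames=1)
        shell_vol = np.pi * (edges[12]**2 - edges[8]**2) * 50.0
        expected = 0.75 * CONC_MOLAR_TO_PER_A3 * shell_vol
        assert ions_associated(prof) == pytest.approx(expected, rel=1e-12)

    def test_linearity_in_excess(self):
        edges = np.linspace(0, 30.0, 61)
        r = 0.5 * (edges[:-1] + edges[1:])
        base = 0.145
        e1 = 0.3 * np.exp(-r / 5.0)
        e2 = 0.1 * np.exp(-((r - 10) / 3.0) ** 2)
        mk = lambda e: IonProfile(bin_edges=edges, conc=base + e, c_inf=base,
                                  h=85.0, species="NA", n_frames=1)
        assert ions_associated(mk(e1 + e2)) == pytest.approx(
            ions_associated(mk(e1)) + ions_associated(mk(e2)), rel=1e-9)

    def test_nonpositive_bulk_rejected(self):
        prof = self._flat_profile(0.0)
        with pytest.raises(AnalysisError):
            ions_associated(prof)


class TestNeutralization:
    def test_exactly_neutralizing_shell(self):
        solute = [{"position": [0, 0, z], "charge": -1.0,
                   "topo_class": "solute", "rho": 2.0, "mobility": "fixed"}
                  for z in (-3.0, 0.0, 3.0)]
        ion_frames = np.array([[[4.0, 0, 0], [0, 4.0, 0], [-4.0, 0, 0]]])
        traj = make_traj(ion_frames, extra_records=solute)
        out = neutralization_degree(traj, cutoff_r=16.0, h=20.0)
        assert out["percent"] == pytest.approx(100.0)

    def test_no_ions_inside_gives_zero(self):
        solute = [{"position": [0, 0, 0], "charge": -2.0,
                   "topo_class": "solute", "rho": 2.0, "mobility": "fixed"}]
        ion_frames = np.array([[[25.0, 0, 0]]])
        traj = make_traj(ion_frames, extra_records=solute)
        out = neutralization_degree(traj, cutoff_r=16.0, h=20.0)
        assert out["percent"] == 0.0


class TestPmf:
    def test_bulk_is_zero(self):
        edges = np.linspace(0, 30, 31)
        prof = IonProfile(edges, np.full(30, 0.2), 0.2, 85.0, "NA", 1)
        assert np.allclose(pmf_profile(prof), 0.0)

    def test_enrichment_ratio(self):
        edges = np.linspace(0, 30, 31)
        conc = np.full(30, 0.2)
        conc[5] = 0.32  # 1.6 x bulk
        prof = IonProfile(edges, conc, 0.2, 85.0, "NA", 1)
        w = pmf_profile(prof)
        assert w[5] == pytest.approx(-np.log(1.6), abs=1e-12)
        assert w[5] == pytest.approx(-0.470, abs=1e-3)

    def test_zero_bins_masked(self):
        edges = np.linspace(0, 30, 31)
        conc = np.full(30, 0.2)
        conc[0] = 0.0
        prof = IonProfile(edges, conc, 0.2, 85.0, "NA", 1)
        assert np.isnan(pmf_profile(prof)[0])


class TestProfileCompare:
    def _peaked(self, scale=1.0):
        edges = np.linspace(0, 30, 61)
        r = 0.5 * (edges[:-1] + edges[1:])
        # excess confined to (5, 13) so the peak region is well defined
        excess = np.where(np.abs(r - 9) < 4,
                          4.0 * np.exp(-((r - 9) / 2.5) ** 2), 0.0)
        conc = 0.145 * (1 + excess)
        # scale the whole profile inside the peak region
        conc = np.where(excess > 0, conc * scale, conc)
        return IonProfile(edges, conc, 0.145, 85.0, "NA", 1)

    def test_identical_profiles(self):
        a = self._peaked()
        out = profile_compare(a, a)
        assert out["max_dW_kT"] == 0.0
        assert out["peak_area_ratio"] == pytest.approx(1.0)

    def test_scaled_peak_region_ratio(self):
        a, b = self._peaked(scale=1.62), self._peaked(scale=1.0)
        out = profile_compare(a, b)
        assert out["peak_area_ratio"] == pytest.approx(1.62, rel=1e-6)
        assert out["max_dW_kT"] == pytest.approx(np.log(1.62), abs=1e-9)

    def test_mismatched_bins_rejected(self):
        a = self._peaked()
        edges = np.linspace(0, 30, 31)
        b = IonProfile(edges, np.full(30, 0.1), 0.1, 85.0, "NA", 1)
        with pytest.raises(AnalysisError):
            profile_compare(a, b)

    def test_disjoint_support_rejected(self):
        edges = np.linspace(0, 30, 31)
        ca, cb = np.zeros(30), np.zeros(30)
        ca[:10], cb[20:] = 0.2, 0.2
        a = IonProfile(edges, ca, 0.2, 85.0, "NA", 1)
        b = IonProfile(edges, cb, 0.2, 85.0, "NA", 1)
        with pytest.raises(AnalysisError):
            profile_compare(a, b)


class TestRadialAngleMap:
    def test_marginalizes_to_radial_histogram(self, rng):
        frames = uniform_cylinder_frames(rng, 40, 60, 30.0, 40.0)
        traj = make_traj(frames)
        m = radial_angle_map(traj, r_bins=12, r_max=30.0, angle_bins=24,
                             h=40.0)
        prof = cylindrical_profile(traj, bins=12, r_max=30.0, h=40.0)
        radial_counts = (prof.conc * CONC_MOLAR_TO_PER_A3
                         * prof.annulus_volumes)
        assert np.allclose(m["counts"].sum(axis=1), radial_counts)

    def test_uniform_ions_give_flat_angular_density(self, rng):
        frames = uniform_cylinder_frames(rng, 800, 100, 20.0, 30.0)
        traj = make_traj(frames)
        m = radial_angle_map(traj, r_bins=4, r_max=20.0, angle_bins=8, h=30.0)
        dens = m["density"]
        assert dens.std() / dens.mean() < 0.15

    def test_single_sector_mode(self):
        # ions pinned at one azimuth, zero axial coordinate
        frames = np.tile(np.array([[[7.0, 0.0, 0.0]]]), (5, 1, 1))
        traj = make_traj(frames)
        m = radial_angle_map(traj, r_bins=4, r_max=20.0, angle_bins=12,
                             h=20.0)
        assert np.count_nonzero(m["counts"]) == 1


class TestConvergence:
    def test_window_variance_decreases(self, rng):
        frames = uniform_cylinder_frames(rng, 600, 60, 30.0, 40.0)
        traj = make_traj(frames)
        var = profile_window_variance(traj, (5, 30, 150), bins=10,
                                      r_max=30.0, h=40.0)
        assert var[5] > var[30] > var[150]

    def test_block_profiles_partition_frames(self, rng):
        frames = uniform_cylinder_frames(rng, 90, 20, 20.0, 30.0)
        traj = make_traj(frames)
        profs = block_profiles(traj, 3, bins=10, r_max=20.0, h=30.0)
        assert len(profs) == 3
        assert all(p.n_frames == 30 for p in profs)
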