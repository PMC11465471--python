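"""Langevin dynamics of explicit ions and a Metropolis MC equilibrium oracle.

Ions move under the pair-class GB forces inside a flat-bottom confining
sphere; the solute is either fixed or positionally restrained (no free
solute dynamics). Integration uses the BAOAB splitting of Langevin
dynamics, which samples configuration space accurately at practical time
steps. The Monte Carlo sampler targets the same energy function by
single-ion displacement moves and serves as an independent equilibrium
reference for validating the integrator.

Units: positions Å, velocities Å/fs, masses amu, energies kcal/mol.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .born import effective_radii
from .constants import ACC_CONV, DEFAULT_TEMPERATURE, KB
from .energy import total_energy_forces
from .params import PairClassTable
from .restraints import PositionRestraint
from .system import ParticleSystem

#: Simulations halt if |total energy| exceeds this (kcal/mol).
ENERGY_BLOWUP = 1.0e8


class SimulationError(RuntimeError):
    def __init__(self, message: str, last_positions: np.ndarray | None = None,
                 step: int | None = None):
        super().__init__(message)
        self.last_positions = last_positions
        self.step = step


@dataclass
class SimConfig:
    """Simulation settings.

    ``friction_ps`` is the Langevin collision frequency in ps^-1; 0.05 is
    the gentle-thermostat value used for heating/equilibration, while
    sampling runs default to 1.0 for faster diffusive decorrelation.
    ``solute_restraint_k`` tethers 'restrained' solute particles to their
    reference positions (kcal/mol/Å^2).
    """

    temperature: float = DEFAULT_TEMPERATURE
    dt_fs: float = 2.0
    friction_ps: float = 1.0
    n_steps: int = 10_000
    seed: int = 0
    snapshot_stride: int = 100
    solute_restraint_k: float = 0.01
    frozen_solute: bool = True
    n_heat_steps: int = 0
    n_equil_steps: int = 0

    def __post_init__(self) -> None:
        if self.dt_fs <= 0:
            raise ValueError("time step must be positive")
        if self.friction_ps < 0:
            raise ValueError("friction must be non-negative")


@dataclass
class Trajectory:
    """Snapshots plus per-frame energies and the provenance of the run."""

    positions: np.ndarray            # (n_frames, N, 3)
    energies: list                   # per-frame EnergyBreakdown dicts
    temperatures: np.ndarray         # instantaneous kinetic T per frame
    config: SimConfig | None
    system: ParticleSystem
    seed: int = 0
    meta: dict = field(default_factory=dict)

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]


class _ForceField:
    """Cached force/energy evaluator for a fixed topology.

    Uses the compiled pair-loop kernels when numba is importable and
    falls back to the vectorized reference implementation otherwise;
    both paths compute the same model (pinned by a unit test).
    """

    def __init__(self, system: ParticleSystem, table: PairClassTable,
                 restraints=None, frozen_solute: bool = True):
        from . import _kernels
        self.system = system
        self.table = table
        self.restraints = list(restraints) if isinstance(
            restraints, (list, tuple)) else ([restraints] if restraints else [])
        self.frozen_solute = frozen_solute
        self._use_kernels = _kernels.HAVE_NUMBA
        self._k = _kernels
        self._solute = np.ascontiguousarray(system.solute_mask)
        self._code = np.ascontiguousarray(system.topo_code, dtype=np.int64)

    def evaluate(self, positions: np.ndarray, compute_forces: bool = True):
        from .energy import EnergyBreakdown
        from .constants import KE_COULOMB
        s = self.system
        if self._use_kernels:
            pos = np.ascontiguousarray(positions, dtype=float)
            radii, dI, live = self._k.radii_kernel(
                pos, s.radii, self._solute, self.frozen_solute)
            ec, ex, es, elj, forces = self._k.energy_forces_kernel(
                pos, s.charges, s.radii, radii, dI, live, s.lj_sigma,
                s.lj_eps, self._code, self.table.gamma, self.table.eps_in,
                self.table.eps_out, KE_COULOMB, compute_forces)
            er = 0.0
            fr = np.zeros_like(pos)
            for item in self.restraints:
                e_i, f_i = item.energy_forces(s, positions=pos)
                er += e_i
                fr += f_i
            bd = EnergyBreakdown(coulomb=float(ec), gb_cross=float(ex),
                                 gb_self=float(es), lj=float(elj),
                                 restraint=float(er))
            return bd, (forces + fr) if compute_forces else None
        sys_at = s.with_positions(positions)
        radii = effective_radii(sys_at, frozen_solute=self.frozen_solute)
        return total_energy_forces(sys_at, radii, self.table,
                                   restraints=self.restraints,
                                   compute_forces=compute_forces)


def kinetic_temperature(velocities: np.ndarray, masses: np.ndarray,
                        mobile: np.ndarray) -> float:
    """Instantaneous kinetic temperature of the mobile particles, K."""
    n_dof = 3 * int(mobile.sum())
    if n_dof == 0:
        return 0.0
    ke = 0.5 * (masses[mobile, None] * velocities[mobile] ** 2).sum() / ACC_CONV
    return 2.0 * ke / (n_dof * KB)


def langevin_step(positions, velocities, forces, masses, mobile,
                  dt_fs: float, friction_ps: float, temperature: float,
                  rng: np.random.Generator, force_field: _ForceField):
    """One BAOAB step; returns (positions, velocities, forces, breakdown).

    Fixed particles do not move. Deterministic for a given generator
    state. Halts with :class:`SimulationError` on non-finite forces.
    """
    if not np.isfinite(forces[mobile]).all():
        raise SimulationError("non-finite force encountered",
                              last_positions=positions)
    m = masses[:, None]
    inv_m = np.where(m > 0, 1.0 / m, 0.0)
    dt = dt_fs
    # B: half kick
    v = velocities + np.where(mobile[:, None],
                              0.5 * dt * forces * ACC_CONV * inv_m, 0.0)
    # A: half drift
    x = positions + np.where(mobile[:, None], 0.5 * dt * v, 0.0)
    # O: Ornstein-Uhlenbeck
    zeta = friction_ps * 1e-3           # ps^-1 -> fs^-1
    c1 = math.exp(-zeta * dt)
    c2 = math.sqrt(max(0.0, 1.0 - c1 * c1))
    sigma_v = np.sqrt(KB * temperature * ACC_CONV * inv_m)
    noise = rng.standard_normal(size=positions.shape)
    v = np.where(mobile[:, None], c1 * v + c2 * sigma_v * noise, 0.0)
    # A: half drift
    x = x + np.where(mobile[:, None], 0.5 * dt * v, 0.0)
    # force at new positions, then B: half kick
    breakdown, forces_new = force_field.evaluate(x)
    if not math.isfinite(breakdown.total) or abs(breakdown.total) > ENERGY_BLOWUP:
        raise SimulationError(
            f"energy blow-up ({breakdown.total:.3g} kcal/mol)",
            last_positions=positions)
    v = v + np.where(mobile[:, None],
                     0.5 * dt * forces_new * ACC_CONV * inv_m, 0.0)
    return x, v, forces_new, breakdown


def minimize(system: ParticleSystem, table: PairClassTable, restraints=None,
             n_steps: int = 200, step0: float = 0.1,
             frozen_solute: bool = True) -> np.ndarray:
    """Crude steepest-descent relaxation of mobile particles.

    Used to remove bad contacts from randomly placed ions before
    dynamics; returns the relaxed coordinates.
    """
    ff = _ForceField(system, table, restraints, frozen_solute)
    x = system.positions.copy()
    mobile = system.mobile_mask
    step = step0
    e_prev, f = ff.evaluate(x)
    for _ in range(n_steps):
        fmax = np.abs(f[mobile]).max() if mobile.any() else 0.0
        if fmax < 1e-3:
            break
        trial = x + np.where(mobile[:, None], step * f / max(fmax, 1e-12), 0.0)
        e_trial, f_trial = ff.evaluate(trial)
        if e_trial.total < e_prev.total:
            x, f, e_prev = trial, f_trial, e_trial
            step = min(step * 1.2, 1.0)
        else:
            step *= 0.5
            if step < 1e-6:
                break
    return x


def run_simulation(system: ParticleSystem, table: PairClassTable,
                   restraints=None, config: SimConfig | None = None,
                   velocities: np.ndarray | None = None) -> Trajectory:
    """Langevin dynamics with optional heat/equilibration staging.

    The solute positional restraint is added automatically for particles
    marked ``restrained``. Snapshots (positions, energy breakdown,
    kinetic temperature) are recorded every ``snapshot_stride`` steps of
    the production phase.
    """
    config = config or SimConfig()
    rng = np.random.default_rng(config.seed)
    items = restraints if isinstance(restraints, (list, tuple)) else (
        [restraints] if restraints is not None else [])
    if any(m == "restrained" for m in system.mobility):
        items = list(items) + [PositionRestraint(k=config.solute_restraint_k)]
    ff = _ForceField(system, table, items, config.frozen_solute)

    x = system.positions.copy()
    masses = system.masses
    mobile = system.mobile_mask
    if velocities is None:
        v = np.zeros_like(x)
        if config.n_heat_steps == 0:
            sigma = np.sqrt(KB * config.temperature * ACC_CONV
                            / np.maximum(masses, 1e-12))[:, None]
            v = np.where(mobile[:, None],
                         sigma * rng.standard_normal(size=x.shape), 0.0)
    else:
        v = np.array(velocities, dtype=float)
    _, f = ff.evaluate(x)

    # heating: linear temperature ramp from 0
    for step in range(config.n_heat_steps):
        t_target = config.temperature * (step + 1) / config.n_heat_steps
        x, v, f, _ = langevin_step(x, v, f, masses, mobile, config.dt_fs,
                                   config.friction_ps, t_target, rng, ff)
    for _ in range(config.n_equil_steps):
        x, v, f, _ = langevin_step(x, v, f, masses, mobile, config.dt_fs,
                                   config.friction_ps, config.temperature,
                                   rng, ff)

    frames, energies, temps = [], [], []
    for step in range(config.n_steps):
        x, v, f, bd = langevin_step(x, v, f, masses, mobile, config.dt_fs,
                                    config.friction_ps, config.temperature,
                                    rng, ff)
        if (step + 1) % config.snapshot_stride == 0:
            frames.append(x.copy())
            energies.append(bd.as_dict())
            temps.append(kinetic_temperature(v, masses, mobile))
    if not frames:
        frames.append(x.copy())
        bd, _ = ff.evaluate(x, compute_forces=False)
        energies.append(bd.as_dict())
        temps.append(kinetic_temperature(v, masses, mobile))
    return Trajectory(positions=np.array(frames), energies=energies,
                      temperatures=np.array(temps), config=config,
                      system=system, seed=config.seed,
                      meta={"restraints": [repr(r) for r in items]})


def mc_sample(system: ParticleSystem, table: PairClassTable,
              restraints=None, temperature: float = DEFAULT_TEMPERATURE,
              n_moves: int = 10_000, seed: int = 0,
              step_size: float = 2.0, sample_stride: int | None = None,
              frozen_solute: bool = True) -> Trajectory:
    """Metropolis sampling of the same energy surface (equilibrium oracle).

    Single-ion spherical-Gaussian displacement moves; the acceptance test
    uses the full energy difference with effective radii recomputed for
    every proposal, so detailed balance holds for the exact model energy.
    Only mobile ions move. Returns a :class:`Trajectory` whose frames are
    decorrelated samples (one every ``sample_stride`` moves, default one
    sweep over the mobile ions).
    """
    rng = np.random.default_rng(seed)
    ff = _ForceField(system, table, restraints, frozen_solute)
    movable = np.flatnonzero(system.mobile_mask & system.ion_mask)
    if movable.size == 0:
        raise SimulationError("no mobile ions to sample")
    if sample_stride is None:
        sample_stride = movable.size
    beta = 1.0 / (KB * temperature)
    x = system.positions.copy()
    e_curr = ff.evaluate(x, compute_forces=False)[0].total
    frames, energies, accepted = [], [], 0
    for move in range(n_moves):
        i = movable[rng.integers(movable.size)]
        trial = x.copy()
        trial[i] += step_size * rng.standard_normal(3)
        e_trial = ff.evaluate(trial, compute_forces=False)[0].total
        if math.isfinite(e_trial) and (
                e_trial <= e_curr
                or rng.random() < math.exp(-beta * (e_trial - e_curr))):
            x, e_curr = trial, e_trial
            accepted += 1
        if (move + 1) % sample_stride == 0:
            frames.append(x.copy())
            energies.append({"total_kcal": e_curr})
    if not frames:
        frames.append(x.copy())
        energies.append({"total_kcal": e_curr})
    traj = Trajectory(positions=np.array(frames), energies=energies,
                      temperatures=np.full(len(frames), temperature),
                      config=None, system=system, seed=seed,
                      meta={"sampler": "metropolis-mc",
                            "acceptance": accepted / max(n_moves, 1),
                            "step_size": step_size})
    return traj
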