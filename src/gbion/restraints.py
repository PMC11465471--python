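"""Restraints: the flat-bottom confining sphere and solute position tethers.

A non-periodic implicit-solvent run has no box; without confinement the
ions would evaporate (entropy always wins in an infinite volume). The
flat-bottom restraint is zero inside radius ``r3`` of an anchor point and
harmonic, k(r - r3)^2, beyond it, so the sphere of radius r3 defines the
simulation volume while leaving the interior physics untouched. The
anchor is a particle, the center of mass of a particle group, or a fixed
point.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .system import ParticleSystem


def flat_bottom_energy_force(r, r3: float, k: float):
    """Energy (kcal/mol) and radial force magnitude at distance r.

    U = 0 for r <= r3 and k (r - r3)^2 beyond; both U and dU/dr are
    continuous at r3. The returned force is -dU/dr (negative = inward).
    """
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("distance must be non-negative")
    excess = np.maximum(0.0, r - r3)
    return k * excess**2, -2.0 * k * excess


@dataclass
class FlatBottomSphere:
    """Flat-bottom spherical restraint on a selection of particles.

    ``anchor`` is a particle index (int), an index sequence (center of
    mass, recomputed every step), or an explicit 3-vector. ``applies_to``
    is a boolean mask or ``"ions"`` (default).
    """

    r3: float
    k: float = 20.0                 # kcal/mol/Å^2
    anchor: int | Sequence[int] | np.ndarray = field(default_factory=lambda: np.zeros(3))
    applies_to: str | np.ndarray = "ions"

    def __post_init__(self) -> None:
        if self.r3 <= 0:
            raise ValueError("r3 must be positive")
        if self.k < 0:
            raise ValueError("k must be non-negative")

    def anchor_point(self, system: ParticleSystem,
                     positions: np.ndarray | None = None) -> np.ndarray:
        pos = system.positions if positions is None else positions
        if isinstance(self.anchor, (int, np.integer)):
            return pos[int(self.anchor)]
        anchor = np.asarray(self.anchor)
        if anchor.ndim == 1 and anchor.shape == (3,) and anchor.dtype.kind == "f":
            return anchor
        idx = np.asarray(self.anchor, dtype=int)
        w = system.masses[idx]
        return (pos[idx] * w[:, None]).sum(0) / w.sum()

    def selection(self, system: ParticleSystem) -> np.ndarray:
        if isinstance(self.applies_to, str):
            if self.applies_to == "ions":
                return system.ion_mask
            if self.applies_to == "all":
                return np.ones(system.n_particles, dtype=bool)
            raise ValueError(f"unknown selection {self.applies_to!r}")
        return np.asarray(self.applies_to, dtype=bool)

    def energy_forces(self, system: ParticleSystem,
                      positions: np.ndarray | None = None):
        pos = system.positions if positions is None else positions
        center = self.anchor_point(system, pos)
        sel = self.selection(system)
        forces = np.zeros_like(pos)
        if not sel.any():
            return 0.0, forces
        rel = pos[sel] - center
        r = np.linalg.norm(rel, axis=1)
        u, fmag = flat_bottom_energy_force(r, self.r3, self.k)
        rsafe = np.where(r == 0, 1.0, r)
        forces[sel] = fmag[:, None] * rel / rsafe[:, None]
        return float(u.sum()), forces


@dataclass
class PositionRestraint:
    """Harmonic tether of selected particles to reference positions.

    U = k * |x - x_ref|^2 per particle (AMBER-style restraint_wt
    convention). Applies to particles with mobility == 'restrained' by
    default.
    """

    k: float = 0.01                  # kcal/mol/Å^2
    applies_to: np.ndarray | None = None

    def energy_forces(self, system: ParticleSystem,
                      positions: np.ndarray | None = None):
        if system.reference_positions is None:
            raise ValueError("system has no reference positions")
        pos = system.positions if positions is None else positions
        if self.applies_to is None:
            sel = np.asarray([m == "restrained" for m in system.mobility])
        else:
            sel = np.asarray(self.applies_to, dtype=bool)
        forces = np.zeros_like(pos)
        if not sel.any():
            return 0.0, forces
        disp = pos[sel] - system.reference_positions[sel]
        forces[sel] = -2.0 * self.k * disp
        return float(self.k * (disp**2).sum()), forces
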