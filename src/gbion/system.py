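"""Particle systems: coordinates, charges, radii, topology classes.

The model distinguishes exactly three interaction topology classes —
``solute``, ``cation`` and ``anion`` — because the pairwise electrostatic
form depends on whether a pair is solute–solute, solute–ion or ion–ion.
Per-species detail (Na vs K, CoHex, ...) enters only through the species
parameter tables layered on top of the class machinery.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

TOPO_CLASSES = ("solute", "cation", "anion")
SOLUTE, CATION, ANION = 0, 1, 2
_CLASS_CODE = {name: i for i, name in enumerate(TOPO_CLASSES)}

MOBILITIES = ("fixed", "restrained", "free")


@dataclass(frozen=True)
class Species:
    """Per-species bead parameters.

    ``rho`` is the intrinsic (cavity) Born radius in Å; ``sigma``/``eps``
    are 12-6 Lennard-Jones parameters (Å, kcal/mol); ``mass`` in amu.
    """

    name: str
    charge: float
    topo_class: str
    rho: float
    sigma: float
    eps: float
    mass: float


# Default bead parameters. Intrinsic radii follow the sigma/2 convention
# for ions; values are literature-style stand-ins, overridable per particle.
SPECIES_TABLE: dict[str, Species] = {
    "NA": Species("NA", +1.0, "cation", 1.87, 3.74, 0.10, 22.99),
    "K": Species("K", +1.0, "cation", 2.26, 4.52, 0.10, 39.10),
    "CL": Species("CL", -1.0, "anion", 2.47, 4.94, 0.10, 35.45),
    # Cobalt hexammine modelled as one rigid +3e sphere.
    "COHEX": Species("COHEX", +3.0, "cation", 3.10, 6.20, 0.20, 161.1),
    # Coarse phosphate pseudo-atom of the B-DNA fixture.
    "PHO": Species("PHO", -1.0, "solute", 2.00, 4.00, 0.20, 94.97),
}

#: Minimal mbondi3-like intrinsic radii for all-atom PDB input, Å.
ELEMENT_RADII: dict[str, float] = {
    "H": 1.30,
    "C": 1.70,
    "N": 1.55,
    "O": 1.50,
    "P": 1.85,
    "S": 1.80,
}


class SystemError(ValueError):
    """Raised when particle records violate the system invariants."""


@dataclass
class ParticleSystem:
    """A validated collection of particles.

    Arrays are indexed by particle. ``topo_code`` holds integer codes
    (0 solute, 1 cation, 2 anion); ``mobility`` is one of ``fixed``,
    ``restrained`` or ``free`` per particle.
    """

    positions: np.ndarray          # (N, 3) Å
    charges: np.ndarray            # (N,) e
    radii: np.ndarray              # (N,) intrinsic Born radii, Å
    lj_sigma: np.ndarray           # (N,) Å
    lj_eps: np.ndarray             # (N,) kcal/mol
    topo_code: np.ndarray          # (N,) int
    species: np.ndarray            # (N,) str
    mobility: np.ndarray           # (N,) str
    masses: np.ndarray             # (N,) amu
    reference_positions: np.ndarray | None = None  # for positional restraints
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        n = self.positions.shape[0]
        for name in ("charges", "radii", "lj_sigma", "lj_eps", "masses"):
            arr = np.asarray(getattr(self, name), dtype=float).ravel()
            if arr.shape != (n,):
                raise SystemError(f"{name} has shape {arr.shape}, expected ({n},)")
            setattr(self, name, arr)
        self.topo_code = np.asarray(self.topo_code, dtype=int).ravel()
        self.species = np.asarray(self.species, dtype=object).ravel()
        self.mobility = np.asarray(self.mobility, dtype=object).ravel()
        _validate(self)

    # -- basic queries -------------------------------------------------
    @property
    def n_particles(self) -> int:
        return self.positions.shape[0]

    @property
    def net_charge(self) -> float:
        return float(self.charges.sum())

    def class_counts(self) -> dict[str, int]:
        return {
            name: int(np.count_nonzero(self.topo_code == code))
            for name, code in _CLASS_CODE.items()
        }

    @property
    def mobile_mask(self) -> np.ndarray:
        """Particles that move during dynamics (free or restrained)."""
        return np.asarray([m != "fixed" for m in self.mobility], dtype=bool)

    @property
    def ion_mask(self) -> np.ndarray:
        return self.topo_code != SOLUTE

    @property
    def solute_mask(self) -> np.ndarray:
        return self.topo_code == SOLUTE

    def select_species(self, name: str) -> np.ndarray:
        return np.asarray([s == name for s in self.species], dtype=bool)

    def with_positions(self, positions: np.ndarray) -> "ParticleSystem":
        """Copy of the system at new coordinates (topology shared)."""
        new = ParticleSystem(
            positions=np.array(positions, dtype=float),
            charges=self.charges,
            radii=self.radii,
            lj_sigma=self.lj_sigma,
            lj_eps=self.lj_eps,
            topo_code=self.topo_code,
            species=self.species,
            mobility=self.mobility,
            masses=self.masses,
            reference_positions=self.reference_positions,
            meta=dict(self.meta),
        )
        return new


def _validate(system: ParticleSystem) -> None:
    if system.n_particles < 1:
        raise SystemError("a system needs at least one particle")
    bad = np.flatnonzero(~np.isfinite(system.positions).all(axis=1))
    if bad.size:
        raise SystemError(f"non-finite coordinate at particle index {bad[0]}")
    bad = np.flatnonzero(system.radii <= 0)
    if bad.size:
        raise SystemError(f"non-positive intrinsic radius at particle index {bad[0]}")
    bad = np.flatnonzero(system.lj_sigma <= 0)
    if bad.size:
        raise SystemError(f"non-positive LJ sigma at particle index {bad[0]}")
    bad = np.flatnonzero(
        (system.topo_code < 0) | (system.topo_code >= len(TOPO_CLASSES))
    )
    if bad.size:
        raise SystemError(f"unknown topology class at particle index {bad[0]}")
    for i, m in enumerate(system.mobility):
        if m not in MOBILITIES:
            raise SystemError(f"unknown mobility {m!r} at particle index {i}")


def build_system(
    records: Iterable[Mapping],
    *,
    reference_positions: bool = True,
) -> ParticleSystem:
    """Assemble and validate a :class:`ParticleSystem` from plain records.

    Each record needs ``position`` and either a ``species`` key found in
    :data:`SPECIES_TABLE` or explicit ``charge``/``topo_class``/``rho``
    (plus optional ``sigma``, ``eps``, ``mass``, ``mobility``) fields.
    Explicit fields override the species defaults.
    """

    recs = list(records)
    cols: dict[str, list] = {k: [] for k in (
        "positions", "charges", "radii", "lj_sigma", "lj_eps",
        "topo_code", "species", "mobility", "masses")}
    for idx, rec in enumerate(recs):
        sp = SPECIES_TABLE.get(str(rec.get("species", "")).upper())
        try:
            charge = float(rec.get("charge", sp.charge if sp else np.nan))
            topo = str(rec.get("topo_class", sp.topo_class if sp else ""))
            rho = float(rec.get("rho", sp.rho if sp else np.nan))
            sigma = float(rec.get("sigma", sp.sigma if sp else 2 * rho))
            eps = float(rec.get("eps", sp.eps if sp else 0.1))
            mass = float(rec.get("mass", sp.mass if sp else 1.0))
        except (TypeError, AttributeError) as exc:
            raise SystemError(f"record {idx}: missing parameters and no "
                              f"known species ({exc})") from exc
        if topo not in _CLASS_CODE:
            raise SystemError(f"record {idx}: unknown topology class {topo!r}")
        cols["positions"].append(np.asarray(rec["position"], dtype=float))
        cols["charges"].append(charge)
        cols["radii"].append(rho)
        cols["lj_sigma"].append(sigma)
        cols["lj_eps"].append(eps)
        cols["topo_code"].append(_CLASS_CODE[topo])
        cols["species"].append(str(rec.get("species", topo)).upper())
        cols["mobility"].append(str(rec.get("mobility", "free" if topo != "solute" else "fixed")))
        cols["masses"].append(mass)
    if not recs:
        raise SystemError("no particle records given")
    system = ParticleSystem(
        positions=np.array(cols["positions"]),
        charges=np.array(cols["charges"]),
        radii=np.array(cols["radii"]),
        lj_sigma=np.array(cols["lj_sigma"]),
        lj_eps=np.array(cols["lj_eps"]),
        topo_code=np.array(cols["topo_code"]),
        species=np.array(cols["species"], dtype=object),
        mobility=np.array(cols["mobility"], dtype=object),
        masses=np.array(cols["masses"]),
    )
    if reference_positions:
        system.reference_positions = system.positions.copy()
    return system


def merge_systems(a: ParticleSystem, b: ParticleSystem) -> ParticleSystem:
    """Concatenate two systems into one."""
    merged = ParticleSystem(
        positions=np.vstack([a.positions, b.positions]),
        charges=np.concatenate([a.charges, b.charges]),
        radii=np.concatenate([a.radii, b.radii]),
        lj_sigma=np.concatenate([a.lj_sigma, b.lj_sigma]),
        lj_eps=np.concatenate([a.lj_eps, b.lj_eps]),
        topo_code=np.concatenate([a.topo_code, b.topo_code]),
        species=np.concatenate([a.species, b.species]),
        mobility=np.concatenate([a.mobility, b.mobility]),
        masses=np.concatenate([a.masses, b.masses]),
        meta={**a.meta, **b.meta},
    )
    refs = []
    for s in (a, b):
        refs.append(s.reference_positions if s.reference_positions is not None
                    else s.positions)
    merged.reference_positions = np.vstack(refs)
    return merged
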