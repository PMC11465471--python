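"""Synthetic test systems: an idealized B-DNA phosphate lattice and ions.

The solute stand-in is a phosphate-only double helix: one -1e pseudo-bead
per phosphate on two strands of an ideal B-form helix (radius 8.9 Å,
rise 3.4 Å/bp, twist 36°/bp, strands offset by 154° so the minor groove
is narrower than the major). With the 5' terminus of each strand
uncharged there are n_bp - 1 phosphates per strand, giving net charge
-2(n_bp - 1)e — the -48e of a 25-bp duplex and -22e of a dodecamer.
This keeps exactly the electrostatics the ion model acts on while
avoiding any force-field dependency.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import PairClassTable, load_preset
from .system import SPECIES_TABLE, ParticleSystem, Species, build_system, merge_systems

#: shipped ion presets and the species they parameterize
PRESET_SPECIES = {
    "NaCl-DNA": ("NA", "CL"),
    "KCl-DNA": ("K", "CL"),
    "CoHex-DNA": ("COHEX", None),
}


class FixtureError(ValueError):
    pass


@dataclass
class BDnaModel:
    """Geometry of the idealized phosphate-lattice duplex."""

    n_bp: int
    helix_radius: float = 8.9        # Å, phosphate strand radius
    rise: float = 3.4                # Å per bp
    twist_deg: float = 36.0          # per bp
    strand_offset_deg: float = 154.0 # minor-groove convention
    rho: float = 2.0                 # pseudo-phosphate intrinsic radius
    sigma: float = 4.0
    eps: float = 0.2
    mass: float = 94.97

    def __post_init__(self) -> None:
        if self.n_bp < 2:
            raise FixtureError("need at least 2 base pairs")

    @property
    def length(self) -> float:
        """Nominal axial length of the duplex, Å (n_bp × rise)."""
        return self.n_bp * self.rise

    @property
    def total_charge(self) -> float:
        return -2.0 * (self.n_bp - 1)

    def phosphate_positions(self) -> np.ndarray:
        """Phosphate coordinates, helix axis along z, centered at z=0."""
        i = np.arange(1, self.n_bp)          # 5' phosphate absent
        z = (i - (self.n_bp - 1) / 2.0) * self.rise
        ang1 = np.radians(self.twist_deg * i)
        ang2 = np.radians(self.twist_deg * i + self.strand_offset_deg)
        r = self.helix_radius
        strand1 = np.stack([r * np.cos(ang1), r * np.sin(ang1), z], axis=1)
        strand2 = np.stack([r * np.cos(ang2), r * np.sin(ang2), z], axis=1)
        return np.vstack([strand1, strand2])

    def build(self) -> ParticleSystem:
        pos = self.phosphate_positions()
        records = [{
            "position": p, "species": "PHO", "charge": -1.0,
            "topo_class": "solute", "rho": self.rho, "sigma": self.sigma,
            "eps": self.eps, "mass": self.mass, "mobility": "fixed",
        } for p in pos]
        system = build_system(records)
        system.meta.update({"fixture": "bdna", "n_bp": self.n_bp,
                            "length": self.length})
        return system


def build_bdna(n_bp: int, **overrides) -> ParticleSystem:
    """Phosphate-only B-form duplex as a fixed solute."""
    return BDnaModel(n_bp=n_bp, **overrides).build()


def place_ions(system: ParticleSystem | None, species_counts: dict,
               center=(0.0, 0.0, 0.0), radius: float = 40.0,
               seed: int = 0, min_dist: float = 2.5,
               max_tries: int = 10_000) -> ParticleSystem:
    """Add ions uniformly at random inside a sphere, rejecting overlaps.

    ``species_counts`` maps species names from the species table (NA, K,
    CL, COHEX, ...) to counts. Placement is deterministic per seed; a
    packing failure after ``max_tries`` rejections per ion is an error.
    """
    rng = np.random.default_rng(seed)
    center = np.asarray(center, dtype=float)
    existing = [] if system is None else [system.positions]
    records = []
    placed: list[np.ndarray] = []
    for name, count in species_counts.items():
        if count < 0:
            raise FixtureError("ion counts must be non-negative")
        if name.upper() not in SPECIES_TABLE:
            raise FixtureError(f"unknown ion species {name!r}")
        for _ in range(int(count)):
            for attempt in range(max_tries):
                u = rng.standard_normal(3)
                u /= np.linalg.norm(u)
                r = radius * rng.random() ** (1.0 / 3.0)
                pos = center + r * u
                pool = existing + [np.array(placed)] if placed else existing
                ok = True
                for arr in pool:
                    if arr.size and np.min(
                            np.linalg.norm(arr - pos, axis=1)) < min_dist:
                        ok = False
                        break
                if ok:
                    placed.append(pos)
                    records.append({"position": pos, "species": name.upper(),
                                    "mobility": "free"})
                    break
            else:
                raise FixtureError(
                    f"could not place ion {name} after {max_tries} tries")
    if not records:
        return system
    ions = build_system(records)
    return ions if system is None else merge_systems(system, ions)


def preset_species(name: str) -> tuple[dict[str, Species], PairClassTable]:
    """Ion species records and the coefficient table for a named preset.

    Available presets: NaCl-DNA, KCl-DNA, CoHex-DNA.
    """
    if name not in PRESET_SPECIES:
        raise FixtureError(
            f"unknown preset {name!r}; available: "
            + ", ".join(sorted(PRESET_SPECIES)))
    table = load_preset(name)
    cation, anion = PRESET_SPECIES[name]
    species = {cation: SPECIES_TABLE[cation]}
    if anion:
        species[anion] = SPECIES_TABLE[anion]
    return species, table


def neutralizing_count(solute_charge: float, ion_charge: float) -> int:
    """Number of ions of charge ``ion_charge`` neutralizing the solute."""
    if ion_charge == 0:
        raise FixtureError("ion charge must be non-zero")
    n = -solute_charge / ion_charge
    if n < 0 or abs(n - round(n)) > 1e-9:
        raise FixtureError(
            f"charge {solute_charge} is not neutralizable by whole "
            f"{ion_charge:+g}e ions")
    return int(round(n))
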