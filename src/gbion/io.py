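"""File I/O: PDB systems, XYZ trajectories with JSON sidecars, manifests.

The PDB dialect used for fixture output stores pseudo-atoms as HETATM
records and repurposes the occupancy column to carry the particle charge
(documented deviation from the standard meaning). Trajectories are plain
multi-frame XYZ with a JSON sidecar holding per-frame energies and the
run configuration, so every figure-style output can be regenerated from
saved files without rerunning dynamics.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import biotite.structure as struc
import biotite.structure.io.pdb as pdb

from .dynamics import SimConfig, Trajectory
from .system import (ELEMENT_RADII, SPECIES_TABLE, ParticleSystem,
                     build_system)


class IOError_(ValueError):
    pass


# --------------------------------------------------------------------------
# PDB
# --------------------------------------------------------------------------

def write_pdb(system: ParticleSystem, path) -> None:
    """Write the system in the fixture PDB dialect (charge in occupancy)."""
    n = system.n_particles
    atoms = struc.AtomArray(n)
    atoms.coord = np.asarray(system.positions, dtype=np.float32)
    atoms.set_annotation("atom_name", np.array(
        [str(s)[:4] for s in system.species]))
    atoms.set_annotation("res_name", np.array(
        [("ION" if code != 0 else "SOL") for code in system.topo_code]))
    atoms.set_annotation("res_id", np.arange(1, n + 1))
    atoms.set_annotation("chain_id", np.array(
        ["A" if code == 0 else "B" for code in system.topo_code]))
    atoms.set_annotation("hetero", np.ones(n, dtype=bool))
    atoms.set_annotation("element", np.array(
        [str(s)[:2].strip() for s in system.species]))
    atoms.set_annotation("occupancy", np.asarray(system.charges, dtype=float))
    atoms.set_annotation("b_factor", np.asarray(system.radii, dtype=float))
    f = pdb.PDBFile()
    f.set_structure(atoms)
    f.write(str(path))


def read_pdb(path, charges_from_occupancy: bool = True) -> ParticleSystem:
    """Read a PDB file into a particle system.

    Known species names (NA, K, CL, COHEX, PHO) get their table
    parameters; other atoms become solute particles with element-based
    intrinsic radii and, unless ``charges_from_occupancy`` is set and the
    occupancy column is populated, zero charge.
    """
    try:
        f = pdb.PDBFile.read(str(path))
        atoms = f.get_structure(model=1, extra_fields=["occupancy", "b_factor"])
    except Exception as exc:
        raise IOError_(f"cannot parse PDB file {path}: {exc}") from exc
    if atoms.array_length() == 0:
        raise IOError_(f"PDB file {path} contains no atoms")
    records = []
    for i in range(atoms.array_length()):
        name = str(atoms.atom_name[i]).strip().upper()
        occ = float(atoms.occupancy[i])
        if name in SPECIES_TABLE:
            rec = {"position": atoms.coord[i], "species": name}
            if charges_from_occupancy and occ != 0.0:
                rec["charge"] = occ
        else:
            elem = str(atoms.element[i]).strip().upper() or name[:1]
            rho = ELEMENT_RADII.get(elem, 1.7)
            rec = {"position": atoms.coord[i], "species": name or elem,
                   "charge": occ if charges_from_occupancy else 0.0,
                   "topo_class": "solute", "rho": rho,
                   "mobility": "fixed"}
        records.append(rec)
    system = build_system(records)
    system.meta["source"] = str(path)
    return system


# --------------------------------------------------------------------------
# trajectories
# --------------------------------------------------------------------------

def write_traj(trajectory: Trajectory, path) -> None:
    """Multi-frame XYZ plus a ``<path>.json`` energy/config sidecar."""
    path = Path(path)
    names = [str(s) for s in trajectory.system.species]
    with path.open("w") as fh:
        for k in range(trajectory.n_frames):
            fh.write(f"{len(names)}\n")
            fh.write(f"frame {k}\n")
            for name, xyz in zip(names, trajectory.positions[k]):
                fh.write(f"{name:<6s} {xyz[0]:.6f} {xyz[1]:.6f} {xyz[2]:.6f}\n")
    sidecar = {
        "n_frames": int(trajectory.n_frames),
        "seed": int(trajectory.seed),
        "energies": trajectory.energies,
        "temperatures": np.asarray(trajectory.temperatures).tolist(),
        "config": dataclasses.asdict(trajectory.config)
        if trajectory.config else None,
        "meta": {k: v for k, v in trajectory.meta.items()
                 if isinstance(v, (str, int, float, list, dict, bool))},
    }
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(sidecar, indent=1))


def read_traj(path, system: ParticleSystem) -> Trajectory:
    """Read an XYZ trajectory written by :func:`write_traj`.

    A truncated final frame is dropped with a warning entry in ``meta``.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    frames = []
    i = 0
    truncated = False
    while i < len(lines):
        try:
            n = int(lines[i].split()[0])
        except (ValueError, IndexError):
            break
        block = lines[i + 2:i + 2 + n]
        if len(block) < n:
            truncated = True
            break
        coords = np.array([[float(v) for v in ln.split()[1:4]]
                           for ln in block])
        frames.append(coords)
        i += 2 + n
    if not frames:
        raise IOError_(f"no complete frames in {path}")
    sidecar_path = path.with_suffix(path.suffix + ".json")
    energies, temps, config, seed = [], [], None, 0
    if sidecar_path.exists():
        sc = json.loads(sidecar_path.read_text())
        energies = sc.get("energies", [])[:len(frames)]
        temps = sc.get("temperatures", [])[:len(frames)]
        seed = sc.get("seed", 0)
        if sc.get("config"):
            config = SimConfig(**sc["config"])
    traj = Trajectory(positions=np.array(frames), energies=energies,
                      temperatures=np.array(temps if temps else
                                            [0.0] * len(frames)),
                      config=config, system=system, seed=seed)
    if truncated:
        traj.meta["warning"] = (f"truncated trajectory: kept "
                                f"{len(frames)} complete frames")
    return traj


# --------------------------------------------------------------------------
# run manifests
# --------------------------------------------------------------------------

@dataclass
class RunManifest:
    """Everything needed to reproduce a run bit-for-bit."""

    config: dict
    seed: int
    preset: str | None = None
    preset_sha256: str | None = None
    version: str = "0.1.0"
    stages: dict = field(default_factory=dict)   # stage -> wall seconds
    outputs: dict = field(default_factory=dict)  # label -> path

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=1))

    @classmethod
    def read(cls, path) -> "RunManifest":
        return cls(**json.loads(Path(path).read_text()))


def preset_hash(table) -> str:
    payload = json.dumps(table.as_dict(), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:16]
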