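"""Sampler cross-validation: Langevin dynamics vs Metropolis Monte Carlo.

Both samplers target the same Boltzmann distribution of the model
energy; their radial ion profiles around a fixed charge must agree
within statistical error. This is the package's internal check that the
integrator samples configuration space correctly.
"""

import numpy as np

from gbion import build_system, load_preset, place_ions
from gbion.dynamics import SimConfig, mc_sample, run_simulation
from gbion.restraints import FlatBottomSphere

center = build_system([{"position": [0, 0, 0], "charge": -4.0,
                        "topo_class": "solute", "rho": 2.0, "sigma": 4.0,
                        "eps": 0.2, "mobility": "fixed", "species": "QC"}])
system = place_ions(center, {"NA": 7, "CL": 3}, radius=11.0, seed=5)
table = load_preset("NaCl-DNA")
restraint = FlatBottomSphere(r3=12.0, k=20.0, anchor=np.zeros(3))

langevin = run_simulation(system, table, restraint,
                          SimConfig(n_steps=120_000, friction_ps=0.5,
                                    snapshot_stride=100, seed=31,
                                    n_equil_steps=5000))
mc = mc_sample(system, table, restraint, n_moves=80_000, seed=32,
               step_size=3.0)

cations = system.select_species("NA")
edges = np.linspace(0.0, 12.0, 5)
print("mean Na+ count per radial shell (7 ions around a fixed -4e charge)")
print(f"{'shell (A)':>12s} {'Langevin':>10s} {'MC':>10s}")
for lo, hi in zip(edges[:-1], edges[1:]):
    row = []
    for traj in (langevin, mc):
        r = np.linalg.norm(traj.positions[:, cations, :], axis=2)
        row.append(((r >= lo) & (r < hi)).sum(axis=1).mean())
    print(f"{lo:5.1f}-{hi:4.1f} {row[0]:10.3f} {row[1]:10.3f}")
print(f"\nMC acceptance rate: {mc.meta['acceptance']:.2f}")
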