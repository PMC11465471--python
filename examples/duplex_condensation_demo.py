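"""Two-duplex demo: trivalent ions turn duplex-duplex repulsion around.

Solute particles are held fixed in this package, so instead of watching
two DNA fragments diffuse together, this demo samples the CoHex3+ ion
atmosphere around a rigid pair of 25-bp duplexes at several imposed
separations and reports the mean total energy of each arrangement. With
bound trivalent counterions the close arrangements are no longer
strongly disfavored — the electrostatic signature of ion-mediated DNA
condensation. A qualitative, stochastic demonstration only.
"""

import numpy as np

from gbion import build_bdna, merge_systems, place_ions, preset_species
from gbion.dynamics import SimConfig, run_simulation
from gbion.restraints import FlatBottomSphere

_, table = preset_species("CoHex-DNA")
print("mean sampled energy of two neutralized 25-bp duplexes (kcal/mol)")
print(f"{'separation (A)':>15s} {'mean E_total':>14s} {'bridging ions':>14s}")
for sep in (74.0, 50.0, 35.0, 25.0):
    a, b = build_bdna(25), build_bdna(25)
    a.positions[:, 0] -= sep / 2
    b.positions[:, 0] += sep / 2
    for duplex in (a, b):
        duplex.reference_positions = duplex.positions.copy()
    pair = merge_systems(a, b)
    system = place_ions(pair, {"COHEX": 32}, radius=70.0, seed=7)
    restraint = FlatBottomSphere(
        r3=80.0, k=20.0, anchor=np.flatnonzero(system.solute_mask))
    config = SimConfig(n_steps=12_000, n_equil_steps=25_000,
                       friction_ps=0.5, snapshot_stride=400, seed=7)
    traj = run_simulation(system, table, restraint, config)
    e_mean = np.mean([e["total_kcal"] for e in traj.energies])
    # ions within 12 Å of both duplex axes are the candidate bridges
    ions = traj.positions[:, system.ion_mask, :]
    da = np.hypot(ions[..., 0] + sep / 2, ions[..., 1])
    db = np.hypot(ions[..., 0] - sep / 2, ions[..., 1])
    bridging = ((da < 14) & (db < 14)).sum(axis=1).mean()
    print(f"{sep:15.1f} {e_mean:14.1f} {bridging:14.2f}")
print("\nIf the sampled energy does not rise (or even falls) as the")
print("duplexes approach, the trivalent ion cloud has neutralized the")
print("bare Coulomb repulsion between the two -48e rods.")
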