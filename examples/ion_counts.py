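"""Salt setup arithmetic: how many ions does a confined DNA system need?

Builds the 12-bp and 25-bp duplex models, computes the cation/anion
counts that produce a 0.145 M bulk concentration in their simulation
volumes, and prints the Manning condensation reference values.
"""

from gbion import manning_reference, sltcap_counts, solvent_volume
from gbion.fixtures import BDnaModel
from gbion.sltcap import nucleic_acid_volume, sltcap_exact

# -- 12-bp duplex in a 40 Å restraining sphere ---------------------------
dodecamer = BDnaModel(n_bp=12)
v_w = solvent_volume(40.0, nucleic_acid_volume(2 * dodecamer.n_bp))
n_plus, n_minus = sltcap_counts(dodecamer.total_charge, 0.145, v_w)
exact = sltcap_exact(dodecamer.total_charge, 0.145, v_w)
print(f"12-bp duplex (Q = {dodecamer.total_charge:+.0f}e), 40 A sphere, 0.145 M:")
print(f"  solvent volume {v_w:,.0f} A^3")
print(f"  unrounded N+ = {exact[0]:.2f}, N- = {exact[1]:.2f}")
print(f"  add {n_plus} cations and {n_minus} anions")

# -- 25-bp duplex in the volume of a 29,255-water reference box ----------
duplex = BDnaModel(n_bp=25)
v_box = 29_255 * 30.0
n_plus, n_minus = sltcap_counts(duplex.total_charge, 0.145, v_box)
print(f"\n25-bp duplex (Q = {duplex.total_charge:+.0f}e), "
      f"{v_box:,.0f} A^3 of water:")
print(f"  add {n_plus} cations and {n_minus} anions")

# -- Manning condensation reference --------------------------------------
for z in (1, 3):
    xi, theta, n_cond = manning_reference(z=z, n_charges=48)
    print(f"\nManning, valence {z}: xi = {xi:.2f}, "
          f"condensed fraction {100 * theta:.0f}% "
          f"({n_cond:.1f} of 48 charges neutralized)")
# The condensed fraction is the charge a line-charge model of B-DNA keeps
# bound regardless of dilution; 76% for monovalent, 92% for trivalent ions.
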