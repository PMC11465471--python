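"""Physical constants and the package-wide unit system.

Units are Å (length), elementary charge e, kcal/mol (energy), K
(temperature), amu (mass) and fs (time) throughout; the Coulomb constant
matches the AMBER convention so canonical-GB cross-checks are meaningful.
"""

from __future__ import annotations

#: Coulomb constant, kcal·Å/(mol·e²).
KE_COULOMB: float = 332.0636

#: Boltzmann constant, kcal/(mol·K).
KB: float = 0.0019872

#: Concentration conversion: multiply mol/L by this to get particles/ų.
CONC_MOLAR_TO_PER_A3: float = 6.02e-4

#: Default solvent (water) dielectric constant.
EPS_OUT_DEFAULT: float = 78.5

#: Conversion from force in kcal/mol/Å over mass in amu to acceleration
#: in Å/fs²:  a[Å/fs²] = ACC_CONV * F[kcal/mol/Å] / m[amu].
ACC_CONV: float = 4.184e-4

#: Default simulation temperature, K.
DEFAULT_TEMPERATURE: float = 300.0

#: Bjerrum length of water at 300 K with the constants above, Å
#: (k_e / (eps_out * k_B * T)).
BJERRUM_WATER_300K: float = 7.1

#: Axial charge spacing of B-DNA (two phosphates per 3.4 Å rise), Å.
BDNA_CHARGE_SPACING: float = 1.7
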