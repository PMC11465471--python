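"""Salt setup arithmetic: SLTCAP ion counts and Manning reference values.

A non-periodic implicit-solvent simulation confines its ions in a
restraining sphere; the number of cations and anions added must be chosen
so that the *bulk* concentration far from the charged solute reaches a
target value c0. SLTCAP solves this for a solute of net charge Q in a
solvent volume V_w:

    N0 = c0 * V_w            (c0 in particles/ų)
    N± = sqrt(N0² + Q²/4) ∓ Q/2

so that N+ - N- = -Q (added salt plus solute is electroneutral) and
N± → N0 in the large-volume limit. Non-integer results are rounded by
fixing whichever count is closest to an integer and deriving the other
from electroneutrality.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .constants import (BDNA_CHARGE_SPACING, BJERRUM_WATER_300K,
                        CONC_MOLAR_TO_PER_A3)

#: Default solute volume estimate for nucleic acids, ų per nucleotide.
VOLUME_PER_NUCLEOTIDE = 300.0


def conc_to_per_A3(c_mol_per_L: float) -> float:
    """Convert a molar concentration to particles per ų."""
    if c_mol_per_L < 0:
        raise ValueError("concentration must be non-negative")
    return c_mol_per_L * CONC_MOLAR_TO_PER_A3


def per_A3_to_conc(n_per_A3: float) -> float:
    """Inverse of :func:`conc_to_per_A3`."""
    if n_per_A3 < 0:
        raise ValueError("number density must be non-negative")
    return n_per_A3 / CONC_MOLAR_TO_PER_A3


def solvent_volume(r_sphere: float, v_solute: float = 0.0) -> float:
    """Solvent volume of a restraining sphere: (4/3)πR³ − V_solute (ų).

    Passing ``v_solute=0`` gives the sphere-only approximation used when
    the solute volume is negligible.
    """
    if r_sphere <= 0:
        raise ValueError("sphere radius must be positive")
    v_sphere = 4.0 / 3.0 * math.pi * r_sphere**3
    if not 0.0 <= v_solute < v_sphere:
        raise ValueError("solute volume must lie in [0, sphere volume)")
    return v_sphere - v_solute


def sltcap_exact(Q: float, c0_molar: float, v_w: float) -> tuple[float, float]:
    """Real-valued SLTCAP cation/anion counts before rounding."""
    if v_w <= 0:
        raise ValueError("solvent volume must be positive")
    if c0_molar < 0:
        raise ValueError("concentration must be non-negative")
    n0 = conc_to_per_A3(c0_molar) * v_w
    root = math.sqrt(n0 * n0 + 0.25 * Q * Q)
    return root - 0.5 * Q, root + 0.5 * Q


def sltcap_counts(Q: float, c0_molar: float, v_w: float) -> tuple[int, int]:
    """Integer (N+, N-) for solute charge Q (e), target c0 (M), V_w (ų).

    Rounding fixes whichever of the two real counts has the fractional
    part closest to an integer, then derives the other from
    electroneutrality, so N+ - N- + round(Q) = 0 holds exactly.
    """
    n_plus, n_minus = sltcap_exact(Q, c0_molar, v_w)
    q_int = round(Q)

    def dist(x: float) -> float:
        return abs(x - round(x))

    if dist(n_plus) <= dist(n_minus):
        np_i = round(n_plus)
        nm_i = np_i + q_int
    else:
        nm_i = round(n_minus)
        np_i = nm_i - q_int
    if np_i < 0 or nm_i < 0:
        # tiny volumes / extreme charge: clamp the co-ion at zero
        if q_int <= 0:
            np_i, nm_i = max(np_i, -q_int), max(nm_i, 0)
        else:
            np_i, nm_i = max(np_i, 0), max(nm_i, q_int)
    return int(np_i), int(nm_i)


@dataclass(frozen=True)
class SaltSpec:
    """A fully resolved salt setup for one simulation sphere."""

    Q: float                   # solute net charge, e
    c0: float                  # target bulk concentration, mol/L
    r_sphere: float            # restraining-sphere radius, Å
    v_solute: float            # solute volume, ų
    v_w: float                 # solvent volume, ų
    n_plus: int
    n_minus: int

    @classmethod
    def for_sphere(cls, Q: float, c0: float, r_sphere: float,
                   v_solute: float = 0.0) -> "SaltSpec":
        v_w = solvent_volume(r_sphere, v_solute)
        n_plus, n_minus = sltcap_counts(Q, c0, v_w)
        return cls(Q, c0, r_sphere, v_solute, v_w, n_plus, n_minus)


def nucleic_acid_volume(n_nucleotides: int,
                        per_nucleotide: float = VOLUME_PER_NUCLEOTIDE) -> float:
    """Rough solute-volume estimate for a nucleic acid, ų."""
    if n_nucleotides < 0:
        raise ValueError("nucleotide count must be non-negative")
    return n_nucleotides * per_nucleotide


def manning_reference(z: float = 1.0,
                      l_B: float = BJERRUM_WATER_300K,
                      b: float = BDNA_CHARGE_SPACING,
                      n_charges: int = 48) -> tuple[float, float, float]:
    """Counterion-condensation reference values for a line charge.

    Returns ``(xi, theta, n_condensed)``: ``xi = l_B/b`` is the
    dimensionless linear charge density, ``theta = max(0, 1 - 1/(z xi))``
    the fraction of the line charge neutralized by condensed counterions
    of valence z (zero below the condensation threshold xi <= 1/z), and
    ``n_condensed = theta * n_charges`` the neutralized charge expressed
    in elementary-charge units (equal to the number of condensed ions for
    monovalent counterions).
    """
    if z < 1 or b <= 0 or l_B <= 0:
        raise ValueError("need z >= 1, b > 0, l_B > 0")
    xi = l_B / b
    theta = max(0.0, 1.0 - 1.0 / (z * xi))
    n_condensed = theta * n_charges
    return xi, theta, n_condensed
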