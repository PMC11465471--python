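# Methods

## Model

The electrostatic solvation model is a generalized Born (GB) energy in
which every pair of interaction topology classes (solute s, cation c,
anion a) has its own coefficients. The pair energy between charges
q_i, q_j at distance d is

    E_ij = k_e [ q_i q_j/(ε_in(a,b) d) − (1/ε_in(a,b) − 1/ε_out) q_i q_j / f ]
    f    = sqrt(d² + R_i R_j exp(−d²/(γ(a,b) R_i R_j)))

with k_e = 332.0636 kcal·Å/(mol·e²) and ε_out = 78.5. The γ→0 limit is
taken continuously as f = d. The displayed form is a reconstruction
pinned uniquely by three exact limits, all enforced by tests:

1. γ = 4, ε_in = 1 reduces to the canonical Still GB pair term; the
   implementation is written so the reduction is bit-for-bit against an
   independently coded canonical-GB routine.
2. γ → 0 collapses the bracket to pure Coulomb screened by ε_out, for
   any ε_in.
3. ε_in → ε_out does the same for any γ.

Solute–solute entries are pinned at (γ=4, ε_in=1): a pure solute is
plain canonical GB. Self energies use the Born expression
−(k_e/2)(1/ε_in − 1/ε_out) q²/R with the particle's *diagonal* class
coefficients ((c,c) for cations, (a,a) for anions, canonical for
solute). Whether the pair-class modification should touch self energies
at all is genuinely open; the diagonal-class choice is the only one that
needs no new parameters, and it is what the energy decomposition
reports. A 12-6 Lennard-Jones term with Lorentz–Berthelot mixing
handles excluded volume. The nonpolar (SASA-proportional) solvation
term is omitted: ion distributions are insensitive to it and the
simulated solutes here are rigid. There are no periodic boundary
conditions and no cutoffs: sums run over all pairs.

## Effective Born radii

R_i comes from Hawkins–Cramer–Truhlar pairwise descreening under the
Coulomb-field approximation: 1/R_i = 1/ρ_i − Σ_j I(d_ij; ρ_i, ρ_j),
where I is the closed-form integral of (4π)⁻¹ r⁻⁴ over the part of
sphere j outside the ρ_i-ball, with the separated, overlapping and
engulfed regimes handled explicitly and no neck or tanh-rescaling
corrections. Correctness is pinned by an independent oracle that
integrates r⁻⁴ exactly along rays over the *union* of neighbour spheres
(Fibonacci angular grid, radial part in closed form): pairwise radii
agree with the union oracle within 5% on random clusters, and the
isolated-ion limit R = ρ is exact. Radii saturating descreening are
clamped at 1000 Å with zero gradient.

Intrinsic radii: a small mbondi3-like element table (H 1.3, C 1.7,
N 1.55, O 1.5, P 1.85 Å) for atomistic PDB input; 2.0 Å for the
fixture's phosphate pseudo-beads; ion radii follow the σ/2 convention
(Na 1.87, K 2.26, Cl 2.47, CoHex 3.10 Å). The ion radii and LJ
parameters are literature-style stand-ins, overridable per particle.

When the solute is fixed (the default for all analyzed systems), solute
radii are computed once from the solute geometry alone and cached; ion
radii are recomputed every step including descreening by the solute.
On the fixture systems this approximation changes total energies by
well under 0.5%.

Forces are the exact negative gradient of the total energy, including
the chain-rule path through R_i(positions); they match central finite
differences to 1e-6 relative, which is the package's internal
correctness bar for the force code.

## Parameters and presets

Preset coefficient files use AMBER-style key aliases: `gi_coef_1_*`
stores K_GB with γ(a,b) = 4·K_GB(a,b) (so K_GB = 1 is canonical), and
`intdiel_ion_1_*` stores K_ε taken directly as ε_in(a,b). Suffixes map
pair slots (`_p` = (s,c), `_n` = (s,a), `_pp` = (c,c), `_pn` = (a,c),
`_nn` = (a,a)). Shipped presets (values as published for DNA systems):

| preset | K_GB (s,c / s,a / c,c / a,c / a,a) | K_ε (same order) |
|---|---|---|
| NaCl-DNA  | 1 / 0.05 / 1 / 0.05 / 1 | 54 / 8 / 54 / 8 / 8 |
| KCl-DNA   | 1 / 0.05 / 1 / 0.05 / 1 | 36 / 8 / 36 / 8 / 8 |
| CoHex-DNA | 0.01 / 0.01 / 0.06 / 0.06 / 0.06 | 1 / 1 / 2 / 2 / 2 |

Validation treats K_GB outside [0, 2] or K_ε outside [1, 78.5] as
warnings (outside the explored parameterization range), and ε_in < 1 or
ε_in > ε_out as hard errors.

## Salt setup

SLTCAP counts: with N0 = c0·V_w (c0 converted from mol/L to
particles/ų by the factor 6.02×10⁻⁴) and solute charge Q,
N± = sqrt(N0² + Q²/4) ∓ Q/2. V_w is the restraining-sphere volume minus
the solute volume; for nucleic acids the default solute-volume estimate
is 300 ų per nucleotide, chosen as a round mid-range value for
hydrated nucleotide volumes — the dodecamer worked example is
insensitive to it across roughly [6,000, 17,000] ų. Rounding fixes
whichever real-valued count is closest to an integer and derives the
other from electroneutrality, so N₊ − N₋ = −Q holds exactly.

Manning references use Bjerrum length l_B = 7.1 Å (k_e/(ε_out k_B T) at
300 K with this unit system) and B-DNA axial charge spacing b = 1.7 Å.

## Sampling

Langevin dynamics uses the BAOAB splitting with a 2 fs time step; fixed
particles are excluded from the update, and `restrained` solute
particles feel a harmonic tether (default 0.01 kcal/mol/Ų, the
production-run setting; heavier tethers are used for staging). The
flat-bottom sphere (default k = 20 kcal/mol/Ų) confines ions to the
simulation volume; its anchor is a particle, a mass-weighted group
center (recomputed every step), or a fixed point. Ion masses: Na 22.99,
K 39.10, Cl 35.45, CoHex³⁺ 161.1 u, the latter as a single rigid +3e
bead.

Friction: heating/equilibration protocols quote 0.05 ps⁻¹; sampling
runs here default to 1 ps⁻¹ and the validation suite uses 0.3–0.5 ps⁻¹.
This deviation is deliberate: the collision frequency is a thermostat
setting, not a physical observable, and at near-ballistic friction
(≲0.1 ps⁻¹) the 2 fs discretization measurably biases the density a
particle samples near the restraint wall, while moderate friction
reproduces the exact uniform-filling distribution (χ² checked).

The Metropolis Monte Carlo sampler proposes single-ion Gaussian
displacements and accepts on the full model energy difference with
radii recomputed for every proposal, so it satisfies detailed balance
for exactly the energy the integrator uses. It serves as the
equilibrium oracle: Langevin and MC radial profiles agree bin-wise
within statistical error on the cross-check systems, and the two agree
to ~2 percentage points on fixture neutralization degrees.

Simulations halt with a diagnostic (and the last stable coordinates) on
non-finite forces or |E| > 1e8 kcal/mol. All runs are deterministic
given a seed, and the trajectory writer emits a JSON sidecar plus a run
manifest sufficient to reproduce a run bit-for-bit.

Problem sizes used by the validation suite are deliberately desk-scale:
hundreds of thousands of Langevin steps (sub-nanosecond trajectories)
and 10⁵–10⁶ MC moves on systems of 1–208 particles. These are the
package's own verification conditions; quantitative production profiles
want at least an order of magnitude more sampling.

## Analysis conventions

Profiles are cylindrical about the ideal helix axis — justified because
every analyzed solute is a rigid ideal model; curvilinear helicoidal
frames would only matter for flexible DNA. c(r) is averaged over frames
within the axial slab of length h (default n_bp·3.4 Å; 85 Å for 25 bp)
and reported in mol/L; the bulk value c(∞) is the mean over the 28–30 Å
annulus. The associated-ion count integrates the excess
[c(r) − c(∞)]·2πr·h by the midpoint rule on the histogram bins, which
recovers flat shells exactly and smooth profiles to better than 0.1% at
the default bin width. Neutralization degree is the frame-averaged net
ion charge within a stated axis distance (default 16 Å, the outer edge
of the external ion-binding shell), as a percentage of |Q_solute|, and
is always reported together with its cutoff. The PMF is
W(r) = −ln c(r)/c(∞) in k_BT, masked where c = 0; "cation affinity" has
no unique estimator, so the PMF minimum is reported as a clearly
labelled proxy. Profile comparison reports the L∞ PMF difference over
commonly populated bins and the ratio of first-peak areas, the peak
region being the contiguous bins around the maximum where c > c(∞).
Radial–azimuth maps measure azimuth relative to the local helical phase
(36° per 3.4 Å of rise) and marginalize exactly onto the 1D profile.

## The synthetic fixture and what it does not capture

The B-DNA stand-in is a phosphate-only double helix: n_bp−1 beads of
−1e per strand (5′ phosphate absent) on two helices of radius 8.9 Å,
rise 3.4 Å/bp, twist 36°/bp, strands offset 154° so the grooves are
inequivalent. This reproduces the net charge (−48e at 25 bp, −22e at
12 bp), the linear charge density that drives condensation physics, and
the groove-phase geometry for angular maps — with zero force-field
dependency. It does **not** capture atomistic charge detail (bases,
backbone partial charges), groove depth/shape, or close-contact ion
binding sites; its excluded volume is a smooth LJ envelope.

Consequences, as measured by the validation suite: monovalent
neutralization of the coarse rod comes out high (≈65–70% at 16 Å vs
≈53% for atomistic references) because the (s,c) preset enhancement
acts on an unobstructed rod, while trivalent CoHex³⁺ neutralization
comes out low (≈56–58% vs ≈90% atomistic) because the CoHex preset
makes solute–cation electrostatics purely Coulombic in water and relies
on atomistic surface structure for its close binding. The valence
*ordering* of neutralization at a 16 Å cutoff is therefore inverted on
this fixture — the corresponding acceptance test is left failing
deliberately, with Langevin and Monte Carlo agreeing on the equilibrium,
rather than adjusted to pass. Passing tests on this fixture validate
the energy model, the samplers and the analysis pipeline; they do not
by themselves certify ion distributions around real, atomistic DNA.

## Numerical choices

- Units: Å, e, kcal/mol, amu, fs; k_B = 0.0019872 kcal/(mol·K);
  force→acceleration conversion 4.184×10⁻⁴ (Å/fs² per kcal/mol/Å/amu).
- Degenerate inputs: coincident particles are rejected before radii
  computation; d = 0 pair energies are rejected (self terms are
  separate); empty trajectories and zero-bulk profiles are rejected by
  the analysis layer.
- The descreening integral and its distance derivative are evaluated
  per geometric regime; derivatives were verified against finite
  differences in all regimes.
- Ion placement rejects positions closer than 2.5 Å to any particle and
  fails loudly after a bounded number of retries.
- The compiled (numba) pair-loop kernels are an optimization of the
  vectorized reference implementation; a unit test pins the two paths
  to ≈1e-12 relative agreement, and the package runs (slowly) without
  numba.

## Known limitations

- No free-solute dynamics: solutes are fixed or positionally
  restrained, so condensation kinetics can only be illustrated, not
  simulated (see `examples/duplex_condensation_demo.py`).
- No salt-dependent screening inside the GB terms: all screening beyond
  ε_out comes from the explicit ions themselves.
- Single-species monovalent or trivalent salt setups; no mixed-valence
  SLTCAP, no divalent parameterization.
- The co-ion (anion) depletion near a strongly charged center is
  nonlinear; the Debye–Hückel validation therefore checks the
  counterion (cation) profile, which stays within the linear-response
  regime over the checked 10–25 Å window.
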