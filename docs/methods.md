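# Methods

## Scope and model

`piscreen` estimates vertical S₁/T₁ excitation energies, singlet–triplet
gaps ΔE_ST = E(S₁) − E(T₁) and oscillator strengths of conjugated organic
molecules with the Pariser–Parr–Pople (PPP) π-electron Hamiltonian, and
classifies molecules as inverted (ΔE_ST < 0) or normal. It treats only the
π system in a minimal basis of one 2p orbital per conjugated heavy atom
under the zero-differential-overlap (ZDO) approximation: the AO overlap
matrix is the identity and all two-electron integrals collapse to the
one- and two-center repulsions γ_rr, γ_rs. σ frameworks, n → π*
transitions, solvation and geometry relaxation are outside the model.

## π-system perception

Bonds are perceived from distances (bonded iff r < 1.15 × sum of covalent
radii) unless an SDF bond block is present, which always wins. The 1.15
scale deliberately lets collapsed geometries form transannular bonds — a
real failure mode of screening data that the per-row error handling is
designed around. π-electron counts per center follow standard PPP valence
rules: sp² C → 1; divalent N (pyridine-type) → 1; trivalent N
(pyrrole/amine-type) → 2; monovalent O (carbonyl) → 1; divalent O
(ether/hydroxyl) → 2. Hydrogens and halogens are σ-only; halogen lone-pair
donation is neglected, a documented modeling choice. Atoms that would
bridge the π system without parameters (e.g. four-coordinate P) raise an
`UnsupportedCenterError`, and odd total π-electron counts are rejected
before any SCF is attempted. Sulfur centers are perceived (S1/S2 keys) but
the shipped table carries no sulfur entries, so they fail with the same
clear error rather than with invented parameters.

Twist angles θ_rs per bond are the average over all dihedrals a–r–s–b with
a, b π neighbors, each folded to [0°, 90°] (only |cos θ| is physical);
bonds without flanking π neighbors get θ = 0.

## Parameterization

All parameters derive from the Hinze–Jaffé valence-state data shipped in
`data/valence_states.csv` (C: IP 11.16 / EA 0.03 eV; pyridine-N:
14.12 / 1.78; pyrrole-N: 28.71 / 11.96; carbonyl-O: 17.70 / 2.47; ether-O:
34.12 / 15.30) plus one empirical constant C = 0.545:

- **γ_rr = IP_v − EA_v** (Pariser–Parr).
- **γ_rs = e²/√(r² + a_rs²)** with a_rs = 2e²/(γ_rr + γ_ss) and
  e² = 14.397 eV·Å (Ohno form): continuous with the one-center scale at
  r → 0 and within 1 % of the bare Coulomb law at 10 Å.
- **β_rs = −C·S_rs·(IP_r + IP_s)·cos θ_rs**, nonzero only for bonded
  pairs. S_rs is the exact 2p–2p π overlap of Slater orbitals with
  hydrogen-like exponents ζ = n·√(2·IP_eff) (atomic units), where
  IP_eff = IP_v − (n_r − 1)γ_rr is the neutral-atom-like π ionization —
  for two-electron donors the tabulated IP_v refers to the positive
  valence state, and using it directly would shrink the orbitals
  unphysically. For C this gives ζ = 1.81 and β(1.40 Å) = −2.97 eV, in the
  range of classic PPP resonance integrals. The cos θ factor multiplies
  the full β, so β(90°) = 0.
- **U_r = −IP_v − (n_r − 1)γ_rr**; core diagonal
  α_r = U_r − Σ_{s≠r} Z_s γ_rs with Z_s the per-center π-electron count.

Overlap integrals are evaluated with the Mulliken auxiliary-integral
recursions (A_k, B_k) in prolate spheroidal coordinates; a B_k power
series is used for near-equal exponents. The test suite checks the
recursion against an independent 3D quadrature to 10⁻⁶ over a 0.8–5 Å
grid. An optional cubic-spline fast path over a 400-point grid (0.5–15
bohr) is available via `overlap_method="spline"`; outside its grid it
falls back to the exact recursion, and on the fixture set it shifts
CIS+DSP gaps by < 4 meV RMSE.

## SCF

The ZDO Roothaan equations are solved by plain fixed-point iteration from
a Hückel guess (core diagonal + β couplings), with Fock elements
F_rr = H_rr + ½P_rr γ_rr + Σ_{s≠r} P_ss γ_rs and
F_rs = H_rs − ½P_rs γ_rs. Convergence is declared at an RMS density change
below 10⁻⁸ (default) within 200 iterations; if the change grows between
iterations, linear damping with factor 0.5 is switched on. No DIIS or
level shifting — at π-system sizes (≲ 30 centers) the damped iteration is
adequate, and non-convergence is returned as a flagged result rather than
an exception so that batch screening can record it per row.

Degenerate orbitals (benzene e-sets, azaphenalene-type frontier blocks)
get a deterministic gauge: within each degenerate block a coordinate-
moment operator (first plus second moments with incommensurate weights) is
diagonalized, then signs are fixed by making the largest-magnitude
coefficient positive. First moments alone are insufficient — for the
nonbonding pair of a square ring all their block elements vanish by
symmetry — hence the second-moment terms. This makes exchange and overlap
observables on degenerate systems reproducible across linear-algebra
backends.

## Excited states

**Exchange gap.** At the SCF level ΔE_ST = 2K with
K = (HL|HL) = Σ_rs (c_rH c_rL) γ_rs (c_sH c_sL) ≥ 0, so inversion is
impossible at this level; the HOMO–LUMO spatial overlap Σ_r |c_rH||c_rL|
is reported as its structural proxy.

**CIS.** Full singles over occ × virt with the spin-adapted ZDO matrices
(singlet: Δε + 2(ia|jb) − (ij|ab); triplet: Δε − (ij|ab)). Oscillator
strengths use the dipole-length form f = (2/3)·ΔE·|μ|² in atomic units
with the ZDO point-charge transition dipole μ = √2 Σ_ia t_ia Σ_r c_ri c_ra
R_r, which is origin-independent because occupied and virtual orbitals are
orthogonal.

**Dynamic spin polarization (DSP).** The open-shell S₁ (HOMO x → LUMO y)
is differentially stabilized relative to T₁ by configurations that are
doubly excited with respect to the ground state: single excitations i → a
from the doubly occupied orbitals below x into the virtuals above y on top
of the x¹y¹ reference. With exchange couplings K_x = (ix|xa),
K_y = (iy|ya), the second-order model correction is

    ΔE^DSP = Σ_{i,a} [ −(3/2)(K_x − K_y)²/D_S
                       + (1/2)(K_x − K_y)²/D_T + (K_x + K_y)²/D_T ]

The singlet couples through the antisymmetric combination K_x − K_y
(additive spin polarization), the triplet through both channels with
smaller weight (competitive polarization); the channel weights are the
spin-coupling factors of the perturbing configurations. Denominators are
the spin-polarized determinant energies written purely in orbital
energies: with the same orbitals used for both multiplicities they reduce
to D = ε_a − ε_i at the SCF reference. A contribution is negative whenever
K_x K_y < 0, which is the generic situation for the symmetry-allowed pairs
of diradicaloid chromophores. Contributions with |D| < 10⁻⁶ eV are dropped
with a per-molecule warning rather than propagated as infinities.

At the **CIS reference** the same sum is evaluated with the CIS state
energy in place of the open-shell determinant energy, so each channel's
denominator grows by (ε_LUMO − ε_HOMO) − ΔE_CIS of the respective state;
since the CIS states lie well below the bare determinants, the CIS-level
DSP is systematically smaller in magnitude than the SCF-level one.
ΔE_ST at the CIS+DSP level is gap_CIS + ΔE^DSP_CIS, optionally followed by
the empirical linear correction 0.53·x − 0.15 (eV), whose coefficients are
configurable.

For degenerate frontier orbitals the gauge-fixed canonical HOMO/LUMO are
used as x, y, with degenerate partners entering the i/a sum as ordinary
members. At the restricted minimum of bond-equalized square
cyclobutadiene the SCF prefers the delocalized frontier combination, for
which every i → a exchange coupling vanishes by symmetry: the DSP total is
then 0 to machine precision. The large textbook singlet stabilization of
the disjoint nonbonding pair belongs to an open-shell reference this
closed-shell model does not visit — a known boundary of the method.

## Screening and metrics

`screen` processes a CSV manifest row by row; any per-molecule failure
(parse error, unsupported center, odd electron count) is captured in the
row's `status` and never aborts the batch. Classification uses
"inverted" as the positive class at a configurable gap level (default
CIS+DSP, threshold 0 eV). From a confusion matrix the report derives
recall, specificity, accuracy, F1 and — since hard binary predictions
admit no continuous ROC — the balanced accuracy (recall + specificity)/2
as ROC-AUC. Regression quality against reference gaps is R², Spearman ρ
and RMSE. Display rounding is half-even at 2 decimals (so 0.625 prints as
0.62); machine-readable outputs keep full precision.

## Fixtures and oracles

All test molecules are generated programmatically: pentalene as two fused
regular pentagons with all nine bonds equal (the maximally symmetric
bond-equalized D2h realization — the internal angles are a documented
choice, and the worked-example tolerances of ±0.02 eV absorb the residual
angular ambiguity), regular n-gons, planar zigzag polyenes, and a
butadiene skeleton with an exact central-bond twist. Independent oracles
re-derive CIS (explicit spin-adapted configuration basis built element by
element, ≤ 10 orbitals), exchange integrals (direct double loops) and
oscillator strengths (independent dipole assembly); production code must
match them to 10⁻⁸ eV / 10⁻¹² / 10⁻⁸ respectively.

## Problem sizes and determinism

The shipped studies run on molecules of 2–13 π centers; SCF + CIS + DSP
for an 8-center system completes in well under a second on one CPU core.
Everything in the default pipeline is deterministic: fixture generation is
pure, the SCF start is the Hückel guess, and degenerate-block gauges are
fixed as described, so repeated runs are bit-reproducible on a given
platform.

## Known limitations

π-only physics (no σ polarization, no n → π* states, weak for
nonalternant azaazulene-type scaffolds), no solvation, vertical gaps on
the input geometry only, oscillator strengths qualitatively ranked rather
than quantitatively accurate, and heteroatom coverage limited to the
shipped C/N/O table. Reparameterization of C = 0.545 or the valence-state
data is deliberately out of scope.
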