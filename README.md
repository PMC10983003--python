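# piscreen

Ultrafast semiempirical screening of conjugated molecules for **inverted
singlet–triplet gaps** (INVEST candidates): molecules whose first excited
singlet S₁ lies *below* the first triplet T₁, violating Hund's rule in the
excited state. Such emitters promise OLEDs with up to 100 % internal quantum
efficiency without the triplet-harvesting bottleneck, but they are rare, and
the coupled-cluster or ADC(2) calculations needed to find them cost minutes
to hours per molecule. `piscreen` computes the vertical gap
ΔE_ST = E(S₁) − E(T₁) in milliseconds per molecule, accurately enough to
prescreen libraries of 10⁴–10⁶ structures.

## Method

The electronic structure is the Pariser–Parr–Pople (PPP) π-electron model:
one 2p orbital per conjugated heavy atom, zero differential overlap, and all
integrals parameterized from Hinze–Jaffé valence-state ionization potentials
(IP_v) and electron affinities (EA_v):

- γ_rr = IP_v − EA_v (Pariser–Parr), γ_rs = e²/√(r² + a²) (Ohno),
- β_rs = −C·S_rs·(IP_r + IP_s) with C = 0.545, where S_rs is the exact
  Slater 2p–2p overlap, attenuated by cos θ for twisted bonds,
- core terms α_r = −IP_v − (n_r − 1)γ_rr − Σ_s Z_s γ_rs.

The closed-shell Roothaan equations **FC** = **CE** are solved by damped
fixed-point iteration from a Hückel guess. On top of the SCF orbitals the
gap ladder is:

| level | expression |
|---|---|
| SCF | ΔE_ST = 2K, K = HOMO–LUMO exchange integral |
| SCF + DSP | 2K + ΔE^DSP (perturbative dynamic spin polarization) |
| CIS | E(S₁) − E(T₁) from full singles CI |
| CIS + DSP (+LC) | CIS gap + DSP vs the CIS states, optional linear correction 0.53·x − 0.15 |

ΔE_ST at the SCF level can never be negative (K ≥ 0); inversion appears only
once the dynamic spin polarization — the admixture of doubly excited
configurations i → a that spin-polarize the open-shell S₁ — is added. The
per-pair DSP decomposition identifies which orbital excitations drive the
inversion, making the screening interpretable as well as fast.

## Worked example

Pentalene with all nine C–C bonds fixed at 1.4 Å (D2h) is a classic
inverted-gap system:

```python
from piscreen import PPPModel
from piscreen.fixtures import pentalene_d2h

results = PPPModel.from_geometry(pentalene_d2h()).fit()
print(results.summary())
```

```
PPP SCF / CIS+DSP results -- pentalene_d2h_1.4
============================================================
pi centers:            8
pi electrons:          8
SCF converged:         True (22 iterations)
HOMO / LUMO energies:  -9.5502 / -2.7872 eV
HOMO-LUMO overlap:     0.2274
------------------------------------------------------------
2K (SCF gap):          +0.1192 eV
DSP correction (SCF):  -0.3803 eV
gap SCF+DSP:           -0.2611 eV
gap CIS:               +0.0743 eV
DSP correction (CIS):  -0.2676 eV
gap CIS+DSP:           -0.1933 eV
gap CIS+DSP+LC:        -0.2525 eV
S1 oscillator strength: 0.0000
```

The small HOMO–LUMO spatial overlap (0.23) keeps the exchange splitting 2K
at 0.12 eV; dynamic spin polarization (−0.38 eV, dominated by the 2→6, 3→8
and 1→7 orbital excitations) overturns it, so both the SCF+DSP and CIS+DSP
gaps come out negative — an inverted singlet–triplet gap. The vanishing S₁
oscillator strength illustrates the intrinsic trade-off: zero spatial
overlap kills both the exchange splitting and the transition dipole.

The same ladder is available from the shell:

```bash
piscreen compute docs/examples/pentalene_d2h.xyz --decompose
piscreen screen manifest.csv --out results.csv   # batch, 1 row per molecule
piscreen metrics results.csv --ref-col ref_gap_eV
```

Batch screening never aborts on a bad molecule: unsupported atoms, odd
electron counts or failed SCFs are reported in a per-row `status` column.

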