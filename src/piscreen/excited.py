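"""Excited-state ladder: 2K, CIS, dynamic spin polarization, gap estimates.

The vertical singlet-triplet gap of a closed-shell conjugated molecule is
computed at four levels:

1. SCF:       dE_ST = 2K, twice the HOMO-LUMO exchange integral.
2. SCF + DSP: 2K plus a perturbative dynamic-spin-polarization correction.
3. CIS:       E(S1) - E(T1) from configuration interaction singles.
4. CIS + DSP: the CIS gap plus the DSP correction referenced to the CIS
   state energies, optionally followed by an empirical linear correction.

The DSP correction sums over single excitations i -> a from the doubly
occupied orbitals below the HOMO (x) into the virtuals above the LUMO (y);
relative to the open-shell x -> y reference these are doubly excited
configurations.  With exchange couplings K_x = (ix|xa), K_y = (iy|ya) the
per-pair contribution is

    dE_DSP(i,a) = -(3/2) (K_x - K_y)^2 / D_S
                 + (1/2) (K_x - K_y)^2 / D_T + (K_x + K_y)^2 / D_T

where D_S and D_T are the energies of the spin-polarized determinants
relative to the singlet/triplet reference, written in terms of orbital
energies.  At the SCF reference both reduce to eps_a - eps_i; at the CIS
reference the state energy replaces the reference-determinant energy, so
the denominators grow by (eps_LUMO - eps_HOMO) - dE_CIS of the respective
state.  The correction stabilizes the open-shell singlet whenever the two
exchange couplings carry opposite relative sign (K_x K_y < 0), which is
the mechanism behind inverted gaps in diradicaloid chromophores.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .constants import BOHR_ANGSTROM, HARTREE_EV
from .exceptions import NotConvergedError

#: published linear correction applied on top of the CIS+DSP gap
LC_SLOPE = 0.53
LC_INTERCEPT = -0.15

#: |denominator| below this threshold (eV) drops a DSP contribution
DENOMINATOR_THRESHOLD = 1e-6


def _mo_pair_density(C: np.ndarray, i: int, j: int) -> np.ndarray:
    """Per-center product c_ri c_rj (the ZDO transition density of i,j)."""
    return C[:, i] * C[:, j]


def exchange_integral(scf, i: int, j: int) -> float:
    """ZDO exchange integral K_ij = (ij|ij) in eV; non-negative."""
    v = _mo_pair_density(scf.C, i, j)
    return float(v @ scf.params.gamma @ v)


def coulomb_integral(scf, i: int, j: int) -> float:
    """ZDO Coulomb integral J_ij = (ii|jj) in eV."""
    di = _mo_pair_density(scf.C, i, i)
    dj = _mo_pair_density(scf.C, j, j)
    return float(di @ scf.params.gamma @ dj)


def homo_lumo_overlap(scf) -> float:
    """Spatial overlap sum_r |c_r,HOMO| |c_r,LUMO|, in [0, 1]."""
    return float(np.sum(np.abs(scf.C[:, scf.homo]) * np.abs(scf.C[:, scf.lumo])))


@dataclass
class CISResult:
    """Spin-resolved CIS solution.

    ``energies`` are excitation energies in eV sorted ascending;
    ``amplitudes[k]`` is the normalized vector of occ->virt coefficients of
    root k over ``pairs``; oscillator strengths are attached for singlets.
    """

    multiplicity: str
    energies: np.ndarray
    amplitudes: np.ndarray          # (n_roots, n_pairs)
    pairs: list[tuple[int, int]]
    oscillator_strengths: np.ndarray | None = None

    @property
    def n_roots(self) -> int:
        return len(self.energies)


def _mo_eri_blocks(scf):
    """Transition densities for all occ->virt pairs plus the gamma matrix."""
    params = scf.params
    n, n_occ = params.n, scf.n_occ
    pairs = [(i, a) for i in range(n_occ) for a in range(n_occ, n)]
    X = np.empty((len(pairs), n))
    for k, (i, a) in enumerate(pairs):
        X[k] = _mo_pair_density(scf.C, i, a)
    return pairs, X


def cis(scf, multiplicity: str, force: bool = False) -> CISResult:
    """Configuration interaction singles over the full occ x virt space.

    Singlet:  A = delta (eps_a - eps_i) + 2 (ia|jb) - (ij|ab)
    Triplet:  A = delta (eps_a - eps_i) - (ij|ab)
    """
    if multiplicity not in {"singlet", "triplet"}:
        raise ValueError(f"unknown multiplicity {multiplicity!r}")
    if not scf.converged and not force:
        raise NotConvergedError(
            "CIS requested on a non-converged SCF reference (pass force=True "
            "to override)")
    params = scf.params
    gamma = params.gamma
    pairs, X = _mo_eri_blocks(scf)
    dim = len(pairs)
    # (ia|jb) for all pair combinations
    iajb = X @ gamma @ X.T
    # (ij|ab): per-center products of occ-occ and virt-virt densities
    ijab = np.empty((dim, dim))
    for k, (i, a) in enumerate(pairs):
        for m, (j, b) in enumerate(pairs):
            ijab[k, m] = float(
                _mo_pair_density(scf.C, i, j) @ gamma
                @ _mo_pair_density(scf.C, a, b))
    A = -ijab
    if multiplicity == "singlet":
        A = A + 2.0 * iajb
    diag = np.array([scf.eps[a] - scf.eps[i] for (i, a) in pairs])
    A[np.diag_indices_from(A)] += diag
    A = 0.5 * (A + A.T)
    energies, vecs = np.linalg.eigh(A)
    result = CISResult(multiplicity, energies, vecs.T.copy(), pairs)
    if multiplicity == "singlet":
        result.oscillator_strengths = np.array(
            [oscillator_strength(scf, result, k) for k in range(dim)])
    return result


def transition_dipole(scf, cis_result: CISResult, root: int) -> np.ndarray:
    """Transition dipole <0|r|root> (e * angstrom) in the ZDO point-charge picture."""
    mu = np.zeros(3)
    for (i, a), t in zip(cis_result.pairs, cis_result.amplitudes[root]):
        v = _mo_pair_density(scf.C, i, a)
        mu += math.sqrt(2.0) * t * (v @ scf.params.coords)
    return mu


def oscillator_strength(scf, cis_result: CISResult, root: int) -> float:
    """Dipole-length oscillator strength f = (2/3) dE |mu|^2 (atomic units)."""
    if cis_result.multiplicity != "singlet":
        raise ValueError("oscillator strengths are defined for singlet roots")
    mu_au = transition_dipole(scf, cis_result, root) / BOHR_ANGSTROM
    de_au = cis_result.energies[root] / HARTREE_EV
    return float((2.0 / 3.0) * de_au * (mu_au @ mu_au))


@dataclass
class DSPResult:
    """Perturbative dynamic-spin-polarization correction.

    ``contributions`` maps each (i, a) pair (0-based MO indices) to its eV
    contribution; ``total`` is their sum and is expected to be <= 0 for
    spin-polarization-stabilized singlets.
    """

    total: float
    contributions: list[tuple[int, int, float]]
    reference: str                  # "SCF" or "CIS"
    warnings: list[str] = field(default_factory=list)


def _dsp_sum(scf, shift_singlet: float, shift_triplet: float,
             reference: str) -> DSPResult:
    params = scf.params
    n, n_occ = params.n, scf.n_occ
    x, y = scf.homo, scf.lumo
    gamma = params.gamma
    cx, cy = scf.C[:, x], scf.C[:, y]
    contributions = []
    warnings: list[str] = []
    total = 0.0
    for i in range(n_occ - 1):
        vi = scf.C[:, i]
        for a in range(n_occ + 1, n):
            va = scf.C[:, a]
            kx = float((vi * cx) @ gamma @ (cx * va))
            ky = float((vi * cy) @ gamma @ (cy * va))
            d = scf.eps[a] - scf.eps[i]
            d_s = d + shift_singlet
            d_t = d + shift_triplet
            if abs(d_s) < DENOMINATOR_THRESHOLD or abs(d_t) < DENOMINATOR_THRESHOLD:
                warnings.append(
                    f"near-zero DSP denominator for pair {i + 1}->{a + 1}; "
                    "contribution dropped")
                continue
            value = (-1.5 * (kx - ky) ** 2 / d_s
                     + 0.5 * (kx - ky) ** 2 / d_t
                     + (kx + ky) ** 2 / d_t)
            contributions.append((i, a, value))
            total += value
    return DSPResult(total, contributions, reference, warnings)


def dsp_correction_scf(scf) -> DSPResult:
    """DSP correction with respect to the SCF (single-determinant) reference."""
    return _dsp_sum(scf, 0.0, 0.0, "SCF")


def dsp_correction_cis(scf, cis_singlet: CISResult,
                       cis_triplet: CISResult) -> DSPResult:
    """DSP correction referenced to the CIS S1/T1 state energies.

    The CIS states lie below the bare open-shell determinants, so the
    denominators grow by (eps_LUMO - eps_HOMO) - dE_CIS per spin channel and
    the correction shrinks relative to the SCF reference.
    """
    gap_hl = scf.eps[scf.lumo] - scf.eps[scf.homo]
    shift_s = gap_hl - float(cis_singlet.energies[0])
    shift_t = gap_hl - float(cis_triplet.energies[0])
    return _dsp_sum(scf, shift_s, shift_t, "CIS")


def linear_correction(gap_cis_dsp: float, slope: float = LC_SLOPE,
                      intercept: float = LC_INTERCEPT) -> float:
    """Empirical affine map applied to the CIS+DSP gap (eV in, eV out)."""
    return slope * gap_cis_dsp + intercept


def dsp_decomposition_report(dsp: DSPResult) -> list[tuple[str, float]]:
    """Contributions sorted by magnitude, labeled 'i -> a' with 1-based
    orbital numbering counted from the lowest MO."""
    ranked = sorted(dsp.contributions, key=lambda t: abs(t[2]), reverse=True)
    return [(f"{i + 1} -> {a + 1}", value) for i, a, value in ranked]


@dataclass
class GapEstimates:
    """The singlet-triplet gap ladder of one molecule (all energies eV)."""

    two_K: float
    dsp_scf: float
    gap_scf: float
    gap_scf_dsp: float
    gap_cis: float
    dsp_cis: float
    gap_cis_dsp: float
    gap_cis_dsp_lc: float
    homo_lumo_overlap: float
    e_s1: float
    e_t1: float
    f_s1: float
    warnings: set[str] = field(default_factory=set)

    def inverted(self, level: str = "cis_dsp", use_lc: bool = False) -> bool:
        value = {
            "scf": self.gap_scf,
            "scf_dsp": self.gap_scf_dsp,
            "cis": self.gap_cis,
            "cis_dsp": self.gap_cis_dsp_lc if use_lc else self.gap_cis_dsp,
            "cis_dsp_lc": self.gap_cis_dsp_lc,
        }[level]
        return value < 0.0


def gap_estimates(scf, lc_slope: float = LC_SLOPE,
                  lc_intercept: float = LC_INTERCEPT,
                  force: bool = False) -> GapEstimates:
    """Populate every level of the gap ladder for a fitted molecule.

    Never raises on scientific pathologies: negative CIS excitation
    energies (restricted-unrestricted instability fingerprints) and
    non-converged references are propagated as warnings.
    """
    warnings: set[str] = set()
    if not scf.converged:
        if not force:
            raise NotConvergedError(
                "gap ladder requested on non-converged SCF (force=True to "
                "override)")
        warnings.add("not_converged")
    two_k = 2.0 * exchange_integral(scf, scf.homo, scf.lumo)
    dsp_s = dsp_correction_scf(scf)
    cis_s = cis(scf, "singlet", force=True)
    cis_t = cis(scf, "triplet", force=True)
    dsp_c = dsp_correction_cis(scf, cis_s, cis_t)
    for w in dsp_s.warnings + dsp_c.warnings:
        warnings.add(w)
    e_s1 = float(cis_s.energies[0])
    e_t1 = float(cis_t.energies[0])
    if e_t1 < 0:
        warnings.add("negative_T1")
    if e_s1 < 0:
        warnings.add("negative_S1")
    gap_cis = e_s1 - e_t1
    gap_cis_dsp = gap_cis + dsp_c.total
    return GapEstimates(
        two_K=two_k,
        dsp_scf=dsp_s.total,
        gap_scf=two_k,
        gap_scf_dsp=two_k + dsp_s.total,
        gap_cis=gap_cis,
        dsp_cis=dsp_c.total,
        gap_cis_dsp=gap_cis_dsp,
        gap_cis_dsp_lc=linear_correction(gap_cis_dsp, lc_slope, lc_intercept),
        homo_lumo_overlap=homo_lumo_overlap(scf),
        e_s1=e_s1,
        e_t1=e_t1,
        f_s1=float(cis_s.oscillator_strengths[0]),
        warnings=warnings,
    )
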