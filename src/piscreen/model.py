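"""Closed-shell PPP self-consistent field model.

:class:`PPPModel` bundles a perceived pi system with its assembled PPP
parameters; :meth:`PPPModel.fit` solves the ZDO Roothaan equations
``F C = C E`` by damped fixed-point iteration from a Hueckel guess and
returns a :class:`PPPResults` carrying orbitals, orbital energies, the
density matrix and convergence diagnostics.  Excited-state quantities
(CIS, DSP corrections, the singlet-triplet gap ladder) are methods on the
results object.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np

from . import excited as _excited
from .geometry import (
    Geometry,
    PiSystem,
    load_geometry,
    perceive_pi_system,
)
from .parameters import (
    BETA_C,
    PPPParameters,
    ValenceStateTable,
    build_parameter_set,
)

DEFAULT_TOL = 1e-8
DEFAULT_MAX_ITER = 200
DEFAULT_DAMPING = 0.5


def huckel_guess(params: PPPParameters) -> np.ndarray:
    """Orbitals of the Hueckel-like matrix (core diagonal + beta couplings)."""
    h = params.beta.copy()
    np.fill_diagonal(h, np.diag(params.hcore))
    _, C = np.linalg.eigh(h)
    return C


def build_fock(P: np.ndarray, params: PPPParameters) -> np.ndarray:
    """ZDO Fock matrix for density P.

    F_rr = H_rr + P_rr gamma_rr / 2 + sum_{s != r} P_ss gamma_rs
    F_rs = H_rs - P_rs gamma_rs / 2
    """
    if P.shape != params.gamma.shape:
        raise ValueError("density matrix shape mismatch")
    pop = np.diag(P)
    F = params.hcore - 0.5 * P * params.gamma
    diag = (np.diag(params.hcore) + 0.5 * pop * np.diag(params.gamma)
            + params.gamma @ pop - np.diag(params.gamma) * pop)
    F[np.diag_indices_from(F)] = diag
    return F


def _gauge_fix(C: np.ndarray, eps: np.ndarray, coords: np.ndarray,
               degeneracy_tol: float = 1e-9) -> np.ndarray:
    """Deterministic gauge for degenerate orbitals.

    Within each degenerate block the gauge is fixed by diagonalizing a
    coordinate-moment operator (a generic diagonal combination of the
    center positions), then signs are fixed by making the largest-magnitude
    coefficient positive.  This makes exchange/overlap observables on
    degenerate systems reproducible across linear-algebra backends.
    """
    n = C.shape[1]
    # first AND second coordinate moments with incommensurate weights: the
    # first moments alone cannot split e.g. the centrosymmetric nonbonding
    # pair of a square ring, whose block elements of x, y, z all vanish
    w = (coords[:, 0] + np.sqrt(2.0) * coords[:, 1]
         + np.sqrt(3.0) * coords[:, 2]
         + np.sqrt(5.0) * coords[:, 0] ** 2
         + np.sqrt(7.0) * coords[:, 1] ** 2
         + np.sqrt(11.0) * coords[:, 2] ** 2)
    i = 0
    C = C.copy()
    while i < n:
        j = i + 1
        while j < n and abs(eps[j] - eps[i]) < degeneracy_tol:
            j += 1
        if j - i > 1:
            block = C[:, i:j]
            M = block.T @ (w[:, None] * block)
            _, V = np.linalg.eigh(0.5 * (M + M.T))
            C[:, i:j] = block @ V
        i = j
    for k in range(n):
        idx = int(np.argmax(np.abs(C[:, k])))
        if C[idx, k] < 0:
            C[:, k] = -C[:, k]
    return C


@dataclass
class PPPModel:
    """PPP Hamiltonian for one conjugated molecule.

    Construct via :meth:`from_geometry` / :meth:`from_file` (or directly
    from a perceived :class:`PiSystem`), then call :meth:`fit`.
    """

    pi_system: PiSystem
    params: PPPParameters

    @classmethod
    def from_geometry(cls, geom: Geometry,
                      table: ValenceStateTable | None = None,
                      cutoff_scale: float = 1.15,
                      c: float = BETA_C,
                      overlap_method: str = "exact") -> "PPPModel":
        ps = perceive_pi_system(geom, cutoff_scale=cutoff_scale)
        params = build_parameter_set(ps, table, c=c,
                                     overlap_method=overlap_method)
        return cls(ps, params)

    @classmethod
    def from_file(cls, path: str | Path, fmt: str | None = None,
                  **kwargs) -> "PPPModel":
        return cls.from_geometry(load_geometry(path, fmt), **kwargs)

    def fit(self, tol: float = DEFAULT_TOL, max_iter: int = DEFAULT_MAX_ITER,
            damping: float = DEFAULT_DAMPING) -> "PPPResults":
        """Solve the SCF equations; never raises on non-convergence.

        Plain (naive variational) fixed-point iteration on the density
        matrix; linear damping with factor ``damping`` is engaged when the
        RMS density change grows between iterations (oscillation rescue).
        """
        params = self.params
        n, n_occ = params.n, params.n_occ
        if n_occ > n:
            raise ValueError("more electron pairs than orbitals")
        C = huckel_guess(params)
        P = 2.0 * C[:, :n_occ] @ C[:, :n_occ].T
        energy_trace: list[float] = []
        converged = False
        damp_on = False
        last_change = np.inf
        n_iter = 0
        for n_iter in range(1, max_iter + 1):
            F = build_fock(P, params)
            eps, C = np.linalg.eigh(F)
            P_new = 2.0 * C[:, :n_occ] @ C[:, :n_occ].T
            energy_trace.append(0.5 * float(np.sum(P_new * (params.hcore + F))))
            change = float(np.sqrt(np.mean((P_new - P) ** 2)))
            if change > last_change and not damp_on:
                damp_on = True
            if damp_on:
                P = (1.0 - damping) * P_new + damping * P
            else:
                P = P_new
            last_change = change
            if change < tol:
                converged = True
                break
        F = build_fock(P, params)
        eps, C = np.linalg.eigh(F)
        C = _gauge_fix(C, eps, params.coords)
        P = 2.0 * C[:, :n_occ] @ C[:, :n_occ].T
        return PPPResults(model=self, C=C, eps=eps, P=P, F=F, n_occ=n_occ,
                          converged=converged, n_iter=n_iter,
                          energy_trace=energy_trace)


@dataclass
class PPPResults:
    """Converged (or flagged) SCF solution plus the excited-state ladder."""

    model: PPPModel
    C: np.ndarray            # MO coefficients, columns ordered by eps
    eps: np.ndarray          # orbital energies (eV)
    P: np.ndarray            # density matrix
    F: np.ndarray            # final Fock matrix
    n_occ: int
    converged: bool
    n_iter: int
    energy_trace: list[float] = dc_field(default_factory=list)

    @property
    def params(self) -> PPPParameters:
        return self.model.params

    @property
    def homo(self) -> int:
        return self.n_occ - 1

    @property
    def lumo(self) -> int:
        return self.n_occ

    # -- excited-state API (delegates to the excited module) ---------------
    def exchange_integral(self, i: int | None = None,
                          j: int | None = None) -> float:
        i = self.homo if i is None else i
        j = self.lumo if j is None else j
        return _excited.exchange_integral(self, i, j)

    def homo_lumo_overlap(self) -> float:
        return _excited.homo_lumo_overlap(self)

    def cis(self, multiplicity: str, force: bool = False):
        return _excited.cis(self, multiplicity, force=force)

    def dsp_scf(self):
        return _excited.dsp_correction_scf(self)

    def gap_estimates(self, **kwargs):
        return _excited.gap_estimates(self, **kwargs)

    def summary(self) -> str:
        """Human-readable report of the SCF solution and gap ladder."""
        ps = self.model.pi_system
        g = self.gap_estimates()
        lines = [
            "PPP SCF / CIS+DSP results"
            f" -- {ps.geometry.identifier or 'molecule'}",
            "=" * 60,
            f"pi centers:            {ps.n_centers}",
            f"pi electrons:          {ps.n_electrons}",
            f"SCF converged:         {self.converged} ({self.n_iter} iterations)",
            f"HOMO / LUMO energies:  {self.eps[self.homo]:+.4f} / "
            f"{self.eps[self.lumo]:+.4f} eV",
            f"HOMO-LUMO overlap:     {g.homo_lumo_overlap:.4f}",
            "-" * 60,
            f"2K (SCF gap):          {g.two_K:+.4f} eV",
            f"DSP correction (SCF):  {g.dsp_scf:+.4f} eV",
            f"gap SCF+DSP:           {g.gap_scf_dsp:+.4f} eV",
            f"gap CIS:               {g.gap_cis:+.4f} eV",
            f"DSP correction (CIS):  {g.dsp_cis:+.4f} eV",
            f"gap CIS+DSP:           {g.gap_cis_dsp:+.4f} eV",
            f"gap CIS+DSP+LC:        {g.gap_cis_dsp_lc:+.4f} eV",
            f"S1 oscillator strength: {g.f_s1:.4f}",
        ]
        if g.warnings:
            lines.append(f"warnings: {', '.join(sorted(g.warnings))}")
        return "\n".join(lines)
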