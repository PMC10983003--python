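"""Deterministic model geometries and independent brute-force oracles.

The geometry generators build the idealized model systems used throughout
the tests (pentalene at D2h, bond-equalized rings, planar polyene chains)
as pure functions of their arguments.  The brute-force routines re-derive
CIS energies, exchange integrals and oscillator strengths from first
principles of the ZDO integral rules with independent loop structures, so
they can serve as oracles for the production code paths.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

from .constants import BOHR_ANGSTROM, HARTREE_EV
from .geometry import Geometry


def pentalene_d2h(bond: float = 1.4) -> Geometry:
    """Pentalene as two regular pentagons of side ``bond`` fused on an edge.

    Planar, D2h-symmetric, all 9 C-C bonds exactly equal to ``bond``; the
    maximally symmetric realization of a bond-equalized pentalene.
    """
    if bond <= 0:
        raise ValueError("bond length must be positive")
    rc = bond / (2.0 * math.sin(math.pi / 5.0))   # pentagon circumradius
    ap = rc * math.cos(math.pi / 5.0)             # apothem
    coords = []
    # shared (bridgehead) edge on the y axis
    coords.append([0.0, bond / 2.0, 0.0])
    coords.append([0.0, -bond / 2.0, 0.0])
    for side in (-1.0, 1.0):
        cx = side * ap
        for ang_deg in (108.0, 180.0, 252.0):
            ang = math.radians(ang_deg)
            x = cx + side * (-rc) * math.cos(ang)
            y = rc * math.sin(ang)
            coords.append([x, y, 0.0])
    return Geometry(["C"] * 8, np.array(coords), identifier=f"pentalene_d2h_{bond}")


def ring_polygon(n: int, bond: float = 1.4, element: str = "C") -> Geometry:
    """Regular n-gon with side length ``bond`` in the xy plane."""
    if n < 3:
        raise ValueError("a ring needs at least 3 atoms")
    rc = bond / (2.0 * math.sin(math.pi / n))
    coords = [[rc * math.cos(2 * math.pi * k / n),
               rc * math.sin(2 * math.pi * k / n), 0.0] for k in range(n)]
    return Geometry([element] * n, np.array(coords),
                    identifier=f"{element}{n}_ring_{bond}")


def polyene_chain(n: int, bond: float = 1.4, angle: float = 120.0) -> Geometry:
    """Planar zigzag all-carbon chain (ethylene for n=2, butadiene for n=4)."""
    if n < 2:
        raise ValueError("chain needs at least 2 atoms")
    half = math.radians(180.0 - angle) / 2.0
    coords = [[k * bond * math.cos(half),
               (k % 2) * bond * math.sin(half), 0.0] for k in range(n)]
    return Geometry(["C"] * n, np.array(coords), identifier=f"polyene_{n}")


def twisted_butadiene(twist_deg: float, bond: float = 1.4) -> Geometry:
    """Butadiene skeleton with the central bond twisted by ``twist_deg``.

    The C1-C2-C3-C4 dihedral equals ``twist_deg`` exactly, making this the
    reference fixture for the twist-angle machinery.
    """
    ang = math.radians(30.0)   # 120 degree valence angles
    c2 = np.array([0.0, 0.0, 0.0])
    c3 = np.array([bond, 0.0, 0.0])
    c1 = c2 + bond * np.array([-math.cos(ang), math.sin(ang), 0.0])
    t = math.radians(twist_deg)
    c4 = c3 + bond * np.array([math.cos(ang),
                               math.sin(ang) * math.cos(t),
                               math.sin(ang) * math.sin(t)])
    return Geometry(["C"] * 4, np.vstack([c1, c2, c3, c4]),
                    identifier=f"butadiene_twist_{twist_deg}")


# ---------------------------------------------------------------------------
# brute-force oracles (independent of the production excited-state code)
# ---------------------------------------------------------------------------

def _mo_eri(C: np.ndarray, gamma: np.ndarray,
            p: int, q: int, r: int, s: int) -> float:
    """ZDO two-electron integral (pq|rs) by direct double summation."""
    total = 0.0
    n = C.shape[0]
    for u in range(n):
        cu = C[u, p] * C[u, q]
        if cu == 0.0:
            continue
        for v in range(n):
            total += cu * gamma[u, v] * C[v, r] * C[v, s]
    return total


def brute_force_exchange(C: np.ndarray, gamma: np.ndarray,
                         i: int, j: int) -> float:
    """Exchange integral K_ij = (ij|ij) by explicit loops."""
    return _mo_eri(C, gamma, i, j, i, j)


def brute_force_cis(scf, params, multiplicity: str) -> np.ndarray:
    """CIS excitation energies from an explicitly built configuration basis.

    Constructs the spin-adapted singly excited configuration Hamiltonian
    element by element from the ZDO integral rules and diagonalizes it.
    Refuses systems with more than 10 orbitals.
    """
    C, eps = scf.C, scf.eps
    n = params.n
    if n > 10:
        raise ValueError("brute-force CIS oracle limited to 10 orbitals")
    n_occ = params.n_occ
    occ = list(range(n_occ))
    virt = list(range(n_occ, n))
    pairs = [(i, a) for i in occ for a in virt]
    dim = len(pairs)
    H = np.zeros((dim, dim))
    for idx, (i, a) in enumerate(pairs):
        for jdx, (j, b) in enumerate(pairs):
            elem = 0.0
            if i == j and a == b:
                elem += eps[a] - eps[i]
            iajb = _mo_eri(C, params.gamma, i, a, j, b)
            ijab = _mo_eri(C, params.gamma, i, j, a, b)
            if multiplicity == "singlet":
                elem += 2.0 * iajb - ijab
            elif multiplicity == "triplet":
                elem += -ijab
            else:
                raise ValueError(multiplicity)
            H[idx, jdx] = elem
    return np.linalg.eigvalsh(H)


def numerical_dipole_oracle(scf, params, cis_result, root: int = 0) -> float:
    """Oscillator strength of a singlet CIS root by independent assembly."""
    n_occ = params.n_occ
    n = params.n
    pairs = [(i, a) for i in range(n_occ) for a in range(n_occ, n)]
    amp = cis_result.amplitudes[root]
    mu = np.zeros(3)
    for (i, a), t in zip(pairs, amp):
        moment = np.zeros(3)
        for u in range(n):
            moment += scf.C[u, i] * scf.C[u, a] * params.coords[u]
        mu += math.sqrt(2.0) * t * moment
    mu_au = mu / BOHR_ANGSTROM
    de_au = cis_result.energies[root] / HARTREE_EV
    return (2.0 / 3.0) * de_au * float(mu_au @ mu_au)


def random_orthonormal(n: int, seed: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    q, _ = np.linalg.qr(rng.standard_normal((n, n)))
    return q
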