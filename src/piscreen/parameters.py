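"""PPP parameter assembly: U_r, gamma_rr, gamma_rs, beta_rs and the core matrix.

Every model parameter derives from valence-state ionization potentials and
electron affinities (Hinze-Jaffe) plus the single empirical constant
C = 0.545 in the resonance integral:

* one-center repulsion (Pariser-Parr):        gamma_rr = IP_v - EA_v
* two-center repulsion (Ohno-type):           gamma_rs = e^2 / sqrt(r^2 + a_rs^2),
  with a_rs = 2 e^2 / (gamma_rr + gamma_ss) so that gamma_rs -> mean one-center
  repulsion as r -> 0 and -> e^2/r at long range
* resonance integral (Ohno-type):             beta_rs = -C S_rs (IP_r + IP_s),
  attenuated by cos(theta_rs) for twisted p orbitals
* atomic valence-state potential:             U_r = -IP_v - (n_r - 1) gamma_rr

S_rs is the exact 2p-2p Slater overlap with hydrogen-like exponents
zeta_r = n sqrt(2 IP_eff) (atomic units), where IP_eff = IP_v - (n_r - 1)
gamma_rr is the neutral-atom-like pi ionization, so that every parameter is
a function of the valence-state data and C alone.  The core matrix has
diagonal alpha_r = U_r - sum_{s != r} Z_s gamma_rs and off-diagonal beta_rs
on bonded pairs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

from .constants import BOHR_ANGSTROM, COULOMB_EV_ANGSTROM, HARTREE_EV
from .exceptions import UnsupportedCenterError
from .geometry import PiSystem
from .slater import cached_overlap_spline, slater_overlap

#: empirical resonance-integral prefactor of the Beveridge-Hinze scheme
BETA_C = 0.545


@dataclass(frozen=True)
class ValenceState:
    key: str
    element: str
    n_pi: int
    ip_ev: float
    ea_ev: float

    @property
    def gamma_rr(self) -> float:
        return self.ip_ev - self.ea_ev

    @property
    def ip_effective(self) -> float:
        """Neutral-atom-like pi ionization (eV); equals IP_v for 1-e donors."""
        return self.ip_ev - (self.n_pi - 1) * self.gamma_rr

    @property
    def zeta(self) -> float:
        """Slater 2p exponent (1/bohr), hydrogen-like from the ionization."""
        return 2.0 * math.sqrt(2.0 * self.ip_effective / HARTREE_EV)


class ValenceStateTable:
    """Map from valence-type key (C, N1, N2, O1, O2, ...) to atomic data."""

    def __init__(self, entries: dict[str, ValenceState]):
        self.entries = entries
        for vs in entries.values():
            if not (vs.ip_ev > vs.ea_ev and vs.ip_ev > 0):
                raise ValueError(f"table entry {vs.key}: requires IP > EA and IP > 0")

    @classmethod
    def from_csv(cls, path: str | Path) -> "ValenceStateTable":
        entries = {}
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, element, n_pi, ip, ea = [x.strip() for x in line.split(",")]
            entries[key] = ValenceState(key, element, int(n_pi),
                                        float(ip), float(ea))
        return cls(entries)

    @classmethod
    def default(cls) -> "ValenceStateTable":
        with resources.as_file(
            resources.files("piscreen.data") / "valence_states.csv"
        ) as p:
            return cls.from_csv(p)

    def __getitem__(self, key: str) -> ValenceState:
        try:
            return self.entries[key]
        except KeyError:
            raise UnsupportedCenterError(
                f"no valence-state parameters for center type {key!r}; "
                f"available: {sorted(self.entries)}"
            ) from None

    def __contains__(self, key: str) -> bool:
        return key in self.entries


def one_center_repulsion(vs: ValenceState) -> float:
    """gamma_rr = IP_v - EA_v (eV)."""
    return vs.ip_ev - vs.ea_ev


def two_center_repulsion(vs_r: ValenceState, vs_s: ValenceState,
                         r_angstrom: float) -> float:
    """Ohno-type two-center repulsion gamma_rs (eV), smooth in distance."""
    if r_angstrom < 0:
        raise ValueError("distance must be non-negative")
    g_rr = one_center_repulsion(vs_r)
    g_ss = one_center_repulsion(vs_s)
    a = 2.0 * COULOMB_EV_ANGSTROM / (g_rr + g_ss)
    return COULOMB_EV_ANGSTROM / math.sqrt(r_angstrom**2 + a**2)


def pi_overlap(vs_r: ValenceState, vs_s: ValenceState, r_angstrom: float,
               method: str = "exact") -> float:
    """2p-pi overlap between two centers at r (angstrom)."""
    r_bohr = r_angstrom / BOHR_ANGSTROM
    if method == "spline":
        return cached_overlap_spline(vs_r.zeta, vs_s.zeta, "pi")(r_bohr)
    return slater_overlap(vs_r.zeta, vs_s.zeta, r_bohr, "pi")


def resonance_integral(vs_r: ValenceState, vs_s: ValenceState,
                       r_angstrom: float, theta_deg: float = 0.0,
                       c: float = BETA_C, overlap_method: str = "exact") -> float:
    """Two-center resonance integral beta_rs (eV), negative for bonded pairs.

    beta = -C * S_pi(r) * (IP_r + IP_s), scaled by cos(theta) for twisted
    p orbitals (beta vanishes at 90 degrees).
    """
    s = pi_overlap(vs_r, vs_s, r_angstrom, overlap_method)
    beta = -c * s * (vs_r.ip_effective + vs_s.ip_effective)
    return beta * math.cos(math.radians(theta_deg))


@dataclass
class PPPParameters:
    """Assembled per-molecule PPP matrices (energies in eV, coords in angstrom)."""

    n: int
    U: np.ndarray          # (n,) atomic valence-state potentials
    Z: np.ndarray          # (n,) effective core charges = pi-electron counts
    gamma: np.ndarray      # (n, n) electron repulsion, gamma_rr on diagonal
    beta: np.ndarray       # (n, n) resonance integrals, nonzero on bonds only
    hcore: np.ndarray      # (n, n) core matrix
    coords: np.ndarray     # (n, 3) pi-center positions
    n_electrons: int
    valence_types: list[str] = field(default_factory=list)

    @property
    def n_occ(self) -> int:
        return self.n_electrons // 2


def build_parameter_set(ps: PiSystem,
                        table: ValenceStateTable | None = None,
                        c: float = BETA_C,
                        overlap_method: str = "exact") -> PPPParameters:
    """Assemble U, Z, gamma, beta and the core matrix for a pi system."""
    if table is None:
        table = ValenceStateTable.default()
    n = ps.n_centers
    states = [table[key] for key in ps.valence_types]
    coords = ps.coords

    Z = np.array([float(k) for k in ps.n_pi])
    gamma = np.zeros((n, n))
    beta = np.zeros((n, n))
    for r in range(n):
        gamma[r, r] = one_center_repulsion(states[r])
        for s in range(r + 1, n):
            d = float(np.linalg.norm(coords[r] - coords[s]))
            gamma[r, s] = gamma[s, r] = two_center_repulsion(
                states[r], states[s], d)
            if ps.adjacency[r, s]:
                beta[r, s] = beta[s, r] = resonance_integral(
                    states[r], states[s], d, ps.twist[r, s], c, overlap_method)

    U = np.array([-vs.ip_ev - (zr - 1.0) * gamma[r, r]
                  for r, (vs, zr) in enumerate(zip(states, Z))])
    hcore = beta.copy()
    for r in range(n):
        hcore[r, r] = U[r] - sum(Z[s] * gamma[r, s] for s in range(n) if s != r)

    return PPPParameters(n, U, Z, gamma, beta, hcore, coords.copy(),
                         ps.n_electrons, list(ps.valence_types))
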