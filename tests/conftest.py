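"""Shared fixtures: fitted model systems and slow-path oracles."""

import math

import numpy as np
import pytest
from scipy import integrate

from piscreen.fixtures import (
    pentalene_d2h,
    polyene_chain,
    ring_polygon,
)
from piscreen.model import PPPModel


@pytest.fixture(scope="session")
def pentalene_results():
    return PPPModel.from_geometry(pentalene_d2h()).fit()


@pytest.fixture(scope="session")
def ethylene_results():
    return PPPModel.from_geometry(polyene_chain(2, bond=1.33)).fit()


@pytest.fixture(scope="session")
def butadiene_results():
    return PPPModel.from_geometry(polyene_chain(4)).fit()


@pytest.fixture(scope="session")
def benzene_results():
    return PPPModel.from_geometry(ring_polygon(6, bond=1.397)).fit()


@pytest.fixture(scope="session")
def cyclobutadiene_results():
    return PPPModel.from_geometry(ring_polygon(4, bond=1.4)).fit()


def quadrature_slater_overlap(zeta_a: float, zeta_b: float, r: float,
                              orientation: str = "pi") -> float:
    """3D numerical quadrature of two Slater 2p orbitals (cylindrical coords).

    Independent oracle for the analytic recursion: the p_x (pi) or p_z
    (sigma, global frame) orbitals are integrated on a (rho, z) grid with
    the azimuthal integral done analytically.
    """
    c = math.sqrt(zeta_a**5 / math.pi) * math.sqrt(zeta_b**5 / math.pi)
    if orientation == "pi":
        def integrand(rho, z):
            ra = math.hypot(rho, z)
            rb = math.hypot(rho, z - r)
            return c * math.pi * rho**3 * math.exp(-zeta_a * ra - zeta_b * rb)
    else:
        def integrand(rho, z):
            ra = math.hypot(rho, z)
            rb = math.hypot(rho, z - r)
            return (c * 2 * math.pi * z * (z - r) * rho
                    * math.exp(-zeta_a * ra - zeta_b * rb))
    val, _ = integrate.dblquad(integrand, -30.0, 30.0 + r, 0.0, 30.0,
                               epsabs=1e-10, epsrel=1e-10)
    return val


def rigid_transform(coords: np.ndarray, seed: int = 0,
                    shift=(3.0, -1.0, 2.0)) -> np.ndarray:
    """A deterministic rotation + translation for invariance tests."""
    rng = np.random.default_rng(seed)
    q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return coords @ q.T + np.asarray(shift)
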