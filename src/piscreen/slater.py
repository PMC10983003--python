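"""Overlap integrals between Slater 2p orbitals.

The two-center overlap of 2p Slater-type orbitals is evaluated exactly in
prolate spheroidal coordinates through the Mulliken auxiliary integrals

    A_k(p) = int_1^inf  x^k exp(-p x) dx
    B_k(q) = int_-1^1   x^k exp(-q x) dx

with p = (zeta_a + zeta_b) R / 2 and q = (zeta_a - zeta_b) R / 2.  The
sigma orientation uses the global-frame convention (both orbitals along the
internuclear axis pointing the same way), for which the overlap of two
identical orbitals tends to +1 as R -> 0.

A cubic-spline fast path over a precomputed distance grid is available for
batch work; outside the grid it falls back to the exact evaluation.
"""

from __future__ import annotations

import math
from functools import lru_cache

import numpy as np
from scipy.interpolate import CubicSpline


def _aux_a(kmax: int, p: float) -> list[float]:
    """A_k(p) for k = 0..kmax via upward recursion (stable for p > 0)."""
    if p <= 0:
        raise ValueError("A_k requires p > 0")
    out = [math.exp(-p) / p]
    for k in range(1, kmax + 1):
        out.append((math.exp(-p) + k * out[k - 1]) / p)
    return out


def _aux_b(kmax: int, q: float) -> list[float]:
    """B_k(q) for k = 0..kmax; series expansion near q = 0."""
    out = []
    if abs(q) < 0.5:
        # B_k = sum_m (-q)^m / m! * (1 + (-1)^(k+m)) / (k + m + 1)
        for k in range(kmax + 1):
            total, term = 0.0, 1.0
            for m in range(0, 40):
                if m > 0:
                    term *= -q / m
                if (k + m) % 2 == 0:
                    total += term * 2.0 / (k + m + 1)
                if abs(term) < 1e-18:
                    break
            out.append(total)
    else:
        out.append((math.exp(q) - math.exp(-q)) / q)
        for k in range(1, kmax + 1):
            out.append(((-1) ** k * math.exp(q) - math.exp(-q) + k * out[k - 1]) / q)
    return out


def slater_overlap(zeta_a: float, zeta_b: float, r: float,
                   orientation: str = "pi") -> float:
    """Exact 2p-2p Slater overlap integral.

    Parameters
    ----------
    zeta_a, zeta_b : orbital exponents in 1/bohr
    r : internuclear distance in bohr
    orientation : "pi" (p orbitals perpendicular to the axis, parallel to
        each other) or "sigma" (both along the axis, global frame)
    """
    if zeta_a <= 0 or zeta_b <= 0:
        raise ValueError("Slater exponents must be positive")
    if r < 0:
        raise ValueError("distance must be non-negative")
    if orientation not in {"pi", "sigma"}:
        raise ValueError(f"unknown orientation {orientation!r}")
    if r < 1e-12:
        # same-center limit: <2p|2p'> = (zeta_a zeta_b)^(5/2) * 2^5 / (zeta_a+zeta_b)^5
        return (zeta_a * zeta_b) ** 2.5 * 32.0 / (zeta_a + zeta_b) ** 5
    p = 0.5 * (zeta_a + zeta_b) * r
    q = 0.5 * (zeta_a - zeta_b) * r
    pref = (zeta_a * zeta_b) ** 2.5 * r**5
    a = _aux_a(4, p)
    b = _aux_b(4, q)
    if orientation == "pi":
        poly = (a[4] * b[0] - a[4] * b[2] - a[2] * b[0]
                + a[2] * b[4] + a[0] * b[2] - a[0] * b[4])
        return pref / 32.0 * poly
    # global frame: +1 at R -> 0, negative (head-to-tail) at bonding distances
    poly = a[4] * b[2] - a[2] * b[4] - a[2] * b[0] + a[0] * b[2]
    return pref / 16.0 * poly


class OverlapSpline:
    """Cubic-spline interpolant of the exact overlap on a distance grid.

    Grid distances are in bohr.  Queries outside the grid fall back to the
    exact recursion, so the spline never extrapolates.
    """

    def __init__(self, zeta_a: float, zeta_b: float, orientation: str = "pi",
                 r_min: float = 0.5, r_max: float = 15.0, n_points: int = 400):
        self.zeta_a, self.zeta_b = zeta_a, zeta_b
        self.orientation = orientation
        self.r_min, self.r_max = r_min, r_max
        grid = np.linspace(r_min, r_max, n_points)
        vals = [slater_overlap(zeta_a, zeta_b, float(r), orientation)
                for r in grid]
        self._spline = CubicSpline(grid, vals)

    def __call__(self, r: float) -> float:
        if r < self.r_min or r > self.r_max:
            return slater_overlap(self.zeta_a, self.zeta_b, r, self.orientation)
        return float(self._spline(r))


@lru_cache(maxsize=64)
def cached_overlap_spline(zeta_a: float, zeta_b: float,
                          orientation: str = "pi") -> OverlapSpline:
    key = tuple(sorted((zeta_a, zeta_b)))
    return OverlapSpline(key[0], key[1], orientation)
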