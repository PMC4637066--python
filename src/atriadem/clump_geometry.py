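"""Geometry of one cell as a clump of n collinear overlapping discs.

A cell of length L and width 2r is represented by n equal discs of radius r
whose centres are spaced d apart along the cell axis, with

    L = (n - 1) d + 2 r
    A = n pi r^2 - (n - 1) S(r, d)

where S is the lens (intersection) area of two adjacent discs.  Contraction
is applied by resizing: given a target length (from sarcomere length) the
pair (r, d) is re-solved under the constraint that the clump area A stays
exactly at its resting value — the 2D incompressibility condition.  Resizes
keep the centroid and orientation fixed and distribute particles
symmetrically; clump kinematics are untouched.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "ClumpGeometry", "clump_length", "lens_area", "clump_area",
    "resize_clump", "particle_layout", "feasible_length_range",
    "union_polar_moment",
]


def clump_length(n: int, d: float, r: float) -> float:
    """Clump length L = (n-1) d + 2 r (um)."""
    if n < 1 or d < 0 or r <= 0:
        raise ValueError("require n >= 1, d >= 0, r > 0")
    return (n - 1) * d + 2.0 * r


def lens_area(r: float, d: float) -> float:
    """Intersection area of two discs of equal radius r at centre distance d:
    S = 2 r^2 arccos(d / 2r) - (d/2) sqrt(4 r^2 - d^2).

    Continuous and strictly decreasing in d on [0, 2r]; pi r^2 at d = 0 and
    0 at d = 2r.
    """
    if r <= 0:
        raise ValueError("radius must be positive")
    if d < 0 or d > 2.0 * r:
        raise ValueError(f"centre distance d={d} outside [0, {2 * r}]")
    return (2.0 * r * r * np.arccos(d / (2.0 * r))
            - 0.5 * d * np.sqrt(4.0 * r * r - d * d))


def clump_area(n: int, r: float, d: float) -> float:
    """Union area of the clump: A = n pi r^2 - (n-1) S(r, d).

    Valid for collinear equal discs with d >= r (adjacent lenses only;
    for d < r next-nearest discs would also overlap) — also accepted for
    d < r since the resting geometry keeps d > r.
    """
    s = lens_area(r, d) if n > 1 else 0.0
    return n * np.pi * r * r - (n - 1) * s


def feasible_length_range(A_target: float, n: int) -> tuple[float, float]:
    """Open interval of clump lengths achievable at fixed area A_target.

    At d -> 2r (tangent): A = n pi r^2, L = 2 n r, so L_max corresponds to
    r = sqrt(A / (n pi)).  At d -> 0 (fully stacked): A = pi r^2, L = 2r,
    the minimum length 2 sqrt(A / pi) / ... the interval endpoints follow
    from the two degenerate limits.
    """
    r_tangent = np.sqrt(A_target / (n * np.pi))
    r_stacked = np.sqrt(A_target / np.pi)
    return (2.0 * r_stacked, 2.0 * n * r_tangent)


def resize_clump(L_target: float, A_target: float, n: int,
                 rtol: float = 1e-12) -> tuple[float, float]:
    """Solve the length and area relations simultaneously for (r, d).

    Eliminates d = (L_target - 2r)/(n-1) and solves the scalar area equation
    in r by bracketed root-finding.  The solution satisfies 0 < d <= 2r.
    """
    if n < 2:
        raise ValueError("resizing needs n >= 2 particles")
    if L_target <= 0 or A_target <= 0:
        raise ValueError("targets must be positive")
    lo, hi = feasible_length_range(A_target, n)
    if not (lo < L_target < hi):
        raise ValueError(
            f"no clump of {n} particles with area {A_target:.6g} um^2 can "
            f"have length {L_target:.6g} um; feasible open interval is "
            f"({lo:.6g}, {hi:.6g}) um")

    def f(r):
        d = (L_target - 2.0 * r) / (n - 1)
        return clump_area(n, r, d) - A_target

    # r runs from the tangent limit (d = 2r, largest L for this r) to the
    # stacked limit (d -> 0); area - target is monotone across the bracket.
    r_lo = L_target / (2.0 * n)     # d = 2r limit
    r_hi = L_target / 2.0           # d = 0 limit
    eps = 1e-14 * L_target
    r = brentq(f, r_lo + eps, r_hi - eps, xtol=1e-300, rtol=rtol,
               maxiter=200)
    d = (L_target - 2.0 * r) / (n - 1)
    return float(r), float(d)


@dataclass(frozen=True)
class ClumpGeometry:
    """Geometry of one clump: n discs of radius r spaced d apart (um)."""

    n: int = 9
    r: float = 8.0
    d: float = 10.5

    def __post_init__(self):
        if self.n < 1 or self.r <= 0:
            raise ValueError("need n >= 1 and r > 0")
        if not (0.0 < self.d <= 2.0 * self.r):
            raise ValueError("need 0 < d <= 2r (overlapping or tangent)")

    @property
    def length(self) -> float:
        return clump_length(self.n, self.d, self.r)

    @property
    def area(self) -> float:
        return clump_area(self.n, self.r, self.d)

    @property
    def lens(self) -> float:
        return lens_area(self.r, self.d)

    def resized(self, L_target: float) -> "ClumpGeometry":
        """Area-conserving resize to a new length."""
        r, d = resize_clump(L_target, self.area, self.n)
        return ClumpGeometry(self.n, r, d)


def particle_layout(geom: ClumpGeometry, centroid, axis) -> tuple[np.ndarray, float]:
    """Particle centres for a clump at ``centroid`` with unit ``axis``.

    Particle k sits at centroid + (k - (n-1)/2) d axis, k = 0..n-1 —
    symmetric about the centroid, so resizing never displaces the clump.
    Returns (centres array of shape (n, 2), radius).
    """
    centroid = np.asarray(centroid, float)
    axis = np.asarray(axis, float)
    norm = np.hypot(*axis)
    if not np.isclose(norm, 1.0, atol=1e-9):
        raise ValueError("axis must be a unit vector")
    k = np.arange(geom.n) - (geom.n - 1) / 2.0
    return centroid + np.outer(k * geom.d, axis), geom.r


def _lens_polar_moment(r: float, d: float, n_quad: int = 48) -> float:
    """Second polar moment of area of the lens about its own centre.

    Integrated with Gauss-Legendre quadrature after the substitution
    u = r sin(phi), which removes the square-root endpoint singularity.
    """
    if d >= 2.0 * r:
        return 0.0
    phi0 = np.arcsin(d / (2.0 * r))
    x, w = np.polynomial.legendre.leggauss(n_quad)
    phi = 0.5 * (x + 1.0) * (0.5 * np.pi - phi0) + phi0
    wq = w * 0.5 * (0.5 * np.pi - phi0)
    c = np.cos(phi)
    integrand = (2.0 * (r * np.sin(phi) - 0.5 * d) ** 2 * (r * c)
                 + (2.0 / 3.0) * (r * c) ** 3) * (r * c)
    return float(2.0 * np.sum(wq * integrand))


def union_polar_moment(n: int, r: float, d: float) -> float:
    """Second polar moment of area of the disc union about the centroid.

    Composes per-disc moments (pi r^4 / 2 plus parallel-axis terms) and
    subtracts the moments of the n-1 lens regions.  Multiplying by the
    material density (and unit thickness) gives the clump's rotational
    inertia.
    """
    offsets = (np.arange(n) - (n - 1) / 2.0) * d
    j_discs = n * np.pi * r ** 4 / 2.0 + np.pi * r * r * np.sum(offsets ** 2)
    if n < 2:
        return float(j_discs)
    mids = 0.5 * (offsets[:-1] + offsets[1:])
    s = lens_area(r, d)
    j_lens = _lens_polar_moment(r, d)
    return float(j_discs - ((n - 1) * j_lens + s * np.sum(mids ** 2)))
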