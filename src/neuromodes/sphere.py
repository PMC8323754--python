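"""Spherical harmonics as cortical eigenmodes.

A cortical hemisphere has the topology of a sphere, so the sphere of equal
area is the natural zeroth-order geometry.  The Laplace–Beltrami eigenmodes
are the spherical harmonics ``Y_lm`` with eigenvalues

    k_lm^2 = l (l + 1) / R_s^2,

independent of m (2l+1-fold degenerate) by rotational symmetry.  There are
``(l_max + 1)^2`` modes up to and including degree ``l_max``.

Conventions: ``Y_lm = c_lm P_l^|m|(cos theta) e^{i m phi}`` with the
Condon–Shortley phase folded into the associated Legendre function (as in
scipy); the real basis combines ``Y_lm`` and ``Y_l,-m`` into cosine (m > 0)
and sine (m < 0) azimuthal dependences with (-1)^m factors, the standard
real spherical harmonics.

The quadrature grid is Gauss–Legendre in cos(theta) crossed with a uniform
trapezoid in phi, which integrates harmonic products exactly up to a
declared degree; orthonormality then holds to machine precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import sph_harm_y

from .domain import SpatialDomain

__all__ = [
    "SphereDomain",
    "SphericalModeSet",
    "spherical_harmonics",
    "sphere_eigenvalue",
    "complex_harmonic",
    "real_harmonic",
    "lm_pairs",
]


def sphere_eigenvalue(l: int, radius: float = 1.0) -> float:
    """Helmholtz eigenvalue ``k^2 = l(l+1)/R_s^2`` (m^-2); m-independent."""
    if l < 0:
        raise ValueError("degree l must be >= 0")
    if radius <= 0:
        raise ValueError("radius must be positive")
    return l * (l + 1) / radius ** 2


def lm_pairs(l_max: int) -> list[tuple[int, int]]:
    """(l, m) indices in (l, m) lexicographic order; (l_max+1)^2 of them."""
    return [(l, m) for l in range(l_max + 1) for m in range(-l, l + 1)]


def complex_harmonic(l: int, m: int, theta: np.ndarray,
                     phi: np.ndarray) -> np.ndarray:
    """Orthonormal complex ``Y_lm(theta, phi)`` (Condon–Shortley phase)."""
    return sph_harm_y(l, m, theta, phi)


def real_harmonic(l: int, m: int, theta: np.ndarray,
                  phi: np.ndarray) -> np.ndarray:
    """Real spherical harmonic built from ``Y_lm`` and ``Y_l,-m``.

    m > 0: ``(-1)^m (Y_lm + Y_lm^*) / sqrt(2)`` (cosine type);
    m = 0: ``Y_l0`` (already real);
    m < 0: ``-i (-1)^m (Y_l|m| - Y_l|m|^*) / sqrt(2)`` (sine type).
    """
    if m == 0:
        return np.real(sph_harm_y(l, 0, theta, phi))
    Y = sph_harm_y(l, abs(m), theta, phi)
    sign = (-1.0) ** m
    if m > 0:
        return sign * np.sqrt(2.0) * np.real(Y)
    return sign * np.sqrt(2.0) * np.imag(Y)


@dataclass
class SphereDomain:
    """Sphere of radius R_s with a product quadrature grid.

    ``exact_degree`` is the highest combined harmonic degree whose surface
    integrals the grid evaluates exactly; orthonormality of modes up to
    ``l_max`` needs ``exact_degree >= 2 l_max``, triple products (Gaunt
    integrals) need ``3 l_max``.
    """

    radius: float = 1.0
    exact_degree: int = 16
    theta: np.ndarray = field(init=False, repr=False)
    phi: np.ndarray = field(init=False, repr=False)
    weights: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        deg = max(int(self.exact_degree), 2)
        # Gauss-Legendre with n nodes is exact for polynomials of degree
        # 2n - 1 in cos(theta); uniform phi grid with n_phi points is exact
        # for e^{i m phi} with |m| < n_phi.
        n_theta = deg // 2 + 1
        n_phi = 2 * deg + 1
        x, wx = np.polynomial.legendre.leggauss(n_theta)
        th = np.arccos(x)
        ph = 2.0 * np.pi * np.arange(n_phi) / n_phi
        wphi = 2.0 * np.pi / n_phi
        TH, PH = np.meshgrid(th, ph, indexing="ij")
        WT = np.broadcast_to((wx * wphi)[:, None], TH.shape)
        self.theta = TH.ravel()
        self.phi = PH.ravel()
        self.weights = (WT.ravel() * self.radius ** 2).copy()

    @property
    def point_count(self) -> int:
        return self.weights.size

    @property
    def area(self) -> float:
        return float(self.weights.sum())

    def positions(self) -> np.ndarray:
        """Cartesian coordinates of the quadrature nodes."""
        st = np.sin(self.theta)
        return self.radius * np.column_stack(
            [st * np.cos(self.phi), st * np.sin(self.phi), np.cos(self.theta)]
        )

    def to_spatial_domain(self) -> SpatialDomain:
        return SpatialDomain(positions=self.positions(),
                             area_weights=self.weights)

    def integrate(self, values: np.ndarray) -> complex | float:
        """Surface integral ``int f dS`` over the quadrature grid."""
        return np.sum(np.asarray(values).ravel() * self.weights)


@dataclass
class SphericalModeSet:
    """Spherical harmonics up to ``l_max`` sampled on a SphereDomain.

    ``modes`` is a (K, (l_max+1)^2) array whose columns follow ``lm_index``.
    Columns are orthonormal under the area-weighted quadrature inner product
    (normalized by R_s^2 so that modes carry unit surface norm).
    """

    domain: SphereDomain
    l_max: int
    kind: str  # "complex" | "real"
    modes: np.ndarray
    lm_index: list[tuple[int, int]]

    @property
    def n_modes(self) -> int:
        return self.modes.shape[1]

    def eigenvalues(self) -> np.ndarray:
        """``k_lm^2 = l(l+1)/R_s^2`` for each column."""
        return np.array([sphere_eigenvalue(l, self.domain.radius)
                         for l, _ in self.lm_index])

    def gram(self) -> np.ndarray:
        """Quadrature Gram matrix; identity for an orthonormal set."""
        W = self.domain.weights
        return self.modes.conj().T @ (W[:, None] * self.modes)

    def column(self, l: int, m: int) -> np.ndarray:
        return self.modes[:, self.lm_index.index((l, m))]

    def degree_block(self, l: int) -> np.ndarray:
        """All 2l+1 columns of degree l."""
        idx = [i for i, (ll, _) in enumerate(self.lm_index) if ll == l]
        return self.modes[:, idx]


def spherical_harmonics(domain: SphereDomain, l_max: int,
                        kind: str = "real") -> SphericalModeSet:
    """Sample the harmonic basis up to degree ``l_max`` on the grid.

    The returned modes are normalized against the *surface* measure of the
    domain (radius included), so that the quadrature Gram matrix is the
    identity for any sphere radius.
    """
    if l_max < 0:
        raise ValueError("l_max must be >= 0")
    if kind not in ("real", "complex"):
        raise ValueError(f"kind must be 'real' or 'complex', got {kind!r}")
    if domain.exact_degree < 2 * l_max:
        raise ValueError(
            f"quadrature exact to degree {domain.exact_degree} cannot "
            f"orthonormalize modes up to l_max={l_max}; rebuild the domain "
            f"with exact_degree >= {2 * l_max}"
        )
    pairs = lm_pairs(l_max)
    th, ph = domain.theta, domain.phi
    fn = real_harmonic if kind == "real" else complex_harmonic
    cols = [fn(l, m, th, ph) for l, m in pairs]
    modes = np.column_stack(cols) / domain.radius  # unit norm on radius R_s
    return SphericalModeSet(domain=domain, l_max=l_max, kind=kind,
                            modes=modes, lm_index=pairs)
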