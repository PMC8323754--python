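"""Seeded synthetic fixtures.

Everything any analysis in this package consumes can be generated here
deterministically: icospheres and deformed spheres (re-exported from the
mesh module), synthetic FC matrices with a prescribed eigen-spectrum,
two-mode beating records, and white-noise records.  Identical spec + seed
gives bitwise-identical output.
"""

from __future__ import annotations

import numpy as np

from .connectivity import CovarianceSpectrum, ModeBasis
from .domain import SpatialDomain
from .mesh import make_deformed_sphere, make_icosphere  # noqa: F401 re-export
from .simulate import ActivityTimeSeries, TwoModeConfig, two_mode_signal

__all__ = [
    "make_icosphere",
    "make_deformed_sphere",
    "random_orthonormal_basis",
    "make_synthetic_fc",
    "make_two_mode_record",
    "make_white_noise_record",
]


def random_orthonormal_basis(domain: SpatialDomain, n_modes: int,
                             seed: int = 0) -> ModeBasis:
    """Random area-weight-orthonormal basis (QR of white noise in the
    half-weighted coordinates)."""
    rng = np.random.default_rng(seed)
    K = domain.point_count
    if n_modes > K:
        raise ValueError("cannot draw more modes than grid points")
    G = rng.standard_normal((K, n_modes))
    Q, _ = np.linalg.qr(G)
    U = Q / np.sqrt(domain.area_weights)[:, None]
    return ModeBasis(modes=U, domain=domain)


def make_synthetic_fc(basis: ModeBasis, kappa: np.ndarray,
                      noise_level: float = 0.0, seed: int = 0
                      ) -> tuple[CovarianceSpectrum, ModeBasis, np.ndarray]:
    """Covariance with prescribed spectrum: ``C_hat = U diag(kappa) U^T W``.

    Optional symmetric noise (Frobenius fraction ``noise_level``) is added
    to the raw kernel.  Returns the covariance plus the generating modes
    and eigenvalues as ground truth for recovery tests.
    """
    kappa = np.asarray(kappa, dtype=float)
    if np.any(kappa < 0):
        raise ValueError("eigenvalue profile kappa must be nonnegative")
    if kappa.size != basis.n_modes:
        raise ValueError("kappa must have one entry per basis mode")
    W = basis.domain.area_weights
    U = basis.modes
    raw = (U * kappa[None, :]) @ U.T  # symmetric kernel
    if noise_level > 0:
        rng = np.random.default_rng(seed)
        E = rng.standard_normal(raw.shape)
        E = 0.5 * (E + E.T)
        raw = raw + noise_level * np.linalg.norm(raw) * E / np.linalg.norm(E)
    weighted = raw * W[None, :]
    cov = CovarianceSpectrum(matrix=weighted,
                             domain=basis.domain)
    return cov, basis, kappa


def make_two_mode_record(cfg: TwoModeConfig | None = None,
                         n_points: int = 64, duration: float = 60.0,
                         dt: float = 0.01) -> tuple[ActivityTimeSeries,
                                                    SpatialDomain,
                                                    TwoModeConfig]:
    """Two-mode beating record on a uniform periodic grid."""
    cfg = cfg or TwoModeConfig()
    dx = cfg.length / n_points
    x = np.arange(n_points) * dx
    t = np.arange(int(round(duration / dt))) * dt
    q = two_mode_signal(cfg, x, t)
    domain = SpatialDomain(positions=x[:, None],
                           area_weights=np.full(n_points, dx))
    ts = ActivityTimeSeries(values=q, dt=dt, domain=domain,
                            provenance="simulated")
    return ts, domain, cfg


def make_white_noise_record(n_channels: int = 8, duration: float = 100.0,
                            dt: float = 0.1, seed: int = 0,
                            sigma: float = 1.0) -> ActivityTimeSeries:
    """Independent Gaussian white noise per channel."""
    rng = np.random.default_rng(seed)
    n = int(round(duration / dt))
    vals = sigma * rng.standard_normal((n_channels, n))
    domain = SpatialDomain.uniform(n_channels)
    return ActivityTimeSeries(values=vals, dt=dt, domain=domain,
                              provenance="simulated")
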