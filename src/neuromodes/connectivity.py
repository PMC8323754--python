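"""Discretized neural-field connectivity algebra.

Linear neural field theory relates three frequency-domain operators on the
cortical surface:

* the *direct* effective connectivity (EC) kernel ``Lambda(r, r', omega)``,
  giving the strength of one-hop propagation;
* the *total* EC or transfer function ``T = (I - Lambda_hat)^{-1}``, the
  Green function of the system (equivalently the evoked response);
* the normalized cross-spectrum / covariance ``C_hat = T_hat T_hat^dagger``
  under spatially white input drive.

The discrete matrices carry the area weights of the sampling grid:
``Lambda_hat[j, k] = Lambda[j, k] * dS_k``, which makes them dimensionless
and turns matrix multiplication into the discrete surface integral.  All
three operators commute for symmetric connectivity and share one real
orthonormal eigenbasis ``u_j``, with eigenvalues related by

    theta_j = 1 / (1 - lambda_j),      kappa_j = |theta_j|^2.

This module implements those relations, their inverses (EC from FC), the
eigendecomposition with an area-weighted inner product, spectral (mode-sum)
reconstruction, and the FC-similarity operator ``S = C^2``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .domain import SpatialDomain

__all__ = [
    "DirectEC",
    "TransferFunction",
    "CovarianceSpectrum",
    "ModeBasis",
    "EigenSpectrum",
    "InputDrive",
    "MarginalStabilityError",
    "weight_ec",
    "transfer_from_ec",
    "ec_from_transfer",
    "transfer_series",
    "covariance_from_transfer",
    "eigendecompose_cov",
    "eigen_relations",
    "spectral_reconstruct",
    "similarity",
    "infer_input",
    "ec_from_covariance",
    "fix_sign",
]

#: condition number above which linear solves refuse to proceed
COND_RAISE = 1e12
#: condition number above which a warning is issued
COND_WARN = 1e8


class MarginalStabilityError(np.linalg.LinAlgError):
    """Raised when ``I - Lambda_hat`` (or a transfer matrix) is singular or
    so ill conditioned that the system is critically / marginally stable."""


def _check_condition(mat: np.ndarray, context: str) -> float:
    cond = np.linalg.cond(mat)
    if cond > COND_RAISE or not np.isfinite(cond):
        raise MarginalStabilityError(
            f"{context}: condition number {cond:.3g} exceeds {COND_RAISE:.0e}; "
            "the system is critically or marginally stable"
        )
    if cond > COND_WARN:
        warnings.warn(
            f"{context}: condition number {cond:.3g} in the warning band "
            f"[{COND_WARN:.0e}, {COND_RAISE:.0e}]",
            RuntimeWarning,
            stacklevel=3,
        )
    return cond


def fix_sign(vectors: np.ndarray) -> np.ndarray:
    """Deterministic sign convention for eigenvector columns.

    The component of largest absolute value in each column is made positive
    (real part for complex vectors); ties resolved by the first such index.
    """
    v = np.array(vectors, copy=True)
    for j in range(v.shape[1]):
        i = int(np.argmax(np.abs(v[:, j])))
        pivot = v[i, j].real if np.iscomplexobj(v) else v[i, j]
        if pivot < 0:
            v[:, j] = -v[:, j]
    return v


@dataclass
class DirectEC:
    """Direct effective connectivity at one frequency.

    ``raw`` is the continuum kernel sampled on the grid (units m^-2);
    ``weighted`` is the dimensionless matrix ``raw * diag(dS)`` that enters
    all matrix formulas.
    """

    raw: np.ndarray
    domain: SpatialDomain
    frequency: float = 0.0
    symmetric: bool | None = None
    weighted: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        raw = np.asarray(self.raw)
        K = self.domain.point_count
        if raw.shape != (K, K):
            raise ValueError(
                f"raw EC kernel is {raw.shape}, domain has {K} points"
            )
        self.raw = raw
        self.weighted = raw * self.domain.area_weights[None, :]
        if self.symmetric is None:
            self.symmetric = bool(
                np.allclose(raw, raw.T, rtol=0.0, atol=1e-12 * max(1.0, np.abs(raw).max()))
            )

    @property
    def point_count(self) -> int:
        return self.domain.point_count

    @classmethod
    def from_weighted(cls, weighted: np.ndarray, domain: SpatialDomain,
                      frequency: float = 0.0) -> "DirectEC":
        """Build from an already area-weighted (dimensionless) matrix."""
        raw = np.asarray(weighted) / domain.area_weights[None, :]
        return cls(raw=raw, domain=domain, frequency=frequency)


@dataclass
class TransferFunction:
    """Total EC / system transfer function ``T_hat`` (dimensionless)."""

    matrix: np.ndarray
    domain: SpatialDomain
    frequency: float = 0.0
    provenance: str = "measured"  # from_ec | from_modes | measured

    def __post_init__(self) -> None:
        mat = np.asarray(self.matrix)
        K = self.domain.point_count
        if mat.shape != (K, K):
            raise ValueError(f"transfer matrix is {mat.shape}, domain has {K} points")
        self.matrix = mat


@dataclass
class CovarianceSpectrum:
    """Normalized cross-spectrum / covariance ``C_hat`` (Hermitian PSD)."""

    matrix: np.ndarray
    domain: SpatialDomain
    frequency: float = 0.0
    noise_normalization: float = 1.0  # N0, m^2 (metadata only)

    def __post_init__(self) -> None:
        mat = np.asarray(self.matrix)
        K = self.domain.point_count
        if mat.shape != (K, K):
            raise ValueError(f"covariance matrix is {mat.shape}, domain has {K} points")
        scale = max(1.0, np.abs(mat).max())
        # Hermitian under the area-weighted inner product: the underlying
        # kernel C(r, r') must be symmetric, i.e. W^{1/2} C_raw W^{1/2}
        # = W^{1/2} C_hat W^{-1/2} Hermitian.  On uniform grids this is the
        # plain Hermitian condition.
        sqw = np.sqrt(self.domain.area_weights)
        B = (sqw[:, None] * mat) / sqw[None, :]
        herm_err = np.abs(B - B.conj().T).max()
        if herm_err > 1e-10 * scale:
            raise ValueError(
                "covariance kernel is not Hermitian under the area-weighted "
                f"inner product (max asymmetry {herm_err:.3g})"
            )
        self.matrix = mat


@dataclass
class ModeBasis:
    """Real area-weight-orthonormal spatial modes (columns of ``modes``).

    Satisfies ``U^T diag(dS) U = I``; on uniform grids this is plain
    orthonormality up to the constant weight.
    """

    modes: np.ndarray
    domain: SpatialDomain
    ordering: str = "descending_kappa"
    degenerate_blocks: list[list[int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        U = np.asarray(self.modes, dtype=float)
        if U.ndim != 2 or U.shape[0] != self.domain.point_count:
            raise ValueError("modes must be K x J with K matching the domain")
        self.modes = U

    @property
    def n_modes(self) -> int:
        return self.modes.shape[1]

    def gram(self) -> np.ndarray:
        """``U^T diag(dS) U`` — identity for an orthonormal basis."""
        W = self.domain.area_weights
        return self.modes.T @ (W[:, None] * self.modes)

    def check_orthonormal(self, tol: float = 1e-8) -> bool:
        G = self.gram()
        return bool(np.abs(G - np.eye(self.n_modes)).max() < tol)

    def project(self, values: np.ndarray) -> np.ndarray:
        """Area-weighted projection ``c_j = sum_k u_j(r_k) v_k dS_k``.

        ``values`` may be a K-vector or a K x N array (one column per time
        sample); the mode index is the leading axis of the result.
        """
        values = np.asarray(values)
        W = self.domain.area_weights
        if values.ndim == 1:
            return self.modes.T @ (W * values)
        return self.modes.T @ (W[:, None] * values)


@dataclass
class EigenSpectrum:
    """Eigenvalues of the commuting operator family at one frequency.

    Any of the three arrays may be None until populated; the populated ones
    must satisfy ``theta = 1/(1 - lam)`` and ``kappa = |theta|^2``.
    """

    lam: np.ndarray | None = None     # direct-EC eigenvalues lambda_j
    theta: np.ndarray | None = None   # transfer eigenvalues
    kappa: np.ndarray | None = None   # covariance eigenvalues

    def validate(self, tol: float = 1e-12) -> None:
        if self.lam is not None and self.theta is not None:
            err = np.abs(self.theta - 1.0 / (1.0 - self.lam)).max()
            if err > tol * max(1.0, np.abs(self.theta).max()):
                raise ValueError(f"theta != 1/(1-lambda): max error {err:.3g}")
        if self.theta is not None and self.kappa is not None:
            err = np.abs(self.kappa - np.abs(self.theta) ** 2).max()
            if err > tol * max(1.0, np.abs(self.kappa).max()):
                raise ValueError(f"kappa != |theta|^2: max error {err:.3g}")


@dataclass
class InputDrive:
    """External drive N.  White drive has cross-spectrum ``N0^2 I``."""

    values: np.ndarray | None = None
    white: bool = True
    normalization: float = 1.0  # N0, m^2
    seed: int | None = None

    def cross_spectrum(self, point_count: int) -> np.ndarray:
        if self.white:
            return self.normalization ** 2 * np.eye(point_count)
        v = np.atleast_2d(self.values)
        return (v @ v.conj().T) / v.shape[1]


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def weight_ec(raw: np.ndarray, domain: SpatialDomain,
              frequency: float = 0.0) -> DirectEC:
    """Area-weight a raw EC kernel: ``Lambda_hat[j,k] = raw[j,k] dS_k``."""
    return DirectEC(raw=np.asarray(raw), domain=domain, frequency=frequency)


def transfer_from_ec(ec: DirectEC) -> TransferFunction:
    """Total EC from direct EC: ``T_hat = (I - Lambda_hat)^{-1}``."""
    K = ec.point_count
    A = np.eye(K) - ec.weighted
    _check_condition(A, "transfer_from_ec")
    T = np.linalg.solve(A, np.eye(K))
    return TransferFunction(matrix=T, domain=ec.domain,
                            frequency=ec.frequency, provenance="from_ec")


def ec_from_transfer(t: TransferFunction) -> DirectEC:
    """Direct EC from total EC: ``Lambda_hat = I - T_hat^{-1}``."""
    K = t.matrix.shape[0]
    _check_condition(t.matrix, "ec_from_transfer")
    lam_w = np.eye(K) - np.linalg.solve(t.matrix, np.eye(K))
    return DirectEC.from_weighted(lam_w, t.domain, frequency=t.frequency)


def transfer_series(ec: DirectEC, order: int) -> TransferFunction:
    """Neumann partial sum ``I + Lambda_hat + ... + Lambda_hat^order``.

    Converges to ``transfer_from_ec`` iff the spectral radius of
    ``Lambda_hat`` is below 1; otherwise a warning is issued and the
    (divergent) partial sum is still returned.
    """
    if order < 0:
        raise ValueError("order must be >= 0")
    L = ec.weighted
    rho = np.abs(np.linalg.eigvals(L)).max()
    if rho >= 1.0:
        warnings.warn(
            f"spectral radius {rho:.3g} >= 1: the propagator series is "
            "outside its radius of convergence",
            RuntimeWarning,
            stacklevel=2,
        )
    K = L.shape[0]
    total = np.eye(K, dtype=L.dtype)
    term = np.eye(K, dtype=L.dtype)
    for _ in range(order):
        term = term @ L
        total = total + term
    return TransferFunction(matrix=total, domain=ec.domain,
                            frequency=ec.frequency, provenance="from_ec")


def covariance_from_transfer(t: TransferFunction,
                             n0: float = 1.0) -> CovarianceSpectrum:
    """White-noise cross-spectrum ``C_hat = T_hat T_hat^dagger``."""
    C = t.matrix @ t.matrix.conj().T
    return CovarianceSpectrum(matrix=C, domain=t.domain,
                              frequency=t.frequency, noise_normalization=n0)


DEGENERACY_GAP = 1e-8


def _degenerate_blocks(values: np.ndarray, rel_gap: float = DEGENERACY_GAP
                       ) -> list[list[int]]:
    """Group indices of (sorted) eigenvalues whose relative gap < rel_gap."""
    scale = max(np.abs(values).max(), 1e-300)
    blocks: list[list[int]] = []
    current = [0]
    for i in range(1, values.size):
        if abs(values[i] - values[i - 1]) < rel_gap * scale:
            current.append(i)
        else:
            blocks.append(current)
            current = [i]
    blocks.append(current)
    return [b for b in blocks if len(b) > 1]


def eigendecompose_cov(c: CovarianceSpectrum, domain: SpatialDomain | None = None
                       ) -> tuple[ModeBasis, EigenSpectrum]:
    """Eigenmodes of a covariance with the area-weighted inner product.

    Solves ``C_hat u_j = kappa_j u_j`` such that ``U^T diag(dS) U = I``.
    The weighted matrix ``C_hat = C_raw diag(dS)`` is similar to the
    symmetric ``W^{1/2} C_raw W^{1/2}``, which is what is actually
    diagonalized; modes are returned sorted by descending ``|kappa|`` with a
    deterministic sign fix.  Degenerate eigenvalue groups (relative gap
    below 1e-8) are recorded so comparisons can be made on subspace
    projectors rather than individual vectors.
    """
    domain = domain or c.domain
    W = domain.area_weights
    sqw = np.sqrt(W)
    # similarity transform to a plain symmetric problem:
    # W^{1/2} C_raw W^{1/2} = W^{1/2} C_hat W^{-1/2}
    B = (sqw[:, None] * c.matrix) / sqw[None, :]
    herm_err = np.abs(B - B.conj().T).max()
    if herm_err > 1e-8 * max(1.0, np.abs(B).max()):
        raise ValueError(
            "covariance kernel is not symmetric under the area-weighted "
            f"inner product (max asymmetry {herm_err:.3g})"
        )
    B = 0.5 * (B + B.conj().T)
    kappa, Y = np.linalg.eigh(B)
    order = np.argsort(-np.abs(kappa), kind="stable")
    kappa = kappa[order]
    U = (Y[:, order] / sqw[:, None])
    if np.iscomplexobj(U):
        if np.abs(U.imag).max() < 1e-12:
            U = U.real
    U = fix_sign(U)
    blocks = _degenerate_blocks(kappa)
    basis = ModeBasis(modes=np.real(U), domain=domain,
                      degenerate_blocks=blocks)
    return basis, EigenSpectrum(kappa=kappa)


def eigen_relations(lam: complex | np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Map direct-EC eigenvalues to transfer and covariance eigenvalues.

    ``theta = 1/(1 - lambda)`` and ``kappa = |theta|^2``.
    """
    lam = np.asarray(lam)
    if np.any(np.abs(1.0 - lam) < 1e-14):
        raise MarginalStabilityError(
            "lambda = 1: the mode is marginally stable and theta diverges"
        )
    theta = 1.0 / (1.0 - lam)
    kappa = np.abs(theta) ** 2
    if theta.ndim == 0:
        return complex(theta), float(kappa)
    return theta, kappa


def spectral_reconstruct(basis: ModeBasis, eigenvalues: np.ndarray,
                         truncation: int | None = None,
                         return_partial: bool = False):
    """Mode-sum reconstruction ``sum_j kappa_j u_j u_j^T diag(dS)``.

    With ``truncation = J`` (all modes) the reconstruction is exact to
    machine precision.  ``return_partial=True`` additionally returns the
    per-mode rank-1 contributions, for cumulative-contribution displays.
    """
    eigenvalues = np.asarray(eigenvalues)
    J = basis.n_modes
    Jp = J if truncation is None else int(truncation)
    if Jp > J:
        raise ValueError(f"truncation {Jp} exceeds available modes {J}")
    W = basis.domain.area_weights
    U = basis.modes
    terms = []
    K = U.shape[0]
    total = np.zeros((K, K), dtype=eigenvalues.dtype)
    for j in range(Jp):
        term = eigenvalues[j] * np.outer(U[:, j], U[:, j]) * W[None, :]
        total = total + term
        if return_partial:
            terms.append(term)
    if return_partial:
        return total, terms
    return total


def similarity(c: CovarianceSpectrum) -> np.ndarray:
    """FC-pattern similarity operator ``S_hat = C_hat^2``.

    The (r1, r2) entry is the area-weighted dot product of the FC patterns
    emanating from r1 and r2; it shares eigenvectors with ``C_hat`` and its
    eigenvalues are ``kappa_j^2``.
    """
    return c.matrix @ c.matrix


def infer_input(t: TransferFunction, q: np.ndarray) -> np.ndarray:
    """Invert the forward map: ``N = T_hat^{-1} Q``."""
    _check_condition(t.matrix, "infer_input")
    return np.linalg.solve(t.matrix, np.asarray(q))


def ec_from_covariance(c: CovarianceSpectrum,
                       domain: SpatialDomain | None = None) -> DirectEC:
    """Direct EC from a symmetric covariance via the eigenvalue relations.

    Takes the positive root ``theta_j = sqrt(kappa_j)`` (the stable branch
    for a real symmetric system), maps ``lambda_j = 1 - 1/theta_j``, and
    reassembles ``Lambda_hat = sum_j lambda_j u_j u_j^T diag(dS)``.
    """
    domain = domain or c.domain
    basis, spec = eigendecompose_cov(c, domain)
    kappa = np.real(spec.kappa)
    if np.any(kappa <= 0):
        raise MarginalStabilityError(
            "covariance has nonpositive eigenvalues; EC inversion requires "
            "a positive-definite FC"
        )
    theta = np.sqrt(kappa)
    lam = 1.0 - 1.0 / theta
    lam_w = spectral_reconstruct(basis, lam)
    return DirectEC.from_weighted(lam_w, domain, frequency=c.frequency)
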