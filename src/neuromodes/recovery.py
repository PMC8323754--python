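"""Recovery of modal transfer coefficients from sparse evoked responses.

The evoked response to a point stimulus at r0 is the Green function
``T(r, r0, tau) = sum_j u_j(r) u_j(r0) theta_j(tau)``.  Sampling it at M
measurement points r_k gives, for each lag tau, the linear system

    a_k(tau) = sum_j b_kj theta_j(tau),      b_kj = u_j(r_k) u_j(r0),

which can be inverted for the modal coefficients theta_j(tau) — and hence
the full transfer function and, via ``Lambda = I - T^{-1}``, the direct EC
— provided the design matrix ``B`` is well conditioned.  Conditioning
degrades as the stimulus (or a measurement point) approaches a zero of a
retained mode, in which case the remedy is to add or substitute
measurement points.

The fit is an independent least-squares solve per lag (optionally ridge
regularized for noisy data); with noiseless data from J <= M modes and a
full-rank design the recovery is exact.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .connectivity import ModeBasis

__all__ = [
    "RecoveryProblem",
    "RecoveryResult",
    "build_design",
    "recover_theta",
    "theta_from_full_response",
    "assemble_transfer",
]

#: |u_j(r0)| below this fraction of the mode's max amplitude is an error
ZERO_THRESHOLD = 1e-3
#: warning tier
ZERO_WARN = 1e-2


@dataclass
class RecoveryProblem:
    """Sparse evoked-response inversion problem.

    ``responses[k, n]`` is a_k(tau_n) measured at point index k;
    ``point_indices`` locate the M measurement points in the basis domain,
    ``r0_index`` the stimulus.  ``n_modes`` retained modes default to
    min(M, J_available).
    """

    basis: ModeBasis
    r0_index: int
    point_indices: np.ndarray
    responses: np.ndarray
    tau: np.ndarray
    n_modes: int | None = None
    noise_level: float = 0.0
    ridge: float = 0.0

    def __post_init__(self) -> None:
        self.point_indices = np.asarray(self.point_indices, dtype=int)
        self.responses = np.atleast_2d(np.asarray(self.responses, float))
        self.tau = np.asarray(self.tau, dtype=float)
        K = self.basis.modes.shape[0]
        if self.point_indices.size < 1:
            raise ValueError("need at least one measurement point")
        for idx in np.concatenate([[self.r0_index], self.point_indices]):
            if not 0 <= idx < K:
                raise ValueError(f"point index {idx} outside the domain "
                                 f"(K = {K})")
        if self.responses.shape != (self.point_indices.size, self.tau.size):
            raise ValueError("responses must be (n_points, n_tau)")
        if self.n_modes is None:
            self.n_modes = min(self.point_indices.size, self.basis.n_modes)


@dataclass
class RecoveryResult:
    """Recovered theta_j(tau) with design diagnostics."""

    theta: np.ndarray           # (J, n_tau)
    tau: np.ndarray
    design: np.ndarray          # (M, J)
    condition_number: float
    residuals: np.ndarray       # per-tau ||B theta - a||
    mode_indices: np.ndarray

    def summary(self) -> str:
        lines = [
            "Sparse evoked-response transfer recovery",
            f"  modes retained : {self.theta.shape[0]}",
            f"  measurements   : {self.design.shape[0]} points x "
            f"{self.tau.size} lags",
            f"  design cond    : {self.condition_number:.3g}",
            f"  residual (max) : {self.residuals.max():.3g}",
            f"  residual (mean): {self.residuals.mean():.3g}",
        ]
        return "\n".join(lines)


def build_design(basis: ModeBasis, r0_index: int,
                 point_indices: np.ndarray,
                 n_modes: int | None = None) -> tuple[np.ndarray, float]:
    """Design matrix ``b_kj = u_j(r_k) u_j(r0)`` and its condition number.

    Warns when the stimulus sits near a zero of a retained mode (the
    corresponding column is then tiny and the inversion ill conditioned);
    raises when it sits essentially on the zero.
    """
    point_indices = np.asarray(point_indices, dtype=int)
    J = n_modes if n_modes is not None else min(point_indices.size,
                                                basis.n_modes)
    U = basis.modes[:, :J]
    u0 = U[r0_index, :]
    umax = np.abs(U).max(axis=0)
    frac = np.abs(u0) / np.where(umax > 0, umax, 1.0)
    dead = np.nonzero(frac < ZERO_THRESHOLD)[0]
    if dead.size:
        raise ValueError(
            f"stimulus point {r0_index} lies on a zero of retained mode(s) "
            f"{dead.tolist()} (|u_j(r0)| < {ZERO_THRESHOLD:g} of the mode "
            "maximum); move the stimulus or drop those modes"
        )
    weak = np.nonzero(frac < ZERO_WARN)[0]
    if weak.size:
        warnings.warn(
            f"stimulus is very near a zero of mode(s) {weak.tolist()}; "
            "conditioning will be poor",
            RuntimeWarning, stacklevel=2)
    B = U[point_indices, :] * u0[None, :]
    cond = float(np.linalg.cond(B))
    return B, cond


def recover_theta(problem: RecoveryProblem) -> RecoveryResult:
    """Least-squares inversion of the sparse evoked-response system.

    Solves ``B theta(tau) = a(tau)`` independently at each lag (ridge
    penalty optional).  Raises on rank-deficient designs with the standard
    remedy in the message.
    """
    B, cond = build_design(problem.basis, problem.r0_index,
                           problem.point_indices, problem.n_modes)
    J = B.shape[1]
    rank = np.linalg.matrix_rank(B)
    if rank < J:
        raise ValueError(
            f"design matrix rank {rank} < {J} retained modes; add or "
            "substitute more measurement points"
        )
    if problem.ridge > 0:
        A = B.T @ B + problem.ridge * np.eye(J)
        theta = np.linalg.solve(A, B.T @ problem.responses)
    else:
        theta, *_ = np.linalg.lstsq(B, problem.responses, rcond=None)
    residuals = np.linalg.norm(B @ theta - problem.responses, axis=0)
    return RecoveryResult(theta=theta, tau=problem.tau, design=B,
                          condition_number=cond, residuals=residuals,
                          mode_indices=np.arange(J))


def theta_from_full_response(response: np.ndarray, basis: ModeBasis,
                             r0_index: int,
                             n_modes: int | None = None) -> np.ndarray:
    """Modal coefficients from a densely sampled response.

    ``theta_j(tau) = (1/u_j(r0)) sum_k u_j(r_k) T(r_k, r0, tau) dS_k`` —
    the area-weighted projection of the response divided by the mode
    amplitude at the stimulus.  Requires |u_j(r0)| above threshold for
    every retained mode.
    """
    response = np.atleast_2d(np.asarray(response, dtype=float))
    J = n_modes if n_modes is not None else basis.n_modes
    U = basis.modes[:, :J]
    u0 = U[r0_index, :]
    umax = np.abs(U).max(axis=0)
    frac = np.abs(u0) / np.where(umax > 0, umax, 1.0)
    dead = np.nonzero(frac < ZERO_THRESHOLD)[0]
    if dead.size:
        raise ValueError(
            f"u_j(r0) is below threshold for retained mode(s) "
            f"{dead.tolist()}; cannot divide by the stimulus amplitude"
        )
    W = basis.domain.area_weights
    proj = U.T @ (W[:, None] * response)  # (J, n_tau)
    return proj / u0[:, None]


def assemble_transfer(basis: ModeBasis, theta: np.ndarray,
                      row_indices: np.ndarray | None = None,
                      col_indices: np.ndarray | None = None) -> np.ndarray:
    """Outer-product synthesis ``T(r, r', tau) = sum_j u_j(r) u_j(r') theta_j``.

    Returns a (n_rows, n_cols, n_tau) array on the requested point pairs
    (defaults to the full grid).  Symmetric in (r, r') for real bases.
    """
    theta = np.atleast_2d(np.asarray(theta, dtype=float))
    J = theta.shape[0]
    U = basis.modes[:, :J]
    rows = U if row_indices is None else U[np.asarray(row_indices, int), :]
    cols = U if col_indices is None else U[np.asarray(col_indices, int), :]
    # einsum over modes: T[a, b, n] = sum_j rows[a, j] cols[b, j] theta[j, n]
    return np.einsum("aj,bj,jn->abn", rows, cols, theta)
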