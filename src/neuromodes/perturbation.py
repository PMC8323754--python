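"""Selection rules, spherical-mode perturbation theory, and gain feedback.

Convolutions of the cortex (and any other smooth parameter variation) act
on the spherical eigenmodes as a perturbation of the Helmholtz operator.
Expanding the perturbation in spherical harmonics, ``V(Omega) = sum a_l'm'
Y_l'm'``, the matrix elements that mix mode (l, m) into (l1, m1) are
proportional to the Gaunt integrals

    G = int Y*_{l1 m1} Y_{l' m'} Y_{l m} dOmega,

which vanish unless the selection rules

    m' = m1 - m      and      |l1 - l| <= l' <= l1 + l

hold (conservation of angular momentum in quantum-mechanical language).
Consequently strong but spatially fine perturbations (high l') cannot mix
the low-order modes that dominate large-scale activity: the low modes are
structurally robust, which is what licenses using a fixed long-term basis
for dynamic-FC tracking.

The module also implements activity-dependent gain feedback on the direct
EC: if local gain dynamics obey a temporal operator Z(omega), the feedback
contributes

    L[i,j] = Z Lambda0[i,j] Q0[j] / (1 - Z Q0[j]),

and the perturbed transfer function is ``T = (I - Lambda0 - L)^{-1}``.
Gaunt values are evaluated exactly (Wigner-3j route via sympy) so that
selection-rule zeros are hard zeros, not small floats.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Callable, Sequence

import numpy as np

from .connectivity import (DirectEC, MarginalStabilityError, TransferFunction,
                           fix_sign)
from .sphere import SphericalModeSet, lm_pairs, sphere_eigenvalue

__all__ = [
    "GauntQuery",
    "gaunt",
    "selection_allowed",
    "PerturbationField",
    "FirstOrderCorrection",
    "first_order_perturb",
    "GainFeedbackSpec",
    "gain_feedback_ec",
    "perturbed_transfer",
    "low_pass_gain",
]


@dataclass(frozen=True)
class GauntQuery:
    """Three harmonic index pairs: (l1, m1 | l', m' | l, m)."""

    l1: int
    m1: int
    lp: int
    mp: int
    l: int
    m: int

    def __post_init__(self) -> None:
        for l, m, name in ((self.l1, self.m1, "1"), (self.lp, self.mp, "'"),
                           (self.l, self.m, "")):
            if l < 0 or abs(m) > l:
                raise ValueError(
                    f"invalid harmonic index (l{name}, m{name}) = ({l}, {m})"
                )


def selection_allowed(q: GauntQuery) -> bool:
    """Angular-momentum selection rules for the triple overlap.

    True iff ``m' = m1 - m`` and ``|l1 - l| <= l' <= l1 + l``.  (An allowed
    query may still integrate to zero by parity when ``l1 + l' + l`` is
    odd; a disallowed one is always exactly zero.)
    """
    return (q.mp == q.m1 - q.m) and (abs(q.l1 - q.l) <= q.lp <= q.l1 + q.l)


@lru_cache(maxsize=200_000)
def _gaunt_exact(l1: int, l2: int, l3: int, m1: int, m2: int, m3: int) -> float:
    import warnings

    from sympy.physics.wigner import gaunt as sympy_gaunt

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", DeprecationWarning)
        return float(sympy_gaunt(l1, l2, l3, m1, m2, m3).evalf(17))


def gaunt(q: GauntQuery) -> float:
    """Exact Gaunt integral ``int Y*_{l1 m1} Y_{l' m'} Y_{l m} dOmega``.

    Uses ``Y*_{l1 m1} = (-1)^{m1} Y_{l1, -m1}`` and the Wigner-3j product
    formula, evaluated symbolically; returns an exact 0.0 whenever the
    selection rules fail.
    """
    if not selection_allowed(q):
        return 0.0
    val = _gaunt_exact(q.l1, q.lp, q.l, -q.m1, q.mp, q.m)
    return ((-1.0) ** q.m1) * val


@dataclass
class PerturbationField:
    """Scalar perturbation of the Helmholtz operator on the sphere.

    ``coefficients`` maps (l', m') to the complex amplitude a_l'm' over the
    complex harmonics Y_l'm'.  The field must be real on the sphere, i.e.
    ``a_{l',-m'} = (-1)^{m'} conj(a_{l'm'})``; the constructor verifies
    this.  ``strength`` is an overall multiplier.
    """

    coefficients: dict[tuple[int, int], complex]
    strength: float = 1.0

    def __post_init__(self) -> None:
        for (l, m), a in self.coefficients.items():
            if l < 0 or abs(m) > l:
                raise ValueError(f"invalid coefficient index ({l}, {m})")
            partner = self.coefficients.get((l, -m), 0.0)
            expect = ((-1.0) ** m) * np.conj(a)
            if abs(partner - expect) > 1e-12 * max(1.0, abs(a)):
                raise ValueError(
                    "perturbation field is not real on the sphere: "
                    f"a_({l},{-m}) must equal (-1)^m conj(a_({l},{m}))"
                )

    @classmethod
    def constant(cls, value: float) -> "PerturbationField":
        """Uniform perturbation V = value (a_00 Y_00 with Y_00 = 1/sqrt(4pi))."""
        return cls(coefficients={(0, 0): value * np.sqrt(4.0 * np.pi)})

    @classmethod
    def real_band(cls, l: int, amplitudes: Sequence[float],
                  strength: float = 1.0) -> "PerturbationField":
        """Real field concentrated in one degree l.

        ``amplitudes`` are real coefficients over the *real* harmonics
        (m = -l..l); they are converted to complex-harmonic coefficients.
        """
        amplitudes = np.asarray(amplitudes, dtype=float)
        if amplitudes.size != 2 * l + 1:
            raise ValueError(f"need {2 * l + 1} amplitudes for degree {l}")
        coeffs: dict[tuple[int, int], complex] = {}
        for b, m in zip(amplitudes, range(-l, l + 1)):
            if b == 0.0:
                continue
            if m == 0:
                coeffs[(l, 0)] = coeffs.get((l, 0), 0.0) + b
            elif m > 0:
                # real cosine harmonic = (-1)^m (Y_lm + Y*_lm)/sqrt(2)
                s = ((-1.0) ** m) / np.sqrt(2.0)
                coeffs[(l, m)] = coeffs.get((l, m), 0.0) + b * s
                coeffs[(l, -m)] = coeffs.get((l, -m), 0.0) + b / np.sqrt(2.0)
            else:
                # real sine harmonic = -i (-1)^m (Y_l|m| - Y*_l|m|)/sqrt(2)
                am = abs(m)
                s = -1j * ((-1.0) ** am) / np.sqrt(2.0)
                coeffs[(l, am)] = coeffs.get((l, am), 0.0) + b * s
                coeffs[(l, -am)] = coeffs.get((l, -am), 0.0) + b * (1j / np.sqrt(2.0))
        return cls(coefficients=coeffs, strength=strength)

    def matrix_elements(self, l_max: int) -> np.ndarray:
        """Matrix of ``<l1 m1| V |l m>`` over the complex basis up to l_max."""
        pairs = lm_pairs(l_max)
        n = len(pairs)
        V = np.zeros((n, n), dtype=complex)
        for i, (l1, m1) in enumerate(pairs):
            for j, (l, m) in enumerate(pairs):
                total = 0.0 + 0.0j
                for (lp, mp), a in self.coefficients.items():
                    if a == 0.0:
                        continue
                    total += a * gaunt(GauntQuery(l1, m1, lp, mp, l, m))
                V[i, j] = self.strength * total
        return V


@dataclass
class FirstOrderCorrection:
    """First-order perturbation output for spherical modes.

    ``shifts[i]`` is the eigenvalue shift delta(k^2) of (post-block-
    diagonalization) mode i; ``mixing[i, j]`` the first-order coefficient
    of unperturbed basis state j in corrected mode i (cross-block only);
    ``block_transforms`` records the within-degree rotation that
    diagonalizes V in each degenerate l-block.
    """

    lm_index: list[tuple[int, int]]
    shifts: np.ndarray
    mixing: np.ndarray
    block_transforms: dict[int, np.ndarray]
    eigenvalues0: np.ndarray

    def corrected_eigenvalues(self) -> np.ndarray:
        return self.eigenvalues0 + self.shifts


def first_order_perturb(modes: SphericalModeSet,
                        pert: PerturbationField) -> FirstOrderCorrection:
    """Degenerate first-order perturbation theory on the spherical basis.

    Within each degree l the (2l+1)-fold degenerate block of the
    perturbation matrix is diagonalized first (its eigenvalues are the
    first-order shifts delta k^2); across blocks the mixing coefficients
    are matrix elements divided by unperturbed eigenvalue gaps
    ``k_l^2 - k_l1^2``.  Selection rules make most elements exact zeros.
    """
    l_max = modes.l_max
    R = modes.domain.radius
    pairs = lm_pairs(l_max)
    V = pert.matrix_elements(l_max)
    herm = np.abs(V - V.conj().T).max()
    if herm > 1e-10 * max(1.0, np.abs(V).max()):
        raise ValueError("perturbation matrix is not Hermitian; the field "
                         "must be real on the sphere")
    n = len(pairs)
    k2 = np.array([sphere_eigenvalue(l, R) for l, _ in pairs])
    shifts = np.zeros(n)
    block_transforms: dict[int, np.ndarray] = {}
    # block-diagonalize within each degenerate l-block
    W = np.eye(n, dtype=complex)
    for l in range(l_max + 1):
        idx = [i for i, (ll, _) in enumerate(pairs) if ll == l]
        block = V[np.ix_(idx, idx)]
        vals, vecs = np.linalg.eigh(block)
        order = np.argsort(vals)
        vals, vecs = vals[order], vecs[:, order]
        shifts[idx] = vals
        W[np.ix_(idx, idx)] = vecs
        block_transforms[l] = vecs
    # cross-block mixing in the block-adapted basis
    Vt = W.conj().T @ V @ W
    mixing = np.zeros((n, n), dtype=complex)
    for i, (li, _) in enumerate(pairs):
        for j, (lj, _) in enumerate(pairs):
            if li == lj:
                continue
            gap = k2[i] - k2[j]
            if abs(gap) < 1e-14:
                raise ValueError(
                    "vanishing eigenvalue gap between modes flagged as "
                    f"non-degenerate (degrees {li} and {lj})"
                )
            mixing[i, j] = Vt[j, i] / gap
    return FirstOrderCorrection(lm_index=pairs, shifts=shifts, mixing=mixing,
                                block_transforms=block_transforms,
                                eigenvalues0=k2)


# ---------------------------------------------------------------------------
# gain feedback
# ---------------------------------------------------------------------------

def low_pass_gain(g: float, tau_z: float) -> Callable[[float], complex]:
    """Default feedback operator ``Z(omega) = g / (1 - i omega tau_z)``."""
    def Z(omega: float) -> complex:
        return g / (1.0 - 1j * omega * tau_z)
    return Z


@dataclass
class GainFeedbackSpec:
    """Activity-dependent gain feedback acting on a baseline EC.

    ``baseline`` is the unperturbed direct EC (weighted form used in all
    formulas); ``steady_state`` the per-point baseline activity Q0 (s^-1);
    ``feedback`` the temporal operator Z(omega) (callable); ``drive`` an
    optional perturbation input N1(omega).
    """

    baseline: DirectEC
    steady_state: np.ndarray
    feedback: Callable[[float], complex]
    drive: np.ndarray | None = None

    def __post_init__(self) -> None:
        q0 = np.asarray(self.steady_state, dtype=complex)
        if q0.ndim != 1 or q0.size != self.baseline.point_count:
            raise ValueError("steady_state must be a K-vector matching the "
                             "baseline EC")
        self.steady_state = q0

    def check_denominator(self, omega_grid: Sequence[float],
                          tol: float = 1e-10) -> None:
        for w in omega_grid:
            z = self.feedback(w)
            if np.any(np.abs(1.0 - z * self.steady_state) < tol):
                raise MarginalStabilityError(
                    f"Z(omega) Q0 = 1 at omega = {w}: singular feedback"
                )


def gain_feedback_ec(spec: GainFeedbackSpec, omega: float) -> np.ndarray:
    """Feedback contribution ``L[i,j] = Z L0[i,j] Q0[j] / (1 - Z Q0[j])``."""
    z = spec.feedback(omega)
    q0 = spec.steady_state
    denom = 1.0 - z * q0
    if np.any(np.abs(denom) < 1e-10):
        raise MarginalStabilityError(
            f"Z(omega) Q0 = 1 within 1e-10 at omega = {omega}: "
            "singular feedback"
        )
    L0 = spec.baseline.weighted.astype(complex)
    return (z * L0 * q0[None, :]) / denom[None, :]


def perturbed_transfer(spec: GainFeedbackSpec, omega: float
                       ) -> TransferFunction:
    """Transfer function with gain feedback: ``T = (I - L0 - L)^{-1}``."""
    K = spec.baseline.point_count
    L = gain_feedback_ec(spec, omega)
    A = np.eye(K) - spec.baseline.weighted - L
    cond = np.linalg.cond(A)
    if cond > 1e12 or not np.isfinite(cond):
        raise MarginalStabilityError(
            f"I - Lambda0 - L is singular (cond {cond:.3g})"
        )
    T = np.linalg.solve(A, np.eye(K, dtype=complex))
    return TransferFunction(matrix=T, domain=spec.baseline.domain,
                            frequency=omega, provenance="from_ec")
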