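"""Temporal structure of eigenmodes: dispersion resonances and pole models.

Neural field transfer functions commonly take the form

    T(k, omega) = A(omega) / [k^2 v^2 + q^2(omega) v^2],

where ``A`` is an overall frequency envelope and ``q^2(omega)`` encodes the
local (e.g. corticothalamic) dynamics.  The resonances of mode j solve the
dispersion equation ``k_j^2 + q^2(omega) = 0``; each root ``omega =
Omega - i gamma`` is a damped oscillation at angular frequency Omega with
decay rate gamma.  The default ``q^2(omega) = (gamma_d - i omega)^2 / v^2``
is the damped-wave closure, which reduces to the undamped wave equation as
``gamma_d -> 0`` and gives the exact roots ``omega = +/- k v - i gamma_d``.

Near its resonances a mode's frequency response is a rational function and
is represented as a pole expansion

    T(k_j, omega) = sum_p  r_jp / (omega - omega_jp),
    omega_jp = Omega_jp - i gamma_jp,   gamma_jp > 0,

one term per resonance.  The Fourier convention is physics style (forward
transform ``e^{+i omega t}``), so decaying responses have their poles in
the lower half plane and the impulse response for tau >= 0 is the residue
sum ``h(tau) = -i sum_p r_jp e^{-i omega_jp tau}``.

Reality of ``h`` requires every pole with ``Omega != 0`` to be paired with
one at ``-Omega``, equal damping, and weight ``-conj(r)``; a purely real
pole at ``Omega = 0`` must have purely imaginary weight.  (The pairing sign
follows from the stated transform convention; the closed-form damped
cosine/sine oscillators are the reference cases, see the tests.)
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "DispersionModel",
    "dispersion_resonances",
    "PoleModel",
    "pole_eval",
    "pole_impulse",
    "damped_oscillator_poles",
]


@dataclass
class DispersionModel:
    """Dispersion specification ``T(k, omega) = A(omega)/(v^2 (k^2 + q^2))``.

    ``q2_poly`` gives q^2(omega) as polynomial coefficients in omega
    (ascending order, complex allowed), enabling exact companion-matrix
    root solves.  Alternatively ``q2`` may be an arbitrary callable, in
    which case roots are found by complex Newton iteration from a seed
    grid.  The default is the damped-wave form
    ``q^2 = (gamma_d - i omega)^2 / v^2``.
    """

    wave_speed: float = 10.0  # v, m/s
    damping: float = 0.0      # gamma_d, 1/s (damped-wave default)
    q2_poly: np.ndarray | None = None
    q2: Callable[[np.ndarray], np.ndarray] | None = None
    envelope: Callable[[np.ndarray], np.ndarray] | None = None  # A(omega)

    def __post_init__(self) -> None:
        if self.wave_speed <= 0:
            raise ValueError("wave speed must be positive")
        if self.q2_poly is None and self.q2 is None:
            # (gamma_d - i w)^2 / v^2 = (gamma^2 - 2 i gamma w - w^2)/v^2
            g, v = self.damping, self.wave_speed
            self.q2_poly = np.array(
                [g ** 2, -2j * g, -1.0], dtype=complex) / v ** 2

    def q2_values(self, omega: np.ndarray) -> np.ndarray:
        if self.q2 is not None:
            return np.asarray(self.q2(omega))
        return np.polynomial.polynomial.polyval(
            np.asarray(omega, dtype=complex), self.q2_poly)

    def envelope_values(self, omega: np.ndarray) -> np.ndarray:
        if self.envelope is None:
            return np.ones_like(np.asarray(omega, dtype=float))
        return np.asarray(self.envelope(omega))

    def transfer(self, k: float, omega: np.ndarray) -> np.ndarray:
        """``A(omega) / (v^2 (k^2 + q^2(omega)))``."""
        v2 = self.wave_speed ** 2
        return self.envelope_values(omega) / (
            v2 * (k ** 2 + self.q2_values(omega)))


def dispersion_resonances(model: DispersionModel, k: float,
                          window: tuple[float, float] | None = None,
                          n_seeds: int = 64,
                          max_damping: float | None = None) -> np.ndarray:
    """Complex roots ``omega`` of ``k^2 + q^2(omega) = 0``.

    Polynomial q^2 is solved exactly via the companion matrix; a callable
    q^2 is root-found by complex Newton from a seed grid spanning the
    declared real-frequency ``window`` (required in that case).  Roots are
    returned sorted by real part; raises if none are found in the window.
    """
    if model.q2 is None:
        coeffs = np.array(model.q2_poly, dtype=complex)
        coeffs[0] += k ** 2
        roots = np.polynomial.polynomial.polyroots(coeffs)
    else:
        if window is None:
            raise ValueError("a frequency window is required for a "
                             "callable q^2 specification")
        lo, hi = window
        seeds = np.linspace(lo, hi, n_seeds).astype(complex)
        seeds = np.concatenate([seeds - 1j, seeds - 10j, seeds + 0.0])
        f = lambda w: k ** 2 + model.q2_values(w)  # noqa: E731
        roots = []
        h = 1e-6 * max(1.0, abs(hi - lo))
        for w in seeds:
            for _ in range(80):
                fw = f(w)
                dfw = (f(w + h) - f(w - h)) / (2 * h)
                if abs(dfw) < 1e-300:
                    break
                step = fw / dfw
                w = w - step
                if abs(step) < 1e-12 * max(1.0, abs(w)):
                    break
            if abs(f(w)) < 1e-8 * max(1.0, k ** 2):
                if not any(abs(w - r) < 1e-6 * max(1.0, abs(w)) for r in roots):
                    roots.append(complex(w))
        roots = np.array(sorted(roots, key=lambda z: (round(z.real, 9), z.imag)))
    if window is not None and roots.size:
        lo, hi = window
        roots = roots[(roots.real >= lo - 1e-9) & (roots.real <= hi + 1e-9)]
    if max_damping is not None and roots.size:
        roots = roots[-roots.imag <= max_damping]
    if roots.size == 0:
        raise ValueError(
            f"no dispersion roots found for k={k} in the declared window"
        )
    return roots[np.argsort(roots.real)]


@dataclass
class PoleModel:
    """Rational (pole) expansion of one mode's frequency response.

    ``poles`` are the complex pole positions ``Omega - i gamma`` and
    ``weights`` their residues.  All dampings must be positive (stability).
    """

    poles: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        p = np.atleast_1d(np.asarray(self.poles, dtype=complex))
        w = np.atleast_1d(np.asarray(self.weights, dtype=complex))
        if p.shape != w.shape:
            raise ValueError("poles and weights must have matching shapes")
        if np.any(-p.imag <= 0):
            raise ValueError("all pole dampings gamma = -Im(omega_p) must "
                             "be positive (stable, decaying modes)")
        self.poles = p
        self.weights = w

    @property
    def min_damping(self) -> float:
        return float((-self.poles.imag).min())

    def is_reality_paired(self, tol: float = 1e-9) -> bool:
        """Check the pairing that makes the impulse response real.

        Each pole at ``Omega - i gamma`` with ``Omega != 0`` needs a partner
        at ``-Omega - i gamma`` with weight ``-conj(r)``; zero-frequency
        poles need purely imaginary weight.
        """
        scale = max(np.abs(self.weights).max(), 1e-300)
        wscale = max(np.abs(self.poles).max(), 1.0)
        unmatched = list(range(self.poles.size))
        while unmatched:
            i = unmatched.pop(0)
            p, r = self.poles[i], self.weights[i]
            if abs(p.real) < tol * wscale:
                if abs(r.real) > tol * scale:
                    return False
                continue
            target = -np.conj(p)
            found = None
            for j in unmatched:
                if (abs(self.poles[j] - target) < tol * wscale
                        and abs(self.weights[j] + np.conj(r)) < tol * scale):
                    found = j
                    break
            if found is None:
                return False
            unmatched.remove(found)
        return True


def damped_oscillator_poles(frequency_hz: float, damping: float,
                            amplitude: float = 1.0,
                            phase: str = "sine") -> PoleModel:
    """Reality-paired pole pair for ``amp * e^{-gamma tau} sin/cos(Omega tau)``.

    The sine oscillator has residues ``-amp/2`` at ``+Omega - i gamma`` and
    ``+amp/2`` at ``-Omega - i gamma``; the cosine one has ``i amp/2`` at
    both.  These follow from the forward transform ``int h e^{+i omega tau}``.
    """
    Om = 2.0 * np.pi * frequency_hz
    if Om == 0.0:
        # pure decay: h = amp e^{-gamma tau}, T = amp i/(omega + i gamma)
        return PoleModel(poles=np.array([-1j * damping]),
                         weights=np.array([1j * amplitude]))
    poles = np.array([Om - 1j * damping, -Om - 1j * damping])
    if phase == "sine":
        weights = np.array([-amplitude / 2.0, amplitude / 2.0])
    elif phase == "cosine":
        weights = np.array([1j * amplitude / 2.0, 1j * amplitude / 2.0])
    else:
        raise ValueError("phase must be 'sine' or 'cosine'")
    return PoleModel(poles=poles, weights=weights)


def pole_eval(model: PoleModel, omega: np.ndarray) -> np.ndarray:
    """Frequency response ``sum_p r_p / (omega - omega_p)``."""
    omega = np.asarray(omega, dtype=complex)
    out = np.zeros_like(omega)
    for p, r in zip(model.poles, model.weights):
        out = out + r / (omega - p)
    return out


def pole_impulse(model: PoleModel, tau: np.ndarray,
                 require_real: bool = True) -> np.ndarray:
    """Impulse response ``h(tau) = -i sum_p r_p e^{-i omega_p tau}``, tau >= 0.

    With reality pairing the imaginary part cancels and a real array is
    returned; an unpaired model raises unless ``require_real=False``.
    """
    tau = np.asarray(tau, dtype=float)
    if require_real and not model.is_reality_paired():
        raise ValueError(
            "pole model violates the reality condition: every pole at "
            "Omega - i gamma needs a partner at -Omega - i gamma with "
            "weight -conj(r)"
        )
    h = np.zeros(tau.shape, dtype=complex)
    for p, r in zip(model.poles, model.weights):
        h = h + (-1j) * r * np.exp(-1j * p * tau)
    h = np.where(tau < 0, 0.0, h)
    if require_real:
        amp = np.abs(h).max()
        if amp > 0 and np.abs(h.imag).max() > 1e-10 * amp:
            raise ValueError("impulse response has a nonvanishing "
                             "imaginary part despite pairing")
        return h.real
    return h
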