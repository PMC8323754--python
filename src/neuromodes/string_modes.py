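"""Eigenmodes of a 1-D string — the canonical pedagogical system.

A uniform string of length L with wave speed v obeys the wave equation
``Q_tt - v^2 Q_xx = 0``.  Separation of variables yields the Helmholtz
equation in space; boundary conditions select a discrete set of sinusoidal
modes:

* fixed ends:  ``u_j(x) = sqrt(2/L) sin(j pi x / L)``, j = 1, 2, ...
* periodic:    ``k_j = 2 pi j / L`` with sine/cosine pairs (and a uniform
  j = 0 mode), the setting used for the two-mode beating examples.

Each mode oscillates at ``omega_j = k_j v`` and is equivalently a
superposition of equal-amplitude left- and right-travelling waves.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Literal

import numpy as np

from .domain import SpatialDomain

__all__ = ["StringDomain", "StringMode", "string_modes", "string_domain_grid"]


@dataclass(frozen=True)
class StringDomain:
    """Interval [0, L] with wave speed v and a boundary condition."""

    length: float  # m
    wave_speed: float  # m/s
    boundary: Literal["fixed", "periodic"] = "fixed"

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError("string length must be positive")
        if self.wave_speed <= 0:
            raise ValueError("wave speed must be positive")
        if self.boundary not in ("fixed", "periodic"):
            raise ValueError(f"unknown boundary kind {self.boundary!r}")


@dataclass(frozen=True)
class StringMode:
    """One string eigenmode: profile, wavenumber and natural frequency."""

    index: int
    wavenumber: float           # k_j, m^-1
    frequency: float            # omega_j = k_j v, rad/s
    profile: Callable[[np.ndarray], np.ndarray]
    phase: float = 0.0
    label: str = ""

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.profile(np.asarray(x, dtype=float))

    def standing_wave(self, x: np.ndarray, t: float) -> np.ndarray:
        """``u_j(x) sin(omega_j t + psi_j)``."""
        return self(x) * np.sin(self.frequency * t + self.phase)

    def traveling_sum(self, x: np.ndarray, t: float) -> np.ndarray:
        """Half-sum of left- and right-travelling sinusoids.

        For a fixed-end (sine) mode,
        ``u sin(wt) = sqrt(2/L)/2 [cos(kx - wt - psi) - cos(kx + wt + psi)]``
        — identical to the standing wave, term by term.
        """
        x = np.asarray(x, dtype=float)
        k, w, psi = self.wavenumber, self.frequency, self.phase
        amp = self._amplitude
        if self._kind == "sin":
            return 0.5 * amp * (np.cos(k * x - w * t - psi)
                                - np.cos(k * x + w * t + psi))
        # cosine profile: cos(kx) sin(wt) = [sin(kx+wt) - sin(kx-wt)] / 2
        return 0.5 * amp * (np.sin(k * x + w * t + psi)
                            - np.sin(k * x - w * t - psi))

    # populated by string_modes
    _kind: str = "sin"
    _amplitude: float = 1.0


def string_modes(domain: StringDomain, j_max: int,
                 include_uniform: bool = False) -> list[StringMode]:
    """First ``j_max`` eigenmodes of the string.

    Fixed ends give ``k_j = j pi / L`` with sine profiles vanishing at both
    ends.  Periodic boundaries give ``k_j = 2 pi j / L`` with a sine and a
    cosine mode per j (the uniform k = 0 mode is included only on request).
    Profiles are normalized to ``int_0^L u_j u_k dx = delta_jk``.
    """
    if j_max < 1:
        raise ValueError("j_max must be >= 1")
    L, v = domain.length, domain.wave_speed
    modes: list[StringMode] = []
    if domain.boundary == "fixed":
        amp = np.sqrt(2.0 / L)
        for j in range(1, j_max + 1):
            k = j * np.pi / L
            modes.append(_make_mode(j, k, k * v, amp, "sin", f"sin_{j}"))
    else:
        if include_uniform:
            amp0 = np.sqrt(1.0 / L)
            modes.append(_make_mode(0, 0.0, 0.0, amp0, "cos", "uniform"))
        amp = np.sqrt(2.0 / L)
        for j in range(1, j_max + 1):
            k = 2.0 * np.pi * j / L
            modes.append(_make_mode(j, k, k * v, amp, "sin", f"sin_{j}"))
            modes.append(_make_mode(j, k, k * v, amp, "cos", f"cos_{j}"))
    return modes


def _make_mode(j: int, k: float, omega: float, amp: float,
               kind: str, label: str) -> StringMode:
    if kind == "sin":
        profile = lambda x, k=k, a=amp: a * np.sin(k * x)  # noqa: E731
    else:
        profile = lambda x, k=k, a=amp: a * np.cos(k * x)  # noqa: E731
    mode = StringMode(index=j, wavenumber=k, frequency=omega,
                      profile=profile, label=label)
    object.__setattr__(mode, "_kind", kind)
    object.__setattr__(mode, "_amplitude", amp)
    return mode


def string_domain_grid(domain: StringDomain, n_points: int) -> SpatialDomain:
    """Midpoint quadrature grid on [0, L] as a SpatialDomain.

    Midpoint weights ``dx = L / n`` integrate products of the low modes to
    high accuracy and keep all weights strictly positive.
    """
    L = domain.length
    dx = L / n_points
    x = (np.arange(n_points) + 0.5) * dx
    return SpatialDomain(positions=x[:, None], area_weights=np.full(n_points, dx))
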