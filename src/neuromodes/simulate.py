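"""Synthetic activity generators.

Everything here realizes the linear stochastic picture exactly: activity is
synthesized in the frequency domain as ``Q(omega) = T_hat(omega) N(omega)``
with spatially uncorrelated Gaussian white drive, so the sample
cross-spectrum converges to ``C_hat = T_hat T_hat^dagger`` by construction
rather than by numerical integration of a differential equation.  Circular
wrap-around from the FFT is mitigated by simulating twice the requested
duration and discarding the first half.

Also provided: evoked (impulse) responses synthesized mode by mode from
pole models, the closed-form two-mode beating signal used to study
windowing artifacts, and band-limited noise with BOLD-like (~0.07 Hz
plateau) or EEG-like (~15 Hz) spectra.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .connectivity import InputDrive, ModeBasis, TransferFunction
from .dispersion import PoleModel, pole_impulse
from .domain import SpatialDomain

__all__ = [
    "SimulationConfig",
    "ActivityTimeSeries",
    "simulate_linear",
    "impulse_response",
    "TwoModeConfig",
    "two_mode_signal",
    "two_mode_instant_cov",
    "two_mode_fast_avg",
    "BandSpec",
    "band_limited_noise",
]


@dataclass
class ActivityTimeSeries:
    """Activity Q(r_k, t_n): K channels by N samples, units s^-1."""

    values: np.ndarray          # (K, N)
    dt: float                   # s
    domain: SpatialDomain | None = None
    t0: float = 0.0
    provenance: str = "simulated"

    def __post_init__(self) -> None:
        v = np.atleast_2d(np.asarray(self.values, dtype=float))
        if not np.all(np.isfinite(v)):
            raise ValueError("activity contains non-finite values")
        if self.dt <= 0:
            raise ValueError("sample interval dt must be positive")
        self.values = v

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples * self.dt

    @property
    def times(self) -> np.ndarray:
        return self.t0 + self.dt * np.arange(self.n_samples)


@dataclass
class SimulationConfig:
    """White-noise-driven linear simulation specification.

    ``transfer`` is either a constant K x K matrix (frequency-flat transfer)
    or a callable ``T(omega) -> (K, K)`` evaluated on the FFT grid.  The
    drive is spatially uncorrelated Gaussian white noise with standard
    deviation ``drive.normalization`` per sample.
    """

    domain: SpatialDomain
    transfer: np.ndarray | Callable[[float], np.ndarray]
    duration: float
    dt: float
    seed: int
    bandwidth: float | None = None  # rad/s; model bandwidth for Nyquist check

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.duration < 10 * self.dt:
            raise ValueError("duration must be much longer than dt")
        nyquist = np.pi / self.dt
        if self.bandwidth is not None and self.bandwidth > nyquist:
            raise ValueError(
                f"model bandwidth {self.bandwidth:.3g} rad/s exceeds the "
                f"Nyquist frequency {nyquist:.3g} rad/s"
            )


def _spectral_radius(mat: np.ndarray) -> float:
    return float(np.abs(np.linalg.eigvals(mat)).max())


def simulate_linear(cfg: SimulationConfig,
                    drive: InputDrive | None = None) -> ActivityTimeSeries:
    """Synthesize ``Q(omega) = T_hat(omega) N(omega)`` with white drive.

    The long-run sample cross-spectrum of the output converges to
    ``N0^2 T_hat T_hat^dagger``.  Identical seeds give bitwise-identical
    output.  Unstable constant transfer models (spectral radius of
    ``I - T^{-1}`` at or above 1... in practice a non-finite or enormous
    transfer norm) are rejected.
    """
    drive = drive or InputDrive(seed=cfg.seed)
    K = cfg.domain.point_count
    n = int(round(cfg.duration / cfg.dt))
    n_sim = 2 * n  # simulate twice the duration, discard the first half
    rng = np.random.default_rng(drive.seed if drive.seed is not None
                                else cfg.seed)
    noise = rng.standard_normal((K, n_sim)) * drive.normalization
    if callable(cfg.transfer):
        freqs = 2.0 * np.pi * np.fft.rfftfreq(n_sim, d=cfg.dt)
        Nw = np.fft.rfft(noise, axis=1)
        Qw = np.empty_like(Nw)
        for i, w in enumerate(freqs):
            Tw = np.asarray(cfg.transfer(w))
            if not np.all(np.isfinite(Tw)):
                raise ValueError(f"transfer function not finite at "
                                 f"omega = {w:.3g} rad/s (unstable model?)")
            Qw[:, i] = Tw @ Nw[:, i]
        q = np.fft.irfft(Qw, n=n_sim, axis=1)
    else:
        T = np.asarray(cfg.transfer)
        if not np.all(np.isfinite(T)):
            raise ValueError("transfer matrix contains non-finite entries")
        q = np.real(T @ noise)
    return ActivityTimeSeries(values=q[:, n:], dt=cfg.dt, domain=cfg.domain,
                              provenance="simulated")


def impulse_response(basis: ModeBasis, pole_models: Sequence[PoleModel],
                     r0_index: int, tau: np.ndarray) -> np.ndarray:
    """Evoked response ``T(r, r0, tau) = sum_j u_j(r) u_j(r0) theta_j(tau)``.

    ``pole_models[j]`` supplies the modal impulse response theta_j(tau) of
    mode j; the spatial factorization is the rank-J mode-sum of the Green
    function.  Returns a (K, n_tau) array.
    """
    if not 0 <= r0_index < basis.modes.shape[0]:
        raise ValueError(f"stimulus index {r0_index} outside the domain")
    if len(pole_models) > basis.n_modes:
        raise ValueError("more pole models than modes in the basis")
    tau = np.asarray(tau, dtype=float)
    K = basis.modes.shape[0]
    out = np.zeros((K, tau.size))
    for j, pm in enumerate(pole_models):
        theta_j = pole_impulse(pm, tau)
        out += np.outer(basis.modes[:, j] * basis.modes[r0_index, j],
                        np.ones_like(tau)) * theta_j[None, :]
    return out


# ---------------------------------------------------------------------------
# two-mode beating signal
# ---------------------------------------------------------------------------

@dataclass
class TwoModeConfig:
    """Two modes, each with a pair of close resonances -> beating.

    Spatial profiles are the lowest nonuniform periodic-string modes
    ``u1 = sin(2 pi x / L)`` and ``u2 = cos(2 pi x / L)``.  Pole frequencies
    Omega_j1, Omega_j2 (rad/s) define centers ``Omega_j = (Omega_j1 +
    Omega_j2)/2`` and half-splits ``dOmega_j = (Omega_j1 - Omega_j2)/2``;
    each mode's coefficient is ``sin(Omega_j1 t) + sin(Omega_j2 t) =
    2 sin(Omega_j t) cos(dOmega_j t)``.

    Defaults follow alpha-band corticothalamic values: fast frequencies of
    order 10 Hz with sub-Hz splitting.
    """

    length: float = 1.0
    omega_11: float = 2 * np.pi * 10.25  # rad/s
    omega_12: float = 2 * np.pi * 9.75
    omega_21: float = 2 * np.pi * 10.40
    omega_22: float = 2 * np.pi * 9.60
    phases: tuple[float, float, float, float] = (0.0, 0.0, 0.0, 0.0)

    @property
    def centers(self) -> tuple[float, float]:
        return ((self.omega_11 + self.omega_12) / 2.0,
                (self.omega_21 + self.omega_22) / 2.0)

    @property
    def half_splits(self) -> tuple[float, float]:
        return ((self.omega_11 - self.omega_12) / 2.0,
                (self.omega_21 - self.omega_22) / 2.0)

    def u1(self, x: np.ndarray) -> np.ndarray:
        return np.sin(2 * np.pi * np.asarray(x) / self.length)

    def u2(self, x: np.ndarray) -> np.ndarray:
        return np.cos(2 * np.pi * np.asarray(x) / self.length)


def two_mode_signal(cfg: TwoModeConfig, x: np.ndarray, t: np.ndarray,
                    form: str = "sum") -> np.ndarray:
    """Beating signal Q(x, t) on the periodic 1-D domain.

    ``form='sum'`` evaluates the four-sinusoid sum; ``form='factored'``
    the equivalent ``2 u_j sin(Omega_j t) cos(dOmega_j t)`` product form.
    Both agree to machine precision (trigonometric identity).  Returns a
    (len(x), len(t)) array.
    """
    x = np.atleast_1d(np.asarray(x, dtype=float))
    t = np.atleast_1d(np.asarray(t, dtype=float))
    p11, p12, p21, p22 = cfg.phases
    u1 = cfg.u1(x)[:, None]
    u2 = cfg.u2(x)[:, None]
    if form == "sum":
        c1 = np.sin(cfg.omega_11 * t + p11) + np.sin(cfg.omega_12 * t + p12)
        c2 = np.sin(cfg.omega_21 * t + p21) + np.sin(cfg.omega_22 * t + p22)
    elif form == "factored":
        O1, O2 = cfg.centers
        d1, d2 = cfg.half_splits
        s1 = (p11 + p12) / 2.0
        e1 = (p11 - p12) / 2.0
        s2 = (p21 + p22) / 2.0
        e2 = (p21 - p22) / 2.0
        c1 = 2.0 * np.sin(O1 * t + s1) * np.cos(d1 * t + e1)
        c2 = 2.0 * np.sin(O2 * t + s2) * np.cos(d2 * t + e2)
    else:
        raise ValueError("form must be 'sum' or 'factored'")
    return u1 * c1[None, :] + u2 * c2[None, :]


def two_mode_instant_cov(cfg: TwoModeConfig, x: np.ndarray,
                         t: float) -> np.ndarray:
    """Instantaneous (tau = 0) covariance kernel c(x, x', t) of the signal.

    Exact product of the per-mode amplitudes at time t — including the
    fast oscillations and the cross term.  Normalization follows the
    unit-pole amplitude ``sin(Omega_j t) cos(dOmega_j t)`` per mode (the
    actual signal coefficient is twice that, so the kernel of Q itself is
    4x this value).
    """
    x = np.atleast_1d(np.asarray(x, dtype=float))
    O1, O2 = cfg.centers
    d1, d2 = cfg.half_splits
    u1, u2 = cfg.u1(x), cfg.u2(x)
    a1 = np.sin(O1 * t) * np.cos(d1 * t)
    a2 = np.sin(O2 * t) * np.cos(d2 * t)
    return (np.outer(u1, u1) * a1 ** 2
            + np.outer(u2, u2) * a2 ** 2
            + (np.outer(u1, u2) + np.outer(u2, u1)) * a1 * a2)


def two_mode_fast_avg(cfg: TwoModeConfig, x: np.ndarray, t: float,
                      warn_ratio: float = 10.0) -> np.ndarray:
    """Kernel averaged over the fast oscillations.

    ``<sin^2> = 1/2`` and the cross term averages out, leaving
    ``(1/2) u1 u1' cos^2(dOmega_1 t) + (1/2) u2 u2' cos^2(dOmega_2 t)``.
    Meaningful only for ``Omega_j >> |dOmega_j|`` (warns otherwise).
    """
    import warnings

    x = np.atleast_1d(np.asarray(x, dtype=float))
    O1, O2 = cfg.centers
    d1, d2 = cfg.half_splits
    for O, d in ((O1, d1), (O2, d2)):
        if d != 0 and abs(O) < warn_ratio * abs(d):
            warnings.warn(
                f"fast/beat separation Omega/|dOmega| = {abs(O / d):.2f} "
                f"< {warn_ratio}: fast averaging is marginal",
                RuntimeWarning, stacklevel=2)
    u1, u2 = cfg.u1(x), cfg.u2(x)
    return (0.5 * np.outer(u1, u1) * np.cos(d1 * t) ** 2
            + 0.5 * np.outer(u2, u2) * np.cos(d2 * t) ** 2)


# ---------------------------------------------------------------------------
# band-limited noise
# ---------------------------------------------------------------------------

@dataclass
class BandSpec:
    """Band-limited noise spectrum specification.

    Kinds: ``bold`` — unit plateau with a 4th-order low-pass roll-off at
    ``cutoff_hz`` (default 0.07 Hz, the hemodynamic plateau edge); ``eeg``
    — same shape with a 15 Hz cutoff; ``white``; or ``custom`` with a
    user-supplied amplitude shape |H(f)|.  ``nominal_tc`` is the 1/e
    crossing of the analytic autocorrelation implied by the spectrum,
    computed at construction (seconds).
    """

    kind: str = "bold"
    cutoff_hz: float | None = None
    shape: Callable[[np.ndarray], np.ndarray] | None = None
    seed: int = 0
    nominal_tc: float = field(init=False, default=np.nan)

    def __post_init__(self) -> None:
        if self.kind not in ("bold", "eeg", "white", "custom"):
            raise ValueError(f"unknown spectrum kind {self.kind!r}")
        if self.kind == "bold" and self.cutoff_hz is None:
            self.cutoff_hz = 0.07
        if self.kind == "eeg" and self.cutoff_hz is None:
            self.cutoff_hz = 15.0
        if self.kind == "custom" and self.shape is None:
            raise ValueError("custom spectra need a shape callable")
        self.nominal_tc = self._analytic_tc()

    def amplitude(self, f: np.ndarray) -> np.ndarray:
        """|H(f)| >= 0; power spectrum is |H|^2."""
        f = np.abs(np.asarray(f, dtype=float))
        if self.kind == "white":
            return np.ones_like(f)
        if self.kind == "custom":
            out = np.asarray(self.shape(f), dtype=float)
            if np.any(out < 0):
                raise ValueError("spectrum shape must be nonnegative")
            return out
        # 4th-order Butterworth-style low pass
        return 1.0 / np.sqrt(1.0 + (f / self.cutoff_hz) ** 8)

    def _analytic_tc(self) -> float:
        """First 1/e crossing of the normalized autocorrelation.

        Computed numerically as the cosine transform of the power
        spectrum; white noise gets tc = 0.
        """
        if self.kind == "white":
            return 0.0
        fc = self.cutoff_hz if self.cutoff_hz else 1.0
        f = np.linspace(0.0, 50.0 * fc, 20001)
        S = self.amplitude(f) ** 2
        taus = np.linspace(0.0, 5.0 / fc, 2001)
        ac = np.trapezoid(S[None, :] * np.cos(2 * np.pi * taus[:, None]
                                              * f[None, :]), f, axis=1)
        ac /= ac[0]
        below = np.nonzero(ac < np.exp(-1.0))[0]
        if below.size == 0:
            return float(taus[-1])
        i = below[0]
        # linear interpolation of the crossing
        t1, t0 = taus[i], taus[i - 1]
        a1, a0 = ac[i], ac[i - 1]
        return float(t0 + (np.exp(-1.0) - a0) * (t1 - t0) / (a1 - a0))


def band_limited_noise(spec: BandSpec, duration: float, dt: float,
                       n_channels: int = 1) -> ActivityTimeSeries:
    """Gaussian noise with the declared spectral shape, unit variance.

    Synthesized by shaping white-noise Fourier amplitudes with |H(f)| and
    inverse transforming; twice the duration is generated and the first
    half discarded to remove circular correlations.  Raises if the record
    is shorter than 20 correlation times.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    tc = spec.nominal_tc
    if tc > 0 and duration < 20.0 * tc:
        raise ValueError(
            f"duration {duration:.3g} s is too short relative to the "
            f"correlation time {tc:.3g} s (need >= {20 * tc:.3g} s)"
        )
    n = int(round(duration / dt))
    n_sim = 2 * n
    rng = np.random.default_rng(spec.seed)
    white = rng.standard_normal((n_channels, n_sim))
    f = np.fft.rfftfreq(n_sim, d=dt)
    H = spec.amplitude(f)
    shaped = np.fft.irfft(np.fft.rfft(white, axis=1) * H[None, :],
                          n=n_sim, axis=1)[:, n:]
    std = shaped.std(axis=1, keepdims=True)
    std[std == 0] = 1.0
    shaped = shaped / std
    return ActivityTimeSeries(values=shaped, dt=dt, provenance="simulated")
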