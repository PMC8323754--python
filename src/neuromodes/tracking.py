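"""Dynamic functional connectivity via mode coefficients.

Instead of estimating FC by temporal averaging in sliding windows — which
trades time resolution for noise and injects artifacts on the scale of the
window length — activity is projected onto a fixed long-term eigenmode
basis at each time sample:

    c_j(t_n) = sum_k u_j(r_k) Q(r_k, t_n) dS_k,

a purely spatial integral with no temporal smoothing.  The instantaneous
FC kernel then factorizes over modes, ``C(r, t+tau; r', t) = sum_j u_j(r)
u_j(r') kappa_j(tau, t)`` with ``kappa_j(tau, t) = c_j(t + tau) c_j(t)``,
and any desired temporal averaging is an explicit, controlled convolution
with a unit-integral window.  Conventional sliding-window covariance FC is
also provided for comparison, together with a classifier for the three
window-length regimes (long-window average, beat-dominated, fast
oscillation) relative to a mode's fast frequency Omega and beat half-split
dOmega.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .connectivity import ModeBasis
from .simulate import ActivityTimeSeries

__all__ = [
    "ModeCoefficients",
    "InstantKernel",
    "WindowSpec",
    "RegimeReport",
    "project_coeffs",
    "coeff_power",
    "instant_kernel",
    "reconstruct_instant_fc",
    "window_average",
    "sliding_window_fc",
    "classify_regime",
    "sample_correlation",
]


@dataclass
class ModeCoefficients:
    """Mode coefficient time series c_j(t_n): J modes by N samples."""

    values: np.ndarray  # (J, N)
    dt: float
    basis: ModeBasis | None = None
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))

    @property
    def n_modes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def times(self) -> np.ndarray:
        return self.t0 + self.dt * np.arange(self.n_samples)


def project_coeffs(q: ActivityTimeSeries, basis: ModeBasis
                   ) -> ModeCoefficients:
    """Spatial projection of activity onto the basis at each time sample.

    No temporal averaging is applied; each column of the result is the
    area-weighted integral of one snapshot against each mode.
    """
    if q.domain is None or basis.domain.point_count != q.n_channels:
        raise ValueError("activity and basis must share a domain")
    if not np.allclose(q.domain.area_weights, basis.domain.area_weights):
        raise ValueError("activity and basis domains have different "
                         "area weights")
    c = basis.project(q.values)
    return ModeCoefficients(values=c, dt=q.dt, basis=basis, t0=q.t0)


def coeff_power(c: ModeCoefficients) -> np.ndarray:
    """Per-mode mean-square coefficient ``<c_j^2>`` over the record."""
    if c.n_samples == 0:
        raise ValueError("empty coefficient series")
    return np.mean(c.values ** 2, axis=1)


@dataclass
class InstantKernel:
    """Per-mode instantaneous kernel kappa_j(tau, t) on a (tau, t) grid.

    ``values[j, a, n]`` is kappa_j(tau_a, t_n).  The symmetric variant uses
    ``c_j(t + tau/2) c_j(t - tau/2)`` and is even in tau; the plain variant
    uses ``c_j(t + tau) c_j(t)``.  At tau = 0 both reduce to c_j(t)^2 >= 0.
    """

    values: np.ndarray          # (J, n_tau, n_t)
    tau: np.ndarray
    t: np.ndarray
    symmetric: bool
    basis: ModeBasis | None = None


def instant_kernel(c: ModeCoefficients, tau: np.ndarray | float = 0.0,
                   symmetric: bool = False) -> InstantKernel:
    """Products of mode coefficients at lagged times, no averaging.

    Lags are rounded to the sample grid.  Edge handling is truncation: the
    time axis of the result keeps only the samples where every requested
    lag is available.
    """
    tau = np.atleast_1d(np.asarray(tau, dtype=float))
    lags = np.round(tau / c.dt).astype(int)
    n = c.n_samples
    if symmetric:
        half = np.round(tau / (2 * c.dt)).astype(int)
        max_h = int(np.abs(half).max()) if half.size else 0
        lo, hi = max_h, n - max_h
        if lo >= hi:
            raise ValueError("lag range exceeds the record span")
        t_idx = np.arange(lo, hi)
        vals = np.empty((c.n_modes, tau.size, t_idx.size))
        for a, h in enumerate(half):
            vals[:, a, :] = (c.values[:, t_idx + h]
                             * c.values[:, t_idx - h])
    else:
        max_pos = int(max(lags.max(initial=0), 0))
        max_neg = int(max(-lags.min(initial=0), 0))
        lo, hi = max_neg, n - max_pos
        if lo >= hi:
            raise ValueError("lag range exceeds the record span")
        t_idx = np.arange(lo, hi)
        vals = np.empty((c.n_modes, tau.size, t_idx.size))
        for a, lag in enumerate(lags):
            vals[:, a, :] = c.values[:, t_idx + lag] * c.values[:, t_idx]
    return InstantKernel(values=vals, tau=tau,
                         t=c.t0 + c.dt * t_idx, symmetric=symmetric,
                         basis=c.basis)


def reconstruct_instant_fc(basis: ModeBasis, kernel: InstantKernel,
                           t_index: int) -> np.ndarray:
    """Rank-J instantaneous FC ``sum_j u_j u_j^T kappa_j(0, t)``."""
    i0 = int(np.argmin(np.abs(kernel.tau)))
    k0 = kernel.values[:, i0, t_index]
    U = basis.modes[:, :k0.size]
    return (U * k0[None, :]) @ U.T


@dataclass
class WindowSpec:
    """Unit-integral temporal weight function for kernel averaging."""

    kind: str = "boxcar"        # boxcar | gaussian
    width: float = 1.0          # Delta t (boxcar full width / gaussian sigma), s
    stride: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("boxcar", "gaussian"):
            raise ValueError(f"unknown window kind {self.kind!r}")
        if self.width <= 0:
            raise ValueError("window width must be positive")

    def discrete_weights(self, dt: float) -> np.ndarray:
        """Samples of w normalized to sum to 1 on the grid."""
        if self.kind == "boxcar":
            m = max(int(round(self.width / dt)), 1)
            w = np.ones(m)
        else:
            sigma = self.width / dt
            half = int(np.ceil(4 * sigma))
            x = np.arange(-half, half + 1)
            w = np.exp(-0.5 * (x / sigma) ** 2)
        return w / w.sum()


def window_average(kernel: InstantKernel, window: WindowSpec,
                   dt: float | None = None) -> InstantKernel:
    """Convolve kappa_j(tau, .) with the unit-integral window in t.

    Truncating edge handling ('valid' convolution): the output time axis
    shrinks by the window support.  As the width approaches the record
    length the result approaches the global time mean.
    """
    if dt is None:
        if kernel.t.size < 2:
            raise ValueError("cannot infer dt from a single-sample kernel")
        dt = float(kernel.t[1] - kernel.t[0])
    w = window.discrete_weights(dt)
    n_t = kernel.values.shape[2]
    if w.size > n_t:
        raise ValueError(
            f"window support ({w.size} samples) exceeds the record "
            f"({n_t} samples)")
    J, n_tau, _ = kernel.values.shape
    out_len = n_t - w.size + 1
    out = np.empty((J, n_tau, out_len))
    for j in range(J):
        for a in range(n_tau):
            out[j, a, :] = np.convolve(kernel.values[j, a, :], w,
                                       mode="valid")
    offset = (w.size - 1) / 2.0 * dt
    return InstantKernel(values=out, tau=kernel.tau,
                         t=kernel.t[:out_len] + offset,
                         symmetric=kernel.symmetric, basis=kernel.basis)


def sliding_window_fc(q: ActivityTimeSeries, t_l: float,
                      stride: float | None = None,
                      demean: bool = True
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Conventional windowed covariance FC.

    Returns (fc, centers): ``fc[w]`` is the K x K covariance of the samples
    in window w (mean subtracted within the window by default — the field
    convention), ``centers[w]`` its center time.  Window length ``t_l`` and
    stride are in seconds; the default stride is half the window.
    """
    n_win = int(round(t_l / q.dt))
    if n_win < 2:
        raise ValueError("window must contain at least 2 samples")
    if n_win > q.n_samples:
        raise ValueError(
            f"window length {t_l:.3g} s exceeds the record "
            f"({q.duration:.3g} s)")
    step = max(int(round((stride if stride is not None else t_l / 2)
                         / q.dt)), 1)
    starts = np.arange(0, q.n_samples - n_win + 1, step)
    K = q.n_channels
    fc = np.empty((starts.size, K, K))
    centers = np.empty(starts.size)
    for w, s in enumerate(starts):
        block = q.values[:, s:s + n_win]
        if demean:
            block = block - block.mean(axis=1, keepdims=True)
        fc[w] = (block @ block.T) / n_win
        centers[w] = q.t0 + (s + (n_win - 1) / 2.0) * q.dt
    return fc, centers


@dataclass
class RegimeReport:
    """Window-length regime relative to a mode's fast and beat timescales."""

    t_l: float
    fast_period: float   # 2 pi / Omega
    beat_period: float   # 2 pi / |dOmega|
    regime: str          # "i" | "ii" | "iii"
    factor: float
    margins: dict[str, float] = field(default_factory=dict)


def classify_regime(t_l: float, omega: float, delta_omega: float,
                    factor: float = 10.0) -> RegimeReport:
    """Classify a window length against the three averaging regimes.

    (i)   t_L >= factor * beat period: the long-term mean FC is recovered;
    (ii)  fast period <~ t_L < factor * beat period: beats of activity
          interact with the window and masquerade as FC dynamics;
    (iii) t_L <= fast period: fast oscillations modulate FC directly.

    ``factor`` operationalizes the "much greater than" of regime (i).
    """
    if omega <= 0:
        raise ValueError("fast frequency Omega must be positive")
    if delta_omega == 0:
        raise ValueError("beat half-split dOmega must be nonzero")
    if t_l <= 0:
        raise ValueError("window length must be positive")
    fast = 2.0 * np.pi / omega
    beat = 2.0 * np.pi / abs(delta_omega)
    if t_l >= factor * beat:
        regime = "i"
    elif t_l <= fast:
        regime = "iii"
    else:
        regime = "ii"
    return RegimeReport(
        t_l=t_l, fast_period=fast, beat_period=beat, regime=regime,
        factor=factor,
        margins={"t_l_over_beat": t_l / beat, "t_l_over_fast": t_l / fast},
    )


def sample_correlation(q: ActivityTimeSeries, tau: float = 0.0,
                       demean: bool = True,
                       min_tc_multiples: float | None = None,
                       t_c: float | None = None) -> np.ndarray:
    """Lagged sample correlation ``C(r, r', tau)`` over the whole record.

    ``C(tau)[i, j] = mean_t Q_i(t + tau) Q_j(t)`` with truncating edge
    handling, so ``C(-tau) = C(tau)^T`` exactly.  tau = 0 gives the
    covariance used for (un-normalized) FC.  If a correlation time ``t_c``
    is supplied, records shorter than 10 (or ``min_tc_multiples``) times
    it trigger a warning.
    """
    lag = int(round(tau / q.dt))
    n = q.n_samples
    if abs(lag) >= n:
        raise ValueError("lag exceeds the record span")
    if t_c is not None:
        need = (min_tc_multiples if min_tc_multiples is not None else 10.0)
        if q.duration < need * t_c:
            warnings.warn(
                f"record of {q.duration:.3g} s is below {need:.0f} "
                f"correlation times ({t_c:.3g} s each); correlation "
                "estimates will be noisy",
                RuntimeWarning, stacklevel=2)
    v = q.values
    if demean:
        v = v - v.mean(axis=1, keepdims=True)
    if lag >= 0:
        a, b = v[:, lag:], v[:, :n - lag]
    else:
        a, b = v[:, :n + lag], v[:, -lag:]
    return (a @ b.T) / a.shape[1]
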