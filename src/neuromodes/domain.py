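"""Discretized spatial domains.

A cortical surface (or any 2-D manifold) is represented by a finite set of
sample points, each carrying the piece of surface area it stands for.  All
inner products in this package are area weighted: for fields ``f``, ``g``
sampled at the points, ``<f, g> = sum_k f_k* g_k dS_k``, the discrete form of
the surface integral.  On a uniform grid this reduces to the plain Euclidean
product up to a constant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["SpatialDomain"]


@dataclass(frozen=True)
class SpatialDomain:
    """A set of surface sample points with their area weights.

    Parameters
    ----------
    positions : (K, d) float array
        Point coordinates in metres.  ``d`` is 1, 2, or 3.
    area_weights : (K,) float array
        Surface area dS_k represented by each point, in m^2 (m for 1-D
        domains).  Must be strictly positive.
    """

    positions: np.ndarray
    area_weights: np.ndarray
    _total_area: float = field(init=False, repr=False, default=0.0)

    def __post_init__(self) -> None:
        pos = np.atleast_2d(np.asarray(self.positions, dtype=float))
        if pos.shape[0] == 1 and pos.shape[1] > 3:
            pos = pos.T
        w = np.asarray(self.area_weights, dtype=float).ravel()
        if pos.shape[0] != w.size:
            raise ValueError(
                f"positions ({pos.shape[0]}) and area_weights ({w.size}) "
                "must have the same number of points"
            )
        if np.any(w <= 0):
            raise ValueError("all area weights must be positive")
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "area_weights", w)
        object.__setattr__(self, "_total_area", float(w.sum()))

    @property
    def point_count(self) -> int:
        return self.area_weights.size

    @property
    def total_area(self) -> float:
        """Total surface area, the sum of the area weights."""
        return self._total_area

    @property
    def weight_matrix(self) -> np.ndarray:
        """diag(dS) as a dense matrix."""
        return np.diag(self.area_weights)

    def inner(self, f: np.ndarray, g: np.ndarray) -> complex | float:
        """Area-weighted inner product ``sum_k conj(f_k) g_k dS_k``."""
        f = np.asarray(f).ravel()
        g = np.asarray(g).ravel()
        return np.sum(np.conj(f) * g * self.area_weights)

    @classmethod
    def uniform(cls, point_count: int, total_area: float = 1.0,
                positions: np.ndarray | None = None) -> "SpatialDomain":
        """Domain with equal area weights ``total_area / K``."""
        if positions is None:
            positions = np.linspace(0.0, 1.0, point_count)[:, None]
        w = np.full(point_count, total_area / point_count)
        return cls(positions=np.asarray(positions, float), area_weights=w)
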