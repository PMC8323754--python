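"""Laplace–Beltrami eigenmodes on triangulated surfaces.

The geometric eigenmodes of a convoluted cortex have no closed form, so the
Helmholtz equation is solved numerically on a triangle mesh.  The standard
discretization is used: cotangent stiffness matrix ``A`` with a lumped
(diagonal) mass matrix ``M`` whose entries are the per-vertex areas (one
third of each incident triangle).  Eigenmodes solve the generalized problem

    A u = k^2 M u,

are M-orthonormal (the discrete area-weighted inner product), have
nonnegative eigenvalues in ascending order, and on a closed mesh start with
an exactly constant mode at k^2 = 0.  On a refined icosphere the spectrum
converges to the spherical values l(l+1)/R^2 with multiplicities 2l+1.

The module also provides the mesh fixtures used throughout: subdivided
icosahedra (icospheres) and radially deformed spheres whose deformation
spectrum is controlled in spherical-harmonic bands, for selection-rule
experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .connectivity import ModeBasis, fix_sign
from .domain import SpatialDomain
from .sphere import real_harmonic, lm_pairs

__all__ = [
    "TriangleMesh",
    "mesh_modes",
    "cotangent_laplacian",
    "make_icosphere",
    "make_deformed_sphere",
]

MIN_FACE_AREA = 1e-14  # m^2; faces below this are degenerate


@dataclass
class TriangleMesh:
    """Triangulated surface: vertices (m), faces, per-vertex lumped areas."""

    vertices: np.ndarray
    faces: np.ndarray
    vertex_areas: np.ndarray = field(init=False, repr=False)
    euler_characteristic: int = field(init=False)

    def __post_init__(self) -> None:
        V = np.asarray(self.vertices, dtype=float)
        F = np.asarray(self.faces, dtype=np.int64)
        if V.ndim != 2 or V.shape[1] != 3:
            raise ValueError("vertices must be an (n, 3) array")
        if F.ndim != 2 or F.shape[1] != 3:
            raise ValueError("faces must be an (m, 3) array")
        if F.min(initial=0) < 0 or F.max(initial=-1) >= V.shape[0]:
            bad = int(np.argmax((F < 0) | (F >= V.shape[0])).item() // 3)
            raise ValueError(
                f"face {bad} references a vertex outside [0, {V.shape[0]})"
            )
        self.vertices = V
        self.faces = F
        areas = self.face_areas()
        if np.any(areas <= MIN_FACE_AREA):
            bad = int(np.argmin(areas))
            raise ValueError(
                f"degenerate face {bad}: area {areas[bad]:.3g} m^2"
            )
        va = np.zeros(V.shape[0])
        np.add.at(va, F.ravel(), np.repeat(areas / 3.0, 3))
        self.vertex_areas = va
        n_edges = len({tuple(sorted(e)) for f in F
                       for e in ((f[0], f[1]), (f[1], f[2]), (f[2], f[0]))})
        self.euler_characteristic = V.shape[0] - n_edges + F.shape[0]

    @property
    def n_vertices(self) -> int:
        return self.vertices.shape[0]

    @property
    def n_faces(self) -> int:
        return self.faces.shape[0]

    def face_areas(self) -> np.ndarray:
        V, F = self.vertices, self.faces
        e1 = V[F[:, 1]] - V[F[:, 0]]
        e2 = V[F[:, 2]] - V[F[:, 0]]
        return 0.5 * np.linalg.norm(np.cross(e1, e2), axis=1)

    @property
    def total_area(self) -> float:
        return float(self.face_areas().sum())

    def to_spatial_domain(self) -> SpatialDomain:
        return SpatialDomain(positions=self.vertices,
                             area_weights=self.vertex_areas)


def cotangent_laplacian(mesh: TriangleMesh) -> tuple[sp.csr_matrix, sp.dia_matrix]:
    """Cotangent stiffness matrix A and lumped mass matrix M.

    ``A`` is symmetric positive semidefinite with row sums zero; ``M`` is
    diagonal with the per-vertex areas.  ``(A, M)`` discretize the
    Laplace–Beltrami operator so that ``A u = k^2 M u`` approximates
    ``-lap u = k^2 u`` on the surface.
    """
    V, F = mesh.vertices, mesh.faces
    n = mesh.n_vertices
    rows, cols, vals = [], [], []
    # cotangent weight at the corner opposite each edge
    for a, b, c in ((0, 1, 2), (1, 2, 0), (2, 0, 1)):
        i, j, k = F[:, a], F[:, b], F[:, c]
        u = V[i] - V[k]
        v = V[j] - V[k]
        cross = np.linalg.norm(np.cross(u, v), axis=1)
        cot = np.einsum("ij,ij->i", u, v) / np.maximum(cross, 1e-300)
        w = 0.5 * cot
        rows += [i, j, i, j]
        cols += [j, i, i, j]
        vals += [-w, -w, w, w]
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    vals = np.concatenate(vals)
    A = sp.csr_matrix((vals, (rows, cols)), shape=(n, n))
    A = 0.5 * (A + A.T)
    M = sp.diags(mesh.vertex_areas)
    return A, M


def mesh_modes(mesh: TriangleMesh, n_modes: int,
               sigma: float = -1e-8) -> tuple[ModeBasis, np.ndarray]:
    """Lowest Laplace–Beltrami eigenmodes of a triangle mesh.

    Solves the generalized eigenproblem in shift-invert mode around zero and
    returns an area-weight-orthonormal ModeBasis (M-orthonormal columns)
    plus ascending eigenvalues k_j^2 (m^-2).  On a closed mesh the first
    eigenvalue is numerically zero with a constant eigenvector.
    """
    if n_modes < 1:
        raise ValueError("n_modes must be >= 1")
    if n_modes >= mesh.n_vertices:
        raise ValueError("n_modes must be below the vertex count")
    A, M = cotangent_laplacian(mesh)
    try:
        vals, vecs = spla.eigsh(A, k=n_modes, M=M, sigma=sigma, which="LM")
    except spla.ArpackNoConvergence as exc:  # pragma: no cover - rare
        raise RuntimeError(f"eigensolver failed to converge: {exc}") from exc
    order = np.argsort(vals)
    vals = np.maximum(vals[order], 0.0)  # clip tiny negatives from the shift
    vecs = fix_sign(vecs[:, order])
    basis = ModeBasis(modes=vecs, domain=mesh.to_spatial_domain(),
                      ordering="ascending_k2")
    return basis, vals


# ---------------------------------------------------------------------------
# mesh fixtures
# ---------------------------------------------------------------------------

def _icosahedron() -> tuple[np.ndarray, np.ndarray]:
    t = (1.0 + np.sqrt(5.0)) / 2.0
    verts = np.array(
        [
            (-1, t, 0), (1, t, 0), (-1, -t, 0), (1, -t, 0),
            (0, -1, t), (0, 1, t), (0, -1, -t), (0, 1, -t),
            (t, 0, -1), (t, 0, 1), (-t, 0, -1), (-t, 0, 1),
        ],
        dtype=float,
    )
    verts /= np.linalg.norm(verts, axis=1)[:, None]
    faces = np.array(
        [
            (0, 11, 5), (0, 5, 1), (0, 1, 7), (0, 7, 10), (0, 10, 11),
            (1, 5, 9), (5, 11, 4), (11, 10, 2), (10, 7, 6), (7, 1, 8),
            (3, 9, 4), (3, 4, 2), (3, 2, 6), (3, 6, 8), (3, 8, 9),
            (4, 9, 5), (2, 4, 11), (6, 2, 10), (8, 6, 7), (9, 8, 1),
        ],
        dtype=np.int64,
    )
    return verts, faces


MAX_SUBDIVISIONS = 7  # 163842 vertices; caps memory use


def make_icosphere(subdivisions: int, radius: float = 1.0) -> TriangleMesh:
    """Subdivided icosahedron projected onto the sphere of given radius.

    Subdivision level n yields ``10 * 4**n + 2`` vertices.  Faces keep a
    consistent outward orientation.
    """
    if subdivisions < 0:
        raise ValueError("subdivisions must be >= 0")
    if subdivisions > MAX_SUBDIVISIONS:
        raise ValueError(
            f"subdivisions capped at {MAX_SUBDIVISIONS} to bound memory"
        )
    verts, faces = _icosahedron()
    for _ in range(subdivisions):
        edge_mid: dict[tuple[int, int], int] = {}
        new_faces = []
        vlist = [v for v in verts]

        def midpoint(i: int, j: int) -> int:
            key = (i, j) if i < j else (j, i)
            if key not in edge_mid:
                m = vlist[i] + vlist[j]
                m /= np.linalg.norm(m)
                edge_mid[key] = len(vlist)
                vlist.append(m)
            return edge_mid[key]

        for a, b, c in faces:
            ab, bc, ca = midpoint(a, b), midpoint(b, c), midpoint(c, a)
            new_faces += [(a, ab, ca), (b, bc, ab), (c, ca, bc), (ab, bc, ca)]
        verts = np.array(vlist)
        faces = np.array(new_faces, dtype=np.int64)
    return TriangleMesh(vertices=verts * radius, faces=faces)


def make_deformed_sphere(base: TriangleMesh, strength: float,
                         l_band: int | None = None,
                         n_bumps: int = 0,
                         bump_width: float = 0.3,
                         seed: int | None = None,
                         l_report_max: int = 12
                         ) -> tuple[TriangleMesh, np.ndarray]:
    """Radially deform an icosphere and report the deformation spectrum.

    The radial field ``d(theta, phi)`` is either a random combination of
    real harmonics of a single degree ``l_band``, or a sum of ``n_bumps``
    localized Gaussian bumps (high-degree content), scaled so that
    ``max |d| = strength * R``.  Vertices move to ``r = R + d``.  Returns
    the mesh and the per-degree power fractions of ``d`` for degrees up to
    ``l_report_max`` (the harmonic band spectrum used by selection-rule
    experiments).

    strength must stay below ~0.5 to avoid self-intersection; this is
    enforced crudely by requiring the deformed radius to stay positive.
    """
    if strength < 0:
        raise ValueError("strength must be nonnegative")
    rng = np.random.default_rng(seed)
    V = base.vertices
    R = np.linalg.norm(V, axis=1)
    radius = float(R.mean())
    theta = np.arccos(np.clip(V[:, 2] / R, -1.0, 1.0))
    phi = np.mod(np.arctan2(V[:, 1], V[:, 0]), 2.0 * np.pi)

    if strength == 0.0:
        d = np.zeros(base.n_vertices)
    elif l_band is not None:
        coeffs = rng.standard_normal(2 * l_band + 1)
        d = np.zeros(base.n_vertices)
        for c, m in zip(coeffs, range(-l_band, l_band + 1)):
            d += c * real_harmonic(l_band, m, theta, phi)
    elif n_bumps > 0:
        d = np.zeros(base.n_vertices)
        for _ in range(n_bumps):
            center = rng.standard_normal(3)
            center /= np.linalg.norm(center)
            ang = np.arccos(np.clip((V / R[:, None]) @ center, -1.0, 1.0))
            d += rng.choice([-1.0, 1.0]) * np.exp(-(ang / bump_width) ** 2)
    else:
        raise ValueError("specify l_band or n_bumps for a nonzero strength")

    if strength > 0:
        d *= strength * radius / np.abs(d).max()
    new_R = R + d
    if np.any(new_R <= 0):
        raise ValueError("deformation too strong: radius crosses zero "
                         "(self-intersecting output)")
    mesh = TriangleMesh(vertices=V * (new_R / R)[:, None], faces=base.faces)

    # report deformation power per harmonic degree via vertex-area quadrature
    areas = base.vertex_areas
    power = np.zeros(l_report_max + 1)
    for l, m in lm_pairs(l_report_max):
        y = real_harmonic(l, m, theta, phi) / radius
        power[l] += float(np.sum(y * d * areas)) ** 2
    total = power.sum()
    spectrum = power / total if total > 0 else power
    return mesh, spectrum
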