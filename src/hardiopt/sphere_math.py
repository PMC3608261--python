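"""Spherical-harmonic algebra and icosahedral sphere meshes.

All angular reconstructions in this package are expressed in a real,
symmetric (even-order) spherical-harmonic basis, the de-facto convention in
HARDI.  For a complex harmonic :math:`Y_l^m` (Condon–Shortley phase as in
:func:`scipy.special.sph_harm_y`), the real basis element indexed by
``(l, m)`` is

* ``m < 0``:  ``sqrt(2) * Im(Y_l^{|m|})``
* ``m = 0``:  ``Re(Y_l^0)``
* ``m > 0``:  ``sqrt(2) * Re(Y_l^m)``

restricted to even ``l``.  The basis is orthonormal on the sphere and
antipodally symmetric, so it represents exactly the class of functions
(diffusivity profiles, ODFs) this package manipulates.  Coefficient vectors
are ordered by ``l`` ascending, then ``m`` ascending; their length is
``R = (lmax + 1)(lmax + 2) / 2``.

Peak extraction operates on recursively subdivided icosahedral meshes.  At
subdivision order ``k`` the mesh has ``10 * 4**k + 2`` vertices; order 7
(163 842 vertices) keeps every unit direction within 0.5 degrees of a mesh
vertex.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.spatial import cKDTree
from scipy.special import sph_harm_y

__all__ = [
    "SphereMesh",
    "SHSeries",
    "sh_index_pairs",
    "n_sh_coeffs",
    "real_sh_basis",
    "fit_sh",
    "legendre_at_zero",
    "tessellate_icosahedron",
    "nearest_vertex_stats",
]

_MAX_LMAX = 8
_MAX_MESH_ORDER = 8


def n_sh_coeffs(lmax: int) -> int:
    """Number of real even-order SH coefficients up to ``lmax``."""
    return (lmax + 1) * (lmax + 2) // 2


def sh_index_pairs(lmax: int) -> list[tuple[int, int]]:
    """(l, m) pairs in storage order: l = 0, 2, ..., lmax; m = -l ... l."""
    return [(l, m) for l in range(0, lmax + 1, 2) for m in range(-l, l + 1)]


def _validate_lmax(lmax: int) -> None:
    if lmax % 2 != 0 or not (0 <= lmax <= _MAX_LMAX):
        raise ValueError(
            f"lmax must be an even integer in [0, {_MAX_LMAX}], got {lmax}"
        )


def _as_unit_directions(directions) -> np.ndarray:
    u = np.atleast_2d(np.asarray(directions, dtype=float))
    if u.ndim != 2 or u.shape[1] != 3:
        raise ValueError(f"directions must have shape (n, 3), got {u.shape}")
    norms = np.linalg.norm(u, axis=1)
    if not np.allclose(norms, 1.0, atol=1e-6):
        worst = float(np.abs(norms - 1.0).max())
        raise ValueError(
            f"directions must be unit vectors (max |norm - 1| = {worst:.2e})"
        )
    return u


def real_sh_basis(directions, lmax: int) -> np.ndarray:
    """Evaluate the real symmetric SH basis at unit ``directions``.

    Returns a design matrix of shape ``(n_directions, R)`` with
    ``R = (lmax+1)(lmax+2)/2`` columns ordered by (l ascending, m ascending).
    """
    _validate_lmax(lmax)
    u = _as_unit_directions(directions)
    theta = np.arccos(np.clip(u[:, 2], -1.0, 1.0))  # polar
    phi = np.arctan2(u[:, 1], u[:, 0])  # azimuth
    cols = np.empty((u.shape[0], n_sh_coeffs(lmax)))
    j = 0
    for l in range(0, lmax + 1, 2):
        # one complex evaluation per |m| serves both signs
        ylm = {m: sph_harm_y(l, m, theta, phi) for m in range(l + 1)}
        for m in range(-l, l + 1):
            if m < 0:
                cols[:, j] = np.sqrt(2.0) * ylm[-m].imag
            elif m == 0:
                cols[:, j] = ylm[0].real
            else:
                cols[:, j] = np.sqrt(2.0) * ylm[m].real
            j += 1
    return cols


@dataclass
class SHSeries:
    """Real even-order spherical-harmonic expansion."""

    lmax: int
    coeffs: np.ndarray

    def __post_init__(self) -> None:
        _validate_lmax(self.lmax)
        self.coeffs = np.asarray(self.coeffs, dtype=float)
        expected = n_sh_coeffs(self.lmax)
        if self.coeffs.shape != (expected,):
            raise ValueError(
                f"lmax={self.lmax} needs {expected} coefficients, "
                f"got shape {self.coeffs.shape}"
            )

    def evaluate(self, directions) -> np.ndarray:
        """Evaluate the series at unit directions (vectorized)."""
        return real_sh_basis(directions, self.lmax) @ self.coeffs

    def degrees(self) -> np.ndarray:
        """Degree l of each stored coefficient."""
        return np.array([l for l, _ in sh_index_pairs(self.lmax)])

    def scaled_by_degree(self, factors: dict[int, float]) -> "SHSeries":
        """New series with each degree-l block multiplied by ``factors[l]``."""
        mult = np.array([factors[l] for l in self.degrees()], dtype=float)
        return SHSeries(self.lmax, self.coeffs * mult)

    def save_csv(self, path) -> None:
        """Write the coefficient table as CSV rows (l, m, coefficient)."""
        with open(path, "w") as fh:
            fh.write("l,m,coefficient\n")
            for (l, m), c in zip(sh_index_pairs(self.lmax), self.coeffs):
                fh.write(f"{l},{m},{c:.17g}\n")

    @classmethod
    def load_csv(cls, path) -> "SHSeries":
        rows = [line.split(",") for line in open(path) if line[0].isdigit()]
        lmax = max(int(r[0]) for r in rows)
        return cls(lmax, np.array([float(r[2]) for r in rows]))


def fit_sh(values, directions, lmax: int) -> SHSeries:
    """Ordinary least-squares SH fit of per-direction scalar samples.

    No regularization is applied; the scheme must provide at least
    ``(lmax+1)(lmax+2)/2`` directions.
    """
    values = np.asarray(values, dtype=float).ravel()
    basis = real_sh_basis(directions, lmax)
    needed = n_sh_coeffs(lmax)
    if basis.shape[0] < needed:
        raise ValueError(
            f"underdetermined SH fit: lmax={lmax} requires at least {needed} "
            f"directions, got {basis.shape[0]}"
        )
    if values.shape[0] != basis.shape[0]:
        raise ValueError("values and directions length mismatch")
    coeffs, *_ = np.linalg.lstsq(basis, values, rcond=None)
    return SHSeries(lmax, coeffs)


def legendre_at_zero(l: int) -> float:
    """Legendre polynomial at the origin, P_l(0) = (-1)^{l/2} (l-1)!!/l!!."""
    if l % 2 != 0 or l < 0:
        raise ValueError(f"l must be a non-negative even integer, got {l}")
    value = 1.0
    for k in range(2, l + 1, 2):  # (l-1)!!/l!! built pairwise
        value *= (k - 1) / k
    return float((-1) ** (l // 2) * value)


# ---------------------------------------------------------------------------
# icosahedral meshes


@dataclass
class SphereMesh:
    """Triangulated unit sphere from recursive icosahedron subdivision."""

    vertices: np.ndarray
    faces: np.ndarray
    order: int
    _neighbors: np.ndarray | None = field(default=None, repr=False)
    _weights: np.ndarray | None = field(default=None, repr=False)

    @property
    def n_vertices(self) -> int:
        return self.vertices.shape[0]

    @property
    def neighbors(self) -> np.ndarray:
        """One-ring adjacency, shape (n_vertices, 6), padded with -1.

        Icosahedral meshes have exactly 5 neighbors at the 12 original
        vertices and 6 everywhere else.
        """
        if self._neighbors is None:
            edges = np.vstack(
                [self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [2, 0]]]
            )
            edges = np.unique(np.sort(edges, axis=1), axis=0)
            both = np.vstack([edges, edges[:, ::-1]])
            order_idx = np.argsort(both[:, 0], kind="stable")
            both = both[order_idx]
            counts = np.bincount(both[:, 0], minlength=self.n_vertices)
            nbr = np.full((self.n_vertices, 6), -1, dtype=np.int64)
            offsets = np.zeros_like(counts)
            np.cumsum(counts[:-1], out=offsets[1:])
            for width in range(6):
                has = counts > width
                nbr[has, width] = both[offsets[has] + width, 1]
            self._neighbors = nbr
        return self._neighbors

    @property
    def vertex_weights(self) -> np.ndarray:
        """Quadrature weights: one third of incident triangle areas, scaled
        so the weights sum to the sphere area 4*pi."""
        if self._weights is None:
            v = self.vertices
            a, b, c = v[self.faces[:, 0]], v[self.faces[:, 1]], v[self.faces[:, 2]]
            tri_area = 0.5 * np.linalg.norm(np.cross(b - a, c - a), axis=1)
            w = np.zeros(self.n_vertices)
            for k in range(3):
                np.add.at(w, self.faces[:, k], tri_area / 3.0)
            self._weights = w * (4.0 * np.pi / w.sum())
        return self._weights

    def nearest_vertex(self, points) -> np.ndarray:
        """Index of the nearest mesh vertex for each query point."""
        _, idx = _mesh_tree(self).query(np.atleast_2d(points))
        return idx

    def write_off(self, path) -> None:
        """Export vertices and faces in OFF format (debugging aid)."""
        with open(path, "w") as fh:
            fh.write("OFF\n")
            fh.write(f"{self.n_vertices} {len(self.faces)} 0\n")
            for v in self.vertices:
                fh.write(f"{v[0]:.17g} {v[1]:.17g} {v[2]:.17g}\n")
            for f in self.faces:
                fh.write(f"3 {f[0]} {f[1]} {f[2]}\n")


_tree_cache: dict[int, cKDTree] = {}


def _mesh_tree(mesh: SphereMesh) -> cKDTree:
    key = id(mesh)
    tree = _tree_cache.get(key)
    if tree is None:
        tree = cKDTree(mesh.vertices)
        _tree_cache[key] = tree
    return tree


def _icosahedron() -> tuple[np.ndarray, np.ndarray]:
    phi = (1.0 + np.sqrt(5.0)) / 2.0
    verts = np.array(
        [
            [-1, phi, 0], [1, phi, 0], [-1, -phi, 0], [1, -phi, 0],
            [0, -1, phi], [0, 1, phi], [0, -1, -phi], [0, 1, -phi],
            [phi, 0, -1], [phi, 0, 1], [-phi, 0, -1], [-phi, 0, 1],
        ],
        dtype=float,
    )
    verts /= np.linalg.norm(verts, axis=1, keepdims=True)
    faces = np.array(
        [
            [0, 11, 5], [0, 5, 1], [0, 1, 7], [0, 7, 10], [0, 10, 11],
            [1, 5, 9], [5, 11, 4], [11, 10, 2], [10, 7, 6], [7, 1, 8],
            [3, 9, 4], [3, 4, 2], [3, 2, 6], [3, 6, 8], [3, 8, 9],
            [4, 9, 5], [2, 4, 11], [6, 2, 10], [8, 6, 7], [9, 8, 1],
        ],
        dtype=np.int64,
    )
    return verts, faces


@lru_cache(maxsize=None)
def tessellate_icosahedron(order: int) -> SphereMesh:
    """Recursively subdivide the regular icosahedron ``order`` times.

    Each pass splits every triangle into four by edge midpoints reprojected
    to the unit sphere, giving ``10 * 4**order + 2`` vertices.  Meshes are
    cached per order (they are immutable in practice).
    """
    if not (0 <= order <= _MAX_MESH_ORDER):
        raise ValueError(
            f"tessellation order must be in [0, {_MAX_MESH_ORDER}] "
            f"(order {order} would exhaust memory)"
        )
    verts, faces = _icosahedron()
    for _ in range(order):
        edges = np.vstack([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]])
        edges = np.sort(edges, axis=1)
        uniq, inverse = np.unique(edges, axis=0, return_inverse=True)
        mids = verts[uniq[:, 0]] + verts[uniq[:, 1]]
        mids /= np.linalg.norm(mids, axis=1, keepdims=True)
        mid_idx = inverse.reshape(3, -1) + len(verts)  # per-edge new ids
        ab, bc, ca = mid_idx
        verts = np.vstack([verts, mids])
        a, b, c = faces[:, 0], faces[:, 1], faces[:, 2]
        faces = np.vstack(
            [
                np.column_stack([a, ab, ca]),
                np.column_stack([b, bc, ab]),
                np.column_stack([c, ca, bc]),
                np.column_stack([ab, bc, ca]),
            ]
        )
    return SphereMesh(vertices=verts, faces=faces, order=order)


def random_unit_vectors(n: int, rng: np.random.Generator) -> np.ndarray:
    """Uniformly distributed unit 3-vectors."""
    v = rng.standard_normal((n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def nearest_vertex_stats(
    mesh: SphereMesh, n_samples: int = 100_000, seed: int = 0
) -> tuple[float, float]:
    """Monte-Carlo (max, mean) angular distance in degrees from uniform
    random unit vectors to their nearest mesh vertex."""
    if n_samples < 10_000:
        raise ValueError("n_samples must be at least 10^4 for a stable estimate")
    rng = np.random.default_rng(seed)
    tree = _mesh_tree(mesh)
    max_d = 0.0
    sum_d = 0.0
    done = 0
    chunk = 200_000
    while done < n_samples:
        m = min(chunk, n_samples - done)
        pts = random_unit_vectors(m, rng)
        chord, _ = tree.query(pts)
        ang = np.degrees(2.0 * np.arcsin(np.clip(chord / 2.0, 0.0, 1.0)))
        max_d = max(max_d, float(ang.max()))
        sum_d += float(ang.sum())
        done += m
    return max_d, sum_d / n_samples
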