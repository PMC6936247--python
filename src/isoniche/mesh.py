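"""Quadrilateral surface meshes and mesh-based ellipsoid overlap.

Ellipsoid overlap has no convenient closed form, so each ellipsoid is
approximated by a quadrilateral surface mesh (a latitude-longitude sphere
grid pushed through the affine map defined by the Cholesky factor of the
shape matrix).  Because the intersection of two ellipsoids is convex, the
convex hull of any point set lying inside both is an inner approximation
of the true intersection; its volume estimates the overlap volume.

The point set combines three sources:

* vertices of mesh A inside ellipsoid B,
* vertices of mesh B inside ellipsoid A,
* intersections of mesh-A edges with surface B and vice versa (roots of a
  quadratic along each edge).

Planar faces under-approximate a convex surface, so the estimate is
biased low; the bias shrinks as faces are quadrisected (each subdivision
level splits every quadrilateral into four and reprojects new vertices
onto the surface).  Directed overlap percentages divide by the hull
volume of each mesh at the *same* subdivision level, so the
discretization bias largely cancels and an ellipsoid overlaps itself by
exactly 100%.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.spatial import ConvexHull, QhullError

from .exceptions import (
    DegenerateCovarianceError,
    ScaleMismatchError,
    ValidationError,
)
from .geometry import Ellipsoid

__all__ = [
    "SurfaceMesh",
    "OverlapEstimate",
    "build_mesh",
    "hull_volume",
    "overlap",
    "mc_overlap_oracle",
]

#: Base latitude-longitude resolution of the level-0 sphere mesh.
BASE_RINGS = 16
BASE_SEGMENTS = 16

# Surface membership tolerance: mesh vertices sit on the boundary
# (Mahalanobis^2 == 1) up to floating-point error.
_SURFACE_TOL = 1e-9


@dataclasses.dataclass(frozen=True)
class SurfaceMesh:
    """Quadrilateral mesh discretizing an ellipsoid surface.

    ``vertices`` lie exactly on the source ellipsoid (squared Mahalanobis
    radius 1 up to round-off); ``faces`` index vertex quadruples.  Faces
    adjacent to the poles of the parameterization are degenerate
    quadrilaterals (two coincident corners) of vanishing area.
    """

    vertices: np.ndarray
    faces: np.ndarray
    subdivision: int
    source: Ellipsoid

    def __post_init__(self) -> None:
        self.vertices.setflags(write=False)
        self.faces.setflags(write=False)

    @property
    def n_vertices(self) -> int:
        return self.vertices.shape[0]

    @property
    def n_faces(self) -> int:
        return self.faces.shape[0]

    def edges(self) -> np.ndarray:
        """Unique non-degenerate edges as an (E, 2) index array."""
        f = self.faces
        pairs = np.concatenate(
            [f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 3]], f[:, [3, 0]]]
        )
        pairs = np.sort(pairs, axis=1)
        pairs = pairs[pairs[:, 0] != pairs[:, 1]]
        return np.unique(pairs, axis=0)


@dataclasses.dataclass(frozen=True)
class OverlapEstimate:
    """Directed overlap between two ellipsoids at a common coverage scale.

    ``percent_of_first`` is the share of the first (row) ellipsoid's mesh
    volume lying in the intersection; ``percent_of_second`` the analogue
    for the second.  ``absolute_volume`` (permil^3) is symmetric.
    """

    percent_of_first: float
    percent_of_second: float
    absolute_volume: float
    subdivision: int


def _unit_sphere_mesh(
    n_rings: int = BASE_RINGS, n_segments: int = BASE_SEGMENTS
) -> tuple[np.ndarray, np.ndarray]:
    """Latitude-longitude quadrilateral mesh of the unit sphere.

    ``n_rings`` latitude bands between the poles, ``n_segments`` longitude
    sectors.  Pole bands yield degenerate quadrilaterals with a repeated
    pole index, which downstream code tolerates.
    """
    theta = np.linspace(0.0, np.pi, n_rings + 1)
    phi = np.linspace(0.0, 2.0 * np.pi, n_segments, endpoint=False)

    verts = [np.array([0.0, 0.0, 1.0])]
    index = np.empty((n_rings + 1, n_segments), dtype=np.int64)
    index[0, :] = 0
    for i in range(1, n_rings):
        ring = np.column_stack(
            [
                np.sin(theta[i]) * np.cos(phi),
                np.sin(theta[i]) * np.sin(phi),
                np.full(n_segments, np.cos(theta[i])),
            ]
        )
        start = len(verts)
        verts.extend(ring)
        index[i, :] = np.arange(start, start + n_segments)
    index[n_rings, :] = len(verts)
    verts.append(np.array([0.0, 0.0, -1.0]))

    faces = []
    for i in range(n_rings):
        for j in range(n_segments):
            jn = (j + 1) % n_segments
            faces.append(
                (index[i, j], index[i, jn], index[i + 1, jn], index[i + 1, j])
            )
    return np.asarray(verts, dtype=float), np.asarray(faces, dtype=np.int64)


def _subdivide_sphere(
    verts: np.ndarray, faces: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Quadrisect every face, reprojecting new vertices onto the sphere.

    Each quad gains four edge midpoints and a centroid, all renormalized
    to unit length; shared edge midpoints are deduplicated so the mesh
    stays watertight.
    """
    verts_list = list(verts)
    midpoint_cache: dict[tuple[int, int], int] = {}

    def midpoint(i: int, j: int) -> int:
        if i == j:
            return i
        key = (i, j) if i < j else (j, i)
        cached = midpoint_cache.get(key)
        if cached is not None:
            return cached
        m = verts_list[i] + verts_list[j]
        m = m / np.linalg.norm(m)
        verts_list.append(m)
        idx = len(verts_list) - 1
        midpoint_cache[key] = idx
        return idx

    new_faces = np.empty((4 * len(faces), 4), dtype=np.int64)
    k = 0
    for a, b, c, d in faces:
        mab = midpoint(a, b)
        mbc = midpoint(b, c)
        mcd = midpoint(c, d)
        mda = midpoint(d, a)
        centroid = verts_list[a] + verts_list[b] + verts_list[c] + verts_list[d]
        centroid = centroid / np.linalg.norm(centroid)
        verts_list.append(centroid)
        f = len(verts_list) - 1
        new_faces[k] = (a, mab, f, mda)
        new_faces[k + 1] = (mab, b, mbc, f)
        new_faces[k + 2] = (f, mbc, c, mcd)
        new_faces[k + 3] = (mda, f, mcd, d)
        k += 4
    return np.asarray(verts_list, dtype=float), new_faces


def build_mesh(e: Ellipsoid, subdivision: int) -> SurfaceMesh:
    """Mesh an ellipsoid surface at the requested subdivision level.

    Level 0 is a 16 x 16 latitude-longitude quadrilateral sphere grid;
    each further level quadrisects every face and reprojects new vertices
    onto the sphere before the affine map ``x = center + L u`` (``L`` the
    lower Cholesky factor of the shape matrix) carries the mesh onto the
    ellipsoid.  Deterministic for fixed inputs.
    """
    subdivision = int(subdivision)
    if subdivision < 0:
        raise ValidationError(
            f"subdivision must be non-negative, got {subdivision}"
        )
    verts, faces = _unit_sphere_mesh()
    for _ in range(subdivision):
        verts, faces = _subdivide_sphere(verts, faces)
    try:
        L = np.linalg.cholesky(e.shape)
    except np.linalg.LinAlgError as err:
        raise DegenerateCovarianceError(str(err)) from err
    vertices = verts @ L.T + e.center
    return SurfaceMesh(
        vertices=vertices, faces=faces, subdivision=subdivision, source=e
    )


def hull_volume(points: np.ndarray) -> float:
    """Convex hull volume of a point cloud; 0 for degenerate input.

    Fewer than four points, or a coplanar/collinear set that Qhull
    rejects, count as negligible volume rather than an error: tangent or
    barely touching ellipsoids legitimately produce such sets.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[0] < 4:
        return 0.0
    try:
        return float(ConvexHull(points).volume)
    except QhullError:
        return 0.0


def _edge_surface_intersections(
    mesh: SurfaceMesh, other: Ellipsoid
) -> np.ndarray:
    """Points where mesh edges cross the other ellipsoid's surface.

    Along each edge ``p + t (q - p)`` the squared Mahalanobis radius
    w.r.t. ``other`` is quadratic in ``t``; real roots in (0, 1) are
    boundary crossings and sharpen the intersection hull.
    """
    edges = mesh.edges()
    L = np.linalg.cholesky(other.shape)
    p = mesh.vertices[edges[:, 0]]
    q = mesh.vertices[edges[:, 1]]
    # Work in the whitened frame where `other` is the unit sphere.
    u = np.linalg.solve(L, (p - other.center).T).T
    d = np.linalg.solve(L, (q - p).T).T
    a = np.einsum("ij,ij->i", d, d)
    b = 2.0 * np.einsum("ij,ij->i", u, d)
    c = np.einsum("ij,ij->i", u, u) - 1.0
    disc = b * b - 4.0 * a * c
    valid = (a > 0) & (disc > 0)
    if not valid.any():
        return np.empty((0, 3))
    sqrt_disc = np.sqrt(disc[valid])
    a_v, b_v = a[valid], b[valid]
    p_v = p[valid]
    seg = q[valid] - p_v
    points = []
    for t in ((-b_v - sqrt_disc) / (2 * a_v), (-b_v + sqrt_disc) / (2 * a_v)):
        inside = (t > 0.0) & (t < 1.0)
        if inside.any():
            points.append(p_v[inside] + t[inside, None] * seg[inside])
    if not points:
        return np.empty((0, 3))
    return np.concatenate(points)


def overlap(
    eA: Ellipsoid, eB: Ellipsoid, subdivision: int = 4
) -> OverlapEstimate:
    """Directed overlap of two ellipsoids via mesh intersection hulls.

    Both ellipsoids must be at the same coverage scale.  The absolute
    intersection volume is symmetric in the arguments; the two directed
    percentages divide it by each mesh's own hull volume at the same
    subdivision level, so identical ellipsoids report exactly 100%.
    """
    if abs(eA.coverage - eB.coverage) > 1e-9:
        raise ScaleMismatchError(
            "scale mismatch: ellipsoids at coverages "
            f"{eA.coverage:.4f} and {eB.coverage:.4f}"
        )
    mesh_a = build_mesh(eA, subdivision)
    mesh_b = build_mesh(eB, subdivision)
    vol_a = hull_volume(mesh_a.vertices)
    vol_b = hull_volume(mesh_b.vertices)

    pieces = [
        mesh_a.vertices[eB.contains(mesh_a.vertices, rtol=_SURFACE_TOL)],
        mesh_b.vertices[eA.contains(mesh_b.vertices, rtol=_SURFACE_TOL)],
        _edge_surface_intersections(mesh_a, eB),
        _edge_surface_intersections(mesh_b, eA),
    ]
    points = np.concatenate([p for p in pieces if len(p)]) if any(
        len(p) for p in pieces
    ) else np.empty((0, 3))

    inter = hull_volume(points)
    # The hull of boundary-crossing points can poke marginally past the
    # inscribed mesh hulls; clamp so nesting reports exactly 100%.
    inter = min(inter, vol_a, vol_b)
    return OverlapEstimate(
        percent_of_first=100.0 * inter / vol_a,
        percent_of_second=100.0 * inter / vol_b,
        absolute_volume=inter,
        subdivision=int(subdivision),
    )


def mc_overlap_oracle(
    eA: Ellipsoid,
    eB: Ellipsoid,
    n_points: int = 1_000_000,
    seed: int | np.random.Generator | None = None,
) -> tuple[float, float]:
    """Monte Carlo rejection estimate of the intersection volume.

    Samples uniformly in the axis-aligned bounding box of ``eA`` and
    counts points falling inside both ellipsoids.  Returns the volume
    estimate and its binomial standard error.  Kept independent of the
    mesh pipeline so it can serve as an oracle for it.
    """
    n_points = int(n_points)
    if n_points < 10_000:
        raise ValidationError(
            f"n_points must be at least 10000, got {n_points}"
        )
    rng = np.random.default_rng(seed)
    half = np.sqrt(np.diag(eA.shape))
    lo, hi = eA.center - half, eA.center + half
    pts = rng.uniform(lo, hi, size=(n_points, 3))
    hits = eA.contains(pts) & eB.contains(pts)
    frac = hits.mean()
    box = float(np.prod(hi - lo))
    se = box * np.sqrt(frac * (1.0 - frac) / n_points)
    return box * float(frac), float(se)
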