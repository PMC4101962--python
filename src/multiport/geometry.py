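"""Exact minimum-distance queries between a drill axis and triangle meshes.

The drill path is modelled as a line *segment* from the entry point on the
skull surface to the target; the clearance of a path is the minimum Euclidean
distance from that segment to the surface of the nearest critical structure.
Two query paths are provided: a brute-force scan over every triangle and an
AABB-pruned scan.  Both evaluate the identical vectorised kernel on the
triangles they visit, so they return bit-identical distances; the pruned path
is simply allowed to skip triangles whose bounding box is provably farther
than the best distance found so far.

All coordinates are millimetres.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .volume_io import StructureMesh

logger = logging.getLogger(__name__)

_PARALLEL_EPS = 1e-12
# ||n||^2 thresholds for triangles: below _DEGEN_NN the triangle is truly
# degenerate (area ~ 0, rejected); below _SLIVER_NN the plane projection is
# numerically meaningless and the exact edge/endpoint candidates are used
# alone (for such slivers they bound the interior within the sliver height)
_DEGEN_NN = 1e-30
_SLIVER_NN = 1e-16


class DegenerateTriangleError(ValueError):
    pass


@dataclass(frozen=True, eq=False)
class Segment:
    """Closed line segment, ``a`` = entry end, ``b`` = target end."""

    a: np.ndarray
    b: np.ndarray

    def __post_init__(self) -> None:
        a = np.asarray(self.a, dtype=float)
        b = np.asarray(self.b, dtype=float)
        if a.shape != (3,) or b.shape != (3,):
            raise ValueError("segment endpoints must be 3-vectors")
        if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
            raise ValueError("segment endpoints must be finite")
        if np.linalg.norm(b - a) == 0.0:
            raise ValueError("segment has zero length")
        object.__setattr__(self, "a", a)
        object.__setattr__(self, "b", b)

    @property
    def length(self) -> float:
        return float(np.linalg.norm(self.b - self.a))

    @property
    def direction(self) -> np.ndarray:
        d = self.b - self.a
        return d / np.linalg.norm(d)


@dataclass(eq=False)
class ClearanceResult:
    """Minimum-distance witness between a segment and a mesh.

    ``distance`` is +inf (with empty witness fields) when there was nothing
    to collide with.
    """

    distance: float
    structure_name: str = ""
    triangle_index: int = -1
    closest_point_on_axis: np.ndarray = field(
        default_factory=lambda: np.full(3, np.nan)
    )
    closest_point_on_mesh: np.ndarray = field(
        default_factory=lambda: np.full(3, np.nan)
    )


# ---------------------------------------------------------------------------
# scalar kernels (witness-producing)
# ---------------------------------------------------------------------------

def closest_point_on_segment(p: np.ndarray, a: np.ndarray, b: np.ndarray):
    """Closest point of segment [a,b] to p, and its parameter in [0,1]."""
    p = np.asarray(p, dtype=float)
    ab = b - a
    t = float(np.dot(p - a, ab) / np.dot(ab, ab))
    t = min(1.0, max(0.0, t))
    return a + t * ab, t


def point_segment_distance(p: np.ndarray, seg: Segment) -> float:
    """Euclidean distance from a point to the closed segment."""
    c, _ = closest_point_on_segment(p, seg.a, seg.b)
    return float(np.linalg.norm(np.asarray(p, dtype=float) - c))


def closest_points_segments(p1, q1, p2, q2):
    """Closest points between closed segments [p1,q1] and [p2,q2].

    Standard two-stage clamping; both segments must be non-degenerate.
    """
    d1 = q1 - p1
    d2 = q2 - p2
    r = p1 - p2
    a = float(np.dot(d1, d1))
    e = float(np.dot(d2, d2))
    f = float(np.dot(d2, r))
    c = float(np.dot(d1, r))
    b = float(np.dot(d1, d2))
    denom = a * e - b * b
    if denom > _PARALLEL_EPS * a * e:
        s = min(1.0, max(0.0, (b * f - c * e) / denom))
    else:
        s = 0.0
    t = (b * s + f) / e
    if t < 0.0:
        t = 0.0
        s = min(1.0, max(0.0, -c / a))
    elif t > 1.0:
        t = 1.0
        s = min(1.0, max(0.0, (b - c) / a))
    return p1 + s * d1, p2 + t * d2, s, t


def _barycentric(p, v0, v1, v2):
    e0 = v1 - v0
    e1 = v2 - v0
    w = p - v0
    d00 = np.dot(e0, e0)
    d01 = np.dot(e0, e1)
    d11 = np.dot(e1, e1)
    d20 = np.dot(w, e0)
    d21 = np.dot(w, e1)
    denom = d00 * d11 - d01 * d01
    v = (d11 * d20 - d01 * d21) / denom
    u = (d00 * d21 - d01 * d20) / denom
    return 1.0 - v - u, v, u


def closest_point_on_triangle(p: np.ndarray, tri: np.ndarray) -> np.ndarray:
    """Closest point of a (non-degenerate) triangle to p."""
    v0, v1, v2 = (np.asarray(v, dtype=float) for v in tri)
    n = np.cross(v1 - v0, v2 - v0)
    nn = float(np.dot(n, n))
    if nn <= _DEGEN_NN:
        raise DegenerateTriangleError("triangle is degenerate")
    if nn > _SLIVER_NN:
        proj = p - (np.dot(p - v0, n) / nn) * n
        w, u, v = _barycentric(proj, v0, v1, v2)
        if w >= 0.0 and u >= 0.0 and v >= 0.0:
            return proj
    best = None
    best_d = np.inf
    for ea, eb in ((v0, v1), (v1, v2), (v2, v0)):
        c, _ = closest_point_on_segment(p, ea, eb)
        d = float(np.linalg.norm(p - c))
        if d < best_d:
            best_d = d
            best = c
    return best


def segment_triangle_closest_points(seg: Segment, tri: np.ndarray):
    """Witness pair (point on segment, point on triangle) at minimum distance.

    If segment and triangle intersect, both witnesses are the intersection
    point and the distance is exactly 0.
    """
    v0, v1, v2 = (np.asarray(v, dtype=float) for v in np.asarray(tri, dtype=float))
    n = np.cross(v1 - v0, v2 - v0)
    nn = float(np.dot(n, n))
    if nn <= _DEGEN_NN:
        raise DegenerateTriangleError("triangle is degenerate")
    d0 = float(np.dot(seg.a - v0, n))
    d1 = float(np.dot(seg.b - v0, n))
    # proper plane crossing -> possible interior intersection
    if nn > _SLIVER_NN and d0 * d1 <= 0.0 and (d0 != 0.0 or d1 != 0.0):
        s = d0 / (d0 - d1)
        x = seg.a + s * (seg.b - seg.a)
        w, u, v = _barycentric(x, v0, v1, v2)
        if w >= 0.0 and u >= 0.0 and v >= 0.0:
            return x, x, 0.0
    best = (None, None, np.inf)
    for ea, eb in ((v0, v1), (v1, v2), (v2, v0)):
        c1, c2, _, _ = closest_points_segments(seg.a, seg.b, ea, eb)
        d = float(np.linalg.norm(c1 - c2))
        if d < best[2]:
            best = (c1, c2, d)
    for p in (seg.a, seg.b):
        c = closest_point_on_triangle(p, (v0, v1, v2))
        d = float(np.linalg.norm(p - c))
        if d < best[2]:
            best = (p.copy(), c, d)
    return best


def segment_triangle_distance(seg: Segment, tri: np.ndarray) -> float:
    """Minimum distance between a closed segment and a closed triangle."""
    return segment_triangle_closest_points(seg, tri)[2]


# ---------------------------------------------------------------------------
# vectorised kernel over many triangles
# ---------------------------------------------------------------------------

def _segments_to_edges_distance(a, b, p, q):
    """Distances from the single segment [a,b] to n segments [p[i],q[i]]."""
    d1 = b - a                        # (3,)
    d2 = q - p                        # (n,3)
    r = a - p                         # (n,3)
    aa = float(np.dot(d1, d1))
    e = np.einsum("ij,ij->i", d2, d2)
    f = np.einsum("ij,ij->i", d2, r)
    c = r @ d1
    bb = d2 @ d1
    denom = aa * e - bb * bb
    parallel = denom <= _PARALLEL_EPS * aa * e
    with np.errstate(divide="ignore", invalid="ignore"):
        s = np.where(parallel, 0.0, np.clip((bb * f - c * e) / denom, 0.0, 1.0))
    t = (bb * s + f) / e
    tlo = t < 0.0
    thi = t > 1.0
    s = np.where(tlo, np.clip(-c / aa, 0.0, 1.0), s)
    s = np.where(thi, np.clip((bb - c) / aa, 0.0, 1.0), s)
    t = np.clip(t, 0.0, 1.0)
    c1 = a + s[:, None] * d1
    c2 = p + t[:, None] * d2
    return np.linalg.norm(c1 - c2, axis=1)


def _point_to_triangles_distance(p, v0, v1, v2, n, nn):
    """Distances from point p to n triangles (normals precomputed)."""
    e0 = v1 - v0
    e1 = v2 - v0
    w = p - v0
    d00 = np.einsum("ij,ij->i", e0, e0)
    d01 = np.einsum("ij,ij->i", e0, e1)
    d11 = np.einsum("ij,ij->i", e1, e1)
    d20 = np.einsum("ij,ij->i", w, e0)
    d21 = np.einsum("ij,ij->i", w, e1)
    denom = d00 * d11 - d01 * d01
    bv = (d11 * d20 - d01 * d21) / denom
    bu = (d00 * d21 - d01 * d20) / denom
    bw = 1.0 - bv - bu
    inside = (bw >= 0.0) & (bv >= 0.0) & (bu >= 0.0) & (nn > _SLIVER_NN)
    plane_dist = np.abs(np.einsum("ij,ij->i", w, n)) / np.sqrt(nn)
    edge_dist = np.full(len(v0), np.inf)
    for ea, eb in ((v0, v1), (v1, v2), (v2, v0)):
        d = eb - ea
        t = np.clip(np.einsum("ij,ij->i", p - ea, d) / np.einsum("ij,ij->i", d, d), 0.0, 1.0)
        edge_dist = np.minimum(edge_dist, np.linalg.norm(p - (ea + t[:, None] * d), axis=1))
    return np.where(inside, plane_dist, edge_dist)


def segment_triangles_distance_batch(seg: Segment, triangles: np.ndarray) -> np.ndarray:
    """Minimum distance from one segment to each of an (n,3,3) triangle array.

    This is the kernel shared by the brute-force and the pruned mesh query;
    it mirrors the scalar candidate decomposition (interior intersection,
    three edges, two endpoints) exactly.
    """
    tris = np.asarray(triangles, dtype=float)
    v0, v1, v2 = tris[:, 0], tris[:, 1], tris[:, 2]
    n = np.cross(v1 - v0, v2 - v0)
    nn = np.einsum("ij,ij->i", n, n)
    if np.any(nn <= _DEGEN_NN):
        raise DegenerateTriangleError("degenerate triangle in batch")

    d0 = np.einsum("ij,ij->i", seg.a - v0, n)
    d1 = np.einsum("ij,ij->i", seg.b - v0, n)
    crossing = (nn > _SLIVER_NN) & (d0 * d1 <= 0.0) & ((d0 != 0.0) | (d1 != 0.0))
    dist = np.full(len(tris), np.inf)
    if np.any(crossing):
        s = d0[crossing] / (d0[crossing] - d1[crossing])
        x = seg.a + s[:, None] * (seg.b - seg.a)
        cw, cu, cv = _barycentric_batch(x, v0[crossing], v1[crossing], v2[crossing])
        hit = (cw >= 0.0) & (cu >= 0.0) & (cv >= 0.0)
        idx = np.flatnonzero(crossing)[hit]
        dist[idx] = 0.0

    todo = dist > 0.0
    if np.any(todo):
        sv0, sv1, sv2 = v0[todo], v1[todo], v2[todo]
        d = np.full(todo.sum(), np.inf)
        for ea, eb in ((sv0, sv1), (sv1, sv2), (sv2, sv0)):
            d = np.minimum(d, _segments_to_edges_distance(seg.a, seg.b, ea, eb))
        sn = n[todo]
        snn = nn[todo]
        for p in (seg.a, seg.b):
            d = np.minimum(d, _point_to_triangles_distance(p, sv0, sv1, sv2, sn, snn))
        dist[todo] = d
    return dist


def _barycentric_batch(p, v0, v1, v2):
    e0 = v1 - v0
    e1 = v2 - v0
    w = p - v0
    d00 = np.einsum("ij,ij->i", e0, e0)
    d01 = np.einsum("ij,ij->i", e0, e1)
    d11 = np.einsum("ij,ij->i", e1, e1)
    d20 = np.einsum("ij,ij->i", w, e0)
    d21 = np.einsum("ij,ij->i", w, e1)
    denom = d00 * d11 - d01 * d01
    bv = (d11 * d20 - d01 * d21) / denom
    bu = (d00 * d21 - d01 * d20) / denom
    return 1.0 - bv - bu, bv, bu


# ---------------------------------------------------------------------------
# mesh-level queries
# ---------------------------------------------------------------------------

def _witness_result(seg: Segment, mesh: StructureMesh, tri_idx: int) -> ClearanceResult:
    tri = mesh.vertices[mesh.faces[tri_idx]]
    pa, pm, d = segment_triangle_closest_points(seg, tri)
    return ClearanceResult(
        distance=d,
        structure_name=mesh.name,
        triangle_index=int(tri_idx),
        closest_point_on_axis=pa,
        closest_point_on_mesh=pm,
    )


def mesh_clearance(seg: Segment, mesh: StructureMesh, method: str = "auto") -> ClearanceResult:
    """Minimum distance between the segment and every triangle of the mesh.

    ``method`` selects ``"brute"`` (scan all triangles), ``"pruned"`` (AABB
    lower-bound pruning) or ``"auto"`` (pruned for large meshes).  All
    methods agree exactly: pruning only skips triangles whose bounding box
    distance already exceeds an achieved upper bound.
    """
    if len(mesh.faces) == 0:
        raise ValueError(f"mesh '{mesh.name}' is empty")
    tris = mesh.triangles()
    if method == "auto":
        method = "pruned" if len(tris) > 256 else "brute"
    if method == "brute":
        dist = segment_triangles_distance_batch(seg, tris)
        idx = int(np.argmin(dist))
        return _witness_result(seg, mesh, idx)
    if method != "pruned":
        raise ValueError(f"unknown method {method!r}")

    # lower bound: AABB(segment) to AABB(triangle) distance
    seg_lo = np.minimum(seg.a, seg.b)
    seg_hi = np.maximum(seg.a, seg.b)
    tri_lo, tri_hi = mesh.triangle_bounds()
    gap = np.maximum(0.0, np.maximum(tri_lo - seg_hi, seg_lo - tri_hi))
    lower = np.linalg.norm(gap, axis=1)

    # cheap upper bound: exact distance of the triangle with the nearest box
    seed = int(np.argmin(lower))
    ub = segment_triangles_distance_batch(seg, tris[seed : seed + 1])[0]
    keep = np.flatnonzero(lower <= ub)
    dist = segment_triangles_distance_batch(seg, tris[keep])
    local = int(np.argmin(dist))
    return _witness_result(seg, mesh, int(keep[local]))


# fixed, incommensurate ray directions for the parity test; if a ray grazes
# an edge or vertex the next direction is tried
_RAY_DIRECTIONS = np.array(
    [
        [0.57735027, 0.57735027, 0.57735027],
        [0.26726124, 0.53452248, 0.80178373],
        [-0.81649658, 0.40824829, 0.40824829],
        [0.12309149, -0.49236596, 0.86164044],
    ]
)
_RAY_EPS = 1e-10


def _ray_parity(p: np.ndarray, tris: np.ndarray, direction: np.ndarray):
    """Count proper ray-triangle crossings; None when a hit is ambiguous."""
    v0, v1, v2 = tris[:, 0], tris[:, 1], tris[:, 2]
    e1 = v1 - v0
    e2 = v2 - v0
    h = np.cross(direction, e2)
    det = np.einsum("ij,ij->i", e1, h)
    scale = np.linalg.norm(e1, axis=1) * np.linalg.norm(e2, axis=1)
    parallel = np.abs(det) <= _RAY_EPS * scale
    with np.errstate(divide="ignore", invalid="ignore"):
        inv = 1.0 / det
        s = p - v0
        u = np.einsum("ij,ij->i", s, h) * inv
        q = np.cross(s, e1)
        v = (q @ direction) * inv
        t = np.einsum("ij,ij->i", q, e2) * inv
    inside = (~parallel) & (u > _RAY_EPS) & (v > _RAY_EPS) & (u + v < 1 - _RAY_EPS) & (
        t > _RAY_EPS
    )
    # ambiguous: a crossing near an edge/vertex of the triangle, a ray origin
    # on the surface, or a near-parallel triangle crossed by the ray band
    near = (~parallel) & (
        (np.abs(u) <= _RAY_EPS)
        | (np.abs(v) <= _RAY_EPS)
        | (np.abs(1 - u - v) <= _RAY_EPS)
        | (np.abs(t) <= _RAY_EPS)
    ) & (u > -1e-6) & (v > -1e-6) & (u + v < 1 + 1e-6) & (t > -1e-6)
    if np.any(near):
        return None
    return int(np.count_nonzero(inside))


def point_in_closed_mesh(p: np.ndarray, mesh: StructureMesh) -> bool:
    """Ray-parity containment test; the mesh must be closed."""
    p = np.asarray(p, dtype=float)
    lo = mesh.vertices.min(axis=0)
    hi = mesh.vertices.max(axis=0)
    if np.any(p < lo) or np.any(p > hi):
        return False
    tris = mesh.vertices[mesh.faces]
    for direction in _RAY_DIRECTIONS:
        crossings = _ray_parity(p, tris, direction)
        if crossings is not None:
            return crossings % 2 == 1
    raise RuntimeError("containment test degenerate for all ray directions")


class _MeshGroup:
    """Concatenated triangles of several meshes for one-shot clearance.

    Equivalent to taking the minimum of per-mesh :func:`mesh_clearance`
    (triangles are concatenated in mesh order, so ties resolve to the first
    mesh exactly as the per-mesh loop would); exists purely to amortise the
    per-call overhead when thousands of candidate entries are evaluated
    against the same critical set.
    """

    def __init__(self, meshes: list[StructureMesh]):
        self.meshes = list(meshes)
        self.tris = np.concatenate([m.triangles() for m in meshes])
        lo = [m.triangle_bounds()[0] for m in meshes]
        hi = [m.triangle_bounds()[1] for m in meshes]
        self.tri_lo = np.concatenate(lo)
        self.tri_hi = np.concatenate(hi)
        counts = [len(m.faces) for m in meshes]
        self.offsets = np.concatenate([[0], np.cumsum(counts)])
        self.mesh_of_tri = np.repeat(np.arange(len(meshes)), counts)

    def min_clearance(self, seg: Segment) -> ClearanceResult:
        seg_lo = np.minimum(seg.a, seg.b)
        seg_hi = np.maximum(seg.a, seg.b)
        gap = np.maximum(0.0, np.maximum(self.tri_lo - seg_hi, seg_lo - self.tri_hi))
        lower = np.linalg.norm(gap, axis=1)
        seed = int(np.argmin(lower))
        ub = segment_triangles_distance_batch(seg, self.tris[seed : seed + 1])[0]
        keep = np.flatnonzero(lower <= ub)
        dist = segment_triangles_distance_batch(seg, self.tris[keep])
        gidx = int(keep[int(np.argmin(dist))])
        mesh_idx = int(self.mesh_of_tri[gidx])
        return _witness_result(
            seg, self.meshes[mesh_idx], gidx - int(self.offsets[mesh_idx])
        )


_GROUP_CACHE: dict[tuple[int, ...], _MeshGroup] = {}


def _mesh_group(meshes: list[StructureMesh]) -> _MeshGroup:
    key = tuple(id(m) for m in meshes)
    group = _GROUP_CACHE.get(key)
    if group is None or any(a is not b for a, b in zip(group.meshes, meshes)):
        if len(_GROUP_CACHE) > 32:
            _GROUP_CACHE.clear()
        group = _MeshGroup(meshes)
        _GROUP_CACHE[key] = group
    return group


def capsule_is_free(
    seg: Segment,
    radius: float,
    meshes: list[StructureMesh],
    inside_cache: dict | None = None,
) -> tuple[bool, ClearanceResult]:
    """Whether a drill capsule of the given radius avoids every mesh.

    Free iff the minimum axis clearance over all meshes is >= ``radius``
    (grazing contact at exactly the radius passes) and neither endpoint lies
    inside a closed mesh.  Containment is skipped, with a warning, for
    non-watertight meshes.  ``inside_cache`` may be supplied to amortise
    repeated endpoint containment tests across many segments sharing
    endpoints (keyed on mesh identity and point bytes).
    """
    if radius < 0.0:
        raise ValueError("radius must be >= 0")
    if not meshes:
        return True, ClearanceResult(distance=np.inf)
    best = _mesh_group(meshes).min_clearance(seg)
    contained = False
    for mesh in meshes:
        if not mesh.is_closed():
            warnings.warn(
                f"mesh '{mesh.name}' is not watertight; containment test skipped",
                stacklevel=2,
            )
            logger.warning("containment skipped for open mesh %s", mesh.name)
            continue
        for p in (seg.a, seg.b):
            if inside_cache is not None:
                key = (id(mesh), p.tobytes())
                if key not in inside_cache:
                    inside_cache[key] = point_in_closed_mesh(p, mesh)
                inside = inside_cache[key]
            else:
                inside = point_in_closed_mesh(p, mesh)
            if inside:
                contained = True
                break
        if contained:
            break
    free = (best.distance >= radius) and not contained
    return free, best
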