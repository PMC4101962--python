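"""Synthetic temporal-bone scenes with analytic ground truth.

Real planning runs start from segmented CT volumes that are not shippable;
the phantom generator stands in for them with scenes whose geometry has
closed forms.  A scene is a hollow hemispherical bone "pot" (dome shell plus
a floor slab, so marching cubes yields a closed skull surface) containing
analytic obstacles that mimic temporal-bone anatomy:

* spheres      — cochlea, jugular bulb, ossicle-mass analogues
* capsules     — facial nerve, chorda tympani, carotid-artery analogues
* torus arcs   — semicircular-canal analogues

Every primitive supports three consistent representations: a voxel label
map, a triangle mesh with a computed chord-error bound, and a closed-form
(or 1-D-minimised, for the torus arc) clearance to any line segment.  That
makes the whole planning pipeline testable against independent ground truth.

Targets sit at depths comparable to the round window (~25 mm), internal
auditory canal (~40 mm) and petrous apex (~55 mm) below the dome apex.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import trimesh
from scipy.optimize import minimize_scalar

from .geometry import (
    Segment,
    closest_points_segments,
    point_segment_distance,
    segment_triangles_distance_batch,
)
from .volume_io import LabelVolume, StructureMesh

BONE_LABEL = 1
BONE_NAME = "bone"


# ---------------------------------------------------------------------------
# primitives
# ---------------------------------------------------------------------------

@dataclass(frozen=True, eq=False)
class SpherePrimitive:
    name: str
    center: tuple[float, float, float]
    radius: float
    critical: bool = True
    label: int = 0

    kind = "sphere"

    def __post_init__(self):
        if self.radius <= 0:
            raise ValueError("sphere radius must be > 0")

    def aabb(self):
        c = np.asarray(self.center)
        return c - self.radius, c + self.radius

    def medial_distance(self, points: np.ndarray) -> np.ndarray:
        return np.linalg.norm(points - np.asarray(self.center), axis=-1)

    def clearance(self, seg: Segment) -> float:
        d = point_segment_distance(np.asarray(self.center), seg) - self.radius
        return max(0.0, d)

    def point_clearance(self, p: np.ndarray) -> float:
        return max(
            0.0, float(np.linalg.norm(p - np.asarray(self.center)) - self.radius)
        )

    def mesh(self, tol: float = 0.05) -> tuple[StructureMesh, float]:
        """Inscribed triangle mesh and its exact chord-error bound (mm)."""
        for sub in (2, 3, 4, 5):
            tm = trimesh.creation.icosphere(subdivisions=sub, radius=self.radius)
            bound = _mesh_sag_point(np.zeros(3), tm, self.radius)
            if bound <= tol:
                break
        tm.apply_translation(np.asarray(self.center))
        return _as_structure(tm, self), bound


@dataclass(frozen=True, eq=False)
class CapsulePrimitive:
    name: str
    a: tuple[float, float, float]
    b: tuple[float, float, float]
    radius: float
    critical: bool = True
    label: int = 0

    kind = "capsule"

    def __post_init__(self):
        if self.radius <= 0:
            raise ValueError("capsule radius must be > 0")
        if np.linalg.norm(np.subtract(self.b, self.a)) == 0:
            raise ValueError("capsule axis has zero length")

    def aabb(self):
        a, b = np.asarray(self.a), np.asarray(self.b)
        return np.minimum(a, b) - self.radius, np.maximum(a, b) + self.radius

    def medial_distance(self, points: np.ndarray) -> np.ndarray:
        a, b = np.asarray(self.a, float), np.asarray(self.b, float)
        ab = b - a
        t = np.clip(((points - a) @ ab) / (ab @ ab), 0.0, 1.0)
        return np.linalg.norm(points - (a + t[..., None] * ab), axis=-1)

    def clearance(self, seg: Segment) -> float:
        c1, c2, _, _ = closest_points_segments(
            seg.a, seg.b, np.asarray(self.a, float), np.asarray(self.b, float)
        )
        return max(0.0, float(np.linalg.norm(c1 - c2)) - self.radius)

    def point_clearance(self, p: np.ndarray) -> float:
        return max(0.0, float(self.medial_distance(p[None, :])[0]) - self.radius)

    def mesh(self, tol: float = 0.05) -> tuple[StructureMesh, float]:
        a, b = np.asarray(self.a, float), np.asarray(self.b, float)
        height = float(np.linalg.norm(b - a))
        for count in (16, 24, 32, 48):
            tm = trimesh.creation.capsule(
                height=height, radius=self.radius, count=(count, count)
            )
            tf = trimesh.geometry.align_vectors([0, 0, 1], (b - a) / height)
            tf[:3, 3] = (a + b) / 2.0
            tm.apply_transform(tf)
            bound = _mesh_sag_segment(a, b, tm, self.radius)
            if bound <= tol:
                break
        return _as_structure(tm, self), bound


@dataclass(frozen=True, eq=False)
class TorusArcPrimitive:
    """Circular-arc tube: arc of radius ``arc_radius`` around ``center`` in
    the plane spanned by the orthonormal ``axis_u``/``axis_v``, swept by a
    tube of ``tube_radius``, for angles in [angle_start, angle_end] radians.
    """

    name: str
    center: tuple[float, float, float]
    axis_u: tuple[float, float, float]
    axis_v: tuple[float, float, float]
    arc_radius: float
    tube_radius: float
    angle_start: float = 0.0
    angle_end: float = np.pi
    critical: bool = True
    label: int = 0

    kind = "torus_arc"

    def __post_init__(self):
        if self.arc_radius <= 0 or self.tube_radius <= 0:
            raise ValueError("torus radii must be > 0")
        u = np.asarray(self.axis_u, float)
        v = np.asarray(self.axis_v, float)
        if abs(np.linalg.norm(u) - 1) > 1e-8 or abs(np.linalg.norm(v) - 1) > 1e-8:
            raise ValueError("axis_u/axis_v must be unit vectors")
        if abs(float(u @ v)) > 1e-8:
            raise ValueError("axis_u and axis_v must be orthogonal")
        if not (0 < self.angle_end - self.angle_start <= 2 * np.pi):
            raise ValueError("angle range must be in (0, 2*pi]")

    def arc_point(self, theta) -> np.ndarray:
        c = np.asarray(self.center, float)
        u = np.asarray(self.axis_u, float)
        v = np.asarray(self.axis_v, float)
        theta = np.asarray(theta, float)
        return c + self.arc_radius * (
            np.cos(theta)[..., None] * u + np.sin(theta)[..., None] * v
        )

    def aabb(self):
        theta = np.linspace(self.angle_start, self.angle_end, 256)
        pts = self.arc_point(theta)
        r = self.tube_radius
        return pts.min(axis=0) - r, pts.max(axis=0) + r

    def medial_distance(self, points: np.ndarray) -> np.ndarray:
        """Distance from points to the medial arc (vectorised, with angular
        clamping to the nearer arc endpoint outside the angular range)."""
        c = np.asarray(self.center, float)
        u = np.asarray(self.axis_u, float)
        v = np.asarray(self.axis_v, float)
        w = np.cross(u, v)
        rel = points - c
        pu = rel @ u
        pv = rel @ v
        pw = rel @ w
        rho = np.hypot(pu, pv)
        # full-circle distance
        d_circle = np.sqrt((rho - self.arc_radius) ** 2 + pw**2)
        theta = np.arctan2(pv, pu)
        # wrap into [angle_start, angle_start + 2*pi)
        theta = self.angle_start + np.mod(theta - self.angle_start, 2 * np.pi)
        in_range = theta <= self.angle_end
        ends = self.arc_point(np.array([self.angle_start, self.angle_end]))
        d_ends = np.minimum(
            np.linalg.norm(points - ends[0], axis=-1),
            np.linalg.norm(points - ends[1], axis=-1),
        )
        return np.where(in_range, d_circle, d_ends)

    @property
    def radius(self) -> float:
        return self.tube_radius

    def clearance(self, seg: Segment) -> float:
        """Semi-analytic: 1-D minimisation of segment distance over the arc
        parameter, multi-started from a dense scan to handle multimodality."""

        def f(theta: float) -> float:
            return point_segment_distance(self.arc_point(theta), seg)

        thetas = np.linspace(self.angle_start, self.angle_end, 129)
        vals = np.array([f(t) for t in thetas])
        best = vals.min()
        order = np.argsort(vals)[:3]
        for i in order:
            lo = thetas[max(0, i - 1)]
            hi = thetas[min(len(thetas) - 1, i + 1)]
            if hi > lo:
                res = minimize_scalar(f, bounds=(lo, hi), method="bounded",
                                      options={"xatol": 1e-10})
                best = min(best, float(res.fun))
        return max(0.0, best - self.tube_radius)

    def point_clearance(self, p: np.ndarray) -> float:
        return max(
            0.0, float(self.medial_distance(p[None, :])[0]) - self.tube_radius
        )

    def mesh(self, tol: float = 0.05) -> tuple[StructureMesh, float]:
        for n_arc, n_tube in ((48, 16), (72, 24), (128, 32)):
            tm = self._tube_mesh(n_arc, n_tube)
            # conservative bound: tube sag + arc polyline sag
            arc_step = (self.angle_end - self.angle_start) / n_arc
            sag = self.tube_radius * (1 - np.cos(np.pi / n_tube)) + (
                self.arc_radius * (1 - np.cos(arc_step / 2))
            )
            if sag <= tol:
                break
        return _as_structure(tm, self), float(sag)

    def _tube_mesh(self, n_arc: int, n_tube: int) -> trimesh.Trimesh:
        u = np.asarray(self.axis_u, float)
        v = np.asarray(self.axis_v, float)
        w = np.cross(u, v)
        thetas = np.linspace(self.angle_start, self.angle_end, n_arc + 1)
        phis = np.arange(n_tube) * (2 * np.pi / n_tube)
        centers = self.arc_point(thetas)                       # (na+1, 3)
        e_r = np.cos(thetas)[:, None] * u + np.sin(thetas)[:, None] * v
        ring = (
            centers[:, None, :]
            + self.tube_radius
            * (
                np.cos(phis)[None, :, None] * e_r[:, None, :]
                + np.sin(phis)[None, :, None] * w[None, None, :]
            )
        )                                                      # (na+1, nt, 3)
        verts = ring.reshape(-1, 3)
        faces = []
        for i in range(n_arc):
            for j in range(n_tube):
                a = i * n_tube + j
                b = i * n_tube + (j + 1) % n_tube
                c = (i + 1) * n_tube + j
                d = (i + 1) * n_tube + (j + 1) % n_tube
                faces.append((a, b, d))
                faces.append((a, d, c))
        # end caps: fans from the arc end points
        cap0 = len(verts)
        cap1 = len(verts) + 1
        verts = np.vstack([verts, centers[0], centers[-1]])
        for j in range(n_tube):
            faces.append((cap0, (j + 1) % n_tube, j))
            base = n_arc * n_tube
            faces.append((cap1, base + j, base + (j + 1) % n_tube))
        return trimesh.Trimesh(verts, np.array(faces), process=False)


Primitive = SpherePrimitive | CapsulePrimitive | TorusArcPrimitive


def _as_structure(tm: trimesh.Trimesh, prim) -> StructureMesh:
    return StructureMesh(
        name=prim.name,
        label=prim.label,
        vertices=np.asarray(tm.vertices),
        faces=np.asarray(tm.faces),
        critical=prim.critical,
    )


def _mesh_sag_point(center: np.ndarray, tm: trimesh.Trimesh, radius: float) -> float:
    """Exact inscribed-mesh sag of a sphere mesh: R minus the closest
    approach of any face plane region to the centre."""
    tris = tm.vertices[tm.faces]
    n = np.cross(tris[:, 1] - tris[:, 0], tris[:, 2] - tris[:, 0])
    d = np.abs(np.einsum("ij,ij->i", tris[:, 0] - center, n)) / np.linalg.norm(
        n, axis=1
    )
    return float(radius - d.min())


def _mesh_sag_segment(a, b, tm: trimesh.Trimesh, radius: float) -> float:
    """Exact sag of a capsule mesh: r minus the minimum distance from the
    medial segment to any mesh triangle."""
    seg = Segment(a=a, b=b)
    d = segment_triangles_distance_batch(seg, tm.vertices[tm.faces])
    return float(radius - d.min())


def analytic_clearance(seg: Segment, primitive) -> float:
    """Closed-form (or 1-D-search) minimum distance from a segment to the
    primitive's surface, clamped at 0 on intersection."""
    if not hasattr(primitive, "clearance"):
        raise TypeError(f"unsupported primitive {type(primitive).__name__}")
    return primitive.clearance(seg)


# ---------------------------------------------------------------------------
# scene specification
# ---------------------------------------------------------------------------

@dataclass(frozen=True, eq=False)
class BoneShell:
    """Hemispherical dome shell (z >= 0) plus a floor slab, so the bone
    surface encloses the working cavity."""

    outer_radius: float
    thickness: float

    def __post_init__(self):
        if self.outer_radius <= 0 or self.thickness <= 0:
            raise ValueError("shell parameters must be > 0")
        if self.thickness >= self.outer_radius:
            raise ValueError("shell thickness must be below the outer radius")

    @property
    def inner_radius(self) -> float:
        return self.outer_radius - self.thickness


@dataclass(eq=False)
class PhantomSpec:
    """Full description of one synthetic scene (deterministic in ``seed``)."""

    seed: int
    bone_shell: BoneShell
    obstacles: list
    targets: dict[str, tuple[float, float, float]]
    spacing: float = 0.25
    mesh_tol: float = 0.05
    corridors: dict[str, dict] = field(default_factory=dict)

    def __post_init__(self) -> None:
        names = [p.name for p in self.obstacles]
        if len(set(names)) != len(names):
            raise ValueError("obstacle names must be unique")
        if self.spacing <= 0:
            raise ValueError("spacing must be > 0")
        relabeled = []
        for i, p in enumerate(self.obstacles):
            if p.label == 0:
                p = dataclasses.replace(p, label=BONE_LABEL + 1 + i)
            relabeled.append(p)
        self.obstacles = relabeled
        inner = self.bone_shell.inner_radius
        for name, t in self.targets.items():
            t = np.asarray(t, float)
            if np.linalg.norm(t) >= inner or t[2] <= 0:
                raise ValueError(
                    f"target {name!r} is not strictly inside the bone shell"
                )

    @property
    def entry_seed(self) -> np.ndarray:
        """Apex of the dome: default centre of the entry region."""
        return np.array([0.0, 0.0, self.bone_shell.outer_radius])

    @property
    def label_names(self) -> dict[int, str]:
        names = {BONE_LABEL: BONE_NAME}
        names.update({p.label: p.name for p in self.obstacles})
        return names

    def to_dict(self) -> dict:
        prims = []
        for p in self.obstacles:
            d = dataclasses.asdict(p)
            d["kind"] = p.kind
            prims.append(d)
        return {
            "seed": int(self.seed),
            "bone_shell": {
                "outer_radius": self.bone_shell.outer_radius,
                "thickness": self.bone_shell.thickness,
            },
            "obstacles": prims,
            "targets": {k: [float(x) for x in v] for k, v in self.targets.items()},
            "spacing": self.spacing,
            "mesh_tol": self.mesh_tol,
            "corridors": self.corridors,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomSpec":
        kinds = {
            "sphere": SpherePrimitive,
            "capsule": CapsulePrimitive,
            "torus_arc": TorusArcPrimitive,
        }
        obstacles = []
        for pd in d["obstacles"]:
            pd = dict(pd)
            kind = pd.pop("kind")
            for key in ("center", "a", "b", "axis_u", "axis_v"):
                if key in pd:
                    pd[key] = tuple(pd[key])
            obstacles.append(kinds[kind](**pd))
        return cls(
            seed=d["seed"],
            bone_shell=BoneShell(**d["bone_shell"]),
            obstacles=obstacles,
            targets={k: tuple(v) for k, v in d["targets"].items()},
            spacing=d.get("spacing", 0.25),
            mesh_tol=d.get("mesh_tol", 0.05),
            corridors=d.get("corridors", {}),
        )


# ---------------------------------------------------------------------------
# scene construction
# ---------------------------------------------------------------------------

class LabelConflictError(ValueError):
    """Two primitives claim the same voxel with different labels."""


def build_phantom(
    spec: PhantomSpec,
) -> tuple[LabelVolume, list[StructureMesh], dict]:
    """Voxelise the scene and mesh the primitives directly.

    Returns the label volume (bone = 1, obstacles in spec order), the
    directly meshed obstacle surfaces, and the analytic registry mapping
    each obstacle name to its primitive and the chord-error bound of its
    mesh.  Overlapping primitives are an error, not a silent overwrite.
    """
    shell = spec.bone_shell
    h = spec.spacing
    pad = 2 * h
    lo = np.array(
        [-shell.outer_radius - pad, -shell.outer_radius - pad, -shell.thickness - pad]
    )
    hi = np.array(
        [shell.outer_radius + pad, shell.outer_radius + pad, shell.outer_radius + pad]
    )
    shape = np.ceil((hi - lo) / h).astype(int) + 1
    origin = lo
    axes = [origin[k] + np.arange(shape[k]) * h for k in range(3)]

    labels = np.zeros(shape, dtype=np.int16)
    X = axes[0][:, None, None]
    Y = axes[1][None, :, None]
    Z = axes[2][None, None, :]
    r = np.sqrt(X**2 + Y**2 + Z**2)
    rho2 = X**2 + Y**2
    dome = (Z >= 0) & (r >= shell.inner_radius) & (r <= shell.outer_radius)
    floor = (
        (Z < 0)
        & (Z >= -shell.thickness)
        & (rho2 <= shell.outer_radius**2)
    )
    labels[dome | floor] = BONE_LABEL
    del r, rho2, dome, floor

    meshes = []
    registry: dict[str, dict] = {}
    for prim in spec.obstacles:
        alo, ahi = prim.aabb()
        sl = []
        for k in range(3):
            i0 = int(np.clip(np.floor((alo[k] - h - origin[k]) / h), 0, shape[k]))
            i1 = int(np.clip(np.ceil((ahi[k] + h - origin[k]) / h) + 1, 0, shape[k]))
            sl.append(slice(i0, i1))
        pts = np.stack(
            np.meshgrid(
                axes[0][sl[0]], axes[1][sl[1]], axes[2][sl[2]], indexing="ij"
            ),
            axis=-1,
        )
        inside = prim.medial_distance(pts) <= prim.radius
        sub = labels[tuple(sl)]
        clash = inside & (sub != 0)
        if np.any(clash):
            other = int(sub[clash][0])
            raise LabelConflictError(
                f"primitive {prim.name!r} overlaps label "
                f"{spec.label_names.get(other, other)!r}"
            )
        sub[inside] = prim.label
        mesh, bound = prim.mesh(spec.mesh_tol)
        meshes.append(mesh)
        registry[prim.name] = {"primitive": prim, "mesh_error": bound}

    volume = LabelVolume(
        voxels=labels, spacing=np.full(3, h), origin=origin,
        label_names=spec.label_names,
    )
    return volume, meshes, registry


# ---------------------------------------------------------------------------
# scene generators
# ---------------------------------------------------------------------------

# slack added on top of the guaranteed corridor clearance so the guarantee
# survives entry-point snapping to mesh centroids and mesh chord error
_CORRIDOR_SLACK = 1.5


def random_scene(
    seed: int,
    n_obstacles: int,
    difficulty: float = 0.5,
    outer_radius: float = 30.0,
    thickness: float = 4.0,
    spacing: float = 0.5,
) -> PhantomSpec:
    """Reproducible random scene with a guaranteed open corridor.

    ``difficulty`` in [0, 1] narrows the guaranteed corridor clearance
    c* = 1.0 + 3.0 * (1 - difficulty) mm from the dome apex to each target;
    obstacles are rejection-sampled to keep at least that clearance (plus an
    internal slack absorbing entry snapping), to stay inside the cavity, and
    not to overlap each other or bury a target.  The recorded c* is stored
    in ``spec.corridors``.
    """
    if not 0.0 <= difficulty <= 1.0:
        raise ValueError("difficulty must be in [0, 1]")
    if n_obstacles < 0:
        raise ValueError("n_obstacles must be >= 0")
    rng = np.random.default_rng(seed)
    shell = BoneShell(outer_radius=outer_radius, thickness=thickness)
    inner = shell.inner_radius
    c_star = 1.0 + 3.0 * (1.0 - difficulty)

    depth = rng.uniform(0.5 * outer_radius, 0.75 * outer_radius)
    az = rng.uniform(0, 2 * np.pi)
    lateral = rng.uniform(0.0, 0.2 * inner)
    target = np.array(
        [lateral * np.cos(az), lateral * np.sin(az), outer_radius - depth]
    )
    apex = np.array([0.0, 0.0, outer_radius])
    corridor = Segment(a=apex, b=target)

    obstacles: list = []
    keep_out = c_star + _CORRIDOR_SLACK
    for i in range(n_obstacles):
        for _ in range(200):
            kind = rng.choice(["sphere", "capsule"])
            if kind == "sphere":
                radius = rng.uniform(1.5, 3.0)
                center = _sample_in_cavity(rng, inner, radius)
                prim = SpherePrimitive(
                    name=f"sphere_{i}", center=tuple(center), radius=radius
                )
            else:
                radius = rng.uniform(0.8, 1.5)
                a = _sample_in_cavity(rng, inner, radius)
                direction = rng.normal(size=3)
                direction /= np.linalg.norm(direction)
                b = a + direction * rng.uniform(4.0, 10.0)
                if np.linalg.norm(b) + radius > inner - 0.5 or b[2] - radius < 0.5:
                    continue
                prim = CapsulePrimitive(
                    name=f"capsule_{i}", a=tuple(a), b=tuple(b), radius=radius
                )
            if prim.clearance(corridor) < keep_out:
                continue
            if prim.point_clearance(target) < 1.0:
                continue
            if any(_primitive_gap(prim, q) < 0.3 for q in obstacles):
                continue
            obstacles.append(prim)
            break
    return PhantomSpec(
        seed=seed,
        bone_shell=shell,
        obstacles=obstacles,
        targets={"t1": tuple(target)},
        spacing=spacing,
        corridors={
            "t1": {"surface_point": [0.0, 0.0, outer_radius], "clearance": c_star}
        },
    )


def _sample_in_cavity(rng, inner: float, radius: float) -> np.ndarray:
    while True:
        p = rng.uniform(-inner, inner, size=3)
        p[2] = abs(p[2])
        if (
            np.linalg.norm(p) + radius <= inner - 0.5
            and p[2] - radius >= 0.5
        ):
            return p


def _primitive_gap(p1, p2) -> float:
    """Surface-to-surface gap between two primitives (medial-set based)."""

    def medial_segments(p):
        if isinstance(p, SpherePrimitive):
            c = np.asarray(p.center, float)
            return [(c, c)]
        if isinstance(p, CapsulePrimitive):
            return [(np.asarray(p.a, float), np.asarray(p.b, float))]
        theta = np.linspace(p.angle_start, p.angle_end, 64)
        pts = p.arc_point(theta)
        return [(pts[i], pts[i + 1]) for i in range(len(pts) - 1)]

    best = np.inf
    for a1, b1 in medial_segments(p1):
        for a2, b2 in medial_segments(p2):
            if np.array_equal(a1, b1) and np.array_equal(a2, b2):
                d = float(np.linalg.norm(a1 - a2))
            elif np.array_equal(a1, b1):
                d = point_segment_distance(a1, Segment(a=a2, b=b2))
            elif np.array_equal(a2, b2):
                d = point_segment_distance(a2, Segment(a=a1, b=b1))
            else:
                c1, c2, _, _ = closest_points_segments(a1, b1, a2, b2)
                d = float(np.linalg.norm(c1 - c2))
            best = min(best, d)
    return best - p1.radius - p2.radius


def temporal_bone_spec(spacing: float = 0.5) -> PhantomSpec:
    """The bundled three-target scene.

    Targets sit at round-window-like (25 mm), internal-auditory-canal-like
    (40 mm) and petrous-apex-like (55 mm) depths below the dome apex.
    Obstacles mimic the facial nerve and chorda tympani (capsules), cochlea
    and jugular bulb (spheres), a semicircular canal (torus arc), the
    carotid artery (capsule) and an ossicle mass (sphere, conventionally
    relabelled noncritical when targeting the round window).
    """
    shell = BoneShell(outer_radius=65.0, thickness=5.0)
    sq = 1.0 / np.sqrt(2.0)
    obstacles = [
        CapsulePrimitive("facial_nerve", a=(7.0, 5.0, 56.0), b=(11.0, 2.5, 42.5),
                         radius=1.2),
        CapsulePrimitive("chorda_tympani", a=(5.0, -5.0, 51.0), b=(12.0, -1.5, 42.0),
                         radius=0.4),
        SpherePrimitive("cochlea", center=(4.0, -8.0, 37.0), radius=4.0),
        TorusArcPrimitive("ssc_canal", center=(-4.0, 12.0, 41.0),
                          axis_u=(1.0, 0.0, 0.0), axis_v=(0.0, sq, sq),
                          arc_radius=4.0, tube_radius=1.2,
                          angle_start=0.0, angle_end=1.5 * np.pi),
        SpherePrimitive("jugular_bulb", center=(-8.0, -14.0, 15.0), radius=6.0),
        CapsulePrimitive("carotid_artery", a=(16.0, 14.0, 6.0), b=(9.0, 22.0, 28.0),
                         radius=3.0),
        SpherePrimitive("ossicles", center=(6.0, 1.0, 51.0), radius=2.0),
    ]
    return PhantomSpec(
        seed=0,
        bone_shell=shell,
        obstacles=obstacles,
        targets={
            "rw": (10.0, 0.0, 40.0),
            "iac": (-6.0, 4.0, 25.0),
            "pa": (2.0, -6.0, 10.0),
        },
        spacing=spacing,
    )
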