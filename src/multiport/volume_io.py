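"""Label volumes, masks and marching-cubes surface extraction.

A labelled CT volume is represented on a regular, axis-aligned voxel grid
with millimetre spacing; voxel index ``(i, j, k)`` maps to the world point
``origin + (i, j, k) * spacing`` (voxel-centre convention).  Cranial bone is
obtained from the raw intensities by simple Hounsfield thresholding, a brain
safety margin by anisotropy-aware Euclidean dilation, and each structure's
surface by marching cubes at iso-level 0.5 on its binary indicator.  The
volume is padded with one background layer before surface extraction so the
resulting meshes are watertight, which the clearance queries require.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import trimesh
from scipy import ndimage
from skimage import measure

_DEGENERATE_AREA = 1e-12  # mm^2; faces at or below this are dropped


class UnsupportedOrientationError(ValueError):
    """Raised for NIfTI affines with rotation beyond axis permutation/flip."""


@dataclass(eq=False)
class LabelVolume:
    """Integer label map on a regular grid (0 = background)."""

    voxels: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray
    label_names: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if not np.issubdtype(self.voxels.dtype, np.integer):
            raise TypeError("label volume voxels must be integer")
        if self.voxels.ndim != 3 or self.voxels.size == 0:
            raise ValueError("voxels must be a non-empty 3-D array")
        if self.voxels.min() < 0:
            raise ValueError("labels must be >= 0")
        self.spacing = np.asarray(self.spacing, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float)
        if self.spacing.shape != (3,) or np.any(self.spacing <= 0):
            raise ValueError("spacing must be three positive components")
        if self.origin.shape != (3,):
            raise ValueError("origin must be a 3-vector")

    def labels(self) -> np.ndarray:
        """Sorted array of labels present, excluding background."""
        u = np.unique(self.voxels)
        return u[u > 0]

    def world_coordinates(self, indices: np.ndarray) -> np.ndarray:
        return self.origin + np.asarray(indices, dtype=float) * self.spacing


@dataclass(eq=False)
class StructureMesh:
    """Named triangle mesh of one anatomical structure, world mm coordinates.

    Degenerate faces (repeated vertex indices or area <= 1e-12 mm^2) are
    removed at construction.
    """

    name: str
    label: int
    vertices: np.ndarray
    faces: np.ndarray
    critical: bool = True

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        if not np.all(np.isfinite(self.vertices)):
            raise ValueError("mesh vertices must be finite")
        if len(self.faces) and (
            self.faces.min() < 0 or self.faces.max() >= len(self.vertices)
        ):
            raise ValueError("face index out of range")
        if len(self.faces):
            distinct = (
                (self.faces[:, 0] != self.faces[:, 1])
                & (self.faces[:, 1] != self.faces[:, 2])
                & (self.faces[:, 0] != self.faces[:, 2])
            )
            tris = self.vertices[self.faces]
            areas = 0.5 * np.linalg.norm(
                np.cross(tris[:, 1] - tris[:, 0], tris[:, 2] - tris[:, 0]), axis=1
            )
            self.faces = self.faces[distinct & (areas > _DEGENERATE_AREA)]
        self._trimesh = None
        self._closed: bool | None = None
        self._tris: np.ndarray | None = None
        self._tri_bounds: tuple[np.ndarray, np.ndarray] | None = None

    def __len__(self) -> int:
        return len(self.faces)

    @property
    def is_empty(self) -> bool:
        return len(self.faces) == 0

    def triangle_centroids(self) -> np.ndarray:
        return self.vertices[self.faces].mean(axis=1)

    def triangles(self) -> np.ndarray:
        """(n, 3, 3) triangle vertex array, cached."""
        if self._tris is None:
            self._tris = self.vertices[self.faces]
        return self._tris

    def triangle_bounds(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-triangle AABB (lo, hi), cached."""
        if self._tri_bounds is None:
            tris = self.triangles()
            self._tri_bounds = (tris.min(axis=1), tris.max(axis=1))
        return self._tri_bounds

    def area(self) -> float:
        tris = self.vertices[self.faces]
        return float(
            0.5
            * np.linalg.norm(
                np.cross(tris[:, 1] - tris[:, 0], tris[:, 2] - tris[:, 0]), axis=1
            ).sum()
        )

    def edge_counts(self) -> np.ndarray:
        """Multiplicity of each undirected edge across all faces."""
        e = np.concatenate(
            [self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [2, 0]]]
        )
        e = np.sort(e, axis=1)
        _, counts = np.unique(e, axis=0, return_counts=True)
        return counts

    def is_closed(self) -> bool:
        """True iff every undirected edge is shared by exactly two faces.

        Cached; mutate ``faces``/``vertices`` only through construction.
        """
        if self._closed is None:
            self._closed = (not self.is_empty) and bool(
                np.all(self.edge_counts() == 2)
            )
        return self._closed

    def as_trimesh(self) -> trimesh.Trimesh:
        if self._trimesh is None:
            tm = trimesh.Trimesh(self.vertices, self.faces, process=False)
            self._trimesh = tm
        return self._trimesh

    def export(self, path: str | Path) -> None:
        """Write the mesh to STL or PLY (chosen by file extension)."""
        self.as_trimesh().export(str(path))


def load_structure_mesh(
    path: str | Path, name: str, label: int = 0, critical: bool = True
) -> StructureMesh:
    """Read an STL/PLY mesh from disk into a StructureMesh."""
    tm = trimesh.load_mesh(str(path), process=False)
    return StructureMesh(
        name=name, label=label, vertices=tm.vertices, faces=tm.faces, critical=critical
    )


# ---------------------------------------------------------------------------
# NIfTI I/O
# ---------------------------------------------------------------------------

def _check_axis_aligned(affine: np.ndarray) -> None:
    rot = affine[:3, :3]
    for axis in range(3):
        col = rot[:, axis]
        nz = np.abs(col) > 1e-6 * max(np.abs(col).max(), 1e-30)
        if nz.sum() != 1:
            raise UnsupportedOrientationError(
                "NIfTI affine is oblique or sheared; only axis permutation "
                "and flips are supported"
            )


def read_label_volume(
    path: str | Path, label_names: dict[int, str] | None = None
) -> LabelVolume:
    """Read an integer NIfTI label map.

    Spacing and origin come from the affine.  Axis permutations and flips are
    normalised to the canonical +x/+y/+z order; any oblique or sheared affine
    raises :class:`UnsupportedOrientationError` rather than being silently
    reinterpreted.  Non-integer voxel data is an error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    if not np.issubdtype(img.get_data_dtype(), np.integer):
        raise TypeError(
            f"label volume must have integer data, got {img.get_data_dtype()}"
        )
    affine = np.asarray(img.affine, dtype=float)
    _check_axis_aligned(affine)
    data = np.asanyarray(img.dataobj)

    # normalise axis order/direction so spacing is positive diagonal
    rot = affine[:3, :3]
    perm = [int(np.argmax(np.abs(rot[:, axis]))) for axis in range(3)]
    if sorted(perm) != [0, 1, 2]:
        raise UnsupportedOrientationError("affine does not permute axes cleanly")
    inv = np.argsort(perm)  # world axis -> voxel axis
    data = np.transpose(data, axes=inv)
    rot = rot[:, inv]
    origin = affine[:3, 3].copy()
    spacing = np.array([rot[w, w] for w in range(3)])
    for w in range(3):
        if spacing[w] < 0:
            data = np.flip(data, axis=w)
            origin[w] = origin[w] + spacing[w] * (data.shape[w] - 1)
            spacing[w] = -spacing[w]
    return LabelVolume(
        voxels=np.ascontiguousarray(data),
        spacing=spacing,
        origin=origin,
        label_names=dict(label_names or {}),
    )


def write_label_volume(volume: LabelVolume, path: str | Path) -> None:
    """Write a LabelVolume as NIfTI with a diagonal affine."""
    affine = np.eye(4)
    affine[:3, :3] = np.diag(volume.spacing)
    affine[:3, 3] = volume.origin
    img = nib.Nifti1Image(volume.voxels.astype(np.int32), affine)
    nib.save(img, str(path))


# ---------------------------------------------------------------------------
# masks
# ---------------------------------------------------------------------------

def threshold_mask(intensities: np.ndarray, threshold: float) -> np.ndarray:
    """Binary mask of voxels with intensity >= threshold (bone extraction)."""
    arr = np.asarray(intensities, dtype=float)
    if np.any(np.isnan(arr)):
        raise ValueError("intensities contain NaN")
    return (arr >= threshold).astype(np.uint8)


def dilate_mask(mask: np.ndarray, margin_mm: float, spacing: np.ndarray) -> np.ndarray:
    """Euclidean dilation of a binary mask by ``margin_mm`` (anisotropy-aware).

    A voxel is foreground in the output iff its centre lies within
    ``margin_mm`` of some input foreground voxel centre.  Used to grow the
    brain/dura mask into a safety margin.
    """
    if margin_mm < 0:
        raise ValueError("margin must be >= 0")
    mask = np.asarray(mask).astype(bool)
    if margin_mm == 0:
        return mask.astype(np.uint8)
    dist = ndimage.distance_transform_edt(~mask, sampling=np.asarray(spacing, dtype=float))
    return (dist <= margin_mm).astype(np.uint8)


# ---------------------------------------------------------------------------
# surface extraction
# ---------------------------------------------------------------------------

# anti-aliasing filter width (voxels) and the minimum structure half-
# thickness (voxels) at which it is safe: thinner structures would be
# eroded below the iso-level and must be extracted from the raw indicator
_SMOOTH_SIGMA = 0.8
_SMOOTH_MIN_DEPTH = 2.0


def extract_surface(
    volume: LabelVolume,
    label: int,
    name: str | None = None,
    critical: bool = True,
    smoothing: str = "auto",
) -> StructureMesh:
    """Marching-cubes surface of one label at iso-level 0.5, world mm.

    Extracting the iso-surface of the raw binary indicator leaves a
    staircase bias of ~9% in surface area that does not vanish with finer
    spacing, so by default the indicator is anti-aliased with a narrow
    Gaussian (sigma 0.8 voxel) before extraction, which recovers sub-voxel
    surface placement.  Structures thinner than about two voxels would be
    eroded below the iso-level by the filter and are automatically extracted
    from the raw indicator instead (``smoothing="auto"``; force with
    ``"on"``/``"off"``).

    The array is padded with background so the surface is closed even when
    the label touches the boundary.  A label absent from the volume yields
    an empty mesh.
    """
    binary = volume.voxels == label
    if name is None:
        name = volume.label_names.get(label, f"label_{label}")
    if not binary.any():
        return StructureMesh(
            name=name,
            label=label,
            vertices=np.zeros((0, 3)),
            faces=np.zeros((0, 3), dtype=np.int64),
            critical=critical,
        )
    if smoothing not in ("auto", "on", "off"):
        raise ValueError(f"unknown smoothing mode {smoothing!r}")
    if smoothing == "auto":
        depth = ndimage.distance_transform_edt(binary)
        smoothing = "on" if depth.max() >= _SMOOTH_MIN_DEPTH else "off"
    pad = 2
    field = np.pad(binary, pad).astype(np.float32)
    if smoothing == "on":
        field = ndimage.gaussian_filter(field, _SMOOTH_SIGMA)
    verts, faces, _, _ = measure.marching_cubes(
        field, level=0.5, spacing=tuple(volume.spacing)
    )
    verts = verts - pad * volume.spacing + volume.origin  # undo padding
    return StructureMesh(
        name=name, label=label, vertices=verts, faces=faces, critical=critical
    )
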