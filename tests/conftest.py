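import numpy as np
import pytest
import trimesh

from multiport.planner import Trajectory
from multiport.volume_io import StructureMesh


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def icosphere_mesh(
    radius=3.0, center=(0.0, 0.0, 0.0), subdivisions=3, name="sphere", critical=True
) -> StructureMesh:
    tm = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
    tm.apply_translation(np.asarray(center, float))
    return StructureMesh(
        name=name, label=2, vertices=tm.vertices, faces=tm.faces, critical=critical
    )


def make_traj(
    entry,
    target=(0.0, 0.0, 0.0),
    clearance=1.0,
    max_diameter=None,
    closest="s",
) -> Trajectory:
    """Hand-built trajectory for metric-level tests (no meshes involved)."""
    entry = np.asarray(entry, float)
    target = np.asarray(target, float)
    d = entry - target
    length = float(np.linalg.norm(d))
    if max_diameter is None:
        max_diameter = 2.0 * clearance
    return Trajectory(
        entry=entry,
        target=target,
        direction=d / length,
        length=length,
        clearance=float(clearance),
        closest_structure=closest,
        feasible=True,
        max_diameter=float(max_diameter),
    )


def random_unit(rng, n=1):
    v = rng.normal(size=(n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)
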