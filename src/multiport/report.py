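"""Planning driver and file-based reporting.

Ties the pipeline together the way a planning session runs: load the
anatomy (either a labelled NIfTI volume plus a structure table, or
per-structure STL/PLY meshes), generate candidate entries, evaluate all
collision-free trajectories per target, select the best triple, summarise
diameters per entry region, and write a self-contained JSON report plus a
CSV summary.  Outputs are byte-stable: rerunning on identical inputs and
configuration reproduces them exactly (sorted keys, no timestamps).

All lengths are millimetres and all angles degrees; per-trajectory
"clearance" is the distance of the drill *axis* to the closest critical
structure, as recorded in the report metadata.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .planner import PlanConfig, Trajectory, find_cfts
from .triple_metrics import (
    InsufficientTrajectoriesError,
    RegionLabeling,
    TrajectoryTriple,
    assign_regions,
    select_best_triple,
    summarize_by_region,
)
from .volume_io import (
    StructureMesh,
    extract_surface,
    load_structure_mesh,
    read_label_volume,
)

logger = logging.getLogger(__name__)

EXIT_OK = 0
EXIT_NO_CFTS = 4
EXIT_TOO_FEW_CFTS = 5


class NoTrajectoriesError(RuntimeError):
    """No collision-free trajectory exists for some target."""


class ConfigError(ValueError):
    pass


def load_config(path: str | Path) -> dict:
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        return yaml.safe_load(text)
    return json.loads(text)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def load_scene(config: dict, base: Path) -> tuple[StructureMesh, list[StructureMesh], dict[str, str]]:
    """Resolve the skull mesh and structure meshes named by the config.

    Returns (skull, structures, digests of every file read).
    """
    inputs = config.get("inputs")
    if not inputs:
        raise ConfigError("config has no 'inputs' section")
    digests: dict[str, str] = {}

    if "volume" in inputs:
        vol_path = (base / inputs["volume"]).resolve()
        if not vol_path.exists():
            raise ConfigError(f"volume not found: {vol_path}")
        digests[str(inputs["volume"])] = _sha256(vol_path)
        table = inputs.get("structures")
        if not table:
            raise ConfigError("volume input requires a 'structures' label table")
        label_names = {int(row["label"]): row["name"] for row in table}
        volume = read_label_volume(vol_path, label_names=label_names)
        skull_label = int(inputs.get("skull_label", 1))
        skull = None
        structures = []
        for row in table:
            mesh = extract_surface(
                volume,
                int(row["label"]),
                name=row["name"],
                critical=bool(row.get("critical", True)),
            )
            if int(row["label"]) == skull_label:
                skull = mesh
            else:
                structures.append(mesh)
        if skull is None:
            raise ConfigError(f"skull label {skull_label} missing from structure table")
    elif "skull_mesh" in inputs:
        skull_path = (base / inputs["skull_mesh"]).resolve()
        if not skull_path.exists():
            raise ConfigError(f"skull mesh not found: {skull_path}")
        digests[str(inputs["skull_mesh"])] = _sha256(skull_path)
        skull = load_structure_mesh(skull_path, name="bone", critical=False)
        structures = []
        for row in inputs.get("structures", []):
            mesh_path = (base / row["mesh"]).resolve()
            if not mesh_path.exists():
                raise ConfigError(f"structure mesh not found: {mesh_path}")
            digests[str(row["mesh"])] = _sha256(mesh_path)
            structures.append(
                load_structure_mesh(
                    mesh_path,
                    name=row["name"],
                    label=int(row.get("label", 0)),
                    critical=bool(row.get("critical", True)),
                )
            )
    else:
        raise ConfigError("inputs must contain 'volume' or 'skull_mesh'")
    known = {m.name for m in structures}
    for tgt in config.get("targets", []):
        for name in tuple(tgt.get("noncritical", ())) + tuple(
            config.get("defaults", {}).get("noncritical", ())
        ):
            if name not in known:
                raise ConfigError(f"unknown structure name in noncritical list: {name!r}")
    return skull, structures, digests


def _plan_config(target_cfg: dict, defaults: dict) -> PlanConfig:
    merged = {**defaults, **target_cfg}
    noncritical = tuple(defaults.get("noncritical", ())) + tuple(
        target_cfg.get("noncritical", ())
    )
    return PlanConfig(
        target=np.asarray(merged["point"], float),
        entry_seed=np.asarray(merged["entry_seed"], float),
        entry_region_radius=float(merged["entry_region_radius"]),
        drill_radius=float(merged.get("drill_radius", 0.5)),
        safety_distance=float(merged.get("safety_distance", 0.0)),
        drill_inaccuracy=float(merged.get("drill_inaccuracy", 0.0)),
        noncritical_names=noncritical,
        target_structure=merged.get("target_structure"),
    )


def _round(x, nd=6):
    return float(np.round(float(x), nd))


def trajectory_record(t: Trajectory) -> dict:
    return {
        "entry": [_round(v) for v in t.entry],
        "target": [_round(v) for v in t.target],
        "length_mm": _round(t.length),
        "clearance_mm": None if not np.isfinite(t.clearance) else _round(t.clearance),
        "closest_structure": t.closest_structure or None,
        "max_diameter_mm": None if t.diameter_unbounded else _round(t.max_diameter),
        "diameter_unbounded": bool(t.diameter_unbounded),
        "risk_value": _round(t.risk_value),
    }


def triple_record(triple: TrajectoryTriple) -> dict:
    return {
        "trajectories": [trajectory_record(t) for t in triple.trajectories],
        "pairwise_angles_deg": [_round(a) for a in triple.angles],
        "cumulative_angle_deg": _round(triple.cumulative_angle),
        "merge_lengths_mm": [
            None if not np.isfinite(m) else _round(m) for m in triple.merge_lengths
        ],
        "score": _round(triple.score),
    }


def run_plan(
    config: dict,
    skull: StructureMesh,
    structures: list[StructureMesh],
    labeling: RegionLabeling | None = None,
) -> dict:
    """Execute the full planning protocol for every configured target.

    Raises :class:`NoTrajectoriesError` if some target admits no CFT and
    :class:`InsufficientTrajectoriesError` if a target has fewer than three
    (so no triple can be formed).
    """
    defaults = config.get("defaults", {})
    selection = config.get("selection", {})
    w_clearance = float(selection.get("w_clearance", 1.0))
    w_angle = float(selection.get("w_angle", 1.0))
    m_cap = selection.get("m_cap", 40)
    m_cap = None if m_cap in (None, "none") else int(m_cap)

    per_target: dict[str, dict] = {}
    for tgt in config.get("targets", []):
        name = tgt["name"]
        plan_cfg = _plan_config(tgt, defaults)
        logger.info("planning target %s", name)
        cfts = find_cfts(plan_cfg, skull, structures)
        if not cfts:
            raise NoTrajectoriesError(f"no collision-free trajectory to target {name!r}")
        if len(cfts) < 3:
            raise InsufficientTrajectoriesError(
                f"only {len(cfts)} collision-free trajectories to target {name!r}; "
                "three are required for a multiport plan"
            )
        triple = select_best_triple(
            cfts,
            w_clearance=w_clearance,
            w_angle=w_angle,
            m_cap=m_cap,
            drill_radius=plan_cfg.drill_radius,
        )
        entry: dict = {
            "n_candidates_feasible": len(cfts),
            "required_clearance_mm": _round(plan_cfg.required_clearance),
            "cfts": [trajectory_record(t) for t in cfts],
            "selected_triple": triple_record(triple),
        }
        if labeling is not None:
            summary = summarize_by_region(cfts, skull, labeling)
            entry["region_summary"] = summary.to_dict(orient="records")
            entry["regions"] = assign_regions(cfts, skull, labeling)
        per_target[name] = entry
    return {
        "software": {"name": "multiport", "version": __version__},
        "clearance_semantics": "axis distance to closest critical structure",
        "units": {"length": "mm", "angle": "deg"},
        "config": config,
        "targets": per_target,
    }


def write_report(report: dict, out_dir: str | Path) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / "report.json"
    path.write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    rows = []
    for tname, entry in sorted(report["targets"].items()):
        for rec in entry.get("region_summary", []):
            rows.append({"target": tname, **rec})
    if rows:
        import pandas as pd

        pd.DataFrame(rows).to_csv(out_dir / "summary.csv", index=False)
    return path


def export_triple_stl(
    triple: TrajectoryTriple, drill_radius: float, out_dir: str | Path
) -> list[Path]:
    """Write one cylinder STL per selected trajectory, for visualisation."""
    import trimesh

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, t in enumerate(triple.trajectories, start=1):
        cyl = trimesh.creation.cylinder(
            radius=drill_radius, segment=np.vstack([t.entry, t.target])
        )
        p = out_dir / f"trajectory_{i}.stl"
        cyl.export(str(p))
        paths.append(p)
    return paths
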