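"""Candidate entry generation and collision-free trajectory (CFT) evaluation.

A straight drill path runs from a candidate entry point on the skull surface
to the target.  Candidates are the centroids of all skull-mesh triangles
within a user-chosen radius of a seed point (the seed is first snapped to the
nearest centroid).  A path is *feasible* when its axis clearance to every
critical structure is at least

    required_clearance = drill_radius + safety_distance + drill_inaccuracy

so the drill cylinder plus the safety and navigation-inaccuracy margins fits.
The skull itself is the drilled medium, never an obstacle; the target's own
structure and any structure listed as noncritical are excluded from the
collision set.  Feasibility is non-strict: clearance exactly equal to the
required value passes.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field

import numpy as np

from .geometry import ClearanceResult, Segment, capsule_is_free
from .volume_io import StructureMesh

logger = logging.getLogger(__name__)


@dataclass(eq=False)
class PlanConfig:
    """Parameters of one planning problem (all lengths mm).

    ``drill_radius`` defaults to 0.5 mm (a 1 mm drill).  ``safety_distance``
    covers segmentation and modelling uncertainty; ``drill_inaccuracy``
    covers the navigation/drilling error of the physical setup.  Both default
    to 0 because appropriate values depend on the clinical setup (scanner,
    fiducials, drill guidance) and must be chosen per case.
    """

    target: np.ndarray
    entry_seed: np.ndarray
    entry_region_radius: float
    drill_radius: float = 0.5
    safety_distance: float = 0.0
    drill_inaccuracy: float = 0.0
    noncritical_names: tuple[str, ...] = ()
    target_structure: str | None = None

    def __post_init__(self) -> None:
        self.target = np.asarray(self.target, dtype=float)
        self.entry_seed = np.asarray(self.entry_seed, dtype=float)
        if self.drill_radius <= 0:
            raise ValueError("drill_radius must be > 0")
        if self.safety_distance < 0 or self.drill_inaccuracy < 0:
            raise ValueError("margins must be >= 0")
        if self.entry_region_radius < 0:
            raise ValueError("entry_region_radius must be >= 0")
        self.noncritical_names = tuple(self.noncritical_names)

    @property
    def required_clearance(self) -> float:
        return self.drill_radius + self.safety_distance + self.drill_inaccuracy


@dataclass(eq=False)
class Trajectory:
    """One evaluated straight drill path.

    ``direction`` is the unit vector from target to entry.  ``clearance`` is
    the minimum axis distance to the critical set (+inf when the critical set
    is empty).  ``max_diameter`` is the largest drill diameter that would
    still keep the safety and inaccuracy margins:
    ``2 * (clearance - safety_distance - drill_inaccuracy)``, floored at 0
    and +inf when the clearance is unbounded.  ``risk_value`` in [0, 1] is
    assigned by :func:`color_code` (0 = coldest/safest of the displayed set).
    """

    entry: np.ndarray
    target: np.ndarray
    direction: np.ndarray
    length: float
    clearance: float
    closest_structure: str
    feasible: bool
    max_diameter: float
    risk_value: float = 0.0
    witness: ClearanceResult | None = field(default=None, repr=False)

    @property
    def diameter_unbounded(self) -> bool:
        return not np.isfinite(self.max_diameter)


def candidate_entries(
    skull: StructureMesh, seed: np.ndarray, rho: float
) -> np.ndarray:
    """Candidate entry points: skull triangle centroids near the seed.

    The seed is snapped to the nearest triangle centroid (lowest index on
    ties); all centroids within Euclidean distance ``rho`` of the snapped
    seed are returned, sorted by that distance with index tie-break, so the
    snapped seed itself is always first.
    """
    if skull.is_empty:
        raise ValueError("skull mesh is empty")
    seed = np.asarray(seed, dtype=float)
    centroids = skull.triangle_centroids()
    snap_idx = int(np.argmin(np.linalg.norm(centroids - seed, axis=1)))
    snapped = centroids[snap_idx]
    d = np.linalg.norm(centroids - snapped, axis=1)
    keep = np.flatnonzero(d <= rho)
    order = np.lexsort((keep, d[keep]))
    return centroids[keep[order]]


def critical_set(
    structures: list[StructureMesh], config: PlanConfig
) -> list[StructureMesh]:
    """Structures that participate in collision checking for this plan."""
    excluded = set(config.noncritical_names)
    if config.target_structure is not None:
        excluded.add(config.target_structure)
    return [m for m in structures if m.critical and m.name not in excluded]


def evaluate_trajectory(
    entry: np.ndarray,
    config: PlanConfig,
    structures: list[StructureMesh],
    _inside_cache: dict | None = None,
) -> Trajectory:
    """Evaluate the straight path from ``entry`` to the configured target."""
    entry = np.asarray(entry, dtype=float)
    if np.allclose(entry, config.target):
        raise ValueError("entry point coincides with the target")
    seg = Segment(a=entry, b=config.target)
    obstacles = critical_set(structures, config)
    free, witness = capsule_is_free(
        seg, config.required_clearance, obstacles, inside_cache=_inside_cache
    )
    clearance = witness.distance
    if np.isfinite(clearance):
        max_diameter = max(
            0.0, 2.0 * (clearance - config.safety_distance - config.drill_inaccuracy)
        )
    else:
        max_diameter = np.inf
    direction = entry - config.target
    length = float(np.linalg.norm(direction))
    return Trajectory(
        entry=entry,
        target=config.target.copy(),
        direction=direction / length,
        length=length,
        clearance=float(clearance),
        closest_structure=witness.structure_name,
        feasible=bool(free),
        max_diameter=float(max_diameter),
        witness=witness,
    )


def color_code(trajectories: list[Trajectory]) -> list[Trajectory]:
    """Assign risk colors by clearance: hottest (1) = smallest clearance.

    risk = (c_max - c) / (c_max - c_min) over the displayed set; a single
    trajectory, or an all-equal set, maps to 0 (coldest).
    """
    if not trajectories:
        return []
    clearances = np.array([t.clearance for t in trajectories])
    finite = clearances[np.isfinite(clearances)]
    if finite.size:
        # infinite clearances (empty critical set) act as the largest value
        clearances = np.minimum(clearances, finite.max())
    else:
        clearances = np.zeros_like(clearances)
    c_max, c_min = clearances.max(), clearances.min()
    if c_max == c_min:
        risks = np.zeros(len(clearances))
    else:
        risks = (c_max - clearances) / (c_max - c_min)
    out = []
    for t, r in zip(trajectories, risks):
        out.append(dataclasses.replace(t, risk_value=float(r)))
    return out


def find_cfts(
    config: PlanConfig,
    skull: StructureMesh,
    structures: list[StructureMesh],
) -> list[Trajectory]:
    """All collision-free trajectories from the entry region to the target.

    Every candidate entry is evaluated; only feasible paths are returned,
    color-coded over the feasible set, in candidate (distance-to-seed)
    order.  An empty list, not an error, means no CFT exists.
    """
    entries = candidate_entries(skull, config.entry_seed, config.entry_region_radius)
    logger.info(
        "evaluating %d candidate entries against %d critical structures",
        len(entries),
        len(critical_set(structures, config)),
    )
    cache: dict = {}
    feasible = []
    for entry in entries:
        t = evaluate_trajectory(entry, config, structures, _inside_cache=cache)
        logger.debug(
            "entry %s clearance %.3f mm (%s) feasible=%s",
            np.array2string(entry, precision=2),
            t.clearance,
            t.closest_structure or "-",
            t.feasible,
        )
        if t.feasible:
            feasible.append(t)
    logger.info("%d of %d candidates are collision-free", len(feasible), len(entries))
    return color_code(feasible)
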