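"""Metrics and selection over triples of collision-free trajectories.

Three ports that share one target intersect near it.  The *cumulative angle*
(CA) — the sum of the three pairwise angles between the target→entry
directions — measures how spread apart the ports are: a large CA pushes the
mutual intersection of the drill canals distally, close to the target, where
the fused cavity is useful working space.  The *merge length* quantifies
that fusion depth for one pair of canals: two cylinders of radii r1, r2
meeting at angle α overlap out to

    L = (r1 + r2) / (2 sin(α/2))

millimetres from the target along each axis.

Triple selection automates the two clinical criteria — maximise the distance
of every path to critical structures, and maximise the spread between the
ports — as a weighted score; the weights are a declared convention of this
package, exposed in the configuration.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .planner import Trajectory
from .volume_io import StructureMesh

TARGET_TOL = 1e-6  # mm; trajectories of one triple must share a target


class InsufficientTrajectoriesError(ValueError):
    pass


@dataclass(eq=False)
class TrajectoryTriple:
    """Three trajectories to one target with their multiport geometry.

    ``angles`` holds the pairwise angles (1-2, 1-3, 2-3) in degrees,
    ``merge_lengths`` the corresponding pairwise fusion depths in mm
    (+inf for a parallel pair), and ``score`` the selection score.
    """

    trajectories: tuple[Trajectory, Trajectory, Trajectory]
    angles: np.ndarray
    cumulative_angle: float
    merge_lengths: np.ndarray
    score: float = float("nan")


def pairwise_angle(t1: Trajectory, t2: Trajectory) -> float:
    """Angle in degrees between two trajectories sharing one target."""
    if np.linalg.norm(t1.target - t2.target) > TARGET_TOL:
        raise ValueError("trajectories do not share a target")
    c = float(np.clip(np.dot(t1.direction, t2.direction), -1.0, 1.0))
    return float(np.degrees(np.arccos(c)))


def cumulative_angle(triple: TrajectoryTriple) -> float:
    """Sum of the three pairwise angles, degrees (the CA benchmark)."""
    return float(np.sum(triple.angles))


def merge_length(t1: Trajectory, t2: Trajectory, r1: float, r2: float) -> float:
    """Fusion depth of two drill canals from the shared target, mm.

    Points at arc length x along the two axes are 2·x·sin(α/2) apart, so the
    cylinders (radii r1, r2) overlap while that separation is below r1 + r2:
    L = (r1 + r2) / (2 sin(α/2)).  α = 0 (parallel canals) overlaps forever
    and returns +inf.
    """
    alpha = np.radians(pairwise_angle(t1, t2))
    s = np.sin(alpha / 2.0)
    if s == 0.0:
        return float("inf")
    return float((r1 + r2) / (2.0 * s))


def make_triple(
    t1: Trajectory,
    t2: Trajectory,
    t3: Trajectory,
    drill_radius: float = 0.5,
) -> TrajectoryTriple:
    """Assemble a TrajectoryTriple, computing angles and merge lengths."""
    trajectories = (t1, t2, t3)
    angles = np.array(
        [pairwise_angle(a, b) for a, b in itertools.combinations(trajectories, 2)]
    )
    merges = np.array(
        [
            merge_length(a, b, drill_radius, drill_radius)
            for a, b in itertools.combinations(trajectories, 2)
        ]
    )
    triple = TrajectoryTriple(
        trajectories=trajectories,
        angles=angles,
        cumulative_angle=float(np.sum(angles)),
        merge_lengths=merges,
    )
    return triple


def score_triple(
    triple: TrajectoryTriple,
    w_clearance: float = 1.0,
    w_angle: float = 1.0,
    clearance_scale: float | None = None,
) -> float:
    """Weighted two-term selection score; higher is better.

    score = w_clearance * (min clearance / clearance_scale)
          + w_angle * (CA / 540)

    ``clearance_scale`` should be the maximum clearance of the candidate set
    so that scores of competing triples are comparable; it defaults to the
    triple's own maximum clearance.  540° is the (unattainable) upper bound
    of the cumulative angle.
    """
    if w_clearance < 0 or w_angle < 0 or (w_clearance == 0 and w_angle == 0):
        raise ValueError("weights must be >= 0 and not both zero")
    clearances = np.array([t.clearance for t in triple.trajectories])
    if clearance_scale is None:
        clearance_scale = clearances.max()
    cmin = clearances.min()
    if not np.isfinite(clearance_scale) or clearance_scale <= 0:
        term = 1.0 if not np.isfinite(cmin) else 0.0
    else:
        term = float(min(cmin, clearance_scale) / clearance_scale)
    return float(w_clearance * term + w_angle * triple.cumulative_angle / 540.0)


def _canonical_order(cfts: list[Trajectory]) -> list[Trajectory]:
    keys = [(-t.clearance, tuple(t.entry)) for t in cfts]
    order = sorted(range(len(cfts)), key=keys.__getitem__)
    return [cfts[i] for i in order]


def select_best_triple(
    cfts: list[Trajectory],
    w_clearance: float = 1.0,
    w_angle: float = 1.0,
    m_cap: int | None = 40,
    drill_radius: float = 0.5,
) -> TrajectoryTriple:
    """Best-scoring triple among the ``m_cap`` highest-clearance CFTs.

    Exhaustive search over all triples of the capped candidate list; ties
    are broken by larger cumulative angle, then by lexicographically smaller
    entry coordinates.  The result does not depend on the input order.
    ``m_cap=None`` disables the cap (full brute force).
    """
    if len(cfts) < 3:
        raise InsufficientTrajectoriesError(
            f"need at least 3 collision-free trajectories, got {len(cfts)}"
        )
    pool = _canonical_order(cfts)
    if m_cap is not None:
        pool = pool[:m_cap]
    clearances = np.array([t.clearance for t in pool])
    finite = clearances[np.isfinite(clearances)]
    scale = float(finite.max()) if finite.size else float("inf")

    best = None
    best_key = None
    for combo in itertools.combinations(range(len(pool)), 3):
        triple = make_triple(*(pool[i] for i in combo), drill_radius=drill_radius)
        triple.score = score_triple(
            triple, w_clearance, w_angle, clearance_scale=scale
        )
        entry_key = sorted(tuple(pool[i].entry) for i in combo)
        key = (-triple.score, -triple.cumulative_angle, entry_key)
        if best_key is None or key < best_key:
            best = triple
            best_key = key
    return best


# ---------------------------------------------------------------------------
# region summaries
# ---------------------------------------------------------------------------

@dataclass(eq=False)
class RegionLabeling:
    """Per-triangle region IDs on the skull mesh with region names.

    Triangles with an ID missing from ``names`` (conventionally 0) report as
    "unassigned".
    """

    triangle_regions: np.ndarray
    names: dict[int, str]

    def __post_init__(self) -> None:
        self.triangle_regions = np.asarray(self.triangle_regions, dtype=np.int64)
        if len(set(self.names.values())) != len(self.names):
            raise ValueError("region names must be unique")

    def region_of_triangle(self, idx: int) -> str:
        return self.names.get(int(self.triangle_regions[idx]), "unassigned")


def azimuthal_sector_labeling(
    skull: StructureMesh, names: list[str], center: tuple[float, float] = (0.0, 0.0)
) -> RegionLabeling:
    """Partition the skull surface into equal azimuthal sectors.

    A convenience labeling for phantom scenes (real cases supply anatomical
    per-triangle labels): triangle centroids are binned by their azimuth
    around ``center`` in the x-y plane into ``len(names)`` equal sectors,
    with region IDs 1..n in the order of ``names``.
    """
    if not names:
        raise ValueError("need at least one region name")
    centroids = skull.triangle_centroids()
    az = np.mod(
        np.arctan2(centroids[:, 1] - center[1], centroids[:, 0] - center[0]),
        2 * np.pi,
    )
    n = len(names)
    ids = np.minimum((az / (2 * np.pi) * n).astype(np.int64), n - 1) + 1
    return RegionLabeling(
        triangle_regions=ids, names={i + 1: nm for i, nm in enumerate(names)}
    )


def assign_regions(
    trajectories: list[Trajectory], skull: StructureMesh, labeling: RegionLabeling
) -> list[str]:
    """Region of each trajectory via nearest skull-triangle centroid."""
    if len(labeling.triangle_regions) != len(skull.faces):
        raise ValueError("labeling does not match the skull mesh")
    if not trajectories:
        return []
    centroids = skull.triangle_centroids()
    tree = cKDTree(centroids)
    _, idx = tree.query(np.array([t.entry for t in trajectories]))
    return [labeling.region_of_triangle(int(i)) for i in np.atleast_1d(idx)]


def _quartiles(values: np.ndarray) -> tuple[float, float, float]:
    # linear interpolation between order statistics ("type 7")
    q1, med, q3 = np.percentile(values, [25, 50, 75], method="linear")
    return float(q1), float(med), float(q3)


def summarize_by_region(
    trajectories: list[Trajectory],
    skull: StructureMesh,
    labeling: RegionLabeling,
) -> pd.DataFrame:
    """Boxplot-style summary of achievable diameters per entry region.

    One row per region plus a pooled "all" row: count, percentage of all
    trajectories, median/Q1/Q3/min/max of the maximum drill diameter, and
    Tukey outliers (outside Q1 - 1.5·IQR, Q3 + 1.5·IQR).  Quartiles use
    linear interpolation between order statistics.
    """
    columns = [
        "region", "n", "percent", "median", "q1", "q3",
        "min", "max", "n_outliers", "outliers",
    ]
    if not trajectories:
        return pd.DataFrame(columns=columns)
    regions = assign_regions(trajectories, skull, labeling)
    diameters = np.array([t.max_diameter for t in trajectories])
    total = len(trajectories)
    rows = []
    names = sorted(set(regions))
    for name in names + ["all"]:
        if name == "all":
            vals = diameters
        else:
            vals = diameters[[i for i, r in enumerate(regions) if r == name]]
        q1, med, q3 = _quartiles(vals)
        iqr = q3 - q1
        lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
        outliers = np.sort(vals[(vals < lo) | (vals > hi)])
        rows.append(
            {
                "region": name,
                "n": int(len(vals)),
                "percent": 100.0 * len(vals) / total,
                "median": med,
                "q1": q1,
                "q3": q3,
                "min": float(vals.min()),
                "max": float(vals.max()),
                "n_outliers": int(len(outliers)),
                "outliers": ";".join(f"{v:g}" for v in outliers),
            }
        )
    return pd.DataFrame(rows, columns=columns)
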