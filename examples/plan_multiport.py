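"""Plan three drill ports to one target in a synthetic temporal-bone scene.

Builds a small random phantom, extracts the skull surface, evaluates every
candidate entry point against the critical structures, and selects the best
triple of collision-free trajectories.
"""

import numpy as np

from multiport import (
    PlanConfig,
    build_phantom,
    extract_surface,
    find_cfts,
    random_scene,
    select_best_triple,
)

spec = random_scene(seed=4, n_obstacles=5, difficulty=0.4, spacing=1.0)
volume, structures, _ = build_phantom(spec)
skull = extract_surface(volume, 1, name="bone", critical=False)

config = PlanConfig(
    target=np.asarray(spec.targets["t1"]),
    entry_seed=spec.entry_seed,          # apex of the bone dome
    entry_region_radius=6.0,             # mm around the seed
    drill_radius=0.5,                    # 1 mm drill
    safety_distance=0.5,                 # segmentation margin, mm
    drill_inaccuracy=0.2,                # navigation error, mm
)

cfts = find_cfts(config, skull, structures)
print(f"{len(cfts)} collision-free trajectories "
      f"(required clearance {config.required_clearance:.1f} mm)")

triple = select_best_triple(cfts, drill_radius=config.drill_radius)
for i, t in enumerate(triple.trajectories, 1):
    print(f"  port {i}: length {t.length:5.1f} mm, "
          f"clearance {t.clearance:4.2f} mm to {t.closest_structure}, "
          f"max drill diameter {t.max_diameter:4.2f} mm")
print(f"cumulative angle {triple.cumulative_angle:.1f} deg "
      "(larger = ports more spread apart)")
print(f"pairwise merge lengths {np.round(triple.merge_lengths, 2)} mm "
      "(depth from the target where two canals fuse into one cavity)")
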