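"""Selection expansion and manual group edits.

Selections expand at node, section or neurite scope; group edits set the
mean radius (proportional scaling) or mean position (rigid translation)
of the selected nodes, or rotate them about their centroid.
"""

import numpy as np

from morphoedit import (
    GenParams,
    Property,
    Scope,
    expand_selection,
    generate,
    rotate_selection,
    set_mean_property,
)

m = generate(GenParams(seed=5))
picked = {m.neurites[0].root_node.id}
section_ids = expand_selection(m, picked, Scope.SECTION)
neurite_ids = expand_selection(m, picked, Scope.NEURITE)
print(f"picked 1 node -> section scope {len(section_ids)} nodes, "
      f"neurite scope {len(neurite_ids)} nodes")

thicker = set_mean_property(m, neurite_ids, Property.RADIUS, 1.5)
radii = [thicker.node(i).radius for i in sorted(neurite_ids)]
print(f"mean radius after proportional edit: {np.mean(radii):.6f} (target 1.5)")

rotated = rotate_selection(m, sorted(section_ids), (0.0, 0.0, 30.0))
a, b = sorted(section_ids)[:2]
d_before = np.linalg.norm(m.node(a).position - m.node(b).position)
d_after = np.linalg.norm(rotated.node(a).position - rotated.node(b).position)
print(f"rotation is rigid: pairwise distance {d_before:.6f} -> {d_after:.6f}")
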