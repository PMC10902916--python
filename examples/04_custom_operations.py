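"""Run user-defined per-section operations.

A custom operation is any callable taking a section's node list and
returning the replacement list; script files defining process(in_nodes)
can be loaded at run time without touching the package.
"""

import tempfile
from pathlib import Path

from morphoedit import (
    GenParams,
    apply_custom,
    flatten_z,
    generate,
    load_custom,
    make_uniform_radius,
)

m = generate(GenParams(seed=4))

flat = apply_custom(m, flatten_z)
print("flatten-z: max |z| over tracing points =",
      max(abs(n.position[2]) for n in flat.neurite_nodes()))

uniform = apply_custom(m, make_uniform_radius(1.0))
print("uniform-radius: distinct neurite radii =",
      sorted({n.radius for n in uniform.neurite_nodes()}))

script = Path(tempfile.mkdtemp()) / "shrink.py"
script.write_text(
    "def process(in_nodes):\n"
    "    out = []\n"
    "    for n in in_nodes:\n"
    "        n = n.copy()\n"
    "        n.radius = n.radius * 0.5\n"
    "        out.append(n)\n"
    "    return out\n"
)
halved = apply_custom(m, load_custom(script))
print("scripted op: mean radius",
      round(sum(n.radius for n in halved.neurite_nodes())
            / sum(1 for _ in halved.neurite_nodes()), 3),
      "vs original",
      round(sum(n.radius for n in m.neurite_nodes())
            / sum(1 for _ in m.neurite_nodes()), 3))
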