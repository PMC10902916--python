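"""Export an approximate membrane mesh (OBJ) from a tracing.

The soma becomes a subdivided icosphere at the derived soma bounding
sphere; each section becomes a parallel-transport tube whose ring radii
follow the node radii.  Editing the tracing and regenerating gives the
updated membrane immediately.
"""

from pathlib import Path

from morphoedit import GenParams, MeshParams, generate, neuron_mesh, write_obj

m = generate(GenParams(seed=3))
mesh = neuron_mesh(m, MeshParams(ring_sides=12, soma_subdivisions=2))
out = Path("scratch_neuron.obj")
write_obj(mesh, out)
print(f"tracing: {m.n_nodes} nodes -> mesh: {len(mesh.vertices)} vertices, "
      f"{len(mesh.faces)} faces -> {out}")
# The OBJ contains only v/f records and re-parses into the same arrays.
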