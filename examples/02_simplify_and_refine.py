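"""Adjust tracing resolution: polyline simplification and refinement.

Nth-point simplification with n = 4 keeps every fourth point of each
section (plus the section endpoints, which are never discarded);
refinement inserts points until a target density (points per um).
"""

from morphoedit import (
    DouglasPeucker,
    GenParams,
    NthPoint,
    RefineParams,
    generate,
    resample_morphology,
)

m = generate(GenParams(seed=2))
print(f"original tracing: {m.n_nodes} points")

nth = resample_morphology(m, NthPoint(4))
print(f"Nth-point (n=4):  {nth.n_nodes} points kept "
      f"({nth.n_nodes / m.n_nodes:.0%} of the original)")

dp = resample_morphology(m, DouglasPeucker(0.5))
print(f"Douglas-Peucker (tol 0.5 um): {dp.n_nodes} points kept")

fine = resample_morphology(m, RefineParams("cubic_hermite", density=0.5))
print(f"cubic Hermite refinement at 0.5 points/um: {fine.n_nodes} points")
# Simplification always preserves each section's first and last node, so
# branch topology is untouched; refinement only ever adds points.
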