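# morphoedit

Headless editing, quality control and meshing of neuronal morphology
tracings.

Digital reconstructions of neurons — SWC files listing sampled points
`(id, type, x, y, z, radius, parent)` along the soma and neurites — are
the standard currency of computational neuroanatomy, but raw tracings
from manual or semi-automatic acquisition routinely carry defects:
duplicated points, oversampled stretches, points buried inside the soma,
detached neurite roots, trajectory kinks, implausible radii.  These
defects corrupt morphometric analyses and can make membrane-surface
reconstruction impossible.  `morphoedit` is a library (plus a thin CLI)
for the people who curate such data: it loads SWC tracings, detects a
catalog of common errors, repairs them automatically where a safe action
exists, adjusts sampling resolution, runs user-written per-section
transforms, and exports both the edited tracing (SWC) and an approximate
membrane mesh (OBJ).

## The model

A tracing is a forest of **nodes** hanging off a **soma** (the SWC
type-1 points).  Non-soma nodes are partitioned into **sections**: maximal
runs of nodes between two consecutive bifurcations (or a bifurcation and
a terminal).  A bifurcation node belongs to its incoming section and is
the *attachment* of each child section.  The soma is approximated by a
bounding sphere with

    c = mean(p_i),    R = mean(|p_i − c| + r_i)

over the soma points `(p_i, r_i)`; for a single-point soma this is the
point itself.

**Error catalog** (all thresholds strict, all configurable):

| check | condition |
|---|---|
| repeated nodes | nodes within `tol` (default 1e-6 um) of each other |
| oversampling | within-section segment shorter than `r_i + r_j` |
| inside soma | neurite node with `\|p − c\| < R` |
| root distance | neurite root with `\|p − c\| > 4R` |
| sharp angle | section-interior angle `< 90°` (straight = 180°) |
| radius order | child branch thicker than the bifurcation node |
| constant radius | a neurite whose radii do not vary |
| branch collision | sibling branch start spheres overlap (`\|c_1 − c_2\| < r_1 + r_2`) |

Repairs include duplicate removal (children re-parented), midpoint moves,
projection onto the soma sphere `p' = c + R·(p − c)/|p − c|`, and outlier
deletion/midpoint placement for sharp angles; repair iterates
detect → apply to a fixed point.

**Resolution adjustment** treats each section as a polyline: Nth-point,
radial-distance, perpendicular-distance, Reumann–Witkam, Opheim, Lang and
Douglas–Peucker simplification (plus the fixed-count Douglas–Peucker-N
variant), all endpoint-preserving subsequences; refinement inserts
`max(0, ceil(L·d) − 1)` points per segment of length `L` at density `d`
(points/um), on the chord or on a cubic Hermite spline with Catmull–Rom
tangents.

**Meshing** renders the soma sphere as a subdivided icosphere and each
section as a parallel-transport tube with one vertex ring per node
(ring radius = node radius), exported as Wavefront OBJ.

A seeded synthetic-morphology generator and a ground-truth error injector
make the whole pipeline testable without any external data.

## Worked example

```python
from morphoedit import (ErrorSpec, GenParams, NthPoint, auto_repair,
                        generate, inject_errors, resample_morphology, run_all)

clean = generate(GenParams(seed=1))                  # 275 nodes, 3 neurites
broken, truth = inject_errors(clean, ErrorSpec.one_of_each(seed=1))
print(len(run_all(broken)))                          # 8  (one finding per catalog entry)

repaired, log = auto_repair(broken)
print(broken.n_nodes, "->", repaired.n_nodes)        # 275 -> 273
print(len(run_all(repaired)))                        # 3  (only report-only findings remain)

simplified = resample_morphology(clean, NthPoint(4))
print(clean.n_nodes, "->", simplified.n_nodes)       # 275 -> 121 (44% kept)
```

The detector finds exactly the eight planted errors; auto-repair removes
the two removable defects (hence 275 → 273 nodes) and moves the others,
after which only the three report-only findings (thick child, constant
radii, branch collision — deliberate judgement calls) remain.  Nth-point
simplification with `n = 4` keeps indices 0, 4, 8, … of every section
plus each section's last node, retaining 121 of 275 points here.

The same workflow from a shell:

```bash
morphoedit synth --seed 1 --out neuron.swc
morphoedit validate neuron.swc                # exit 0: clean
morphoedit simplify neuron.swc -o small.swc --method nth --n 4
morphoedit mesh neuron.swc -o neuron.obj
```

See `examples/` for one narrative script per capability.

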