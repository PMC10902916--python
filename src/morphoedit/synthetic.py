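"""Seeded synthetic morphologies and ground-truth error injection.

The generator grows branching neurite trees with tapering radii around a
three-point soma, constructed so that a fresh morphology passes the whole
detection catalog cleanly: consecutive spacing exceeds the sum of node
radii, turn angles stay shallow, radii taper strictly, roots sit on the
soma sphere, and sibling branches start well apart.  Distances from the
soma center increase monotonically along every path, so no node can fall
back inside the soma.

The injector then mutates a clean morphology to plant a requested number
of instances of each catalog error, recording exactly which nodes were
affected.  Mutations are site-disjoint (each reserves its whole section or
subtree) and every candidate site is verified against the full catalog:
a site whose mutation would trigger any unplanned finding is rejected and
another candidate is drawn.  This makes the returned labels an exact
ground truth: the catalog on the mutated morphology yields precisely the
planted findings.

This is a test-fixture generator, not a neuron growth simulator; see the
methods note for what it does and does not emulate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .core_model import (
    ROOT,
    Morphology,
    Node,
    Section,
    build_morphology,
    soma_sphere,
)
from .validate import CHECK_FUNCS, CheckId, Finding, ValidationConfig

_MIN_RADIUS = 1e-6
_RADIAL_MIN = 0.15  # minimum radial component of any growth direction


class GenerationError(ValueError):
    """Generator parameters are infeasible."""


class InjectionError(ValueError):
    """Not enough eligible sites for a requested error count."""


@dataclass
class GenParams:
    """Growth parameters (lengths and radii in micrometers)."""

    n_neurites: int = 3
    depth: int = 3  # number of bifurcation levels per neurite
    nodes_per_section: tuple[int, int] = (4, 8)
    segment_length: tuple[float, float] = (3.0, 6.0)
    root_radius: float = 0.8
    taper: float = 0.97  # per-node radius multiplier, strictly < 1
    soma_radius: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.taper < 1.0):
            raise GenerationError("taper must be in (0, 1)")
        if self.segment_length[0] <= 0:
            raise GenerationError("segment lengths must be > 0")
        if self.n_neurites < 1 or self.depth < 0:
            raise GenerationError("need n_neurites >= 1 and depth >= 0")
        max_path = (self.depth + 1) * self.nodes_per_section[1]
        if self.root_radius * self.taper**max_path < _MIN_RADIUS:
            raise GenerationError(
                "taper drives radii below the representable minimum; "
                "reduce depth/nodes or raise taper/root_radius"
            )


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _rotate(v: np.ndarray, axis: np.ndarray, angle_rad: float) -> np.ndarray:
    """Rodrigues rotation of v about a unit axis."""
    c, s = np.cos(angle_rad), np.sin(angle_rad)
    return v * c + np.cross(axis, v) * s + axis * (axis @ v) * (1 - c)


def _jitter(d: np.ndarray, rng: np.random.Generator, max_deg: float) -> np.ndarray:
    angle = np.radians(rng.uniform(0.0, max_deg))
    while True:
        raw = rng.normal(size=3)
        axis = raw - (raw @ d) * d
        n = np.linalg.norm(axis)
        if n > 1e-8:
            break
    return _unit(_rotate(d, axis / n, angle))


def _outward(d: np.ndarray, pos: np.ndarray) -> np.ndarray:
    """Bias a direction so the distance from the origin strictly grows."""
    rhat = _unit(pos)
    rc = d @ rhat
    if rc < _RADIAL_MIN:
        d = _unit(d + (_RADIAL_MIN - rc + 0.05) * rhat)
    return d


def generate(params: GenParams | None = None) -> Morphology:
    """Grow a clean, deterministic synthetic morphology.

    Same seed, same parameters -> identical output (byte-identical SWC).
    With ``depth = 0`` each neurite is a single unbranched section.
    """
    params = params or GenParams()
    rng = np.random.default_rng(params.seed)
    records: list[Node] = []
    next_id = 1

    def new_node(type_code: int, pos, radius: float, parent: int) -> Node:
        nonlocal next_id
        node = Node(next_id, type_code, np.asarray(pos, dtype=float), radius, parent)
        records.append(node)
        next_id += 1
        return node

    # three-point soma: an equilateral triangle of equal-radius points whose
    # derived bounding sphere has exactly params.soma_radius
    a = rho = params.soma_radius / 2.0
    soma_ids = []
    for k, ang in enumerate((0.0, 120.0, 240.0)):
        pos = (a * np.cos(np.radians(ang)), a * np.sin(np.radians(ang)), 0.0)
        parent = ROOT if k == 0 else soma_ids[-1]
        soma_ids.append(new_node(1, pos, rho, parent).id)

    R = params.soma_radius
    kinds = [3, 2, 4]  # basal, axon, apical, then cycle through basal
    lo, hi = params.nodes_per_section
    llo, lhi = params.segment_length

    def grow_section(
        pos: np.ndarray, d: np.ndarray, radius: float, parent: int, type_code: int, depth_left: int
    ) -> None:
        n_nodes = int(rng.integers(lo, hi + 1))
        node = None
        for _ in range(n_nodes):
            radius *= params.taper
            node = new_node(type_code, pos, radius, parent)
            parent = node.id
            d = _outward(_jitter(d, rng, 20.0), pos)
            pos = pos + d * rng.uniform(llo, lhi)
        if depth_left > 0:
            bif_pos, bif_r = node.position, node.radius
            for _ in range(50):
                while True:
                    raw = rng.normal(size=3)
                    axis = raw - (raw @ d) * d
                    n = np.linalg.norm(axis)
                    if n > 1e-8:
                        axis = axis / n
                        break
                angle = np.radians(rng.uniform(30.0, 45.0))
                dirs = [
                    _outward(_unit(_rotate(d, axis, sgn * angle)), bif_pos)
                    for sgn in (+1.0, -1.0)
                ]
                lens = [rng.uniform(llo, lhi) for _ in dirs]
                starts = [bif_pos + dd * ll for dd, ll in zip(dirs, lens)]
                child_r = bif_r * params.taper
                if np.linalg.norm(starts[0] - starts[1]) > 1.5 * 2 * child_r:
                    break
            else:  # pragma: no cover - extremely unlikely with sane params
                raise GenerationError("could not separate sibling branches")
            for dd, ss in zip(dirs, starts):
                grow_section(ss, dd, bif_r, node.id, type_code, depth_left - 1)

    for i in range(params.n_neurites):
        az = 2 * np.pi * i / params.n_neurites + rng.uniform(-0.2, 0.2)
        el = rng.uniform(-0.6, 0.6)
        u = np.array([np.cos(el) * np.cos(az), np.cos(el) * np.sin(az), np.sin(el)])
        root_pos = u * 1.2 * R
        grow_section(root_pos, u, params.root_radius, soma_ids[0], kinds[i % 3], params.depth)

    return build_morphology(
        records, provenance=f"synthetic morphology (seed={params.seed})"
    )


# ---------------------------------------------------------------------------
# error injection


@dataclass
class ErrorSpec:
    """Requested number of injected sites per catalog check."""

    counts: dict[CheckId, int] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        norm: dict[CheckId, int] = {}
        for key, val in self.counts.items():
            check = key if isinstance(key, CheckId) else CheckId(key)
            if val < 0:
                raise ValueError("requested counts must be >= 0")
            norm[check] = int(val)
        self.counts = norm

    @classmethod
    def one_of_each(cls, seed: int = 0) -> "ErrorSpec":
        return cls({check: 1 for check in CheckId}, seed=seed)


#: Injection order: mutations reserving whole neurites/subtrees go first so
#: the node-local ones can still find free sites.
_INJECT_ORDER = [
    CheckId.CONSTANT_RADIUS,
    CheckId.BIFURCATION_COLLISION,
    CheckId.ROOT_DISTANCE,
    CheckId.RADIUS_ORDER,
    CheckId.SHARP_ANGLE,
    CheckId.INSIDE_SOMA,
    CheckId.OVERSAMPLING,
    CheckId.REPEATED_NODES,
]


class _Injector:
    def __init__(self, m: Morphology, cfg: ValidationConfig, rng: np.random.Generator):
        self.cfg = cfg
        self.rng = rng
        self.work = m.copy()
        self.records = {n.id: n for n in self.work.to_records()}
        self.order = [n.id for n in self.work.nodes()]
        self.reserved: set[int] = set()
        self.expected: dict[CheckId, set[tuple[int, ...]]] = {c: set() for c in CheckId}
        self.truth: list[Finding] = []

    def _rebuild(self) -> Morphology:
        return build_morphology(
            [self.records[i].copy() for i in self.order], provenance=self.work.provenance
        )

    def _try(self, check: CheckId, node_ids: tuple[int, ...], mutate, reserve: set[int]) -> bool:
        """Apply ``mutate`` on a scratch copy; commit only if the catalog on
        the result shows exactly the already-planted findings plus this one."""
        saved = {i: self.records[i].copy() for i in reserve}
        mutate(self.records)
        candidate = self._rebuild()
        want = {c: set(v) for c, v in self.expected.items()}
        want[check].add(node_ids)
        logger = logging.getLogger("morphoedit.validate")
        level = logger.level
        logger.setLevel(logging.ERROR)  # expected skip-warnings during trials
        try:
            for c in CheckId:
                got = {f.node_ids for f in CHECK_FUNCS[c](candidate, self.cfg)}
                if got != want[c]:
                    self.records.update(saved)  # revert
                    return False
        finally:
            logger.setLevel(level)
        self.expected = want
        self.reserved |= reserve
        self.work = candidate
        self.truth.append(Finding(check, node_ids))
        return True

    def _shuffled(self, items: list) -> list:
        items = list(items)
        if items:
            idx = self.rng.permutation(len(items))
            items = [items[i] for i in idx]
        return items

    def _free_section(self, sec: Section) -> bool:
        return not (set(sec.node_ids) & self.reserved)

    def inject(self, check: CheckId, count: int) -> None:
        for _ in range(count):
            if not self._inject_one(check):
                raise InjectionError(f"no eligible site left for {check.value}")

    # -- one candidate mutation per check ---------------------------------
    def _inject_one(self, check: CheckId) -> bool:
        m = self.work
        center, R = soma_sphere(m.soma)
        sections = [s for nr in m.neurites for s in nr.sections()]

        if check is CheckId.CONSTANT_RADIUS:
            for nr in self._shuffled(m.neurites):
                ids = sorted(n.id for n in nr.nodes())
                if set(ids) & self.reserved:
                    continue
                rmin = min(n.radius for n in nr.nodes())

                def mutate(rec, ids=ids, rmin=rmin):
                    for i in ids:
                        rec[i].radius = rmin

                if self._try(check, tuple(ids), mutate, set(ids)):
                    return True
            return False

        if check is CheckId.BIFURCATION_COLLISION:
            for sec in self._shuffled([s for s in sections if len(s.children) >= 2]):
                cs1, cs2 = sec.children[0], sec.children[1]
                subtree = [n.id for s in cs1.walk() for n in s.nodes]
                # the mutation involves only the translated subtree, the
                # sibling child section and the bifurcation node itself
                reserve = set(subtree) | set(cs2.node_ids) | {sec.nodes[-1].id}
                if reserve & self.reserved:
                    continue
                c1, c2 = cs1.nodes[0], cs2.nodes[0]
                gap = np.linalg.norm(c1.position - c2.position)
                target = 0.6 * (c1.radius + c2.radius)
                delta = (1.0 - target / gap) * (c2.position - c1.position)

                def mutate(rec, subtree=subtree, delta=delta):
                    for i in subtree:
                        rec[i].position = rec[i].position + delta

                ids = tuple(sorted((c1.id, c2.id)))
                if self._try(check, ids, mutate, reserve):
                    return True
            return False

        if check is CheckId.ROOT_DISTANCE:
            for nr in self._shuffled(m.neurites):
                sec = nr.root_section
                if len(sec.nodes) < 2:
                    continue
                r, c = sec.nodes[0], sec.nodes[1]
                if {r.id, c.id} & self.reserved:
                    continue
                # push the root outward along the reversed first-segment
                # direction: the angle at c is unchanged
                d1 = _unit(c.position - r.position)
                t = 6.0 * R + float(np.linalg.norm(c.position - center))
                new_pos = c.position - d1 * t

                def mutate(rec, rid=r.id, new_pos=new_pos):
                    rec[rid].position = new_pos

                if self._try(check, (r.id,), mutate, {r.id, c.id}):
                    return True
            return False

        if check is CheckId.RADIUS_ORDER:
            cands = []
            for sec in sections:
                if len(sec.children) >= 2:
                    cands.extend((sec, child) for child in sec.children)
            for sec, child in self._shuffled(cands):
                b = sec.nodes[-1]
                # involved: the bifurcation node, the inflated child's
                # section and the sibling starts (their radii bound the
                # collision check at this bifurcation)
                reserve = {b.id} | set(child.node_ids) | {
                    ch.nodes[0].id for ch in sec.children
                }
                if reserve & self.reserved:
                    continue
                c = child.nodes[0]

                def mutate(rec, cid=c.id, r=b.radius * 1.3):
                    rec[cid].radius = r

                if self._try(check, (b.id, c.id), mutate, reserve):
                    return True
            return False

        if check is CheckId.SHARP_ANGLE:
            cands = [
                s for s in sections if len(s.nodes) >= 3 and not s.children
            ]
            for sec in self._shuffled(cands):
                if not self._free_section(sec):
                    continue
                i, j, k = sec.nodes[-3], sec.nodes[-2], sec.nodes[-1]
                new_pos = k.position + 0.7 * (k.position - i.position)

                def mutate(rec, jid=j.id, new_pos=new_pos):
                    rec[jid].position = new_pos

                if self._try(check, (i.id, j.id, k.id), mutate, set(sec.node_ids)):
                    return True
            return False

        if check is CheckId.INSIDE_SOMA:
            # a neurite root is the only node with no tested angle whose
            # displacement toward the soma cannot fold a trajectory
            for nr in self._shuffled(m.neurites):
                sec = nr.root_section
                if len(sec.nodes) < 2:
                    continue
                r, c = sec.nodes[0], sec.nodes[1]
                if {r.id, c.id} & self.reserved:
                    continue
                new_pos = center + _unit(r.position - center) * 0.5 * R

                def mutate(rec, rid=r.id, new_pos=new_pos):
                    rec[rid].position = new_pos

                if self._try(check, (r.id,), mutate, {r.id, c.id}):
                    return True
            return False

        if check is CheckId.OVERSAMPLING:
            cands = [s for s in sections if len(s.nodes) >= 2 and not s.children]
            for sec in self._shuffled(cands):
                if not self._free_section(sec):
                    continue
                p, j = sec.nodes[-2], sec.nodes[-1]
                d = _unit(j.position - p.position)
                new_pos = p.position + d * 0.5 * (p.radius + j.radius)

                def mutate(rec, jid=j.id, new_pos=new_pos):
                    rec[jid].position = new_pos

                if self._try(check, (p.id, j.id), mutate, set(sec.node_ids)):
                    return True
            return False

        if check is CheckId.REPEATED_NODES:
            cands = [s for s in sections if len(s.nodes) >= 3 and not s.children]
            for sec in self._shuffled(cands):
                if not self._free_section(sec):
                    continue
                p, j = sec.nodes[-2], sec.nodes[-1]

                def mutate(rec, jid=j.id, pos=p.position.copy()):
                    rec[jid].position = pos

                ids = tuple(sorted((p.id, j.id)))
                if self._try(check, ids, mutate, set(sec.node_ids)):
                    return True
            return False

        raise AssertionError(f"unhandled check {check}")  # pragma: no cover


def inject_errors(
    m: Morphology,
    spec: ErrorSpec,
    cfg: ValidationConfig | None = None,
) -> tuple[Morphology, list[Finding]]:
    """Plant catalog errors into a clean morphology.

    Returns the mutated morphology and the ground-truth findings (check id
    + affected node ids), sorted in catalog order.  Raises
    :class:`InjectionError` when a requested count cannot be placed.
    """
    cfg = cfg or ValidationConfig()
    inj = _Injector(m, cfg, np.random.default_rng(spec.seed))
    for check in _INJECT_ORDER:
        count = spec.counts.get(check, 0)
        if count:
            inj.inject(check, count)
    order = {c: i for i, c in enumerate(CHECK_FUNCS)}
    truth = sorted(inj.truth, key=lambda f: (order[f.check_id], min(f.node_ids)))
    return inj.work, truth
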