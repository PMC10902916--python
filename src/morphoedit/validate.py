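"""Automatic tracing-error detection catalog.

Eight checks covering the errors most frequently seen in reconstructed
tracings: coincident (repeated) nodes, oversampled segments, neurite nodes
inside the soma volume, neurite roots too far from the soma, sharp turns
in a trajectory, child branches thicker than their parent, neurites with
constant radii, and overlapping child branches at a bifurcation.

Every check is pure (the morphology is never modified) and returns
:class:`Finding` objects naming the affected nodes, measured quantities
and the corrective actions that apply.  All thresholds use *strict*
inequalities: a value exactly at the threshold passes.

Conventions:

* Segments are consecutive node pairs *within* a section; the implicit
  segment between a bifurcation and a child section's first node is not a
  within-section segment and is not tested for oversampling or angles.
* Segments not longer than ``position_tolerance`` count as repeated nodes
  and are excluded from the oversampling and sharp-angle checks, keeping
  the catalog entries disjoint.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.spatial import cKDTree

from .core_model import Morphology, Section, soma_sphere

logger = logging.getLogger(__name__)


class CheckId(enum.Enum):
    REPEATED_NODES = "repeated_nodes"
    OVERSAMPLING = "oversampling"
    INSIDE_SOMA = "inside_soma"
    ROOT_DISTANCE = "root_distance"
    SHARP_ANGLE = "sharp_angle"
    RADIUS_ORDER = "radius_order"
    CONSTANT_RADIUS = "constant_radius"
    BIFURCATION_COLLISION = "bifurcation_collision"


class Action(enum.Enum):
    REPORT = "report"
    REMOVE = "remove"
    MOVE_MIDPOINT = "move_midpoint"
    PROJECT_TO_SOMA_SURFACE = "project_to_soma_surface"
    MOVE_ROOT_TO_SOMA_SURFACE = "move_root_to_soma_surface"
    REMOVE_OUTLIER = "remove_outlier"
    MOVE_OUTLIER_MIDPOINT = "move_outlier_midpoint"


#: Corrective actions applicable to each check.  The last three checks are
#: report-only: deciding whether e.g. a thick child branch is an error
#: requires user judgement.
ACTIONS_BY_CHECK: dict[CheckId, tuple[Action, ...]] = {
    CheckId.REPEATED_NODES: (Action.REPORT, Action.REMOVE, Action.MOVE_MIDPOINT),
    CheckId.OVERSAMPLING: (Action.REPORT, Action.REMOVE, Action.MOVE_MIDPOINT),
    CheckId.INSIDE_SOMA: (Action.REPORT, Action.REMOVE, Action.PROJECT_TO_SOMA_SURFACE),
    CheckId.ROOT_DISTANCE: (Action.REPORT, Action.MOVE_ROOT_TO_SOMA_SURFACE),
    CheckId.SHARP_ANGLE: (Action.REPORT, Action.REMOVE_OUTLIER, Action.MOVE_OUTLIER_MIDPOINT),
    CheckId.RADIUS_ORDER: (Action.REPORT,),
    CheckId.CONSTANT_RADIUS: (Action.REPORT,),
    CheckId.BIFURCATION_COLLISION: (Action.REPORT,),
}


@dataclass(frozen=True)
class Finding:
    """One detected potential error."""

    check_id: CheckId
    node_ids: tuple[int, ...]
    section: int | None = None  # id of the containing section's first node
    details: dict = field(default_factory=dict)

    @property
    def actions(self) -> tuple[Action, ...]:
        return ACTIONS_BY_CHECK[self.check_id]

    def to_json(self) -> dict:
        return {
            "check_id": self.check_id.value,
            "node_ids": list(self.node_ids),
            "section": self.section,
            "details": {k: v for k, v in sorted(self.details.items())},
            "actions": [a.value for a in self.actions],
        }


@dataclass
class ValidationConfig:
    """Tunable thresholds of the detection catalog.

    ``oversampling_threshold`` of None means the adaptive default: a
    segment is oversampled when shorter than the sum of its two node radii.
    A float fixes the threshold in micrometers.  ``soma_distance_factor``
    flags neurite roots farther than that multiple of the soma radius.
    """

    position_tolerance: float = 1e-6
    oversampling_threshold: float | None = None  # None = sum of radii
    soma_distance_factor: float = 4.0
    sharp_angle_threshold: float = 90.0
    constant_radius_tolerance: float = 0.0

    def __post_init__(self) -> None:
        for name in (
            "position_tolerance",
            "soma_distance_factor",
            "sharp_angle_threshold",
            "constant_radius_tolerance",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.oversampling_threshold is not None and self.oversampling_threshold < 0:
            raise ValueError("oversampling_threshold must be >= 0")


def _sections(m: Morphology):
    for neurite in m.neurites:
        yield from neurite.sections()


def _section_ref(sec: Section) -> int:
    return sec.nodes[0].id


# ---------------------------------------------------------------------------
# the eight checks


def check_repeated_nodes(m: Morphology, cfg: ValidationConfig | None = None) -> list[Finding]:
    """Groups of nodes sharing the same 3D position (within tolerance).

    Grouping is the connected components of the "within tolerance of each
    other" graph over all nodes (soma included), found with a k-d tree;
    this matches an exhaustive pairwise scan.
    """
    cfg = cfg or ValidationConfig()
    nodes = list(m.nodes())
    if len(nodes) < 2:
        return []
    ids = [n.id for n in nodes]
    pos = np.array([n.position for n in nodes])
    pairs = cKDTree(pos).query_pairs(cfg.position_tolerance, output_type="ndarray")
    if len(pairs) == 0:
        return []
    parent = list(range(len(nodes)))

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for a, b in pairs:
        ra, rb = find(int(a)), find(int(b))
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)
    groups: dict[int, list[int]] = {}
    for i in range(len(nodes)):
        groups.setdefault(find(i), []).append(i)
    findings = []
    for members in groups.values():
        if len(members) < 2:
            continue
        gid = sorted(ids[i] for i in members)
        gpos = pos[members]
        dmax = max(
            float(np.linalg.norm(gpos[i] - gpos[j]))
            for i in range(len(members))
            for j in range(i + 1, len(members))
        )
        sec = m.section_of(gid[0])
        findings.append(
            Finding(
                CheckId.REPEATED_NODES,
                tuple(gid),
                _section_ref(sec) if sec else None,
                {"max_pairwise_distance": dmax},
            )
        )
    findings.sort(key=lambda f: f.node_ids[0])
    return findings


def check_oversampling(m: Morphology, cfg: ValidationConfig | None = None) -> list[Finding]:
    """Within-section segments shorter than the oversampling threshold.

    The default threshold is the sum of the segment's two node radii; a
    segment exactly at the threshold is not flagged.  Zero-length segments
    (below ``position_tolerance``) are left to the repeated-nodes check.
    """
    cfg = cfg or ValidationConfig()
    findings = []
    for sec in _sections(m):
        if len(sec.nodes) < 2:
            continue
        pos = np.array([n.position for n in sec.nodes])
        radii = np.array([n.radius for n in sec.nodes])
        dist = np.linalg.norm(np.diff(pos, axis=0), axis=1)
        if cfg.oversampling_threshold is None:
            thr = radii[:-1] + radii[1:]
        else:
            thr = np.full(len(dist), cfg.oversampling_threshold)
        for k in np.nonzero((dist < thr) & (dist > cfg.position_tolerance))[0]:
            a, b = sec.nodes[k], sec.nodes[k + 1]
            findings.append(
                Finding(
                    CheckId.OVERSAMPLING,
                    (a.id, b.id),
                    _section_ref(sec),
                    {"distance": float(dist[k]), "threshold": float(thr[k])},
                )
            )
    findings.sort(key=lambda f: min(f.node_ids))
    return findings


def check_nodes_inside_soma(m: Morphology, cfg: ValidationConfig | None = None) -> list[Finding]:
    """Neurite nodes strictly inside the soma bounding sphere."""
    cfg = cfg or ValidationConfig()
    if not m.soma.nodes:
        logger.warning("inside-soma check skipped: empty soma")
        return []
    center, radius = soma_sphere(m.soma)
    findings = []
    for n in m.neurite_nodes():
        d = float(np.linalg.norm(n.position - center))
        if d < radius:
            sec = m.section_of(n.id)
            findings.append(
                Finding(
                    CheckId.INSIDE_SOMA,
                    (n.id,),
                    _section_ref(sec) if sec else None,
                    {"distance_to_center": d, "soma_radius": float(radius)},
                )
            )
    findings.sort(key=lambda f: f.node_ids[0])
    return findings


def check_root_distance(m: Morphology, cfg: ValidationConfig | None = None) -> list[Finding]:
    """Neurite roots farther than ``soma_distance_factor`` soma radii."""
    cfg = cfg or ValidationConfig()
    if not m.soma.nodes:
        logger.warning("root-distance check skipped: empty soma")
        return []
    center, radius = soma_sphere(m.soma)
    limit = cfg.soma_distance_factor * radius
    findings = []
    for neurite in m.neurites:
        root = neurite.root_node
        d = float(np.linalg.norm(root.position - center))
        if d > limit:
            findings.append(
                Finding(
                    CheckId.ROOT_DISTANCE,
                    (root.id,),
                    _section_ref(neurite.root_section),
                    {"distance_to_center": d, "limit": float(limit)},
                )
            )
    findings.sort(key=lambda f: f.node_ids[0])
    return findings


def check_sharp_angles(m: Morphology, cfg: ValidationConfig | None = None) -> list[Finding]:
    """Sharp turns: interior angle at a node below the threshold.

    For each section-interior node j with within-section neighbors i and
    k, the interior angle between (i - j) and (k - j) is computed; a
    straight trajectory gives 180 degrees and is never flagged.  Nodes on
    zero-length segments are skipped (deferred to the repeated-nodes
    check).  Bifurcation nodes are never section-interior, hence excluded.
    """
    cfg = cfg or ValidationConfig()
    findings = []
    for sec in _sections(m):
        if len(sec.nodes) < 3:
            continue
        pos = np.array([n.position for n in sec.nodes])
        for j in range(1, len(sec.nodes) - 1):
            v1 = pos[j - 1] - pos[j]
            v2 = pos[j + 1] - pos[j]
            n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
            if n1 <= cfg.position_tolerance or n2 <= cfg.position_tolerance:
                logger.warning(
                    "sharp-angle check: zero-length segment at node %d skipped",
                    sec.nodes[j].id,
                )
                continue
            angle = float(np.degrees(np.arccos(np.clip(v1 @ v2 / (n1 * n2), -1.0, 1.0))))
            if angle < cfg.sharp_angle_threshold:
                findings.append(
                    Finding(
                        CheckId.SHARP_ANGLE,
                        (sec.nodes[j - 1].id, sec.nodes[j].id, sec.nodes[j + 1].id),
                        _section_ref(sec),
                        {"angle_deg": angle},
                    )
                )
    findings.sort(key=lambda f: min(f.node_ids))
    return findings


def check_radius_order(m: Morphology, cfg: ValidationConfig | None = None) -> list[Finding]:
    """Child branches thicker than their parent at a bifurcation.

    Compares each child section's first-node radius against the
    bifurcation node's radius (the last sample before the split); equal
    radii pass.  Report-only.
    """
    cfg = cfg or ValidationConfig()
    findings = []
    for sec in _sections(m):
        if len(sec.children) < 2:
            continue
        b = sec.nodes[-1]
        for child in sec.children:
            c = child.nodes[0]
            if c.radius > b.radius:
                findings.append(
                    Finding(
                        CheckId.RADIUS_ORDER,
                        (b.id, c.id),
                        _section_ref(child),
                        {"parent_radius": float(b.radius), "child_radius": float(c.radius)},
                    )
                )
    findings.sort(key=lambda f: min(f.node_ids))
    return findings


def check_constant_radius(m: Morphology, cfg: ValidationConfig | None = None) -> list[Finding]:
    """Neurites whose radii do not vary (within tolerance).  Report-only.

    A single-node neurite is vacuously constant and is flagged.
    """
    cfg = cfg or ValidationConfig()
    findings = []
    for neurite in m.neurites:
        radii = [n.radius for n in neurite.nodes()]
        if max(radii) - min(radii) <= cfg.constant_radius_tolerance:
            ids = tuple(sorted(n.id for n in neurite.nodes()))
            findings.append(
                Finding(
                    CheckId.CONSTANT_RADIUS,
                    ids,
                    _section_ref(neurite.root_section),
                    {"radius": float(radii[0]), "n_nodes": len(radii)},
                )
            )
    findings.sort(key=lambda f: min(f.node_ids))
    return findings


def check_bifurcation_collision(
    m: Morphology, cfg: ValidationConfig | None = None
) -> list[Finding]:
    """Overlapping child branches at a bifurcation.  Report-only.

    Surrogate for membrane interpenetration: the bounding spheres of the
    two child sections' first nodes overlap, i.e. ``|c1 - c2| < r1 + r2``
    (strict).
    """
    cfg = cfg or ValidationConfig()
    findings = []
    for sec in _sections(m):
        if len(sec.children) < 2:
            continue
        firsts = [child.nodes[0] for child in sec.children]
        for i in range(len(firsts)):
            for j in range(i + 1, len(firsts)):
                a, b = firsts[i], firsts[j]
                d = float(np.linalg.norm(a.position - b.position))
                if d < a.radius + b.radius:
                    findings.append(
                        Finding(
                            CheckId.BIFURCATION_COLLISION,
                            tuple(sorted((a.id, b.id))),
                            _section_ref(sec),
                            {"distance": d, "radius_sum": float(a.radius + b.radius)},
                        )
                    )
    findings.sort(key=lambda f: min(f.node_ids))
    return findings


#: Catalog order; also the sort order of :func:`run_all` output.
CHECK_FUNCS: dict[CheckId, Callable[[Morphology, ValidationConfig], list[Finding]]] = {
    CheckId.REPEATED_NODES: check_repeated_nodes,
    CheckId.OVERSAMPLING: check_oversampling,
    CheckId.INSIDE_SOMA: check_nodes_inside_soma,
    CheckId.ROOT_DISTANCE: check_root_distance,
    CheckId.SHARP_ANGLE: check_sharp_angles,
    CheckId.RADIUS_ORDER: check_radius_order,
    CheckId.CONSTANT_RADIUS: check_constant_radius,
    CheckId.BIFURCATION_COLLISION: check_bifurcation_collision,
}


def run_all(m: Morphology, cfg: ValidationConfig | None = None) -> list[Finding]:
    """Run the whole catalog; deterministic order (check, smallest id)."""
    cfg = cfg or ValidationConfig()
    order = {c: i for i, c in enumerate(CHECK_FUNCS)}
    findings = [f for func in CHECK_FUNCS.values() for f in func(m, cfg)]
    findings.sort(key=lambda f: (order[f.check_id], min(f.node_ids)))
    return findings


def findings_to_json(findings: list[Finding]) -> list[dict]:
    return [f.to_json() for f in findings]
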