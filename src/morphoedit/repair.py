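"""Corrective actions for detected tracing errors.

Each action takes a finding produced from a morphology and returns a new,
repaired morphology (the input is never modified).  Node removal is
topology-preserving: the removed node's children are re-parented to its
parent, so the number of neurites never changes.  :func:`auto_repair`
iterates detect -> apply per check until the mutable checks are clean or
an iteration limit is reached.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core_model import ROOT, Morphology, Node, build_morphology
from .validate import (
    CHECK_FUNCS,
    Action,
    CheckId,
    Finding,
    ValidationConfig,
    soma_sphere,
)


class RepairError(ValueError):
    """The requested action cannot be applied to this finding."""


#: Checks with actions that modify the morphology; catalog order.
MUTABLE_CHECKS = (
    CheckId.REPEATED_NODES,
    CheckId.OVERSAMPLING,
    CheckId.INSIDE_SOMA,
    CheckId.ROOT_DISTANCE,
    CheckId.SHARP_ANGLE,
)


@dataclass
class RepairPlan:
    """Chosen action per check, plus the iteration limit for auto repair."""

    actions: dict[CheckId, Action] = field(default_factory=dict)
    iteration_limit: int = 10

    def __post_init__(self) -> None:
        from .validate import ACTIONS_BY_CHECK

        norm: dict[CheckId, Action] = {}
        for key, val in self.actions.items():
            check = key if isinstance(key, CheckId) else CheckId(key)
            action = val if isinstance(val, Action) else Action(val)
            if action not in ACTIONS_BY_CHECK[check]:
                raise RepairError(f"action {action.value} not applicable to {check.value}")
            norm[check] = action
        self.actions = norm


def default_plan() -> RepairPlan:
    """A conservative mutating plan for the five repairable checks."""
    return RepairPlan(
        {
            CheckId.REPEATED_NODES: Action.REMOVE,
            CheckId.OVERSAMPLING: Action.REMOVE,
            CheckId.INSIDE_SOMA: Action.PROJECT_TO_SOMA_SURFACE,
            CheckId.ROOT_DISTANCE: Action.MOVE_ROOT_TO_SOMA_SURFACE,
            CheckId.SHARP_ANGLE: Action.MOVE_OUTLIER_MIDPOINT,
        }
    )


@dataclass
class RepairLogEntry:
    """One applied mutation: what, where, and the before/after values."""

    check_id: CheckId | None
    action: Action
    node_ids: tuple[int, ...]
    detail: dict = field(default_factory=dict)

    def to_json(self) -> dict:
        return {
            "check_id": self.check_id.value if self.check_id else None,
            "action": self.action.value,
            "node_ids": list(self.node_ids),
            "detail": self.detail,
        }


# ---------------------------------------------------------------------------
# record-level surgery helpers


class _Workspace:
    """Flat, mutable view of a morphology's node records."""

    def __init__(self, m: Morphology):
        self.records: list[Node] = m.to_records()
        self.by_id = {n.id: n for n in self.records}
        self.children: dict[int, list[int]] = {}
        for n in self.records:
            if n.type_code != 1:
                self.children.setdefault(n.parent_id, []).append(n.id)
        self.soma_ids = {n.id for n in self.records if n.type_code == 1}
        self.provenance = m.provenance

    def is_bifurcation(self, node_id: int) -> bool:
        return len(self.children.get(node_id, [])) >= 2

    def is_sole_section_node(self, node_id: int) -> bool:
        """True for a node that is both first and last of its section:
        its parent is a bifurcation/soma/ROOT and it has != 1 child."""
        n = self.by_id[node_id]
        first = (
            n.parent_id == ROOT
            or n.parent_id in self.soma_ids
            or self.is_bifurcation(n.parent_id)
        )
        return first and len(self.children.get(node_id, [])) != 1

    def remove(self, node_id: int) -> None:
        """Delete a node; its children are re-parented to its parent."""
        node = self.by_id[node_id]
        if node_id in self.soma_ids and len(self.soma_ids) == 1:
            raise RepairError("refusing to remove the only soma node")
        for child_id in self.children.get(node_id, []):
            self.by_id[child_id].parent_id = node.parent_id
        # soma children of a removed soma node
        for n in self.records:
            if n.parent_id == node_id:
                n.parent_id = node.parent_id
        self.records.remove(node)
        del self.by_id[node_id]
        # rebuild child map lazily: correctness over speed at these sizes
        self.children = {}
        for n in self.records:
            if n.type_code != 1:
                self.children.setdefault(n.parent_id, []).append(n.id)
        self.soma_ids.discard(node_id)

    def build(self) -> Morphology:
        return build_morphology(self.records, provenance=self.provenance)


def _removal_candidates(ws: _Workspace, ids: tuple[int, ...]) -> list[int]:
    """Nodes of a coincident/oversampled group ordered by removal
    preference: later nodes first, never a bifurcation while a plain
    partner exists, never a section's sole node."""
    cands = [i for i in ids if not ws.is_sole_section_node(i)]
    cands.sort(key=lambda i: (ws.is_bifurcation(i), -i))
    return cands


def _keep_of_group(ws: _Workspace, ids: tuple[int, ...]) -> int:
    """Which member of a repeated-node group survives: the bifurcation
    member if present (smallest id among them), else the smallest id."""
    bifs = [i for i in ids if ws.is_bifurcation(i)]
    return min(bifs) if bifs else min(ids)


def _project_to_sphere(ws: _Workspace, node_id: int, center: np.ndarray, radius: float) -> None:
    node = ws.by_id[node_id]
    v = node.position - center
    norm = np.linalg.norm(v)
    if norm < 1e-12:
        kids = ws.children.get(node_id, [])
        if kids:
            v = ws.by_id[kids[0]].position - center
            norm = np.linalg.norm(v)
        if norm < 1e-12:
            v, norm = np.array([1.0, 0.0, 0.0]), 1.0
    node.position = center + radius * v / norm


def apply_action(m: Morphology, finding: Finding, action: Action) -> Morphology:
    """Apply one corrective action; returns a new morphology.

    Raises :class:`RepairError` if the action is not in the finding's
    action set or would break the topology (e.g. no removable member).
    """
    if action not in finding.actions:
        raise RepairError(
            f"action {action.value} not applicable to {finding.check_id.value}"
        )
    if action is Action.REPORT:
        return m
    ws = _Workspace(m)
    for i in finding.node_ids:
        if i not in ws.by_id:
            raise RepairError(f"finding references unknown node {i} (stale finding?)")

    check = finding.check_id
    if action is Action.REMOVE:
        if check is CheckId.REPEATED_NODES:
            keep = _keep_of_group(ws, finding.node_ids)
            doomed = [i for i in finding.node_ids if i != keep]
            for i in doomed:
                if ws.is_sole_section_node(i):
                    raise RepairError(f"cannot remove sole section node {i}")
                ws.remove(i)
        else:  # oversampling pair
            cands = _removal_candidates(ws, finding.node_ids)
            if not cands:
                raise RepairError(
                    f"no removable member in {finding.node_ids} (all protected)"
                )
            ws.remove(cands[0])
    elif action is Action.MOVE_MIDPOINT:
        if check is CheckId.REPEATED_NODES:
            keep = _keep_of_group(ws, finding.node_ids)
            targets = [i for i in finding.node_ids if i != keep]
        else:
            targets = [finding.node_ids[-1]]
        for i in targets:
            node = ws.by_id[i]
            kids = ws.children.get(i, [])
            if not kids or node.parent_id == ROOT:
                # leaf (or parentless) offender: fall back to removal
                if ws.is_sole_section_node(i):
                    raise RepairError(f"cannot remove sole section node {i}")
                ws.remove(i)
            else:
                parent = ws.by_id[node.parent_id]
                first_child = ws.by_id[kids[0]]
                node.position = 0.5 * (parent.position + first_child.position)
    elif action in (Action.PROJECT_TO_SOMA_SURFACE, Action.MOVE_ROOT_TO_SOMA_SURFACE):
        center, radius = soma_sphere(m.soma)  # soma points are not touched
        _project_to_sphere(ws, finding.node_ids[0], center, radius)
    elif action is Action.REMOVE_OUTLIER:
        _i, j, _k = finding.node_ids
        ws.remove(j)
    elif action is Action.MOVE_OUTLIER_MIDPOINT:
        i, j, k = finding.node_ids
        ws.by_id[j].position = 0.5 * (ws.by_id[i].position + ws.by_id[k].position)
    else:  # pragma: no cover
        raise RepairError(f"unhandled action {action}")
    return ws.build()


def auto_repair(
    m: Morphology,
    cfg: ValidationConfig | None = None,
    plan: RepairPlan | None = None,
) -> tuple[Morphology, list[RepairLogEntry]]:
    """Iterate detect -> apply until the planned checks are clean.

    Findings are re-detected after every mutation (a repair can shift or
    remove nodes referenced by other findings).  Checks planned as REPORT
    never mutate.  If findings remain after the iteration limit, the
    partial result is returned and a warning entry is appended to the log.
    """
    cfg = cfg or ValidationConfig()
    plan = plan or default_plan()
    current = m
    log: list[RepairLogEntry] = []
    clean = False
    for _ in range(plan.iteration_limit):
        mutated = False
        for check in MUTABLE_CHECKS:
            action = plan.actions.get(check, Action.REPORT)
            if action is Action.REPORT:
                continue
            budget = None
            while True:
                findings = CHECK_FUNCS[check](current, cfg)
                if budget is None:
                    budget = len(findings) + plan.iteration_limit
                if not findings or budget <= 0:
                    break
                budget -= 1
                f = findings[0]
                before = {
                    i: (list(map(float, current.node(i).position)), float(current.node(i).radius))
                    for i in f.node_ids
                }
                current = apply_action(current, f, action)
                after = {
                    i: (list(map(float, current.node(i).position)), float(current.node(i).radius))
                    for i in f.node_ids
                    if current.has_node(i)
                }
                log.append(
                    RepairLogEntry(check, action, f.node_ids, {"before": before, "after": after})
                )
                mutated = True
        remaining = [
            f
            for check in MUTABLE_CHECKS
            if plan.actions.get(check, Action.REPORT) is not Action.REPORT
            for f in CHECK_FUNCS[check](current, cfg)
        ]
        if not remaining:
            clean = True
            break
        if not mutated:
            break
    if not clean:
        log.append(
            RepairLogEntry(
                None,
                Action.REPORT,
                (),
                {"warning": "iteration limit reached with findings remaining"},
            )
        )
    return current, log
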