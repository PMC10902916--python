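"""User-defined per-section operations.

A custom operation is a plain callable that receives the ordered node
list of one section (``in_nodes``) and returns the replacement node list
(``out_nodes``).  It may read and modify positions, radii and identifiers,
and may change the node count.  Operations are applied section by section
over a selection (or the whole tracing) without touching the soma, and
the result is re-assembled with globally unique ids.

Script files are loaded with :func:`load_custom`: the file must define a
function named ``process(in_nodes)``; nothing is executed at load time
beyond the module body, and loading has no effect on any morphology.

Application is transactional: if the operation raises, or returns an
empty or invalid node list for any section, the input morphology is left
untouched and the error names the offending section.
"""

from __future__ import annotations

from os import PathLike
from typing import Callable, Iterable, Sequence

import numpy as np

from .core_model import Morphology, Node, build_morphology

ENTRY_POINT = "process"

CustomOp = Callable[[list[Node]], list[Node]]


class PluginError(ValueError):
    pass


def flatten_z(in_nodes: list[Node]) -> list[Node]:
    """Example op: project every tracing point onto the XY plane (z = 0)."""
    out = []
    for n in in_nodes:
        n = n.copy()
        n.position[2] = 0.0
        out.append(n)
    return out


def make_uniform_radius(radius: float = 1.0) -> CustomOp:
    """Example op factory: set every tracing point's radius to a constant."""

    def op(in_nodes: list[Node]) -> list[Node]:
        out = []
        for n in in_nodes:
            n = n.copy()
            n.radius = float(radius)
            out.append(n)
        return out

    return op


def identity_op(in_nodes: list[Node]) -> list[Node]:
    return [n.copy() for n in in_nodes]


def apply_custom(
    m: Morphology, op: CustomOp, selection: Iterable[int] | None = None
) -> Morphology:
    """Apply a custom operation to every section intersecting the selection
    (all sections when the selection is None or empty).

    The returned morphology has fresh, globally unique node ids; structural
    validity is re-asserted on assembly.
    """
    selected = set(selection) if selection else None
    new_records: list[Node] = []
    next_id = 1
    remap: dict[int, int] = {}

    def emit(node: Node, parent_new: int) -> int:
        nonlocal next_id
        out = node.copy()
        out.id = next_id
        out.parent_id = parent_new
        new_records.append(out)
        next_id += 1
        return out.id

    for soma_node in m.soma.nodes:
        parent = -1 if soma_node.parent_id == -1 else remap[soma_node.parent_id]
        remap[soma_node.id] = emit(soma_node, parent)

    for neurite in m.neurites:
        # (section, new parent id of its first node) in pre-order
        stack = [(neurite.root_section, remap.get(neurite.root_section.nodes[0].parent_id, -1))]
        while stack:
            sec, parent_new = stack.pop()
            touched = selected is None or (set(sec.node_ids) & selected)
            if touched:
                out_nodes = _run_op(op, sec)
            else:
                out_nodes = [n.copy() for n in sec.nodes]
            cur_parent = parent_new
            for n in out_nodes:
                cur_parent = emit(n, cur_parent)
            last_new = cur_parent
            for child in reversed(sec.children):
                stack.append((child, last_new))
    return build_morphology(new_records, provenance=m.provenance)


def _run_op(op: CustomOp, sec) -> list[Node]:
    ref = sec.nodes[0].id
    try:
        out = op([n.copy() for n in sec.nodes])
    except Exception as exc:
        raise PluginError(f"custom op failed on section at node {ref}: {exc}") from exc
    out = list(out) if out is not None else []
    if not out:
        raise PluginError(f"custom op returned no nodes for section at node {ref}")
    ids = [n.id for n in out]
    if len(set(ids)) != len(ids):
        raise PluginError(f"custom op returned duplicate ids for section at node {ref}")
    for n in out:
        if not isinstance(n, Node):
            raise PluginError(f"custom op returned a non-Node for section at node {ref}")
        if not np.all(np.isfinite(n.position)):
            raise PluginError(f"custom op produced non-finite position at node {ref}")
    return out


def load_custom(source: str | PathLike, entry_point: str = ENTRY_POINT) -> CustomOp:
    """Load a custom operation from a Python script file.

    The script must define ``process(in_nodes) -> out_nodes``.  Syntax
    errors and a missing entry point raise :class:`PluginError` with
    file/line diagnostics.  Loading is side-effect-free on morphologies.
    """
    path = str(source)
    with open(path, "r", encoding="utf-8") as fh:
        text = fh.read()
    namespace: dict = {"Node": Node, "np": np}
    try:
        code = compile(text, path, "exec")
        exec(code, namespace)
    except SyntaxError as exc:
        raise PluginError(f"{path}:{exc.lineno}: syntax error: {exc.msg}") from exc
    except Exception as exc:
        raise PluginError(f"{path}: error while loading script: {exc}") from exc
    func = namespace.get(entry_point)
    if not callable(func):
        raise PluginError(f"{path}: script does not define a callable {entry_point!r}")
    return func
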