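"""Core domain model for neuronal morphology tracings.

A tracing is a set of sampled points ("nodes"), each carrying a 3D position
(micrometers), a radius (micrometers), an SWC type code and a parent link.
Type-1 nodes describe the soma; the remaining nodes form neurites (axon,
basal/apical dendrites), which are trees of *sections*: maximal runs of
nodes between two consecutive bifurcations (or a bifurcation and a
terminal).  A bifurcation node belongs to its incoming, parent-side section
and is recorded as the *attachment* of each child section.

The soma is internally approximated by a bounding sphere whose center is
the centroid of the soma points and whose radius is the mean of
``|p_i - center| + r_i`` over the soma points; for a single-point soma this
reduces to the point itself.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np
from scipy.spatial.transform import Rotation

#: Sentinel parent id for nodes with no parent.
ROOT = -1

SWC_SOMA = 1
SWC_AXON = 2
SWC_BASAL = 3
SWC_APICAL = 4


class StructuralError(ValueError):
    """A morphology violates a structural invariant (bad parent, cycle...)."""

    def __init__(self, message: str, node_id: int | None = None):
        super().__init__(message)
        self.node_id = node_id


class EditError(ValueError):
    """An edit operation is not applicable to the given selection."""


class NeuriteKind(enum.Enum):
    AXON = "axon"
    BASAL = "basal"
    APICAL = "apical"
    OTHER = "other"

    @classmethod
    def from_type_code(cls, code: int) -> "NeuriteKind":
        return {SWC_AXON: cls.AXON, SWC_BASAL: cls.BASAL, SWC_APICAL: cls.APICAL}.get(
            code, cls.OTHER
        )


class Scope(enum.Enum):
    """Granularity of a selection expansion."""

    NODE = "node"
    SECTION = "section"
    NEURITE = "neurite"


class Property(enum.Enum):
    RADIUS = "radius"
    POSITION = "position"


@dataclass(eq=False)  # identity equality: positions are numpy arrays
class Node:
    """One tracing point: id, SWC type, position (um), radius (um), parent."""

    id: int
    type_code: int
    position: np.ndarray
    radius: float
    parent_id: int = ROOT

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,):
            raise ValueError(f"node {self.id}: position must be a 3-vector")
        self.radius = float(self.radius)

    def copy(self) -> "Node":
        return Node(self.id, self.type_code, self.position.copy(), self.radius, self.parent_id)


@dataclass
class Soma:
    """The soma point set (SWC type 1) in input order."""

    nodes: list[Node] = field(default_factory=list)

    def sphere(self) -> tuple[np.ndarray, float]:
        return soma_sphere(self)


@dataclass
class Section:
    """An ordered run of nodes between bifurcations/terminals.

    ``attachment`` is the id of the node this section hangs from: the
    bifurcation node for child sections, or the soma node / ROOT for the
    first section of a neurite.  Interior nodes have exactly one child; the
    last node is a terminal or a bifurcation.
    """

    nodes: list[Node]
    attachment: int = ROOT
    children: list["Section"] = field(default_factory=list)

    @property
    def node_ids(self) -> list[int]:
        return [n.id for n in self.nodes]

    def walk(self) -> Iterator["Section"]:
        """Pre-order traversal of this section subtree."""
        stack = [self]
        while stack:
            s = stack.pop()
            yield s
            stack.extend(reversed(s.children))


@dataclass
class Neurite:
    """A process emanating from the soma: a tree of sections."""

    kind: NeuriteKind
    root_section: Section

    @property
    def root_node(self) -> Node:
        return self.root_section.nodes[0]

    def sections(self) -> list[Section]:
        return list(self.root_section.walk())

    def nodes(self) -> list[Node]:
        return [n for s in self.sections() for n in s.nodes]


@dataclass
class Morphology:
    """Soma plus neurite trees, with an id index over all nodes."""

    soma: Soma
    neurites: list[Neurite]
    provenance: str = ""

    def __post_init__(self) -> None:
        self._index: dict[int, Node] = {}
        self._section_of: dict[int, Section] = {}
        self._neurite_of: dict[int, Neurite] = {}
        for n in self.soma.nodes:
            self._index[n.id] = n
        for neurite in self.neurites:
            for sec in neurite.sections():
                for n in sec.nodes:
                    self._index[n.id] = n
                    self._section_of[n.id] = sec
                    self._neurite_of[n.id] = neurite

    # -- queries ----------------------------------------------------------
    def node(self, node_id: int) -> Node:
        try:
            return self._index[node_id]
        except KeyError:
            raise StructuralError(f"unknown node id {node_id}", node_id) from None

    def has_node(self, node_id: int) -> bool:
        return node_id in self._index

    def section_of(self, node_id: int) -> Section | None:
        """The neurite section containing the node (None for soma nodes)."""
        return self._section_of.get(node_id)

    def neurite_of(self, node_id: int) -> Neurite | None:
        return self._neurite_of.get(node_id)

    def nodes(self) -> Iterator[Node]:
        """All nodes, soma first, then neurites in pre-order."""
        yield from self.soma.nodes
        for neurite in self.neurites:
            for sec in neurite.sections():
                yield from sec.nodes

    def neurite_nodes(self) -> Iterator[Node]:
        for neurite in self.neurites:
            yield from neurite.nodes()

    @property
    def n_nodes(self) -> int:
        return len(self._index)

    def children_of(self, node_id: int) -> list[Node]:
        """Non-soma children of a node, in record order."""
        return [n for n in self.nodes() if n.parent_id == node_id and n.type_code != SWC_SOMA]

    # -- conversion -------------------------------------------------------
    def to_records(self) -> list[Node]:
        """Flat node records (copies), soma first then neurites pre-order.

        ``build_morphology(m.to_records())`` reproduces ``m`` exactly.
        """
        return [n.copy() for n in self.nodes()]

    def copy(self) -> "Morphology":
        return build_morphology(self.to_records(), provenance=self.provenance)


def soma_sphere(soma: Soma) -> tuple[np.ndarray, float]:
    """Bounding sphere of the soma point set.

    Center is the centroid of the soma node positions; radius the mean of
    ``|p_i - center| + r_i``.  A single-node soma yields that node's
    position and radius.
    """
    if not soma.nodes:
        raise StructuralError("soma is empty; no sphere can be derived")
    pos = np.array([n.position for n in soma.nodes])
    radii = np.array([n.radius for n in soma.nodes])
    center = pos.mean(axis=0)
    radius = float(np.mean(np.linalg.norm(pos - center, axis=1) + radii))
    return center, radius


def build_morphology(records: Sequence[Node], provenance: str = "") -> Morphology:
    """Assemble a :class:`Morphology` from flat SWC node records.

    Type-1 records become the soma (input order preserved); the remaining
    records are partitioned into sections delimited by bifurcations and
    terminals.  Raises :class:`StructuralError` on duplicate ids, unknown
    parents, soma points hanging from neurite nodes, or parent-link cycles.
    """
    if not records:
        raise StructuralError("no records")
    by_id: dict[int, Node] = {}
    for rec in records:
        if rec.id in by_id:
            raise StructuralError(f"duplicate node id {rec.id}", rec.id)
        if rec.id <= 0:
            raise StructuralError(f"node id {rec.id} is not a positive integer", rec.id)
        by_id[rec.id] = rec.copy()
    for rec in by_id.values():
        if rec.parent_id != ROOT and rec.parent_id not in by_id:
            raise StructuralError(
                f"node {rec.id} references unknown parent {rec.parent_id}", rec.id
            )

    # cycle detection by walking parent chains with memoization
    state: dict[int, int] = {}  # 0 in progress, 1 done
    for rec in by_id.values():
        chain = []
        cur = rec.id
        while cur != ROOT and state.get(cur) != 1:
            if state.get(cur) == 0:
                raise StructuralError(f"cycle in parent links at node {cur}", cur)
            state[cur] = 0
            chain.append(cur)
            cur = by_id[cur].parent_id
        for c in chain:
            state[c] = 1

    soma_ids = {i for i, n in by_id.items() if n.type_code == SWC_SOMA}
    children: dict[int, list[int]] = {}
    for rec in by_id.values():  # insertion order == record order
        children.setdefault(rec.parent_id, []).append(rec.id)

    soma = Soma([by_id[i] for i in by_id if i in soma_ids])
    for n in soma.nodes:
        if n.parent_id != ROOT and n.parent_id not in soma_ids:
            raise StructuralError(
                f"soma node {n.id} has non-soma parent {n.parent_id}", n.id
            )

    def neurite_children(node_id: int) -> list[int]:
        return [c for c in children.get(node_id, []) if c not in soma_ids]

    # neurite roots: non-soma nodes whose parent is ROOT or a soma node
    roots = [
        i
        for i, n in by_id.items()
        if i not in soma_ids and (n.parent_id == ROOT or n.parent_id in soma_ids)
    ]

    neurites: list[Neurite] = []
    seen: set[int] = set()
    for root_id in roots:
        root_rec = by_id[root_id]
        root_section = _build_section_tree(root_id, root_rec.parent_id, by_id, neurite_children, seen)
        neurites.append(Neurite(NeuriteKind.from_type_code(root_rec.type_code), root_section))

    stray = set(by_id) - soma_ids - seen
    if stray:
        sid = min(stray)
        raise StructuralError(f"node {sid} unreachable from any root (cycle?)", sid)
    return Morphology(soma, neurites, provenance)


def _build_section_tree(
    first_id: int,
    attachment: int,
    by_id: dict[int, Node],
    neurite_children,
    seen: set[int],
) -> Section:
    """Iteratively build the section tree hanging from ``first_id``."""
    root = Section(nodes=[], attachment=attachment)
    stack: list[tuple[int, Section]] = [(first_id, root)]
    while stack:
        cur, section = stack.pop()
        while True:
            seen.add(cur)
            section.nodes.append(by_id[cur])
            kids = neurite_children(cur)
            if len(kids) == 1:
                cur = kids[0]
                continue
            # child sections appear in the order their first nodes appear
            # in the input records
            pairs = []
            for kid in kids:
                child = Section(nodes=[], attachment=cur)
                section.children.append(child)
                pairs.append((kid, child))
            stack.extend(reversed(pairs))
            break
    return root


# ---------------------------------------------------------------------------
# selection semantics


def expand_selection(
    m: Morphology,
    picked: Iterable[int],
    scope: Scope,
    accumulate_with: Iterable[int] = (),
) -> set[int]:
    """Expand picked node ids to the requested scope.

    NODE returns the picked ids; SECTION the full node lists of every
    section containing a picked node; NEURITE all nodes of the containing
    neurites.  Soma nodes expand to themselves at every scope (the soma is
    not part of any neurite section).  The result is unioned with
    ``accumulate_with`` to support accumulative selections.
    """
    picked = set(picked)
    for i in picked:
        m.node(i)  # raises on unknown id
    out: set[int] = set(accumulate_with)
    if scope is Scope.NODE:
        out |= picked
        return out
    for i in picked:
        if scope is Scope.SECTION:
            sec = m.section_of(i)
            out.update(sec.node_ids if sec is not None else [i])
        else:
            neurite = m.neurite_of(i)
            if neurite is None:
                out.add(i)
            else:
                out.update(n.id for n in neurite.nodes())
    return out


# ---------------------------------------------------------------------------
# manual edits (pure: return a new morphology)


def set_mean_property(
    m: Morphology, ids: Iterable[int], prop: Property, target
) -> Morphology:
    """Set the mean radius or mean position of the selected nodes.

    Radii are scaled proportionally (each multiplied by ``target/mean``),
    preserving radius ratios.  Positions are rigidly translated so the
    selection centroid lands on ``target``.
    """
    ids = sorted(set(ids))
    if not ids:
        raise EditError("empty selection")
    out = m.copy()
    nodes = [out.node(i) for i in ids]
    if prop is Property.RADIUS:
        mean = float(np.mean([n.radius for n in nodes]))
        if mean <= 0.0:
            raise EditError("current mean radius is 0; proportional scaling undefined")
        scale = float(target) / mean
        for n in nodes:
            n.radius *= scale
    else:
        target = np.asarray(target, dtype=float)
        if target.shape != (3,):
            raise EditError("POSITION target must be a 3-vector")
        centroid = np.mean([n.position for n in nodes], axis=0)
        delta = target - centroid
        for n in nodes:
            n.position = n.position + delta
    return out


def rotate_selection(m: Morphology, ids: Iterable[int], angles_deg) -> Morphology:
    """Rigidly rotate the selected nodes about their centroid.

    ``angles_deg`` are three angles in degrees applied in intrinsic
    X -> Y -> Z order.  Disabled for single-node selections (a rotation of
    one point about its own centroid is meaningless).
    """
    ids = sorted(set(ids))
    if len(ids) < 2:
        raise EditError("rotation is disabled for single node selections")
    out = m.copy()
    nodes = [out.node(i) for i in ids]
    rot = Rotation.from_euler("XYZ", np.asarray(angles_deg, dtype=float), degrees=True)
    centroid = np.mean([n.position for n in nodes], axis=0)
    for n in nodes:
        n.position = centroid + rot.apply(n.position - centroid)
    return out
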