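"""Section resampling: polyline simplification and spline refinement.

Morphological sections are polylines, so resolution adjustment reduces to
classic polyline algorithms.  Seven simplifiers are provided (Nth point,
radial distance, perpendicular distance, Reumann-Witkam, Opheim, Lang,
Douglas-Peucker) plus the fixed-point-count Douglas-Peucker-N variant.
Every simplifier returns a *subsequence* of the input nodes, always
retaining the first and last node of each section, and never modifies the
kept nodes.

Refinement inserts nodes per segment until the requested point density
(points per micrometer) is reached: a segment of chord length ``L`` gets
``max(0, ceil(L * density) - 1)`` new points at equal parameter spacing,
either on the chord (linear) or on a cubic Hermite spline with
Catmull-Rom tangents (one-sided at section endpoints), which smooths the
trajectory.  Radii of inserted points are always interpolated linearly.

All thresholds use strict comparisons: a point exactly at the tolerance
is kept by the distance-based rules (dropped only when strictly closer
than the tolerance), and Douglas-Peucker keeps a point only while its
chord distance strictly exceeds the tolerance.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence, Union

import numpy as np

from .core_model import Morphology, Node, build_morphology

_INSERT_CAP = 10_000  # safety cap on inserted points per segment


class ResampleError(ValueError):
    pass


# ---------------------------------------------------------------------------
# parameter types


@dataclass(frozen=True)
class NthPoint:
    """Keep indices 0, n, 2n, ... plus the last point."""

    n: int

    def __post_init__(self):
        if self.n < 2:
            raise ResampleError("NthPoint requires n >= 2")


@dataclass(frozen=True)
class RadialDistance:
    """Drop successive points strictly closer than ``tol`` to the key."""

    tol: float

    def __post_init__(self):
        if self.tol < 0:
            raise ResampleError("tolerance must be >= 0")


@dataclass(frozen=True)
class PerpendicularDistance:
    """Drop a point strictly closer than ``tol`` to the line through its
    (original-sequence) neighbors; the follower of a dropped point is kept."""

    tol: float

    def __post_init__(self):
        if self.tol < 0:
            raise ResampleError("tolerance must be >= 0")


@dataclass(frozen=True)
class ReumannWitkam:
    """Drop points strictly within ``tol`` of the current chord line."""

    tol: float

    def __post_init__(self):
        if self.tol < 0:
            raise ResampleError("tolerance must be >= 0")


@dataclass(frozen=True)
class Opheim:
    """Radial min/max tolerances combined with a direction ray."""

    min_tol: float
    max_tol: float

    def __post_init__(self):
        if self.min_tol < 0 or self.max_tol < self.min_tol:
            raise ResampleError("need 0 <= min_tol <= max_tol")


@dataclass(frozen=True)
class Lang:
    """Look-ahead window with a perpendicular tolerance."""

    tol: float
    lookahead: int = 7

    def __post_init__(self):
        if self.tol < 0 or self.lookahead < 2:
            raise ResampleError("need tol >= 0 and lookahead >= 2")


@dataclass(frozen=True)
class DouglasPeucker:
    """Recursively keep the farthest-from-chord point while its distance
    strictly exceeds ``tol``."""

    tol: float

    def __post_init__(self):
        if self.tol < 0:
            raise ResampleError("tolerance must be >= 0")


@dataclass(frozen=True)
class DouglasPeuckerN:
    """Keep exactly ``count`` points by repeatedly adding the globally
    farthest-from-chord point (ties broken toward the smallest index)."""

    count: int

    def __post_init__(self):
        if self.count < 2:
            raise ResampleError("DouglasPeuckerN requires count >= 2")


SimplifyParams = Union[
    NthPoint,
    RadialDistance,
    PerpendicularDistance,
    ReumannWitkam,
    Opheim,
    Lang,
    DouglasPeucker,
    DouglasPeuckerN,
]


@dataclass(frozen=True)
class RefineParams:
    """``method`` is "linear" or "cubic_hermite"; density in points/um."""

    method: str = "linear"
    density: float = 0.5

    def __post_init__(self):
        if self.method not in ("linear", "cubic_hermite"):
            raise ResampleError(f"unknown refinement method {self.method!r}")
        if self.density < 0:
            raise ResampleError("density must be >= 0")


# ---------------------------------------------------------------------------
# geometry helpers


def _pt_segment_dist(p: np.ndarray, a: np.ndarray, b: np.ndarray) -> float:
    ab = b - a
    denom = float(ab @ ab)
    if denom < 1e-24:
        return float(np.linalg.norm(p - a))
    t = float(np.clip((p - a) @ ab / denom, 0.0, 1.0))
    return float(np.linalg.norm(p - (a + t * ab)))


def _pt_line_dist(p: np.ndarray, a: np.ndarray, b: np.ndarray) -> float:
    ab = b - a
    denom = float(np.linalg.norm(ab))
    if denom < 1e-12:
        return float(np.linalg.norm(p - a))
    return float(np.linalg.norm(np.cross(p - a, ab)) / denom)


# ---------------------------------------------------------------------------
# kept-index computation per method


def _idx_nth(pts: np.ndarray, p: NthPoint) -> list[int]:
    k = len(pts)
    return sorted(set(range(0, k, p.n)) | {k - 1})


def _idx_radial(pts: np.ndarray, p: RadialDistance) -> list[int]:
    k = len(pts)
    keep = [0]
    key = 0
    for i in range(1, k - 1):
        if np.linalg.norm(pts[i] - pts[key]) < p.tol:
            continue
        keep.append(i)
        key = i
    keep.append(k - 1)
    return sorted(set(keep))


def _idx_perpendicular(pts: np.ndarray, p: PerpendicularDistance) -> list[int]:
    k = len(pts)
    keep = [0]
    i = 1
    while i < k - 1:
        if _pt_line_dist(pts[i], pts[i - 1], pts[i + 1]) < p.tol:
            i += 2  # drop i; its follower is kept implicitly
        else:
            keep.append(i)
            i += 1
    keep.append(k - 1)
    return sorted(set(keep))


def _idx_reumann_witkam(pts: np.ndarray, p: ReumannWitkam) -> list[int]:
    k = len(pts)
    keep = [0]
    key = 0
    while key + 2 < k:
        a, b = pts[key], pts[key + 1]
        i = key + 2
        while i < k - 1 and _pt_line_dist(pts[i], a, b) < p.tol:
            i += 1
        if i >= k - 1:
            break
        keep.append(i)
        key = i
    keep.append(k - 1)
    return sorted(set(keep))


def _idx_opheim(pts: np.ndarray, p: Opheim) -> list[int]:
    k = len(pts)
    keep = [0]
    key = 0
    while key < k - 1:
        # ray from key through the first point at least min_tol away
        r = key + 1
        while r < k and np.linalg.norm(pts[r] - pts[key]) < p.min_tol:
            r += 1
        if r >= k - 1:
            break
        nxt = r
        i = r + 1
        while (
            i < k - 1
            and np.linalg.norm(pts[i] - pts[key]) < p.max_tol
            and _pt_line_dist(pts[i], pts[key], pts[r]) < p.min_tol
        ):
            nxt = i
            i += 1
        keep.append(nxt)
        key = nxt
    keep.append(k - 1)
    return sorted(set(keep))


def _idx_lang(pts: np.ndarray, p: Lang) -> list[int]:
    k = len(pts)
    keep = [0]
    key = 0
    while key < k - 1:
        end = min(key + p.lookahead, k - 1)
        while end > key + 1:
            dmax = max(
                _pt_segment_dist(pts[j], pts[key], pts[end]) for j in range(key + 1, end)
            )
            if dmax < p.tol:
                break
            end -= 1
        keep.append(end)
        key = end
    return sorted(set(keep))


def _idx_douglas_peucker(pts: np.ndarray, p: DouglasPeucker) -> list[int]:
    k = len(pts)
    keep = {0, k - 1}
    stack = [(0, k - 1)]
    while stack:
        a, b = stack.pop()
        if b - a < 2:
            continue
        dists = [_pt_segment_dist(pts[j], pts[a], pts[b]) for j in range(a + 1, b)]
        jrel = int(np.argmax(dists))
        if dists[jrel] > p.tol:
            j = a + 1 + jrel
            keep.add(j)
            stack.append((a, j))
            stack.append((j, b))
    return sorted(keep)


def _idx_douglas_peucker_n(pts: np.ndarray, p: DouglasPeuckerN) -> list[int]:
    k = len(pts)
    if p.count >= k:
        return list(range(k))
    keep = [0, k - 1]
    while len(keep) < p.count:
        best = None  # (distance, index)
        for a, b in zip(keep, keep[1:]):
            for j in range(a + 1, b):
                d = _pt_segment_dist(pts[j], pts[a], pts[b])
                if best is None or d > best[0]:
                    best = (d, j)
        if best is None:
            break  # no interior points left
        keep = sorted(keep + [best[1]])
    return keep


_DISPATCH = {
    NthPoint: _idx_nth,
    RadialDistance: _idx_radial,
    PerpendicularDistance: _idx_perpendicular,
    ReumannWitkam: _idx_reumann_witkam,
    Opheim: _idx_opheim,
    Lang: _idx_lang,
    DouglasPeucker: _idx_douglas_peucker,
    DouglasPeuckerN: _idx_douglas_peucker_n,
}


def simplify_indices(points: np.ndarray, params: SimplifyParams) -> list[int]:
    """Kept indices (sorted, includes 0 and last) for a polyline."""
    points = np.asarray(points, dtype=float)
    if len(points) < 2:
        return list(range(len(points)))
    return _DISPATCH[type(params)](points, params)


def simplify_section(nodes: Sequence[Node], params: SimplifyParams) -> list[Node]:
    """Simplify one section's node list; kept nodes are returned unmodified.

    Sections with fewer than 2 nodes are returned unchanged (warning).
    """
    if len(nodes) < 2:
        warnings.warn("section with < 2 nodes cannot be simplified", stacklevel=2)
        return list(nodes)
    pts = np.array([n.position for n in nodes])
    return [nodes[i] for i in simplify_indices(pts, params)]


# ---------------------------------------------------------------------------
# refinement


def _hermite_tangents(pts: np.ndarray) -> np.ndarray:
    """Catmull-Rom tangents; one-sided differences at the endpoints."""
    m = np.empty_like(pts)
    m[0] = pts[1] - pts[0]
    m[-1] = pts[-1] - pts[-2]
    if len(pts) > 2:
        m[1:-1] = 0.5 * (pts[2:] - pts[:-2])
    return m


def refine_section(
    nodes: Sequence[Node], params: RefineParams, next_id: int | None = None
) -> list[Node]:
    """Insert nodes per segment until the point density is reached.

    All original nodes are kept unmodified; inserted nodes get fresh ids
    (starting at ``next_id``, default max section id + 1) and linearly
    interpolated radii.  ``density = 0`` returns the input.
    """
    if len(nodes) < 2:
        warnings.warn("section with < 2 nodes cannot be refined", stacklevel=2)
        return list(nodes)
    if params.density == 0:
        return list(nodes)
    pts = np.array([n.position for n in nodes])
    if next_id is None:
        next_id = max(n.id for n in nodes) + 1
    ids = itertools.count(next_id)
    tangents = _hermite_tangents(pts) if params.method == "cubic_hermite" else None

    out: list[Node] = [nodes[0]]
    for s in range(len(nodes) - 1):
        a, b = nodes[s], nodes[s + 1]
        L = float(np.linalg.norm(pts[s + 1] - pts[s]))
        n_insert = max(0, math.ceil(L * params.density) - 1)
        if n_insert > _INSERT_CAP:
            raise ResampleError(
                f"density {params.density} would insert {n_insert} points in one "
                f"segment (cap {_INSERT_CAP})"
            )
        for j in range(1, n_insert + 1):
            t = j / (n_insert + 1)
            if tangents is None:
                pos = (1 - t) * pts[s] + t * pts[s + 1]
            else:
                h00 = 2 * t**3 - 3 * t**2 + 1
                h10 = t**3 - 2 * t**2 + t
                h01 = -2 * t**3 + 3 * t**2
                h11 = t**3 - t**2
                pos = h00 * pts[s] + h10 * tangents[s] + h01 * pts[s + 1] + h11 * tangents[s + 1]
            radius = (1 - t) * a.radius + t * b.radius
            out.append(Node(next(ids), b.type_code, pos, radius, parent_id=out[-1].id))
        out.append(b)
    return out


# ---------------------------------------------------------------------------
# whole-morphology application


def resample_morphology(
    m: Morphology,
    params: SimplifyParams | RefineParams,
    selection: Iterable[int] | None = None,
) -> Morphology:
    """Apply a simplifier or refinement to the selected sections.

    A section is processed when any of its nodes is in ``selection``; a
    ``None`` (or empty) selection processes the whole tracing.  Untouched
    sections are preserved as-is.  Soma points are never resampled:
    sections are neurite-only by construction.
    """
    selected = set(selection) if selection else None
    refine = isinstance(params, RefineParams)
    next_id = max((n.id for n in m.nodes()), default=0) + 1

    new_records: list[Node] = [n.copy() for n in m.soma.nodes]
    for neurite in m.neurites:
        for sec in neurite.sections():
            touched = selected is None or (set(sec.node_ids) & selected)
            if touched and len(sec.nodes) >= 2:
                if refine:
                    chain = refine_section(sec.nodes, params, next_id=next_id)
                    next_id = max(next_id, max(n.id for n in chain) + 1)
                else:
                    chain = simplify_section(sec.nodes, params)
            else:
                chain = list(sec.nodes)
            chain = [n.copy() for n in chain]
            chain[0].parent_id = sec.nodes[0].parent_id
            for prev, cur in zip(chain, chain[1:]):
                cur.parent_id = prev.id
            new_records.extend(chain)
    return build_morphology(new_records, provenance=m.provenance)
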