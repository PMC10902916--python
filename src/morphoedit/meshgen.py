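"""Approximate membrane mesh: soma sphere plus per-section tubes.

The soma is rendered as a subdivided icosahedral sphere at the derived
soma bounding sphere.  Each neurite section becomes a generalized
cylinder: one ring of vertices per node (ring radius = node radius),
oriented by parallel-transport frames propagated along the section so the
tube does not twist, with consecutive rings stitched by triangles and the
open ends closed by triangle fans.  Child-section tubes start with an
extra ring at their attachment (bifurcation) node, so branch joins
overlap instead of leaving gaps; no blending surface is attempted.

This is a deliberately simple, deterministic approximation of the
membrane — sufficient for visual inspection and for propagating tracing
edits straight into a surface — not a watertight multi-branch mesh.
"""

from __future__ import annotations

from dataclasses import dataclass
from os import PathLike
from typing import TextIO

import numpy as np
import trimesh

from .core_model import Morphology, soma_sphere


class MeshError(ValueError):
    pass


@dataclass
class MeshParams:
    ring_sides: int = 16
    soma_subdivisions: int = 2
    cap_ends: bool = True

    def __post_init__(self) -> None:
        if self.ring_sides < 3:
            raise MeshError("ring_sides must be >= 3")
        if self.soma_subdivisions < 0:
            raise MeshError("soma_subdivisions must be >= 0")


@dataclass
class TriangleMesh:
    """Vertices (um) and 0-based triangular faces."""

    vertices: np.ndarray
    faces: np.ndarray

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=int).reshape(-1, 3)

    def validate(self) -> None:
        if len(self.vertices) == 0 or len(self.faces) == 0:
            raise MeshError("empty mesh")
        if not np.all(np.isfinite(self.vertices)):
            raise MeshError("non-finite vertex coordinate")
        if self.faces.min(initial=0) < 0 or self.faces.max(initial=-1) >= len(self.vertices):
            raise MeshError("face index out of range")


def _initial_normal(d: np.ndarray) -> np.ndarray:
    """Deterministic unit vector orthogonal to d: seed with the coordinate
    axis of d's smallest-magnitude component."""
    axis = np.zeros(3)
    axis[int(np.argmin(np.abs(d)))] = 1.0
    n = axis - (axis @ d) * d
    return n / np.linalg.norm(n)


def _transport(n: np.ndarray, d_prev: np.ndarray, d_next: np.ndarray) -> np.ndarray:
    """Rotate normal n by the rotation taking d_prev to d_next."""
    axis = np.cross(d_prev, d_next)
    s = np.linalg.norm(axis)
    c = float(d_prev @ d_next)
    if s < 1e-12:
        return n  # parallel (or degenerate): keep the frame
    axis = axis / s
    angle = np.arctan2(s, c)
    ca, sa = np.cos(angle), np.sin(angle)
    n2 = n * ca + np.cross(axis, n) * sa + axis * (axis @ n) * (1 - ca)
    # re-orthogonalize against drift
    n2 = n2 - (n2 @ d_next) * d_next
    return n2 / np.linalg.norm(n2)


def tube_mesh(
    points: np.ndarray,
    radii: np.ndarray,
    ring_sides: int = 16,
    cap_ends: bool = True,
) -> TriangleMesh:
    """Generalized cylinder along a polyline with per-point radii.

    One ring of ``ring_sides`` vertices per point, parallel-transported
    frames, 2 * ring_sides side triangles per segment, and (optionally)
    fan caps with an apex vertex at each end point.  Faces wind outward.
    """
    points = np.asarray(points, dtype=float).reshape(-1, 3)
    radii = np.asarray(radii, dtype=float).reshape(-1)
    if len(points) < 2:
        raise MeshError("a tube needs at least 2 points")
    if np.any(radii <= 0):
        raise MeshError("tube radii must be > 0")
    seg = np.diff(points, axis=0)
    seg_len = np.linalg.norm(seg, axis=1)
    if np.any(seg_len < 1e-12):
        raise MeshError("zero-length tube segment")
    dirs = seg / seg_len[:, None]

    # per-point direction: average of adjacent segment directions
    node_dirs = np.empty_like(points)
    node_dirs[0] = dirs[0]
    node_dirs[-1] = dirs[-1]
    for i in range(1, len(points) - 1):
        v = dirs[i - 1] + dirs[i]
        n = np.linalg.norm(v)
        node_dirs[i] = v / n if n > 1e-12 else dirs[i]

    normal = _initial_normal(node_dirs[0])
    theta = 2 * np.pi * np.arange(ring_sides) / ring_sides
    verts: list[np.ndarray] = []
    for i in range(len(points)):
        if i > 0:
            normal = _transport(normal, node_dirs[i - 1], node_dirs[i])
        binormal = np.cross(node_dirs[i], normal)
        ring = (
            points[i]
            + radii[i] * (np.outer(np.cos(theta), normal) + np.outer(np.sin(theta), binormal))
        )
        verts.append(ring)
    vertices = np.vstack(verts)
    faces: list[tuple[int, int, int]] = []
    s = ring_sides
    for i in range(len(points) - 1):
        a, b = i * s, (i + 1) * s
        for j in range(s):
            j2 = (j + 1) % s
            faces.append((a + j, b + j2, b + j))
            faces.append((a + j, a + j2, b + j2))
    if cap_ends:
        start_apex = len(vertices)
        end_apex = start_apex + 1
        vertices = np.vstack([vertices, points[0], points[-1]])
        last = (len(points) - 1) * s
        for j in range(s):
            j2 = (j + 1) % s
            faces.append((start_apex, j2, j))
            faces.append((end_apex, last + j, last + j2))
    return TriangleMesh(vertices, np.array(faces, dtype=int))


def soma_mesh(m: Morphology, subdivisions: int = 2) -> TriangleMesh:
    """Icosahedral sphere at the derived soma bounding sphere."""
    center, radius = soma_sphere(m.soma)
    ico = trimesh.creation.icosphere(subdivisions=subdivisions, radius=1.0)
    return TriangleMesh(np.asarray(ico.vertices) * radius + center, np.asarray(ico.faces))


def neuron_mesh(m: Morphology, params: MeshParams | None = None) -> TriangleMesh:
    """Membrane approximation for a whole morphology.

    Deterministic for fixed input.  Raises :class:`MeshError` on an empty
    morphology or on any non-positive node radius (naming the node).
    """
    params = params or MeshParams()
    if not m.soma.nodes and not m.neurites:
        raise MeshError("empty morphology")
    for n in m.neurite_nodes():
        if n.radius <= 0:
            raise MeshError(f"node {n.id} has non-positive radius {n.radius}")
    parts: list[TriangleMesh] = []
    if m.soma.nodes:
        parts.append(soma_mesh(m, params.soma_subdivisions))
    for neurite in m.neurites:
        for sec in neurite.sections():
            nodes = list(sec.nodes)
            pts = [n.position for n in nodes]
            rad = [n.radius for n in nodes]
            att = m.section_of(sec.attachment) if sec.attachment != -1 else None
            if att is not None:
                # start the tube at the bifurcation node so joins overlap
                b = m.node(sec.attachment)
                pts = [b.position] + pts
                rad = [b.radius] + rad
            if len(pts) < 2:
                continue  # single-node root section: covered by the soma ball
            parts.append(tube_mesh(np.array(pts), np.array(rad), params.ring_sides, params.cap_ends))
    if not parts:
        raise MeshError("morphology produced no mesh parts")
    offsets = np.cumsum([0] + [len(p.vertices) for p in parts[:-1]])
    vertices = np.vstack([p.vertices for p in parts])
    faces = np.vstack([p.faces + off for p, off in zip(parts, offsets)])
    mesh = TriangleMesh(vertices, faces)
    mesh.validate()
    return mesh


# ---------------------------------------------------------------------------
# OBJ I/O (v/f records only)


def write_obj(mesh: TriangleMesh, dest: str | PathLike | TextIO) -> None:
    """Write Wavefront OBJ: ``v x y z`` then ``f i j k`` (1-based),
    coordinates with 6 decimals.  Validates the mesh before any output."""
    mesh.validate()
    if hasattr(dest, "write"):
        _write_obj_stream(mesh, dest)
        return
    with open(dest, "w", encoding="utf-8") as fh:
        _write_obj_stream(mesh, fh)


def _write_obj_stream(mesh: TriangleMesh, stream: TextIO) -> None:
    for x, y, z in mesh.vertices:
        stream.write(f"v {x:.6f} {y:.6f} {z:.6f}\n")
    for i, j, k in mesh.faces + 1:
        stream.write(f"f {i} {j} {k}\n")


def read_obj(source: str | PathLike | TextIO) -> TriangleMesh:
    """Parse an OBJ file (v/f triangle records; comments skipped)."""
    if hasattr(source, "read"):
        lines = source.read().splitlines()
    else:
        with open(source, "r", encoding="utf-8") as fh:
            lines = fh.read().splitlines()
    verts: list[list[float]] = []
    faces: list[list[int]] = []
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        if fields[0] == "v" and len(fields) == 4:
            verts.append([float(f) for f in fields[1:]])
        elif fields[0] == "f" and len(fields) == 4:
            faces.append([int(f.split("/")[0]) - 1 for f in fields[1:]])
        else:
            raise MeshError(f"line {lineno}: unsupported OBJ record {fields[0]!r}")
    mesh = TriangleMesh(np.array(verts, dtype=float), np.array(faces, dtype=int))
    mesh.validate()
    return mesh
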