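"""Reading and writing SWC files (CNIC 7-column dialect).

Dialect: 1-based integer ids, ``-1`` parent for roots, ``#`` comments,
whitespace-separated columns ``id type x y z radius parent``.  The writer
renumbers nodes contiguously 1..N in depth-first order (soma first,
parents before children) and formats coordinates and radii with 6 decimal
places, so a second write of a re-read file is byte-identical.

The soma is always written as the raw point set that was read (1-point,
3-point or contour) — never replaced by the derived bounding sphere, which
is an internal approximation only.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from os import PathLike
from typing import TextIO

from .core_model import ROOT, Morphology, Node, StructuralError, build_morphology


class SWCError(ValueError):
    """A malformed SWC file; carries the offending 1-based line number."""

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


@dataclass
class ParseReport:
    """What the reader saw: warnings are never silently dropped."""

    warnings: list[tuple[int, str]] = field(default_factory=list)
    n_nodes: int = 0
    n_comments: int = 0


def read_swc(source: str | PathLike | TextIO) -> tuple[Morphology, ParseReport]:
    """Parse an SWC file or text stream into a morphology.

    Comment (``#``) and blank lines are skipped.  Zero or negative radii
    are accepted with a warning (meshing later requires positive radii).
    Malformed lines, duplicate ids, unknown parents and cycles raise
    :class:`SWCError` naming the line.
    """
    if hasattr(source, "read"):
        return _read_stream(source)
    with open(source, "r", encoding="utf-8") as fh:
        return _read_stream(fh)


def _read_stream(stream: TextIO) -> tuple[Morphology, ParseReport]:
    report = ParseReport()
    records: list[Node] = []
    line_of: dict[int, int] = {}
    seen_ids: set[int] = set()
    comments: list[str] = []
    for lineno, raw in enumerate(stream, start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            report.n_comments += 1
            comments.append(line.lstrip("#").strip())
            continue
        fields = line.split()
        if len(fields) != 7:
            raise SWCError(f"expected 7 fields, found {len(fields)}", lineno)
        try:
            nid = int(fields[0])
            type_code = int(fields[1])
            x, y, z, radius = (float(f) for f in fields[2:6])
            parent = int(fields[6])
        except ValueError:
            raise SWCError(f"non-numeric field in {fields!r}", lineno) from None
        if nid in seen_ids:
            raise SWCError(f"duplicate node id {nid}", lineno)
        seen_ids.add(nid)
        line_of[nid] = lineno
        if radius <= 0.0:
            report.warnings.append((lineno, f"node {nid}: non-positive radius {radius}"))
        records.append(Node(nid, type_code, (x, y, z), radius, parent))
    if not records:
        raise SWCError("no data lines in SWC input")
    report.n_nodes = len(records)
    try:
        morph = build_morphology(records, provenance="\n".join(comments))
    except StructuralError as exc:
        raise SWCError(str(exc), line_of.get(exc.node_id)) from exc
    return morph, report


def write_swc(m: Morphology, dest: str | PathLike | TextIO) -> None:
    """Write a morphology as SWC.

    Nodes are renumbered contiguously 1..N in depth-first topological
    order: soma points first (input order, parent links preserved), then
    each neurite pre-order.  A ``#`` provenance header is emitted.
    """
    if hasattr(dest, "write"):
        _write_stream(m, dest)
        return
    with open(dest, "w", encoding="utf-8") as fh:
        _write_stream(m, fh)


def _write_stream(m: Morphology, stream: TextIO) -> None:
    # the comment header round-trips: the reader recovers it as provenance
    provenance = m.provenance or "morphoedit SWC export"
    for line in provenance.splitlines():
        stream.write(f"# {line}\n")
    remap: dict[int, int] = {}
    ordered = list(m.nodes())  # soma first, then neurites pre-order
    for new_id, node in enumerate(ordered, start=1):
        remap[node.id] = new_id
    for node in ordered:
        parent = ROOT if node.parent_id == ROOT else remap[node.parent_id]
        x, y, z = node.position
        stream.write(
            f"{remap[node.id]} {node.type_code} "
            f"{x:.6f} {y:.6f} {z:.6f} {node.radius:.6f} {parent}\n"
        )


def dumps(m: Morphology) -> str:
    """The SWC text of a morphology (convenience wrapper over write_swc)."""
    buf = io.StringIO()
    write_swc(m, buf)
    return buf.getvalue()


def loads(text: str) -> tuple[Morphology, ParseReport]:
    """Parse SWC text (convenience wrapper over read_swc)."""
    return read_swc(io.StringIO(text))
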