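"""Binary and ASCII STL writing/reading, byte-exact.

Binary layout: 80-byte header (never starting with "solid"), 4-byte
little-endian facet count, then 50 bytes per facet (12 float32 + 2-byte
attribute count, always 0).  File size is exactly ``84 + 50 * n``.

Units: STL is unitless; files written here use 1 STL unit = 1 mm, the
slicer-world convention.  Stored normals are recomputed from vertex
winding at write time rather than trusted from upstream.
"""

from __future__ import annotations

import re
import struct
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import StlFormatError
from .solid_mesh import TriangleMesh, validate_watertight

__all__ = ["StlDocument", "write_stl", "read_stl", "write_document"]

_TOOL_TAG = "tactilemesh 1.0.0"
_FACET_DTYPE = np.dtype(
    [("normal", "<f4", (3,)), ("vectors", "<f4", (3, 3)), ("attr", "<u2")]
)


@dataclass(frozen=True)
class StlDocument:
    """Facet soup as stored in a file: float32 normals and vertices."""

    header: bytes  # exactly 80 bytes for binary provenance; name for ASCII
    normals: np.ndarray = field(repr=False)  # (n, 3) float32
    vectors: np.ndarray = field(repr=False)  # (n, 3, 3) float32

    @property
    def n_facets(self) -> int:
        return len(self.normals)


def _mesh_to_document(mesh: TriangleMesh, header_text: str) -> StlDocument:
    vectors = mesh.vertices[mesh.triangles].astype("<f4")
    # Normals from the float32-rounded vertices so stored and recomputed
    # normals agree on read-back.
    v64 = vectors.astype(np.float64)
    n = np.cross(v64[:, 1] - v64[:, 0], v64[:, 2] - v64[:, 0])
    length = np.linalg.norm(n, axis=1, keepdims=True)
    length[length == 0] = 1.0
    normals = (n / length).astype("<f4")
    header = header_text.encode("ascii", "replace")[:80].ljust(80, b"\0")
    if header.startswith(b"solid"):
        raise StlFormatError("binary STL header must not start with 'solid'")
    return StlDocument(header, normals, vectors)


def write_stl(
    mesh: TriangleMesh,
    path,
    dialect: str = "binary",
    name: str = "tactilemesh_model",
    validate: bool = True,
) -> Path:
    """Write ``mesh`` as STL; refuses non-manifold meshes when ``validate``."""
    if dialect not in ("binary", "ascii"):
        raise StlFormatError(f"unknown STL dialect: {dialect!r}")
    if validate:
        report = validate_watertight(mesh)
        if not report.is_watertight:
            raise StlFormatError(f"refusing to write non-manifold mesh: {report.summary()}")
    doc = _mesh_to_document(mesh, f"{_TOOL_TAG} {name}")
    return write_document(doc, path, dialect=dialect, name=name)


def write_document(
    doc: StlDocument, path, dialect: str = "binary", name: str = "tactilemesh_model"
) -> Path:
    """Write an :class:`StlDocument` verbatim (used for byte-exact round trips)."""
    p = Path(path)
    if dialect == "binary":
        rec = np.zeros(doc.n_facets, dtype=_FACET_DTYPE)
        rec["normal"] = doc.normals
        rec["vectors"] = doc.vectors
        payload = doc.header[:80].ljust(80, b"\0") + struct.pack(
            "<I", doc.n_facets
        ) + rec.tobytes()
        p.write_bytes(payload)
    elif dialect == "ascii":
        lines = [f"solid {name}"]
        for nrm, tri in zip(doc.normals, doc.vectors):
            lines.append(f"  facet normal {_fmt(nrm[0])} {_fmt(nrm[1])} {_fmt(nrm[2])}")
            lines.append("    outer loop")
            for v in tri:
                lines.append(f"      vertex {_fmt(v[0])} {_fmt(v[1])} {_fmt(v[2])}")
            lines.append("    endloop")
            lines.append("  endfacet")
        lines.append(f"endsolid {name}")
        p.write_text("\n".join(lines) + "\n")
    else:
        raise StlFormatError(f"unknown STL dialect: {dialect!r}")
    return p


def _fmt(x: float) -> str:
    """6-significant-digit scientific notation."""
    return f"{float(x):.5e}"


def read_stl(path) -> StlDocument:
    """Read an STL file, auto-detecting the dialect.

    Binary is assumed when the file size matches ``84 + 50 * count`` for
    the declared facet count; otherwise the file must parse as ASCII.
    """
    p = Path(path)
    data = p.read_bytes()
    if len(data) >= 84:
        (count,) = struct.unpack_from("<I", data, 80)
        expected = 84 + 50 * count
        if len(data) == expected:
            rec = np.frombuffer(data[84:], dtype=_FACET_DTYPE)
            return StlDocument(data[:80], rec["normal"].copy(), rec["vectors"].copy())
        if not data.lstrip()[:5] == b"solid":
            raise StlFormatError(
                f"corrupt STL: declared {count} facet(s) imply {expected} bytes, "
                f"file has {len(data)}"
            )
    if data.lstrip()[:5] == b"solid":
        return _parse_ascii(p, data)
    raise StlFormatError(f"corrupt STL: {p} is neither valid binary nor ASCII")


_VERTEX_RE = re.compile(r"^vertex\s+(\S+)\s+(\S+)\s+(\S+)$")
_NORMAL_RE = re.compile(r"^facet\s+normal\s+(\S+)\s+(\S+)\s+(\S+)$")


def _parse_ascii(path: Path, data: bytes) -> StlDocument:
    try:
        text = data.decode("ascii")
    except UnicodeDecodeError as exc:
        raise StlFormatError(f"corrupt STL: {path} is not ASCII ({exc})") from exc

    normals: list[list[float]] = []
    facets: list[list[list[float]]] = []
    current: list[list[float]] | None = None
    name = ""
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("solid"):
            name = line[5:].strip()
        elif line.startswith("facet normal"):
            m = _NORMAL_RE.match(line)
            if not m:
                raise StlFormatError(f"ASCII STL parse failure at line {lineno}: {raw!r}")
            normals.append([_f32(m.group(i), lineno) for i in (1, 2, 3)])
            current = []
        elif line.startswith("vertex"):
            m = _VERTEX_RE.match(line)
            if not m or current is None:
                raise StlFormatError(f"ASCII STL parse failure at line {lineno}: {raw!r}")
            current.append([_f32(m.group(i), lineno) for i in (1, 2, 3)])
        elif line.startswith("endfacet"):
            if current is None or len(current) != 3:
                raise StlFormatError(
                    f"ASCII STL parse failure at line {lineno}: facet without 3 vertices"
                )
            facets.append(current)
            current = None
        elif line.startswith(("outer loop", "endloop", "endsolid")):
            continue
        else:
            raise StlFormatError(f"ASCII STL parse failure at line {lineno}: {raw!r}")

    header = f"{_TOOL_TAG} {name}".encode("ascii", "replace")[:80].ljust(80, b"\0")
    return StlDocument(
        header,
        np.asarray(normals, dtype="<f4").reshape(-1, 3),
        np.asarray(facets, dtype="<f4").reshape(-1, 3, 3),
    )


def _f32(token: str, lineno: int) -> float:
    try:
        return float(np.float32(token))
    except ValueError as exc:
        raise StlFormatError(
            f"ASCII STL parse failure at line {lineno}: bad number {token!r}"
        ) from exc
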