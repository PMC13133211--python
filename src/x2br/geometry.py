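"""Triangle-mesh container, validity checks, and PLY/OBJ input/output.

The :class:`TriMesh` is the currency passed between every pipeline stage:
phantom generation, occupancy sampling, projection rendering, isosurface
extraction, registration, and metric evaluation.  It deliberately stores
nothing but vertices and faces; derived quantities (normals, volume,
adjacency) are computed on demand and cached where cheap.
"""

from __future__ import annotations

import json
import struct
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "TriMesh",
    "PartLabeledMesh",
    "MeshError",
    "load_mesh",
    "save_mesh",
    "load_part_labels",
    "save_part_labels",
]


class MeshError(ValueError):
    """Raised for invalid or degenerate mesh input."""


class TriMesh:
    """Triangle surface mesh with float64 vertices and int64 face indices.

    Parameters
    ----------
    vertices : (n, 3) array_like
        Vertex coordinates.
    faces : (m, 3) array_like
        Vertex-index triples, counter-clockwise when viewed from outside.
    """

    def __init__(self, vertices, faces):
        self.vertices = np.ascontiguousarray(vertices, dtype=np.float64)
        self.faces = np.ascontiguousarray(faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise MeshError(f"vertices must be (n, 3), got {self.vertices.shape}")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise MeshError(f"faces must be (m, 3), got {self.faces.shape}")
        if len(self.faces) and self.faces.max() >= len(self.vertices):
            raise MeshError("face index out of range")

    # ------------------------------------------------------------------
    # basic quantities
    # ------------------------------------------------------------------
    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    @property
    def is_empty(self) -> bool:
        return len(self.faces) == 0

    def triangles(self) -> np.ndarray:
        """(m, 3, 3) array of face corner coordinates."""
        return self.vertices[self.faces]

    def bounds(self) -> np.ndarray:
        """(2, 3) array [min; max] of the axis-aligned bounding box."""
        if len(self.vertices) == 0:
            raise MeshError("empty mesh has no bounds")
        return np.vstack([self.vertices.min(axis=0), self.vertices.max(axis=0)])

    def extents(self) -> np.ndarray:
        b = self.bounds()
        return b[1] - b[0]

    def bbox_diagonal(self) -> float:
        return float(np.linalg.norm(self.extents()))

    def face_normals(self, normalize: bool = True) -> np.ndarray:
        t = self.triangles()
        n = np.cross(t[:, 1] - t[:, 0], t[:, 2] - t[:, 0])
        if normalize:
            norm = np.linalg.norm(n, axis=1, keepdims=True)
            norm[norm == 0] = 1.0
            n = n / norm
        return n

    def face_areas(self) -> np.ndarray:
        t = self.triangles()
        return 0.5 * np.linalg.norm(
            np.cross(t[:, 1] - t[:, 0], t[:, 2] - t[:, 0]), axis=1
        )

    def area(self) -> float:
        return float(self.face_areas().sum())

    def vertex_normals(self) -> np.ndarray:
        """Area-weighted average of incident face normals, unit length."""
        fn = self.face_normals(normalize=False)  # area-weighted
        vn = np.zeros_like(self.vertices)
        for k in range(3):
            np.add.at(vn, self.faces[:, k], fn)
        norm = np.linalg.norm(vn, axis=1, keepdims=True)
        norm[norm == 0] = 1.0
        return vn / norm

    def mean_edge_length(self) -> float:
        e = self.edges_unique()
        d = np.linalg.norm(self.vertices[e[:, 0]] - self.vertices[e[:, 1]], axis=1)
        return float(d.mean())

    def signed_volume(self) -> float:
        """Volume by the divergence theorem; positive for outward orientation."""
        t = self.triangles()
        return float(np.einsum("ij,ij->i", t[:, 0], np.cross(t[:, 1], t[:, 2])).sum() / 6.0)

    def volume(self) -> float:
        return abs(self.signed_volume())

    def centroid(self) -> np.ndarray:
        """Volume centroid (assumes closed mesh)."""
        t = self.triangles()
        det = np.einsum("ij,ij->i", t[:, 0], np.cross(t[:, 1], t[:, 2]))
        c = t.sum(axis=1) / 4.0
        vol6 = det.sum()
        if abs(vol6) < 1e-300:
            return self.vertices.mean(axis=0)
        return (c * det[:, None]).sum(axis=0) / vol6

    # ------------------------------------------------------------------
    # topology
    # ------------------------------------------------------------------
    def edges(self) -> np.ndarray:
        """(3m, 2) directed edges in face order."""
        f = self.faces
        return np.concatenate([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]])

    def edges_unique(self) -> np.ndarray:
        e = np.sort(self.edges(), axis=1)
        return np.unique(e, axis=0)

    def euler_characteristic(self) -> int:
        return self.n_vertices - len(self.edges_unique()) + self.n_faces

    def is_watertight(self) -> bool:
        """Every undirected edge used by exactly two faces, once per direction."""
        return len(self.open_edges()) == 0 and self._edge_use_ok()

    def _edge_use_ok(self) -> bool:
        e = np.sort(self.edges(), axis=1)
        _, counts = np.unique(e, axis=0, return_counts=True)
        return bool(np.all(counts == 2))

    def open_edges(self) -> np.ndarray:
        """Undirected edges not shared by exactly one forward+one reverse face."""
        e = self.edges()
        # encode directed edges; an interior edge appears once in each direction
        n = self.n_vertices
        code = e[:, 0] * n + e[:, 1]
        rev = e[:, 1] * n + e[:, 0]
        unmatched = ~np.isin(code, rev)
        return e[unmatched]

    def is_oriented_outward(self) -> bool:
        return self.signed_volume() > 0

    def has_degenerate_faces(self, tol: float = 1e-14) -> bool:
        return bool(np.any(self.face_areas() <= tol))

    def validate(self) -> None:
        """Raise :class:`MeshError` unless watertight, outward, non-degenerate."""
        if not self.is_watertight():
            n_open = len(self.open_edges())
            raise MeshError(f"mesh is not watertight ({n_open} unmatched directed edges)")
        if not self.is_oriented_outward():
            raise MeshError("mesh faces are not consistently oriented outward")
        if self.has_degenerate_faces():
            raise MeshError("mesh contains zero-area faces")

    # ------------------------------------------------------------------
    # transforms / composition
    # ------------------------------------------------------------------
    def copy(self) -> "TriMesh":
        return TriMesh(self.vertices.copy(), self.faces.copy())

    def translated(self, offset) -> "TriMesh":
        return TriMesh(self.vertices + np.asarray(offset, dtype=float), self.faces)

    def scaled(self, factor: float) -> "TriMesh":
        return TriMesh(self.vertices * float(factor), self.faces)

    def transformed(self, rotation=None, translation=None, scale: float = 1.0) -> "TriMesh":
        v = self.vertices * float(scale)
        if rotation is not None:
            v = v @ np.asarray(rotation, dtype=float).T
        if translation is not None:
            v = v + np.asarray(translation, dtype=float)
        return TriMesh(v, self.faces)

    def flipped(self) -> "TriMesh":
        return TriMesh(self.vertices, self.faces[:, ::-1])

    @staticmethod
    def concatenate(meshes: list["TriMesh"]) -> "TriMesh":
        """Disjoint union; face indices are offset per component."""
        vs, fs, off = [], [], 0
        for m in meshes:
            vs.append(m.vertices)
            fs.append(m.faces + off)
            off += m.n_vertices
        return TriMesh(np.concatenate(vs), np.concatenate(fs))

    def __repr__(self) -> str:  # pragma: no cover
        return f"TriMesh(n_vertices={self.n_vertices}, n_faces={self.n_faces})"


@dataclass
class PartLabeledMesh:
    """A mesh whose faces are partitioned into named parts.

    ``part_of_face`` holds one part name per face.  Each part's sub-mesh is
    expected to be watertight on its own (parts are disjoint components).
    """

    mesh: TriMesh
    part_of_face: np.ndarray  # (m,) array of str

    def __post_init__(self):
        self.part_of_face = np.asarray(self.part_of_face)
        if len(self.part_of_face) != self.mesh.n_faces:
            raise MeshError("part_of_face length must equal face count")

    @property
    def part_names(self) -> list[str]:
        seen: dict[str, None] = {}
        for p in self.part_of_face:
            seen.setdefault(str(p), None)
        return list(seen)

    def submesh(self, part: str) -> TriMesh:
        """Watertight sub-mesh of one part, with vertices re-indexed."""
        mask = self.part_of_face == part
        if not mask.any():
            raise MeshError(f"unknown part {part!r}")
        faces = self.mesh.faces[mask]
        used = np.unique(faces)
        remap = np.full(self.mesh.n_vertices, -1, dtype=np.int64)
        remap[used] = np.arange(len(used))
        return TriMesh(self.mesh.vertices[used], remap[faces])

    def select(self, parts: list[str]) -> "PartLabeledMesh":
        """Sub-mesh containing exactly the named parts, labels preserved."""
        if not parts:
            raise MeshError("empty part selection")
        for p in parts:
            if p not in self.part_names:
                raise MeshError(f"unknown part {p!r}")
        mask = np.isin(self.part_of_face, list(parts))
        faces = self.mesh.faces[mask]
        used = np.unique(faces)
        remap = np.full(self.mesh.n_vertices, -1, dtype=np.int64)
        remap[used] = np.arange(len(used))
        return PartLabeledMesh(
            TriMesh(self.mesh.vertices[used], remap[faces]),
            self.part_of_face[mask].copy(),
        )


# ----------------------------------------------------------------------
# I/O: PLY (binary little-endian or ascii) and OBJ
# ----------------------------------------------------------------------

def save_mesh(mesh: TriMesh, path, binary: bool = True) -> None:
    """Write PLY (``.ply``, binary little-endian by default) or OBJ (``.obj``)."""
    path = Path(path)
    if path.suffix.lower() == ".obj":
        _save_obj(mesh, path)
    elif path.suffix.lower() == ".ply":
        _save_ply(mesh, path, binary=binary)
    else:
        raise MeshError(f"unsupported mesh format {path.suffix!r}")


def load_mesh(path) -> TriMesh:
    path = Path(path)
    if path.suffix.lower() == ".obj":
        return _load_obj(path)
    if path.suffix.lower() == ".ply":
        return _load_ply(path)
    raise MeshError(f"unsupported mesh format {path.suffix!r}")


def _save_obj(mesh: TriMesh, path: Path) -> None:
    with open(path, "w") as fh:
        for v in mesh.vertices:
            fh.write(f"v {v[0]:.9g} {v[1]:.9g} {v[2]:.9g}\n")
        for f in mesh.faces + 1:
            fh.write(f"f {f[0]} {f[1]} {f[2]}\n")


def _load_obj(path: Path) -> TriMesh:
    verts, faces = [], []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if parts[0] == "v":
                verts.append([float(x) for x in parts[1:4]])
            elif parts[0] == "f":
                idx = [int(tok.split("/")[0]) - 1 for tok in parts[1:]]
                for k in range(1, len(idx) - 1):  # fan-triangulate
                    faces.append([idx[0], idx[k], idx[k + 1]])
    return TriMesh(np.array(verts), np.array(faces))


def _save_ply(mesh: TriMesh, path: Path, binary: bool = True) -> None:
    fmt = "binary_little_endian" if binary else "ascii"
    header = (
        "ply\n"
        f"format {fmt} 1.0\n"
        f"element vertex {mesh.n_vertices}\n"
        "property float x\nproperty float y\nproperty float z\n"
        f"element face {mesh.n_faces}\n"
        "property list uchar int vertex_indices\n"
        "end_header\n"
    )
    if binary:
        with open(path, "wb") as fh:
            fh.write(header.encode("ascii"))
            fh.write(mesh.vertices.astype("<f4").tobytes())
            rows = bytearray()
            for tri in mesh.faces.astype("<i4"):
                rows += struct.pack("<B3i", 3, *tri)
            fh.write(bytes(rows))
    else:
        with open(path, "w") as fh:
            fh.write(header)
            for v in mesh.vertices:
                fh.write(f"{v[0]:.9g} {v[1]:.9g} {v[2]:.9g}\n")
            for f in mesh.faces:
                fh.write(f"3 {f[0]} {f[1]} {f[2]}\n")


def _load_ply(path: Path) -> TriMesh:
    with open(path, "rb") as fh:
        data = fh.read()
    end = data.find(b"end_header\n")
    if end < 0:
        raise MeshError("malformed PLY header")
    header = data[:end].decode("ascii").splitlines()
    body = data[end + len(b"end_header\n"):]
    fmt, n_vert, n_face = None, 0, 0
    for line in header:
        parts = line.split()
        if not parts:
            continue
        if parts[0] == "format":
            fmt = parts[1]
        elif parts[0] == "element" and parts[1] == "vertex":
            n_vert = int(parts[2])
        elif parts[0] == "element" and parts[1] == "face":
            n_face = int(parts[2])
    if fmt == "ascii":
        lines = body.decode("ascii").splitlines()
        verts = np.array([[float(x) for x in ln.split()[:3]] for ln in lines[:n_vert]])
        faces = np.array(
            [[int(x) for x in ln.split()[1:4]] for ln in lines[n_vert:n_vert + n_face]]
        )
        return TriMesh(verts, faces)
    if fmt == "binary_little_endian":
        vbytes = n_vert * 12
        verts = np.frombuffer(body[:vbytes], dtype="<f4").reshape(n_vert, 3)
        faces = np.empty((n_face, 3), dtype=np.int64)
        off = vbytes
        for i in range(n_face):
            cnt = body[off]
            if cnt != 3:
                raise MeshError("only triangle PLY faces supported")
            faces[i] = struct.unpack_from("<3i", body, off + 1)
            off += 1 + 12
        return TriMesh(verts.astype(np.float64), faces)
    raise MeshError(f"unsupported PLY format {fmt!r}")


def save_part_labels(labeled: PartLabeledMesh, path) -> None:
    """JSON sidecar mapping part name -> sorted list of face indices."""
    table: dict[str, list[int]] = {}
    for name in labeled.part_names:
        table[name] = np.nonzero(labeled.part_of_face == name)[0].tolist()
    with open(path, "w") as fh:
        json.dump(table, fh)


def load_part_labels(mesh: TriMesh, path) -> PartLabeledMesh:
    with open(path) as fh:
        table = json.load(fh)
    labels = np.empty(mesh.n_faces, dtype=object)
    for name, idx in table.items():
        labels[np.asarray(idx, dtype=int)] = name
    if any(l is None for l in labels):
        raise MeshError("part label sidecar does not cover every face")
    return PartLabeledMesh(mesh, labels.astype(str))
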