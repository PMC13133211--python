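"""Quadric edge-collapse mesh simplification.

Greedy contraction of the cheapest edge under the accumulated plane-quadric
error, with manifold link-condition and normal-flip guards so watertight
inputs stay watertight and keep their genus.
"""

from __future__ import annotations

import heapq
import warnings

import numpy as np

from .geometry import MeshError, TriMesh

__all__ = ["simplify"]


def _vertex_quadrics(mesh: TriMesh) -> np.ndarray:
    """(n, 4, 4) sum of area-weighted plane quadrics over incident faces."""
    tri = mesh.triangles()
    n = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    area = np.linalg.norm(n, axis=1) / 2.0
    unit = n / np.maximum(np.linalg.norm(n, axis=1, keepdims=True), 1e-300)
    d = -np.einsum("ij,ij->i", unit, tri[:, 0])
    plane = np.concatenate([unit, d[:, None]], axis=1)  # (m, 4)
    K = plane[:, :, None] * plane[:, None, :] * area[:, None, None]
    Q = np.zeros((mesh.n_vertices, 4, 4))
    for k in range(3):
        np.add.at(Q, mesh.faces[:, k], K)
    return Q


def _optimal_point(Q: np.ndarray, va: np.ndarray, vb: np.ndarray):
    A = Q[:3, :3]
    b = -Q[:3, 3]
    try:
        if abs(np.linalg.det(A)) > 1e-10 * max(np.trace(A) ** 3 / 27.0, 1e-30):
            v = np.linalg.solve(A, b)
            return v, _quadric_cost(Q, v)
    except np.linalg.LinAlgError:  # pragma: no cover
        pass
    candidates = [va, vb, (va + vb) / 2.0]
    costs = [_quadric_cost(Q, c) for c in candidates]
    i = int(np.argmin(costs))
    return candidates[i], costs[i]


def _quadric_cost(Q: np.ndarray, v: np.ndarray) -> float:
    h = np.append(v, 1.0)
    return float(h @ Q @ h)


def simplify(mesh: TriMesh, target_faces: int) -> TriMesh:
    """Collapse edges until at most ``target_faces`` faces remain.

    The input must be watertight; the result is watertight with the same
    Euler characteristic.  Targets below the minimum closed surface (4
    faces) are clamped with a warning.
    """
    if not mesh.is_watertight():
        raise MeshError("simplification requires a watertight mesh")
    if target_faces < 4:
        warnings.warn("target clamped to 4 faces (minimum closed surface)", RuntimeWarning)
        target_faces = 4
    if mesh.n_faces <= target_faces:
        return mesh.copy()

    V = mesh.vertices.copy()
    F = mesh.faces.copy()
    alive = np.ones(len(F), dtype=bool)
    Q = _vertex_quadrics(mesh)

    vert_faces: list[set[int]] = [set() for _ in range(len(V))]
    for fi, f in enumerate(F):
        for v in f:
            vert_faces[v].add(fi)
    version = np.zeros(len(V), dtype=np.int64)

    def neighbors(v: int) -> set[int]:
        out: set[int] = set()
        for fi in vert_faces[v]:
            out.update(F[fi])
        out.discard(v)
        return out

    def push_edge(heap, a: int, b: int):
        if a > b:
            a, b = b, a
        pos, cost = _optimal_point(Q[a] + Q[b], V[a], V[b])
        heapq.heappush(heap, (cost, int(version[a]), int(version[b]), a, b, pos))

    heap: list = []
    for a, b in mesh.edges_unique():
        push_edge(heap, int(a), int(b))

    n_alive = int(alive.sum())
    while n_alive > target_faces and heap:
        cost, va_ver, vb_ver, a, b, pos = heapq.heappop(heap)
        if version[a] != va_ver or version[b] != vb_ver:
            continue  # stale entry
        shared = vert_faces[a] & vert_faces[b]
        if len(shared) != 2:
            continue  # edge no longer manifold-interior
        # link condition: common vertex-neighbors must be exactly the two
        # vertices opposite the collapsing edge
        opposite = set()
        for fi in shared:
            opposite.update(int(v) for v in F[fi] if v != a and v != b)
        if neighbors(a) & neighbors(b) != opposite or len(opposite) != 2:
            continue
        # normal-flip / degeneracy guard on surviving faces
        affected = (vert_faces[a] | vert_faces[b]) - shared
        ok = True
        for fi in affected:
            f = F[fi]
            old = V[f]
            new = np.array([pos if v in (a, b) else V[v] for v in f])
            n_old = np.cross(old[1] - old[0], old[2] - old[0])
            n_new = np.cross(new[1] - new[0], new[2] - new[0])
            if np.linalg.norm(n_new) < 1e-14 or np.dot(n_old, n_new) <= 0:
                ok = False
                break
        if not ok:
            continue

        # commit: b merges into a at pos
        V[a] = pos
        Q[a] = Q[a] + Q[b]
        for fi in shared:
            alive[fi] = False
            for v in F[fi]:
                vert_faces[v].discard(fi)
        n_alive -= len(shared)
        for fi in vert_faces[b] - shared:
            F[fi][F[fi] == b] = a
            vert_faces[a].add(fi)
        vert_faces[b] = set()
        version[a] += 1
        version[b] += 1
        for nb in neighbors(a):
            push_edge(heap, a, int(nb))

    F = F[alive]
    used = np.unique(F)
    remap = np.full(len(V), -1, dtype=np.int64)
    remap[used] = np.arange(len(used))
    out = TriMesh(V[used], remap[F])
    if not out.is_watertight():  # pragma: no cover - guards should prevent this
        raise MeshError("simplification produced a non-watertight mesh")
    return out
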