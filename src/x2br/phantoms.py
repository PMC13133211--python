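"""Procedural watertight phantoms: analytic primitives, a toy thorax, and
known deformations.

These stand in for segmented clinical bone meshes.  Every generator is
deterministic given its seed, every output passes the watertightness and
orientation checks, and the primitives carry closed-form inclusion tests so
downstream ray-parity labeling can be verified against an exact oracle.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .geometry import MeshError, PartLabeledMesh, TriMesh

__all__ = [
    "PrimitiveSpec",
    "GenerationError",
    "make_primitive",
    "analytic_occupancy",
    "make_toy_thorax",
    "deform_known",
    "distinct_primitive_specs",
]


def distinct_primitive_specs() -> list["PrimitiveSpec"]:
    """Eight primitives that stay mutually distinguishable after unit-box
    normalization (differing aspect ratios, topology, orientation); the
    standard fixture set for conditional-reconstruction experiments."""
    return [
        PrimitiveSpec("sphere", {"radius": 0.35}, 3),
        PrimitiveSpec("ellipsoid", {"radii": (0.4, 0.2, 0.14)}, 3),
        PrimitiveSpec("ellipsoid", {"radii": (0.12, 0.33, 0.24)}, 3),
        PrimitiveSpec("torus", {"ring_radius": 0.3, "tube_radius": 0.12}, 3),
        PrimitiveSpec("torus", {"ring_radius": 0.32, "tube_radius": 0.05}, 3),
        PrimitiveSpec("capsule", {"a": (0, 0, -0.3), "b": (0, 0, 0.3), "radius": 0.16}, 3),
        PrimitiveSpec("capsule", {"a": (-0.28, -0.22, -0.2), "b": (0.28, 0.22, 0.2),
                                  "radius": 0.09}, 3),
        PrimitiveSpec("ellipsoid", {"radii": (0.3, 0.3, 0.12)}, 3),
    ]

logger = logging.getLogger(__name__)

_KINDS = ("sphere", "ellipsoid", "torus", "capsule")


class GenerationError(RuntimeError):
    """Raised when phantom generation cannot produce valid disjoint parts."""


@dataclass(frozen=True)
class PrimitiveSpec:
    """Description of one analytic solid.

    Parameters by kind:

    * ``sphere``: ``center`` (3,), ``radius``
    * ``ellipsoid``: ``center`` (3,), ``radii`` (3,)
    * ``torus``: ``center`` (3,), ``ring_radius`` R, ``tube_radius`` r
      (axis of revolution = z)
    * ``capsule``: ``a``, ``b`` segment endpoints (3,), ``radius``
    """

    kind: str
    parameters: dict = field(default_factory=dict)
    resolution: int = 4

    def __post_init__(self):
        if self.kind not in _KINDS:
            raise ValueError(f"unknown primitive kind {self.kind!r}")
        if self.resolution < 1:
            raise ValueError("resolution must be >= 1")
        p = self.parameters
        positive = {
            "sphere": ["radius"],
            "ellipsoid": [],
            "torus": ["ring_radius", "tube_radius"],
            "capsule": ["radius"],
        }[self.kind]
        for key in positive:
            if key not in p or p[key] <= 0:
                raise ValueError(f"{self.kind} requires positive {key!r}")
        if self.kind == "ellipsoid":
            radii = np.asarray(p.get("radii", []), dtype=float)
            if radii.shape != (3,) or np.any(radii <= 0):
                raise ValueError("ellipsoid requires 3 positive radii")
        if self.kind == "torus" and p["tube_radius"] >= p["ring_radius"]:
            raise ValueError("torus tube_radius must be < ring_radius")
        if self.kind == "capsule":
            a = np.asarray(p.get("a", []), dtype=float)
            b = np.asarray(p.get("b", []), dtype=float)
            if a.shape != (3,) or b.shape != (3,):
                raise ValueError("capsule requires 3-vector endpoints 'a' and 'b'")


# ----------------------------------------------------------------------
# primitive meshing
# ----------------------------------------------------------------------

def _icosahedron() -> tuple[np.ndarray, np.ndarray]:
    phi = (1.0 + np.sqrt(5.0)) / 2.0
    v = np.array(
        [
            [-1, phi, 0], [1, phi, 0], [-1, -phi, 0], [1, -phi, 0],
            [0, -1, phi], [0, 1, phi], [0, -1, -phi], [0, 1, -phi],
            [phi, 0, -1], [phi, 0, 1], [-phi, 0, -1], [-phi, 0, 1],
        ],
        dtype=float,
    )
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    f = np.array(
        [
            [0, 11, 5], [0, 5, 1], [0, 1, 7], [0, 7, 10], [0, 10, 11],
            [1, 5, 9], [5, 11, 4], [11, 10, 2], [10, 7, 6], [7, 1, 8],
            [3, 9, 4], [3, 4, 2], [3, 2, 6], [3, 6, 8], [3, 8, 9],
            [4, 9, 5], [2, 4, 11], [6, 2, 10], [8, 6, 7], [9, 8, 1],
        ],
        dtype=np.int64,
    )
    return v, f


def _subdivide_once(v: np.ndarray, f: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    edges = np.sort(
        np.concatenate([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]]), axis=1
    )
    uniq, inv = np.unique(edges, axis=0, return_inverse=True)
    mid = (v[uniq[:, 0]] + v[uniq[:, 1]]) / 2.0
    mid_idx = inv.reshape(3, -1).T + len(v)  # (m, 3): midpoints of (01, 12, 20)
    a, b, c = f[:, 0], f[:, 1], f[:, 2]
    ab, bc, ca = mid_idx[:, 0], mid_idx[:, 1], mid_idx[:, 2]
    new_f = np.concatenate(
        [
            np.stack([a, ab, ca], axis=1),
            np.stack([b, bc, ab], axis=1),
            np.stack([c, ca, bc], axis=1),
            np.stack([ab, bc, ca], axis=1),
        ]
    )
    return np.concatenate([v, mid]), new_f


def icosphere(subdivisions: int = 4) -> TriMesh:
    """Unit icosphere; ``subdivisions`` quadruples the face count each level."""
    v, f = _icosahedron()
    for _ in range(subdivisions):
        v, f = _subdivide_once(v, f)
        v = v / np.linalg.norm(v, axis=1, keepdims=True)
    return TriMesh(v, f)


def _torus_mesh(R: float, r: float, n_major: int, n_minor: int) -> TriMesh:
    u = np.arange(n_major) * (2 * np.pi / n_major)
    w = np.arange(n_minor) * (2 * np.pi / n_minor)
    uu, ww = np.meshgrid(u, w, indexing="ij")
    x = (R + r * np.cos(ww)) * np.cos(uu)
    y = (R + r * np.cos(ww)) * np.sin(uu)
    z = r * np.sin(ww)
    verts = np.stack([x.ravel(), y.ravel(), z.ravel()], axis=1)

    i = np.repeat(np.arange(n_major), n_minor)
    j = np.tile(np.arange(n_minor), n_major)
    i1 = (i + 1) % n_major
    j1 = (j + 1) % n_minor
    v00 = i * n_minor + j
    v10 = i1 * n_minor + j
    v01 = i * n_minor + j1
    v11 = i1 * n_minor + j1
    faces = np.concatenate(
        [np.stack([v00, v10, v11], axis=1), np.stack([v00, v11, v01], axis=1)]
    )
    m = TriMesh(verts, faces)
    return m if m.signed_volume() > 0 else m.flipped()


def _capsule_mesh(a: np.ndarray, b: np.ndarray, radius: float,
                  n_theta: int, n_phi: int) -> TriMesh:
    """Capsule as a UV sphere split at the equator with a cylinder inserted.

    Built along +z then rotated onto the segment a->b.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    h = np.linalg.norm(b - a) / 2.0
    # rings from bottom pole to top pole; hemisphere latitudes exclude poles
    lats_bot = -np.pi / 2 + np.arange(1, n_phi + 1) * (np.pi / 2 / n_phi)
    lats_top = np.arange(0, n_phi) * (np.pi / 2 / n_phi)
    theta = np.arange(n_theta) * (2 * np.pi / n_theta)
    rings = []
    for lat in lats_bot:
        rc = radius * np.cos(lat)
        rings.append(np.stack(
            [rc * np.cos(theta), rc * np.sin(theta),
             np.full(n_theta, -h + radius * np.sin(lat))], axis=1))
    # a few intermediate cylinder rings so long capsules sample smooth
    # deformations along their axis; capped to keep vertex counts desk-scale
    ring_gap = radius * np.pi / 2 / n_phi
    n_cyl = min(int(np.ceil(2 * h / max(ring_gap, 1e-9))) - 1, 6)
    for i in range(max(n_cyl, 0)):
        zc = -h + (i + 1) * 2 * h / (n_cyl + 1)
        rings.append(np.stack(
            [radius * np.cos(theta), radius * np.sin(theta),
             np.full(n_theta, zc)], axis=1))
    for lat in lats_top:
        rc = radius * np.cos(lat)
        rings.append(np.stack(
            [rc * np.cos(theta), rc * np.sin(theta),
             np.full(n_theta, h + radius * np.sin(lat))], axis=1))
    verts = [np.array([[0.0, 0.0, -h - radius]])] + rings + \
            [np.array([[0.0, 0.0, h + radius]])]
    verts = np.concatenate(verts)
    n_rings = len(rings)
    top_pole = 1 + n_rings * n_theta

    faces = []
    ring0 = 1  # first ring offset
    for k in range(n_theta):  # bottom cap fan
        k1 = (k + 1) % n_theta
        faces.append([0, ring0 + k1, ring0 + k])
    for r_i in range(n_rings - 1):  # ring-to-ring quads
        lo = ring0 + r_i * n_theta
        hi = lo + n_theta
        for k in range(n_theta):
            k1 = (k + 1) % n_theta
            faces.append([lo + k, lo + k1, hi + k1])
            faces.append([lo + k, hi + k1, hi + k])
    last = ring0 + (n_rings - 1) * n_theta
    for k in range(n_theta):  # top cap fan
        k1 = (k + 1) % n_theta
        faces.append([top_pole, last + k, last + k1])

    mesh = TriMesh(verts, np.asarray(faces))
    # orient +z axis onto segment direction
    axis = (b - a) / (2 * h) if h > 0 else np.array([0.0, 0.0, 1.0])
    z = np.array([0.0, 0.0, 1.0])
    vcross = np.cross(z, axis)
    c = float(np.dot(z, axis))
    if np.linalg.norm(vcross) < 1e-12:
        rot = np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
    else:
        vx = np.array([[0, -vcross[2], vcross[1]],
                       [vcross[2], 0, -vcross[0]],
                       [-vcross[1], vcross[0], 0]])
        rot = np.eye(3) + vx + vx @ vx / (1 + c)
    out = mesh.transformed(rotation=rot, translation=(a + b) / 2.0)
    return out if out.signed_volume() > 0 else out.flipped()


def make_primitive(spec: PrimitiveSpec, seed: int = 0) -> TriMesh:
    """Mesh one analytic primitive; deterministic given (spec, seed)."""
    p = spec.parameters
    res = spec.resolution
    if spec.kind == "sphere":
        m = icosphere(res).scaled(p["radius"])
        m = m.translated(p.get("center", (0, 0, 0)))
    elif spec.kind == "ellipsoid":
        radii = np.asarray(p["radii"], dtype=float)
        m = icosphere(res)
        m = TriMesh(m.vertices * radii, m.faces)
        m = m.translated(p.get("center", (0, 0, 0)))
    elif spec.kind == "torus":
        n = 8 * 2 ** (res - 1)
        m = _torus_mesh(p["ring_radius"], p["tube_radius"], n, max(n // 2, 8))
        m = m.translated(p.get("center", (0, 0, 0)))
    elif spec.kind == "capsule":
        n = 8 * 2 ** (res - 1)
        m = _capsule_mesh(np.asarray(p["a"], float), np.asarray(p["b"], float),
                          p["radius"], n, max(n // 4, 4))
    else:  # pragma: no cover - guarded by PrimitiveSpec
        raise ValueError(spec.kind)
    m.validate()
    return m


# ----------------------------------------------------------------------
# analytic inclusion oracle
# ----------------------------------------------------------------------

def _point_segment_distance(points: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    ab = b - a
    denom = float(ab @ ab)
    if denom == 0:
        return np.linalg.norm(points - a, axis=1)
    t = np.clip((points - a) @ ab / denom, 0.0, 1.0)
    closest = a + t[:, None] * ab
    return np.linalg.norm(points - closest, axis=1)


def analytic_occupancy(spec: PrimitiveSpec, points) -> np.ndarray:
    """Exact inside(1)/outside(0) membership from the closed-form solid."""
    pts = np.asarray(points, dtype=float).reshape(-1, 3)
    p = spec.parameters
    center = np.asarray(p.get("center", (0, 0, 0)), dtype=float)
    if spec.kind == "sphere":
        inside = np.linalg.norm(pts - center, axis=1) <= p["radius"]
    elif spec.kind == "ellipsoid":
        radii = np.asarray(p["radii"], dtype=float)
        inside = np.sum(((pts - center) / radii) ** 2, axis=1) <= 1.0
    elif spec.kind == "torus":
        q = pts - center
        rho = np.hypot(q[:, 0], q[:, 1])
        inside = (rho - p["ring_radius"]) ** 2 + q[:, 2] ** 2 <= p["tube_radius"] ** 2
    elif spec.kind == "capsule":
        d = _point_segment_distance(pts, np.asarray(p["a"], float), np.asarray(p["b"], float))
        inside = d <= p["radius"]
    else:  # pragma: no cover
        raise ValueError(f"unsupported kind {spec.kind!r}")
    return inside.astype(np.uint8)


# ----------------------------------------------------------------------
# toy thorax
# ----------------------------------------------------------------------

def _bend_around_axis(mesh: TriMesh, arc_radius: float, phi0: float, z_level: float) -> TriMesh:
    """Wrap a capsule built along y into an arc of radius ``arc_radius``
    around the vertical axis.  Exact torus-segment bend: topology (hence
    watertightness) is preserved."""
    v = mesh.vertices
    phi = phi0 + v[:, 1] / arc_radius
    rad = arc_radius + v[:, 0]
    out = np.stack([rad * np.cos(phi), rad * np.sin(phi), z_level + v[:, 2]], axis=1)
    m = TriMesh(out, mesh.faces)
    return m if m.signed_volume() > 0 else m.flipped()


def _rib_centerline(arc_radius: float, phi0: float, half_span: float,
                    z_level: float, n: int = 32) -> np.ndarray:
    s = np.linspace(-half_span, half_span, n)
    phi = phi0 + s / arc_radius
    return np.stack(
        [arc_radius * np.cos(phi), arc_radius * np.sin(phi), np.full(n, z_level)],
        axis=1,
    )


def _segments_far(c1: np.ndarray, r1: float, c2: np.ndarray, r2: float) -> bool:
    d = np.linalg.norm(c1[:, None, :] - c2[None, :, :], axis=2)
    return bool(d.min() > (r1 + r2) * 1.05)


def make_toy_thorax(
    n_rib_pairs: int,
    n_vertebrae: int,
    jitter: float = 0.0,
    seed: int = 0,
    resolution: int = 2,
    max_retries: int = 8,
) -> PartLabeledMesh:
    """Spine (stack of disjoint capsules) plus curved rib-pair capsules.

    Part labels: ``"spine"`` and ``"rib_pair_01"`` ... .  Parts are pairwise
    disjoint solids so that ray-parity occupancy stays valid on the union;
    jittered layouts that would make parts collide are regenerated from
    ``seed + 1`` (logged), and generation fails after ``max_retries``.
    """
    if n_rib_pairs < 1 or n_vertebrae < 1:
        raise ValueError("need at least one rib pair and one vertebra")
    if jitter < 0:
        raise ValueError("jitter must be non-negative")

    for attempt in range(max_retries):
        try:
            return _build_thorax(n_rib_pairs, n_vertebrae, jitter, seed + attempt, resolution)
        except GenerationError as exc:
            logger.warning("thorax layout collided (%s); retrying with seed+1", exc)
    raise GenerationError(
        f"could not place disjoint parts after {max_retries} retries; reduce jitter"
    )


def _build_thorax(n_rib_pairs, n_vertebrae, jitter, seed, resolution) -> PartLabeledMesh:
    rng = np.random.default_rng(seed)
    spine_r = 0.055
    rib_r = 0.028
    arc_radius = 0.30
    z_lo, z_hi = -0.40, 0.40
    gap = 0.015

    meshes: list[TriMesh] = []
    labels: list[str] = []
    centerlines: list[tuple[np.ndarray, float, str]] = []

    # spine: n_vertebrae stacked capsules with disk gaps
    seg = (z_hi - z_lo) / n_vertebrae
    half = max(seg / 2 - gap - spine_r, 0.004)
    spine_parts = []
    for i in range(n_vertebrae):
        zc = z_lo + (i + 0.5) * seg
        a = np.array([0.0, 0.0, zc - half])
        b = np.array([0.0, 0.0, zc + half])
        spine_parts.append(_capsule_mesh(a, b, spine_r, 8 * 2 ** (resolution - 1), 4))
        centerlines.append((np.stack([a, b]), spine_r, "spine"))
    meshes.append(TriMesh.concatenate(spine_parts))
    labels.append("spine")

    # ribs: arcs around the spine, one pair (left+right) per level
    rib_levels = np.linspace(z_lo + 0.08, z_hi - 0.08, n_rib_pairs)
    half_span = arc_radius * np.deg2rad(55)
    for k in range(n_rib_pairs):
        name = f"rib_pair_{k + 1:02d}"
        z_k = rib_levels[k] + jitter * rng.standard_normal()
        span_k = half_span * (1 + jitter * rng.standard_normal())
        pair = []
        for phi0 in (np.pi / 2, -np.pi / 2):  # left / right
            phi_k = phi0 + jitter * rng.standard_normal()
            straight = _capsule_mesh(
                np.array([0.0, -span_k, 0.0]), np.array([0.0, span_k, 0.0]),
                rib_r, 8 * 2 ** (resolution - 1), 4,
            )
            pair.append(_bend_around_axis(straight, arc_radius, phi_k, z_k))
            centerlines.append(
                (_rib_centerline(arc_radius, phi_k, span_k + rib_r, z_k), rib_r, name)
            )
        meshes.append(TriMesh.concatenate(pair))
        labels.append(name)

    # disjointness check between different parts
    for i in range(len(centerlines)):
        for j in range(i + 1, len(centerlines)):
            ci, ri, ni = centerlines[i]
            cj, rj, nj = centerlines[j]
            if ni == nj:
                continue
            if not _segments_far(ci, ri, cj, rj):
                raise GenerationError(f"parts {ni!r} and {nj!r} collide")

    mesh = TriMesh.concatenate(meshes)
    part_of_face = np.concatenate(
        [np.full(m.n_faces, lab, dtype=object) for m, lab in zip(meshes, labels)]
    ).astype(str)
    out = PartLabeledMesh(mesh, part_of_face)
    out.mesh.validate()
    return out


# ----------------------------------------------------------------------
# known deformations
# ----------------------------------------------------------------------

def deform_known(mesh, mode: str, magnitude: float, seed: int = 0):
    """Apply a deformation with known ground truth.

    Returns ``(deformed, displacements)`` where ``displacements`` is the
    exact (n_vertices, 3) offset added to each vertex.  ``part_articulation``
    requires a :class:`PartLabeledMesh` and rigidly translates one rib pair.
    """
    labeled = None
    if isinstance(mesh, PartLabeledMesh):
        labeled = mesh
        base = mesh.mesh
    else:
        base = mesh
    rng = np.random.default_rng(seed)
    v = base.vertices
    disp = np.zeros_like(v)

    if mode == "translation":
        if magnitude != 0:
            d = rng.normal(size=3)
            d /= np.linalg.norm(d)
            disp[:] = magnitude * d
    elif mode == "bend":
        if magnitude != 0:
            lo, hi = v[:, 2].min(), v[:, 2].max()
            span = max(hi - lo, 1e-12)
            diag = base.bbox_diagonal()
            disp[:, 0] = magnitude * diag * np.sin(np.pi * (v[:, 2] - lo) / span)
    elif mode == "part_articulation":
        if labeled is None:
            raise MeshError("part_articulation requires a PartLabeledMesh")
        ribs = [p for p in labeled.part_names if p != "spine"]
        if not ribs:
            raise MeshError("no rib parts to articulate")
        part = ribs[rng.integers(len(ribs))]
        vmask = np.zeros(base.n_vertices, dtype=bool)
        vmask[np.unique(base.faces[labeled.part_of_face == part])] = True
        # rigid in-plane shift of the whole pair; horizontal so the moved
        # rib stays unambiguous against its vertical neighbors
        disp[vmask] = magnitude * np.array([1.0, 0.0, 0.0])
    else:
        raise ValueError(f"unknown deformation mode {mode!r}")

    out = TriMesh(v + disp, base.faces)
    if mode == "part_articulation" and magnitude != 0:
        warnings.warn(
            "articulated part moved rigidly; output may self-intersect",
            RuntimeWarning,
            stacklevel=2,
        )
    if labeled is not None:
        return PartLabeledMesh(out, labeled.part_of_face.copy()), disp
    return out, disp
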