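"""Vectorized ray/triangle machinery for watertight meshes.

All queries share one strategy: rotate the scene so the ray direction becomes
+z, bin triangles into a 2D grid on the perpendicular plane, then answer each
ray from the handful of triangles overlapping its bin.  For a watertight,
consistently oriented mesh this gives

* parity crossing counts (inside/outside tests), and
* exact interior chord lengths (line integrals of the indicator function),
  via the identity  chord = sum over hits of sign(n_z) * z_hit.
"""

from __future__ import annotations

import numpy as np

from .geometry import TriMesh

__all__ = ["RayCaster", "random_directions"]


def random_directions(n: int, seed: int) -> np.ndarray:
    """(n, 3) unit vectors drawn uniformly on the sphere, reproducibly."""
    rng = np.random.default_rng(seed)
    v = rng.normal(size=(n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def _basis_for(direction: np.ndarray) -> np.ndarray:
    """Orthonormal 3x3 whose columns (u, v, d) map world into ray-aligned frame."""
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    helper = np.array([1.0, 0.0, 0.0]) if abs(d[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    u = np.cross(helper, d)
    u /= np.linalg.norm(u)
    v = np.cross(d, u)
    return np.column_stack([u, v, d])


class RayCaster:
    """Casts parallel rays along one fixed direction through a triangle soup.

    Parameters
    ----------
    mesh : TriMesh
        Consistently outward-oriented triangle mesh.
    direction : (3,) array_like
        Shared ray direction (normalized internally).
    n_bins : int, optional
        Grid resolution on the perpendicular plane; defaults to a heuristic
        based on triangle count.
    """

    def __init__(self, mesh: TriMesh, direction, n_bins: int | None = None):
        self._basis = _basis_for(direction)
        tri = mesh.triangles() @ self._basis  # (m, 3, 3) in ray frame
        self._tri = tri
        m = len(tri)
        if n_bins is None:
            n_bins = int(np.clip(np.sqrt(max(m, 1) / 4.0), 1, 128))
        self._nb = n_bins

        xy = tri[:, :, :2]
        lo = xy.min(axis=(0, 1)) - 1e-9
        hi = xy.max(axis=(0, 1)) + 1e-9
        self._lo, self._span = lo, np.maximum(hi - lo, 1e-12)

        # plane coefficients: z(x, y) = (n . A - nx*x - ny*y) / nz
        e1 = tri[:, 1] - tri[:, 0]
        e2 = tri[:, 2] - tri[:, 0]
        n = np.cross(e1, e2)
        nz = n[:, 2].copy()
        nz[nz == 0] = 1e-300  # grazing triangles; measure-zero for random dirs
        self._n = n
        self._nz = nz
        self._plane_d = np.einsum("ij,ij->i", n, tri[:, 0])

        # bin -> triangle index lists
        tmin = np.floor((xy.min(axis=1) - lo) / self._span * n_bins).astype(int)
        tmax = np.floor((xy.max(axis=1) - lo) / self._span * n_bins).astype(int)
        tmin = np.clip(tmin, 0, n_bins - 1)
        tmax = np.clip(tmax, 0, n_bins - 1)
        buckets: list[list[int]] = [[] for _ in range(n_bins * n_bins)]
        for t in range(m):
            for ix in range(tmin[t, 0], tmax[t, 0] + 1):
                base = ix * n_bins
                for iy in range(tmin[t, 1], tmax[t, 1] + 1):
                    buckets[base + iy].append(t)
        self._buckets = [np.asarray(b, dtype=np.int64) for b in buckets]

    # ------------------------------------------------------------------
    def _bin_of(self, xy: np.ndarray) -> np.ndarray:
        idx = np.floor((xy - self._lo) / self._span * self._nb).astype(int)
        idx = np.clip(idx, 0, self._nb - 1)
        return idx[:, 0] * self._nb + idx[:, 1]

    def _per_bin(self, points: np.ndarray):
        """Yield (point_rows, candidate_triangles, frame_points) per occupied bin."""
        p = points @ self._basis
        bins = self._bin_of(p[:, :2])
        order = np.argsort(bins, kind="stable")
        sorted_bins = bins[order]
        starts = np.searchsorted(sorted_bins, np.arange(self._nb * self._nb))
        ends = np.searchsorted(sorted_bins, np.arange(self._nb * self._nb), side="right")
        for b in np.unique(sorted_bins):
            rows = order[starts[b]:ends[b]]
            yield rows, self._buckets[b], p[rows]

    def _hits(self, tri_idx: np.ndarray, p: np.ndarray):
        """Boolean hit matrix (n_pts, n_tri) and hit depths z."""
        tri = self._tri[tri_idx]  # (t, 3, 3)
        px = p[:, None, 0]
        py = p[:, None, 1]
        ax, ay = tri[None, :, 0, 0], tri[None, :, 0, 1]
        bx, by = tri[None, :, 1, 0], tri[None, :, 1, 1]
        cx, cy = tri[None, :, 2, 0], tri[None, :, 2, 1]
        s1 = (bx - ax) * (py - ay) - (by - ay) * (px - ax)
        s2 = (cx - bx) * (py - by) - (cy - by) * (px - bx)
        s3 = (ax - cx) * (py - cy) - (ay - cy) * (px - cx)
        hit = ((s1 > 0) & (s2 > 0) & (s3 > 0)) | ((s1 < 0) & (s2 < 0) & (s3 < 0))
        n = self._n[tri_idx]
        z = (self._plane_d[tri_idx][None, :] - n[None, :, 0] * px - n[None, :, 1] * py)
        z = z / self._nz[tri_idx][None, :]
        return hit, z

    # ------------------------------------------------------------------
    def crossings_above(self, points: np.ndarray) -> np.ndarray:
        """Number of surface crossings of the half-ray from each point."""
        points = np.asarray(points, dtype=float)
        out = np.zeros(len(points), dtype=np.int64)
        for rows, tris, p in self._per_bin(points):
            if len(tris) == 0:
                continue
            hit, z = self._hits(tris, p)
            out[rows] = np.sum(hit & (z > p[:, 2][:, None]), axis=1)
        return out

    def parity_inside(self, points: np.ndarray) -> np.ndarray:
        """1 where the crossing count is odd (point inside), else 0."""
        return (self.crossings_above(points) % 2).astype(np.uint8)

    def chord_lengths(self, points: np.ndarray) -> np.ndarray:
        """Total interior length of the full line through each point.

        Uses the signed-depth identity; the point's own position along the
        ray is irrelevant.
        """
        points = np.asarray(points, dtype=float)
        out = np.zeros(len(points), dtype=float)
        sgn = np.sign(self._nz)
        for rows, tris, p in self._per_bin(points):
            if len(tris) == 0:
                continue
            hit, z = self._hits(tris, p)
            out[rows] = np.sum(hit * sgn[tris][None, :] * z, axis=1)
        return np.maximum(out, 0.0)
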