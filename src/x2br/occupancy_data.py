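"""Occupancy supervision: mesh normalization, ray-parity point labels,
binary voxelization, and training-point subsampling.

Conventions
-----------
* The normalized bounding volume is the axis-aligned cube ``[-0.5, 0.5]^3``;
  meshes are centered and isotropically scaled so the longest axis spans
  ``1 - 2 * padding`` (default padding 0.05).
* A point is labeled occupied when a ray from it crosses the surface an odd
  number of times; three pseudo-random ray directions vote to suppress
  grazing artifacts.
* A voxel is occupied when its center is inside the solid or its cube
  intersects the surface (interior + crossing shell), the convention under
  which volumetric IoU is computed downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import h5py
import numpy as np

from .geometry import MeshError, TriMesh
from .raycast import RayCaster, random_directions

__all__ = [
    "AffineTransform",
    "OccupancySample",
    "VoxelGrid",
    "PADDED_BOX_MIN",
    "PADDED_BOX_MAX",
    "normalize_mesh",
    "occupancy_labels",
    "sample_training_points",
    "voxelize",
    "voxelize_on_grid",
    "save_occupancy_pool",
    "load_occupancy_pool",
]

PADDED_BOX_MIN = -0.5
PADDED_BOX_MAX = 0.5
DEFAULT_PADDING = 0.05
_N_VOTE_RAYS = 3
_RAY_SEED = 0x5EED


@dataclass(frozen=True)
class AffineTransform:
    """Isotropic scale + translation, ``x -> scale * x + offset``."""

    scale: float
    offset: np.ndarray

    def apply(self, points: np.ndarray) -> np.ndarray:
        return points * self.scale + self.offset

    def inverse(self) -> "AffineTransform":
        return AffineTransform(1.0 / self.scale, -np.asarray(self.offset) / self.scale)


@dataclass
class OccupancySample:
    """Query points with binary inside/outside labels for one phantom."""

    points: np.ndarray  # (t, 3)
    labels: np.ndarray  # (t,) uint8 in {0, 1}
    source_id: str = ""

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.uint8)
        if len(self.points) != len(self.labels):
            raise ValueError("points and labels must have equal length")
        if self.labels.size and not np.isin(self.labels, (0, 1)).all():
            raise ValueError("labels must be binary")


@dataclass
class VoxelGrid:
    """Scalar grid over an axis-aligned box.

    ``values[i, j, k]`` is the value of the voxel whose center is
    ``origin + (i + 0.5, j + 0.5, k + 0.5) * pitch``.
    """

    values: np.ndarray
    origin: np.ndarray
    pitch: float

    def __post_init__(self):
        self.values = np.asarray(self.values)
        self.origin = np.asarray(self.origin, dtype=np.float64)
        if self.pitch <= 0:
            raise ValueError("pitch must be positive")

    @property
    def resolution(self) -> tuple[int, int, int]:
        return self.values.shape

    def centers(self) -> np.ndarray:
        """(n, 3) voxel-center coordinates in C order."""
        idx = np.stack(
            np.meshgrid(*[np.arange(r) for r in self.values.shape], indexing="ij"),
            axis=-1,
        ).reshape(-1, 3)
        return self.origin + (idx + 0.5) * self.pitch

    def occupied_volume(self) -> float:
        return float(np.count_nonzero(self.values)) * self.pitch ** 3


# ----------------------------------------------------------------------

def normalize_mesh(mesh: TriMesh, padding: float = DEFAULT_PADDING):
    """Center at the origin and scale the longest axis to ``1 - 2*padding``.

    Returns ``(normalized_mesh, transform)`` where ``transform`` maps
    original coordinates into the normalized frame and is invertible.
    """
    if not 0 <= padding < 0.5:
        raise ValueError("padding must lie in [0, 0.5)")
    if mesh.n_vertices == 0:
        raise MeshError("cannot normalize an empty mesh")
    bounds = mesh.bounds()
    extent = bounds[1] - bounds[0]
    longest = float(extent.max())
    if longest <= 0:
        raise MeshError("mesh has zero extent")
    scale = (1.0 - 2.0 * padding) / longest
    center = (bounds[0] + bounds[1]) / 2.0
    transform = AffineTransform(scale, -center * scale)
    return TriMesh(transform.apply(mesh.vertices), mesh.faces), transform


def occupancy_labels(
    mesh: TriMesh,
    points,
    n_rays: int = _N_VOTE_RAYS,
    ray_seed: int = _RAY_SEED,
) -> np.ndarray:
    """Ray-parity inside/outside labels with a majority vote over directions.

    Each of ``n_rays`` pseudo-random directions is shared by all points (the
    vote makes grazing hits on any single direction harmless); deterministic
    for a fixed ``ray_seed``.
    """
    if not mesh.is_watertight():
        n_open = len(mesh.open_edges())
        raise MeshError(
            f"occupancy labels need a watertight mesh ({n_open} unmatched directed edges)"
        )
    pts = np.asarray(points, dtype=float).reshape(-1, 3)
    dirs = random_directions(n_rays, ray_seed)
    votes = np.zeros(len(pts), dtype=np.int64)
    for d in dirs:
        votes += RayCaster(mesh, d).parity_inside(pts)
    return (votes * 2 > n_rays).astype(np.uint8)


def sample_training_points(
    mesh: TriMesh,
    n_pool: int = 100_000,
    t_batch: int = 2_048,
    seed: int = 0,
    source_id: str = "",
):
    """Uniform occupancy pool over the padded cube plus a batch sampler.

    Returns ``(pool, draw)``: ``pool`` is the full :class:`OccupancySample`
    of ``n_pool`` labeled points; ``draw(batch_index)`` yields a
    without-replacement subset of ``t_batch`` points, deterministic given
    ``(seed, batch_index)``.
    """
    if t_batch > n_pool:
        raise ValueError("t_batch cannot exceed n_pool")
    rng = np.random.default_rng(seed)
    pts = rng.uniform(PADDED_BOX_MIN, PADDED_BOX_MAX, size=(n_pool, 3))
    labels = occupancy_labels(mesh, pts)
    pool = OccupancySample(pts, labels, source_id=source_id)

    def draw(batch_index: int = 0) -> OccupancySample:
        sub_rng = np.random.default_rng((seed, batch_index))
        idx = sub_rng.choice(n_pool, size=t_batch, replace=False)
        return OccupancySample(pts[idx], labels[idx], source_id=source_id)

    return pool, draw


# ----------------------------------------------------------------------
# voxelization
# ----------------------------------------------------------------------

def _surface_crossing_mask(mesh: TriMesh, origin, pitch, shape) -> np.ndarray:
    """Conservative voxel/surface intersection: triangles are subdivided
    until their edges are shorter than half a voxel, then every voxel
    containing a sample vertex is marked."""
    tri = mesh.triangles()
    mask = np.zeros(shape, dtype=bool)
    limit = pitch / 2.0
    work = [tri]
    while work:
        t = work.pop()
        edge = np.linalg.norm(
            t - t[:, [1, 2, 0], :], axis=2
        ).max(axis=1)
        fine = t[edge <= limit]
        coarse = t[edge > limit]
        for chunk in (fine.reshape(-1, 3), (fine.sum(axis=1) / 3.0)):
            if len(chunk) == 0:
                continue
            idx = np.floor((chunk - origin) / pitch).astype(int)
            ok = np.all((idx >= 0) & (idx < np.asarray(shape)), axis=1)
            idx = idx[ok]
            mask[idx[:, 0], idx[:, 1], idx[:, 2]] = True
        if len(coarse):
            a, b, c = coarse[:, 0], coarse[:, 1], coarse[:, 2]
            ab, bc, ca = (a + b) / 2, (b + c) / 2, (c + a) / 2
            work.append(
                np.concatenate(
                    [
                        np.stack([a, ab, ca], axis=1),
                        np.stack([ab, b, bc], axis=1),
                        np.stack([ca, bc, c], axis=1),
                        np.stack([ab, bc, ca], axis=1),
                    ]
                )
            )
    return mask


def voxelize_on_grid(mesh: TriMesh, origin, pitch: float, shape) -> VoxelGrid:
    """Binary occupancy on an explicit grid: center-inside OR surface-crossing."""
    origin = np.asarray(origin, dtype=float)
    shape = tuple(int(s) for s in shape)
    grid = VoxelGrid(np.zeros(shape, dtype=np.uint8), origin, float(pitch))
    inside = occupancy_labels(mesh, grid.centers()).reshape(shape).astype(bool)
    crossing = _surface_crossing_mask(mesh, origin, pitch, shape)
    grid.values = (inside | crossing).astype(np.uint8)
    return grid


def voxelize(mesh: TriMesh, resolution: int = 32) -> VoxelGrid:
    """Binary grid over the padded unit cube at ``resolution^3``."""
    if resolution < 2:
        raise ValueError("resolution must be >= 2")
    pitch = (PADDED_BOX_MAX - PADDED_BOX_MIN) / resolution
    origin = np.full(3, PADDED_BOX_MIN)
    return voxelize_on_grid(mesh, origin, pitch, (resolution,) * 3)


# ----------------------------------------------------------------------
# pool I/O (HDF5 layout: datasets `points` float32 (n, 3), `labels` uint8
# (n,), attribute `source_id`)
# ----------------------------------------------------------------------

def save_occupancy_pool(sample: OccupancySample, path) -> None:
    with h5py.File(path, "w") as fh:
        fh.create_dataset("points", data=sample.points.astype(np.float32))
        fh.create_dataset("labels", data=sample.labels.astype(np.uint8))
        fh.attrs["source_id"] = sample.source_id


def load_occupancy_pool(path) -> OccupancySample:
    with h5py.File(path, "r") as fh:
        return OccupancySample(
            fh["points"][:].astype(np.float64),
            fh["labels"][:],
            source_id=str(fh.attrs.get("source_id", "")),
        )
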