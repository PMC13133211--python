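"""Synthetic radiograph rendering and forward-projected part boxes.

Geometry is an orthographic parallel beam.  The viewing direction for angle
``a`` (degrees) is the anterior-posterior axis ``+y`` rotated by ``a`` about
the vertical ``z`` axis; the image plane is spanned by the rotated ``x``
axis (image columns, left to right) and ``z`` (image rows, top to bottom).

Pixel intensity is ``1 - L / L_max`` where ``L`` is the interior chord
length of the pixel's ray (binary density: 1 inside bone, 0 outside) and
``L_max`` the diagonal of the padded unit cube, so bone renders bright on a
white-ish background, mimicking an inverted radiograph.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from PIL import Image
from skimage import exposure

from .geometry import MeshError, PartLabeledMesh, TriMesh
from .raycast import RayCaster

__all__ = [
    "ProjectionImage",
    "Box2D",
    "view_direction",
    "render_projection",
    "clahe",
    "project_part_bboxes",
    "save_png16",
    "load_png16",
    "save_yolo_boxes",
]

_BOX_DIAGONAL = np.sqrt(3.0)  # padded unit cube [-0.5, 0.5]^3


@dataclass
class ProjectionImage:
    """Square grayscale projection with its acquisition angle."""

    pixels: np.ndarray  # (h, w) float in [0, 1]
    view_angle: float = 0.0
    geometry: str = "parallel"
    source_id: str = ""

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2 or self.pixels.shape[0] != self.pixels.shape[1]:
            raise ValueError("projection image must be square (h == w)")
        if self.pixels.min() < -1e-9 or self.pixels.max() > 1 + 1e-9:
            raise ValueError("intensities must lie in [0, 1]")
        self.view_angle = float(self.view_angle) % 360.0

    @property
    def size(self) -> int:
        return self.pixels.shape[0]


@dataclass(frozen=True)
class Box2D:
    """Axis-aligned 2D box in normalized [0, 1] image coordinates."""

    part: str
    center_x: float
    center_y: float
    width: float
    height: float

    def __post_init__(self):
        if self.width <= 0 or self.height <= 0:
            raise ValueError("box must have positive extent")
        for v in (self.center_x - self.width / 2, self.center_y - self.height / 2):
            if v < -1e-9:
                raise ValueError("box extends outside the image")
        for v in (self.center_x + self.width / 2, self.center_y + self.height / 2):
            if v > 1 + 1e-9:
                raise ValueError("box extends outside the image")


def view_direction(angle_deg: float) -> np.ndarray:
    """Unit ray direction through the scene for a view angle in degrees."""
    a = np.deg2rad(angle_deg)
    return np.array([-np.sin(a), np.cos(a), 0.0])


def _image_frame(angle_deg: float):
    """Right/down/direction unit vectors of the image plane."""
    a = np.deg2rad(angle_deg)
    right = np.array([np.cos(a), np.sin(a), 0.0])
    down = np.array([0.0, 0.0, -1.0])
    return right, down, view_direction(angle_deg)


def _pixel_centers(size: int) -> np.ndarray:
    """1D coordinates of pixel centers across [-0.5, 0.5]."""
    return (np.arange(size) + 0.5) / size - 0.5


def render_projection(
    mesh: TriMesh,
    angle: float = 0.0,
    size: int = 224,
    rays_per_pixel: int = 1,
    source_id: str = "",
) -> ProjectionImage:
    """Orthographic chord-length projection of a watertight mesh.

    ``rays_per_pixel`` > 1 supersamples each pixel on a regular subgrid and
    averages, reducing aliasing on thin structures.
    """
    if not mesh.is_watertight():
        raise MeshError("projection rendering needs a watertight mesh")
    right, down, direction = _image_frame(angle)
    u = _pixel_centers(size)
    sub = int(np.ceil(np.sqrt(rays_per_pixel)))
    chord = np.zeros((size, size))
    caster = RayCaster(mesh, direction)
    for si in range(sub):
        for sj in range(sub):
            du = (si + 0.5) / sub / size - 0.5 / size
            dv = (sj + 0.5) / sub / size - 0.5 / size
            rows = (u + dv)[:, None]  # (size, 1) coords along `down`
            cols = (u + du)[None, :]
            origins = rows[..., None] * down + cols[..., None] * right
            chord += caster.chord_lengths(origins.reshape(-1, 3)).reshape(size, size)
    chord /= sub * sub
    pixels = 1.0 - np.clip(chord / _BOX_DIAGONAL, 0.0, 1.0)
    return ProjectionImage(pixels, view_angle=angle, source_id=source_id)


def chord_image(image: ProjectionImage) -> np.ndarray:
    """Invert the intensity mapping back to raw chord lengths."""
    return (1.0 - image.pixels) * _BOX_DIAGONAL


def clahe(image: ProjectionImage, clip_limit: float = 0.01, tiles: int = 8) -> ProjectionImage:
    """Contrast-limited adaptive histogram equalization, range-preserving."""
    if tiles > image.size:
        raise ValueError("tile count cannot exceed image size")
    px = image.pixels
    if px.max() - px.min() < 1e-12:
        return ProjectionImage(px.copy(), image.view_angle, image.geometry, image.source_id)
    out = exposure.equalize_adapthist(
        px, kernel_size=max(image.size // tiles, 1), clip_limit=clip_limit
    )
    return ProjectionImage(
        np.clip(out, 0.0, 1.0), image.view_angle, image.geometry, image.source_id
    )


def project_part_bboxes(
    labeled: PartLabeledMesh, angle: float = 0.0, size: int = 512
) -> list[Box2D]:
    """Tight 2D bounds of each part's projected vertices, in [0, 1] coords.

    The image x axis increases to the right, y increases downward, matching
    :func:`render_projection` pixel layout.  Empty parts are skipped with a
    warning.
    """
    right, down, _ = _image_frame(angle)
    boxes: list[Box2D] = []
    for part in labeled.part_names:
        sub = labeled.submesh(part)
        if sub.n_vertices == 0:  # pragma: no cover - construction prevents it
            warnings.warn(f"part {part!r} has no vertices; skipped", RuntimeWarning)
            continue
        px = sub.vertices @ right + 0.5  # [0, 1] across the image
        py = sub.vertices @ down + 0.5
        x0, x1 = float(px.min()), float(px.max())
        y0, y1 = float(py.min()), float(py.max())
        x0, x1 = max(x0, 0.0), min(x1, 1.0)
        y0, y1 = max(y0, 0.0), min(y1, 1.0)
        boxes.append(
            Box2D(part, (x0 + x1) / 2, (y0 + y1) / 2, x1 - x0, y1 - y0)
        )
    return boxes


# ----------------------------------------------------------------------
# I/O
# ----------------------------------------------------------------------

def save_png16(image: ProjectionImage, path) -> None:
    arr = np.round(image.pixels * 65535.0).astype(np.uint16)
    Image.fromarray(arr, mode="I;16").save(path)


def load_png16(path, view_angle: float = 0.0, source_id: str = "") -> ProjectionImage:
    arr = np.asarray(Image.open(path), dtype=np.float64)
    if arr.max() > 255:
        arr /= 65535.0
    elif arr.max() > 1:
        arr /= 255.0
    return ProjectionImage(arr, view_angle=view_angle, source_id=source_id)


def save_yolo_boxes(boxes: list[Box2D], path, class_map_path=None) -> None:
    """YOLO-style text: one `class cx cy w h` line per box, plus a JSON
    class map from class index to part name."""
    names = [b.part for b in boxes]
    with open(path, "w") as fh:
        for i, b in enumerate(boxes):
            fh.write(f"{i} {b.center_x:.6f} {b.center_y:.6f} {b.width:.6f} {b.height:.6f}\n")
    if class_map_path is not None:
        with open(class_map_path, "w") as fh:
            json.dump({str(i): n for i, n in enumerate(names)}, fh)
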