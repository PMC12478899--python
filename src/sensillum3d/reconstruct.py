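"""3D reconstruction: nested contours from masks, physical scaling, cropping.

Each predicted mask section yields its complete contour nesting tree (outer
boundaries and hole boundaries alike — sensilla are wall structures inside
the sacculus lumen, so both carry signal). Contour vertices are mapped to
physical µm using the voxel calibration, the mask-to-section scale factor,
and the section's global z index, then concatenated into a sacculus point
cloud from which individual sensilla are cut by axis-aligned crop boxes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from shapely.geometry import Point, Polygon
from skimage import measure

from .clouds import SacculusCloud, SensillumCloud
from .geometry import LabelStack, VoxelGeometry

__all__ = [
    "ContourSlice",
    "extract_contours",
    "stack_contours",
    "crop_sensillum",
    "load_crop_boxes",
    "reconstruct_cloud",
]


@dataclass
class ContourSlice:
    """All closed contours of one section with their containment depths.

    Contours are (n, 2) arrays of subpixel ``(row, col)`` vertices;
    ``nesting_depth[i] == 0`` marks an outermost boundary, odd depths are
    hole boundaries.
    """

    z_index: int
    contours: list[np.ndarray] = field(default_factory=list)
    nesting_depth: list[int] = field(default_factory=list)


def extract_contours(mask: np.ndarray, z_index: int = 0) -> ContourSlice:
    """Full nesting tree of boundary polygons of a binary mask.

    The mask is zero-padded by one pixel first so regions touching the border
    still produce closed contours; coordinates are shifted back afterwards.
    Depth is the number of other contours strictly containing the polygon.
    """
    mask = np.asarray(mask)
    padded = np.pad((mask > 0).astype(float), 1)
    raw = measure.find_contours(padded, 0.5)
    contours = [c - 1.0 for c in raw]  # undo padding offset
    polys = [Polygon(c) if len(c) >= 4 else None for c in contours]
    depths = []
    for i, ci in enumerate(contours):
        probe = Point(ci[0])
        depth = 0
        for j, pj in enumerate(polys):
            if i == j or pj is None or not pj.is_valid:
                continue
            if pj.contains(probe):
                depth += 1
        depths.append(depth)
    return ContourSlice(z_index=z_index, contours=contours, nesting_depth=depths)


def stack_contours(slices: list[ContourSlice], geometry: VoxelGeometry,
                   mask_scale: float = 1.0, condition: str = "unknown",
                   include_holes: bool = True) -> SacculusCloud:
    """Assemble contour slices into a physically calibrated point cloud.

    A contour vertex ``(row, col)`` of the slice at ``z_index`` maps to
    ``x = col * mask_scale * pixel_x``, ``y = row * mask_scale * pixel_y``,
    ``z = z_index * slice_z`` (nm, converted to µm). ``mask_scale`` is the
    ratio of original section width to mask width, applied as a coordinate
    factor rather than by resampling the masks.
    """
    if mask_scale <= 0:
        raise ValueError("mask_scale must be positive")
    zs = [s.z_index for s in slices]
    if zs != sorted(zs):
        raise ValueError("slices must be ordered by z_index")
    pts = []
    for sl in slices:
        for contour, depth in zip(sl.contours, sl.nesting_depth):
            if not include_holes and depth % 2 == 1:
                continue
            x = contour[:, 1] * mask_scale * geometry.pixel_x / 1000.0
            y = contour[:, 0] * mask_scale * geometry.pixel_y / 1000.0
            z = np.full(len(contour), sl.z_index * geometry.slice_z / 1000.0)
            pts.append(np.column_stack([x, y, z]))
    if not pts:
        points = np.empty((0, 3))
    else:
        points = np.concatenate(pts)
    return SacculusCloud(points=points, condition=condition, geometry=geometry,
                         metadata={"mask_scale": mask_scale,
                                   "n_slices": len(slices)})


def crop_sensillum(cloud: SacculusCloud, box: tuple, chamber: int,
                   sensillum_id: str) -> SensillumCloud:
    """Cut the points strictly inside an axis-aligned box (µm) out of the cloud.

    ``box`` is ``(min_xyz, max_xyz)``; an empty selection is an error — the
    box does not intersect the structure it was meant to isolate.
    """
    lo = np.asarray(box[0], dtype=float)
    hi = np.asarray(box[1], dtype=float)
    if (hi <= lo).any():
        raise ValueError(f"degenerate crop box {box}")
    inside = np.all((cloud.points > lo) & (cloud.points < hi), axis=1)
    if not inside.any():
        raise ValueError(f"empty crop: box {box} contains no points")
    return SensillumCloud(points=cloud.points[inside], chamber=chamber,
                          condition=cloud.condition, sensillum_id=sensillum_id,
                          metadata={"crop_box": [lo.tolist(), hi.tolist()]})


def load_crop_boxes(path: str | Path) -> list[dict]:
    """Read declarative crop boxes: [{"id", "chamber", "min_um", "max_um"}, ...]."""
    boxes = json.loads(Path(path).read_text())
    for b in boxes:
        for key in ("id", "chamber", "min_um", "max_um"):
            if key not in b:
                raise ValueError(f"crop box missing field {key!r}: {b}")
    return boxes


def reconstruct_cloud(masks: LabelStack, mask_scale: float = 1.0,
                      condition: str = "unknown", include_holes: bool = True,
                      ) -> SacculusCloud:
    """Convenience wrapper: extract contours from every section and stack them."""
    slices = [extract_contours(sec, z_index=masks.origin_index + i)
              for i, sec in enumerate(masks.sections)]
    return stack_contours(slices, masks.geometry, mask_scale=mask_scale,
                          condition=condition, include_holes=include_holes)
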