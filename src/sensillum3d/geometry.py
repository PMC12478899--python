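"""Core containers: voxel calibration and ordered section stacks.

Physical conventions used throughout the package:

* pixel sizes and slice thickness are stored in **nanometres**, point-cloud
  coordinates in **micrometres**;
* a pixel ``(row, col)`` of section ``z_index`` maps to physical
  ``x = col * pixel_x``, ``y = row * pixel_y``, ``z = z_index * slice_z``
  (0-based indices, origin at the top-left pixel corner).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import tifffile

__all__ = [
    "VoxelGeometry",
    "ImageStack",
    "LabelStack",
    "read_stack",
    "write_stack",
]


@dataclass(frozen=True)
class VoxelGeometry:
    """Physical calibration of a section stack (all values in nm)."""

    pixel_x: float
    pixel_y: float
    slice_z: float

    def __post_init__(self) -> None:
        for name in ("pixel_x", "pixel_y", "slice_z"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"VoxelGeometry.{name} must be positive, got {v!r}")

    @property
    def voxel_diagonal_um(self) -> float:
        """Length of the voxel body diagonal in µm."""
        return float(np.sqrt(self.pixel_x**2 + self.pixel_y**2 + self.slice_z**2)) / 1000.0

    def to_dict(self) -> dict:
        return {"pixel_x": self.pixel_x, "pixel_y": self.pixel_y, "slice_z": self.slice_z}

    @classmethod
    def from_dict(cls, d: dict) -> "VoxelGeometry":
        return cls(pixel_x=d["pixel_x"], pixel_y=d["pixel_y"], slice_z=d["slice_z"])


def _validate_sections(sections: np.ndarray) -> np.ndarray:
    arr = np.asarray(sections)
    if arr.ndim != 3 or arr.shape[0] < 1:
        raise ValueError(f"stack must be (n_sections, rows, cols) with n>=1, got shape {arr.shape}")
    return arr


@dataclass
class ImageStack:
    """Ordered grayscale sections plus physical calibration.

    ``origin_index`` is the z index of the first section, letting two
    sub-stacks from one acquisition share a global z numbering.
    """

    sections: np.ndarray  # (n, rows, cols)
    geometry: VoxelGeometry
    origin_index: int = 0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.sections = _validate_sections(self.sections)

    @property
    def n_sections(self) -> int:
        return int(self.sections.shape[0])

    @property
    def section_shape(self) -> tuple[int, int]:
        return (int(self.sections.shape[1]), int(self.sections.shape[2]))

    @property
    def depth_um(self) -> float:
        """Physical depth of the stack in µm (n sections × slice thickness)."""
        return self.n_sections * self.geometry.slice_z / 1000.0

    @property
    def fov_um(self) -> tuple[float, float]:
        """Physical field of view (y, x) in µm."""
        r, c = self.section_shape
        return (r * self.geometry.pixel_y / 1000.0, c * self.geometry.pixel_x / 1000.0)

    def with_sections(self, sections: np.ndarray, **geometry_updates) -> "ImageStack":
        geom = replace(self.geometry, **geometry_updates) if geometry_updates else self.geometry
        return ImageStack(sections=np.asarray(sections), geometry=geom,
                          origin_index=self.origin_index, metadata=dict(self.metadata))


@dataclass
class LabelStack:
    """Binary masks paired with an ImageStack; values are exactly {0, 1}."""

    sections: np.ndarray
    geometry: VoxelGeometry
    origin_index: int = 0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.sections = _validate_sections(self.sections)
        vals = np.unique(self.sections)
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("LabelStack values must be binary {0, 1}")
        self.sections = self.sections.astype(np.uint8)

    @property
    def n_sections(self) -> int:
        return int(self.sections.shape[0])

    @property
    def section_shape(self) -> tuple[int, int]:
        return (int(self.sections.shape[1]), int(self.sections.shape[2]))


def write_stack(stack: ImageStack | LabelStack, path: str | Path) -> Path:
    """Write a stack as multi-page TIFF with a JSON geometry sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    data = stack.sections
    if isinstance(stack, LabelStack):
        data = (data * 255).astype(np.uint8)
    tifffile.imwrite(path, data)
    sidecar = {
        "geometry": stack.geometry.to_dict(),
        "origin_index": stack.origin_index,
        "is_label": isinstance(stack, LabelStack),
        "metadata": _jsonable(stack.metadata),
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))
    return path


def read_stack(path: str | Path) -> ImageStack | LabelStack:
    """Read a multi-page TIFF stack and its JSON geometry sidecar."""
    path = Path(path)
    data = tifffile.imread(path)
    if data.ndim == 2:
        data = data[None]
    side = json.loads(path.with_suffix(".json").read_text())
    geom = VoxelGeometry.from_dict(side["geometry"])
    cls = LabelStack if side.get("is_label") else ImageStack
    if side.get("is_label"):
        data = (data > 0).astype(np.uint8)
    return cls(sections=data, geometry=geom, origin_index=side.get("origin_index", 0),
               metadata=side.get("metadata", {}))


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
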