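"""Point-cloud containers (coordinates in µm) and PLY/XYZ text I/O."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .geometry import VoxelGeometry, _jsonable

__all__ = ["SacculusCloud", "SensillumCloud", "write_cloud", "read_cloud"]


def _as_points(points: np.ndarray) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError(f"points must be (n, 3), got shape {pts.shape}")
    if not np.isfinite(pts).all():
        raise ValueError("points contain non-finite coordinates")
    return pts


@dataclass
class SacculusCloud:
    """Whole-sacculus point cloud reconstructed from mask contours."""

    points: np.ndarray  # (n, 3) µm
    condition: str = "unknown"  # high_RH / low_RH
    geometry: VoxelGeometry | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.points = _as_points(self.points)


@dataclass
class SensillumCloud:
    """A single cropped sensillum: the per-unit object of morphometric analysis.

    ``provenance`` accumulates the rigid transforms applied since cropping as
    ``{"rotation": 3x3, "translation": 3-vector}`` dicts, oldest first.
    """

    points: np.ndarray  # (n, 3) µm
    chamber: int = 1
    condition: str = "unknown"
    sensillum_id: str = "s0"
    metadata: dict = field(default_factory=dict)
    provenance: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.points = _as_points(self.points)
        if self.chamber not in (1, 2, 3):
            raise ValueError(f"chamber must be 1, 2 or 3, got {self.chamber}")

    @property
    def centroid(self) -> np.ndarray:
        return self.points.mean(axis=0)

    def replace_points(self, points: np.ndarray, extra_provenance: dict | None = None) -> "SensillumCloud":
        prov = list(self.provenance)
        if extra_provenance is not None:
            prov.append(_jsonable(extra_provenance))
        return SensillumCloud(points=points, chamber=self.chamber, condition=self.condition,
                              sensillum_id=self.sensillum_id, metadata=dict(self.metadata),
                              provenance=prov)


def write_cloud(cloud: SacculusCloud | SensillumCloud, path: str | Path) -> Path:
    """Write a cloud as ASCII PLY (``.ply``) or XYZ text (``.xyz``), plus a JSON sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pts = cloud.points
    if path.suffix == ".xyz":
        np.savetxt(path, pts, fmt="%.6f")
    else:
        header = (
            "ply\nformat ascii 1.0\n"
            f"element vertex {len(pts)}\n"
            "property float x\nproperty float y\nproperty float z\nend_header\n"
        )
        body = "\n".join(" ".join(f"{v:.6f}" for v in p) for p in pts)
        path.write_text(header + body + "\n")
    side: dict = {"metadata": _jsonable(cloud.metadata)}
    if isinstance(cloud, SensillumCloud):
        side.update(kind="sensillum", chamber=cloud.chamber, condition=cloud.condition,
                    sensillum_id=cloud.sensillum_id, provenance=_jsonable(cloud.provenance))
    else:
        side.update(kind="sacculus", condition=cloud.condition,
                    geometry=cloud.geometry.to_dict() if cloud.geometry else None)
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(side, indent=2))
    return path


def read_cloud(path: str | Path) -> SacculusCloud | SensillumCloud:
    path = Path(path)
    if path.suffix == ".xyz":
        pts = np.loadtxt(path, ndmin=2)
    else:
        lines = path.read_text().splitlines()
        start = lines.index("end_header") + 1
        pts = np.array([[float(v) for v in ln.split()] for ln in lines[start:] if ln.strip()])
    sidecar = path.with_suffix(path.suffix + ".json")
    side = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    if side.get("kind") == "sensillum":
        return SensillumCloud(points=pts, chamber=side["chamber"], condition=side["condition"],
                              sensillum_id=side["sensillum_id"], metadata=side.get("metadata", {}),
                              provenance=side.get("provenance", []))
    geom = side.get("geometry")
    return SacculusCloud(points=pts, condition=side.get("condition", "unknown"),
                         geometry=VoxelGeometry.from_dict(geom) if geom else None,
                         metadata=side.get("metadata", {}))
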