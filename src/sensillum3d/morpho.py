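"""Width-vs-height profiles and the half-height width summary.

An aligned sensillum cloud is triangulated (Delaunay), the surface is sliced
at uniformly spaced heights, and the width at each height is the maximum
pairwise XY distance among the cross-section vertices. Raw profiles are
denoised with a triangular-weighted moving average, then summarized by the
width at half the total height.

Note on terminology: the half-height summary follows this field's usage of
"FWHM" — the width of the structure evaluated at half its total height — and
is *not* the conventional full-width-at-half-maximum of a peaked curve.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import trimesh
from scipy.spatial import Delaunay, QhullError
from scipy.spatial.distance import pdist

from .clouds import SensillumCloud

__all__ = [
    "WidthProfile",
    "FwhmRecord",
    "build_mesh",
    "slice_widths",
    "smooth_profile",
    "fwhm",
    "profile_sensillum",
]

log = logging.getLogger(__name__)


@dataclass
class WidthProfile:
    """Ordered (height µm, width µm) samples along one sensillum's axis."""

    sensillum_id: str
    chamber: int
    condition: str
    heights: np.ndarray
    widths: np.ndarray
    smoothed: bool = False
    empty_slices: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.heights = np.asarray(self.heights, dtype=float)
        self.widths = np.asarray(self.widths, dtype=float)
        if self.heights.ndim != 1 or self.heights.shape != self.widths.shape:
            raise ValueError("heights and widths must be matching 1D arrays")
        if len(self.heights) >= 2 and not (np.diff(self.heights) > 0).all():
            raise ValueError("heights must be strictly increasing")
        if (self.widths < 0).any():
            raise ValueError("widths must be >= 0")


@dataclass(frozen=True)
class FwhmRecord:
    """Total height and the width at half that height for one sensillum."""

    sensillum_id: str
    chamber: int
    condition: str
    height_total: float
    width_at_half_height: float


def build_mesh(cloud: SensillumCloud) -> trimesh.Trimesh:
    """Triangulated surface over the cloud (Delaunay boundary faces).

    The vertex array is the full point set; faces are the boundary triangles
    of the 3D Delaunay tetrahedralization (each belonging to exactly one
    tetrahedron). The mesh is a slicing substrate, not a rendering asset.
    """
    pts = cloud.points
    if len(pts) < 4:
        raise ValueError("need at least 4 points to build a mesh")
    try:
        tetra = Delaunay(pts)
    except QhullError as exc:
        raise ValueError(f"degenerate (coplanar) cloud: {exc}") from exc
    faces: dict[tuple, np.ndarray] = {}
    opposite = [(1, 2, 3), (0, 2, 3), (0, 1, 3), (0, 1, 2)]
    for simplex in tetra.simplices:
        for tri in opposite:
            face = simplex[list(tri)]
            key = tuple(sorted(face))
            if key in faces:
                del faces[key]
            else:
                faces[key] = face
    boundary = np.array(list(faces.values()))
    return trimesh.Trimesh(vertices=pts, faces=boundary, process=False)


def _section_width(mesh: trimesh.Trimesh, z: float) -> float:
    """Max pairwise XY distance among mesh/plane intersection vertices; 0 if empty."""
    section = mesh.section(plane_origin=[0.0, 0.0, z], plane_normal=[0.0, 0.0, 1.0])
    if section is None or len(section.vertices) < 2:
        return 0.0
    xy = np.asarray(section.vertices)[:, :2]
    if len(xy) > 400:
        # max pairwise distance is attained on the convex hull
        from scipy.spatial import ConvexHull
        try:
            xy = xy[ConvexHull(xy).vertices]
        except QhullError:
            pass
    return float(pdist(xy).max())


def slice_widths(mesh: trimesh.Trimesh, n_slices: int = 100, *,
                 sensillum_id: str = "s0", chamber: int = 1,
                 condition: str = "unknown") -> WidthProfile:
    """Raw width profile: n uniform heights spanning the mesh z range.

    Empty cross-sections at interior heights (mesh gaps) are filled by linear
    interpolation between the flanking nonempty slices and flagged in
    ``empty_slices``. The two boundary levels pass through the mesh's extreme
    vertices, where the plane cuts only a degenerate sliver, so their widths
    are linearly extrapolated from the two nearest interior slices (exact for
    a linear taper, constant for a prism).
    """
    if n_slices < 2:
        raise ValueError("n_slices must be >= 2")
    zmin, zmax = float(mesh.vertices[:, 2].min()), float(mesh.vertices[:, 2].max())
    heights = np.linspace(zmin, zmax, n_slices)
    widths = np.zeros(n_slices)
    widths[1:-1] = [_section_width(mesh, z) for z in heights[1:-1]]
    empty = [int(i) for i in np.flatnonzero(widths[1:-1] == 0.0) + 1]
    if empty:
        log.info("filling %d empty interior cross-sections by interpolation",
                 len(empty))
        good = widths > 0
        if good.sum() >= 2:
            idx = np.arange(1, n_slices - 1)
            bad = idx[widths[idx] == 0.0]
            widths[bad] = np.interp(heights[bad], heights[good], widths[good])
    if n_slices >= 4:
        widths[0] = max(0.0, widths[1] + (widths[1] - widths[2])
                        / (heights[1] - heights[2]) * (heights[0] - heights[1]))
        widths[-1] = max(0.0, widths[-2] + (widths[-2] - widths[-3])
                         / (heights[-2] - heights[-3]) * (heights[-1] - heights[-2]))
    else:
        widths[0], widths[-1] = widths[1], widths[-2]
    return WidthProfile(sensillum_id=sensillum_id, chamber=chamber, condition=condition,
                        heights=heights, widths=widths, smoothed=False,
                        empty_slices=empty)


def smooth_profile(profile: WidthProfile, window: int = 5,
                   uniform_weights: bool = False) -> WidthProfile:
    """Weighted moving average with triangular weights 1,2,…,k,…,2,1.

    Edges use the truncated, renormalized window; heights are unchanged.
    ``window`` must be odd; ``window=1`` is the identity.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be odd and >= 1")
    half = window // 2
    if uniform_weights:
        weights = np.ones(window)
    else:
        weights = np.concatenate([np.arange(1, half + 2), np.arange(half, 0, -1)]).astype(float)
    w = profile.widths
    out = np.empty_like(w)
    for i in range(len(w)):
        lo = max(0, i - half)
        hi = min(len(w), i + half + 1)
        wts = weights[lo - (i - half): window - ((i + half + 1) - hi)]
        out[i] = np.sum(w[lo:hi] * wts) / wts.sum()
    return WidthProfile(sensillum_id=profile.sensillum_id, chamber=profile.chamber,
                        condition=profile.condition, heights=profile.heights,
                        widths=out, smoothed=True, empty_slices=list(profile.empty_slices))


def fwhm(profile: WidthProfile) -> FwhmRecord:
    """Total height and the linearly interpolated width at its midpoint."""
    if len(profile.heights) < 2:
        raise ValueError("profile must have at least 2 samples")
    height_total = float(profile.heights[-1] - profile.heights[0])
    z_half = float(profile.heights[0]) + height_total / 2.0
    width_half = float(np.interp(z_half, profile.heights, profile.widths))
    return FwhmRecord(sensillum_id=profile.sensillum_id, chamber=profile.chamber,
                      condition=profile.condition, height_total=height_total,
                      width_at_half_height=width_half)


def profile_sensillum(cloud: SensillumCloud, n_slices: int = 100, window: int = 5,
                      ) -> tuple[WidthProfile, WidthProfile, FwhmRecord]:
    """Mesh, slice, smooth and summarize one aligned sensillum.

    Returns (raw profile, smoothed profile, half-height record).
    """
    mesh = build_mesh(cloud)
    raw = slice_widths(mesh, n_slices, sensillum_id=cloud.sensillum_id,
                       chamber=cloud.chamber, condition=cloud.condition)
    smoothed = smooth_profile(raw, window)
    return raw, smoothed, fwhm(smoothed)
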