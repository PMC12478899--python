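"""Synthetic phantoms with known geometry for every downstream stage.

The generator produces three kinds of ground-truth objects:

* cone-surface point clouds (``make_sensillum_cloud``) — stand-ins for
  cropped sensilla, with base width, height, taper slope and orientation
  recorded in metadata;
* voxelized image/label stacks (``make_phantom_stack``) — bright conical
  "sensilla" in a darker matrix with additive Gaussian noise, plus the exact
  noise-free binary occupancy;
* long-format width-profile tables (``make_profile_dataset``) — draws from
  the linear mixed model the statistics stage assumes.

A cone with base width :math:`w_0` and taper slope :math:`m \\le 0` has
analytic width :math:`w(z) = \\max(w_0 + m z, 0)` at height ``z`` above its
base; all generators honour this closed form so downstream measurements can
be checked against it exactly.

Default per-chamber cone dimensions mirror the reported morphology of the
sacculus: hygro-sensilla bases near 3.4 µm (high RH) and 2.6 µm (low RH) in
Chamber 1, squat near-isometric cones in Chamber 2, and intermediate
olfactory cones in Chamber 3, with the per-condition taper slopes used as
d(width)/d(height) directly. Heights default to the full-cone value
``base_width / |slope|`` so each sensillum tapers to a point.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.transform import rescale as _sk_rescale

from .clouds import SensillumCloud
from .geometry import ImageStack, LabelStack, VoxelGeometry
from .transforms import rotation_between

__all__ = [
    "ConeSpec",
    "PhantomStackSpec",
    "DEFAULT_CHAMBER_PARAMS",
    "make_sensillum_cloud",
    "make_phantom_stack",
    "make_split_resolution_pair",
    "make_profile_dataset",
]


#: (chamber, condition) -> (base_width µm, taper slope, height µm).
#: Base widths and slopes follow the reported per-chamber means; heights are
#: the full-cone closure base/|slope| (the study reports no heights).
DEFAULT_CHAMBER_PARAMS: dict[tuple[int, str], tuple[float, float, float]] = {
    (1, "high_RH"): (3.36, -0.472, 3.36 / 0.472),
    (1, "low_RH"): (2.59, -0.403, 2.59 / 0.403),
    (2, "high_RH"): (3.30, -0.959, 3.30 / 0.959),
    (2, "low_RH"): (2.64, -1.120, 2.64 / 1.120),
    (3, "high_RH"): (3.20, -0.541, 3.20 / 0.541),
    (3, "low_RH"): (2.54, -0.652, 2.54 / 0.652),
}


@dataclass(frozen=True)
class ConeSpec:
    """Geometry of one synthetic sensillum (µm units).

    ``taper_slope`` is d(width)/d(height) and must be <= 0; the analytic
    width at height z above the base is ``max(base_width + taper_slope*z, 0)``.
    """

    base_width: float
    height: float
    taper_slope: float = 0.0
    axis_direction: tuple[float, float, float] = (0.0, 0.0, 1.0)
    apex_offset: tuple[float, float, float] = (0.0, 0.0, 0.0)
    noise_sd: float = 0.0
    points_n: int = 2000

    def __post_init__(self) -> None:
        if self.base_width <= 0:
            raise ValueError(f"base_width must be positive, got {self.base_width}")
        if self.height <= 0:
            raise ValueError(f"height must be positive, got {self.height}")
        if self.taper_slope > 0:
            raise ValueError(f"taper_slope must be <= 0, got {self.taper_slope}")
        if self.points_n < 4:
            raise ValueError(f"points_n must be >= 4, got {self.points_n}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if np.linalg.norm(self.axis_direction) < 1e-12:
            raise ValueError("axis_direction must be a nonzero vector")

    def width_at(self, z: np.ndarray | float) -> np.ndarray | float:
        """Analytic width of the cone at height z above the base."""
        return np.clip(self.base_width + self.taper_slope * np.asarray(z, dtype=float), 0.0, None)

    @property
    def effective_height(self) -> float:
        """Height at which the taper reaches zero width, capped at ``height``."""
        if self.taper_slope < 0:
            return float(min(self.height, -self.base_width / self.taper_slope))
        return float(self.height)

    def to_dict(self) -> dict:
        return {
            "base_width": self.base_width,
            "height": self.height,
            "taper_slope": self.taper_slope,
            "axis_direction": list(self.axis_direction),
            "apex_offset": list(self.apex_offset),
            "noise_sd": self.noise_sd,
            "points_n": self.points_n,
        }


@dataclass(frozen=True)
class PhantomStackSpec:
    """One synthetic acquisition: volume shape, calibration, cones, intensities."""

    sections_n: int
    section_shape: tuple[int, int]
    geometry: VoxelGeometry
    cones: tuple[ConeSpec, ...] = ()
    background_level: float = 50.0
    foreground_level: float = 200.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sections_n < 1:
            raise ValueError("sections_n must be >= 1")
        if min(self.section_shape) < 1:
            raise ValueError("section_shape must be positive")
        for lvl in (self.background_level, self.foreground_level):
            if not 0 <= lvl <= 255:
                raise ValueError(f"intensity level {lvl} outside [0, 255]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        object.__setattr__(self, "cones", tuple(self.cones))


def _sample_cone_z(rng: np.random.Generator, r0: float, m: float, z_max: float, n: int) -> np.ndarray:
    """Sample heights on a linear-taper surface uniformly by lateral area.

    The lateral area element is proportional to the local radius
    r(z) = r0 + m z, so the height density is linear in z; inverting the CDF
    gives the quadratic root below.
    """
    u = rng.uniform(size=n)
    total = r0 * z_max + 0.5 * m * z_max**2
    if abs(m) < 1e-12:
        return u * total / r0
    disc = np.clip(r0**2 + 2.0 * m * u * total, 0.0, None)
    return (np.sqrt(disc) - r0) / m


def make_sensillum_cloud(spec: ConeSpec, seed: int, *, chamber: int = 1,
                         condition: str = "unknown", sensillum_id: str = "s0") -> SensillumCloud:
    """Sample ``spec.points_n`` points on the cone surface.

    Points are drawn uniformly by area on the lateral surface (slice point
    density ~constant, mimicking cuticle-surface contours), rotated so the
    cone axis maps onto ``spec.axis_direction``, translated by
    ``spec.apex_offset``, then jittered with isotropic Gaussian noise.
    """
    rng = np.random.default_rng(seed)
    r0 = spec.base_width / 2.0
    m = spec.taper_slope / 2.0  # d(radius)/dz
    z_max = spec.effective_height
    z = _sample_cone_z(rng, r0, m, z_max, spec.points_n)
    radius = np.clip(r0 + m * z, 0.0, None)
    theta = rng.uniform(0.0, 2.0 * np.pi, size=spec.points_n)
    pts = np.column_stack([radius * np.cos(theta), radius * np.sin(theta), z])
    rot = rotation_between([0.0, 0.0, 1.0], spec.axis_direction)
    pts = pts @ rot.T + np.asarray(spec.apex_offset, dtype=float)
    if spec.noise_sd > 0:
        pts = pts + rng.normal(scale=spec.noise_sd, size=pts.shape)
    meta = {"truth": spec.to_dict(), "seed": seed, "axis_true": list(np.asarray(spec.axis_direction) / np.linalg.norm(spec.axis_direction))}
    return SensillumCloud(points=pts, chamber=chamber, condition=condition,
                          sensillum_id=sensillum_id, metadata=meta)


def _cone_occupancy(spec: ConeSpec, coords_um: np.ndarray) -> np.ndarray:
    """Boolean solid-cone membership for an (n, 3) array of µm coordinates."""
    rot = rotation_between([0.0, 0.0, 1.0], spec.axis_direction)
    local = (coords_um - np.asarray(spec.apex_offset, dtype=float)) @ rot
    z = local[:, 2]
    radius = np.clip((spec.base_width + spec.taper_slope * z) / 2.0, 0.0, None)
    inside_z = (z >= 0.0) & (z <= spec.effective_height)
    return inside_z & (local[:, 0] ** 2 + local[:, 1] ** 2 <= radius**2)


def make_phantom_stack(spec: PhantomStackSpec) -> tuple[ImageStack, LabelStack]:
    """Render the voxelized union of cones plus its exact binary occupancy.

    A voxel is foreground iff its **center** lies inside some cone. Noise-free
    foreground voxels have image intensity exactly ``foreground_level``.
    """
    rows, cols = spec.section_shape
    g = spec.geometry
    # voxel centers in µm
    zc = (np.arange(spec.sections_n) + 0.5) * g.slice_z / 1000.0
    yc = (np.arange(rows) + 0.5) * g.pixel_y / 1000.0
    xc = (np.arange(cols) + 0.5) * g.pixel_x / 1000.0
    zz, yy, xx = np.meshgrid(zc, yc, xc, indexing="ij")
    coords = np.column_stack([xx.ravel(), yy.ravel(), zz.ravel()])
    occupancy = np.zeros(coords.shape[0], dtype=bool)
    vol_max = np.array([xc[-1] + 0.5 * g.pixel_x / 1000.0,
                        yc[-1] + 0.5 * g.pixel_y / 1000.0,
                        zc[-1] + 0.5 * g.slice_z / 1000.0])
    for cone in spec.cones:
        occupancy |= _cone_occupancy(cone, coords)
        # cheap out-of-volume check on the cone's bounding sphere
        center = np.asarray(cone.apex_offset) + np.asarray(cone.axis_direction, dtype=float) / np.linalg.norm(cone.axis_direction) * cone.effective_height / 2.0
        reach = np.hypot(cone.base_width / 2.0, cone.effective_height / 2.0)
        if (center - reach < 0).any() or (center + reach > vol_max).any():
            warnings.warn("cone may extend outside the phantom volume; it will be clipped",
                          stacklevel=2)
    labels = occupancy.reshape(spec.sections_n, rows, cols).astype(np.uint8)
    images = np.where(labels > 0, float(spec.foreground_level), float(spec.background_level))
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        images = images + rng.normal(scale=spec.noise_sd, size=images.shape)
    images = np.clip(np.rint(images), 0, 255).astype(np.uint8)
    meta = {"truth": {"cones": [c.to_dict() for c in spec.cones],
                      "background_level": spec.background_level,
                      "foreground_level": spec.foreground_level,
                      "noise_sd": spec.noise_sd, "seed": spec.seed}}
    return (ImageStack(sections=images, geometry=g, metadata=dict(meta)),
            LabelStack(sections=labels, geometry=g, metadata=dict(meta)))


def make_split_resolution_pair(spec: PhantomStackSpec, break_index: int,
                               coarse_pixel_nm: float, shift_px: tuple[float, float],
                               ) -> tuple[ImageStack, ImageStack]:
    """Emulate an interrupted acquisition resumed at a coarser XY pixel size.

    Set 1 holds the sections before ``break_index`` at the spec's (fine) pixel
    size. Set 2 holds the remaining sections resampled to ``coarse_pixel_nm``
    and translated by ``shift_px`` — the displacement expressed in **fine**
    pixels, recorded in Set 2 metadata as ``true_shift_fine_px`` for recovery
    tests. With equal pixel sizes and zero shift, Set 2 is the bit-exact
    continuation of Set 1.
    """
    if not 0 < break_index < spec.sections_n:
        raise ValueError(f"break_index must be in (0, {spec.sections_n}), got {break_index}")
    fine = spec.geometry.pixel_x
    if coarse_pixel_nm < fine:
        raise ValueError("coarse_pixel_nm must be >= the fine pixel size")
    images, _ = make_phantom_stack(spec)
    set1 = ImageStack(sections=images.sections[:break_index].copy(), geometry=spec.geometry,
                      origin_index=0, metadata={"role": "set1"})
    tail = images.sections[break_index:]
    shift = np.asarray(shift_px, dtype=float)
    identity = coarse_pixel_nm == fine and not shift.any()
    if identity:
        coarse_sections = tail.copy()
    else:
        factor = fine / coarse_pixel_nm  # < 1: downsample
        shift_coarse = shift * (fine / coarse_pixel_nm)
        out = []
        for sec in tail.astype(float):
            coarse = _sk_rescale(sec, factor, anti_aliasing=True, preserve_range=True)
            if shift.any():
                coarse = np.real(np.fft.ifft2(ndimage.fourier_shift(np.fft.fft2(coarse), shift_coarse)))
            out.append(coarse)
        coarse_sections = np.stack(out)
    geom2 = VoxelGeometry(pixel_x=coarse_pixel_nm, pixel_y=coarse_pixel_nm,
                          slice_z=spec.geometry.slice_z)
    set2 = ImageStack(sections=coarse_sections, geometry=geom2, origin_index=break_index,
                      metadata={"role": "set2", "true_shift_fine_px": shift.tolist()})
    return set1, set2


def make_profile_dataset(n_sensilla_per_group: int, slopes: dict[str, float],
                         intercepts: dict[str, float], sensillum_sd: float,
                         residual_sd: float, heights_grid: np.ndarray, seed: int,
                         ) -> pd.DataFrame:
    """Draw (sensillum, group, height, width) rows from the linear mixed model.

    width = intercept(group) + slope(group)·height + b(sensillum) + ε with
    b ~ N(0, sensillum_sd²) and ε ~ N(0, residual_sd²). Ground truth is stored
    in ``DataFrame.attrs["truth"]``.
    """
    if n_sensilla_per_group < 2:
        raise ValueError("need at least 2 sensilla per group")
    if set(slopes) != set(intercepts):
        raise ValueError("slopes and intercepts must cover the same groups")
    rng = np.random.default_rng(seed)
    heights = np.asarray(heights_grid, dtype=float)
    rows = []
    for group in sorted(slopes):
        for i in range(n_sensilla_per_group):
            sid = f"{group}_s{i:02d}"
            b = rng.normal(scale=sensillum_sd) if sensillum_sd > 0 else 0.0
            eps = rng.normal(scale=residual_sd, size=heights.size) if residual_sd > 0 else 0.0
            width = intercepts[group] + slopes[group] * heights + b + eps
            for h, w in zip(heights, np.atleast_1d(width)):
                rows.append((sid, group, float(h), float(w)))
    df = pd.DataFrame(rows, columns=["sensillum_id", "group", "height", "width"])
    df.attrs["truth"] = {"slopes": dict(slopes), "intercepts": dict(intercepts),
                         "sensillum_sd": sensillum_sd, "residual_sd": residual_sd,
                         "seed": seed}
    return df
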