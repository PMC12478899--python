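"""Orient sensilla along +Z so height profiles are comparable.

Two routes, matching the two morphologies found in the sacculus:

* ``pca_orient`` — for elongated sensilla the covariance eigenvector with the
  largest eigenvalue is the length axis; it is rotated onto +Z by the minimal
  rotation and the wider end (the base) is placed at low z.
* ``ransac_register`` — for squat sensilla whose length and width are similar
  (the Chamber-2 morphology) PCA is ambiguous, so each cloud is registered to
  a synthetic cone target by feature-correspondence RANSAC: voxel
  downsampling, surface normals, point-feature histograms, random-sample
  rigid estimation with inlier maximization.

All transforms are strictly rigid (rotation + translation, no scaling) and
are appended to each cloud's provenance so the aligned cloud is reproducible
from the raw crop.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .clouds import SensillumCloud
from .synthgen import ConeSpec, make_sensillum_cloud
from .transforms import kabsch, rotation_about_axis, rotation_between

__all__ = [
    "RigidTransform",
    "AmbiguousAxisError",
    "center_cloud",
    "pca_orient",
    "make_cone_target",
    "ransac_register",
    "align_chamber",
]

log = logging.getLogger(__name__)

#: λ1/λ2 ratio below which the principal axis is considered ambiguous.
ELONGATION_THRESHOLD = 1.5


class AmbiguousAxisError(ValueError):
    """Near-isotropic covariance: use cone-target registration instead."""


@dataclass
class RigidTransform:
    """Rigid map p -> rotation @ p + translation with registration diagnostics."""

    rotation: np.ndarray
    translation: np.ndarray
    fitness: float = 1.0
    inlier_rmse: float = 0.0
    succeeded: bool = True

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        if self.rotation.shape != (3, 3):
            raise ValueError("rotation must be 3x3")
        if not np.isclose(np.linalg.det(self.rotation), 1.0, atol=1e-6):
            raise ValueError("rotation determinant must be +1")

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, dtype=float) @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self ∘ other: apply ``other`` first, then ``self``."""
        return RigidTransform(rotation=self.rotation @ other.rotation,
                              translation=self.rotation @ other.translation + self.translation,
                              fitness=self.fitness, inlier_rmse=self.inlier_rmse,
                              succeeded=self.succeeded and other.succeeded)

    @classmethod
    def identity(cls, **kw) -> "RigidTransform":
        return cls(rotation=np.eye(3), translation=np.zeros(3), **kw)

    def to_provenance(self) -> dict:
        return {"rotation": self.rotation.tolist(), "translation": self.translation.tolist()}


def center_cloud(cloud: SensillumCloud) -> tuple[SensillumCloud, RigidTransform]:
    """Translate the centroid to the origin."""
    t = RigidTransform(rotation=np.eye(3), translation=-cloud.centroid)
    return cloud.replace_points(t.apply(cloud.points), t.to_provenance()), t


def _principal_axes(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    cov = np.cov(points.T)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    return evals[order], evecs[:, order]


def _base_at_low_z(points: np.ndarray) -> bool:
    """True if the bottom-quartile z slab is radially wider than the top one."""
    z = points[:, 2]
    qlo, qhi = np.quantile(z, [0.25, 0.75])
    r = np.hypot(points[:, 0], points[:, 1])
    return float(r[z <= qlo].mean()) >= float(r[z >= qhi].mean())


def pca_orient(cloud: SensillumCloud, elongation_threshold: float = ELONGATION_THRESHOLD,
               ) -> tuple[SensillumCloud, RigidTransform]:
    """Rotate the dominant covariance axis onto +Z, base (wider end) at low z.

    Requires an elongated shape: the leading eigenvalue must exceed the second
    by ``elongation_threshold``; otherwise the length axis is not identifiable
    from variance and an :class:`AmbiguousAxisError` is raised.
    """
    centered, t_center = center_cloud(cloud)
    pts = centered.points
    evals, evecs = _principal_axes(pts)
    if evals[1] <= 0 or evals[0] / evals[1] < elongation_threshold:
        ratio = evals[0] / evals[1] if evals[1] > 0 else np.inf
        raise AmbiguousAxisError(
            f"ambiguous axis: eigenvalue ratio {ratio:.2f} < {elongation_threshold}; "
            "register to a cone target instead")
    rot = rotation_between(evecs[:, 0], [0.0, 0.0, 1.0])
    pts = pts @ rot.T
    if not _base_at_low_z(pts):
        flip = rotation_about_axis([1.0, 0.0, 0.0], np.pi)
        rot = flip @ rot
        pts = pts @ flip.T
    t = RigidTransform(rotation=rot, translation=np.zeros(3))
    oriented = centered.replace_points(pts, t.to_provenance())
    return oriented, t.compose(t_center)


def make_cone_target(base_width: float, height: float, points_n: int = 2000,
                     seed: int = 0) -> SensillumCloud:
    """Cone-surface target, axis +Z, base at z = 0, apex at z = height."""
    spec = ConeSpec(base_width=base_width, height=height,
                    taper_slope=-base_width / height, points_n=points_n)
    cloud = make_sensillum_cloud(spec, seed=seed, chamber=2, sensillum_id="cone_target")
    return cloud


# -- feature-based global registration ---------------------------------------

def _voxel_downsample(points: np.ndarray, voxel: float) -> np.ndarray:
    """Average points falling into the same cubic voxel."""
    keys = np.floor(points / voxel).astype(np.int64)
    _, inverse = np.unique(keys, axis=0, return_inverse=True)
    n = inverse.max() + 1
    sums = np.zeros((n, 3))
    counts = np.zeros(n)
    np.add.at(sums, inverse, points)
    np.add.at(counts, inverse, 1.0)
    return sums / counts[:, None]


def _normals(points: np.ndarray, k: int = 12) -> np.ndarray:
    """Surface normals from local PCA, oriented away from the cloud centroid."""
    tree = cKDTree(points)
    k = min(k, len(points))
    _, idx = tree.query(points, k=k)
    normals = np.empty_like(points)
    centroid = points.mean(axis=0)
    for i, nb in enumerate(idx):
        local = points[nb] - points[nb].mean(axis=0)
        _, _, vt = np.linalg.svd(local, full_matrices=False)
        n = vt[-1]
        if np.dot(n, points[i] - centroid) < 0:
            n = -n
        normals[i] = n
    return normals


def _point_features(points: np.ndarray, normals: np.ndarray, k: int = 12,
                    bins: int = 11) -> np.ndarray:
    """Per-point histograms of the Darboux-frame angles with k neighbours.

    For each neighbour pair the three classic angles (alpha, phi, theta) are
    binned into ``bins`` bins each and concatenated into a 3*bins descriptor.
    Rotation-invariant, so it survives the arbitrary orientations of crops.
    """
    tree = cKDTree(points)
    k = min(k + 1, len(points))
    _, idx = tree.query(points, k=k)
    feats = np.zeros((len(points), 3 * bins))
    for i, nb in enumerate(idx):
        nb = nb[nb != i]
        d = points[nb] - points[i]
        dist = np.linalg.norm(d, axis=1)
        keep = dist > 1e-12
        if not keep.any():
            continue
        d = d[keep] / dist[keep, None]
        u = normals[i]
        v = np.cross(d, u)
        vn = np.linalg.norm(v, axis=1)
        ok = vn > 1e-12
        if not ok.any():
            continue
        v = v[ok] / vn[ok, None]
        d = d[ok]
        nq = normals[nb[keep][ok]]
        w = np.cross(u, v)
        alpha = np.einsum("ij,ij->i", v, nq)
        phi = d @ u
        theta = np.arctan2(np.einsum("ij,ij->i", w, nq), nq @ u)
        h1, _ = np.histogram(alpha, bins=bins, range=(-1, 1))
        h2, _ = np.histogram(phi, bins=bins, range=(-1, 1))
        h3, _ = np.histogram(theta, bins=bins, range=(-np.pi, np.pi))
        f = np.concatenate([h1, h2, h3]).astype(float)
        feats[i] = f / f.sum()
    return feats


def ransac_register(moving: SensillumCloud, target: SensillumCloud, voxel: float,
                    seed: int = 0, n_iterations: int = 2000,
                    distance_factor: float = 1.5, fitness_floor: float = 0.2,
                    ) -> tuple[SensillumCloud, RigidTransform]:
    """Global rigid registration of ``moving`` onto ``target``.

    Both clouds are voxel-downsampled; putative correspondences come from
    nearest neighbours in point-feature-histogram space; RANSAC samples
    3-point subsets, estimates a rigid transform by least squares, and keeps
    the transform with the most correspondences within ``distance_factor *
    voxel``. The winning transform is re-estimated from all inliers and
    applied to the full-resolution moving cloud. If the final fitness falls
    below ``fitness_floor`` the cloud is returned untransformed with
    ``succeeded=False``.
    """
    if voxel <= 0:
        raise ValueError("voxel must be positive")
    rng = np.random.default_rng(seed)
    down_m = _voxel_downsample(moving.points, voxel)
    down_t = _voxel_downsample(target.points, voxel)
    if len(down_m) < 4 or len(down_t) < 4:
        raise ValueError("too few points after downsampling; reduce voxel size")
    norm_m = _normals(down_m)
    norm_t = _normals(down_t)
    feat_m = _point_features(down_m, norm_m)
    feat_t = _point_features(down_t, norm_t)
    corr = cKDTree(feat_t).query(feat_m, k=1)[1]
    corr_pts = down_t[corr]
    thresh = distance_factor * voxel
    tree_t = cKDTree(down_t)
    n = len(down_m)
    # cheap scoring subset; the winning hypothesis is re-scored on all points
    score_idx = rng.choice(n, size=min(n, 150), replace=False)

    best_score = -1
    best_rt: tuple[np.ndarray, np.ndarray] | None = None
    for _ in range(n_iterations):
        sample = rng.choice(n, size=3, replace=False)
        src = down_m[sample]
        dst = corr_pts[sample]
        # prune samples whose pairwise distances disagree (not rigid-compatible)
        # or whose triangle is too small to pin down a rotation
        ds = np.linalg.norm(src - np.roll(src, 1, axis=0), axis=1)
        dt = np.linalg.norm(dst - np.roll(dst, 1, axis=0), axis=1)
        if (np.abs(ds - dt) > 2 * thresh).any() or ds.min() < 2 * voxel:
            continue
        r, t = kabsch(src, dst)
        moved = down_m[score_idx] @ r.T + t
        score = int((tree_t.query(moved)[0] < thresh).sum())
        if score > best_score:
            best_score = score
            best_rt = (r, t)
            if score > 0.95 * len(score_idx):
                break
    if best_rt is None:
        log.warning("registration failed for %s: no consistent correspondence set",
                    moving.sensillum_id)
        return moving, RigidTransform.identity(fitness=0.0, inlier_rmse=np.inf,
                                               succeeded=False)
    # re-estimate from all nearest-neighbour inliers of the winning hypothesis
    r, t = best_rt
    for _ in range(3):
        moved = down_m @ r.T + t
        dist, nn = tree_t.query(moved)
        inl = dist < thresh
        if inl.sum() < 3:
            break
        r, t = kabsch(down_m[inl], down_t[nn[inl]])
    moved = down_m @ r.T + t
    resid = tree_t.query(moved)[0]
    inliers = resid < thresh
    fitness = float(inliers.mean())
    rmse = float(np.sqrt(np.mean(resid[inliers] ** 2))) if inliers.any() else np.inf
    if fitness < fitness_floor:
        log.warning("registration failed for %s: fitness %.3f < %.3f",
                    moving.sensillum_id, fitness, fitness_floor)
        return moving, RigidTransform.identity(fitness=fitness, inlier_rmse=rmse,
                                               succeeded=False)
    transform = RigidTransform(rotation=r, translation=t, fitness=fitness,
                               inlier_rmse=rmse)
    out = moving.replace_points(transform.apply(moving.points), transform.to_provenance())
    return out, transform


def _default_voxel(points: np.ndarray) -> float:
    # 4% of the bounding-box diagonal: coarse enough to erase the per-section
    # contour-ring anisotropy of reconstructed clouds (at 2% the downsampled
    # cloud keeps the ring structure and normal estimates degrade)
    bbox = points.max(axis=0) - points.min(axis=0)
    return 0.04 * float(np.linalg.norm(bbox))


def align_chamber(clouds: list[SensillumCloud], strategy: str = "pca_then_ransac",
                  seed: int = 0, voxel: float | None = None,
                  cone_dims: tuple[float, float] | None = None,
                  ) -> list[tuple[SensillumCloud, RigidTransform]]:
    """Align every sensillum of a chamber onto a common +Z frame.

    ``pca_then_ransac``: the cloud with the highest eigenvalue ratio is
    PCA-oriented and serves as the registration target for the rest.
    ``cone_target``: all clouds register to a synthetic cone whose base/height
    default to the median bounding-box dimensions of the crops (the Chamber-2
    route). Per-cloud failures are recorded, not raised, so one bad crop does
    not abort the batch.
    """
    if not clouds:
        raise ValueError("align_chamber requires at least one cloud")
    if strategy not in ("pca_then_ransac", "cone_target"):
        raise ValueError(f"unknown strategy {strategy!r}")
    results: list[tuple[SensillumCloud, RigidTransform]] = []
    if strategy == "pca_then_ransac":
        ratios = []
        for c in clouds:
            evals, _ = _principal_axes(c.points - c.centroid)
            ratios.append(evals[0] / max(evals[1], 1e-12))
        rep = int(np.argmax(ratios))
        oriented_rep, t_rep = pca_orient(clouds[rep])
        for i, c in enumerate(clouds):
            if i == rep:
                results.append((oriented_rep, t_rep))
                continue
            centered, t_c = center_cloud(c)
            vox = voxel if voxel is not None else _default_voxel(centered.points)
            try:
                aligned, t_r = ransac_register(centered, oriented_rep, vox, seed=seed + i)
            except ValueError as exc:
                log.warning("alignment failed for %s: %s", c.sensillum_id, exc)
                aligned, t_r = centered, RigidTransform.identity(fitness=0.0, succeeded=False)
            results.append((aligned, t_r.compose(t_c)))
    else:
        if cone_dims is None:
            spans = np.stack([c.points.max(axis=0) - c.points.min(axis=0) for c in clouds])
            med = np.median(spans, axis=0)
            cone_dims = (float((med[0] + med[1]) / 2.0), float(med[2]))
        target = make_cone_target(cone_dims[0], cone_dims[1], seed=seed)
        # cone target has base at z=0; center it to match centered moving clouds
        target, _ = center_cloud(target)
        for i, c in enumerate(clouds):
            centered, t_c = center_cloud(c)
            vox = voxel if voxel is not None else _default_voxel(centered.points)
            try:
                aligned, t_r = ransac_register(centered, target, vox, seed=seed + i)
            except ValueError as exc:
                log.warning("alignment failed for %s: %s", c.sensillum_id, exc)
                aligned, t_r = centered, RigidTransform.identity(fitness=0.0, succeeded=False)
            results.append((aligned, t_r.compose(t_c)))
    return results
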