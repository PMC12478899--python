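"""End-to-end orchestration: synth → harmonize → segment → reconstruct →
align → morpho → stats, from one JSON-serializable config.

Every stage reads what the previous stage wrote, so any stage can be disabled
and its outputs supplied externally. A run manifest records the config, the
seed, per-stage outputs and wall time.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import align as align_mod
from . import harmonize as harm_mod
from . import morpho as morpho_mod
from . import reconstruct as recon_mod
from . import segment as seg_mod
from . import stats as stats_mod
from .clouds import SensillumCloud, write_cloud
from .geometry import ImageStack, VoxelGeometry, read_stack, write_stack
from .synthgen import (DEFAULT_CHAMBER_PARAMS, ConeSpec, PhantomStackSpec,
                       make_phantom_stack, make_sensillum_cloud,
                       make_split_resolution_pair)
from .transforms import rotation_about_axis, rotation_between

__all__ = ["RunConfig", "default_config", "run", "demo_dataset"]

log = logging.getLogger(__name__)

CONDITIONS = ("high_RH", "low_RH")
CHAMBERS = (1, 2, 3)


@dataclass
class RunConfig:
    """One pipeline run: stage toggles, per-stage parameters, seed, paths."""

    out_dir: str
    seed: int = 0
    stages: dict = field(default_factory=lambda: {
        "synth": True, "harmonize": True, "segment": True, "reconstruct": True,
        "align": True, "morpho": True, "stats": True})
    synth: dict = field(default_factory=dict)
    harmonize: dict = field(default_factory=dict)
    segment: dict = field(default_factory=dict)
    reconstruct: dict = field(default_factory=dict)
    align: dict = field(default_factory=dict)
    morpho: dict = field(default_factory=dict)
    stats: dict = field(default_factory=dict)

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        return cls(**json.loads(Path(path).read_text()))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))


def default_config(out_dir: str, seed: int = 0) -> RunConfig:
    """Desk-scale defaults: 2 conditions × 3 chambers × 4 sensilla phantoms.

    Voxel pitch 200 nm XY / 150 nm Z keeps each stack around 64² × ~50
    sections so the full pipeline completes in about a minute; cone
    dimensions per chamber and condition follow
    :data:`~sensillum3d.synthgen.DEFAULT_CHAMBER_PARAMS`.
    """
    return RunConfig(
        out_dir=out_dir,
        seed=seed,
        synth={
            "n_sensilla": 4,
            "pixel_nm": 200.0,
            "slice_nm": 150.0,
            "background_level": 50,
            "foreground_level": 200,
            "noise_sd": 8.0,
            "width_sd": 0.13,        # per-sensillum base-width variability (µm)
            "tilt_max_deg": 6.0,
            "split_break_fraction": 0.5,
            "split_coarse_factor": 1.4118,
            "split_shift_px": [4.0, -2.0],
        },
        harmonize={"upsample_factor": 10},
        segment={"method": "threshold"},
        reconstruct={"include_holes": True, "crop_margin_um": 0.45},
        align={"voxel": None},
        morpho={"n_slices": 60, "window": 5},
        stats={},
    )


# -- synth stage ---------------------------------------------------------------

def _chamber_layout(n: int, fov_um: float, margin_um: float) -> list[tuple[float, float]]:
    """XY grid positions for n cones inside a square field of view."""
    side = int(np.ceil(np.sqrt(n)))
    coords = np.linspace(margin_um, fov_um - margin_um, side)
    return [(coords[i % side], coords[i // side]) for i in range(n)]


def _synth_stage(cfg: RunConfig, out: Path) -> dict:
    """Render one phantom stack per condition × chamber plus ground truth."""
    p = cfg.synth
    rng = np.random.default_rng(cfg.seed)
    stack_dir = out / "stacks"
    stack_dir.mkdir(parents=True, exist_ok=True)
    outputs = {}
    truth_all = {}
    for condition in CONDITIONS:
        for chamber in CHAMBERS:
            base, slope, height = DEFAULT_CHAMBER_PARAMS[(chamber, condition)]
            n = p["n_sensilla"]
            margin = base / 2 + 1.0
            side = int(np.ceil(np.sqrt(n)))
            fov = side * (base + 2.0) + 1.2
            cols = int(np.ceil(fov * 1000 / p["pixel_nm"]))
            cols += -cols % 8  # friendly canvas size
            fov = cols * p["pixel_nm"] / 1000.0
            sections = int(np.ceil((height + 1.0) * 1000 / p["slice_nm"]))
            geometry = VoxelGeometry(pixel_x=p["pixel_nm"], pixel_y=p["pixel_nm"],
                                     slice_z=p["slice_nm"])
            cones, truths = [], []
            for i, (cx, cy) in enumerate(_chamber_layout(n, fov, margin)):
                w = max(0.5, base + rng.normal(scale=p["width_sd"]))
                tilt = np.radians(rng.uniform(0, p["tilt_max_deg"]))
                azim = rng.uniform(0, 2 * np.pi)
                axis = (np.sin(tilt) * np.cos(azim), np.sin(tilt) * np.sin(azim),
                        np.cos(tilt))
                cone = ConeSpec(base_width=w, height=height, taper_slope=slope,
                                axis_direction=axis, apex_offset=(cx, cy, 0.3),
                                points_n=1500)
                cones.append(cone)
                truths.append({"id": f"{condition}_c{chamber}_s{i}",
                               "cone": cone.to_dict()})
            spec = PhantomStackSpec(
                sections_n=sections, section_shape=(cols, cols), geometry=geometry,
                cones=tuple(cones), background_level=p["background_level"],
                foreground_level=p["foreground_level"], noise_sd=p["noise_sd"],
                seed=int(rng.integers(2**31 - 1)))
            images, labels = make_phantom_stack(spec)
            key = f"{condition}_c{chamber}"
            write_stack(images, stack_dir / f"{key}.tif")
            write_stack(labels, stack_dir / f"{key}_labels.tif")
            truth_all[key] = truths
            outputs[key] = str(stack_dir / f"{key}.tif")
            # the high-RH acquisition was interrupted: store the split pair too
            if condition == "high_RH":
                break_index = max(1, int(sections * p["split_break_fraction"]))
                coarse = p["pixel_nm"] * p["split_coarse_factor"]
                set1, set2 = make_split_resolution_pair(
                    spec, break_index, coarse, tuple(p["split_shift_px"]))
                write_stack(set1, stack_dir / f"{key}_set1.tif")
                write_stack(set2, stack_dir / f"{key}_set2.tif")
    (stack_dir / "truth.json").write_text(json.dumps(truth_all, indent=2))
    return outputs


# -- remaining stages ----------------------------------------------------------

def _harmonize_stage(cfg: RunConfig, out: Path) -> dict:
    """Merge each high-RH split pair back onto the fine grid."""
    stack_dir = out / "stacks"
    harm_dir = out / "harmonized"
    harm_dir.mkdir(parents=True, exist_ok=True)
    reports = {}
    for chamber in CHAMBERS:
        key = f"high_RH_c{chamber}"
        set1 = read_stack(stack_dir / f"{key}_set1.tif")
        set2 = read_stack(stack_dir / f"{key}_set2.tif")
        merged, report = harm_mod.merge_stacks(
            set1, set2, upsample_factor=cfg.harmonize.get("upsample_factor", 10))
        write_stack(merged, harm_dir / f"{key}.tif")
        report["true_shift_fine_px"] = set2.metadata.get("true_shift_fine_px")
        reports[key] = report
    (harm_dir / "alignment_report.json").write_text(json.dumps(reports, indent=2))
    return reports


def _segment_stage(cfg: RunConfig, out: Path) -> dict:
    """Binary masks for every condition × chamber stack."""
    stack_dir = out / "stacks"
    mask_dir = out / "masks"
    mask_dir.mkdir(parents=True, exist_ok=True)
    method = cfg.segment.get("method", "threshold")
    outputs = {}
    harm_dir = out / "harmonized"
    for condition in CONDITIONS:
        for chamber in CHAMBERS:
            key = f"{condition}_c{chamber}"
            # the high-RH volume goes through harmonization first, as in the
            # original acquisition; low RH was imaged without interruption
            source = harm_dir / f"{key}.tif"
            if condition == "high_RH" and cfg.stages.get("harmonize", True) and source.exists():
                images = read_stack(source)
            else:
                images = read_stack(stack_dir / f"{key}.tif")
            if method == "threshold":
                level = cfg.segment.get("level")
                if level is None:
                    level = 0.5 * (float(images.sections.min()) + float(images.sections.max()))
                masks = seg_mod.threshold_segment(images, level)
            elif method == "unet":
                labels = read_stack(stack_dir / f"{key}_labels.tif")
                tc = seg_mod.TrainConfig(**cfg.segment.get("train", {}),
                                         seed=cfg.seed)
                model, _metrics = seg_mod.train_unet(images, labels, tc)
                masks = seg_mod.predict_masks(model, images)
            else:
                raise ValueError(f"unknown segmentation method {method!r}")
            write_stack(masks, mask_dir / f"{key}.tif")
            outputs[key] = str(mask_dir / f"{key}.tif")
    return outputs


def _crop_box_from_truth(cone: dict, margin: float) -> tuple[np.ndarray, np.ndarray]:
    """Axis-aligned box around a ground-truth cone, from its noise-free surface."""
    spec = ConeSpec(**{k: tuple(v) if isinstance(v, list) else v
                       for k, v in cone.items()})
    pts = make_sensillum_cloud(spec, seed=0).points
    return pts.min(axis=0) - margin, pts.max(axis=0) + margin


def _reconstruct_stage(cfg: RunConfig, out: Path) -> dict:
    mask_dir = out / "masks"
    crop_dir = out / "crops"
    crop_dir.mkdir(parents=True, exist_ok=True)
    truth = json.loads((out / "stacks" / "truth.json").read_text())
    margin = cfg.reconstruct.get("crop_margin_um", 0.45)
    outputs = {}
    for condition in CONDITIONS:
        for chamber in CHAMBERS:
            key = f"{condition}_c{chamber}"
            masks = read_stack(mask_dir / f"{key}.tif")
            cloud = recon_mod.reconstruct_cloud(
                masks, condition=condition,
                include_holes=cfg.reconstruct.get("include_holes", True))
            write_cloud(cloud, crop_dir / f"{key}_sacculus.ply")
            for entry in truth[key]:
                box = _crop_box_from_truth(entry["cone"], margin)
                sens = recon_mod.crop_sensillum(cloud, box, chamber, entry["id"])
                sens.metadata["truth"] = entry["cone"]
                write_cloud(sens, crop_dir / f"{entry['id']}.ply")
                outputs[entry["id"]] = str(crop_dir / f"{entry['id']}.ply")
    return outputs


def _align_stage(cfg: RunConfig, out: Path) -> dict:
    from .clouds import read_cloud
    crop_dir = out / "crops"
    aligned_dir = out / "aligned"
    aligned_dir.mkdir(parents=True, exist_ok=True)
    truth = json.loads((out / "stacks" / "truth.json").read_text())
    transforms = {}
    for condition in CONDITIONS:
        for chamber in CHAMBERS:
            key = f"{condition}_c{chamber}"
            clouds = [read_cloud(crop_dir / f"{e['id']}.ply") for e in truth[key]]
            strategy = "cone_target" if chamber == 2 else "pca_then_ransac"
            results = align_mod.align_chamber(clouds, strategy=strategy,
                                              seed=cfg.seed,
                                              voxel=cfg.align.get("voxel"))
            for cloud, tf in results:
                write_cloud(cloud, aligned_dir / f"{cloud.sensillum_id}.ply")
                transforms[cloud.sensillum_id] = {
                    "rotation": tf.rotation.tolist(),
                    "translation": tf.translation.tolist(),
                    "fitness": tf.fitness, "inlier_rmse": float(tf.inlier_rmse),
                    "succeeded": tf.succeeded, "strategy": strategy,
                    "seed": cfg.seed}
    (aligned_dir / "transforms.json").write_text(json.dumps(transforms, indent=2))
    return transforms


def _morpho_stage(cfg: RunConfig, out: Path) -> dict:
    from .clouds import read_cloud
    aligned_dir = out / "aligned"
    truth = json.loads((out / "stacks" / "truth.json").read_text())
    profile_rows, fwhm_rows = [], []
    for condition in CONDITIONS:
        for chamber in CHAMBERS:
            for entry in truth[f"{condition}_c{chamber}"]:
                cloud = read_cloud(aligned_dir / f"{entry['id']}.ply")
                _raw, smoothed, record = morpho_mod.profile_sensillum(
                    cloud, n_slices=cfg.morpho.get("n_slices", 60),
                    window=cfg.morpho.get("window", 5))
                rel = smoothed.heights - smoothed.heights[0]
                for h, w in zip(rel, smoothed.widths):
                    profile_rows.append((entry["id"], chamber, condition,
                                         float(h), float(w), True))
                fwhm_rows.append((entry["id"], chamber, condition,
                                  record.height_total, record.width_at_half_height))
    profiles = pd.DataFrame(profile_rows, columns=[
        "sensillum_id", "chamber", "condition", "height_um", "width_um", "smoothed"])
    fwhm = pd.DataFrame(fwhm_rows, columns=[
        "sensillum_id", "chamber", "condition", "height_total_um",
        "width_at_half_height_um"])
    profiles.to_csv(out / "profiles.csv", index=False)
    fwhm.to_csv(out / "fwhm.csv", index=False)
    return {"profiles": str(out / "profiles.csv"), "fwhm": str(out / "fwhm.csv"),
            "n_profiles": int(profiles["sensillum_id"].nunique()),
            "n_fwhm": len(fwhm)}


def _stats_stage(cfg: RunConfig, out: Path) -> dict:
    profiles = pd.read_csv(out / "profiles.csv")
    fwhm = pd.read_csv(out / "fwhm.csv")
    stats_dir = out / "stats"
    stats_dir.mkdir(parents=True, exist_ok=True)
    models = {}
    comparisons = []
    for chamber in sorted(profiles["chamber"].unique()):
        sub = profiles[profiles["chamber"] == chamber].rename(
            columns={"condition": "group", "height_um": "height", "width_um": "width"})
        res = stats_mod.fit_mixed(sub[["sensillum_id", "group", "height", "width"]])
        models[int(chamber)] = {
            "slopes": res.slopes, "intercepts": res.intercepts,
            "slope_ci": {k: list(v) for k, v in res.slope_ci.items()},
            "random_intercept_sd": res.random_intercept_sd,
            "residual_sd": res.residual_sd, "converged": res.converged}
        rec = fwhm[fwhm["chamber"] == chamber].rename(
            columns={"width_at_half_height_um": "width_at_half_height"})
        comp = stats_mod.compare_fwhm(rec, chamber=chamber)
        comparisons.append({"chamber": int(chamber), "U": comp.statistic_U,
                            "p_value": comp.p_value, "median_diff": comp.median_diff,
                            "n_high": comp.n_high, "n_low": comp.n_low,
                            "method": comp.method})
    (stats_dir / "models.json").write_text(json.dumps(models, indent=2))
    comp_df = pd.DataFrame(comparisons)
    comp_df.to_csv(stats_dir / "comparisons.csv", index=False)
    summary = stats_mod.summarize_conditions(
        profiles.rename(columns={"height_um": "height", "width_um": "width"}),
        fwhm.rename(columns={"width_at_half_height_um": "width_at_half_height"}))
    summary.to_csv(stats_dir / "summary.csv", index=False)
    report_lines = ["Per-chamber condition comparison", "=" * 40]
    for _, row in summary.iterrows():
        report_lines.append(
            f"chamber {row['chamber']} {row['condition']:>8}: n={row['n']} "
            f"mean width={row['mean_width']:.3f} µm, median half-height width="
            f"{row['median_fwhm']:.3f} µm {row['significance']}")
    (stats_dir / "report.txt").write_text("\n".join(report_lines) + "\n")
    return {"models": models, "comparisons": comparisons,
            "summary": str(stats_dir / "summary.csv")}


_STAGES = [
    ("synth", _synth_stage),
    ("harmonize", _harmonize_stage),
    ("segment", _segment_stage),
    ("reconstruct", _reconstruct_stage),
    ("align", _align_stage),
    ("morpho", _morpho_stage),
    ("stats", _stats_stage),
]


def run(config: RunConfig) -> dict:
    """Execute the enabled stages in order; returns (and writes) the manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": asdict(config), "seed": config.seed, "stages": {}}
    t_total = time.time()
    for name, fn in _STAGES:
        if not config.stages.get(name, True):
            manifest["stages"][name] = {"status": "skipped"}
            continue
        t0 = time.time()
        log.info("stage %s ...", name)
        try:
            outputs = fn(config, out)
        except Exception as exc:
            manifest["stages"][name] = {"status": "failed", "error": str(exc)}
            (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
            raise RuntimeError(f"pipeline halted at stage {name!r}: {exc}") from exc
        manifest["stages"][name] = {"status": "completed",
                                    "wall_s": round(time.time() - t0, 2),
                                    "outputs": outputs}
    manifest["wall_s_total"] = round(time.time() - t_total, 2)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def demo_dataset(out_dir: str | Path = "demo_run", seed: int = 0) -> Path:
    """Run the full desk-scale demo (2 conditions × 3 chambers × 4 sensilla)."""
    cfg = default_config(str(out_dir), seed=seed)
    run(cfg)
    return Path(out_dir)
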