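"""End-to-end reproducible runs: config, seeding, logging, reporting.

A :class:`RunConfig` (validated, YAML round-trippable) drives the full
phantom → segmentation → morphometry → density-map → perfusion workflow.
Every stochastic stage carries an explicit seed; the run report records
every parameter, chosen threshold, seed and output checksum, so an
identical config reproduces an identical report (modulo the timestamp).
"""

from __future__ import annotations

import hashlib
import json
import logging
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import yaml
from pydantic import BaseModel, Field, ValidationError, model_validator

from . import density_maps as dm
from . import morphometry as mm
from . import phantoms as ph
from . import sampling_stats as ss
from . import segmentation as seg
from . import volume_io as vio

__all__ = ["RunConfig", "ConfigError", "run_pipeline", "load_config"]

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Invalid run configuration; message lists the offending keys."""


class PhantomConfig(BaseModel):
    root_radius_um: float = ph.DEFAULT_ROOT_RADIUS_UM
    depth: int = ph.DEFAULT_DEPTH
    branch_angle_deg: float = ph.DEFAULT_BRANCH_ANGLE_DEG
    tortuosity_amplitude_um: float = 2.0
    murray_exponent: float = 3.0
    voxel_size_um: float = Field(gt=0)
    noise_sigma: float = 10.0
    fg_intensity: float = 200.0
    bg_intensity: float = 50.0
    seed: int = 0


class SegmentationConfig(BaseModel):
    method: str = "otsu"
    fixed_value: float | None = None
    min_voxels: int = seg.DEFAULT_MIN_VOXELS
    tissue: str = "bounding_hull"  # "bounding_hull" | "full_volume"

    @model_validator(mode="after")
    def _check(self):
        if self.method not in ("otsu", "fixed"):
            raise ValueError("segmentation.method must be 'otsu' or 'fixed'")
        if self.method == "fixed" and self.fixed_value is None:
            raise ValueError("segmentation.fixed_value required for fixed method")
        if self.tissue not in ("bounding_hull", "full_volume"):
            raise ValueError("segmentation.tissue must be bounding_hull or full_volume")
        return self


class MorphometryConfig(BaseModel):
    n_sections: int = 20
    axis: int = 0
    min_area_px: int = 2
    border_policy: str = "exclude"
    bin_width_um: float = mm.DEFAULT_BIN_WIDTH_UM


class DensitySceneConfig(BaseModel):
    extent_um: tuple[float, float] = (1000.0, 1000.0)
    fiber_pitch_um: float = 50.0
    capillaries_per_fiber: float = 1.5
    kernel_size_um: float = 150.0
    stride_um: float | None = None
    seed: int = 0


class PerfusionConfig(BaseModel):
    true_props: tuple[float, float, float] = (0.91, 0.07, 0.02)
    n_animals: int = 3
    sections_per_animal: int = 3
    fovs_per_section: int = 4
    capillaries_per_fov: int = 105
    seed: int = 0


class RunConfig(BaseModel):
    """Full pipeline configuration; round-trips losslessly through YAML."""

    name: str = "run"
    output_dir: Path
    phantom: PhantomConfig
    segmentation: SegmentationConfig = SegmentationConfig()
    morphometry: MorphometryConfig = MorphometryConfig()
    density: DensitySceneConfig = DensitySceneConfig()
    perfusion: PerfusionConfig = PerfusionConfig()

    def to_yaml(self, path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(json.loads(self.model_dump_json())))
        return path

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        try:
            return cls.model_validate(yaml.safe_load(Path(path).read_text()))
        except ValidationError as e:  # re-raise with offending keys listed
            raise ConfigError(_format_validation_error(e)) from e


def _format_validation_error(e: ValidationError) -> str:
    keys = [".".join(str(p) for p in err["loc"]) for err in e.errors()]
    return "invalid configuration keys: " + ", ".join(keys)


def load_config(path) -> RunConfig:
    return RunConfig.from_yaml(path)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute phantom → segment → morphometry → density → perfusion.

    Returns the run report (also written to ``report.json`` in the output
    directory) containing every parameter, seed and threshold used, the
    computed quantities, and a checksum for every output file.
    """
    if isinstance(config, dict):
        try:
            config = RunConfig.model_validate(config)
        except ValidationError as e:
            raise ConfigError(_format_validation_error(e)) from e
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    files: dict[str, Path] = {}
    results: dict = {}

    # --- phantom -----------------------------------------------------------
    pc = config.phantom
    logger.info("stage phantom: seed=%d depth=%d", pc.seed, pc.depth)
    tree = ph.generate_vessel_tree(
        root_radius_um=pc.root_radius_um,
        depth=pc.depth,
        branch_angle_deg=pc.branch_angle_deg,
        tortuosity_amplitude_um=pc.tortuosity_amplitude_um,
        murray_exponent=pc.murray_exponent,
        seed=pc.seed,
    )
    files["tree_csv"] = tree.write_csv(out / "phantom_tree.csv")
    vol, truth = ph.rasterize_tree(
        tree,
        voxel_size_um=pc.voxel_size_um,
        fg_intensity=pc.fg_intensity,
        bg_intensity=pc.bg_intensity,
        noise_sigma=pc.noise_sigma,
        seed=pc.seed + 1,
    )
    files["phantom_tif"] = vio.write_volume(vol, out / "phantom.tif")
    results["phantom"] = {
        "n_segments": len(tree.segments),
        "analytic_volume_um3": tree.total_volume_um3(),
        "truth_voxels": truth.count(),
        "volume_shape": list(vol.shape),
    }

    # --- segmentation ------------------------------------------------------
    sc = config.segmentation
    logger.info("stage segment: method=%s", sc.method)
    vessel = seg.threshold_volume(vol, method=sc.method, fixed_value=sc.fixed_value)
    vessel = seg.despeckle(vessel, min_voxels=sc.min_voxels)
    if sc.tissue == "full_volume":
        tissue = vio.BinaryMask(
            data=np.ones(vol.shape, dtype=bool), voxel_size_um=vol.voxel_size_um
        )
    else:
        tissue = seg.tissue_mask(vessel, method="bounding_hull")
    results["segmentation"] = {
        "threshold": vessel.meta.get("threshold"),
        "method": sc.method,
        "min_voxels": sc.min_voxels,
        "vessel_voxels": vessel.count(),
        "tissue_voxels": tissue.count(),
        "truth_agreement": float((vessel.data == truth.data).mean()),
    }

    # --- morphometry -------------------------------------------------------
    mc = config.morphometry
    vvtv = mm.vascular_volume_fraction(vessel, tissue)
    sections = mm.extract_equidistant_sections(vessel, mc.n_sections, axis=mc.axis)
    profiles = [
        cs
        for i, sec in enumerate(sections)
        for cs in mm.measure_cross_sections(
            sec,
            vessel.voxel_size_um,
            min_area_px=mc.min_area_px,
            border_policy=mc.border_policy,
            section_index=i,
        )
    ]
    dist = mm.diameter_distribution(profiles, bin_width_um=mc.bin_width_um)
    results["morphometry"] = {
        "vv_tv": vvtv,
        "truth_vv_tv_box": truth.count() / truth.data.size,
        "n_sections": mc.n_sections,
        "n_profiles": dist.n,
        "median_diameter_um": dist.median_um,
        "bin_edges_um": dist.bin_edges_um.tolist(),
        "proportions": dist.proportions.tolist(),
    }

    # --- density map -------------------------------------------------------
    dc = config.density
    scene = ph.generate_histology_scene(
        extent_um=dc.extent_um,
        fiber_pitch_um=dc.fiber_pitch_um,
        capillary_per_fiber_profile=dc.capillaries_per_fiber,
        seed=dc.seed,
    )
    files["scene_csv"] = vio.write_points(scene, out / "histology_scene.csv")
    cap_map = dm.capillary_density_map(scene, dc.kernel_size_um, dc.stride_um)
    cf_map = dm.cf_ratio_map(scene, dc.kernel_size_um, dc.stride_um)
    for key, m in (("capillary_density", cap_map), ("cf_ratio", cf_map)):
        written = m.write(out / key)
        files[f"{key}_csv"] = written["csv"]
        files[f"{key}_meta"] = written["meta"]
    results["density"] = {
        "n_capillaries": int((scene.points["label"] == "capillary").sum()),
        "n_fibers": int((scene.points["label"] == "fiber").sum()),
        "kernel_size_um": dc.kernel_size_um,
        "stride_um": cap_map.stride_um,
        "mean_capillary_density_per_um2": float(np.nanmean(cap_map.grid)),
        "mean_cf_ratio": float(np.nanmean(cf_map.grid[cf_map.defined])),
    }

    # --- perfusion ---------------------------------------------------------
    fc = config.perfusion
    counts = ph.generate_classification_counts(
        true_props=fc.true_props,
        n_animals=fc.n_animals,
        sections_per_animal=fc.sections_per_animal,
        fovs_per_section=fc.fovs_per_section,
        capillaries_per_fov=fc.capillaries_per_fov,
        seed=fc.seed,
    )
    files["counts_csv"] = counts.write_csv(out / "classification_counts.csv")
    summary = ss.summarize_perfusion(counts)
    files["perfusion_json"] = summary.write_json(out / "perfusion_summary.json")
    results["perfusion"] = summary.to_report()

    report = {
        "name": config.name,
        "timestamp_utc": datetime.now(timezone.utc).isoformat(),
        "config": json.loads(config.model_dump_json()),
        "results": results,
        "files": {
            k: {"path": str(p), "sha256": _sha256(p)} for k, p in files.items()
        },
    }
    (out / "report.json").write_text(json.dumps(report, indent=2))
    return report
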