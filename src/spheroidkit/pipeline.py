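"""End-to-end orchestration: stack -> labels -> features -> surface -> graphs.

``PipelineConfig`` carries every tunable under its canonical YAML name
(``ImageZScalingFactor``, ``NucleiBackgroundFactor``, ``Alpha``, ...) with
the standard defaults; ``run_pipeline`` executes the stages in order and
writes all artefacts (label TIFF, feature CSV, surface PLY/JSON, GraphML
graphs, radial profile CSV, JSON report) into an output directory.  Runs
are deterministic for a fixed seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from pathlib import Path

import numpy as np
import tifffile
import yaml

from . import geometry, graphs, spatial
from .features import extract_features
from .io import VoxelImage, prepare_image, read_stack
from .segmentation import SegmentationConfig, segment

__all__ = ["PipelineConfig", "run_pipeline"]

logger = logging.getLogger(__name__)

_DEFAULTS = {
    "ImageZScalingFactor": None,  # axial_pitch / lateral_pitch when None
    "ImageScalingFactor": 0.5,
    "NucleiFilterRange": 3,
    "NucleiThresholdRange": 25,
    "NucleiBackgroundFactor": 0.25,
    "NucleiSeedDetectionMinRadius": 3.0,
    "NucleiSeedDetectionMaxRadius": 6.0,
    "NucleiSeedDilation": 2,
    "NucleiMinCount": 250,
    "NucleiMaxCount": 42_500,
    "OutlierDistanceThreshold": 20.0,
    "Alpha": 90.0,
    "EdgeDistanceThreshold": 40.0,
}


@dataclasses.dataclass
class PipelineConfig:
    """Pipeline parameters keyed by their canonical configuration names."""

    params: dict = dataclasses.field(default_factory=dict)
    seed: int = 0
    n_bins: int = 20
    surface_cut: float = 0.1
    core_cut: float = 0.75
    lateral_pitch: float = 0.325
    axial_pitch: float = 1.29

    def __post_init__(self) -> None:
        unknown = set(self.params) - set(_DEFAULTS)
        if unknown:
            raise ValueError(f"unknown parameter name(s): {sorted(unknown)}")
        merged = dict(_DEFAULTS)
        for key, value in self.params.items():
            logger.info("config override: %s = %r", key, value)
            merged[key] = value
        self.params = merged

    @classmethod
    def from_yaml(cls, path: str | Path, **kwargs) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        meta = {k: data.pop(k) for k in list(data) if k in
                ("seed", "n_bins", "surface_cut", "core_cut", "lateral_pitch", "axial_pitch")}
        meta.update(kwargs)
        return cls(params=data, **meta)

    def segmentation_config(self) -> SegmentationConfig:
        p = self.params
        return SegmentationConfig(
            nuclei_filter_range=p["NucleiFilterRange"],
            nuclei_threshold_range=p["NucleiThresholdRange"],
            gamma=p["NucleiBackgroundFactor"],
            r_min=p["NucleiSeedDetectionMinRadius"],
            r_max=p["NucleiSeedDetectionMaxRadius"],
            seed_dilation_radius=p["NucleiSeedDilation"],
            min_count=p["NucleiMinCount"],
            max_count=p["NucleiMaxCount"],
        )


def run_pipeline(
    stack_path: str | Path,
    out_dir: str | Path,
    config: PipelineConfig | None = None,
    rcp_reps: int = 0,
) -> dict:
    """Run the full analysis on a stack and write all artefacts.

    Returns the report dictionary (also written as ``report.json``).  Set
    ``rcp_reps`` > 0 to add a random-cell-position ensemble profile.
    """
    cfg = config or PipelineConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"stack": str(stack_path), "seed": cfg.seed, "parameters": cfg.params}
    t0 = time.time()

    stack = read_stack(stack_path, lateral_pitch=cfg.lateral_pitch, axial_pitch=cfg.axial_pitch)
    image = prepare_image(
        stack,
        z_scaling_factor=cfg.params["ImageZScalingFactor"],
        image_scaling_factor=cfg.params["ImageScalingFactor"],
    )
    report["image_shape"] = list(image.shape)
    report["pitch_um"] = image.pitch

    labels = segment(image, cfg.segmentation_config())
    report["n_nuclei"] = labels.n_objects
    dtype = np.uint16 if labels.n_objects <= 65_535 else np.uint32
    tifffile.imwrite(out / "labels.tif", labels.labels.astype(dtype))

    table = extract_features(labels, image)
    centroids = table[["centroid_z", "centroid_y", "centroid_x"]].to_numpy()

    if len(centroids) >= 4:
        kept = geometry.remove_outliers(centroids, cfg.params["OutlierDistanceThreshold"])
        surface = geometry.build_alpha_shape(kept, alpha=cfg.params["Alpha"])
        surface.write_ply(out / "surface.ply")
        report["surface"] = surface.to_json(out / "surface.json")
        dist, nds = geometry.depth_from_surface(centroids, surface)
        table["nds"] = nds

        thr = cfg.params["EdgeDistanceThreshold"]
        pcg = graphs.build_pcg(centroids, thr)
        dcg = graphs.build_dcg(centroids, thr)
        pcg.write_graphml(out / "pcg.graphml")
        dcg.write_graphml(out / "dcg.graphml")
        dens = graphs.density_features(pcg, pitch=image.pitch)
        dens.to_csv(out / "density_pcg.csv", index=False)
        report["pcg_edges"] = pcg.n_edges
        report["dcg_edges"] = dcg.n_edges
        report["mean_density_cells_per_uv"] = float(dens["degree"].mean())

        profile = spatial.radial_profile(dens["degree"].to_numpy(), nds, n_bins=cfg.n_bins)
        _write_profile(out / "radial_profile.csv", profile)

        max_depth_um = float(dist.max() * image.pitch)
        regions = spatial.summarize_regions(
            nds, dens["degree"].to_numpy(), max_depth_um,
            surface_cut=cfg.surface_cut, core_cut=cfg.core_cut,
        )
        report["regions"] = {
            "mean_radius_um": regions.mean_radius_um,
            "outer_thickness_um": regions.outer_thickness_um,
            "mean_density": {k: _float_or_none(v) for k, v in regions.mean_density.items()},
        }

        if rcp_reps > 0:
            spec = spatial.RcpSpec(n_cells=len(centroids), n_reps=rcp_reps, seed=cfg.seed)
            rcp_prof, _ = spatial.rcp_profile_ensemble(
                surface, spec, edge_distance_threshold=thr, n_bins=cfg.n_bins
            )
            _write_profile(out / "rcp_profile.csv", rcp_prof)

    table.to_csv(out / "features.csv", index=False)
    report["runtime_s"] = round(time.time() - t0, 2)
    (out / "report.json").write_text(json.dumps(report, indent=2))
    logger.info("pipeline finished: %d nuclei in %.1fs", report["n_nuclei"], report["runtime_s"])
    return report


def _float_or_none(v):
    return None if v is None or (isinstance(v, float) and np.isnan(v)) else float(v)


def _write_profile(path: Path, profile: spatial.RadialProfile) -> None:
    import pandas as pd

    pd.DataFrame({
        "bin_low": profile.bin_edges[:-1],
        "bin_high": profile.bin_edges[1:],
        "mean": profile.mean,
        "se": profile.se,
        "n": profile.n,
    }).to_csv(path, index=False)
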