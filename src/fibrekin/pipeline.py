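"""End-to-end orchestration: generate -> segment -> morph -> simulate -> analyze.

A :class:`PipelineConfig` holds every stage parameter, including every
seed, and round-trips losslessly through YAML; ``run_pipeline`` executes
the enabled stages into a run directory and writes a manifest (config
hash, package and library versions) so fixed-seed reruns are
bit-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import scipy
import yaml

from . import __version__
from .damage import CRITERIA, DamageSchedule, run_damage_simulation
from .io import (
    write_history_csv,
    write_lumen_stats_csv,
    write_volume,
    write_vtk,
    read_volume,
)
from .kinetics import categorize_criteria
from .meshing import assign_materials, build_mesh, connected_components
from .segmentation import extract_lumen, fiber_descriptors, porosity, segment, slice_ellipse_stats
from .synthetic import carve_notch, generate_fiber, preset, scaled_preset

__all__ = ["PipelineConfig", "ConfigError", "run_pipeline", "load_config", "save_config"]

log = logging.getLogger("fibrekin")


class ConfigError(ValueError):
    """Invalid pipeline configuration."""


@dataclass
class PipelineConfig:
    """All pipeline parameters; every random stage has an explicit seed."""

    # generation
    preset: str = "FU19"
    diameter_voxels: int = 14
    length_diameters: float = 3.0
    seed: int = 0
    input_volume: str | None = None  # skip generation, read this TIFF instead
    voxel_size: float | None = None  # override when reading a bare TIFF

    # segmentation
    threshold: int | None = None
    opening_radius: int = 0

    # mechanics
    E0: float = 20000.0  # MPa
    nu0: float = 0.3
    ground: float = 1e-6

    # damage schedule
    criteria: tuple[str, ...] = tuple(c.value for c in CRITERIA)
    strain_0: float = 0.002
    strain_break: float = 0.04
    n_increments: int = 25
    f: float = 1.0
    mode: str = "threshold"
    sigma_c: float | None = 90.0  # MPa; ignored in fraction mode
    band: float = 0.0
    stop_fraction: float = 0.01

    # analysis
    kmeans_seed: int = 0
    smoothing_window: int = 5

    # stage toggles
    stages: tuple[str, ...] = ("generate", "segment", "morph", "simulate", "analyze")

    def validate(self) -> None:
        known = {"generate", "segment", "morph", "simulate", "analyze"}
        unknown = set(self.stages) - known
        if unknown:
            raise ConfigError(f"unknown stages: {sorted(unknown)}")
        if self.input_volume is not None and not Path(self.input_volume).exists():
            raise ConfigError(f"input volume not found: {self.input_volume}")
        if self.input_volume is None and "generate" not in self.stages:
            raise ConfigError("either enable the generate stage or provide input_volume")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["criteria"] = list(self.criteria)
        d["stages"] = list(self.stages)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        names = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - names
        if unknown:
            raise ConfigError(f"unknown config fields: {sorted(unknown)}")
        d = dict(d)
        for key in ("criteria", "stages"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


def save_config(config: PipelineConfig, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))
    return path


def load_config(path: str | Path) -> PipelineConfig:
    data = yaml.safe_load(Path(path).read_text())
    if not isinstance(data, dict):
        raise ConfigError(f"config file {path} does not contain a mapping")
    return PipelineConfig.from_dict(data)


def _manifest(config: PipelineConfig, inputs: dict) -> dict:
    return {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "inputs": inputs,
        "versions": {
            "fibrekin": __version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
        },
    }


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> Path:
    """Execute the enabled stages into ``out_dir``; returns the directory.

    Never mutates its inputs on disk; all outputs land under the run
    directory. Stage failures abort with the stage name in the log and
    exception chain.
    """
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    volume = None
    stage = "init"
    try:
        if config.input_volume is not None:
            stage = "load"
            volume = read_volume(config.input_volume, voxel_size=config.voxel_size)
        elif "generate" in config.stages:
            stage = "generate"
            spec, notch = scaled_preset(
                config.preset, config.diameter_voxels, config.length_diameters
            )
            volume = generate_fiber(spec, seed=config.seed)
            volume = carve_notch(volume, notch)
            write_volume(volume, out / "volume.tif")

        if "segment" in config.stages:
            stage = "segment"
            volume = segment(volume, threshold=config.threshold, opening_radius=config.opening_radius)
            write_volume(volume, out / "segmented.tif")

        results: dict = {}
        if "morph" in config.stages:
            stage = "morph"
            lumen = extract_lumen(volume)
            desc = fiber_descriptors(volume)
            results["morphometrics"] = {
                "equivalent_diameter_um": desc.equivalent_diameter,
                "shape_factor": desc.shape_factor,
                "length_um": desc.length,
                "porosity": porosity(volume, lumen),
            }
            if (lumen > 0).sum() >= 5:
                stats = slice_ellipse_stats(lumen, volume.voxel_size, seg=volume)
                write_lumen_stats_csv(stats, out / "lumen_stats.csv")
                results["morphometrics"].update(
                    mean_lumen_area_um2=stats.mean_area,
                    median_lumen_area_um2=stats.median_area,
                    mean_lumen_aspect=stats.mean_aspect,
                    median_lumen_aspect=stats.median_aspect,
                )

        histories = {}
        if "simulate" in config.stages:
            stage = "simulate"
            mesh = build_mesh(volume)
            report = connected_components(mesh)
            for lbl in report.non_spanning:
                log.info("component %d (%d elements) does not span the loading ends",
                         lbl, report.sizes[lbl - 1])
            L = mesh.length
            schedule = DamageSchedule(
                U0=config.strain_0 * L,
                U_break=config.strain_break * L,
                n_increments=config.n_increments,
                f=config.f,
                mode=config.mode,
                sigma_c=config.sigma_c if config.mode == "threshold" else None,
                band=config.band,
                stop_fraction=config.stop_fraction,
            )
            for crit in config.criteria:
                materials = assign_materials(mesh, volume, config.E0, config.nu0, config.ground)
                log.info("simulating criterion %s (%d elements)", crit, mesh.n_elements)
                hist = run_damage_simulation(mesh, materials, crit, schedule)
                histories[crit] = hist
                write_history_csv(hist, out / f"history_{crit}.csv")
            # damaged mask of the last criterion run, for visualization
            write_vtk(mesh, out / "mesh.vtk", cell_data={"damaged": materials.damaged.astype(float)})

        if "analyze" in config.stages and histories:
            stage = "analyze"
            reports, degenerate = categorize_criteria(
                histories, seed=config.kmeans_seed, smoothing_window=config.smoothing_window
            )
            results["kinetics"] = {
                crit.value: {
                    "onset": rep.stages.onset,
                    "saturation": rep.stages.saturation,
                    "modality": rep.modality,
                    "final_ratio": rep.final_ratio,
                    "category": rep.category,
                }
                for crit, rep in reports.items()
            }
            results["kinetics_degenerate"] = degenerate

        (out / "report.json").write_text(json.dumps(results, indent=2))
        inputs = {"input_volume": config.input_volume}
        (out / "manifest.json").write_text(json.dumps(_manifest(config, inputs), indent=2))
    except Exception:
        log.exception("pipeline failed in stage %r", stage)
        raise
    return out
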