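"""End-to-end pipeline: configuration, staged execution, run manifest.

``run_pipeline`` executes calibrate → segment → classify → porosity
summaries on either a DICOM directory or a simulated phantom scene, writing
CSV/TIFF/JSON artifacts plus a summary JSON that records the seed, the
config hash and every file produced. Identical config + seed reproduces an
identical summary (timestamps excluded by design).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from . import __version__
from .calibration import apply_calibration, fit_two_point
from .phantoms import FruitPhantomSpec, make_multi_fruit_scene, solve_cortex_for_mixture
from .porosity import regional_summary, whole_fruit_porosity
from .segmentation import RegionBands, classify_regions, segment_fruits
from .volume_io import read_dicom_series, write_metrics, write_volume

log = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name for diagnostics."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """All tunables of an end-to-end run, with documented defaults."""

    juice_grey: float = 49.0           # 0 % porosity reference (int16)
    air_grey: float = -1007.0          # 100 % porosity reference (int16)
    min_fruit_volume_mm3: float = 50.0
    expected_max_fruits: int = 3
    seed_band: tuple[float, float] = (0.0, 10.0)
    core_band: tuple[float, float] = (5.0, 15.0)
    cortex_band: tuple[float, float] = (15.0, 30.0)
    cavity_threshold_pct: float = 90.0
    smooth_radius_mm: float = 1.0
    inner_fraction: float = 0.35
    noise_sd_grey: float = 10.0        # forward-model noise for simulated scenes
    n_fruits: int = 3                  # simulated scene size
    target_mixture_pct: float | None = None
    roi_edge_mm: float = 0.5
    blob_diameter_range_um: tuple[float, float] = (20.0, 150.0)
    weight_strategy: str = "loading_x_variance"
    weight_components: int = 2
    rng_seed: int = 20240830
    output_dir: str = "pomoct_out"

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        d = dataclasses.asdict(self)
        d = {k: (list(v) if isinstance(v, tuple) else v) for k, v in d.items()}
        path.write_text(yaml.safe_dump(d, sort_keys=True))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        fields = {f.name: f for f in dataclasses.fields(cls)}
        unknown = set(d) - set(fields)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for k, v in d.items():
            if isinstance(v, list):
                d[k] = tuple(v)
        return cls(**d)

    def hash(self) -> str:
        d = dataclasses.asdict(self)
        blob = json.dumps(d, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def bands(self) -> RegionBands:
        return RegionBands(self.seed_band, self.core_band, self.cortex_band,
                           self.cavity_threshold_pct)


def run_pipeline(
    config: RunConfig,
    input_dir: str | Path | None = None,
    out_dir: str | Path | None = None,
    write_volumes: bool = True,
) -> dict[str, Any]:
    """Execute the macro-scale pipeline and write its artifact bundle.

    ``input_dir`` may point at a DICOM series; when omitted, a synthetic
    multi-fruit scene is simulated from the config (seeded, optionally with
    the cortex porosity solved to hit ``target_mixture_pct``). Returns the
    summary dict also written to ``summary.json``.
    """
    out = Path(out_dir or config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: list[str] = []
    summary: dict[str, Any] = {
        "version": __version__,
        "seed": config.rng_seed,
        "config_hash": config.hash(),
        "input": str(input_dir) if input_dir else "simulated",
    }

    def _stage(name, fn, *args, **kw):
        try:
            return fn(*args, **kw)
        except StageError:
            raise
        except Exception as exc:  # tag failures with the stage name
            _write_summary(out, summary, manifest, partial=True)
            raise StageError(name, exc) from exc

    # --- input ------------------------------------------------------------
    truth = None
    if input_dir is not None:
        if not Path(input_dir).is_dir():
            _write_summary(out, summary, manifest, partial=True)
            raise StageError("input", FileNotFoundError(f"{input_dir} is not a directory"))
        volume = _stage("input", read_dicom_series, input_dir)
    else:
        def _simulate():
            spec = FruitPhantomSpec(seed=config.rng_seed)
            if config.target_mixture_pct is not None:
                spec = solve_cortex_for_mixture(spec, config.target_mixture_pct)
            specs = [dataclasses.replace(spec, seed=config.rng_seed + i)
                     for i in range(config.n_fruits)]
            return make_multi_fruit_scene(
                specs, calib=fit_two_point(config.juice_grey, config.air_grey),
                noise_sd=config.noise_sd_grey, seed=config.rng_seed)
        volume, truth = _stage("simulate", _simulate)

    # --- calibrate / segment / classify ------------------------------------
    calib = _stage("calibrate", fit_two_point, config.juice_grey, config.air_grey)
    pmap = _stage("calibrate", apply_calibration, volume, calib, True)
    masks = _stage("segment", segment_fruits, volume, calib,
                   config.min_fruit_volume_mm3, config.expected_max_fruits)
    regions = _stage("classify", classify_regions, pmap, masks, config.bands(),
                     config.smooth_radius_mm, config.inner_fraction)

    # --- porosity summaries -------------------------------------------------
    per_fruit = _stage("porosity", whole_fruit_porosity, pmap, masks)
    regional = _stage("porosity", regional_summary, pmap, regions, masks)

    per_fruit_df = regional.copy()
    fruit_rows = [{"fruit_id": fid, "whole_fruit_porosity_pct": val,
                   "voxel_count": masks.voxel_counts[fid]}
                  for fid, val in per_fruit.items()]
    p1 = write_metrics(fruit_rows, out / "whole_fruit_porosity.csv")
    p2 = write_metrics(per_fruit_df, out / "regional_summary.csv")
    manifest += [p1.name, p2.name]
    if write_volumes:
        v1 = write_volume(pmap, out / "porosity.tif")
        manifest += [v1.name, v1.name + ".json"]

    summary["fruit_count"] = masks.fruit_count
    summary["whole_fruit_porosity_pct"] = {str(k): v for k, v in per_fruit.items()}
    summary["mean_scene_porosity_pct"] = float(np.mean(list(per_fruit.values())))
    summary["calibration"] = {"juice_grey": calib.juice_grey,
                              "air_grey": calib.air_grey,
                              "slope": calib.slope, "intercept": calib.intercept}
    if truth is not None:
        summary["truth_mixture_pct"] = [ph.mixture_mean for ph in truth.phantoms]
    _write_summary(out, summary, manifest)
    return summary


def _write_summary(out: Path, summary: dict, manifest: list[str],
                   partial: bool = False) -> None:
    summary = dict(summary)
    summary["partial"] = partial
    summary["manifest"] = sorted(set(manifest + ["summary.json"]))
    (out / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
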