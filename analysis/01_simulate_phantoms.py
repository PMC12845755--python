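#!/usr/bin/env python
"""Simulate the synthetic study inputs: a 3-fruit CT scene, a cellular ROI,
and a quality-trait table.

Writes volumes (binary) under scratch/ and tabular ground truth under
results/. Everything downstream (02–04) can regenerate these from the same
seed instead of reading the files; this driver exists to make the inputs
inspectable.
"""

from pathlib import Path

from pomoct.calibration import fit_two_point
from pomoct.phantoms import (CellPhantomSpec, FruitPhantomSpec,
                             make_cell_phantom, make_multi_fruit_scene,
                             make_quality_table)
from pomoct.volume_io import write_metrics, write_volume

SEED = 20240830
RESULTS = Path(__file__).resolve().parents[1] / "results"
SCRATCH = Path(__file__).resolve().parents[1] / "scratch"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    SCRATCH.mkdir(exist_ok=True)
    calib = fit_two_point()

    specs = [FruitPhantomSpec(seed=SEED + i) for i in range(3)]
    grey, truth = make_multi_fruit_scene(specs, calib=calib, noise_sd=10.0,
                                         seed=SEED)
    write_volume(grey, SCRATCH / "scene_grey.tif")
    write_volume(truth.porosity, SCRATCH / "scene_porosity_truth.tif")
    print(f"scene: {grey.shape} voxels, {truth.fruits.fruit_count} fruits, "
          f"region mixtures {[round(p.mixture_mean, 2) for p in truth.phantoms]} %")

    cell = make_cell_phantom(CellPhantomSpec(seed=SEED))
    write_volume(cell.grey, SCRATCH / "cell_roi_grey.tif")
    write_metrics(cell.truth.round(4), SCRATCH / "cell_roi_truth.csv")
    summary = (cell.truth.groupby("polarity").diameter_um
               .agg(["count", "mean", "std"]).round(3).reset_index())
    write_metrics(summary, RESULTS / "cell_roi_truth_summary.csv")
    print(f"cell ROI: {cell.grey.shape} voxels, "
          f"{(cell.truth.polarity == 'bright').sum()} cells "
          f"(packing {cell.achieved_packing_fraction:.3f}), "
          f"gas fraction {cell.achieved_pore_volume_ratio:.3f}")

    table, qt_truth = make_quality_table(seed=SEED)
    out = table.params.join(table.treatments)
    out.to_csv(RESULTS / "quality_table.csv")
    print(f"quality table: {table.params.shape[0]} samples x "
          f"{table.params.shape[1]} traits -> {RESULTS / 'quality_table.csv'}")


if __name__ == "__main__":
    main()
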