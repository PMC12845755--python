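"""Shared fixtures: synthetic phantoms generated once per session."""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

from pomoct.calibration import apply_calibration, fit_two_point
from pomoct.microstructure import detect_blobs, enhance_contrast
from pomoct.phantoms import (CellPhantomSpec, FruitPhantomSpec,
                             make_cell_phantom, make_fruit_phantom,
                             porosity_to_grey)
from pomoct.segmentation import classify_regions, segment_fruits


@pytest.fixture(scope="session")
def calib():
    return fit_two_point()


#: compact fruit geometry used throughout the suite (fast to voxelize)
SMALL_FRUIT = FruitPhantomSpec(
    semi_axes_mm=(14.0, 10.0, 10.0), core_radius_mm=3.5,
    core_half_height_mm=6.0, seed_semi_axes_mm=(2.5, 1.0, 1.0),
    seed_ring_radius_mm=1.8, cavity_semi_axes_mm=(3.5, 1.5, 1.5),
    cavity_ring_radius_mm=4.0, seed=2)


@pytest.fixture(scope="session")
def small_fruit():
    return make_fruit_phantom(SMALL_FRUIT)


@pytest.fixture(scope="session")
def small_fruit_pipeline(small_fruit, calib):
    """Phantom pushed through forward model + segmentation + classification."""
    grey = porosity_to_grey(small_fruit.porosity, calib, noise_sd=10.0, seed=3)
    pmap = apply_calibration(grey, calib, clip=True)
    masks = segment_fruits(grey, calib)
    regions = classify_regions(pmap, masks)
    return grey, pmap, masks, regions


@pytest.fixture(scope="session")
def cell_phantom():
    return make_cell_phantom(CellPhantomSpec(seed=5))


@pytest.fixture(scope="session")
def cell_detection(cell_phantom):
    grey = cell_phantom.grey
    enh = enhance_contrast(grey)
    cells = detect_blobs(enh, "bright", grey.spacing_mm,
                         diameter_range_um=(30.0, 150.0))
    pores = detect_blobs(enh, "dark", grey.spacing_mm,
                         diameter_range_um=(8.0, 200.0))
    return enh, cells, pores


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def small_fruit_variant(**overrides) -> FruitPhantomSpec:
    return dataclasses.replace(SMALL_FRUIT, **overrides)
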