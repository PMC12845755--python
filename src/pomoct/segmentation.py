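"""Fruit and anatomical-region segmentation of whole-fruit CT scenes.

The scene-level workflow: Otsu thresholding separates tissue from background
air, 26-connected components become individual fruits (smallest first
discarded below a minimum volume), internal cavities are folded into each
fruit by 3D hole filling, and the porosity map is then banded into
anatomical regions — seed, core, cortex, cavity — using the characteristic
porosity ranges of apple parenchyma (seeds 0–10 %, core 5–15 %, cortex
15–30 %, gas-filled cavities ≈100 %).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .calibration import PorosityCalibration, PorosityVolume
from .volume_io import GreyVolume

REGION_CODES = {"background": 0, "cortex": 1, "core": 2, "seed": 3, "cavity": 4}
REGION_NAMES = {v: k for k, v in REGION_CODES.items()}


def otsu_threshold(values, bins: int = 256) -> float:
    """Between-class-variance-maximizing threshold of a 1D sample.

    Returns the interior bin edge of a ``bins``-bin histogram that maximizes
    the between-class variance of the induced binarization (values < edge vs
    values >= edge). Ties break to the lowest qualifying edge.

    Raises ``ValueError("degenerate histogram")`` for constant input.
    """
    values = np.asarray(values, dtype=np.float64).ravel()
    if values.size < 2 or np.min(values) == np.max(values):
        raise ValueError("degenerate histogram: need >= 2 distinct values")
    counts, edges = np.histogram(values, bins=bins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    w = counts.astype(np.float64)
    total = w.sum()
    cum_w = np.cumsum(w)
    cum_m = np.cumsum(w * centers)
    # candidate thresholds: interior edges edges[1..bins-1]; class 0 = bins < k
    w0 = cum_w[:-1] / total
    w1 = 1.0 - w0
    mu0 = np.divide(cum_m[:-1], cum_w[:-1], out=np.zeros(bins - 1), where=cum_w[:-1] > 0)
    mu1 = np.divide(cum_m[-1] - cum_m[:-1], cum_w[-1] - cum_w[:-1],
                    out=np.zeros(bins - 1), where=(cum_w[-1] - cum_w[:-1]) > 0)
    between = w0 * w1 * (mu0 - mu1) ** 2
    k = int(np.argmax(between))  # argmax returns the first (lowest) maximizer
    return float(edges[k + 1])


@dataclass
class FruitMasks:
    """Per-fruit labels of a multi-fruit scene (0 = background air)."""

    labels: np.ndarray
    spacing_mm: tuple[float, float, float]
    voxel_counts: dict[int, int] = field(default_factory=dict)
    centroids_mm: dict[int, tuple[float, float, float]] = field(default_factory=dict)

    @property
    def fruit_count(self) -> int:
        return len(self.voxel_counts)

    def mask(self, fruit_id: int) -> np.ndarray:
        return self.labels == fruit_id


def segment_fruits(
    volume: GreyVolume,
    calib: PorosityCalibration | None = None,
    min_volume_mm3: float = 50.0,
    expected_max: int = 3,
    fixed_threshold: float | None = None,
    min_class_separation: float = 100.0,
) -> FruitMasks:
    """Separate individual fruits from a scene by thresholding + labeling.

    Tissue/background separation uses Otsu on the grey histogram (or a fixed
    grey threshold), components are 26-connected, components smaller than
    ``min_volume_mm3`` are discarded, and interior holes (gas cavities) are
    filled into each fruit's extent. Labels are ordered by descending size.

    An Otsu split whose class means differ by less than
    ``min_class_separation`` grey units is treated as background noise
    (tissue sits hundreds of grey units above air on the int16 scale), so an
    all-air scene raises "no fruit detected" instead of thresholding noise.
    """
    if fixed_threshold is not None:
        thr = float(fixed_threshold)
    else:
        try:
            thr = otsu_threshold(volume.voxels)
        except ValueError as exc:
            raise ValueError("no fruit detected") from exc
        above = volume.voxels >= thr
        if not above.any() or above.all() or (
                float(volume.voxels[above].mean())
                - float(volume.voxels[~above].mean()) < min_class_separation):
            raise ValueError("no fruit detected: no tissue/air contrast")
    tissue = volume.voxels >= thr  # tissue is brighter (denser) than air
    structure = np.ones((3, 3, 3), dtype=bool)  # 26-connectivity
    labeled, n = ndimage.label(tissue, structure=structure)
    if n == 0:
        raise ValueError("no fruit detected")
    voxel_mm3 = volume.voxel_volume_mm3
    sizes = ndimage.sum_labels(np.ones_like(labeled), labeled, index=np.arange(1, n + 1))
    keep = [i + 1 for i, s in enumerate(sizes) if s * voxel_mm3 >= min_volume_mm3]
    if not keep:
        raise ValueError("no fruit detected: all components below minimum volume")
    keep.sort(key=lambda lab: -sizes[lab - 1])
    if len(keep) > expected_max:
        warnings.warn(
            f"{len(keep)} components exceed expected_max={expected_max}; "
            "keeping the largest", stacklevel=2,
        )
        keep = keep[:expected_max]

    out = np.zeros(volume.shape, dtype=np.int32)
    counts: dict[int, int] = {}
    centroids: dict[int, tuple[float, float, float]] = {}
    spacing = np.asarray(volume.spacing_mm)
    for new_id, lab in enumerate(keep, start=1):
        m = ndimage.binary_fill_holes(labeled == lab)
        out[m] = new_id
        counts[new_id] = int(m.sum())
        com = ndimage.center_of_mass(m)
        centroids[new_id] = tuple(float(c * s) for c, s in zip(com, spacing))
    return FruitMasks(out, volume.spacing_mm, counts, centroids)


@dataclass(frozen=True)
class RegionBands:
    """Porosity bands (%) characterizing apple anatomical regions."""

    seed: tuple[float, float] = (0.0, 10.0)
    core: tuple[float, float] = (5.0, 15.0)
    cortex: tuple[float, float] = (15.0, 30.0)
    cavity_threshold: float = 90.0

    def validate(self) -> None:
        for name, (lo, hi) in (("seed", self.seed), ("core", self.core),
                               ("cortex", self.cortex)):
            if not (0 <= lo < hi <= 100):
                raise ValueError(f"invalid band spec: {name} band {lo}-{hi}")
        if not (0 < self.cavity_threshold <= 100):
            raise ValueError("invalid band spec: cavity threshold outside (0, 100]")
        if self.cortex[1] > self.cavity_threshold:
            raise ValueError("invalid band spec: cortex band crosses cavity threshold")


@dataclass
class RegionLabels:
    """Anatomical region map; codes per :data:`REGION_CODES`.

    Regions partition every fruit mask: each fruit voxel carries exactly one
    of {cortex, core, seed, cavity}; background stays 0.
    """

    regions: np.ndarray
    spacing_mm: tuple[float, float, float]

    def counts(self, mask: np.ndarray | None = None) -> dict[str, int]:
        sel = self.regions if mask is None else self.regions[mask]
        return {name: int(np.sum(sel == code))
                for name, code in REGION_CODES.items() if code != 0}


def _ball_kernel(radius_mm: float, spacing: tuple[float, float, float]) -> np.ndarray:
    half = [max(0, int(np.floor(radius_mm / s))) for s in spacing]
    grids = np.meshgrid(*[np.arange(-h, h + 1) * s for h, s in zip(half, spacing)],
                        indexing="ij")
    dist2 = sum(g ** 2 for g in grids)
    kernel = (dist2 <= radius_mm ** 2).astype(np.float64)
    return kernel


def classify_regions(
    pmap: PorosityVolume,
    masks: FruitMasks,
    bands: RegionBands = RegionBands(),
    smooth_radius_mm: float = 1.0,
    inner_fraction: float = 0.35,
) -> RegionLabels:
    """Band the porosity map into seed/core/cortex/cavity per fruit.

    Porosity is first locally averaged over a ball of ``smooth_radius_mm``
    (mask-aware, so background air does not bleed in). Voxels at or above the
    cavity threshold become cavity. Remaining tissue is assigned by band
    membership; the seed band (0–10) and core band (5–15) overlap, which is
    resolved inside the inner radial zone (normalized radius <
    ``inner_fraction`` of the fruit's equivalent radius) by the overlap
    midpoint, while voxels outside the inner zone are cortex-eligible only.
    Tissue voxels left unassigned take the label of the nearest assigned
    region (anisotropic Euclidean distance).
    """
    if pmap.shape != masks.labels.shape:
        raise ValueError("porosity map and masks must share shape")
    bands.validate()
    spacing = pmap.spacing_mm
    regions = np.zeros(pmap.shape, dtype=np.uint8)

    kernel = _ball_kernel(smooth_radius_mm, spacing)
    ksum = kernel.sum()
    overlap_lo = max(bands.seed[0], bands.core[0])
    overlap_hi = min(bands.seed[1], bands.core[1])
    overlap_mid = 0.5 * (overlap_lo + overlap_hi)

    for fid in masks.voxel_counts:
        fmask = masks.mask(fid)
        if ksum > 1:
            num = ndimage.convolve(pmap.porosity * fmask, kernel, mode="constant")
            den = ndimage.convolve(fmask.astype(np.float64), kernel, mode="constant")
            ps = np.where(den > 0, num / np.maximum(den, 1e-12), 0.0)
        else:
            ps = pmap.porosity
        ps = np.where(fmask, ps, np.nan)

        # normalized radial position from the fruit centroid (mm metric)
        centroid = masks.centroids_mm[fid]
        coords = np.meshgrid(*[np.arange(n) * s for n, s in zip(pmap.shape, spacing)],
                             indexing="ij", sparse=True)
        r_mm = np.sqrt(sum((c - c0) ** 2 for c, c0 in zip(coords, centroid)))
        eq_radius = (3 * masks.voxel_counts[fid] * pmap.voxel_volume_mm3 / (4 * np.pi)) ** (1 / 3)
        inner = r_mm < inner_fraction * eq_radius

        cavity = fmask & (ps >= bands.cavity_threshold)
        tissue = fmask & ~cavity
        in_seed = (ps >= bands.seed[0]) & (ps <= bands.seed[1])
        in_core = (ps >= bands.core[0]) & (ps <= bands.core[1])
        in_cortex = (ps >= bands.cortex[0]) & (ps <= bands.cortex[1])

        seed = tissue & inner & in_seed & (~in_core | (ps < overlap_mid))
        core = tissue & inner & in_core & ~seed
        cortex = tissue & in_cortex & ~seed & ~core

        sub = np.zeros(pmap.shape, dtype=np.uint8)
        sub[cortex] = REGION_CODES["cortex"]
        sub[core] = REGION_CODES["core"]
        sub[seed] = REGION_CODES["seed"]
        sub[cavity] = REGION_CODES["cavity"]

        unassigned = tissue & (sub == 0)
        if unassigned.any():
            assigned = sub > 0
            if not assigned.any():
                raise ValueError("invalid band spec: no voxel matches any band")
            _, idx = ndimage.distance_transform_edt(
                ~assigned, sampling=spacing, return_indices=True)
            sub[unassigned] = sub[tuple(i[unassigned] for i in idx)]
        regions[fmask] = sub[fmask]

    return RegionLabels(regions, spacing)
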