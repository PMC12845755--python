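"""Synthetic ground-truth generators for the CT pipeline.

Three generators stand in for unavailable scan data, each with exact,
queryable ground truth:

* whole-fruit phantoms — a voxelized ellipsoidal fruit at the low-resolution
  scanning geometry (0.5 mm slices, 339 µm in-plane) with anatomically
  nested regions: a core cylinder, a ring of dense seeds, gas-filled carpel
  cavity lobes, and cortex filling the rest; each region carries its
  characteristic porosity plus small intra-region jitter;
* cellular phantoms — a 0.5 mm cube at 6.6 µm isotropic resolution packed
  with non-overlapping bright cell spheres (random sequential adsorption)
  and dark pore spheres in an intermediate cell-wall/juice matrix;
* quality tables — trait matrices with a planted two-latent-factor group
  structure (seed/cell traits on factor 1, morphology/porosity on factor 2,
  sensory traits on both) and treatment-level factor shifts.

Every generator is bit-deterministic given its seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .calibration import PorosityCalibration, PorosityVolume, fit_two_point
from .segmentation import REGION_CODES, FruitMasks, RegionLabels
from .quality import QualityTable
from .volume_io import INT16_MAX, INT16_MIN, GreyVolume

AIR_POROSITY = 100.0

# ---------------------------------------------------------------------------
# whole-fruit phantom


@dataclass(frozen=True)
class FruitPhantomSpec:
    """Geometry + porosity recipe for one synthetic fruit."""

    semi_axes_mm: tuple[float, float, float] = (24.0, 17.0, 17.0)
    core_radius_mm: float = 5.5
    core_half_height_mm: float = 10.0
    seed_count: int = 5
    seed_semi_axes_mm: tuple[float, float, float] = (4.0, 1.5, 1.5)
    seed_ring_radius_mm: float = 2.8
    cavity_lobes: int = 5
    cavity_semi_axes_mm: tuple[float, float, float] = (6.0, 2.4, 2.4)
    cavity_ring_radius_mm: float = 6.5
    porosity_seed: float = 4.0
    porosity_core: float = 10.0
    porosity_cortex: float = 22.0
    porosity_cavity: float = 100.0
    jitter_sd: float = 1.0
    spacing_mm: tuple[float, float, float] = (0.5, 0.339, 0.339)
    margin_vox: int = 4
    grid_shape: tuple[int, int, int] | None = None
    seed: int = 0

    def validate(self) -> None:
        for p in (self.porosity_seed, self.porosity_core,
                  self.porosity_cortex, self.porosity_cavity):
            if not (0 <= p <= 100):
                raise ValueError("region porosities must lie in [0, 100]")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("spacing must be positive")
        a = self.semi_axes_mm
        # interior structures must nest inside the fruit ellipsoid
        if self.core_half_height_mm >= a[0] or self.core_radius_mm >= min(a[1], a[2]):
            raise ValueError("geometry overflow: core exceeds fruit bounds")
        seed_reach = self.seed_ring_radius_mm + max(self.seed_semi_axes_mm[1:])
        cav_reach = self.cavity_ring_radius_mm + max(self.cavity_semi_axes_mm[1:])
        if seed_reach >= min(a[1], a[2]) or cav_reach >= min(a[1], a[2]):
            raise ValueError("geometry overflow: seeds/cavities exceed fruit bounds")
        if (self.seed_semi_axes_mm[0] >= a[0]
                or self.cavity_semi_axes_mm[0] >= a[0]):
            raise ValueError("geometry overflow: structure too long for fruit")


@dataclass
class FruitPhantom:
    """A voxelized fruit with exact region labels and analytic bookkeeping."""

    porosity: PorosityVolume         # background voxels carry air (100 %)
    regions: RegionLabels
    mask: np.ndarray
    region_counts: dict[str, int]
    mixture_mean: float              # voxel-weighted mix of region base values
    spec: FruitPhantomSpec


def _ellipsoid(coords, center, semi_axes) -> np.ndarray:
    return sum(((c - c0) / a) ** 2
               for c, c0, a in zip(coords, center, semi_axes)) <= 1.0


def make_fruit_phantom(spec: FruitPhantomSpec = FruitPhantomSpec()) -> FruitPhantom:
    """Voxelize a fruit phantom with known per-region porosity.

    Paint order (later wins): cortex ellipsoid → core cylinder → cavity
    lobes → seeds, which nests the anatomy. Tissue voxels get zero-mean
    Gaussian intra-region jitter (SD ``jitter_sd``, clipped to [0, 100]);
    cavity voxels are exact 100 % gas; background is air.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    spacing = np.asarray(spec.spacing_mm)
    if spec.grid_shape is not None:
        shape = tuple(spec.grid_shape)
    else:
        shape = tuple(int(np.ceil(2 * a / s)) + 2 * spec.margin_vox
                      for a, s in zip(spec.semi_axes_mm, spacing))
    center = (np.asarray(shape) - 1) * spacing / 2.0
    coords = np.meshgrid(*[np.arange(n) * s for n, s in zip(shape, spacing)],
                         indexing="ij", sparse=True)
    if any(2 * a >= n * s for a, n, s in zip(spec.semi_axes_mm, shape, spacing)):
        raise ValueError("geometry overflow: fruit exceeds grid")

    regions = np.zeros(shape, dtype=np.uint8)
    fruit = _ellipsoid(coords, center, spec.semi_axes_mm)
    regions[fruit] = REGION_CODES["cortex"]

    radial2 = (coords[1] - center[1]) ** 2 + (coords[2] - center[2]) ** 2
    core = (fruit
            & (radial2 <= spec.core_radius_mm ** 2)
            & (np.abs(coords[0] - center[0]) <= spec.core_half_height_mm))
    regions[core] = REGION_CODES["core"]

    for k in range(spec.cavity_lobes):
        ang = 2 * np.pi * (k + 0.5) / max(spec.cavity_lobes, 1)
        c = (center[0],
             center[1] + spec.cavity_ring_radius_mm * np.cos(ang),
             center[2] + spec.cavity_ring_radius_mm * np.sin(ang))
        regions[_ellipsoid(coords, c, spec.cavity_semi_axes_mm)] = REGION_CODES["cavity"]

    for k in range(spec.seed_count):
        ang = 2 * np.pi * k / max(spec.seed_count, 1)
        c = (center[0],
             center[1] + spec.seed_ring_radius_mm * np.cos(ang),
             center[2] + spec.seed_ring_radius_mm * np.sin(ang))
        regions[_ellipsoid(coords, c, spec.seed_semi_axes_mm)] = REGION_CODES["seed"]

    base = {REGION_CODES["cortex"]: spec.porosity_cortex,
            REGION_CODES["core"]: spec.porosity_core,
            REGION_CODES["seed"]: spec.porosity_seed,
            REGION_CODES["cavity"]: spec.porosity_cavity}
    porosity = np.full(shape, AIR_POROSITY, dtype=np.float64)
    counts: dict[str, int] = {}
    for code, value in base.items():
        m = regions == code
        name = {v: k for k, v in REGION_CODES.items()}[code]
        counts[name] = int(m.sum())
        porosity[m] = value
    tissue = fruit & (regions != REGION_CODES["cavity"])
    if spec.jitter_sd > 0:
        porosity[tissue] = np.clip(
            porosity[tissue] + rng.normal(0.0, spec.jitter_sd, int(tissue.sum())),
            0.0, 100.0)

    n_fruit = int(fruit.sum())
    mixture = sum(base[REGION_CODES[name]] * n for name, n in counts.items()) / n_fruit
    return FruitPhantom(
        porosity=PorosityVolume(porosity, spec.spacing_mm, clipped=True),
        regions=RegionLabels(regions, spec.spacing_mm),
        mask=fruit,
        region_counts=counts,
        mixture_mean=float(mixture),
        spec=spec,
    )


def solve_cortex_for_mixture(
    spec: FruitPhantomSpec, target_mean_pct: float
) -> FruitPhantomSpec:
    """Adjust cortex porosity so the voxel-weighted region mixture hits a target.

    Voxelizes once to obtain exact region voxel counts, then solves the
    single linear equation for the cortex value. Raises if the solution
    leaves the physiological cortex band (15–30 %).
    """
    probe = make_fruit_phantom(dataclasses.replace(spec, jitter_sd=0.0))
    n = probe.region_counts
    n_fruit = sum(n.values())
    other = (spec.porosity_seed * n["seed"] + spec.porosity_core * n["core"]
             + spec.porosity_cavity * n["cavity"])
    cortex = (target_mean_pct * n_fruit - other) / n["cortex"]
    if not (15.0 <= cortex <= 30.0):
        raise ValueError(
            f"target mixture {target_mean_pct}% needs cortex porosity "
            f"{cortex:.2f}%, outside the 15-30% band")
    return dataclasses.replace(spec, porosity_cortex=float(cortex))


def porosity_to_grey(
    truth: PorosityVolume,
    calib: PorosityCalibration,
    noise_sd: float = 10.0,
    seed: int | np.random.Generator = 0,
) -> GreyVolume:
    """Forward model: porosity → int16 grey values plus Gaussian noise.

    ``g = juice − (p/100)(juice − air) + N(0, σ)``, rounded and clamped to
    the int16 range. Background air voxels (100 % porosity in the truth
    map) land at the air grey level plus noise, as in a real scan.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    g = np.asarray(calib.grey(truth.porosity), dtype=np.float64)
    if noise_sd > 0:
        g = g + rng.normal(0.0, noise_sd, g.shape)
    g = np.clip(np.rint(g), INT16_MIN, INT16_MAX).astype(np.int16)
    return GreyVolume(g, truth.spacing_mm, {"synthetic": True})


@dataclass
class SceneTruth:
    """Ground truth for a multi-fruit scene."""

    porosity: PorosityVolume
    regions: RegionLabels
    fruits: FruitMasks
    phantoms: list[FruitPhantom]


def make_multi_fruit_scene(
    specs: list[FruitPhantomSpec],
    gap_mm: float = 4.0,
    calib: PorosityCalibration | None = None,
    noise_sd: float = 10.0,
    seed: int | np.random.Generator = 0,
) -> tuple[GreyVolume, SceneTruth]:
    """Place 1–3 fruit phantoms on a row (col axis) with fixed gaps.

    Fruits cannot collide by construction (each occupies its own column
    span); the combined truth carries per-fruit labels ordered left to
    right. Grey values come from the forward model with ``noise_sd``.
    """
    if not 1 <= len(specs) <= 3:
        raise ValueError("scene supports 1-3 fruits")
    spacing = specs[0].spacing_mm
    if any(s.spacing_mm != spacing for s in specs):
        raise ValueError("all fruits in a scene must share voxel spacing")
    phantoms = [make_fruit_phantom(s) for s in specs]
    shapes = [p.porosity.shape for p in phantoms]
    gap_vox = int(round(gap_mm / spacing[2]))

    n_slice = max(s[0] for s in shapes)
    n_row = max(s[1] for s in shapes)
    n_col = sum(s[2] for s in shapes) + gap_vox * (len(specs) - 1)
    porosity = np.full((n_slice, n_row, n_col), AIR_POROSITY, dtype=np.float64)
    regions = np.zeros((n_slice, n_row, n_col), dtype=np.uint8)
    labels = np.zeros((n_slice, n_row, n_col), dtype=np.int32)

    col0 = 0
    counts: dict[int, int] = {}
    centroids: dict[int, tuple[float, float, float]] = {}
    for fid, ph in enumerate(phantoms, start=1):
        ds, dr, dc = ph.porosity.shape
        s0 = (n_slice - ds) // 2
        r0 = (n_row - dr) // 2
        sl = (slice(s0, s0 + ds), slice(r0, r0 + dr), slice(col0, col0 + dc))
        porosity[sl][ph.mask] = ph.porosity.porosity[ph.mask]
        regions[sl][ph.mask] = ph.regions.regions[ph.mask]
        labels[sl][ph.mask] = fid
        counts[fid] = int(ph.mask.sum())
        com = [float(np.mean(idx)) for idx in np.nonzero(labels == fid)]
        centroids[fid] = tuple(c * s for c, s in zip(com, spacing))
        col0 += dc + gap_vox

    truth = SceneTruth(
        porosity=PorosityVolume(porosity, spacing, clipped=True),
        regions=RegionLabels(regions, spacing),
        fruits=FruitMasks(labels, spacing, counts, centroids),
        phantoms=phantoms,
    )
    calib = calib or fit_two_point()
    grey = porosity_to_grey(truth.porosity, calib, noise_sd=noise_sd, seed=seed)
    return grey, truth


# ---------------------------------------------------------------------------
# cellular phantom (high-resolution ROI)


@dataclass(frozen=True)
class CellPhantomSpec:
    """Recipe for a packed-sphere cellular ROI."""

    edge_mm: float = 0.5
    voxel_um: float = 6.6
    cell_diameter_um_mean: float = 69.0
    cell_diameter_um_sd: float = 2.0
    packing_fraction: float = 0.25        # analytic cell volume / cube volume
    n_cells: int | None = None            # exact count override (stops RSA)
    pore_diameter_um_mean: float = 30.0
    pore_diameter_um_sd: float = 4.0
    pore_fraction_interstitial: float = 0.2
    pore_volume_ratio: float | None = None  # direct target override
    cell_grey: int = 1500
    matrix_grey: int = 800
    pore_grey: int = -900
    noise_sd: float = 60.0
    min_gap_um: float = 2.0
    max_failures: int = 100_000       # RSA saturation patience
    seed: int = 0

    def validate(self) -> None:
        if not (0 < self.packing_fraction <= 0.74):
            raise ValueError("packing fraction must lie in (0, 0.74]")
        if self.cell_diameter_um_mean <= 0 or self.pore_diameter_um_mean <= 0:
            raise ValueError("diameters must be positive")
        if self.edge_mm <= 0 or self.voxel_um <= 0:
            raise ValueError("geometry must be positive")


@dataclass
class CellPhantom:
    """A cellular ROI with its exact sphere inventory."""

    grey: GreyVolume
    truth: pd.DataFrame              # center mm, diameter_um, polarity, voxel_count
    achieved_packing_fraction: float     # voxel-counted cell volume fraction
    achieved_pore_volume_ratio: float    # voxel-counted pore volume fraction
    spec: CellPhantomSpec


def _rsa_insert(
    rng: np.random.Generator,
    edge_um: float,
    diam_mean: float,
    diam_sd: float,
    margin_um: float,
    existing_centers: np.ndarray,
    existing_radii: np.ndarray,
    min_gap_um: float,
    stop_volume_um3: float | None,
    stop_count: int | None,
    max_failures: int = 100_000,
) -> tuple[np.ndarray, np.ndarray]:
    """Random sequential adsorption of non-overlapping spheres in a cube.

    Spheres stay fully inside (``margin_um`` from every face) and keep
    ``min_gap_um`` clearance from one another and from ``existing_*``
    spheres. Stops at the target volume / count, or raises once
    ``max_failures`` consecutive rejections suggest saturation.
    """
    cap = stop_count if stop_count is not None else 4096
    centers = np.empty((cap, 3))
    radii = np.empty(cap)
    n_acc = 0
    volume = 0.0
    failures = 0
    n_exist = len(existing_radii)
    while True:
        if stop_count is not None and n_acc >= stop_count:
            break
        if stop_count is None and stop_volume_um3 is not None and volume >= stop_volume_um3:
            break
        if failures >= max_failures:
            if stop_count is not None or stop_volume_um3 is not None:
                raise RuntimeError(
                    f"packing failed: achieved volume {volume:.3g} µm³ "
                    f"with {n_acc} spheres")
            break
        if n_acc == cap:
            centers = np.concatenate([centers, np.empty((cap, 3))])
            radii = np.concatenate([radii, np.empty(cap)])
            cap *= 2
        r = 0.5 * abs(rng.normal(diam_mean, diam_sd))
        lo, hi = r + margin_um, edge_um - r - margin_um
        if hi <= lo:
            failures += 1
            continue
        c = rng.uniform(lo, hi, size=3)
        clearance = r + min_gap_um
        if n_acc and np.any(
                ((centers[:n_acc] - c) ** 2).sum(axis=1)
                < (radii[:n_acc] + clearance) ** 2):
            failures += 1
            continue
        if n_exist and np.any(
                ((existing_centers - c) ** 2).sum(axis=1)
                < (existing_radii + clearance) ** 2):
            failures += 1
            continue
        centers[n_acc] = c
        radii[n_acc] = r
        n_acc += 1
        volume += 4.0 / 3.0 * np.pi * r ** 3
        failures = 0
    return centers[:n_acc].copy(), radii[:n_acc].copy()


def make_cell_phantom(spec: CellPhantomSpec = CellPhantomSpec()) -> CellPhantom:
    """Generate a cellular ROI by RSA sphere packing with exact truth.

    Bright cell spheres are inserted by strict non-overlap RSA until the
    target packing fraction (or exact ``n_cells``) is reached. Dark pore
    spheres follow in the interstitial space: they avoid cells but may
    merge with one another (gas channels interconnect), and insertion
    stops when the voxel union reaches the target gas volume, so the
    achieved pore fraction matches the target to within one sphere. All
    spheres stay fully inside the cube (≥ 1 voxel margin), so none touches
    the ROI boundary.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    edge_um = spec.edge_mm * 1000.0
    n = int(round(edge_um / spec.voxel_um))
    cube_um3 = (n * spec.voxel_um) ** 3
    margin = spec.voxel_um  # keep every sphere strictly interior

    cell_target = None if spec.n_cells is not None else spec.packing_fraction * cube_um3
    cell_centers, cell_radii = _rsa_insert(
        rng, edge_um, spec.cell_diameter_um_mean, spec.cell_diameter_um_sd,
        margin, np.empty((0, 3)), np.empty(0), spec.min_gap_um,
        cell_target, spec.n_cells, max_failures=spec.max_failures)

    grid = np.full((n, n, n), spec.matrix_grey, dtype=np.float64)
    rows: list[dict] = []

    def _sphere_mask(c, r):
        lo_idx = np.maximum(0, np.floor((c - r) / spec.voxel_um).astype(int))
        hi_idx = np.minimum(n, np.ceil((c + r) / spec.voxel_um).astype(int) + 1)
        local = np.meshgrid(
            *[(np.arange(a, b) + 0.5) * spec.voxel_um - cc
              for a, b, cc in zip(lo_idx, hi_idx, c)],
            indexing="ij", sparse=True)
        inside = sum(g ** 2 for g in local) <= r ** 2
        return tuple(slice(a, b) for a, b in zip(lo_idx, hi_idx)), inside

    def _record(c, r, polarity, count):
        rows.append({
            "center_slice_mm": c[0] / 1000.0, "center_row_mm": c[1] / 1000.0,
            "center_col_mm": c[2] / 1000.0, "diameter_um": 2 * r,
            "polarity": polarity, "voxel_count": int(count),
        })

    for c, r in zip(cell_centers, cell_radii):
        sl, inside = _sphere_mask(c, r)
        grid[sl][inside] = spec.cell_grey
        _record(c, r, "bright", inside.sum())
    cell_vox = sum(row["voxel_count"] for row in rows)

    # pores: non-overlapping with cells but free to merge with one another
    # (intercellular gas channels are interconnected); insertion tracks the
    # voxel union so the achieved gas fraction lands on the target exactly
    if spec.pore_volume_ratio is not None:
        pore_target_vox = int(round(spec.pore_volume_ratio * n ** 3))
    else:
        interstitial_vox = n ** 3 - cell_vox
        pore_target_vox = int(round(spec.pore_fraction_interstitial * interstitial_vox))
    pore_mask = np.zeros((n, n, n), dtype=bool)
    pore_vox = 0
    failures = 0
    while pore_vox < pore_target_vox:
        if failures >= spec.max_failures:
            raise RuntimeError(
                f"packing failed: pore fraction stalled at {pore_vox / n ** 3:.4f}")
        # batched candidates; only the cell-overlap constraint rejects
        radii = 0.5 * np.abs(rng.normal(spec.pore_diameter_um_mean,
                                        spec.pore_diameter_um_sd, size=256))
        lo = radii + margin
        hi = edge_um - radii - margin
        feasible = hi > lo
        cand = lo[:, None] + rng.uniform(0.0, 1.0, size=(256, 3)) * (hi - lo)[:, None]
        if len(cell_radii):
            d2 = ((cand[:, None, :] - cell_centers[None, :, :]) ** 2).sum(axis=2)
            clear = (radii[:, None] + cell_radii[None, :] + spec.min_gap_um) ** 2
            feasible &= ~(d2 < clear).any(axis=1)
        if not feasible.any():
            failures += 256
            continue
        failures = 0
        for c, r in zip(cand[feasible], radii[feasible]):
            sl, inside = _sphere_mask(c, r)
            new = inside & ~pore_mask[sl]
            added = int(new.sum())
            pore_mask[sl][inside] = True
            pore_vox += added
            _record(c, r, "dark", added)
            if pore_vox >= pore_target_vox:
                break
    grid[pore_mask] = spec.pore_grey

    truth = pd.DataFrame(rows, columns=[
        "center_slice_mm", "center_row_mm", "center_col_mm",
        "diameter_um", "polarity", "voxel_count"])
    if spec.noise_sd > 0:
        grid = grid + rng.normal(0.0, spec.noise_sd, grid.shape)
    grid = np.clip(np.rint(grid), INT16_MIN, INT16_MAX).astype(np.int16)
    sp = spec.voxel_um / 1000.0
    return CellPhantom(
        grey=GreyVolume(grid, (sp, sp, sp), {"synthetic": True}),
        truth=truth,
        achieved_packing_fraction=cell_vox / n ** 3,
        achieved_pore_volume_ratio=pore_vox / n ** 3,
        spec=spec,
    )


# ---------------------------------------------------------------------------
# quality table with planted two-factor group structure

#: trait → (group, loading on F1, loading on F2, raw mean, raw scale).
#: Group B alternates the sign of its F2 loading and group A carries a small
#: compensating cross-loading so that Σ_traits l1·l2 = 0 exactly: the planted
#: factors then coincide with the principal axes instead of rotating toward
#: a general factor, which keeps the A/B/C pattern identifiable.
DEFAULT_TRAITS: dict[str, tuple[str, float, float, float, float]] = {
    "seed_count":       ("A", 0.85, -0.0735, 8.0, 1.5),
    "seed_weight_g":    ("A", 0.85, -0.0735, 0.35, 0.08),
    "seed_length_mm":   ("A", 0.85, -0.0735, 8.5, 1.0),
    "cell_diameter_um": ("A", 0.85, -0.0735, 69.0, 1.2),
    "height_mm":        ("B", 0.50, 0.50, 55.0, 3.0),
    "sugar_brix":       ("B", 0.50, -0.50, 12.5, 1.2),
    "firmness_n":       ("B", 0.50, 0.50, 70.0, 6.0),
    "color_index":      ("B", 0.50, -0.50, 35.0, 5.0),
    "pore_diameter_um": ("B", 0.50, 0.50, 30.0, 3.0),
    "diameter_mm":      ("C", 0.00, 0.85, 55.0, 4.0),
    "weight_g":         ("C", 0.00, 0.85, 160.0, 20.0),
    "porosity_pct":     ("C", 0.00, 0.85, 26.5, 2.0),
}

#: treatment level → (shift of F1, shift of F2) in latent SD units
DEFAULT_TREATMENTS: dict[str, dict[str, tuple[float, float]]] = {
    "crop_load": {"high": (-1.0, 0.0), "standard": (0.0, 0.0), "low": (1.0, 0.0)},
}


@dataclass
class QualityTruth:
    groups: dict[str, str]
    factor_scores: pd.DataFrame
    loadings: pd.DataFrame


def make_quality_table(
    n_per_level: int = 9,
    treatments: dict[str, dict[str, tuple[float, float]]] | None = None,
    traits: dict[str, tuple[str, float, float, float, float]] | None = None,
    noise_inflation: float = 1.0,
    seed: int = 0,
) -> tuple[QualityTable, QualityTruth]:
    """Generate a quality table from two latent anatomical factors.

    Each trait is ``x = l1·F1 + l2·F2 + ε`` on a standardized scale (ε sized
    so the trait has unit total variance, times ``noise_inflation``), then
    mapped to realistic units. Treatment levels shift the latent factor
    means by the stated effect sizes; the full cross of all factor levels is
    replicated ``n_per_level`` times.
    """
    treatments = treatments if treatments is not None else DEFAULT_TREATMENTS
    traits = traits if traits is not None else DEFAULT_TRAITS
    groups = {t: g for t, (g, *_rest) in traits.items()}
    from collections import Counter
    if min(Counter(groups.values()).values()) < 2:
        raise ValueError("undersized design: need >= 2 parameters per group")
    for factor, levels in treatments.items():
        if len(levels) < 2:
            raise ValueError(f"factor {factor!r} needs >= 2 levels")

    rng = np.random.default_rng(seed)
    factor_names = list(treatments)
    level_lists = [list(treatments[f].items()) for f in factor_names]
    cells: list[tuple[tuple[str, ...], np.ndarray]] = []
    import itertools
    for combo in itertools.product(*level_lists):
        labels = tuple(name for name, _ in combo)
        delta = np.sum([np.asarray(d) for _, d in combo], axis=0)
        cells.append((labels, delta))

    rows, label_rows, f_rows, ids = [], [], [], []
    i = 0
    for labels, delta in cells:
        for _ in range(n_per_level):
            f = rng.normal(0.0, 1.0, size=2) + delta
            sample = {}
            for trait, (_g, l1, l2, mean, scale) in traits.items():
                resid_var = max(1e-6, 1.0 - l1 ** 2 - l2 ** 2)
                eps = rng.normal(0.0, np.sqrt(resid_var) * noise_inflation)
                sample[trait] = mean + scale * (l1 * f[0] + l2 * f[1] + eps)
            rows.append(sample)
            label_rows.append(dict(zip(factor_names, labels)))
            f_rows.append({"F1": f[0], "F2": f[1]})
            ids.append(f"S{i:03d}")
            i += 1

    params = pd.DataFrame(rows, index=ids)
    table = QualityTable(params=params,
                         treatments=pd.DataFrame(label_rows, index=ids))
    loadings = pd.DataFrame(
        {"F1": {t: v[1] for t, v in traits.items()},
         "F2": {t: v[2] for t, v in traits.items()}})
    return table, QualityTruth(groups, pd.DataFrame(f_rows, index=ids), loadings)


# ---------------------------------------------------------------------------
# synthetic DICOM series writer (reader-test support)


def write_synthetic_dicom_series(
    volume: GreyVolume,
    directory: str | Path,
    rescale_slope: float = 1.0,
    rescale_intercept: float = 0.0,
    filename_pattern: str = "slice_{:03d}.dcm",
) -> list[Path]:
    """Write a GreyVolume as a minimal single-frame synthetic DICOM series.

    Stored pixel values are ``(grey − intercept) / slope`` so that a reader
    applying the rescale header recovers the volume exactly. Intended for
    round-trip testing of :func:`pomoct.volume_io.read_dicom_series`.
    """
    import pydicom
    from pydicom.dataset import FileDataset, FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, generate_uid

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    series_uid = generate_uid()
    slice_sp, row_sp, col_sp = volume.spacing_mm
    paths = []
    for i in range(volume.shape[0]):
        stored = (volume.voxels[i].astype(np.float64) - rescale_intercept) / rescale_slope
        stored = np.rint(stored).astype(np.int16)
        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = pydicom.uid.CTImageStorage
        meta.MediaStorageSOPInstanceUID = generate_uid()
        meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds = FileDataset(None, {}, file_meta=meta, preamble=b"\0" * 128)
        ds.SOPClassUID = meta.MediaStorageSOPClassUID
        ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
        ds.Modality = "CT"
        ds.SeriesInstanceUID = series_uid
        ds.InstanceNumber = i + 1
        ds.ImagePositionPatient = [0.0, 0.0, i * slice_sp]
        ds.SliceThickness = slice_sp
        ds.SpacingBetweenSlices = slice_sp
        ds.PixelSpacing = [row_sp, col_sp]
        ds.Rows, ds.Columns = stored.shape
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 1  # signed
        ds.RescaleSlope = rescale_slope
        ds.RescaleIntercept = rescale_intercept
        ds.PixelData = stored.tobytes()
        path = directory / filename_pattern.format(i)
        ds.save_as(path, enforce_file_format=True)
        paths.append(path)
    return paths
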