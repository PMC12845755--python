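"""Macro-scale porosity summaries and treatment statistics.

Whole-fruit and per-region porosity means, 2D slice maps, interpolated line
profiles across the fruit, one-way ANOVA + Tukey HSD group comparisons, and
macro–micro correlation (both Pearson and Spearman, since tissue-level
porosity and cellular morphometrics need not be linearly related).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .calibration import PorosityVolume
from .segmentation import REGION_CODES, REGION_NAMES, FruitMasks, RegionLabels

AXES = {"slice": 0, "row": 1, "col": 2}


def whole_fruit_porosity(
    pmap: PorosityVolume,
    masks: FruitMasks,
    include_cavity: bool = True,
    regions: RegionLabels | None = None,
) -> dict[int, float]:
    """Arithmetic mean porosity over each fruit mask.

    Gas-filled cavity voxels count toward the mean by default (the fruit's
    internal void space is part of its porosity); pass
    ``include_cavity=False`` with a region map to restrict to tissue.
    """
    if pmap.shape != masks.labels.shape:
        raise ValueError("shapes do not match")
    if not include_cavity and regions is None:
        raise ValueError("excluding cavities requires a region map")
    out: dict[int, float] = {}
    for fid in masks.voxel_counts:
        m = masks.mask(fid)
        if not include_cavity:
            m = m & (regions.regions != REGION_CODES["cavity"])
        if not m.any():
            raise ValueError(f"no fruit voxels for fruit {fid}")
        out[fid] = float(pmap.porosity[m].mean())
    return out


def line_profile(
    pmap: PorosityVolume,
    start_mm: tuple[float, float, float],
    end_mm: tuple[float, float, float],
    n_samples: int = 100,
) -> pd.DataFrame:
    """Trilinearly interpolated porosity along a segment (positions in mm)."""
    if n_samples < 2:
        raise ValueError("need at least 2 samples")
    start = np.asarray(start_mm, dtype=np.float64)
    end = np.asarray(end_mm, dtype=np.float64)
    spacing = np.asarray(pmap.spacing_mm)
    extent = (np.asarray(pmap.shape) - 1) * spacing
    for pt in (start, end):
        if np.any(pt < 0) or np.any(pt > extent):
            raise ValueError("profile outside volume")
    t = np.linspace(0.0, 1.0, n_samples)
    points_mm = start[None, :] + t[:, None] * (end - start)[None, :]
    coords_vox = (points_mm / spacing).T
    values = ndimage.map_coordinates(pmap.porosity, coords_vox, order=1, mode="nearest")
    position = t * np.linalg.norm(end - start)
    return pd.DataFrame({"position_mm": position, "porosity_pct": values})


def slice_porosity_map(pmap: PorosityVolume, axis: str = "slice", index: int = 0):
    """Extract one plane of the porosity map with its in-plane spacings (mm)."""
    ax = AXES[axis]
    if not (0 <= index < pmap.shape[ax]):
        raise IndexError(f"index {index} out of range for axis {axis!r}")
    plane = np.take(pmap.porosity, index, axis=ax)
    in_plane = tuple(s for i, s in enumerate(pmap.spacing_mm) if i != ax)
    return plane, in_plane


def regional_summary(
    pmap: PorosityVolume, regions: RegionLabels, masks: FruitMasks | None = None
) -> pd.DataFrame:
    """Mean, SD and voxel count of porosity per anatomical region (per fruit).

    Absent regions appear with count 0 and NaN mean/SD so that downstream
    tables keep a fixed schema.
    """
    if pmap.shape != regions.regions.shape:
        raise ValueError("shapes do not match")
    fruit_ids = list(masks.voxel_counts) if masks is not None else [None]
    rows = []
    for fid in fruit_ids:
        sel = masks.mask(fid) if fid is not None else np.ones(pmap.shape, bool)
        for code, name in sorted(REGION_NAMES.items()):
            if name == "background":
                continue
            m = sel & (regions.regions == code)
            n = int(m.sum())
            rows.append({
                "fruit_id": fid if fid is not None else 1,
                "region": name,
                "mean_porosity_pct": float(pmap.porosity[m].mean()) if n else np.nan,
                "sd_porosity_pct": float(pmap.porosity[m].std()) if n else np.nan,
                "voxel_count": n,
            })
    return pd.DataFrame(rows)


@dataclass
class GroupComparison:
    f_statistic: float
    p_value: float
    tukey: pd.DataFrame  # pairwise: group_a, group_b, mean_diff, p_adj, ci_lo, ci_hi


def compare_groups(values: pd.DataFrame, value_col: str = "value",
                   group_col: str = "group", alpha: float = 0.05) -> GroupComparison:
    """One-way ANOVA with Tukey HSD pairwise comparisons at ``alpha``."""
    groups = {g: np.asarray(sub[value_col], dtype=np.float64)
              for g, sub in values.groupby(group_col, sort=True)}
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    for g, arr in groups.items():
        if arr.size < 2:
            raise ValueError(f"insufficient replication in group {g!r}")
    names = list(groups)
    arrays = [groups[g] for g in names]
    if all(np.ptp(a) == 0 for a in arrays) and len({a[0] for a in arrays}) == 1:
        f, p = 0.0, 1.0
    else:
        f, p = stats.f_oneway(*arrays)
        if not np.isfinite(f):
            f, p = 0.0, 1.0
    hsd = stats.tukey_hsd(*arrays)
    ci = hsd.confidence_interval(confidence_level=1 - alpha)
    rows = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            rows.append({
                "group_a": names[i], "group_b": names[j],
                "mean_diff": float(arrays[i].mean() - arrays[j].mean()),
                "p_adj": float(hsd.pvalue[i, j]),
                "ci_lo": float(ci.low[i, j]), "ci_hi": float(ci.high[i, j]),
            })
    return GroupComparison(float(f), float(p), pd.DataFrame(rows))


def macro_micro_correlation(macro, micro) -> dict[str, float]:
    """Pearson and Spearman correlation between paired macro/micro samples.

    Returns NaN markers when either vector is constant (correlation
    undefined).
    """
    x = np.asarray(macro, dtype=np.float64)
    y = np.asarray(micro, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("macro and micro must be paired 1D samples")
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        nan = float("nan")
        return {"pearson_r": nan, "pearson_p": nan,
                "spearman_r": nan, "spearman_p": nan}
    pr = stats.pearsonr(x, y)
    sr = stats.spearmanr(x, y)
    return {"pearson_r": float(pr.statistic), "pearson_p": float(pr.pvalue),
            "spearman_r": float(sr.statistic), "spearman_p": float(sr.pvalue)}
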