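"""Two-point grey-value → porosity calibration.

CT grey values (signed 16-bit) are mapped linearly onto porosity percent
using two reference materials: apple juice (0 % porosity, pure liquid) and
external air (100 % porosity). With the default anchors (juice 49,
air −1007) the model is

    porosity(g) = 100 · (juice − g) / (juice − air)

i.e. strictly decreasing in grey value. The raw model is unclamped so that
out-of-range voxels (dense seeds, metal) remain diagnosable; clamping to
[0, 100] is an explicit flag when producing a porosity map.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np

from .volume_io import GreyVolume

#: default reference anchors for 'Gala' apple scans (int16 grey values)
DEFAULT_JUICE_GREY = 49
DEFAULT_AIR_GREY = -1007


@dataclass(frozen=True)
class PorosityCalibration:
    """The unique line through (juice_grey, 0 %) and (air_grey, 100 %)."""

    juice_grey: float
    air_grey: float
    r_squared: float | None = None

    @property
    def slope(self) -> float:
        """Porosity percent per grey unit (negative when air is darker)."""
        return 100.0 / (self.air_grey - self.juice_grey)

    @property
    def intercept(self) -> float:
        return -self.slope * self.juice_grey

    def porosity(self, grey) -> np.ndarray | float:
        return self.slope * np.asarray(grey, dtype=np.float64) + self.intercept

    def grey(self, porosity) -> np.ndarray | float:
        """Inverse map: porosity percent → (unrounded) grey value."""
        return (np.asarray(porosity, dtype=np.float64) - self.intercept) / self.slope

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps({
            "juice_grey": self.juice_grey, "air_grey": self.air_grey,
            "slope": self.slope, "intercept": self.intercept,
            "r_squared": self.r_squared,
        }, indent=1))
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "PorosityCalibration":
        d = json.loads(Path(path).read_text())
        return cls(d["juice_grey"], d["air_grey"], d.get("r_squared"))


@dataclass
class PorosityVolume:
    """Voxelwise porosity percentages on the source volume's grid."""

    porosity: np.ndarray
    spacing_mm: tuple[float, float, float]
    clipped: bool = False
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.porosity = np.asarray(self.porosity, dtype=np.float64)
        if self.porosity.ndim != 3:
            raise ValueError("porosity must be a 3D array")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)  # type: ignore[assignment]
        if self.clipped and (
            np.nanmin(self.porosity) < 0 or np.nanmax(self.porosity) > 100
        ):
            raise ValueError("clipped porosity volume has values outside [0, 100]")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.porosity.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing_mm))


def fit_two_point(
    juice_grey: float = DEFAULT_JUICE_GREY,
    air_grey: float = DEFAULT_AIR_GREY,
) -> PorosityCalibration:
    """Fit the linear model through (juice_grey, 0) and (air_grey, 100).

    Raises ``ValueError("degenerate calibration")`` on equal anchors.
    """
    if juice_grey == air_grey:
        raise ValueError("degenerate calibration: reference greys are equal")
    return PorosityCalibration(float(juice_grey), float(air_grey))


def apply_calibration(
    volume: GreyVolume, calib: PorosityCalibration, clip: bool = True
) -> PorosityVolume:
    """Voxelwise affine grey→porosity map; optionally clamp to [0, 100]."""
    if volume.voxels.size == 0:
        raise ValueError("empty volume")
    p = calib.porosity(volume.voxels)
    if clip:
        p = np.clip(p, 0.0, 100.0)
    return PorosityVolume(p, volume.spacing_mm, clipped=clip)


@dataclass
class ValidationReport:
    """Spot-check of the calibration against known porosity at sampled voxels."""

    coordinates: np.ndarray     # (n, 3) voxel indices
    predicted: np.ndarray       # % porosity from the calibration
    true: np.ndarray            # % porosity ground truth
    r_squared: float


def validate_by_sampling(
    volume: GreyVolume,
    truth: PorosityVolume,
    calib: PorosityCalibration,
    n: int = 10,
    seed: int | np.random.Generator = 0,
) -> ValidationReport:
    """Sample ``n`` distinct voxels and score predicted vs true porosity.

    Mirrors the random spot-check used to validate grey→porosity regression
    models on scan data: voxels are drawn uniformly without replacement and
    the coefficient of determination of the calibration's predictions against
    the known porosity is reported.
    """
    if volume.shape != truth.shape:
        raise ValueError("volume and truth must share shape")
    if n < 2:
        raise ValueError("need n >= 2 samples")
    total = volume.voxels.size
    if n > total:
        raise ValueError("sample too large: n exceeds voxel count")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    flat = rng.choice(total, size=n, replace=False)
    coords = np.column_stack(np.unravel_index(flat, volume.shape))
    predicted = np.asarray(calib.porosity(volume.voxels.reshape(-1)[flat]))
    true = truth.porosity.reshape(-1)[flat]
    ss_res = float(np.sum((true - predicted) ** 2))
    ss_tot = float(np.sum((true - true.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else (1.0 if ss_res == 0 else float("nan"))
    return ValidationReport(coords, predicted, true, r2)
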