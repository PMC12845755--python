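"""Volumetric I/O for the CT pipeline.

Reads single-frame DICOM series into :class:`GreyVolume` (signed 16-bit,
axis order ``(slice, row, col)``) and writes grey/porosity volumes as
multi-page TIFF stacks or per-slice CSV files with a JSON spacing sidecar.
Tabular morphometrics go out as plain delimited text.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pydicom
import tifffile

log = logging.getLogger(__name__)

INT16_MIN, INT16_MAX = -32768, 32767

#: fallback inter-slice spacing (mm) when the series carries no usable tag;
#: matches the whole-fruit scanning protocol this package targets
DEFAULT_SLICE_SPACING_MM = 0.5


@dataclass
class GreyVolume:
    """A reconstructed CT volume of signed 16-bit grey values.

    Attributes
    ----------
    voxels : ndarray, int16, shape (slice, row, col)
    spacing_mm : (slice_thickness, row_spacing, col_spacing), mm
    series_meta : free-form scan metadata carried along for provenance
    """

    voxels: np.ndarray
    spacing_mm: tuple[float, float, float]
    series_meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError("GreyVolume requires a 3D array (slice, row, col)")
        if self.voxels.dtype != np.int16:
            if np.issubdtype(self.voxels.dtype, np.floating) or (
                self.voxels.min() < INT16_MIN or self.voxels.max() > INT16_MAX
            ):
                raise ValueError("voxel values do not fit the signed 16-bit range")
            self.voxels = self.voxels.astype(np.int16)
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)  # type: ignore[assignment]
        if len(self.spacing_mm) != 3 or any(
            not np.isfinite(s) or s <= 0 for s in self.spacing_mm
        ):
            raise ValueError("spacing_mm must be three strictly positive finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing_mm))


def _dicom_sort_key(ds: pydicom.Dataset) -> float:
    pos = getattr(ds, "ImagePositionPatient", None)
    if pos is not None and len(pos) == 3:
        return float(pos[2])
    loc = getattr(ds, "SliceLocation", None)
    if loc is not None:
        return float(loc)
    return float(getattr(ds, "InstanceNumber", 0))


def read_dicom_series(directory: str | Path) -> GreyVolume:
    """Read a single-frame DICOM series into a :class:`GreyVolume`.

    Slices are ordered by slice-position tag (fallback: instance number),
    independent of on-disk file names. Per-file rescale slope/intercept is
    applied before casting to int16; out-of-range values are clamped with
    a warning.

    Raises
    ------
    FileNotFoundError
        if the directory contains no readable DICOM file ("no DICOM found").
    ValueError
        on mixed series UIDs or inconsistent slice dimensions
        ("inconsistent series").
    """
    directory = Path(directory)
    datasets: list[pydicom.Dataset] = []
    for path in sorted(directory.iterdir()) if directory.is_dir() else []:
        if not path.is_file():
            continue
        try:
            ds = pydicom.dcmread(path)
            _ = ds.pixel_array  # force decode; skip non-image files
        except Exception:
            continue
        datasets.append(ds)
    if not datasets:
        raise FileNotFoundError(f"no DICOM found in {directory}")

    uids = {getattr(ds, "SeriesInstanceUID", None) for ds in datasets}
    if len(uids) > 1:
        raise ValueError("inconsistent series: multiple SeriesInstanceUIDs")
    dims = {(int(ds.Rows), int(ds.Columns)) for ds in datasets}
    if len(dims) > 1:
        raise ValueError("inconsistent series: slice dimensions differ")

    datasets.sort(key=_dicom_sort_key)

    slices = []
    for ds in datasets:
        arr = ds.pixel_array.astype(np.float64)
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        arr = arr * slope + intercept
        if arr.min() < INT16_MIN or arr.max() > INT16_MAX:
            warnings.warn(
                "rescaled grey values exceed the int16 range; clamping",
                stacklevel=2,
            )
            arr = np.clip(arr, INT16_MIN, INT16_MAX)
        slices.append(np.rint(arr).astype(np.int16))
    voxels = np.stack(slices, axis=0)

    first = datasets[0]
    pixel_spacing = getattr(first, "PixelSpacing", None)
    if pixel_spacing is not None:
        row_sp, col_sp = float(pixel_spacing[0]), float(pixel_spacing[1])
    else:
        warnings.warn("no PixelSpacing tag; assuming 1 mm in-plane", stacklevel=2)
        row_sp = col_sp = 1.0
    slice_sp = _slice_spacing(datasets)

    meta = {
        "series_uid": str(getattr(first, "SeriesInstanceUID", "")),
        "modality": str(getattr(first, "Modality", "")),
        "n_files": len(datasets),
        "source": str(directory),
    }
    return GreyVolume(voxels, (slice_sp, row_sp, col_sp), meta)


def _slice_spacing(datasets: Sequence[pydicom.Dataset]) -> float:
    tag = getattr(datasets[0], "SpacingBetweenSlices", None)
    if tag is not None and float(tag) > 0:
        return float(tag)
    if len(datasets) > 1:
        positions = [_dicom_sort_key(ds) for ds in datasets]
        diffs = np.diff(sorted(positions))
        if np.all(diffs > 0):
            return float(np.median(diffs))
    tag = getattr(datasets[0], "SliceThickness", None)
    if tag is not None and float(tag) > 0:
        return float(tag)
    warnings.warn(
        f"no usable slice-spacing tag; falling back to {DEFAULT_SLICE_SPACING_MM} mm",
        stacklevel=3,
    )
    return DEFAULT_SLICE_SPACING_MM


# ---------------------------------------------------------------------------
# volume writing / reading (TIFF stack or CSV slices, + JSON sidecar)

def _volume_payload(volume) -> tuple[np.ndarray, tuple[float, float, float], str]:
    """Return (array, spacing, kind) for GreyVolume- or PorosityVolume-likes."""
    if hasattr(volume, "voxels"):
        return np.asarray(volume.voxels), volume.spacing_mm, "grey"
    if hasattr(volume, "porosity"):
        return np.asarray(volume.porosity, dtype=np.float32), volume.spacing_mm, "porosity"
    raise TypeError("expected a GreyVolume or PorosityVolume")


def write_volume(volume, path: str | Path, format: str = "tiff_stack") -> Path:
    """Write a volume losslessly (int16) or as float32 (porosity maps).

    ``tiff_stack`` writes a multi-page TIFF; ``csv_slices`` writes one CSV
    per slice into a directory. Both record spacing and value kind in a JSON
    sidecar next to the data.
    """
    path = Path(path)
    arr, spacing, kind = _volume_payload(volume)
    sidecar = {"spacing_mm": list(spacing), "kind": kind, "dtype": str(arr.dtype),
               "shape": list(arr.shape)}
    if format == "tiff_stack":
        path.parent.mkdir(parents=True, exist_ok=True)
        tifffile.imwrite(path, arr, photometric="minisblack")
        sidecar_path = path.with_suffix(path.suffix + ".json")
    elif format == "csv_slices":
        path.mkdir(parents=True, exist_ok=True)
        for i in range(arr.shape[0]):
            np.savetxt(path / f"slice_{i:04d}.csv", arr[i], delimiter=",",
                       fmt="%d" if arr.dtype.kind == "i" else "%.6g")
        sidecar_path = path / "metadata.json"
    else:
        raise ValueError(f"unknown format: {format!r}")
    sidecar_path.write_text(json.dumps(sidecar, indent=1))
    return path


def read_volume(path: str | Path):
    """Read a volume written by :func:`write_volume` (round-trip partner)."""
    from .calibration import PorosityVolume  # local import; avoids a cycle

    path = Path(path)
    if path.is_dir():
        sidecar = json.loads((path / "metadata.json").read_text())
        files = sorted(path.glob("slice_*.csv"))
        arr = np.stack([np.loadtxt(f, delimiter=",", ndmin=2) for f in files])
        arr = arr.astype(sidecar["dtype"])
    else:
        sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        arr = tifffile.imread(path)
        if arr.ndim == 2:
            arr = arr[None]
    spacing = tuple(sidecar["spacing_mm"])
    if sidecar["kind"] == "grey":
        return GreyVolume(arr, spacing)
    return PorosityVolume(arr, spacing)


def write_metrics(records: Iterable[Mapping[str, Any] | Any], path: str | Path) -> Path:
    """Write a homogeneous record table as CSV (header + deterministic columns).

    Records may be mappings or dataclass instances; all must share one schema
    ("schema mismatch" otherwise). An empty iterable yields a header-only file
    only when the schema can be inferred from a pandas DataFrame input.
    """
    path = Path(path)
    if isinstance(records, pd.DataFrame):
        df = records
    else:
        rows = []
        schema: tuple[str, ...] | None = None
        for rec in records:
            if dataclasses.is_dataclass(rec) and not isinstance(rec, type):
                rec = dataclasses.asdict(rec)
            if not isinstance(rec, Mapping):
                raise TypeError("records must be mappings or dataclasses")
            keys = tuple(rec.keys())
            if schema is None:
                schema = keys
            elif set(keys) != set(schema):
                raise ValueError("schema mismatch between records")
            rows.append({k: rec[k] for k in schema})
        df = pd.DataFrame(rows, columns=list(schema) if schema else None)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path
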