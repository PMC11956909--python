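"""Shared containers and coordinate conventions.

World coordinates are always micrometres (μm), corner-anchored: voxel
``(i, j, k)`` of a label volume spans the half-open box
``[i*sx, (i+1)*sx) x [j*sy, (j+1)*sy) x [k*sz, (k+1)*sz)``, so a point maps
to the voxel ``floor(coord / spacing)``.  Label arrays are indexed
``[ix, iy, iz]`` (x fastest-varying coordinate first); image stacks follow
the microscopy page order ``[iz, iy, ix]``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import tifffile

#: Required columns of a cell point table, the exchange format between stages.
POINT_COLUMNS = ("x_um", "y_um", "z_um", "cell_type", "subject_id", "group")

BACKGROUND_LABEL = 0


def validate_point_table(points: pd.DataFrame) -> None:
    """Raise ``ValueError`` if *points* lacks the cell-point-table columns."""
    missing = [c for c in POINT_COLUMNS if c not in points.columns]
    if missing:
        raise ValueError(f"point table missing columns: {missing}")
    coords = points[["x_um", "y_um", "z_um"]].to_numpy(float)
    if coords.size and not np.all(np.isfinite(coords)):
        raise ValueError("point table contains non-finite coordinates")


def read_points(path: str | Path) -> pd.DataFrame:
    """Read a cell point table from CSV or Parquet (by extension)."""
    path = Path(path)
    if path.suffix == ".parquet":
        points = pd.read_parquet(path)
    else:
        points = pd.read_csv(path)
    validate_point_table(points)
    return points


def write_points(points: pd.DataFrame, path: str | Path) -> None:
    path = Path(path)
    if path.suffix == ".parquet":
        points.to_parquet(path, index=False)
    else:
        points.to_csv(path, index=False)


@dataclass
class LabelVolume:
    """Integer region labels on a regular anisotropic grid.

    Parameters
    ----------
    labels
        Integer array indexed ``[ix, iy, iz]``; 0 is background.
    spacing_um
        Voxel edge lengths ``(sx, sy, sz)`` in μm.
    regions
        Region table with columns ``region_id``, ``name``, ``volume_mm3``.
    """

    labels: np.ndarray
    spacing_um: tuple[float, float, float]
    regions: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["region_id", "name", "volume_mm3"]))

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("labels must be a 3-D array")
        self.spacing_um = tuple(float(s) for s in self.spacing_um)
        if any(s <= 0 for s in self.spacing_um):
            raise ValueError("voxel spacing must be positive")

    @property
    def voxel_volume_mm3(self) -> float:
        sx, sy, sz = self.spacing_um
        return (sx * sy * sz) * 1e-9

    @property
    def extent_um(self) -> tuple[float, float, float]:
        """Physical size (x, y, z) of the volume in μm."""
        return tuple(n * s for n, s in zip(self.labels.shape, self.spacing_um))

    def voxel_of(self, coords_um: np.ndarray) -> np.ndarray:
        """Map ``(n, 3)`` world coordinates to integer voxel indices (floor)."""
        coords_um = np.asarray(coords_um, dtype=float)
        return np.floor(coords_um / np.asarray(self.spacing_um)).astype(np.int64)

    def label_at(self, coords_um: np.ndarray) -> np.ndarray:
        """Region label for each point; out-of-volume points get background."""
        idx = self.voxel_of(np.atleast_2d(coords_um))
        shape = np.asarray(self.labels.shape)
        inside = np.all((idx >= 0) & (idx < shape), axis=1)
        out = np.full(len(idx), BACKGROUND_LABEL, dtype=self.labels.dtype)
        ii = idx[inside]
        out[inside] = self.labels[ii[:, 0], ii[:, 1], ii[:, 2]]
        return out

    def region_volume_mm3(self, region_id: int) -> float:
        row = self.regions.loc[self.regions["region_id"] == region_id]
        if row.empty:
            raise KeyError(f"unknown region id {region_id}")
        return float(row["volume_mm3"].iloc[0])

    # -- I/O ---------------------------------------------------------------
    def save(self, volume_path: str | Path, regions_path: str | Path | None = None) -> None:
        """Write the label array as NIfTI (spacing in the affine) + region CSV."""
        affine = np.diag([*self.spacing_um, 1.0])
        img = nib.Nifti1Image(self.labels.astype(np.int32), affine)
        img.header.set_zooms(self.spacing_um)
        nib.save(img, str(volume_path))
        if regions_path is not None:
            self.regions.to_csv(regions_path, index=False)

    @classmethod
    def load(cls, volume_path: str | Path, regions_path: str | Path | None = None) -> "LabelVolume":
        img = nib.load(str(volume_path))
        labels = np.asarray(img.dataobj).astype(np.int32)
        spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
        regions = (pd.read_csv(regions_path) if regions_path is not None
                   else pd.DataFrame(columns=["region_id", "name", "volume_mm3"]))
        return cls(labels=labels, spacing_um=spacing, regions=regions)


@dataclass
class ImageStack:
    """A 3-D intensity stack with physical voxel spacing.

    ``data`` is indexed ``[iz, iy, ix]`` (TIFF page order); ``spacing_um``
    is ``(sx, sy, sz)``, default STPT-like 1 x 1 x 50 μm.
    """

    data: np.ndarray
    spacing_um: tuple[float, float, float] = (1.0, 1.0, 50.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("stack must be a 3-D array")
        self.spacing_um = tuple(float(s) for s in self.spacing_um)
        if any(s <= 0 for s in self.spacing_um):
            raise ValueError("voxel spacing must be positive")

    @property
    def extent_um(self) -> tuple[float, float, float]:
        """Physical size (x, y, z) in μm."""
        nz, ny, nx = self.data.shape
        sx, sy, sz = self.spacing_um
        return (nx * sx, ny * sy, nz * sz)

    def save(self, path: str | Path) -> None:
        tifffile.imwrite(
            str(path), self.data.astype(np.float32),
            photometric="minisblack",
            resolution=(1e4 / self.spacing_um[0], 1e4 / self.spacing_um[1]),
            metadata={"spacing": self.spacing_um[2], "unit": "um"},
        )

    @classmethod
    def load(cls, path: str | Path,
             spacing_um: tuple[float, float, float] = (1.0, 1.0, 50.0)) -> "ImageStack":
        return cls(data=tifffile.imread(str(path)), spacing_um=spacing_um)
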