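"""Assign cells to atlas regions and build region x cell-type density matrices.

Densities are volumetric (cells/mm³): the count of a cell type inside a
region divided by the region volume.  The max-normalized variant divides
each cell type's regional densities by that type's maximum over regions,
mapping each composition profile into [0, 1] — the form consumed by the
composition clustering stage.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import BACKGROUND_LABEL, LabelVolume, validate_point_table

log = logging.getLogger(__name__)


def assign_regions(points: pd.DataFrame, atlas: LabelVolume) -> pd.DataFrame:
    """Return a copy of *points* with a ``region_id`` column.

    Each point gets the label of the voxel containing it under the half-open
    grid convention (a point exactly on a shared voxel face belongs to the
    higher-index voxel).  Points outside the volume get the background label;
    their count is logged.
    """
    validate_point_table(points)
    out = points.copy()
    coords = out[["x_um", "y_um", "z_um"]].to_numpy(float)
    out["region_id"] = atlas.label_at(coords) if len(out) else np.array([], dtype=int)
    extent = np.asarray(atlas.extent_um)
    n_outside = int(np.sum(np.any((coords < 0) | (coords >= extent), axis=1))) \
        if len(out) else 0
    if n_outside:
        log.info("assign_regions: %d of %d points fall outside the label volume",
                 n_outside, len(out))
    return out


@dataclass
class RegionDensityMatrix:
    """Region x cell-type counts and densities, with per-subject slices.

    ``per_subject`` is tidy (region_id, cell_type, subject_id, count,
    density_cells_per_mm3); ``densities`` is the wide aggregate (unweighted
    mean over subjects); ``normalized`` is filled by :func:`max_normalize`.
    """

    per_subject: pd.DataFrame
    densities: pd.DataFrame
    counts: pd.DataFrame
    n_outside_atlas: int = 0
    normalized: pd.DataFrame | None = None
    zero_cell_types: list[str] = field(default_factory=list)


def region_density_matrix(points: pd.DataFrame, atlas: LabelVolume) -> RegionDensityMatrix:
    """Count points per (region, cell type, subject) and convert to densities.

    Background (out-of-atlas) points are excluded from the matrix but
    reported in ``n_outside_atlas``.  Subjects absent from a (region, type)
    cell contribute an explicit zero, so the aggregate is the unweighted
    mean density over all subjects present in *points*.
    """
    if "region_id" not in points.columns:
        raise ValueError("points must carry a region_id column (run assign_regions)")
    regions = atlas.regions.sort_values("region_id")
    if (regions["volume_mm3"] <= 0).any():
        bad = regions.loc[regions["volume_mm3"] <= 0, "region_id"].tolist()
        raise ValueError(f"regions with zero volume cannot carry densities: {bad}")

    in_atlas = points[points["region_id"] != BACKGROUND_LABEL]
    n_outside = len(points) - len(in_atlas)

    cell_types = sorted(points["cell_type"].unique())
    subjects = sorted(points["subject_id"].unique())
    full_index = pd.MultiIndex.from_product(
        [regions["region_id"], cell_types, subjects],
        names=["region_id", "cell_type", "subject_id"])
    counts = (in_atlas.groupby(["region_id", "cell_type", "subject_id"])
              .size().reindex(full_index, fill_value=0).rename("count"))
    tidy = counts.reset_index()
    volumes = regions.set_index("region_id")["volume_mm3"]
    tidy["density_cells_per_mm3"] = (
        tidy["count"] / tidy["region_id"].map(volumes).to_numpy())

    dens_wide = tidy.pivot_table(index="region_id", columns="cell_type",
                                 values="density_cells_per_mm3", aggfunc="mean")
    count_wide = tidy.pivot_table(index="region_id", columns="cell_type",
                                  values="count", aggfunc="sum")
    return RegionDensityMatrix(per_subject=tidy, densities=dens_wide,
                               counts=count_wide, n_outside_atlas=n_outside)


def max_normalize(matrix: RegionDensityMatrix) -> RegionDensityMatrix:
    """Divide each cell type's column by its maximum regional density.

    All-zero columns stay zero and are recorded in ``zero_cell_types`` with
    a warning.  Returns the same object with ``normalized`` filled in.
    """
    dens = matrix.densities
    col_max = dens.max(axis=0)
    zero_cols = col_max.index[col_max == 0].tolist()
    if zero_cols:
        warnings.warn(f"cell types with zero density everywhere: {zero_cols}",
                      stacklevel=2)
    safe = col_max.replace(0, 1.0)
    matrix.normalized = dens / safe
    matrix.zero_cell_types = zero_cols
    return matrix
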