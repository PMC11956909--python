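"""Synthetic brains: toy atlases, Poisson point clouds, and nuclear image stacks.

The generator emulates the kind of data produced by whole-brain nuclear
labelling experiments: an integer label volume standing in for a reference
atlas, per-region homogeneous Poisson point processes for each cell type
(with optional multiplicative group effects, e.g. sex), and anisotropic
Gaussian-blob image stacks standing in for serial two-photon sections.
Everything is reproducible from a single root seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .core import BACKGROUND_LABEL, ImageStack, LabelVolume, validate_point_table


# ---------------------------------------------------------------------------
# geometries

@dataclass(frozen=True)
class Box:
    """Axis-aligned half-open box ``[lo, hi)`` in μm."""

    lo: tuple[float, float, float]
    hi: tuple[float, float, float]

    def __post_init__(self) -> None:
        if not all(h > l for l, h in zip(self.lo, self.hi)):
            raise ValueError(f"box must have positive extent: lo={self.lo} hi={self.hi}")

    def contains(self, pts: np.ndarray) -> np.ndarray:
        lo = np.asarray(self.lo)
        hi = np.asarray(self.hi)
        return np.all((pts >= lo) & (pts < hi), axis=1)

    @property
    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        return np.asarray(self.lo, float), np.asarray(self.hi, float)


@dataclass(frozen=True)
class Sphere:
    """Closed ball of ``radius_um`` around ``center`` (μm)."""

    center: tuple[float, float, float]
    radius_um: float

    def __post_init__(self) -> None:
        if self.radius_um <= 0:
            raise ValueError("sphere radius must be positive")

    def contains(self, pts: np.ndarray) -> np.ndarray:
        d2 = np.sum((pts - np.asarray(self.center)) ** 2, axis=1)
        return d2 <= self.radius_um ** 2

    @property
    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        c = np.asarray(self.center, float)
        r = self.radius_um
        return c - r, c + r


Geometry = Box | Sphere


@dataclass(frozen=True)
class RegionSpec:
    region_id: int
    name: str
    geometry: Geometry


@dataclass
class AtlasSpec:
    """Recipe for a toy label volume."""

    extent_um: tuple[float, float, float]
    spacing_um: tuple[float, float, float]
    regions: list[RegionSpec] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [r.region_id for r in self.regions]
        if len(set(ids)) != len(ids):
            raise ValueError("region ids must be unique")
        if any(i <= 0 for i in ids):
            raise ValueError("region ids must be > 0 (0 is background)")
        ext = np.asarray(self.extent_um, float)
        for r in self.regions:
            lo, hi = r.geometry.bounds
            if np.any(lo < 0) or np.any(hi > ext):
                raise ValueError(
                    f"region {r.region_id} ({r.name}) extends outside the volume "
                    f"extent {tuple(ext)}")


@dataclass
class IntensityTable:
    """Per-(region, cell type) Poisson intensities in cells/mm³.

    ``group_effects`` holds optional multiplicative modifiers per
    (cell_type, group); an absent pair means multiplier 1.
    """

    entries: pd.DataFrame  # region_id, cell_type, density_per_mm3
    group_effects: pd.DataFrame | None = None  # cell_type, group, multiplier

    def __post_init__(self) -> None:
        req = {"region_id", "cell_type", "density_per_mm3"}
        if not req.issubset(self.entries.columns):
            raise ValueError(f"intensity entries need columns {sorted(req)}")
        if (self.entries["density_per_mm3"] < 0).any():
            raise ValueError("intensities must be >= 0")
        dup = self.entries.duplicated(["region_id", "cell_type"])
        if dup.any():
            raise ValueError("duplicate (region_id, cell_type) intensity entries")
        if self.group_effects is not None:
            if (self.group_effects["multiplier"] <= 0).any():
                raise ValueError("group multipliers must be > 0")

    @property
    def cell_types(self) -> list[str]:
        return sorted(self.entries["cell_type"].unique())

    def multiplier(self, cell_type: str, group: str) -> float:
        if self.group_effects is None:
            return 1.0
        m = self.group_effects.query(
            "cell_type == @cell_type and group == @group")["multiplier"]
        return float(m.iloc[0]) if len(m) else 1.0


# ---------------------------------------------------------------------------
# atlas construction

def build_toy_atlas(spec: AtlasSpec) -> LabelVolume:
    """Rasterise an :class:`AtlasSpec` onto its voxel grid.

    A voxel gets label ``r`` iff its *center* lies inside region ``r``'s
    geometry.  A voxel center claimed by two regions is an error (the
    regions overlap).
    """
    spacing = np.asarray(spec.spacing_um, float)
    shape = np.round(np.asarray(spec.extent_um) / spacing).astype(int)
    labels = np.zeros(tuple(shape), dtype=np.int32)

    rows = []
    voxel_volume = float(np.prod(spacing)) * 1e-9
    for region in spec.regions:
        lo, hi = region.geometry.bounds
        i_lo = np.maximum(np.floor(lo / spacing).astype(int), 0)
        i_hi = np.minimum(np.ceil(hi / spacing).astype(int), shape)
        axes = [ (np.arange(i_lo[d], i_hi[d]) + 0.5) * spacing[d] for d in range(3) ]
        if any(len(a) == 0 for a in axes):
            rows.append((region.region_id, region.name, 0.0))
            continue
        cx, cy, cz = np.meshgrid(*axes, indexing="ij")
        centers = np.column_stack([cx.ravel(), cy.ravel(), cz.ravel()])
        inside = region.geometry.contains(centers)
        sub = labels[i_lo[0]:i_hi[0], i_lo[1]:i_hi[1], i_lo[2]:i_hi[2]]
        mask = inside.reshape(sub.shape)
        clash = mask & (sub != BACKGROUND_LABEL)
        if clash.any():
            other = int(sub[clash][0])
            raise ValueError(
                f"regions {other} and {region.region_id} overlap "
                "(a voxel center lies in both)")
        sub[mask] = region.region_id
        rows.append((region.region_id, region.name, int(mask.sum()) * voxel_volume))

    regions = pd.DataFrame(rows, columns=["region_id", "name", "volume_mm3"])
    return LabelVolume(labels=labels, spacing_um=tuple(spacing), regions=regions)


# ---------------------------------------------------------------------------
# point sampling

def _subject_seeds(seed: int, n: int) -> list[np.random.SeedSequence]:
    """Deterministic per-subject streams: children of ``SeedSequence(seed)``."""
    return np.random.SeedSequence(seed).spawn(n)


def sample_point_cloud(
    atlas: LabelVolume,
    intensities: IntensityTable,
    subject_id: str,
    group: str = "NA",
    seed: int | np.random.SeedSequence = 0,
) -> pd.DataFrame:
    """Draw one subject's cells: a homogeneous Poisson process per region.

    Within each labelled region, each cell type is sampled with intensity
    ``density_per_mm3 x group multiplier``: a Poisson total over the region's
    voxels, placed uniformly inside uniformly-chosen labelled voxels (which
    is exactly the homogeneous process restricted to the region's voxelised
    support).
    """
    known = set(atlas.regions["region_id"].tolist())
    wanted = set(intensities.entries["region_id"].tolist())
    unknown = sorted(wanted - known)
    if unknown:
        raise ValueError(f"intensity entries reference unknown region ids {unknown}")

    rng = np.random.default_rng(seed)
    spacing = np.asarray(atlas.spacing_um)
    voxel_mm3 = atlas.voxel_volume_mm3

    frames = []
    entries = intensities.entries.sort_values(
        ["region_id", "cell_type"]).reset_index(drop=True)
    voxels_by_region = {
        rid: np.argwhere(atlas.labels == rid)
        for rid in sorted(wanted)
    }
    for _, row in entries.iterrows():
        rid = row["region_id"]
        ctype = row["cell_type"]
        lam = float(row["density_per_mm3"]) * intensities.multiplier(ctype, group)
        voxels = voxels_by_region[rid]
        if lam == 0 or len(voxels) == 0:
            continue
        n = rng.poisson(lam * voxel_mm3 * len(voxels))
        if n == 0:
            continue
        chosen = voxels[rng.integers(0, len(voxels), size=n)]
        coords = (chosen + rng.random((n, 3))) * spacing
        frames.append(pd.DataFrame({
            "x_um": coords[:, 0], "y_um": coords[:, 1], "z_um": coords[:, 2],
            "cell_type": ctype, "subject_id": subject_id, "group": group,
        }))
    if not frames:
        return pd.DataFrame(
            columns=["x_um", "y_um", "z_um", "cell_type", "subject_id", "group"])
    out = pd.concat(frames, ignore_index=True)
    validate_point_table(out)
    return out


def sample_cohort(
    atlas: LabelVolume,
    intensities: IntensityTable,
    subjects: Sequence[tuple[str, str]],
    seed: int = 0,
) -> pd.DataFrame:
    """Sample several subjects ``(subject_id, group)`` from one root seed."""
    seeds = _subject_seeds(seed, len(subjects))
    frames = [
        sample_point_cloud(atlas, intensities, sid, grp, seed=ss)
        for (sid, grp), ss in zip(subjects, seeds)
    ]
    frames = [f for f in frames if len(f)]
    if not frames:
        return pd.DataFrame(
            columns=["x_um", "y_um", "z_um", "cell_type", "subject_id", "group"])
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# image rendering

@dataclass
class ImageSpec:
    """Recipe for a synthetic nuclear-signal stack (STPT-like anisotropy)."""

    shape: tuple[int, int, int] = (8, 256, 256)  # (nz, ny, nx)
    spacing_um: tuple[float, float, float] = (1.0, 1.0, 50.0)  # (sx, sy, sz)
    nucleus_radius_um: float = 3.0
    amplitude: float = 100.0
    background: float = 10.0
    noise_sd: float = 10.0
    psf_sigma_um: float = 0.0

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.spacing_um):
            raise ValueError("spacing must be positive")
        if self.nucleus_radius_um <= 0:
            raise ValueError("nucleus radius must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be >= 0")


def render_nuclei_stack(
    points: pd.DataFrame,
    image_spec: ImageSpec,
    seed: int | np.random.SeedSequence = 0,
) -> tuple[ImageStack, pd.DataFrame]:
    """Render nuclei as anisotropy-aware Gaussian blobs plus Gaussian noise.

    Each point becomes an additive Gaussian blob with per-axis standard
    deviation ``sqrt(radius² + psf_sigma²)`` μm on a constant background;
    independent pixel noise of ``noise_sd`` is added on top.  Returns the
    stack and the ground-truth centroid table.
    """
    nz, ny, nx = image_spec.shape
    sx, sy, sz = image_spec.spacing_um
    extent = np.array([nx * sx, ny * sy, nz * sz])

    coords = points[["x_um", "y_um", "z_um"]].to_numpy(float) if len(points) else \
        np.empty((0, 3))
    outside = np.where(np.any((coords < 0) | (coords >= extent), axis=1))[0]
    if len(outside):
        raise ValueError(
            f"{len(outside)} points lie outside the stack extent {tuple(extent)}: "
            f"row indices {outside[:10].tolist()}")

    rng = np.random.default_rng(seed)
    data = np.full((nz, ny, nx), float(image_spec.background))
    sigma = math.hypot(image_spec.nucleus_radius_um, image_spec.psf_sigma_um)
    spacing = np.array([sz, sy, sx])  # array axis order (z, y, x)
    half = np.maximum(np.ceil(4.0 * sigma / spacing).astype(int), 0)

    for x, y, z in coords:
        center = np.array([z, y, x])  # μm, (z, y, x)
        ic = np.floor(center / spacing).astype(int)
        lo = np.maximum(ic - half, 0)
        hi = np.minimum(ic + half + 1, np.array([nz, ny, nx]))
        ax = [(np.arange(lo[d], hi[d]) + 0.5) * spacing[d] - center[d] for d in range(3)]
        gz = np.exp(-0.5 * (ax[0] / sigma) ** 2)
        gy = np.exp(-0.5 * (ax[1] / sigma) ** 2)
        gx = np.exp(-0.5 * (ax[2] / sigma) ** 2)
        blob = gz[:, None, None] * gy[None, :, None] * gx[None, None, :]
        data[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] += image_spec.amplitude * blob

    if image_spec.noise_sd > 0:
        data += rng.normal(0.0, image_spec.noise_sd, size=data.shape)

    truth = pd.DataFrame(coords, columns=["x_um", "y_um", "z_um"])
    return ImageStack(data=data, spacing_um=image_spec.spacing_um), truth


def sample_nuclei_scene(
    n: int,
    image_spec: ImageSpec,
    min_separation_um: float = 15.0,
    margin_um: float = 10.0,
    seed: int | np.random.SeedSequence = 0,
) -> pd.DataFrame:
    """Ground-truth nucleus positions for a detection test scene.

    Nuclei sit at z-slice centers (a nucleus is much thinner than the
    inter-plane spacing, so it is captured by a single optical section) and
    keep a minimum in-plane separation within each slice, emulating a field
    sparse enough that nuclei rarely touch.
    """
    nz, ny, nx = image_spec.shape
    sx, sy, sz = image_spec.spacing_um
    rng = np.random.default_rng(seed)
    pts: list[np.ndarray] = []
    attempts = 0
    while len(pts) < n:
        attempts += 1
        if attempts > 200 * n:
            raise ValueError("cannot place nuclei at this separation/density")
        cand = np.array([
            rng.random() * (nx * sx - 2 * margin_um) + margin_um,
            rng.random() * (ny * sy - 2 * margin_um) + margin_um,
            (rng.integers(0, nz) + 0.5) * sz,
        ])
        ok = all(p[2] != cand[2]
                 or math.hypot(p[0] - cand[0], p[1] - cand[1]) >= min_separation_um
                 for p in pts)
        if ok:
            pts.append(cand)
    return pd.DataFrame(np.array(pts), columns=["x_um", "y_um", "z_um"])


# ---------------------------------------------------------------------------
# shipped demo fixture

#: Default cell types of the demo brain, loosely echoing an excitatory
#: marker, an interneuron marker and a neuropeptide marker.
DEMO_CELL_TYPES = ("exc", "inh", "npy")


def demo_atlas_spec(spacing_um: float = 50.0) -> AtlasSpec:
    """A 4x4x4 mm toy brain with 8 disjoint regions.

    Region sizes and the intensity ladder in :func:`demo_intensity_table`
    are chosen so that regional densities span roughly 2x10⁴ to 5.3x10⁵
    cells/mm³ while a 6-subject cohort stays near 10⁵ points in total.
    """
    regions = [
        RegionSpec(1, "cortex_like", Box((200, 200, 200), (650, 500, 450))),
        RegionSpec(2, "thalamus_like", Box((1800, 200, 200), (2100, 500, 450))),
        RegionSpec(3, "striatum_like", Box((3000, 300, 200), (3300, 600, 400))),
        RegionSpec(4, "hippocampus_like", Box((200, 1800, 300), (500, 2000, 500))),
        RegionSpec(5, "hypothalamus_like", Box((1600, 1700, 300), (1800, 1900, 500))),
        RegionSpec(6, "midbrain_like", Box((2800, 1800, 300), (3000, 2000, 450))),
        RegionSpec(7, "dense_nucleus", Sphere((700, 3000, 600), 85.0)),
        RegionSpec(8, "compact_nucleus", Sphere((2000, 3050, 600), 100.0)),
    ]
    return AtlasSpec(extent_um=(4000.0, 4000.0, 4000.0),
                     spacing_um=(spacing_um,) * 3, regions=regions)


def demo_intensity_table(male_exc_multiplier: float = 1.2) -> IntensityTable:
    """Demo intensities (cells/mm³) spanning the realistic density range.

    A multiplicative group effect on the excitatory type in group "M"
    provides a known positive for the two-group comparison stage.
    """
    lam = {  # region_id -> (exc, inh, npy), thousands of cells per mm3
        1: (25, 20, 30),
        2: (20, 45, 25),
        3: (30, 60, 90),
        4: (45, 30, 100),
        5: (60, 150, 40),
        6: (90, 40, 60),
        7: (530, 80, 50),
        8: (120, 350, 300),
    }
    rows = [
        (rid, ctype, 1000.0 * dens)
        for rid, densities in lam.items()
        for ctype, dens in zip(DEMO_CELL_TYPES, densities)
    ]
    entries = pd.DataFrame(rows, columns=["region_id", "cell_type", "density_per_mm3"])
    effects = pd.DataFrame(
        [("exc", "M", male_exc_multiplier)],
        columns=["cell_type", "group", "multiplier"])
    return IntensityTable(entries=entries, group_effects=effects)


def demo_subjects(n_subjects: int = 6) -> list[tuple[str, str]]:
    """Alternating male/female subject labels, e.g. [(s01, M), (s02, F), ...]."""
    return [(f"s{i + 1:02d}", "M" if i % 2 == 0 else "F") for i in range(n_subjects)]


# ---------------------------------------------------------------------------
# planted-structure fixtures for the clustering stages

def planted_block_matrix(
    n_regions_per_block: int = 4,
    n_blocks: int = 4,
    n_types: int = 8,
    noise: float = 0.05,
    seed: int | np.random.SeedSequence = 0,
    low: float = 4.0e4,
    high: float = 4.0e5,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Region x cell-type density matrix with a planted block structure.

    Each block of regions shares a composition profile (its own pair of
    high-density cell types against a low baseline); every entry gets
    multiplicative lognormal noise ``exp(noise * N(0,1))``.  Returns the
    wide density matrix and the planted block label per region.
    """
    if n_types < 2 * n_blocks:
        raise ValueError("need at least two cell types per block")
    rng = np.random.default_rng(seed)
    labels = np.repeat(np.arange(n_blocks), n_regions_per_block)
    base = np.full((n_blocks, n_types), low)
    for b in range(n_blocks):
        base[b, 2 * b] = high
        base[b, 2 * b + 1] = 0.6 * high
    dens = base[labels] * np.exp(noise * rng.standard_normal(
        (len(labels), n_types)))
    matrix = pd.DataFrame(
        dens,
        index=pd.Index([f"r{i + 1:02d}" for i in range(len(labels))], name="region_id"),
        columns=[f"t{j + 1}" for j in range(n_types)],
    )
    return matrix, labels
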