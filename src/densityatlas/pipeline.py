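"""End-to-end orchestration: generate -> detect -> quantify -> cluster ->
parcellate -> compare, with a hashed output manifest for reproducibility."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .composition_clustering import (correlation_distance, cut_tree,
                                     hierarchical_cluster, linkage_frame,
                                     save_clustermap)
from .core import write_points
from .density_parcellation import (DEFAULT_LEVELS, cluster_region_overlap,
                                   percentile_sweep, threshold_table)
from .group_comparison import compare_groups
from .image_detection import detect_nuclei, match_detections
from .region_quantification import (assign_regions, max_normalize,
                                    region_density_matrix)
from .synthetic_data import (ImageSpec, build_toy_atlas, demo_atlas_spec,
                             demo_intensity_table, demo_subjects,
                             render_nuclei_stack, sample_cohort,
                             sample_nuclei_scene)

log = logging.getLogger(__name__)

#: Analysis conventions in effect, recorded in every run manifest.
CONVENTIONS = {
    "neighbor_counts": "self excluded, boundary inclusive (distance <= epsilon)",
    "core_condition": "neighbor count >= MinPoints",
    "percentile_estimator": "linear interpolation between order statistics",
    "minpoints_rounding": "nearest integer, .5 up",
    "border_assignment": "cluster of the lowest-index core neighbor",
    "pooling": "DBSCAN on the union of subjects' points with pooled MinPoints",
    "voxel_convention": "half-open, corner-anchored; point -> floor(coord/spacing)",
    "aggregation": "unweighted mean density over subjects",
}


@dataclass
class PipelineConfig:
    """Validated configuration for a full demo run."""

    outdir: str
    seed: int = 0
    n_subjects: int = 6
    atlas_spacing_um: float = 50.0
    epsilon_um: float = 150.0
    levels: tuple = DEFAULT_LEVELS
    k_clusters: int = 4
    alpha: float = 0.05
    parcellate_cell_types: list[str] | None = None  # None = all cell types
    run_detection: bool = True
    detection_n_nuclei: int = 50
    intensity_scale: float = 1.0  # scales all demo intensities (for quick runs)
    make_figures: bool = False

    def validate(self) -> None:
        if self.epsilon_um <= 0:
            raise ValueError("epsilon_um must be positive")
        if self.atlas_spacing_um <= 0:
            raise ValueError("atlas_spacing_um must be positive")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        if self.k_clusters < 1:
            raise ValueError("k_clusters must be >= 1")
        if not all(0 < lv < 100 for lv in self.levels):
            raise ValueError("levels must be percentiles in (0, 100)")
        if self.intensity_scale <= 0:
            raise ValueError("intensity_scale must be positive")
        if self.detection_n_nuclei < 1:
            raise ValueError("detection_n_nuclei must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        cfg = cls(**raw)
        if isinstance(cfg.levels, list):
            cfg.levels = tuple(cfg.levels)
        cfg.validate()
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["levels"] = list(self.levels)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(1 << 20), b""):
            h.update(block)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all enabled stages and return the manifest (also written as JSON).

    Any stage failure aborts the run with the stage name and cause; outputs
    produced so far are retained and listed under a ``failed/`` marker.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "config.yaml")

    log.info("densityatlas %s, seed=%d", __version__, config.seed)
    for key, val in CONVENTIONS.items():
        log.info("convention %s: %s", key, val)

    root = np.random.SeedSequence(config.seed)
    ss_cohort, ss_detect = root.spawn(2)
    # data products only: the config echo contains the output path itself
    produced: list[Path] = []
    state: dict = {}

    def stage(name):
        def wrap(fn):
            try:
                fn()
            except Exception as exc:
                marker_dir = outdir / "failed"
                marker_dir.mkdir(exist_ok=True)
                (marker_dir / f"{name}.txt").write_text(
                    f"stage {name} failed: {exc}\n")
                raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc
        return wrap

    @stage("generate")
    def _generate():
        atlas = build_toy_atlas(demo_atlas_spec(config.atlas_spacing_um))
        intens = demo_intensity_table()
        if config.intensity_scale != 1.0:
            intens.entries = intens.entries.assign(
                density_per_mm3=intens.entries["density_per_mm3"]
                * config.intensity_scale)
        points = sample_cohort(atlas, intens, demo_subjects(config.n_subjects),
                               seed=ss_cohort.generate_state(1)[0] % (2 ** 31))
        atlas.save(outdir / "atlas.nii", outdir / "regions.csv")
        write_points(points, outdir / "points.csv")
        produced.extend([outdir / "atlas.nii", outdir / "regions.csv",
                         outdir / "points.csv"])
        state["atlas"], state["points"] = atlas, points

    @stage("detect")
    def _detect():
        if not config.run_detection:
            return
        rng = np.random.default_rng(ss_detect.generate_state(1)[0] % (2 ** 31))
        spec = ImageSpec(shape=(8, 256, 256), nucleus_radius_um=3.0,
                         amplitude=100.0, background=10.0, noise_sd=10.0)
        pts = sample_nuclei_scene(config.detection_n_nuclei, spec, seed=rng)
        stack, truth = render_nuclei_stack(pts, spec, seed=rng)
        stack.save(outdir / "stack.tif")
        result = detect_nuclei(stack, tensor_sigma_um=spec.nucleus_radius_um,
                               response_percentile=99.0, min_size_voxels=5)
        result.centroids.to_csv(outdir / "detected_centroids.csv", index=False)
        metrics = match_detections(result.centroids, truth, radius_um=5.0)
        (outdir / "detection_metrics.json").write_text(
            json.dumps(asdict(metrics), indent=2) + "\n")
        produced.extend([outdir / "stack.tif", outdir / "detected_centroids.csv",
                         outdir / "detection_metrics.json"])

    @stage("quantify")
    def _quantify():
        points = assign_regions(state["points"], state["atlas"])
        matrix = max_normalize(region_density_matrix(points, state["atlas"]))
        matrix.per_subject.to_csv(outdir / "density_per_subject.csv", index=False)
        matrix.densities.to_csv(outdir / "density_matrix.csv")
        matrix.normalized.to_csv(outdir / "normalized_matrix.csv")
        produced.extend([outdir / "density_per_subject.csv",
                         outdir / "density_matrix.csv",
                         outdir / "normalized_matrix.csv"])
        state["points_assigned"], state["matrix"] = points, matrix

    @stage("cluster")
    def _cluster():
        matrix = state["matrix"]
        dist = correlation_distance(matrix.normalized)
        tree = hierarchical_cluster(dist, method="ward")
        k = min(config.k_clusters, tree.n_leaves)
        labels = cut_tree(tree, k)
        linkage_frame(tree).to_csv(outdir / "linkage.csv", index=False)
        pd.DataFrame({"region_id": tree.leaf_ids, "cluster": labels}).to_csv(
            outdir / "cluster_labels.csv", index=False)
        produced.extend([outdir / "linkage.csv", outdir / "cluster_labels.csv"])
        if config.make_figures:
            save_clustermap(matrix.normalized, tree, str(outdir / "clustermap.png"))
            produced.append(outdir / "clustermap.png")

    @stage("parcellate")
    def _parcellate():
        points = state["points_assigned"]
        types = (config.parcellate_cell_types
                 or sorted(points["cell_type"].unique()))
        thresholds = threshold_table(points[points["cell_type"].isin(types)],
                                     config.epsilon_um, config.levels)
        thresholds.to_csv(outdir / "thresholds.csv", index=False)
        produced.append(outdir / "thresholds.csv")
        for ctype in types:
            sub = points[points["cell_type"] == ctype].reset_index(drop=True)
            sweep = percentile_sweep(
                sub, thresholds[thresholds["cell_type"] == ctype])
            frames = [res.to_frame() for res in sweep]
            pd.concat(frames, ignore_index=True).to_csv(
                outdir / f"parcellation_{ctype}.csv", index=False)
            summaries = {str(res.level): res.summaries(sub).to_dict("records")
                         for res in sweep}
            (outdir / f"clusters_{ctype}.json").write_text(
                json.dumps(summaries, indent=2) + "\n")
            overlaps = [cluster_region_overlap(res, sub).assign(level=res.level)
                        for res in sweep]
            pd.concat(overlaps, ignore_index=True).to_csv(
                outdir / f"overlap_{ctype}.csv", index=False)
            produced.extend([outdir / f"parcellation_{ctype}.csv",
                             outdir / f"clusters_{ctype}.json",
                             outdir / f"overlap_{ctype}.csv"])

    @stage("compare")
    def _compare():
        groups = state["points"]["group"].unique()
        subj_groups = state["points"][["subject_id", "group"]].drop_duplicates()
        per_subject = state["matrix"].per_subject.merge(subj_groups, on="subject_id")
        table = compare_groups(per_subject, str(groups[0]), str(groups[1]),
                               alpha=config.alpha)
        table.to_csv(outdir / "comparison.csv", index=False)
        produced.append(outdir / "comparison.csv")

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "conventions": CONVENTIONS,
        "outputs": {p.name: _sha256(p) for p in sorted(produced)},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
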