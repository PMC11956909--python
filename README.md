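# densityatlas

Whole-brain cell-type density analysis for point-cloud neuroanatomy:
region-level density quantification against a labelled reference volume,
hierarchical clustering of regions by cell-type composition, and an
unsupervised *density-based spatial parcellation* that delineates brain
structures purely from local cell densities. A synthetic-brain generator and
an unsupervised nuclei detector make every stage testable end to end without
any imaging data.

## Who this is for

Labs producing whole-brain cell coordinates — e.g. serial two-photon
tomography (STPT) of Cre-reporter mice with nuclei detected per section and
registered to a common coordinate framework — who want to go from
`(x, y, z, cell type, subject)` tables to regional densities, composition
clusters, and unbiased density-defined parcels.

## The core method

For a cell type with points \(p_1..p_n\) (μm), define for each cell its
neighbor count within a fixed radius ε (default **150 μm**):

```
c(p) = #{ q ≠ p : ‖p − q‖ ≤ ε }
```

so `c(p) / V_ε` with `V_ε = (4/3)π(ε/1000)³ mm³ ≈ 0.01414 mm³` is a local
density in cells/mm³ (one neighbor ≈ 70.7 cells/mm³). Per subject, take the
nine deciles (10th–90th percentile) of the count distribution; average each
level over subjects and multiply by the number of subjects to get nine
pooled **MinPoints** thresholds. Running DBSCAN (core point ⇔
`c(p) ≥ MinPoints`) on the pooled cloud at each threshold produces a nested
series of spatial clusters: low percentiles trace broad territories, high
percentiles isolate only the densest anatomical foci. Cluster–region
agreement is scored with Dice/Jaccard over point sets.

Around that core: densities per atlas region (`count / volume`), column-wise
max normalization, `1 − Pearson r` profile distances with Ward linkage for
composition clustering, Welch + Benjamini–Hochberg two-group comparison, and
a curvature-tensor (Hessian-of-Gaussian) nuclei detector with
connected-components segmentation for anisotropic stacks (1×1×50 μm).

## Worked example

```python
import densityatlas as da

atlas = da.build_toy_atlas(da.demo_atlas_spec())          # 4×4×4 mm, 8 regions
points = da.sample_cohort(atlas, da.demo_intensity_table(),
                          da.demo_subjects(6), seed=1)    # 116015 cells

assigned = da.assign_regions(points, atlas)
matrix = da.max_normalize(da.region_density_matrix(assigned, atlas))
print(matrix.densities.round(0))
```

```
cell_type       exc       inh       npy
region_id
1           27210.0   20079.0   29748.0
2           21881.0   44326.0   25230.0
...
7          580250.0   77833.0   48625.0
8          127792.0  354083.0  305542.0
```

Densities recover the generating intensities (region 7 was simulated at
530,000 cells/mm³ for the excitatory type; region 1 at 25,000 with a ×1.2
male multiplier, hence the ≈27,200 cohort mean). The percentile sweep:

```python
exc = points[points.cell_type == "exc"].reset_index(drop=True)
thresholds = da.threshold_table(exc)                      # ε = 150 μm default
print(thresholds[["level", "minpoints_pooled", "density_cells_per_mm3"]])

sweep = da.percentile_sweep(exc, thresholds)
for res in (sweep[0], sweep[-1]):
    print(f"level {res.level}: {res.n_clusters} clusters, "
          f"{(res.labels == -1).sum()} noise points")
```

```
 level  minpoints_pooled  density_cells_per_mm3
    10               950                11200.0
    ...
    90             13159               155136.0
level 10: 8 clusters, 0 noise points
level 90: 1 clusters, 25556 noise points
```

At the 10th percentile every region forms its own spatial cluster; by the
90th only the densest nucleus survives — and it coincides exactly with the
atlas region that generated it:

```python
overlap = da.cluster_region_overlap(
    sweep[-1], assigned[assigned.cell_type == "exc"].reset_index(drop=True))
print(overlap)
#  cluster_id  region_id  dice  jaccard  cluster_in_region_frac
#           0          7   1.0      1.0                     1.0
```

## Command line

```bash
densityatlas generate --outdir out --seed 1 --n-subjects 6
densityatlas quantify --points out/points.csv --atlas out/atlas.nii \
    --regions out/regions.csv --outdir out
densityatlas parcellate --points out/points.csv --epsilon 150 --outdir out
densityatlas cluster --matrix out/normalized_matrix.csv --k 4 --outdir out
densityatlas compare --per-subject out/density_per_subject.csv --out out/cmp.csv
densityatlas run --config config.yaml        # full pipeline + hashed manifest
```

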