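# myomatrix

Reconstruction and quantification of branching myofibrillar networks
("myofibrillar matrix") from labeled 3D muscle image volumes.

Striated muscle sarcomeres can branch and merge, linking neighbouring
myofibrils into a single mesh. Given a volume in which every myofibrillar
segment carries a unique integer label (plus masks for the sarcotubular
system and the cell boundary), this package rebuilds the longitudinal
segment graph, detects and classifies split/merge junction events, tracks
myofibrils down the muscle's long axis, and computes branching, morphometric,
volumetric and spatial statistics. A ground-truthed synthetic muscle
generator makes the whole pipeline testable without any imaging data.

## Modules

| module | purpose |
| --- | --- |
| `myomatrix.volume_io` | TIFF/HDF5 volume I/O, reorientation (axis permutation + flips), integer binning with modal-label reduction |
| `myomatrix.synthetic_muscle` | ground-truthed generator of branching muscle volumes spanning 0%–~66% branching regimes |
| `myomatrix.structure_segmentation` | probability-map thresholding, outlier removal, cell volume-fraction composition |
| `myomatrix.matrix_topology` | segment graph construction, split/merge event classification, myofibril tracking with field-of-view censoring, branching statistics |
| `myomatrix.morphometry_spatial` | per-slice CSA/circularity, volume-weighted mean CSA, sarcolemma distance transform, peripheral-bias permutation test |
| `myomatrix.group_stats` | SuperPlot per-cell summaries; gated group comparisons (ANOVA + Brown–Forsythe → Tukey/Dunn; Shapiro–Wilk → t-test/rank-sum) |

## CLI

```sh
# generate a synthetic volume + ground truth
myomatrix simulate --config sim.yaml

# segment graph, tracking, branching metrics
myomatrix topology --labels labels.tif --cell cell.tif --srt srt.tif \
    --max-gap 4 --out results/

# per-slice morphometry
myomatrix morphometry --labels labels.tif --out morpho.csv

# volume fractions from probability maps
myomatrix segment --config seg.yaml

# SuperPlot summaries + group comparison
myomatrix stats --metrics metrics.csv --groups groups.yaml --out stats.json
```

A minimal simulate config:

```yaml
generator:
  shape: [512, 64, 64]        # (long, row, col) voxels
  voxel_size: [20.0, 20.0, 20.0]  # nm
  n_myofibrils: 9
  sarcomere_length: 500.0     # nm
  srt_gap_thickness: 40.0     # nm
  myofibril_radius_mean: 80.0 # nm
  cell_margin: 40.0           # nm
  p_single: 0.27              # P(single branching event) per sarcomere
  p_multi: 0.39               # P(multi branching event) per sarcomere
  multi_multiplicity_pmf: {3: 0.34, 4: 0.66}
  p_merge_fraction: 0.5
  seed: 0
output:
  directory: out/
  format: tiff_stack
```

## Conventions

- Volumes are stored `(long, row, col)` with the muscle's longitudinal axis
  as axis 0; voxel sizes are nanometres.
- Label 0 is background; each myofibrillar segment has a unique positive
  label, and labels are never reused after a junction event.
- An event with two resultant (or incoming) segments is a *single* branching
  event; three or more is *multi*; its branch count is the larger side minus
  one. Splits and merges both count as branching.
- Cells, not myofibrils, are the unit of replication in all group summaries
  (mean ± SE over cell means).
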