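# atlas-msi

Anatomy-driven MALDI mass-spectrometry-imaging (MSI) analysis pipeline with a
synthetic phantom generator. The pipeline distils per-pixel mass spectra into
atlas-aligned region statistics:

1. **preprocessing** — Gauss smoothing, morphological TopHat baseline
   subtraction, per-pixel TIC normalization, and cross-sample m/z alignment on
   common peaks (≥ 85 % presence) with a linear per-sample recalibration.
2. **feature_extraction** — global base-peak spectrum (per-bin max over every
   pixel of every sample), peak picking on it, extraction of pixels × features
   image cubes, and a class-dependent log variance-stabilizing transform
   (metabolites only).
3. **registration** — atlas-section selection by hippocampus maximum cord
   length, affine (moments-initialised, multi-resolution MSE) followed by
   B-spline refinement (iterative optical-flow residual projected onto a
   control grid), and resampling of cubes onto the atlas grid.
4. **roi_stats** — per-animal ROI × hemisphere means, paired L-vs-R t-tests
   within groups, unpaired between-group t-tests, Benjamini-Hochberg FDR per
   (ROI × comparison) family, block randomization, and a metabolite-ratio
   post-mortem QC.
5. **annotation** — theoretical monoisotopic/adduct masses, PTM/adduct
   delta-pair detection with spatial-correlation support, ppm compound
   matching.
6. **synthetic_data** — toy atlas (cortex/striatum/hippocampus/thalamus +
   midline), geometrically deformed phantom sections with serialized truth
   transforms and landmarks, and complete imzML studies with planted
   group × hemisphere effects, Poisson noise, and mass-calibration drift.

Everything runs from open formats only: imzML/ibd, PNG/TIFF label maps + JSON
legends, CSV/TSV tables, YAML configs, JSON transforms, HDF5 cubes.

## Test

```sh
python -m pytest tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (analytic masses,
delta-pair detection, planted-effect recovery on a full 32-animal synthetic
study, null calibration of the paired test, registration recovery, and oracle
equivalence checks). The full suite takes a few minutes; the end-to-end
recovery test alone runs a complete simulate → analyze cycle.

## CLI

```sh
atlas-msi --out-dir demo --seed 1 simulate        # write a synthetic study
atlas-msi run-all demo                            # full analysis -> demo/results/
atlas-msi annotate --formula C5H9NO4              # theoretical [M-H]- mass
atlas-msi register demo                           # registration diagnostics
atlas-msi features demo                           # picked base-peak features
```

A study directory contains `study.yaml`, `design.csv`, `atlas/` (label maps +
legends), `sections/` (imzML + per-section label maps), and `truth/`
(generator ground truth: planted effects, transforms, landmarks).

## Real-data hook

The toy atlas stands in for a real reference atlas. To use real data, provide
imzML sections plus `<stem>.meta.yaml` sidecars, label-map PNGs with JSON
legends for the atlas (`read_labelmap`), and a `study.yaml`/`design.csv`
matching the synthetic layout; externally computed transforms can be imported
through the `SectionTransform` JSON schema.
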