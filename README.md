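# patchseg

Patch-based CNN voxel classification for tumour localization and
segmentation on multiparametric MR, testable end to end on synthetic
phantoms. The pipeline:

1. **phantom** — synthetic co-registered multiparametric volumes (T2w,
   DWI b0, DWI high-b) with ground-truth tumour masks, hyperintense
   distractors, optional artefacts and channel misalignment.
2. **preprocess** — per-sequence intensity standardization (mean 0, SD 1)
   and a simplified deformable registration stage (B-spline free-form,
   mutual information, bending-energy penalty) aligning sequences to the
   DWI-b0 reference.
3. **sampling** — decomposition of each labelled volume into four strata
   (tumour T; a 10 mm physical-distance shell B1; remaining
   diffusion-hyperintense voxels B2 above the standardized 2.0 cutoff;
   everything else B3) and class-balanced patch draws with quotas
   N : N/4 : N/2 : N/4.
4. **model** — a nine-layer convolutional patch classifier (conv 24 →
   conv 48 → pool → conv 96 → pool → conv 192 → pool → fc → fc, 360
   filters total; full padding, leaky rectifiers, dropout 1/3 after pools
   and 1/2 after the hidden fc), trained with Adadelta on cross-entropy +
   L2 and patience-based early stopping. Implemented in pure NumPy.
5. **infer** — per-voxel probability maps and segmentation by thresholding
   at p ≥ 0.5 plus largest-connected-component selection.
6. **evaluate** — per-subject Dice and voxelwise ROC AUC, plus an
   ICC(A,1)-based stability protocol across repeated sampling/training
   runs.

## Tests

```sh
python -m pytest -q tests/
```

The suite includes property tests against independent brute-force oracles
(exhaustive distance scans for the dilation strata, flood-fill connected
components, Mann–Whitney pair counting for AUC, two-way ANOVA for the ICC)
and a scaled-down end-to-end acceptance experiment (20 + 10 phantom
subjects); the full run takes several minutes on one CPU.

## CLI

```sh
patchseg phantom --n 30 --seed 7 --out cohort/ [--distractor-large] [--artefact fat_suppression_band]
patchseg preprocess --subject cohort/sub-000 --out pre/sub-000 [--register]
patchseg sample --subject cohort/sub-000 --out patches --n 5000 --m 21
patchseg train --patches patches --out model.npz
patchseg predict --model model.npz --subject cohort/sub-001 --out pred/ [--threshold 0.5] [--connectivity 26]
patchseg evaluate --pred pred/ --truth cohort/ --out report.tsv
patchseg stability --config exp.yaml --out stab/ --n-runs 4
patchseg run-all --config exp.yaml --out exp/
```

`run-all` drives the whole experiment from a single YAML config (see
`patchseg.experiment.ExperimentConfig`; `desk_scale_config()` returns a
ready-made single-CPU configuration). Volumes are read and written as
NIfTI with spacing metadata; cohort manifests are plain TSV.

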