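# restconn

Resting-state fMRI connectivity analysis and clinical-outcome prediction,
exercised end-to-end on synthetic cohorts with planted effects.

The pipeline implements:

- **Synthetic cohorts** (`restconn.synth`): 4-D BOLD runs on a common grid
  with a band-limited latent signal planted in a spherical seed region,
  target regions coupled to it with per-subject strength, WM/CSF nuisance
  signals, drifts, motion traces with injected spike frames, and an
  integer-consistent clinical outcome linearly driven by the coupling.
  Fully reproducible from a single RNG seed.
- **Confound modeling** (`restconn.confounds`): framewise displacement,
  artifact-frame detection from within-subject percentiles of the motion
  and global-signal-change diagnostics, per-frame scrubbing regressors,
  compartment PCA (top-5 WM + top-5 CSF components from unsmoothed data),
  and assembled designs for two strategies (`acompcor`, `gsr`).
- **Denoising** (`restconn.denoise`): confound regression → linear detrend
  → tanh despiking → ideal 0.01–0.1 Hz band-pass, plus 6-mm FWHM spatial
  smoothing with edge renormalization.
- **Connectivity** (`restconn.connectivity`): voxelwise global brain
  connectivity (mean squared correlation with all in-mask voxels; signed
  variant behind a flag) and spherical-seed Fisher-z FC maps.
- **Group statistics** (`restconn.group_stats`): covariate-adjusted
  one-sample t-maps and cluster-extent FWE correction by sign-flip
  permutation (Freedman–Lane), voxel-forming threshold p < .001 two-sided.
- **Prediction** (`restconn.prediction`): leave-one-out elastic-net
  prediction of the percent-change outcome with training-fold-only
  covariate residualization, feature standardization and nested
  hyperparameter selection; permutation p-values for r and MSE;
  sign-separated weight-map clusters; baseline-score specificity control.
- **Clinical statistics** (`restconn.clinical`): percent change, Cohen's d,
  pooled two-sample t, 50:50 chi-squared, paired t, demographics table.
- **Orchestration** (`restconn.pipeline`, `restconn.cli`): YAML-driven
  pipeline with per-stage seeding and provenance JSON.

## CLI

```sh
restconn synth --out-dir cohort --n-subjects 22 --rng-seed 1
restconn denoise --bold cohort/sub-01_bold.nii --motion cohort/sub-01_motion.txt \
    --brain-mask cohort/mask_brain.nii --gm-mask cohort/mask_gm.nii \
    --wm-mask cohort/mask_wm.nii --csf-mask cohort/mask_csf.nii \
    --denoise-strategy acompcor --out sub-01_clean.nii
restconn connectivity --bold sub-01_clean.nii --brain-mask cohort/mask_brain.nii \
    --seed-mm 0,15,3 --out-prefix sub-01
restconn group sub-*_seed_fc_z.nii --subjects subjects.tsv --out-prefix group
restconn predict sub-*_gbc.nii --subjects subjects.tsv --feature-kind gbc \
    --n-perm 1000 --out-prefix prediction_gbc
restconn clinical --subjects cohort/subjects.tsv --out table1.tsv
restconn run-all pipeline.yaml --both-strategies
restconn validate-config pipeline.yaml
```

A pipeline YAML has a `paths` block (`bold`, `motion`, the four masks,
`subjects`, `output_dir`) and optional `denoise` / `connectivity` /
`prediction` / `group` blocks plus `tr_seconds` and `rng_seed`; see
`restconn.pipeline.PipelineConfig.from_dict`.

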