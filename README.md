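# netsync

Between-network synchronization analysis for resting-state fMRI, as a
tested, reusable pipeline:

1. **Temporal preprocessing** — nuisance regression (motion-like
   regressors, white-matter and CSF mean signals) followed by retention
   of frequencies below 0.08 Hz (ideal FFT brick-wall by default, an
   order-4 Butterworth behind a flag).
2. **Group spatial ICA** — subjects are voxelwise variance-normalized
   and temporally concatenated, PCA-reduced to a configurable number of
   components (default 20), and unmixed with FastICA (logcosh contrast,
   seeded restarts, plus a one-unit polish that releases the exact
   spatial-decorrelation constraint). Maps are z-scored over the brain
   mask and sign-oriented to non-negative skewness.
3. **Template matching** — each named network template (e.g. DMN, CEN,
   CAN, SN, AN) is assigned the component with the highest
   goodness-of-fit score (mean z inside the template minus mean z
   outside); a close second (ratio ≥ 0.9 by default) is kept as a
   component of interest. The full GOF matrix is persisted for audit.
4. **Dual regression** — stage 1 regresses the group maps (jointly, with
   intercept) into each subject's 4D data to get subject network time
   courses; stage 2 regresses those time courses back into the data to
   get subject spatial maps, z-scored.
5. **Network statistics** — per-subject pairwise Pearson correlations
   between network time courses; pooled two-sample t-tests per network
   pair (optionally age-adjusted via a common-slope residualization, and
   optionally on Fisher-z values); Monte-Carlo cluster-size correction
   on the network-pair graph (connected supra-threshold edges, null of
   the maximum cluster size from group-label permutations); voxelwise
   permutation cluster-extent tests on subject maps (z > 2.3,
   26-connectivity); Pearson brain–behavior correlations; and
   summary-statistics utilities (pooled t from printed means/SDs, 2×2
   chi-square) for reproducing published tables.
6. **Synthetic phantom generator** — group studies with planted network
   blobs, group-specific inter-network correlation matrices (realized
   *exactly* in each subject's empirical correlation), subject-level
   heterogeneity, low-frequency latent signals, motion/tissue confounds,
   Gaussian noise, and behavior scores linearly tied to a chosen edge —
   with a JSON truth record that fully determines regeneration.

## CLI

A study lives in a flat directory: `sub-<id>.nii` per subject, optional
`sub-<id>_confounds.tsv`, `mask.nii` / `wm_mask.nii` / `csf_mask.nii`,
a `design.tsv` (columns `subject_id`, `group`, `age`,
`depression_score`, `executive_score`) and a `templates/` directory
(NIfTI masks + `names.tsv` manifest).

```bash
# generate a synthetic study with known ground truth
netsync simulate --seed 1 --out study/ --subjects-per-group 16

# run the whole chain
netsync run --seed 1 --data study/ --out results/

# or stage by stage (each reads the previous stage's persisted outputs)
netsync preprocess --seed 1 --data study/ --out results/
netsync ica       --seed 1 --design study/design.tsv --out results/
netsync match     --seed 1 --templates study/templates --out results/
netsync dualreg   --seed 1 --design study/design.tsv --out results/
netsync netstats  --seed 1 --design study/design.tsv --out results/
netsync report    --out results/
```

Configuration is YAML/JSON (`--config file.yaml`); CLI flags override
file values, and the effective config is written beside the outputs.
A single global seed drives every stochastic stage through
stage-name-hashed child seeds, so any stage is independently
reproducible.

## Outputs

`results/` after a full run:

```
config.yaml                      effective configuration
preprocessed/sub-*.nii           filtered, nuisance-regressed volumes
ica/group_maps.nii               K z-scored group component maps
ica/mixing.tsv                   temporal mixing matrix
match/assignments.csv            template -> component assignments
match/gof_matrix.csv             full GOF audit matrix
dualreg/sub-*_timecourses.tsv    stage-1 subject time courses
dualreg/sub-*_maps.nii           stage-2 subject spatial maps
netstats/subject_edge_values.csv per-subject network-pair correlations
netstats/edge_stats.csv          per-edge group tests (raw + age-adjusted)
netstats/clusters.json           Monte-Carlo cluster correction results
netstats/behavior.csv            edge x score Pearson correlations
netstats/voxelwise/              per-network voxelwise z maps + clusters
```
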