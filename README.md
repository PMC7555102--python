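# pallidoparc

Connectivity-based parcellation (CBP) of the globus pallidus and its full
statistical surface, as a tested, reusable Python pipeline.

The internal and external pallidal segments (GPi, GPe) receive and send
topographically ordered projections — limbic territories anteriorly,
associative territories in between, sensorimotor territories posteriorly.
Diffusion-tractography CBP recovers this organization by assigning each
seed voxel to the remote target with the strongest connectivity evidence.
The package implements the whole analysis chain that turns per-subject
track-density maps into group-level territory maps and statistics, and
exercises it end to end on synthetic multi-subject cohorts with known
ground truth, so every step is verifiable. It is aimed at researchers who
want a transparent, unit-tested reference implementation of this family of
analyses rather than a neuroimaging GUI.

## The method

For each subject, seed region (GPi or GPe), pathway (striatopallidal,
subthalamopallidal, pallidothalamic) and target territory *t*, a
track-density map *D_t* over the seed ROI is

1. **normalized**: *D̂_t = D_t / mean(D_t)*, the mean taken over strictly
   positive in-ROI voxels, making densities comparable across targets;
2. **hard-segmented** by winner-takes-all: voxel *v* gets label
   *argmax_t D̂_t(v)* (unlabeled if all densities vanish; ties to the
   lowest target index in the fixed order limbic, associative,
   sensorimotor, other).

Subject parcels on the common template grid are binarized, averaged into
per-label probability maps, and thresholded inclusively at 50% — "present
in at least half the sample" — to give maximum probability maps (MPMs):
12 for GPi (4 territories × 3 pathways) and 8 for GPe (4 × 2) per
hemisphere, each with a volume (mm³) and center of gravity (COG, template
mm). On top of the maps:

- **Dice** *D = 2|A∩B| / (|A|+|B|)* between functionally homologous MPMs
  of different pathways (spatial coherence);
- **Tanimoto-based reproducibility** with the inverse-size weight
  *α = 2/(N(A)+N(B))*: overlap-by-label
  *OBL = Σ_m α N(A∩B) / Σ_m α N(A∪B)* over all unordered subject pairs
  *m*, and the total accumulated overlap TAO, the same double sum taken
  additionally over the *n* labels of a parcellation;
- **lateralization**: the streamline density index
  *SDI = 100·v/V_ROI* per parcel, tested left vs right with a paired
  sign-flip permutation test (50,000 permutations, α = .05) using t-max
  family-wise correction, plus the per-subject lateralization index
  *LI = (L−R)/(L+R)* with ±0.1 dominance cutoffs;
- **stimulation-site proximity**: Euclidean distances from sensorimotor
  map COGs to named coordinates, nearest-voxel site membership, and
  per-site map rankings.

The synthetic cohort generator places Gaussian density profiles with
strictly increasing peaks along the anteroposterior axis (mean-equalized
over an ellipsoidal seed ROI), adds per-subject rigid jitter and
multiplicative log-normal noise, and keeps the noiseless argmax as the
ground-truth label field — so parcellation accuracy, reproducibility and
test calibration can all be measured against a known answer.

## Worked example

```python
from pallidoparc.io_pipeline import StudyConfig, run_synthetic_study

summary = run_synthetic_study(StudyConfig(rng_seed=1, n_subjects=20))
print(summary.mpm_counts)          # {'GPi': 12, 'GPe': 8}
print(round(summary.label_recovery, 3))   # 0.915
perm = summary.permutation
print(perm[perm.p_corrected < 0.05][["nucleus", "pathway", "label", "t_obs"]].head(3))
```

```
{'GPi': 12, 'GPe': 8}
0.915
  nucleus             pathway        label     t_obs
0     GPi     striatopallidal       limbic  4.411469
1     GPi     striatopallidal  associative -8.382953
4     GPi  subthalamopallidal       limbic  3.393408
```

Twelve GPi and eight GPe thresholded MPMs per hemisphere; on average 91.5%
of seed voxels recover their true territory label under the default noise;
and the study's planted left-sided limbic enlargement is detected in every
pathway family (limbic left > right, with the complementary associative
effect in the opposite direction).

The same pipeline runs from the shell: `pallidoparc run --out results/run
--seed 1`, with `simulate`, `parcellate` (YAML manifest of NIfTI volumes),
`mpm`, `laterality` and `proximity` subcommands for the individual stages.
The numbered scripts under `analysis/` reproduce the full narrative study
and write their tables under `results/`.

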