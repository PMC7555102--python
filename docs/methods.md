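# Methods

## Scope and design

The package implements a two-stage, hypothesis-driven connectivity-based
parcellation (CBP) of the internal and external globus pallidus and every
statistic reported on top of it. Tractography itself (fODF estimation,
streamline generation, tractogram filtering) and subject-to-template
registration are outside the package: density maps are consumed as inputs
already living on one template grid, or synthesized by the cohort
generator. The repository is organised as an analysis project — numbered
narrative drivers under `analysis/` over the library under
`src/pallidoparc/`, where all computation lives so the tests and the
acceptance script import the same code paths the drivers use.

## Hard segmentation

`cbp_engine.normalize_density` divides each in-ROI voxel by the map's mean
intensity. The mean is taken over **strictly positive** in-ROI voxels by
default: maps with sparse spatial coverage would otherwise be inflated
relative to maps covering the whole ROI purely by their many zeros. Since
a mean over all ROI voxels is an equally defensible reading of "mean
intensity value", both behaviours are exposed (`mean_mode="positive" |
"all"`) so results can be compared under either convention.

`winner_takes_all` assigns each voxel the label of the largest normalized
density. Voxels with no positive evidence under any target stay unlabeled
(0) — hard segmentation presumes evidence of connectivity. Exact ties go
to the lowest target index, with the target order fixed as (limbic,
associative, sensorimotor, other); the rule is deterministic and matches
the fixed ordering used throughout the outputs. Multiplying any input map
by a positive constant does not change the parcellation (the
normalization divides it out); this scale invariance is asserted in the
tests.

`two_stage_parcellate` chains the stages: relay nuclei (striatum, STN,
thalamus) are parcellated by cortical connectivity, then each pallidal
segment is parcellated against the relay clusters, one parcellation per
(nucleus, pathway). With 4 functional groups this yields 12 GPi maps
(3 pathways) and 8 GPe maps (2 pathways). Stage-1 cluster provenance is
recorded in each output's metadata. Tracking parameters associated with
stage-2 seeding in the original protocol concern tractography and are out
of scope here.

## Group maps

Per-label probability maps count the fraction of subjects whose parcel
covers each voxel; thresholding is **inclusive** (≥), so a voxel present
in exactly half the sample survives the default 50% threshold. Because
each label's MPM is thresholded independently, MPMs of different labels
may overlap at group level even though subject parcels are exclusive; the
tests include a constructed case demonstrating a shared voxel. Volume is
voxel count × |det| of the affine's linear part. The center of gravity is
the **unweighted** centroid of the binary thresholded mask mapped through
the affine (RAS mm, 0-based voxel indices); a probability-weighted variant
is available as an option for sensitivity checks, not as the default,
since the reported COGs refer to the thresholded maps.

## Overlap statistics

Dice and Tanimoto are computed on voxel counts exactly as defined; the
identity D = 2T/(1+T) and D ≥ T are asserted as properties. OBL and TAO
sum α-weighted intersection and union counts over all C(S,2) unordered
subject pairs (and, for TAO, over labels), with α = 2/(N(A)+N(B)). Pairs
in which **both** masks are empty are skipped with a warning rather than
treated as 0/0 — α is undefined at N(A)+N(B) = 0. Dice is computed between
50%-thresholded group MPMs of different pathways, while OBL/TAO operate on
subject-level parcels; both entry points are exposed because the two
families of comparisons live at these different levels.

## Lateralization

SDI = 100·v/V_ROI per (subject, nucleus, pathway, label, hemisphere). The
permutation test forms per-subject left−right difference vectors over the
4 labels of one (nucleus, pathway) family — the correction family is
per-pathway by default and configurable — and flips whole subjects'
difference vectors, preserving the cross-variable correlation that t-max
correction relies on. The test is two-sided via |t|, and p-values use the
add-one estimator (1+b)/(m+1), which cannot return zero. Variables with
zero-variance differences have no finite t: all-zero differences are
reported with t = 0 and p = 1 (the null coincides with the observation);
nonzero constant differences are reported as undefined and excluded from
the max with a warning. An exhaustive 2ⁿ sign-flip enumeration
(`exhaustive_sign_flip_pvalues`) provides the exact reference for small
cohorts and anchors the Monte-Carlo estimator's calibration test.

## Site proximity

Distances are Euclidean in template mm. Site membership maps the mm
coordinate through the inverse affine and rounds to the nearest voxel —
sites are point coordinates and masks binary, so no partial-volume
interpolation is attempted. Coordinates outside the grid are "outside"
with a warning. Published stimulation-site coordinates are input data
carried with per-row citation tags, never constants in code.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes,
with every parameter explicit in `CohortConfig`:

- **Seed ROI**: an ellipsoid (half-axes 40% of each grid dimension)
  centered in a 24×28×24 grid at 1.25 mm isotropic — a connected,
  symmetric stand-in of realistic pallidal size (~4,300 voxels).
- **Density profiles**: one Gaussian bump per target along the
  anteroposterior axis, peaks at normalized positions (0.15, 0.4, 0.65,
  0.9) — strictly increasing, enforcing the limbic → associative →
  sensorimotor → other ordering. The default width (0.10 normalized) keeps
  territories sharply segregated: only voxels within roughly two voxel
  layers of a boundary have a non-negligible chance of flipping under the
  default noise. Each bump is divided by its in-ROI mean, so the
  pipeline's mean normalization is the identity on noiseless data and the
  noiseless winner-takes-all equals the generator's truth exactly.
- **Noise**: i.i.d. multiplicative log-normal with unit mean and CV 0.3 —
  a stand-in for count-like tractography noise, whose true subject-level
  distribution is not characterized; the parameter is config, not a claim.
- **Jitter**: a per-subject rigid translation of the profile along the
  gradient axis (SD 0.625 mm = half a voxel), emulating residual
  registration error. The ROI itself does not move — all subjects share
  one template-space ROI, matching a template-space group analysis.
- **Planted lateralization**: a per-label shift of the profile peak
  applied to left-hemisphere cohorts (default: limbic +0.05 normalized
  units). Shifting a peak moves its posterior boundary by about half the
  shift, genuinely enlarging the territory. A *multiplicative* per-label
  gain — the first idea for planting an effect — is exactly cancelled by
  the per-map mean normalization, and a purely *additive* density offset
  turns out to shrink the boosted parcel (it flattens the profile where
  densities exceed the ROI mean); the center shift is the mechanism whose
  direction and size are predictable.
- Left and right hemispheres are independent cohorts with derived seeds;
  all randomness flows from `rng_seed` through `numpy.random.default_rng`.

What passing tests on these cohorts show: the implementation of every
formula and rule is correct, the pipeline recovers known structure at
realistic noise, and the permutation test is calibrated. What they do not
show: that real track-density maps satisfy the generator's assumptions
(independent voxel noise, a single smooth gradient axis, rigid jitter);
conclusions about real data still require real data.

## Problem sizes and numerical choices

The default study uses 20 subjects per (nucleus, pathway, hemisphere)
cohort on the 24×28×24 grid, 50,000 permutations for inference and 2,000
permutations × 500 replicates for the null-calibration experiment — sizes
chosen so the full study, the test suite and the acceptance script each
complete in seconds on one CPU while keeping Monte-Carlo error well below
the asserted tolerances (2 percentage points for monotonicity checks,
0.01 for enumeration agreement). Permutations are processed in batches
bounded at a few million doubles of working memory. Floating-point
tolerances: probability-map integrality is checked at 1e−6; metric oracle
agreement at 1e−12; exact equality is asserted only where the computation
is exact (noiseless recovery, map counts).

## Deposited-map regression

`regression.deposited_map_report` recomputes volumes, COGs and Dice from
any directory of binary NIfTI group maps, so published group-level maps
can be checked against their reported tables. The tests exercise the
harness on a synthetic stand-in deposit with known counts and overlaps;
comparing against the actual published values requires downloading the
deposited maps and pointing the harness at that directory.

## Known limitations

- No soft/probabilistic assignment and no connectivity-threshold
  segmentation alternative; winner-takes-all is the only rule.
- The generator's gradient is one-dimensional; real territories curve.
- OBL/TAO empty-pair skipping means cohorts in which a label is absent in
  most subjects are summarized from few pairs; the skipped-pair count is
  surfaced via warnings.
- The t-max family is per-(nucleus, pathway); a joint family across
  pathways is available by passing the combined matrix but is not the
  default.
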