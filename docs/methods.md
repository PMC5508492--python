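# Methods

## Scope and design

`icadenoise` evaluates ICA-based denoising of resting-state fMRI on
synthetic cohorts with known ground truth. Because the clinical data
behind the original evaluation design cannot be redistributed, the
package instead makes every latent quantity observable: the generator
records exactly which spatial maps and time courses were mixed into
each scan, so classification accuracy, cleanup specificity and
connectivity recovery can be scored against a known answer rather than
against expert ratings.

The pipeline stages are kept in their published orderings:

* **all-noise strategy ("fix")** — 5 mm FWHM Gaussian smoothing →
  100 s high-pass → spatial ICA → score every noise family →
  non-aggressive regression of flagged components;
* **motion-only strategy ("aroma")** — smoothing → spatial ICA →
  score motion features only → non-aggressive regression → high-pass.

## Synthetic data generator

One subject is a 32 × 32 × 24 grid of 3 mm voxels with 120 frames at
TR = 3 s (standard clinical EPI geometry). The brain is an ellipsoid;
the edge rim is the brain minus its 2-voxel erosion (≈ 6 mm); gray
matter is a cortical shell between the rim and a central white-matter
core (the gray/white boundary adapts downward on very small test grids
so both tissues always exist); CSF is a central ventricle ellipsoid and
the "vessel" is a thin posterior midline track mimicking the sagittal
sinus.

Sources are mixed linearly, `X = offset + Σ map_k ⊗ tc_k + ε`:

* **signal** (default 5 networks): Gaussian blobs weighted into gray
  matter; time courses are band-limited Gaussian processes in
  0.01–0.1 Hz, the conventional resting-state band.
* **motion** (3): maps confined to the edge rim; time courses are
  Gaussian noise plus Poisson-placed spikes (rate 0.05/frame,
  amplitude 5–9 SD) and, with probability 0.5, a saw-tooth segment.
* **physiological** (2): maps on CSF/vessel; narrowband 0.11–0.16 Hz
  time courses (aliased cardiac/respiratory energy).
* **vascular** (1): vessel-weighted maps with very slow 0.003–0.02 Hz
  oscillations (vascular tone).

All time courses are demeaned and scaled to unit SD; maps have unit
peak, so the amplitude ratios (signal 1, motion 3, physiological 2,
vascular 1.5, white mixing noise SD 0.5, offset 100) set the relative
energies directly. No SNR figures exist for the target population, so
these are one-time choices meant to be "plausibly difficult": motion
dominates, signal is recoverable but not trivially. Cohorts share
group-level signal maps up to Gaussian spatial jitter (SD 1 voxel), so
split-half reproducibility has true structure to find. With
`mixing_noise_sd = 0` the data equal the recorded mixing exactly
(machine precision), which the tests exploit.

What the generator does **not** emulate: MR physics (T2* decay,
distortion, slice timing), rigid-body motion resampling (motion exists
only as edge-localised components — which is all the evaluated methods
see), registration across subjects (everything shares one grid), and
non-stationary or non-Gaussian background noise. Passing tests
therefore show the machinery is correct and the orderings hold under
realistic relative energies, not that the numbers transfer to any
clinical cohort.

## Spatial ICA

PCA whitening followed by fixed-point negentropy maximisation with
symmetric decorrelation (scikit-learn's parallel FastICA, logcosh
contrast) on the spatial dimension. Spatial maps are z-scored over
in-mask voxels with a positive-skewness sign convention; time courses
are re-estimated by least squares so
`data ≈ mean_volume + global_tc ⊗ 1 + timecourses · spatial_maps`.
The spatially constant direction cannot live in zero-mean maps, so the
per-timepoint spatial mean is stored separately as `global_timecourse`;
without it, exact back-projection of disjoint-support sources is
impossible. Explained-variance fractions share out the joint fit's
energy proportionally to each component's raw energy, so they sum to
≤ 1 even for correlated maps.

Automatic dimensionality is the smallest k retaining 95% of PCA
variance, capped at min(T/2, 60). On these synthetic scans the white
noise tail pushes the estimate to ~6–10 components, below the source
count; that is acceptable here (component merging is part of what the
classifier must survive) and is not treated as a calibration target.

## Component classification

Seven features transcribe the visual criteria a rater applies
(suprathreshold set = |z| > 2, matching the default review threshold):

| feature | meaning |
|---|---|
| `edge_fraction` | suprathreshold weight in the edge rim |
| `speckle_extent` | suprathreshold fraction of the brain (0.25 ≈ "a quarter of the brain") |
| `n_clusters` | 26-connected suprathreshold clusters |
| `high_freq_fraction` | periodogram power above 0.1 Hz |
| `spike_score` | max |Δtc| / (1.4826 × MAD of Δtc); if the MAD is zero but jumps exist, the mean |Δtc| replaces it so isolated impulses still register |
| `sawtooth_score` | |skewness of Δtc| (ramps-with-resets are one-sided) |
| `csf_vessel_fraction` | suprathreshold weight in CSF/vessel |

The **heuristic scorer** sums weighted sub-scores (clipped to [0,100]).
Weights were fixed once from the feature ranges of canonical signal and
noise components; the motion-only mode uses the edge/spike/high-frequency
subset with the *same* weights, so the all-noise score dominates the
motion-only score by construction — that ordering, not the absolute
scale, carries the FIX-removes-more-than-AROMA structure. Its default
operating threshold is 40.

The **trained scorer** is a regularised linear discriminant
(lsqr solver, Ledoit–Wolf shrinkage) on the 7 features, scored as
100 × P(noise); it is deterministic given the training data. Classifier
quality is evaluated by leave-one-subject-out sweeps: train on all
other subjects, binarise the held-out scores at each threshold
(score ≥ threshold → noise), average TPR/TNR across subjects. With
this convention TPR is non-decreasing and TNR non-increasing in the
threshold; published FIX tables run the opposite direction because
FIX's threshold axis is reversed — the selection rule is direction-free
and reproduces the published worked examples either way. The rule uses
**mean** TPR/TNR (the published report quotes means at the chosen
threshold).

## Denoising

High-pass filtering projects out a discrete-cosine basis spanning
[0, 1/cutoff) Hz and restores temporal means — exactly linear and
deterministic, unlike running-line smoothers. Smoothing applies a
separable Gaussian with FWHM in mm converted per-axis to voxels; no
renormalisation at the mask boundary (values bleed identically for
every strategy, so comparisons stay fair).

Non-aggressive cleanup fits **all** component time courses jointly to
each voxel and subtracts only the flagged columns' contribution;
aggressive cleanup residualises against the flagged columns alone.
Both demean regressors and restore voxel means. Non-aggressive removal
is not a projection: it can raise variance at individual voxels when
noise and signal time courses correlate; the guaranteed ordering is
only aggressive ≥ non-aggressive variance removed, and that is what is
tested. Rank-deficient designs (condition number > 1e10) are refused
with the condition number in the message. The all-noise path does not
re-apply the high-pass after cleanup.

## Dual regression and metrics

Stage 1 regresses each volume on the variance-normalised template maps
plus an intercept; stage 2 regresses each voxel series on all stage-1
time courses (demeaned, intercept included) and converts each t
statistic to a Z score through the normal quantile of its t cumulative
probability at T − N − 1 degrees of freedom, clipped at |Z| = 38 where
double precision saturates. Z maps serve identifiability and |%ΔZ|;
the raw parameter estimates serve reproducibility (each metric follows
the wording of the evaluation it mirrors). Out-of-mask voxels are 0.

* **Identifiability**: mean |Z| inside the template mask
  (|template| > 2.3 by default; 1.5 and 3.1 as sensitivity settings)
  over mean |Z| outside, with "outside" = the brain minus the mask
  (the defensible in-brain choice).
* **Split-half reproducibility**: per random half-split, group-mean
  parameter-estimate maps per NOI restricted to gray matter > 0.5;
  the N × N cross-correlation's diagonal is standardised against the
  pooled off-diagonal null (pooling over the whole matrix; a Fisher
  transform is available but off by default). 500 splits by default;
  tests use 100. Per-NOI split means stay noisy under the null because
  splits share subjects; the cohort mean is the calibrated quantity.
* **tDoF loss**: removed components / volumes × 100 — a count, never
  the variance the components carry.
* **%ΔSTD**: voxelwise percent reduction in temporal SD, undefined
  (NaN) where the original SD is 0. Group exceedance tests use
  one-sample t statistics against a floor with sign-flip max-statistic
  permutation FWE control, optionally TFCE-enhanced
  (E = 0.5, H = 2, dh = max/100, 26-connectivity, positive values
  only). Default 1000 permutations; tests use 100–200.
* **|%ΔZ|**: percent absolute change of the summed Z inside the NOI
  mask (same |template| > 2.3 mask as identifiability); compared
  across NOIs by one-way ANOVA with Bonferroni pairwise follow-up and
  between strategies by a paired t test. Degenerate edge cases: all
  groups equal constants give F = 0, p = 1; identical paired samples
  give t = 0, p = 1; constant non-zero paired differences are an error
  (the statistic is unbounded).
* **Grayplots**: gray-then-white voxel rows (probability > 0.5),
  demeaned and scaled to unit SD (constant rows become zeros), with
  the tissue boundary annotated in the rendering.

## The experiment runner

`run_experiment` simulates a cohort, runs each strategy, dual-regresses
originals (smoothed + filtered) and cleaned data against one shared
atlas, and emits TSV/NIfTI artefacts plus a single `report.json` with
no timestamps, so identical (config, seed) runs are byte-identical.
All randomness derives from one master seed through named substreams
(simulate, ica, splits, permutations). Ground-truth labels for
estimated components come from best-absolute-correlation matching
against the simulated sources — the stand-in for manual rating. If the
LOSO sweep selects no threshold (or cannot be trained), the runner
falls back to the heuristic scorer at threshold 40 and logs it,
mirroring how a classifier that fails the rule would be set aside in
practice.

## Problem sizes

Defaults mirror the study conditions (20 subjects, 32 × 32 × 24 × 120,
20 templates, 500 splits, 1000 permutations). The test suite scales the
stochastic pieces down — 100 splits, 100–200 permutations, 10 master
seeds for the multi-seed recovery checks — sizes chosen so the full
suite runs comfortably on a single CPU while keeping each comparison's
direction statistically unambiguous.

## Known limitations

* Auto-dimensionality underestimates the source count in the presence
  of a heavy white-noise tail; merged components are labelled by their
  best-matching source.
* The heuristic scorer's weights are fixed by construction, not
  learned; it exists to give the motion-only strategy an untrained
  operating point and to order the two modes, not to maximise accuracy.
* The TFCE transform is a straightforward threshold-stepping
  implementation; it is not byte-compatible with optimised
  implementations in standard neuroimaging suites.
* Pseudo-Z pooling uses the whole off-diagonal; per-row pooling would
  change absolute values (direction of effects is unaffected).
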