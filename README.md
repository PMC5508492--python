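# icadenoise

Evaluation pipeline for ICA-based denoising of resting-state fMRI
(rs-fMRI), built around synthetic cohorts with known ground truth.

Automated ICA cleanup comes in two philosophies: a *focused* classifier
that removes only motion-related components (the ICA-AROMA approach)
and a *trained, all-noise* classifier that removes every artefact
family it recognises (the FIX approach). Which is worth the effort in a
noisy, heterogeneous population — and at what cost in temporal degrees
of freedom — is an empirical question. This package re-creates the full
evaluation loop on simulated data where the answer key is known: it
generates multi-subject BOLD-like 4D volumes mixed from known signal
networks plus motion / physiological / vascular noise sources, runs
single-subject spatial ICA, classifies and removes components in both
pipeline orderings, estimates functional connectivity by template-based
dual regression, and scores everything with the standard metric suite.

Who it is for: methods researchers who want a controlled, fully
reproducible testbed for component-classification and denoising ideas,
and anyone who needs reference implementations of the metrics below
against brute-force-verified oracles.

## The core quantities

* **TPR / TNR** — percentage of true signal / true artefact components
  correctly classified, evaluated by leave-one-subject-out (LOSO)
  cross-validation and swept over the score threshold. The operating
  threshold is chosen by the rule: among thresholds with
  **mean TPR > 90%**, take the highest mean TNR, provided it is
  **≥ 10%**; otherwise no threshold qualifies.
* **Non-aggressive cleanup** — with component time courses
  `M = [M_signal, M_noise]` fit jointly to each voxel series `y`,
  the cleaned series is `y − M_noise β̂_noise`: only the variance
  *uniquely* attributable to noise is removed.
* **RSN identifiability** — mean |Z| inside the thresholded network
  template (|Z| > 2.3) over mean |Z| outside; > 1 means the network
  stands out.
* **Split-half pseudo-Z reproducibility** — correlate group-mean maps
  between random half-cohorts for every template pair; standardise the
  matched (diagonal) correlations against the mismatched
  (off-diagonal) null: `pseudo-Z_i = (r_ii − mean(off)) / SD(off)`,
  averaged over 500 random splits.
* **tDoF loss** — removed components as a percentage of the volume
  count; **%ΔSTD** — voxelwise percent reduction of temporal SD;
  **|%ΔZ|** — percent absolute change of summed Z within a template
  mask; **grayplots** — voxels × time heatmaps ordered by tissue.

See `docs/methods.md` for the model, parameter defaults and numerical
choices.

## Worked example

Apply the threshold rule to the packaged patient-trained benchmark
table:

```bash
icadenoise check-sweep src/icadenoise/data/fix_sweep_patient_trained.tsv
```

```
thresholds: [1.0, 2.0, 5.0, 10.0, 20.0, 30.0, 40.0, 50.0]
mean TPR:   [98.1, 97.7, 97.3, 96.3, 91.7, 88.0, 83.6, 79.4]
mean TNR:   [61.3, 65.3, 71.8, 78.5, 86.9, 91.6, 94.0, 96.0]
mean TPR > 90.0: thresholds [1.0, 2.0, 5.0, 10.0, 20.0]
selected threshold 20 (mean TPR 91.7, mean TNR 86.9)
```

Thresholds 1–20 keep mean TPR above the 90% floor; among them, 20 has
the highest mean TNR (86.9% ≥ 10%), so 20 is the operating point. On
the generic-trained table the rule selects nothing (every threshold
with TPR > 90% has TNR ≤ 4%), the situation in which a classifier is
set aside.

End-to-end on synthetic data — simulate a small cohort, clean it with
ground-truth component labels, and measure the benefit:

```python
import numpy as np
import icadenoise as icd
from icadenoise import denoise, ica, dualreg, metrics

cfg = icd.SynthConfig(n_subjects=6, seed=1)
cohort = icd.make_cohort(cfg)
atlas = icd.make_noi_atlas([g for _, _, g in cohort], 20, seed=2,
                           brain_mask=cohort[0][0].brain_mask,
                           gray_matter=cohort[0][1].gray)

pe_o, pe_c, id_o, id_c, removed = [], [], [], [], []
for img, masks, gt in cohort:
    pre = denoise.highpass_filter(denoise.gaussian_smooth(img))
    decomp, tags = ica.wrap_ground_truth(pre, gt)
    noise_ids = [i for i, t in enumerate(tags) if t != "signal"]
    result = denoise.nonaggressive_clean(pre, decomp, noise_ids)
    removed.append(result.tdof_lost)
    dr_o = dualreg.template_dual_regression(pre, atlas)
    dr_c = dualreg.template_dual_regression(result.cleaned, atlas)
    pe_o.append(dr_o.pe_maps); pe_c.append(dr_c.pe_maps)
    id_o.append(np.mean([metrics.rsn_identifiability(
        dr_o.zmap_grid(n), atlas.templates[n], 2.3, img.brain_mask)
        for n in range(5)]))
    id_c.append(np.mean([metrics.rsn_identifiability(
        dr_c.zmap_grid(n), atlas.templates[n], 2.3, img.brain_mask)
        for n in range(5)]))

gray = cohort[0][1].gray[cohort[0][0].brain_mask]
rep_o = metrics.split_half_reproducibility(np.stack(pe_o), gray,
                                           n_splits=100, seed=0)
rep_c = metrics.split_half_reproducibility(np.stack(pe_c), gray,
                                           n_splits=100, seed=0)
print(f"mean identifiability: {np.mean(id_o):.2f} -> {np.mean(id_c):.2f}")
print(f"matched-NOI pseudo-Z: {np.nanmean(rep_o.mean_pseudo_z[:5]):.1f}"
      f" -> {np.nanmean(rep_c.mean_pseudo_z[:5]):.1f}")
print(f"tDoF loss: {np.mean([metrics.tdof_loss_percent(r, cfg.n_frames)"
      f" for r in removed]):.1f}%")
```

```
mean identifiability: 9.36 -> 9.57
matched-NOI pseudo-Z: 8.2 -> 16.8
tDoF loss: 5.0%
```

Removing the six known noise components per subject raises network
identifiability slightly and roughly doubles split-half
reproducibility, at a cost of 6/120 = 5% of the temporal degrees of
freedom. The one-command version of the whole study (both strategies,
LOSO sweep and threshold selection, %ΔSTD group tests, grayplots,
JSON report) is:

```bash
icadenoise run --out results/study --seed 0
```

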