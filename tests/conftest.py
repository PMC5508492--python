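"""Shared fixtures: small synthetic subjects and the multi-seed study run."""

from __future__ import annotations

import numpy as np
import pytest

import icadenoise as icd
from icadenoise import classify, denoise, dualreg, ica, metrics

TINY = icd.SynthConfig(n_subjects=4, grid_shape=(16, 16, 12), n_frames=60,
                       k_signal=2, seed=0)

N_STUDY_SEEDS = 10
HEURISTIC_THRESHOLD = 40.0


@pytest.fixture(scope="session")
def tiny_config() -> icd.SynthConfig:
    return TINY


@pytest.fixture(scope="session")
def tiny_subject():
    """One small subject: (Image4D, TissueMasks, GroundTruth)."""
    return icd.make_subject(TINY, 42)


@pytest.fixture(scope="session")
def default_subject():
    """One subject at the full study geometry (32x32x24, T=120)."""
    return icd.make_subject(icd.SynthConfig(), 7)


def make_decomposition(mask: np.ndarray, map_grids, timecourses,
                       tr_seconds: float = 3.0) -> ica.ComponentDecomposition:
    """Hand-built decomposition from explicit map grids and time courses."""
    maps = np.stack([g[mask] for g in map_grids])
    tcs = np.asarray(timecourses, dtype=float)
    K = maps.shape[0]
    return ica.ComponentDecomposition(
        spatial_maps=maps, timecourses=tcs,
        variance_fraction=np.full(K, 1.0 / max(K, 1)),
        mask=mask, mean_volume=np.zeros(int(mask.sum())),
        tr_seconds=tr_seconds)


@pytest.fixture(scope="session")
def study_stats():
    """The study conditions, run once per master seed.

    For each of 10 master seeds: a default 20-subject cohort is
    simulated, pre-processed (5 mm smoothing + 100 s high-pass), cleaned
    non-aggressively with ground-truth component labels, and dual-
    regressed against the cohort's 20-template NOI atlas. Per-seed
    summaries of identifiability, split-half pseudo-Z (100 splits),
    removal counts by scorer mode, %dSTD by region, stage-1 signal
    time-course recovery, and the LOSO-selected threshold are returned.
    """
    per_seed = []
    for m in range(N_STUDY_SEEDS):
        cfg = icd.SynthConfig(seed=m)
        cohort = icd.make_cohort(cfg)
        brain = cohort[0][0].brain_mask
        masks = cohort[0][1]
        atlas = icd.make_noi_atlas([g for _, _, g in cohort], 20,
                                   seed=m + 1000, brain_mask=brain,
                                   gray_matter=masks.gray)
        deep_gray = (masks.gray > 0.5) & ~masks.edge_rim
        id_o, id_c, pe_o, pe_c = [], [], [], []
        counts_all, counts_mo = [], []
        edge_dstd, deep_dstd = [], []
        tc_o, tc_c = [], []
        feats_labels = []
        for img, _, gt in cohort:
            pre = denoise.highpass_filter(denoise.gaussian_smooth(img))
            dwrap, tags = ica.wrap_ground_truth(pre, gt)
            noise_ids = [i for i, t in enumerate(tags) if t != "signal"]
            clean = denoise.nonaggressive_clean(pre, dwrap, noise_ids).cleaned
            dr_o = dualreg.template_dual_regression(pre, atlas)
            dr_c = dualreg.template_dual_regression(clean, atlas)
            pe_o.append(dr_o.pe_maps)
            pe_c.append(dr_c.pe_maps)
            for n in range(cfg.k_signal):
                id_o.append(metrics.rsn_identifiability(
                    dr_o.zmap_grid(n), atlas.templates[n], 2.3, brain))
                id_c.append(metrics.rsn_identifiability(
                    dr_c.zmap_grid(n), atlas.templates[n], 2.3, brain))
                tc_o.append(abs(np.corrcoef(dr_o.timecourses[:, n],
                                            gt.signal_timecourses[:, n])[0, 1]))
                tc_c.append(abs(np.corrcoef(dr_c.timecourses[:, n],
                                            gt.signal_timecourses[:, n])[0, 1]))
            feats = classify.component_features(dwrap, masks)
            feats_labels.append((feats, classify.LabelSet.from_subtypes(tags)))
            s_all = classify.noise_score(feats, "all-noise").scores
            s_mo = classify.noise_score(feats, "motion-only").scores
            counts_all.append(int((s_all >= HEURISTIC_THRESHOLD).sum()))
            counts_mo.append(int((s_mo >= HEURISTIC_THRESHOLD).sum()))
            ids_mo = np.flatnonzero(s_mo >= HEURISTIC_THRESHOLD)
            clean_mo = denoise.nonaggressive_clean(pre, dwrap, ids_mo).cleaned
            ds = metrics.delta_std_map(pre, clean_mo).values
            edge_dstd.append(np.nanmean(ds[masks.edge_rim]))
            deep_dstd.append(np.nanmean(ds[deep_gray]))
        gray_v = masks.gray[brain]
        rep_o = metrics.split_half_reproducibility(np.stack(pe_o), gray_v,
                                                   n_splits=100, seed=m)
        rep_c = metrics.split_half_reproducibility(np.stack(pe_c), gray_v,
                                                   n_splits=100, seed=m)
        matched = slice(0, cfg.k_signal)
        sweep = classify.loso_sweep(feats_labels, range(1, 51))
        per_seed.append({
            "ident_orig": float(np.mean(id_o)),
            "ident_clean": float(np.mean(id_c)),
            "pseudo_z_orig": float(np.nanmean(rep_o.mean_pseudo_z[matched])),
            "pseudo_z_clean": float(np.nanmean(rep_c.mean_pseudo_z[matched])),
            "counts_all": counts_all,
            "counts_motion_only": counts_mo,
            "dstd_edge": float(np.mean(edge_dstd)),
            "dstd_deep_gray": float(np.mean(deep_dstd)),
            "tc_corr_orig": float(np.mean(tc_o)),
            "tc_corr_clean": float(np.mean(tc_c)),
            "loso_selected": classify.select_optimal_threshold(sweep),
        })
    return per_seed
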