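"""Configuration, NIfTI/TSV/JSON plumbing, and the one-command experiment.

``run_experiment`` reproduces the full synthetic study: simulate a
cohort, run each denoising strategy, dual-regress original and cleaned
data against one NOI atlas, and compute the metric suite into a single
JSON report plus TSV/NIfTI artefacts. All randomness flows from one
master seed through named substreams (simulate, ica, splits,
permutations), so every stage is independently reproducible.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from . import classify, denoise, dualreg, ica, metrics
from .synthgen import (GroundTruth, Image4D, SynthConfig, TissueMasks,
                       make_cohort, make_noi_atlas)

__all__ = [
    "ExperimentConfig",
    "StudyReport",
    "run_experiment",
    "check_sweep_tsv",
    "load_reference_sweep",
    "ground_truth_labels",
    "save_image4d",
    "load_image4d",
    "save_volume",
    "load_volume",
    "save_tissue_masks",
    "load_tissue_masks",
    "save_decomposition",
    "save_atlas",
    "load_atlas",
]

log = logging.getLogger(__name__)

DEFAULT_THRESHOLDS = (1, 2, 5, 10, 20, 30, 40, 50)
#: operating point of the untrained (heuristic) scorer, used for the
#: motion-only strategy and as the fallback when the sweep rule selects nothing
HEURISTIC_THRESHOLD = 40.0


# ---------------------------------------------------------------------------
# NIfTI / TSV IO
# ---------------------------------------------------------------------------

def _affine(voxel_size_mm) -> np.ndarray:
    return np.diag(list(voxel_size_mm) + [1.0])


def save_volume(arr: np.ndarray, path, voxel_size_mm=(3.0, 3.0, 3.0)) -> None:
    img = nib.Nifti1Image(np.asarray(arr, dtype=np.float32),
                          _affine(voxel_size_mm))
    img.to_filename(str(path))


def load_volume(path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).get_fdata(), dtype=float)


def save_image4d(img: Image4D, path, mask_path=None) -> None:
    nii = nib.Nifti1Image(np.asarray(img.voxels, dtype=np.float32),
                          _affine(img.voxel_size_mm))
    nii.header["pixdim"][4] = img.tr_seconds
    nii.to_filename(str(path))
    if mask_path is not None:
        save_volume(img.brain_mask.astype(np.float32), mask_path,
                    img.voxel_size_mm)


def load_image4d(path, mask_path) -> Image4D:
    nii = nib.load(str(path))
    voxels = np.asarray(nii.get_fdata(), dtype=float)
    zooms = nii.header.get_zooms()
    tr = float(zooms[3]) if len(zooms) > 3 and zooms[3] > 0 else 1.0
    mask = load_volume(mask_path) > 0.5
    return Image4D(voxels=voxels, voxel_size_mm=tuple(zooms[:3]),
                   tr_seconds=tr, brain_mask=mask)


def save_tissue_masks(masks: TissueMasks, outdir, voxel_size_mm) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name in ("gray", "white", "csf", "edge_rim", "vessel"):
        save_volume(np.asarray(getattr(masks, name), dtype=float),
                    outdir / f"{name}.nii.gz", voxel_size_mm)


def load_tissue_masks(outdir) -> TissueMasks:
    outdir = Path(outdir)
    arrs = {name: load_volume(outdir / f"{name}.nii.gz")
            for name in ("gray", "white", "csf", "edge_rim", "vessel")}
    arrs["edge_rim"] = arrs["edge_rim"] > 0.5
    arrs["vessel"] = arrs["vessel"] > 0.5
    return TissueMasks(**arrs)


def save_decomposition(decomp: ica.ComponentDecomposition, outdir,
                       voxel_size_mm=(3.0, 3.0, 3.0)) -> None:
    """Write maps/mix/variance in the spirit of a MELODIC output directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    K = decomp.n_components
    maps4d = np.stack([decomp.map_grid(k) for k in range(K)], axis=-1)
    save_volume(maps4d, outdir / "component_maps.nii.gz", voxel_size_mm)
    save_volume(decomp.mask.astype(float), outdir / "mask.nii.gz",
                voxel_size_mm)
    pd.DataFrame(decomp.timecourses,
                 columns=[f"ic{k:03d}" for k in range(K)]
                 ).to_csv(outdir / "mixing.tsv", sep="\t", index=False)
    pd.DataFrame({"component": np.arange(K),
                  "variance_fraction": decomp.variance_fraction}
                 ).to_csv(outdir / "variance.tsv", sep="\t", index=False)
    (outdir / "meta.json").write_text(json.dumps(
        {"tr_seconds": decomp.tr_seconds, "n_components": K}))


def save_atlas(atlas: dualreg.NOIAtlas, outdir,
               voxel_size_mm=(3.0, 3.0, 3.0)) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    save_volume(np.moveaxis(atlas.templates, 0, -1),
                outdir / "templates.nii.gz", voxel_size_mm)
    save_volume(atlas.gray_matter, outdir / "gray_matter.nii.gz",
                voxel_size_mm)
    save_volume(atlas.brain_mask.astype(float), outdir / "brain_mask.nii.gz",
                voxel_size_mm)
    pd.DataFrame({"label": list(atlas.labels)}).to_csv(
        outdir / "labels.tsv", sep="\t", index=False)


def load_atlas(outdir) -> dualreg.NOIAtlas:
    outdir = Path(outdir)
    templates = np.moveaxis(load_volume(outdir / "templates.nii.gz"), -1, 0)
    labels = tuple(pd.read_csv(outdir / "labels.tsv", sep="\t")["label"])
    return dualreg.NOIAtlas(
        templates=templates, labels=labels,
        gray_matter=load_volume(outdir / "gray_matter.nii.gz"),
        brain_mask=load_volume(outdir / "brain_mask.nii.gz") > 0.5)


# ---------------------------------------------------------------------------
# packaged reference sweep tables
# ---------------------------------------------------------------------------

def load_reference_sweep(which: str) -> classify.ThresholdSweep:
    """Packaged benchmark classification-performance tables.

    ``which`` is ``"generic"`` or ``"patient"``: published LOSO TPR/TNR
    sweeps of a FIX classifier on an acute-stroke rs-fMRI cohort after
    generic (healthy-cohort) and study-specific (patient) training.
    """
    from importlib.resources import files
    name = {"generic": "fix_sweep_generic_trained.tsv",
            "patient": "fix_sweep_patient_trained.tsv"}[which]
    with files("icadenoise.data").joinpath(name).open("rb") as fh:
        return classify.ThresholdSweep.from_tsv(fh)


def check_sweep_tsv(path, tpr_floor: float = 90.0, tnr_min: float = 10.0,
                    echo=print) -> float | None:
    """Apply the optimal-threshold rule to a sweep TSV, printing the trace."""
    sweep = classify.ThresholdSweep.from_tsv(path)
    ok = np.flatnonzero(sweep.mean_tpr > tpr_floor)
    echo(f"thresholds: {sweep.thresholds.tolist()}")
    echo(f"mean TPR:   {sweep.mean_tpr.tolist()}")
    echo(f"mean TNR:   {sweep.mean_tnr.tolist()}")
    echo(f"mean TPR > {tpr_floor}: thresholds "
         f"{sweep.thresholds[ok].tolist() if ok.size else 'none'}")
    selected = classify.select_optimal_threshold(sweep, tpr_floor=tpr_floor,
                                                 tnr_min=tnr_min)
    if selected is None:
        echo(f"no threshold satisfies the rule (TPR > {tpr_floor}, "
             f"TNR >= {tnr_min}): selected none")
    else:
        i = int(np.flatnonzero(sweep.thresholds == selected)[0])
        echo(f"selected threshold {selected:g} "
             f"(mean TPR {sweep.mean_tpr[i]:.1f}, "
             f"mean TNR {sweep.mean_tnr[i]:.1f})")
    return selected


# ---------------------------------------------------------------------------
# experiment configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExperimentConfig:
    """Everything the one-command experiment needs."""

    synth: SynthConfig = field(default_factory=SynthConfig)
    strategies: tuple[str, ...] = ("fix", "aroma")
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS
    n_templates: int = 20
    mask_thresholds: tuple[float, ...] = (1.5, 2.3, 3.1)
    summary_mask_threshold: float = 2.3
    n_splits: int = 500
    n_perm: int = 1000
    delta_std_floors: tuple[float, ...] = (35.0, 45.0, 55.0, 65.0)
    delta_std_prob_threshold: float = 25.0
    use_tfce: bool = True
    run_group_tests: bool = True
    n_grayplots: int = 2
    seed: int = 0

    def validate(self) -> None:
        if list(self.thresholds) != sorted(self.thresholds):
            raise ValueError("thresholds must be sorted ascending")
        for s in self.strategies:
            if s not in ("fix", "aroma"):
                raise ValueError(f"unknown strategy {s!r}")
        if self.n_templates < self.synth.k_signal:
            raise ValueError("n_templates must be >= k_signal")
        self.synth.validate()

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        synth = SynthConfig(**raw.pop("synth", {}))
        for key in ("strategies", "thresholds", "mask_thresholds",
                    "delta_std_floors"):
            if key in raw:
                raw[key] = tuple(raw[key])
        cfg = cls(synth=synth, **raw)
        cfg.validate()
        return cfg

    def substream_seeds(self) -> dict[str, int]:
        names = ("simulate", "ica", "splits", "permutations")
        state = np.random.SeedSequence(self.seed).generate_state(len(names))
        return {n: int(s % (2**31 - 1)) for n, s in zip(names, state)}


@dataclass
class StudyReport:
    """In-memory twin of the report JSON run_experiment writes."""

    payload: dict

    def __getitem__(self, key):
        return self.payload[key]

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.payload, indent=2,
                                         sort_keys=True))


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return v if np.isfinite(v) else None
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    if isinstance(obj, np.ndarray):
        return _jsonable(obj.tolist())
    return obj


# ---------------------------------------------------------------------------
# ground-truth labelling of estimated components
# ---------------------------------------------------------------------------

def ground_truth_labels(decomp: ica.ComponentDecomposition,
                        gt: GroundTruth) -> classify.LabelSet:
    """Label estimated components from the simulated sources they match.

    Stand-in for manual rating: a component is "signal" when its best
    absolute spatial correlation over the true signal maps beats its
    best over the true noise maps, "noise" otherwise (with the winning
    subtype recorded).
    """
    mask = decomp.mask
    sig = gt.signal_maps[:, mask]
    noi = gt.noise_maps[:, mask]

    def corr(refs: np.ndarray) -> np.ndarray:
        if refs.shape[0] == 0:
            return np.zeros((decomp.n_components, 0))
        a = decomp.spatial_maps
        a = (a - a.mean(1, keepdims=True)) / np.where(
            a.std(1, keepdims=True) == 0, 1, a.std(1, keepdims=True))
        b = (refs - refs.mean(1, keepdims=True)) / np.where(
            refs.std(1, keepdims=True) == 0, 1, refs.std(1, keepdims=True))
        return np.abs(a @ b.T / a.shape[1])

    r_sig, r_noi = corr(sig), corr(noi)
    best_sig = r_sig.max(axis=1) if r_sig.shape[1] else np.zeros(decomp.n_components)
    best_noi = r_noi.max(axis=1) if r_noi.shape[1] else np.zeros(decomp.n_components)
    tags = []
    for k in range(decomp.n_components):
        if best_sig[k] >= best_noi[k]:
            tags.append("signal")
        else:
            tags.append(gt.noise_subtypes[int(np.argmax(r_noi[k]))])
    return classify.LabelSet.from_subtypes(tags, provenance="ground-truth")


# ---------------------------------------------------------------------------
# the experiment
# ---------------------------------------------------------------------------

def _strategy_inputs(img: Image4D, strategy: str) -> Image4D:
    work = denoise.gaussian_smooth(img)
    if strategy == "fix":
        work = denoise.highpass_filter(work)
    return work


def run_experiment(config: ExperimentConfig, outdir) -> StudyReport:
    """Simulate, denoise, dual-regress, and measure; write all artefacts.

    Deterministic given the master seed. The report JSON carries no
    timestamps, so identical (config, seed) runs are byte-identical.
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = config.substream_seeds()
    files: dict[str, str] = {}

    def register(key: str, relpath: str) -> Path:
        files[key] = relpath
        path = outdir / relpath
        path.parent.mkdir(parents=True, exist_ok=True)
        return path

    log.info("simulate: %d subjects, grid %s, seed %d",
             config.synth.n_subjects, config.synth.grid_shape,
             seeds["simulate"])
    synth = config.synth.replace(seed=seeds["simulate"])
    cohort = make_cohort(synth)
    masks = cohort[0][1]
    atlas = make_noi_atlas([gt for _, _, gt in cohort], config.n_templates,
                           seed=seeds["simulate"] + 1,
                           brain_mask=cohort[0][0].brain_mask,
                           gray_matter=masks.gray)
    save_atlas(atlas, outdir / "atlas", synth.voxel_size_mm)
    files["atlas"] = "atlas/templates.nii.gz"
    save_tissue_masks(masks, outdir / "masks", synth.voxel_size_mm)
    files["masks"] = "masks/gray.nii.gz"
    brain = cohort[0][0].brain_mask
    matched = list(range(synth.k_signal))

    # pre-processed, uncorrected reference: smooth + high-pass
    originals = [denoise.highpass_filter(denoise.gaussian_smooth(img))
                 for img, _, _ in cohort]
    dr_orig = [dualreg.template_dual_regression(o, atlas, f"sub-{s:02d}")
               for s, o in enumerate(originals)]

    report: dict = {
        "seed": config.seed,
        "substream_seeds": seeds,
        "n_subjects": synth.n_subjects,
        "n_templates": config.n_templates,
        "matched_networks": matched,
        "strategies": {},
        "files": files,
    }

    for strategy in config.strategies:
        log.info("strategy %s: decompose + classify", strategy)
        works = [_strategy_inputs(img, strategy) for img, _, _ in cohort]
        decomps, feats, labels = [], [], []
        for s, work in enumerate(works):
            d = ica.decompose(work, k="auto", seed=seeds["ica"] + s)
            decomps.append(d)
            feats.append(classify.component_features(d, masks))
            labels.append(ground_truth_labels(d, cohort[s][2]))

        entry: dict = {"n_components": [d.n_components for d in decomps]}
        mode = "all-noise" if strategy == "fix" else "motion-only"
        if strategy == "fix":
            try:
                sweep = classify.loso_sweep(list(zip(feats, labels)),
                                            config.thresholds)
            except ValueError as exc:   # e.g. a fold with single-class training
                log.warning("%s: LOSO sweep impossible (%s); "
                            "using heuristic scorer", strategy, exc)
                sweep, selected = None, None
            if sweep is not None:
                sweep_path = register(f"{strategy}_sweep",
                                      f"{strategy}/threshold_sweep.tsv")
                sweep.to_tsv(sweep_path)
                selected = classify.select_optimal_threshold(sweep)
                entry["sweep"] = {
                    "thresholds": sweep.thresholds, "mean_tpr": sweep.mean_tpr,
                    "mean_tnr": sweep.mean_tnr, "median_tpr": sweep.median_tpr,
                    "median_tnr": sweep.median_tnr}
            if selected is None:
                log.warning("%s: sweep rule selected no threshold; "
                            "falling back to heuristic %g", strategy,
                            HEURISTIC_THRESHOLD)
                threshold, scorer = HEURISTIC_THRESHOLD, classify.HeuristicScorer()
            else:
                threshold = selected
                scorer = classify.train_scorer(list(zip(feats, labels)))
            entry["selected_threshold"] = selected
        else:
            threshold, scorer = HEURISTIC_THRESHOLD, classify.HeuristicScorer()
            entry["selected_threshold"] = None
        entry["applied_threshold"] = threshold

        cleaned_imgs, removed_counts, var_removed = [], [], []
        for s, (work, d, f) in enumerate(zip(works, decomps, feats)):
            scores = scorer.score(f, mode=mode).scores
            ids = np.flatnonzero(scores >= threshold)
            res = denoise.nonaggressive_clean(work, d, ids)
            cleaned = res.cleaned
            if strategy == "aroma":
                cleaned = denoise.highpass_filter(cleaned)
            cleaned_imgs.append(cleaned)
            removed_counts.append(len(ids))
            var_removed.append(ica.variance_fraction_of(d, ids))
            log.info("%s sub-%02d: removed %d/%d components", strategy, s,
                     len(ids), d.n_components)
        entry["removed_components"] = removed_counts
        entry["variance_removed_fraction"] = var_removed
        entry["tdof_loss_percent"] = [
            metrics.tdof_loss_percent(r, synth.n_frames)
            for r in removed_counts]

        dr_clean = [dualreg.template_dual_regression(c, atlas, f"sub-{s:02d}")
                    for s, c in enumerate(cleaned_imgs)]

        # identifiability at every mask threshold, orig vs cleaned
        ident: dict = {}
        for thr in config.mask_thresholds:
            def ratios(drs):
                out = np.zeros((len(drs), len(matched)))
                for s, dr in enumerate(drs):
                    for j, n in enumerate(matched):
                        out[s, j] = metrics.rsn_identifiability(
                            dr.zmap_grid(n), atlas.templates[n], thr, brain)
                return out
            ident[str(thr)] = {
                "original_mean": ratios(dr_orig).mean(),
                "cleaned_mean": ratios(dr_clean).mean()}
        entry["identifiability"] = ident

        gray_v = atlas.gray_matter[brain]
        pe_orig = np.stack([dr.pe_maps for dr in dr_orig])
        pe_clean = np.stack([dr.pe_maps for dr in dr_clean])
        rep_o = metrics.split_half_reproducibility(
            pe_orig, gray_v, config.n_splits, seeds["splits"])
        rep_c = metrics.split_half_reproducibility(
            pe_clean, gray_v, config.n_splits, seeds["splits"])
        entry["reproducibility"] = {
            "original_mean_pseudo_z": rep_o.mean_pseudo_z,
            "cleaned_mean_pseudo_z": rep_c.mean_pseudo_z,
            "matched_mean_original": np.nanmean(rep_o.mean_pseudo_z[matched]),
            "matched_mean_cleaned": np.nanmean(rep_c.mean_pseudo_z[matched]),
            "n_splits": config.n_splits}

        dstd = np.stack([metrics.delta_std_map(o, c).values
                         for o, c in zip(originals, cleaned_imgs)])
        prob = metrics.delta_std_probability_map(
            dstd, config.delta_std_prob_threshold)
        save_volume(prob, register(f"{strategy}_dstd_prob",
                                   f"{strategy}/delta_std_probability.nii.gz"),
                    synth.voxel_size_mm)
        entry["delta_std"] = {
            "mean_in_brain": np.nanmean(dstd[:, brain]),
            "mean_edge_rim": np.nanmean(dstd[:, masks.edge_rim]),
            "mean_deep_gray": np.nanmean(
                dstd[:, (masks.gray > 0.5) & ~masks.edge_rim])}
        if config.run_group_tests:
            sig_counts = {}
            for floor in config.delta_std_floors:
                sig, _ = metrics.delta_std_group_test(
                    dstd, floor, n_perm=config.n_perm,
                    use_tfce=config.use_tfce, seed=seeds["permutations"],
                    mask=brain)
                save_volume(sig.astype(float),
                            register(f"{strategy}_dstd_sig_{floor:g}",
                                     f"{strategy}/delta_std_sig_gt{floor:g}.nii.gz"),
                            synth.voxel_size_mm)
                sig_counts[f"{floor:g}"] = int(sig.sum())
            entry["delta_std"]["significant_voxels_by_floor"] = sig_counts

        noi_masks = [np.abs(atlas.templates[n]) > config.summary_mask_threshold
                     for n in matched]
        dz = np.zeros((synth.n_subjects, len(matched)))
        for s in range(synth.n_subjects):
            for j, n in enumerate(matched):
                dz[s, j] = metrics.percent_delta_z(
                    dr_orig[s].zmap_grid(n), dr_clean[s].zmap_grid(n),
                    noi_masks[j])
        entry["percent_delta_z"] = {
            "per_subject_mean": dz.mean(axis=1), "grand_mean": dz.mean(),
            "values": dz}
        if len(matched) >= 2:
            F, p, _ = metrics.anova_across_nois(dz)
            entry["percent_delta_z"]["anova"] = {"F": F, "p": p}

        for s in range(min(config.n_grayplots, synth.n_subjects)):
            gp = metrics.grayplot(cleaned_imgs[s], masks)
            metrics.render_grayplot(
                gp, register(f"{strategy}_grayplot_{s}",
                             f"{strategy}/grayplot_sub-{s:02d}.png"),
                title=f"{strategy} sub-{s:02d}")

        report["strategies"][strategy] = entry

    if len(config.strategies) == 2:
        a, b = config.strategies
        da = report["strategies"][a]["percent_delta_z"]["per_subject_mean"]
        db = report["strategies"][b]["percent_delta_z"]["per_subject_mean"]
        try:
            t, p = metrics.paired_ttest(np.asarray(da), np.asarray(db))
            report["strategy_comparison"] = {
                "pair": [a, b], "paired_t": t, "p": p}
        except ValueError as exc:
            report["strategy_comparison"] = {"pair": [a, b],
                                             "error": str(exc)}

    payload = _jsonable(report)
    study = StudyReport(payload)
    study.save(outdir / "report.json")
    files["report"] = "report.json"
    missing = [rel for rel in files.values() if not (outdir / rel).exists()]
    if missing:
        raise RuntimeError(f"report references missing artefacts: {missing}")
    return study
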