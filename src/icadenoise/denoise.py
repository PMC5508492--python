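"""Smoothing, high-pass filtering, component regression, pipeline orderings.

Two cleanup formulations are provided. *Non-aggressive* regression fits
every component time course jointly to each voxel series and subtracts
only the part attributed to the flagged noise components, preserving
variance shared with signal components. *Aggressive* regression takes
residuals after projecting onto the noise time courses alone, removing
shared variance too.

``run_strategy`` composes the two published pipeline orderings:

* ``fix``:   smooth -> high-pass -> ICA -> score all noise types -> non-aggressive clean
* ``aroma``: smooth -> ICA -> score motion only -> non-aggressive clean -> high-pass
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from . import classify as _classify
from .ica import ComponentDecomposition, decompose
from .synthgen import Image4D, TissueMasks

__all__ = [
    "CleanupResult",
    "gaussian_smooth",
    "highpass_filter",
    "nonaggressive_clean",
    "aggressive_clean",
    "run_strategy",
]

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))
#: refuse regressions whose design is numerically rank-deficient
MAX_CONDITION_NUMBER = 1e10


@dataclass
class CleanupResult:
    """Cleaned data plus the bookkeeping of what was removed.

    Each removed component counts as one lost temporal degree of
    freedom; the total tDoF is the number of volumes.
    """

    cleaned: Image4D
    removed_ids: frozenset[int]
    mode: str                     # "aggressive" | "non-aggressive"
    tdof_lost: int
    tdof_total: int
    decomposition: ComponentDecomposition | None = None
    scores: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("aggressive", "non-aggressive"):
            raise ValueError(f"unknown cleanup mode {self.mode!r}")
        if self.tdof_lost != len(self.removed_ids):
            raise ValueError("tdof_lost must equal the removed-component count")
        if self.tdof_total != self.cleaned.n_frames:
            raise ValueError("tdof_total must equal the volume count")


def gaussian_smooth(img: Image4D, fwhm_mm: float = 5.0) -> Image4D:
    """Separable Gaussian smoothing of each volume (kernel FWHM in mm)."""
    if fwhm_mm < 0:
        raise ValueError("fwhm must be >= 0")
    if fwhm_mm == 0:
        return Image4D(img.voxels.copy(), img.voxel_size_mm, img.tr_seconds,
                       img.brain_mask.copy())
    sigmas = [fwhm_mm * FWHM_TO_SIGMA / vs for vs in img.voxel_size_mm] + [0.0]
    out = ndimage.gaussian_filter(img.voxels, sigma=sigmas, mode="constant")
    return Image4D(out, img.voxel_size_mm, img.tr_seconds,
                   img.brain_mask.copy())


def _dct_drift_basis(T: int, tr: float, cutoff_s: float) -> np.ndarray:
    """Unit-norm discrete-cosine columns spanning frequencies below 1/cutoff."""
    t = np.arange(T)
    ks = []
    k = 1
    while k / (2.0 * T * tr) < 1.0 / cutoff_s:
        ks.append(k)
        k += 1
    if not ks:
        return np.zeros((T, 0))
    basis = np.stack([np.cos(np.pi * k * (t + 0.5) / T) for k in ks], axis=1)
    return basis / np.linalg.norm(basis, axis=0)


def highpass_filter(img: Image4D, cutoff_s: float = 100.0) -> Image4D:
    """Remove fluctuations slower than 1/cutoff_s Hz; temporal mean restored.

    Implemented as projection onto the orthogonal complement of a
    discrete-cosine drift basis spanning [0, 1/cutoff_s) -- exactly
    linear and deterministic.
    """
    if cutoff_s <= 2.0 * img.tr_seconds:
        raise ValueError("cutoff_s must exceed 2 x TR")
    X = img.masked_data()
    mean = X.mean(axis=0)
    B = _dct_drift_basis(img.n_frames, img.tr_seconds, cutoff_s)
    Xc = X - mean
    if B.shape[1]:
        Xc = Xc - B @ (B.T @ Xc)
    return img.with_masked_data(Xc + mean)


def _fit_components(img: Image4D, decomp: ComponentDecomposition,
                    noise_ids) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[int]]:
    ids = sorted(set(int(i) for i in noise_ids))
    if ids and (min(ids) < 0 or max(ids) >= decomp.n_components):
        raise KeyError(f"noise_ids outside 0..{decomp.n_components - 1}")
    if decomp.mask.shape != img.spatial_shape or \
            not np.array_equal(decomp.mask, img.brain_mask):
        raise ValueError("decomposition mask does not match image grid")
    X = img.masked_data()
    mean = X.mean(axis=0)
    M = decomp.timecourses - decomp.timecourses.mean(axis=0)
    return X, mean, M, ids


def _check_condition(M: np.ndarray) -> None:
    if M.shape[1] == 0:
        return
    cond = np.linalg.cond(M)
    if not np.isfinite(cond) or cond > MAX_CONDITION_NUMBER:
        raise np.linalg.LinAlgError(
            f"rank-deficient component time-course matrix (cond={cond:.3g})")


def nonaggressive_clean(img: Image4D, decomp: ComponentDecomposition,
                        noise_ids) -> CleanupResult:
    """Remove only the variance uniquely attributable to noise components.

    All K component time courses are fit jointly to every in-mask voxel
    series; the noise columns' fitted contribution is subtracted.
    Temporal means are preserved.
    """
    X, mean, M, ids = _fit_components(img, decomp, noise_ids)
    if ids:
        _check_condition(M)
        beta = np.linalg.lstsq(M, X - mean, rcond=None)[0]   # (K, V)
        cleaned = X - M[:, ids] @ beta[ids]
    else:
        cleaned = X.copy()
    return CleanupResult(cleaned=img.with_masked_data(cleaned),
                         removed_ids=frozenset(ids), mode="non-aggressive",
                         tdof_lost=len(ids), tdof_total=img.n_frames)


def aggressive_clean(img: Image4D, decomp: ComponentDecomposition,
                     noise_ids) -> CleanupResult:
    """Residualise each voxel series against the noise time courses alone."""
    X, mean, M, ids = _fit_components(img, decomp, noise_ids)
    if ids:
        Mn = M[:, ids]
        _check_condition(Mn)
        beta = np.linalg.lstsq(Mn, X - mean, rcond=None)[0]
        cleaned = X - Mn @ beta
    else:
        cleaned = X.copy()
    return CleanupResult(cleaned=img.with_masked_data(cleaned),
                         removed_ids=frozenset(ids), mode="aggressive",
                         tdof_lost=len(ids), tdof_total=img.n_frames)


def run_strategy(img: Image4D, masks: TissueMasks, strategy: str,
                 scorer=None, threshold: float = 40.0,
                 k: int | str = "auto", smooth_fwhm_mm: float = 5.0,
                 highpass_cutoff_s: float = 100.0,
                 ica_seed: int = 0) -> CleanupResult:
    """Full single-subject denoising pipeline in the given strategy's order.

    ``scorer`` is any object with ``score(features, mode) -> NoiseScores``
    (default: the heuristic scorer). Components scoring at or above
    ``threshold`` are removed non-aggressively.
    """
    if strategy not in ("fix", "aroma"):
        raise ValueError(f"unknown strategy {strategy!r}")
    if scorer is None:
        scorer = _classify.HeuristicScorer()

    work = gaussian_smooth(img, smooth_fwhm_mm)
    if strategy == "fix":
        work = highpass_filter(work, highpass_cutoff_s)
    decomp = decompose(work, k=k, seed=ica_seed)
    features = _classify.component_features(decomp, masks)
    mode = "all-noise" if strategy == "fix" else "motion-only"
    scores = scorer.score(features, mode=mode)
    noise_ids = np.flatnonzero(scores.scores >= threshold)
    result = nonaggressive_clean(work, decomp, noise_ids)
    cleaned = result.cleaned
    if strategy == "aroma":
        cleaned = highpass_filter(cleaned, highpass_cutoff_s)
    return CleanupResult(cleaned=cleaned, removed_ids=result.removed_ids,
                         mode="non-aggressive", tdof_lost=result.tdof_lost,
                         tdof_total=result.tdof_total, decomposition=decomp,
                         scores=scores.scores)
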