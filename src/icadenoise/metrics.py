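"""Evaluation metrics for denoising strategies.

Covers: RSN identifiability (in/out Z-ratio against a thresholded
template mask), split-half pseudo-Z reproducibility, temporal
degrees-of-freedom loss, voxelwise %dSTD maps with one-sample
permutation group tests (optionally TFCE-enhanced), |%dZ| functional
connectivity change with ANOVA and paired t-tests, grayplots, and a
basic threshold-free cluster enhancement transform.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats

from .synthgen import Image4D, TissueMasks

__all__ = [
    "IdentifiabilityResult",
    "ReproducibilityResult",
    "DeltaSTDMap",
    "GrayplotMatrix",
    "rsn_identifiability",
    "split_half_reproducibility",
    "tdof_loss_percent",
    "delta_std_map",
    "delta_std_group_test",
    "tfce",
    "delta_std_probability_map",
    "percent_delta_z",
    "anova_across_nois",
    "paired_ttest",
    "grayplot",
    "render_grayplot",
]

log = logging.getLogger(__name__)

RSN_MASK_THRESHOLDS = (1.5, 2.3, 3.1)
_CONN26 = np.ones((3, 3, 3), dtype=bool)


# ---------------------------------------------------------------------------
# RSN identifiability
# ---------------------------------------------------------------------------

@dataclass
class IdentifiabilityResult:
    """In/out |Z| ratios, one row per subject, one column per NOI."""

    ratios: np.ndarray          # (n_subjects, n_nois)
    mask_threshold: float


def rsn_identifiability(zmap: np.ndarray, template: np.ndarray,
                        mask_threshold: float = 2.3,
                        domain_mask: np.ndarray | None = None) -> float:
    """Mean |Z| inside the RSN mask divided by mean |Z| outside it.

    The RSN mask is |template| > mask_threshold; "outside" is the rest
    of the domain (the brain, by default the whole array). A ratio > 1
    means the network stands out from the background.
    """
    zmap = np.asarray(zmap, dtype=float)
    template = np.asarray(template, dtype=float)
    if zmap.shape != template.shape:
        raise ValueError("zmap and template shapes differ")
    domain = np.ones(zmap.shape, dtype=bool) if domain_mask is None \
        else np.asarray(domain_mask, dtype=bool)
    inside = (np.abs(template) > mask_threshold) & domain
    outside = domain & ~inside
    if not inside.any():
        raise ValueError("empty RSN mask at this threshold")
    if not outside.any():
        raise ValueError("empty outside region")
    denom = np.abs(zmap[outside]).mean()
    if denom == 0:
        raise ValueError("zero mean |Z| outside the mask: ratio undefined")
    return float(np.abs(zmap[inside]).mean() / denom)


# ---------------------------------------------------------------------------
# split-half reproducibility
# ---------------------------------------------------------------------------

@dataclass
class ReproducibilityResult:
    """Mean and SD of per-NOI pseudo-Z over random group splits."""

    mean_pseudo_z: np.ndarray   # (N,), NaN for flagged NOIs
    sd_pseudo_z: np.ndarray
    n_splits: int
    seed: int


def split_half_reproducibility(subject_maps: np.ndarray,
                               gray_matter: np.ndarray,
                               n_splits: int = 500, seed: int = 0,
                               fisher: bool = False) -> ReproducibilityResult:
    """Split-half reproducibility of group-mean NOI maps as pseudo-Z.

    ``subject_maps`` is (S, N, V): one stage-2 parameter-estimate map
    per subject per NOI over the in-mask voxels; ``gray_matter`` is the
    matching (V,) probability vector (maps are restricted to > 0.5).
    Each split halves the cohort, correlates half-1 NOI i with half-2
    NOI j (N x N matrix), and standardises the diagonal against the
    pooled off-diagonal null:
    pseudo-Z_i = (r_ii - mean(off)) / SD(off). With ``fisher`` the
    correlations are arctanh-transformed first.
    """
    maps = np.asarray(subject_maps, dtype=float)
    S, N, V = maps.shape
    if S < 4:
        raise ValueError("split-half reproducibility needs >= 4 subjects")
    if n_splits < 1:
        raise ValueError("n_splits must be >= 1")
    gray = np.asarray(gray_matter, dtype=float)
    maps = maps[:, :, gray > 0.5]
    if maps.shape[2] < 2:
        raise ValueError("fewer than 2 gray-matter voxels")
    if S % 2:
        log.warning("odd cohort size %d: dropping one subject per split", S)
    half = S // 2
    rng = np.random.default_rng(seed)
    off_mask = ~np.eye(N, dtype=bool)
    acc = np.zeros((n_splits, N))
    excluded = np.zeros(N, dtype=bool)
    for s in range(n_splits):
        perm = rng.permutation(S)
        g1 = maps[perm[:half]].mean(axis=0)
        g2 = maps[perm[half:2 * half]].mean(axis=0)
        sd1, sd2 = g1.std(axis=1), g2.std(axis=1)
        bad = (sd1 == 0) | (sd2 == 0)
        if bad.any() and not excluded[bad].all():
            log.warning("zero-variance masked map for NOIs %s: excluded",
                        np.flatnonzero(bad).tolist())
            excluded |= bad
        a = (g1 - g1.mean(axis=1, keepdims=True)) / np.where(sd1 == 0, 1, sd1)[:, None]
        b = (g2 - g2.mean(axis=1, keepdims=True)) / np.where(sd2 == 0, 1, sd2)[:, None]
        R = a @ b.T / maps.shape[2]
        if fisher:
            R = np.arctanh(np.clip(R, -0.999999, 0.999999))
        off = R[off_mask]
        mu, sd = off.mean(), off.std()
        acc[s] = (np.diag(R) - mu) / (sd if sd > 0 else 1.0)
    acc[:, excluded] = np.nan
    return ReproducibilityResult(mean_pseudo_z=acc.mean(axis=0),
                                 sd_pseudo_z=acc.std(axis=0),
                                 n_splits=n_splits, seed=seed)


# ---------------------------------------------------------------------------
# tDoF and %dSTD
# ---------------------------------------------------------------------------

def tdof_loss_percent(n_removed: int, n_volumes: int) -> float:
    """Lost temporal degrees of freedom as a percentage of the volumes."""
    if not 0 <= n_removed <= n_volumes:
        raise ValueError("need 0 <= n_removed <= n_volumes")
    return 100.0 * n_removed / n_volumes


@dataclass
class DeltaSTDMap:
    """Voxelwise percent reduction in temporal SD (NaN where undefined)."""

    values: np.ndarray
    subject_id: str = ""
    strategy: str = ""


def delta_std_map(original: Image4D, corrected: Image4D,
                  subject_id: str = "", strategy: str = "") -> DeltaSTDMap:
    """100 x (SD_orig - SD_corr) / SD_orig per in-mask voxel."""
    if original.voxels.shape != corrected.voxels.shape:
        raise ValueError("original/corrected grids differ")
    sd_o = original.voxels.std(axis=3)
    sd_c = corrected.voxels.std(axis=3)
    values = np.full(sd_o.shape, np.nan)
    ok = original.brain_mask & (sd_o > 0)
    values[ok] = 100.0 * (sd_o[ok] - sd_c[ok]) / sd_o[ok]
    return DeltaSTDMap(values=values, subject_id=subject_id, strategy=strategy)


def tfce(stat_map: np.ndarray, E: float = 0.5, H: float = 2.0,
         dh: float | None = None, connectivity: int = 26) -> np.ndarray:
    """Threshold-free cluster enhancement of a (positive) statistic map.

    For each voxel, integrates extent(h)^E * h^H over thresholds h from
    dh up to the voxel's value (step dh); extent is the size of the
    suprathreshold connected component containing the voxel. Negative
    values contribute nothing (enhance -map separately if needed).
    """
    stat = np.asarray(stat_map, dtype=float)
    structure = _CONN26 if connectivity == 26 else \
        ndimage.generate_binary_structure(stat.ndim, 1)
    peak = stat.max(initial=0.0)
    if peak <= 0:
        return np.zeros_like(stat)
    if dh is None:
        dh = peak / 100.0
    if dh <= 0:
        raise ValueError("dh must be positive")
    out = np.zeros_like(stat)
    h = dh
    while h <= peak + 1e-12:
        supra = stat >= h
        lab, n = ndimage.label(supra, structure=structure)
        if n == 0:
            break
        sizes = np.bincount(lab.ravel())
        out[supra] += (sizes[lab[supra]] ** E) * (h ** H) * dh
        h += dh
    return out


def delta_std_group_test(maps: np.ndarray, floor_percent: float,
                         n_perm: int = 1000, alpha: float = 0.01,
                         use_tfce: bool = True, seed: int = 0,
                         mask: np.ndarray | None = None,
                         ) -> tuple[np.ndarray, np.ndarray]:
    """One-sample test that %dSTD exceeds a floor, FWE-controlled.

    ``maps`` is (S, nx, ny, nz). The voxelwise one-sample t statistic
    of (map - floor) is compared against a sign-flip permutation null
    of the maximum statistic (TFCE-enhanced when ``use_tfce``), giving
    family-wise-corrected p-values. Returns ``(significant_mask, p_map)``.
    """
    data = np.asarray(maps, dtype=float) - floor_percent
    S = data.shape[0]
    if S < 4:
        raise ValueError("group test needs >= 4 maps")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if mask is None:
        mask = np.all(np.isfinite(data), axis=0)
    data = np.where(mask, np.nan_to_num(data), 0.0)

    def tstat(d: np.ndarray) -> np.ndarray:
        mu = d.mean(axis=0)
        sd = d.std(axis=0, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(sd > 0, mu / (sd / np.sqrt(S)), 0.0)
        return np.where(mask, t, 0.0)

    def enhance(t: np.ndarray) -> np.ndarray:
        return tfce(t) if use_tfce else t

    obs = enhance(tstat(data))
    rng = np.random.default_rng(seed)
    exceed = np.ones(obs.shape)               # the observed stat counts once
    for _ in range(n_perm):
        flips = rng.choice([-1.0, 1.0], size=S)
        null_max = enhance(tstat(data * flips[:, None, None, None])).max()
        exceed += null_max >= obs
    p_map = np.where(mask, exceed / (n_perm + 1), 1.0)
    return (p_map < alpha) & mask, p_map


def delta_std_probability_map(maps: np.ndarray,
                              threshold_percent: float = 25.0) -> np.ndarray:
    """Fraction of subjects whose %dSTD exceeds the threshold, per voxel."""
    maps = np.asarray(maps, dtype=float)
    if maps.ndim < 2 or maps.shape[0] < 1:
        raise ValueError("need at least one map")
    with np.errstate(invalid="ignore"):
        above = maps > threshold_percent
    return above.mean(axis=0)


# ---------------------------------------------------------------------------
# |%dZ| and group statistics
# ---------------------------------------------------------------------------

def percent_delta_z(z_original: np.ndarray, z_corrected: np.ndarray,
                    noi_mask: np.ndarray) -> float:
    """|100 x (sum Z_corr - sum Z_orig) / sum Z_orig| within a NOI mask."""
    noi_mask = np.asarray(noi_mask, dtype=bool)
    z_original = np.asarray(z_original, dtype=float)
    if z_original.shape != np.asarray(z_corrected).shape \
            or z_original.shape != noi_mask.shape:
        raise ValueError("map/mask shapes differ")
    s_orig = float(z_original[noi_mask].sum())
    if s_orig == 0:
        raise ZeroDivisionError("summed original Z is zero in this NOI")
    s_corr = float(np.asarray(z_corrected)[noi_mask].sum())
    return abs(100.0 * (s_corr - s_orig) / s_orig)


def anova_across_nois(values: np.ndarray,
                      ) -> tuple[float, float, np.ndarray]:
    """One-way ANOVA over NOI groups with Bonferroni pairwise follow-up.

    ``values`` is (subjects, NOIs). Returns (F, p, adjusted pairwise p
    matrix). If every group is the same constant, F = 0 and p = 1.
    """
    vals = np.asarray(values, dtype=float)
    if vals.ndim != 2 or vals.shape[0] < 2 or vals.shape[1] < 2:
        raise ValueError("need >= 2 subjects and >= 2 NOIs")
    if not np.all(np.isfinite(vals)):
        raise ValueError("non-finite values")
    S, N = vals.shape
    grand = vals.mean()
    ssb = S * np.sum((vals.mean(axis=0) - grand) ** 2)
    ssw = np.sum((vals - vals.mean(axis=0)) ** 2)
    dfb, dfw = N - 1, N * (S - 1)
    if ssw == 0:
        F, p = (0.0, 1.0) if ssb == 0 else (np.inf, 0.0)
    else:
        F = (ssb / dfb) / (ssw / dfw)
        p = float(stats.f.sf(F, dfb, dfw))
    m = N * (N - 1) // 2
    pair_p = np.ones((N, N))
    for i in range(N):
        for j in range(i + 1, N):
            if vals[:, i].std() == 0 and vals[:, j].std() == 0:
                raw = 1.0 if vals[:, i].mean() == vals[:, j].mean() else 0.0
            else:
                raw = float(stats.ttest_ind(vals[:, i], vals[:, j]).pvalue)
            pair_p[i, j] = pair_p[j, i] = min(1.0, raw * m)
    return float(F), float(p), pair_p


def paired_ttest(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sided paired t-test; errors on zero difference variance."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise ValueError("need two equal-length 1-D samples of size >= 2")
    d = a - b
    if not d.any():
        return 0.0, 1.0      # identical samples: no effect, by convention
    if d.std(ddof=1) == 0:
        raise ValueError("zero variance of paired differences: t undefined")
    res = stats.ttest_rel(a, b)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# grayplots
# ---------------------------------------------------------------------------

@dataclass
class GrayplotMatrix:
    """Voxels x time heatmap matrix, gray-matter rows above white-matter."""

    matrix: np.ndarray   # (n_gray + n_white, T), rows demeaned / unit SD
    n_gray: int
    n_white: int


def grayplot(img: Image4D, masks: TissueMasks) -> GrayplotMatrix:
    """Normalised voxel time-series ordered gray-then-white by voxel index."""
    gray_sel = (masks.gray > 0.5) & img.brain_mask
    white_sel = (masks.white > 0.5) & img.brain_mask
    if not gray_sel.any() or not white_sel.any():
        raise ValueError("empty gray or white tissue selection")
    rows = np.concatenate([img.voxels[gray_sel], img.voxels[white_sel]])
    rows = rows - rows.mean(axis=1, keepdims=True)
    sd = rows.std(axis=1, keepdims=True)
    rows = np.divide(rows, sd, out=np.zeros_like(rows), where=sd > 0)
    return GrayplotMatrix(matrix=rows, n_gray=int(gray_sel.sum()),
                          n_white=int(white_sel.sum()))


def render_grayplot(gp: GrayplotMatrix, path, title: str = "") -> None:
    """Render a grayplot PNG with the gray/white boundary annotated."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 4))
    ax.imshow(gp.matrix, aspect="auto", cmap="gray", vmin=-2, vmax=2,
              interpolation="nearest")
    ax.axhline(gp.n_gray - 0.5, color="tab:blue", lw=1.0)
    ax.set_xlabel("frame")
    ax.set_ylabel("voxel (gray | white)")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
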