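"""Template-based dual regression: NOI time courses and Z-score maps.

Stage 1 regresses every volume on the template maps (spatial
regression), yielding one time course per network of interest. Stage 2
regresses every voxel series on all those time courses jointly
(temporal regression); each coefficient's t statistic is mapped to a
Z score through the normal quantile of its t cumulative probability.
The same atlas is used for corrected and uncorrected data, so maps are
directly comparable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "NOIAtlas",
    "ConnectivityResult",
    "stage1_timecourses",
    "stage2_zmaps",
    "template_dual_regression",
]

MAX_CONDITION_NUMBER = 1e10
#: |Z| ceiling; normal quantiles saturate near here in double precision
Z_CLIP = 38.0


@dataclass
class NOIAtlas:
    """Z-valued network-of-interest templates sharing one voxel grid."""

    templates: np.ndarray    # (N, nx, ny, nz)
    labels: tuple[str, ...]
    gray_matter: np.ndarray  # probability grid
    brain_mask: np.ndarray   # bool grid

    def __post_init__(self) -> None:
        self.templates = np.asarray(self.templates, dtype=float)
        if self.templates.ndim != 4 or self.templates.shape[0] < 1:
            raise ValueError("templates must be (N, nx, ny, nz) with N >= 1")
        if len(self.labels) != self.templates.shape[0]:
            raise ValueError("one label per template required")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("labels must be unique")
        if not np.all(np.isfinite(self.templates)):
            raise ValueError("non-finite template values")
        self.brain_mask = np.asarray(self.brain_mask, dtype=bool)

    @property
    def n_templates(self) -> int:
        return self.templates.shape[0]

    def masked_templates(self, mask: np.ndarray | None = None) -> np.ndarray:
        """Templates flattened to (N, V) over the given (or own) mask."""
        return self.templates[:, self.brain_mask if mask is None else mask]


@dataclass
class ConnectivityResult:
    """Per-subject dual-regression output for one atlas."""

    timecourses: np.ndarray   # (T, N)
    zmaps: np.ndarray         # (N, V)
    pe_maps: np.ndarray       # (N, V) stage-2 parameter estimates
    subject_id: str
    atlas: NOIAtlas

    def __post_init__(self) -> None:
        if self.zmaps.shape[0] != self.atlas.n_templates:
            raise ValueError("zmaps/atlas template count mismatch")
        if not np.all(np.isfinite(self.zmaps)):
            raise ValueError("non-finite Z maps")

    def zmap_grid(self, i: int) -> np.ndarray:
        out = np.zeros(self.atlas.brain_mask.shape)
        out[self.atlas.brain_mask] = self.zmaps[i]
        return out


def _design_condition(D: np.ndarray) -> float:
    return float(np.linalg.cond(D))


def stage1_timecourses(img, atlas: NOIAtlas) -> np.ndarray:
    """Spatial regression: one time course per template, (T, N).

    Template columns are variance-normalised and an intercept is
    included, so time-course scales are comparable across networks.
    """
    if atlas.templates.shape[1:] != img.spatial_shape:
        raise ValueError("atlas grid does not match image grid")
    mask = img.brain_mask
    X = img.masked_data()                        # (T, V)
    tmpl = atlas.masked_templates(mask).T        # (V, N)
    sd = tmpl.std(axis=0)
    if np.any(sd == 0):
        raise np.linalg.LinAlgError("a template is constant over the mask")
    D = np.column_stack([np.ones(tmpl.shape[0]), tmpl / sd])
    cond = _design_condition(D)
    if cond > MAX_CONDITION_NUMBER:
        raise np.linalg.LinAlgError(
            f"rank-deficient stage-1 design (cond={cond:.3g})")
    coef = np.linalg.lstsq(D, X.T, rcond=None)[0]  # (N+1, T)
    return coef[1:].T                              # drop intercept


def stage2_zmaps(img, timecourses: np.ndarray,
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Temporal regression: per-voxel multiple regression on all N
    time courses (demeaned, intercept included).

    Returns ``(zmaps, pe_maps)``, both (N, V): Z scores of the fit and
    the raw parameter estimates. Z is the normal quantile of the t
    cumulative probability at T - N - 1 degrees of freedom.
    """
    X = img.masked_data()
    T, V = X.shape
    M = np.asarray(timecourses, dtype=float)
    N = M.shape[1]
    if T <= N + 1:
        raise ValueError(f"T={T} must exceed N+1={N + 1}")
    G = np.column_stack([np.ones(T), M - M.mean(axis=0)])
    cond = _design_condition(G)
    if cond > MAX_CONDITION_NUMBER:
        raise np.linalg.LinAlgError(
            f"rank-deficient stage-2 design (cond={cond:.3g}); "
            "duplicate or constant regressors?")
    gram_inv = np.linalg.inv(G.T @ G)
    beta = gram_inv @ (G.T @ X)                    # (N+1, V)
    resid = X - G @ beta
    dof = T - (N + 1)
    sigma2 = np.sum(resid ** 2, axis=0) / dof
    se = np.sqrt(np.outer(np.diag(gram_inv)[1:], sigma2))
    pe = beta[1:]
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = np.where(se > 0, pe / se, 0.0)
    z = np.sign(tstat) * stats.norm.isf(stats.t.sf(np.abs(tstat), dof))
    z = np.clip(np.nan_to_num(z, nan=0.0, posinf=Z_CLIP, neginf=-Z_CLIP),
                -Z_CLIP, Z_CLIP)
    return z, pe


def template_dual_regression(img, atlas: NOIAtlas,
                             subject_id: str = "") -> ConnectivityResult:
    """Stage 1 followed by stage 2 with the same atlas."""
    tcs = stage1_timecourses(img, atlas)
    if np.all(tcs.std(axis=0) == 0):
        raise np.linalg.LinAlgError(
            "zero-variance stage-1 time courses (degenerate data)")
    zmaps, pe = stage2_zmaps(img, tcs)
    return ConnectivityResult(timecourses=tcs, zmaps=zmaps, pe_maps=pe,
                              subject_id=subject_id, atlas=atlas)
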