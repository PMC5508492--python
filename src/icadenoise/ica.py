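"""Single-subject spatial ICA: decomposition, variance accounting, matching.

The decomposition follows the classic spatial-ICA recipe for fMRI:
PCA whitening of the voxel-space data followed by fixed-point
negentropy maximisation with symmetric decorrelation (FastICA), run on
the spatial dimension so the recovered sources are spatial maps and
the mixing matrix holds their time courses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.decomposition import FastICA

from .synthgen import GroundTruth, Image4D

__all__ = [
    "ComponentDecomposition",
    "decompose",
    "auto_dimensionality",
    "variance_fraction_of",
    "match_components",
    "wrap_ground_truth",
]

#: auto-dimensionality: smallest k retaining this PCA variance fraction ...
PCA_VARIANCE_RETENTION = 0.95
#: ... capped at min(T // 2, this)
MAX_AUTO_COMPONENTS = 60


@dataclass
class ComponentDecomposition:
    """Paired spatial maps and time courses from a spatial-ICA run.

    ``spatial_maps`` rows are z-scored over the in-mask voxels (zero
    mean, unit SD); ``timecourses`` are the least-squares back-projection
    of the data onto those maps, so
    ``data ~= mean_volume + timecourses @ spatial_maps``.
    """

    spatial_maps: np.ndarray      # (K, V)
    timecourses: np.ndarray       # (T, K)
    variance_fraction: np.ndarray  # (K,)
    mask: np.ndarray              # (nx, ny, nz) bool
    mean_volume: np.ndarray       # (V,)
    tr_seconds: float
    #: per-timepoint spatial mean removed before the fit; zero-mean maps
    #: cannot carry a spatially constant direction, so it is kept separately
    global_timecourse: np.ndarray | None = None

    def __post_init__(self) -> None:
        K, V = self.spatial_maps.shape
        T = self.timecourses.shape[0]
        if self.timecourses.shape[1] != K:
            raise ValueError("timecourses/spatial_maps component mismatch")
        if K > T - 1:
            raise ValueError(f"K={K} exceeds T-1={T - 1}")
        if int(self.mask.sum()) != V:
            raise ValueError("mask voxel count does not match spatial_maps")
        if not (np.all(np.isfinite(self.spatial_maps))
                and np.all(np.isfinite(self.timecourses))):
            raise ValueError("non-finite decomposition values")
        if self.variance_fraction.sum() > 1.0 + 1e-6:
            raise ValueError("variance fractions sum above 1")

    @property
    def n_components(self) -> int:
        return self.spatial_maps.shape[0]

    def map_grid(self, k: int) -> np.ndarray:
        """Spatial map ``k`` unflattened onto the grid (zeros outside mask)."""
        out = np.zeros(self.mask.shape)
        out[self.mask] = self.spatial_maps[k]
        return out

    def reconstruct(self, component_ids=None) -> np.ndarray:
        """Back-projected (T, V) data from all (or selected) components."""
        ids = np.arange(self.n_components) if component_ids is None \
            else np.asarray(list(component_ids))
        out = self.mean_volume + self.timecourses[:, ids] @ self.spatial_maps[ids]
        if self.global_timecourse is not None:
            out = out + self.global_timecourse[:, None]
        return out


def _zscore_rows(maps: np.ndarray) -> np.ndarray:
    mu = maps.mean(axis=1, keepdims=True)
    sd = maps.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return (maps - mu) / sd


def _finish(maps_z: np.ndarray, Xcc: np.ndarray, mask: np.ndarray,
            mean_volume: np.ndarray, tr: float,
            global_tc: np.ndarray) -> ComponentDecomposition:
    """Sign-fix, back-project time courses, order by explained variance.

    ``Xcc`` is the doubly-centred data (voxel means and per-timepoint
    spatial means removed).
    """
    # sign convention: positive skewness of each spatial map
    flip = stats.skew(maps_z, axis=1) < 0
    maps_z[flip] *= -1.0

    gram = maps_z @ maps_z.T
    M = np.linalg.solve(gram, maps_z @ Xcc.T).T      # (T, K)

    total = np.sum(Xcc ** 2)
    if total > 0:
        raw = np.sum(M ** 2, axis=0) * np.sum(maps_z ** 2, axis=1)
        # correlated maps double-count energy; share out the joint fit's
        # sum of squares proportionally so the fractions sum to <= 1
        fit_ss = np.sum((M @ maps_z) ** 2)
        vf = raw * (fit_ss / raw.sum() / total) if raw.sum() > 0 \
            else np.zeros(maps_z.shape[0])
    else:
        vf = np.zeros(maps_z.shape[0])
    order = np.argsort(vf)[::-1]
    return ComponentDecomposition(
        spatial_maps=maps_z[order], timecourses=M[:, order],
        variance_fraction=np.minimum(vf[order], 1.0), mask=mask,
        mean_volume=mean_volume, tr_seconds=tr, global_timecourse=global_tc)


def auto_dimensionality(Xc: np.ndarray) -> int:
    """Smallest k with >= 95% PCA variance retention, capped at min(T/2, 60)."""
    sv = np.linalg.svd(Xc, compute_uv=False)
    var = sv ** 2
    frac = np.cumsum(var) / var.sum()
    k = int(np.searchsorted(frac, PCA_VARIANCE_RETENTION) + 1)
    return max(1, min(k, Xc.shape[0] // 2, MAX_AUTO_COMPONENTS))


def decompose(img: Image4D, k: int | str = "auto",
              seed: int = 0) -> ComponentDecomposition:
    """Spatial-ICA decomposition of a 4D image into k components.

    Deterministic given ``seed`` (FastICA initialisation).
    """
    X = img.masked_data()                      # (T, V)
    T = X.shape[0]
    mean_volume = X.mean(axis=0)
    Xc = X - mean_volume
    if not np.any(Xc.std(axis=0) > 0):
        raise ValueError("degenerate data: zero temporal variance everywhere")
    global_tc = Xc.mean(axis=1)
    Xcc = Xc - global_tc[:, None]
    if k == "auto":
        k = auto_dimensionality(Xcc)
    k = int(k)
    if k > T - 1:
        raise ValueError(f"k={k} exceeds T-1={T - 1}")
    if k < 1:
        raise ValueError("k must be >= 1")

    ica = FastICA(n_components=k, algorithm="parallel", fun="logcosh",
                  whiten="unit-variance", max_iter=1000, tol=1e-7,
                  random_state=seed)
    sources = ica.fit_transform(Xcc.T)         # (V, K) spatial sources
    maps_z = _zscore_rows(sources.T)
    return _finish(maps_z, Xcc, img.brain_mask, mean_volume, img.tr_seconds,
                   global_tc)


def variance_fraction_of(decomp: ComponentDecomposition,
                         component_ids) -> float:
    """Summed explained-variance fraction of the given components."""
    ids = np.asarray(sorted(set(int(i) for i in component_ids)), dtype=int)
    if ids.size == 0:
        return 0.0
    if ids.min() < 0 or ids.max() >= decomp.n_components:
        raise KeyError(f"unknown component id in {ids.tolist()}")
    return float(decomp.variance_fraction[ids].sum())


def match_components(decomp: ComponentDecomposition,
                     reference_maps: np.ndarray) -> list[tuple[int, int, float]]:
    """Greedy one-to-one matching of components to reference maps.

    Components are processed in descending variance order (the
    decomposition's own ordering); each takes the unused reference with
    the highest absolute spatial correlation. Returns
    ``(component, reference, r)`` triples.
    """
    refs = np.asarray(reference_maps, dtype=float)
    if refs.ndim == 4:  # grids -> in-mask rows
        if refs.shape[1:] != decomp.mask.shape:
            raise ValueError("reference grid does not match decomposition grid")
        refs = refs[:, decomp.mask]
    if refs.shape[1] != decomp.spatial_maps.shape[1]:
        raise ValueError("reference maps live on a different voxel grid")
    A = _zscore_rows(decomp.spatial_maps.copy())
    B = _zscore_rows(refs.copy())
    R = A @ B.T / A.shape[1]
    pairs: list[tuple[int, int, float]] = []
    used: set[int] = set()
    for comp in range(A.shape[0]):
        free = [j for j in range(B.shape[0]) if j not in used]
        if not free:
            break
        j = max(free, key=lambda j: abs(R[comp, j]))
        used.add(j)
        pairs.append((comp, j, float(R[comp, j])))
    return pairs


def wrap_ground_truth(img: Image4D, gt: GroundTruth,
                      ) -> tuple[ComponentDecomposition, list[str]]:
    """Wrap a subject's GroundTruth as a ComponentDecomposition.

    Spatial maps are the exact simulated source maps (z-scored); time
    courses are re-estimated by least squares against the actual data so
    the usual back-projection identity holds. Lets classifier and
    cleanup behaviour be tested independently of ICA recovery error.
    Returns the decomposition plus per-component type tags
    (``"signal"`` or a noise subtype).
    """
    mask = img.brain_mask
    maps = np.concatenate([gt.signal_maps[:, mask], gt.noise_maps[:, mask]],
                          axis=0)
    tags = ["signal"] * gt.signal_maps.shape[0] + list(gt.noise_subtypes)
    keep = maps.std(axis=1) > 0
    maps, tags = maps[keep], [t for t, k in zip(tags, keep) if k]
    if maps.shape[0] == 0:
        raise ValueError("ground truth has no non-degenerate sources")
    X = img.masked_data()
    mean_volume = X.mean(axis=0)
    Xc = X - mean_volume
    global_tc = Xc.mean(axis=1)
    maps_z = _zscore_rows(maps)
    # keep tag alignment: sort by variance inside _finish, so tag via maps
    decomp = _finish(maps_z.copy(), Xc - global_tc[:, None], mask,
                     mean_volume, img.tr_seconds, global_tc)
    # recover the tag order after variance sorting by map identity
    order = []
    remaining = list(range(maps_z.shape[0]))
    flip = stats.skew(maps_z, axis=1) < 0
    maps_signed = maps_z * np.where(flip, -1.0, 1.0)[:, None]
    for row in decomp.spatial_maps:
        j = min(remaining,
                key=lambda j: float(np.sum((maps_signed[j] - row) ** 2)))
        remaining.remove(j)
        order.append(j)
    return decomp, [tags[j] for j in order]
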