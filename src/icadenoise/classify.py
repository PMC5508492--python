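"""Component classification: noise features, scorers, LOSO threshold sweeps.

Encodes the visual criteria a human rater applies to an independent
component as computable features -- peripheral (edge-rim) localisation,
speckled spatial extent and cluster count, high-frequency temporal
power, spikes and saw-tooth structure in the time course, and loading
on CSF/venous-vessel voxels -- then scores components as noise either
with a fixed monotone combination of those features (heuristic scorer)
or with a regularised linear discriminant trained on labelled cohorts.

Classifier quality is summarised by leave-one-subject-out TPR/TNR
sweeps over a binarisation threshold, and the operating threshold is
picked by the rule: among thresholds with mean TPR above a floor
(default 90%), take the one with the highest mean TNR, provided that
TNR reaches a minimum (default 10%).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage, signal, stats
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from .ica import ComponentDecomposition
from .synthgen import TissueMasks

__all__ = [
    "FEATURE_COLUMNS",
    "DEFAULT_WEIGHTS",
    "NoiseScores",
    "LabelSet",
    "ThresholdSweep",
    "component_features",
    "noise_score",
    "rule_based_labels",
    "HeuristicScorer",
    "TrainedScorer",
    "train_scorer",
    "evaluate_tpr_tnr",
    "loso_sweep",
    "select_optimal_threshold",
    "lesion_overlap",
]

log = logging.getLogger(__name__)

FEATURE_COLUMNS = (
    "edge_fraction", "speckle_extent", "n_clusters", "high_freq_fraction",
    "spike_score", "sawtooth_score", "csf_vessel_fraction",
)

#: |z| threshold defining a component's suprathreshold spatial set
SPATIAL_Z_THRESHOLD = 2.0
#: frequency (Hz) above which temporal power counts as high-frequency
HIGH_FREQ_CUTOFF_HZ = 0.1
#: speckled components cover at least this fraction of the brain
SPECKLE_EXTENT_RULE = 0.25

#: weights of the heuristic noise score (summed sub-scores, clipped to 100).
#: Motion-only mode restricts to edge_fraction, spike_score and
#: high_freq_fraction; because the weights are shared and sub-scores are
#: non-negative, the all-noise score always dominates the motion-only score.
DEFAULT_WEIGHTS = {
    "edge_fraction": 35.0,
    "speckle_extent": 20.0,
    "n_clusters": 10.0,
    "high_freq_fraction": 25.0,
    "spike_score": 25.0,
    "sawtooth_score": 10.0,
    "csf_vessel_fraction": 35.0,
}
MOTION_FEATURES = ("edge_fraction", "spike_score", "high_freq_fraction")


@dataclass
class NoiseScores:
    """Per-component noise-likeness in [0, 100]; higher = more noise-like."""

    scores: np.ndarray
    mode: str  # "all-noise" | "motion-only"

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.mode not in ("all-noise", "motion-only"):
            raise ValueError(f"unknown score mode {self.mode!r}")
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("non-finite noise scores")


@dataclass
class LabelSet:
    """Binary signal/noise labels with optional subtype and provenance."""

    labels: np.ndarray                    # array of "signal"/"noise"
    subtype: tuple[str, ...] | None = None
    provenance: str = "rule"              # ground-truth | rule | trained

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=object)
        bad = set(self.labels) - {"signal", "noise"}
        if bad:
            raise ValueError(f"labels must be signal/noise, got {bad}")

    @classmethod
    def from_subtypes(cls, tags, provenance: str = "ground-truth") -> "LabelSet":
        labels = np.array(["signal" if t == "signal" else "noise" for t in tags],
                          dtype=object)
        return cls(labels=labels, subtype=tuple(tags), provenance=provenance)

    @property
    def is_noise(self) -> np.ndarray:
        return self.labels == "noise"

    def __len__(self) -> int:
        return len(self.labels)


# ---------------------------------------------------------------------------
# features
# ---------------------------------------------------------------------------

_CONN26 = np.ones((3, 3, 3), dtype=bool)


def _spike_score(tc: np.ndarray) -> float:
    d = np.diff(tc)
    peak = np.abs(d).max() if d.size else 0.0
    if peak == 0:
        return 0.0
    mad = np.median(np.abs(d - np.median(d)))
    denom = 1.4826 * mad
    if denom == 0:
        # a handful of isolated jumps in an otherwise flat series: fall back
        # to the mean absolute difference so the score stays finite
        denom = 1.4826 * np.mean(np.abs(d))
        if denom == 0:
            return 0.0
    return float(peak / denom)


def _sawtooth_score(tc: np.ndarray) -> float:
    """|skewness| of the first differences: ramps-with-resets are one-sided."""
    d = np.diff(tc)
    if d.size < 3 or d.std() == 0:
        return 0.0
    return float(abs(stats.skew(d)))


def _high_freq_fraction(tc: np.ndarray, tr: float) -> float:
    f, p = signal.periodogram(tc, fs=1.0 / tr, detrend="constant")
    keep = f > 0
    total = p[keep].sum()
    if total == 0:
        return 0.0
    return float(p[keep & (f > HIGH_FREQ_CUTOFF_HZ)].sum() / total)


def component_features(decomp: ComponentDecomposition,
                       masks: TissueMasks) -> pd.DataFrame:
    """Noise features for every component of a decomposition.

    One row per component, columns ``FEATURE_COLUMNS``. Spatial features
    use the suprathreshold set |z| > 2 inside the brain mask; spectral
    features use the periodogram of the back-projected time course.
    """
    if masks.gray.shape != decomp.mask.shape:
        raise ValueError("tissue masks live on a different grid")
    brain = decomp.mask
    n_brain = int(brain.sum())
    csf_vessel = (masks.csf > 0.5) | masks.vessel
    rows = []
    for k in range(decomp.n_components):
        grid = decomp.map_grid(k)
        supra = (np.abs(grid) > SPATIAL_Z_THRESHOLD) & brain
        n_supra = int(supra.sum())
        if n_supra:
            edge = float((supra & masks.edge_rim).sum() / n_supra)
            csfv = float((supra & csf_vessel).sum() / n_supra)
            _, n_clusters = ndimage.label(supra, structure=_CONN26)
        else:
            edge = csfv = 0.0
            n_clusters = 0
        tc = decomp.timecourses[:, k]
        rows.append({
            "edge_fraction": edge,
            "speckle_extent": n_supra / n_brain,
            "n_clusters": n_clusters,
            "high_freq_fraction": _high_freq_fraction(tc, decomp.tr_seconds),
            "spike_score": _spike_score(tc),
            "sawtooth_score": _sawtooth_score(tc),
            "csf_vessel_fraction": csfv,
        })
    return pd.DataFrame(rows, columns=list(FEATURE_COLUMNS))


def _subscores(features: pd.DataFrame) -> pd.DataFrame:
    """Map raw features to noise-likeness sub-scores in [0, 1]."""
    s = pd.DataFrame(index=features.index)
    s["edge_fraction"] = features["edge_fraction"].clip(0, 1)
    s["speckle_extent"] = (features["speckle_extent"]
                           / SPECKLE_EXTENT_RULE).clip(0, 1)
    s["n_clusters"] = ((features["n_clusters"] - 1) / 19.0).clip(0, 1)
    s["high_freq_fraction"] = features["high_freq_fraction"].clip(0, 1)
    s["spike_score"] = (features["spike_score"] / 20.0).clip(0, 1)
    s["sawtooth_score"] = (features["sawtooth_score"] / 2.0).clip(0, 1)
    s["csf_vessel_fraction"] = features["csf_vessel_fraction"].clip(0, 1)
    return s


def noise_score(features: pd.DataFrame, mode: str = "all-noise",
                weights: dict[str, float] | None = None) -> NoiseScores:
    """Monotone weighted combination of features, scaled to [0, 100].

    ``motion-only`` mode uses only the motion-linked features
    (edge_fraction, spike_score, high_freq_fraction); ``all-noise``
    uses every feature. A component with all noise features at zero
    scores exactly 0.
    """
    if mode not in ("all-noise", "motion-only"):
        raise ValueError(f"unknown mode {mode!r}")
    w = dict(DEFAULT_WEIGHTS if weights is None else weights)
    if any(not np.isfinite(v) for v in w.values()):
        raise ValueError("weights must be finite")
    cols = MOTION_FEATURES if mode == "motion-only" else FEATURE_COLUMNS
    sub = _subscores(features)
    raw = sum(w[c] * sub[c] for c in cols)
    return NoiseScores(scores=np.clip(raw.to_numpy(dtype=float), 0.0, 100.0),
                       mode=mode)


def rule_based_labels(features: pd.DataFrame) -> LabelSet:
    """Threshold rules transcribing the manual rating criteria directly."""
    noise = (
        (features["edge_fraction"] > 0.5)
        | ((features["speckle_extent"] >= SPECKLE_EXTENT_RULE)
           & (features["n_clusters"] >= 10))
        | (features["high_freq_fraction"] > 0.5)
        | (features["spike_score"] > 10.0)
        | (features["csf_vessel_fraction"] > 0.5)
    )
    labels = np.where(noise, "noise", "signal").astype(object)
    return LabelSet(labels=labels, provenance="rule")


# ---------------------------------------------------------------------------
# scorers
# ---------------------------------------------------------------------------

@dataclass
class HeuristicScorer:
    """Fixed-weight scorer; the untrained stand-in for a shipped classifier."""

    weights: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_WEIGHTS))

    def score(self, features: pd.DataFrame,
              mode: str = "all-noise") -> NoiseScores:
        return noise_score(features, mode=mode, weights=self.weights)


@dataclass
class TrainedScorer:
    """Regularised linear discriminant over the 7 features.

    Scores are 100 x P(noise | features); deterministic given the
    training data (closed-form lsqr solver, Ledoit-Wolf shrinkage).
    """

    model: LinearDiscriminantAnalysis

    def score(self, features: pd.DataFrame,
              mode: str = "all-noise") -> NoiseScores:
        X = features[list(FEATURE_COLUMNS)].to_numpy(dtype=float)
        p_noise = self.model.predict_proba(X)[:, list(self.model.classes_).index(1)]
        return NoiseScores(scores=100.0 * p_noise, mode=mode)


def train_scorer(tables: list[tuple[pd.DataFrame, LabelSet]]) -> TrainedScorer:
    """Fit a TrainedScorer on labelled feature tables from >= 2 subjects."""
    if len(tables) < 2:
        raise ValueError("training needs feature tables from >= 2 subjects")
    X = np.concatenate([t[list(FEATURE_COLUMNS)].to_numpy(dtype=float)
                        for t, _ in tables])
    y = np.concatenate([lab.is_noise.astype(int) for _, lab in tables])
    if len(np.unique(y)) < 2:
        raise ValueError("training data contains a single class")
    model = LinearDiscriminantAnalysis(solver="lsqr", shrinkage="auto")
    model.fit(X, y)
    return TrainedScorer(model=model)


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

def evaluate_tpr_tnr(predicted: LabelSet, truth: LabelSet,
                     ) -> tuple[float, float]:
    """TPR/TNR percentages of a predicted labelling against the truth.

    TPR = % of true signal components predicted signal; TNR = % of true
    noise components predicted noise.
    """
    if len(predicted) != len(truth):
        raise ValueError("label sets cover different components")
    true_sig = ~truth.is_noise
    true_noise = truth.is_noise
    if not true_sig.any():
        raise ValueError("TPR undefined: no true signal components")
    if not true_noise.any():
        raise ValueError("TNR undefined: no true noise components")
    tpr = 100.0 * np.sum(true_sig & ~predicted.is_noise) / true_sig.sum()
    tnr = 100.0 * np.sum(true_noise & predicted.is_noise) / true_noise.sum()
    return float(tpr), float(tnr)


@dataclass
class ThresholdSweep:
    """Per-threshold mean/median TPR/TNR percentages across subjects."""

    thresholds: np.ndarray
    mean_tpr: np.ndarray
    median_tpr: np.ndarray
    mean_tnr: np.ndarray
    median_tnr: np.ndarray

    def __post_init__(self) -> None:
        self.thresholds = np.asarray(self.thresholds, dtype=float)
        for name in ("mean_tpr", "median_tpr", "mean_tnr", "median_tnr"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != self.thresholds.shape:
                raise ValueError(f"{name} length mismatch")
            if arr.size and (np.nanmin(arr) < 0 or np.nanmax(arr) > 100):
                raise ValueError(f"{name} outside [0, 100]")
            setattr(self, name, arr)

    _ROWS = ("mean_tpr", "mean_tnr", "median_tpr", "median_tnr")

    def to_tsv(self, path) -> None:
        cols = [str(int(t)) if float(t).is_integer() else str(t)
                for t in self.thresholds]
        df = pd.DataFrame(np.vstack([getattr(self, r) for r in self._ROWS]),
                          index=list(self._ROWS), columns=cols)
        df.index.name = "statistic"
        df.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path) -> "ThresholdSweep":
        try:
            df = pd.read_csv(path, sep="\t", index_col=0)
        except Exception as exc:
            raise ValueError(f"cannot parse sweep TSV {path}: {exc}") from exc
        missing = [r for r in cls._ROWS if r not in df.index]
        if missing:
            raise ValueError(f"sweep TSV {path} lacks rows {missing}")
        try:
            thresholds = np.array([float(c) for c in df.columns])
        except ValueError as exc:
            raise ValueError(
                f"sweep TSV {path}: non-numeric threshold column: {exc}"
            ) from exc
        kw = {}
        for row in cls._ROWS:
            try:
                kw[row] = df.loc[row].astype(float).to_numpy()
            except ValueError as exc:
                raise ValueError(
                    f"sweep TSV {path}: non-numeric value in row {row!r}: {exc}"
                ) from exc
        return cls(thresholds=thresholds, **kw)


def loso_sweep(cohort: list[tuple[pd.DataFrame, LabelSet]],
               thresholds) -> ThresholdSweep:
    """Leave-one-subject-out TPR/TNR sweep.

    Each fold trains on all other subjects' labelled features, scores
    the held-out subject, and binarises at every threshold
    (score >= threshold -> noise). Subjects whose truth lacks one class
    are excluded from the statistic that class defines (and logged).
    """
    if len(cohort) < 2:
        raise ValueError("LOSO needs >= 2 subjects")
    thresholds = np.asarray(sorted(thresholds), dtype=float)
    n_sub = len(cohort)
    tpr = np.full((n_sub, thresholds.size), np.nan)
    tnr = np.full((n_sub, thresholds.size), np.nan)
    for i, (features, truth) in enumerate(cohort):
        scorer = train_scorer([cohort[j] for j in range(n_sub) if j != i])
        scores = scorer.score(features).scores
        true_sig = ~truth.is_noise
        true_noise = truth.is_noise
        if not true_sig.any():
            log.warning("LOSO fold %d: no true signal components; "
                        "subject excluded from TPR", i)
        if not true_noise.any():
            log.warning("LOSO fold %d: no true noise components; "
                        "subject excluded from TNR", i)
        for t, th in enumerate(thresholds):
            pred_noise = scores >= th
            if true_sig.any():
                tpr[i, t] = 100.0 * np.sum(true_sig & ~pred_noise) / true_sig.sum()
            if true_noise.any():
                tnr[i, t] = 100.0 * np.sum(true_noise & pred_noise) / true_noise.sum()
    with np.errstate(all="ignore"):
        return ThresholdSweep(
            thresholds=thresholds,
            mean_tpr=np.nanmean(tpr, axis=0),
            median_tpr=np.nanmedian(tpr, axis=0),
            mean_tnr=np.nanmean(tnr, axis=0),
            median_tnr=np.nanmedian(tnr, axis=0),
        )


def select_optimal_threshold(sweep: ThresholdSweep, tpr_floor: float = 90.0,
                             tnr_min: float = 10.0) -> float | None:
    """Operating-threshold rule.

    Among thresholds whose mean TPR exceeds ``tpr_floor``, pick the one
    maximising mean TNR, provided that maximum reaches ``tnr_min``;
    otherwise return None. Ties resolve to the largest threshold.
    """
    ok = np.flatnonzero(sweep.mean_tpr > tpr_floor)
    if ok.size == 0:
        return None
    best_tnr = np.nanmax(sweep.mean_tnr[ok])
    if not (best_tnr >= tnr_min):
        return None
    winners = ok[sweep.mean_tnr[ok] == best_tnr]
    return float(sweep.thresholds[winners.max()])


def lesion_overlap(component_mask: np.ndarray,
                   lesion_mask: np.ndarray) -> float:
    """Fraction of a component's suprathreshold voxels inside the lesion."""
    component_mask = np.asarray(component_mask, dtype=bool)
    lesion_mask = np.asarray(lesion_mask, dtype=bool)
    if component_mask.shape != lesion_mask.shape:
        raise ValueError("component and lesion masks on different grids")
    n = int(component_mask.sum())
    if n == 0:
        raise ValueError("empty component voxel set")
    return float((component_mask & lesion_mask).sum() / n)
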