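"""Seeded synthetic resting-state fMRI cohorts with known signal and noise sources.

Every downstream stage of the evaluation pipeline (ICA, component
classification, denoising, dual regression, metrics) is exercised on data
from this module, so the generator writes down exactly what it mixed:
smooth gray-matter network maps driven by low-frequency (0.01-0.1 Hz)
time courses, plus three families of structured noise -- motion
(edge-of-brain maps, spiky/saw-tooth time courses), physiological
(CSF/vessel maps, narrowband high-frequency time courses) and vascular
(vessel-weighted maps, very slow oscillations) -- on top of white
mixing noise and a constant in-brain offset.

The grid defaults (32 x 32 x 24 voxels of 3 mm, 120 frames at TR 3 s)
emulate a standard clinical resting-state EPI acquisition.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "SynthConfig",
    "SynthConfigError",
    "Image4D",
    "TissueMasks",
    "GroundTruth",
    "NOISE_SUBTYPES",
    "make_subject",
    "make_cohort",
    "make_noi_atlas",
    "make_lesion_mask",
    "reconstruct",
]

NOISE_SUBTYPES = ("motion", "physiological", "vascular")


class SynthConfigError(ValueError):
    """A SynthConfig field violates its invariant; the message names the field."""


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SynthConfig:
    """Cohort-generation parameters.

    Amplitudes are relative: signal time courses have unit standard
    deviation and spatial maps unit peak, so ``motion_amplitude=3.0``
    means motion sources mix at three times the signal amplitude.
    """

    n_subjects: int = 20
    grid_shape: tuple[int, int, int] = (32, 32, 24)
    voxel_size_mm: tuple[float, float, float] = (3.0, 3.0, 3.0)
    tr_seconds: float = 3.0
    n_frames: int = 120
    k_signal: int = 5
    k_motion: int = 3
    k_physiological: int = 2
    k_vascular: int = 1
    signal_band_hz: tuple[float, float] = (0.01, 0.1)
    physio_band_hz: tuple[float, float] = (0.11, 0.16)
    vascular_band_hz: tuple[float, float] = (0.003, 0.02)
    spike_rate_per_frame: float = 0.05
    sawtooth_prob: float = 0.5
    signal_amplitude: float = 1.0
    motion_amplitude: float = 3.0
    physio_amplitude: float = 2.0
    vascular_amplitude: float = 1.5
    mixing_noise_sd: float = 0.5
    offset: float = 100.0
    spatial_jitter_sd_vox: float = 1.0
    lesion_radius_range_vox: tuple[float, float] = (2.0, 4.0)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("grid_shape", "voxel_size_mm", "signal_band_hz",
                     "physio_band_hz", "vascular_band_hz",
                     "lesion_radius_range_vox"):
            object.__setattr__(self, name, tuple(getattr(self, name)))

    @property
    def k_noise(self) -> int:
        return self.k_motion + self.k_physiological + self.k_vascular

    def validate(self) -> None:
        def bad(name: str, why: str) -> SynthConfigError:
            return SynthConfigError(f"invalid SynthConfig.{name}: {why}")

        if self.n_subjects < 1:
            raise bad("n_subjects", "must be >= 1")
        if len(self.grid_shape) != 3 or any(d < 8 for d in self.grid_shape):
            raise bad("grid_shape", "needs three dims, each >= 8")
        if any(v <= 0 for v in self.voxel_size_mm):
            raise bad("voxel_size_mm", "must be positive")
        if self.tr_seconds <= 0:
            raise bad("tr_seconds", "must be positive")
        if self.n_frames < 2:
            raise bad("n_frames", "must be >= 2")
        if self.k_signal < 0 or self.k_motion < 0 or self.k_physiological < 0 \
                or self.k_vascular < 0:
            raise bad("k_signal/k_*", "source counts must be >= 0")
        if self.k_signal + self.k_noise > self.n_frames - 1:
            raise bad("k_signal", "k_signal + k_noise must be <= n_frames - 1")
        nyquist = 0.5 / self.tr_seconds
        for name in ("signal_band_hz", "physio_band_hz", "vascular_band_hz"):
            lo, hi = getattr(self, name)
            if not (0 <= lo < hi <= nyquist):
                raise bad(name, f"need 0 <= low < high <= Nyquist ({nyquist:g} Hz)")
        if self.spike_rate_per_frame < 0:
            raise bad("spike_rate_per_frame", "must be >= 0")
        if not 0 <= self.sawtooth_prob <= 1:
            raise bad("sawtooth_prob", "must be in [0, 1]")
        for name in ("signal_amplitude", "motion_amplitude", "physio_amplitude",
                     "vascular_amplitude"):
            if getattr(self, name) < 0:
                raise bad(name, "must be >= 0")
        if self.mixing_noise_sd < 0:
            raise bad("mixing_noise_sd", "must be >= 0")
        if self.spatial_jitter_sd_vox < 0:
            raise bad("spatial_jitter_sd_vox", "must be >= 0")
        lo, hi = self.lesion_radius_range_vox
        if not 0 < lo <= hi:
            raise bad("lesion_radius_range_vox", "need 0 < low <= high")

    def replace(self, **kw) -> "SynthConfig":
        return dataclasses.replace(self, **kw)


# ---------------------------------------------------------------------------
# domain containers
# ---------------------------------------------------------------------------

@dataclass
class Image4D:
    """A masked 4D voxel time-series with its grid geometry."""

    voxels: np.ndarray            # (nx, ny, nz, T)
    voxel_size_mm: tuple[float, float, float]
    tr_seconds: float
    brain_mask: np.ndarray        # (nx, ny, nz) bool

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=float)
        self.brain_mask = np.asarray(self.brain_mask, dtype=bool)
        if self.voxels.ndim != 4:
            raise ValueError("voxels must be 4-dimensional (nx, ny, nz, T)")
        if self.voxels.shape[:3] != self.brain_mask.shape:
            raise ValueError("brain_mask shape must equal the spatial shape")
        if self.voxels.shape[3] < 2:
            raise ValueError("need at least 2 frames")
        if not self.brain_mask.any():
            raise ValueError("brain_mask has no voxels")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("voxels contain non-finite values")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.voxels.shape[:3]

    @property
    def n_frames(self) -> int:
        return self.voxels.shape[3]

    def masked_data(self) -> np.ndarray:
        """In-mask time-series as a (T, V) matrix."""
        return self.voxels[self.brain_mask].T.copy()

    def with_masked_data(self, data: np.ndarray) -> "Image4D":
        """New Image4D whose in-mask series are replaced by ``data`` (T, V)."""
        out = np.zeros_like(self.voxels)
        out[self.brain_mask] = np.asarray(data).T
        return Image4D(out, self.voxel_size_mm, self.tr_seconds,
                       self.brain_mask.copy())


@dataclass
class TissueMasks:
    """Probabilistic tissue maps plus edge-rim and vessel masks, one grid."""

    gray: np.ndarray
    white: np.ndarray
    csf: np.ndarray
    edge_rim: np.ndarray   # bool
    vessel: np.ndarray     # bool

    def __post_init__(self) -> None:
        for name in ("gray", "white", "csf"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.min() < 0 or arr.max() > 1:
                raise ValueError(f"{name} probabilities must lie in [0, 1]")
            setattr(self, name, arr)
        self.edge_rim = np.asarray(self.edge_rim, dtype=bool)
        self.vessel = np.asarray(self.vessel, dtype=bool)


@dataclass
class GroundTruth:
    """The latent sources a subject's data were mixed from.

    ``reconstruct`` rebuilds the noiseless data from these fields exactly,
    so recovery can be judged against a known answer.
    """

    signal_maps: np.ndarray         # (k_signal, nx, ny, nz), amplitude-scaled
    signal_timecourses: np.ndarray  # (T, k_signal), zero mean, unit SD
    noise_maps: np.ndarray          # (k_noise, nx, ny, nz), amplitude-scaled
    noise_subtypes: tuple[str, ...]
    noise_timecourses: np.ndarray   # (T, k_noise), zero mean, unit SD
    mixing_noise_sd: float
    lesion_mask: np.ndarray         # bool
    offset: float = 0.0

    def __post_init__(self) -> None:
        for tag in self.noise_subtypes:
            if tag not in NOISE_SUBTYPES:
                raise ValueError(f"unknown noise subtype {tag!r}")
        for name in ("signal_maps", "noise_maps", "signal_timecourses",
                     "noise_timecourses"):
            if not np.all(np.isfinite(np.asarray(getattr(self, name)))):
                raise ValueError(f"{name} contains non-finite values")


def reconstruct(gt: GroundTruth, brain_mask: np.ndarray) -> np.ndarray:
    """Noiseless 4D data implied by a GroundTruth (exact linear mixing)."""
    shape = brain_mask.shape
    T = gt.signal_timecourses.shape[0] if gt.signal_timecourses.size else \
        gt.noise_timecourses.shape[0]
    out = np.zeros(shape + (T,), dtype=float)
    out[brain_mask] = gt.offset
    for k in range(gt.signal_maps.shape[0]):
        out += gt.signal_maps[k][..., None] * gt.signal_timecourses[:, k]
    for j in range(gt.noise_maps.shape[0]):
        out += gt.noise_maps[j][..., None] * gt.noise_timecourses[:, j]
    return out


# ---------------------------------------------------------------------------
# geometry: brain, tissues, vessels
# ---------------------------------------------------------------------------

def _brain_mask(shape: tuple[int, int, int]) -> np.ndarray:
    nx, ny, nz = shape
    cx, cy, cz = (nx - 1) / 2, (ny - 1) / 2, (nz - 1) / 2
    ax, ay, az = 0.42 * nx, 0.42 * ny, 0.40 * nz
    x, y, z = np.mgrid[:nx, :ny, :nz]
    return ((x - cx) / ax) ** 2 + ((y - cy) / ay) ** 2 + ((z - cz) / az) ** 2 <= 1.0


def _tissue_masks(brain: np.ndarray) -> TissueMasks:
    nx, ny, nz = brain.shape
    cx, cy, cz = (nx - 1) / 2, (ny - 1) / 2, (nz - 1) / 2
    depth = ndimage.distance_transform_edt(brain)
    edge_rim = brain & ~ndimage.binary_erosion(brain, iterations=2)

    # central "ventricle" ellipsoid
    x, y, z = np.mgrid[:nx, :ny, :nz]
    vent = (((x - cx) / (0.11 * nx)) ** 2 + ((y - cy) / (0.14 * ny)) ** 2
            + ((z - cz) / (0.11 * nz)) ** 2 <= 1.0) & brain

    # posterior midline vessel (sagittal-sinus-like): a thin deep-to-edge track
    vessel = (np.abs(x - cx) <= 0.6) & (y > cy + 0.22 * ny) \
        & (np.abs(z - cz) <= 0.15 * nz) & brain & (depth >= 1.0)

    # gray shell between the 2-voxel rim and the white-matter core; the
    # core boundary adapts downward on small grids so both tissues exist
    t_white = min(6.0, 0.7 * depth.max())
    gray = np.where((depth >= 2) & (depth < t_white), 0.9,
                    np.where((depth > 0) & (depth < 2), 0.35, 0.05))
    white = np.where(depth >= t_white, 0.9, np.where(depth >= 2, 0.08, 0.02))
    csf = np.zeros(brain.shape)
    csf[vent] = 0.95
    gray[vent] = 0.02
    white[vent] = 0.02
    gray[~brain] = 0.0
    white[~brain] = 0.0
    csf[~brain] = 0.0
    return TissueMasks(gray=gray, white=white, csf=csf,
                       edge_rim=edge_rim, vessel=vessel)


def _smooth_field(rng: np.random.Generator, shape, sigma=2.0) -> np.ndarray:
    f = ndimage.gaussian_filter(rng.normal(size=shape), sigma)
    return f


def _unit_peak(m: np.ndarray) -> np.ndarray:
    peak = np.abs(m).max()
    return m / peak if peak > 0 else m


def _signal_map(center, gray: np.ndarray, brain: np.ndarray,
                sigma_vox: float = 2.0) -> np.ndarray:
    grids = np.mgrid[[slice(0, n) for n in brain.shape]]
    r2 = sum((g - c) ** 2 for g, c in zip(grids, center))
    blob = np.exp(-r2 / (2 * sigma_vox ** 2))
    m = blob * (0.15 + 0.85 * gray) * brain
    return _unit_peak(m)


def _noise_map(rng: np.random.Generator, weight: np.ndarray) -> np.ndarray:
    m = np.abs(_smooth_field(rng, weight.shape, sigma=1.5)) * weight
    return _unit_peak(m)


# ---------------------------------------------------------------------------
# time courses
# ---------------------------------------------------------------------------

def _standardise(tc: np.ndarray) -> np.ndarray:
    tc = tc - tc.mean()
    sd = tc.std()
    return tc / sd if sd > 0 else tc


def _bandlimited(rng: np.random.Generator, T: int, tr: float,
                 lo: float, hi: float) -> np.ndarray:
    freqs = np.fft.rfftfreq(T, d=tr)
    spec = rng.normal(size=freqs.size) + 1j * rng.normal(size=freqs.size)
    keep = (freqs >= lo) & (freqs <= hi)
    if not keep.any():
        keep[np.argmin(np.abs(freqs - 0.5 * (lo + hi)))] = True
    spec = np.where(keep, spec, 0.0)
    return _standardise(np.fft.irfft(spec, n=T))


def _motion_timecourse(rng: np.random.Generator, T: int,
                       spike_rate: float, sawtooth_prob: float) -> np.ndarray:
    tc = rng.normal(size=T)
    n_spikes = rng.poisson(spike_rate * T)
    if n_spikes > 0:
        pos = rng.integers(0, T, size=n_spikes)
        amp = rng.uniform(5.0, 9.0, size=n_spikes) * rng.choice([-1, 1], n_spikes)
        tc[pos] += amp
    if rng.uniform() < sawtooth_prob:
        seg = max(8, T // 6)
        start = rng.integers(0, max(1, T - seg))
        period = rng.integers(4, 9)
        ramp = (np.arange(seg) % period) / (period - 1) - 0.5
        tc[start:start + seg] += 4.0 * ramp
    return _standardise(tc)


# ---------------------------------------------------------------------------
# subject / cohort assembly
# ---------------------------------------------------------------------------

def _sample_signal_centers(rng: np.random.Generator, config: SynthConfig,
                           gray: np.ndarray) -> np.ndarray:
    cand = np.argwhere(gray > 0.5)
    idx = rng.choice(cand.shape[0], size=config.k_signal, replace=False)
    return cand[idx].astype(float)


def make_subject(config: SynthConfig, subject_seed: int,
                 signal_centers: np.ndarray | None = None,
                 ) -> tuple[Image4D, TissueMasks, GroundTruth]:
    """Generate one subject: data, tissue masks, and the mixed ground truth.

    Identical ``(config, subject_seed)`` (and ``signal_centers``, when
    given) reproduces bit-identical output.
    """
    config.validate()
    rng = np.random.default_rng(subject_seed)
    shape, T = config.grid_shape, config.n_frames
    brain = _brain_mask(shape)
    masks = _tissue_masks(brain)

    if signal_centers is None and config.k_signal > 0:
        signal_centers = _sample_signal_centers(rng, config, masks.gray)

    sig_maps = np.zeros((config.k_signal,) + shape)
    sig_tcs = np.zeros((T, config.k_signal))
    for k in range(config.k_signal):
        sig_maps[k] = config.signal_amplitude * _signal_map(
            signal_centers[k], masks.gray, brain)
        sig_tcs[:, k] = _bandlimited(rng, T, config.tr_seconds,
                                     *config.signal_band_hz)

    noise_specs: list[tuple[str, np.ndarray, float, tuple[float, float] | None]] = []
    rim_w = masks.edge_rim.astype(float)
    physio_w = masks.csf + 0.6 * masks.vessel
    vasc_w = ndimage.binary_dilation(masks.vessel).astype(float) * brain \
        + 0.3 * masks.csf
    for _ in range(config.k_motion):
        noise_specs.append(("motion", rim_w, config.motion_amplitude, None))
    for _ in range(config.k_physiological):
        noise_specs.append(("physiological", physio_w, config.physio_amplitude,
                            config.physio_band_hz))
    for _ in range(config.k_vascular):
        noise_specs.append(("vascular", vasc_w, config.vascular_amplitude,
                            config.vascular_band_hz))

    noise_maps = np.zeros((len(noise_specs),) + shape)
    noise_tcs = np.zeros((T, len(noise_specs)))
    subtypes: list[str] = []
    for j, (tag, weight, amp, band) in enumerate(noise_specs):
        noise_maps[j] = amp * _noise_map(rng, weight)
        if tag == "motion":
            noise_tcs[:, j] = _motion_timecourse(
                rng, T, config.spike_rate_per_frame, config.sawtooth_prob)
        else:
            noise_tcs[:, j] = _bandlimited(rng, T, config.tr_seconds, *band)
        subtypes.append(tag)

    lesion = make_lesion_mask(config, int(rng.integers(0, 2**31 - 1)))

    gt = GroundTruth(signal_maps=sig_maps, signal_timecourses=sig_tcs,
                     noise_maps=noise_maps, noise_subtypes=tuple(subtypes),
                     noise_timecourses=noise_tcs,
                     mixing_noise_sd=config.mixing_noise_sd,
                     lesion_mask=lesion, offset=config.offset)

    voxels = reconstruct(gt, brain)
    if config.mixing_noise_sd > 0:
        white = rng.normal(0.0, config.mixing_noise_sd,
                           size=(int(brain.sum()), T))
        voxels[brain] += white
    img = Image4D(voxels=voxels, voxel_size_mm=config.voxel_size_mm,
                  tr_seconds=config.tr_seconds, brain_mask=brain)
    return img, masks, gt


def make_cohort(config: SynthConfig,
                ) -> list[tuple[Image4D, TissueMasks, GroundTruth]]:
    """Generate a cohort sharing group-level signal maps up to spatial jitter.

    Per-subject seeds are derived deterministically from ``config.seed``;
    time courses and noise sources are independent across subjects.
    """
    config.validate()
    if config.n_subjects < 2:
        raise SynthConfigError(
            "invalid SynthConfig.n_subjects: cohort needs >= 2 subjects "
            "(group metrics are undefined otherwise)")
    master = np.random.default_rng(config.seed)
    brain = _brain_mask(config.grid_shape)
    gray = _tissue_masks(brain).gray
    centers = _sample_signal_centers(master, config, gray) \
        if config.k_signal > 0 else np.zeros((0, 3))
    subject_seeds = master.integers(0, 2**31 - 1, size=config.n_subjects)
    cohort = []
    for s in range(config.n_subjects):
        jitter = master.normal(0.0, config.spatial_jitter_sd_vox,
                               size=centers.shape)
        cohort.append(make_subject(config, int(subject_seeds[s]),
                                   signal_centers=centers + jitter))
    return cohort


def make_lesion_mask(config: SynthConfig, seed: int) -> np.ndarray:
    """One connected spherical lesion inside the brain (>= 1 voxel)."""
    rng = np.random.default_rng(seed)
    brain = _brain_mask(config.grid_shape)
    depth = ndimage.distance_transform_edt(brain)
    lo, hi = config.lesion_radius_range_vox
    radius = max(rng.uniform(lo, hi), 1.0)
    interior = np.argwhere(depth >= radius + 1)
    if interior.shape[0] == 0:
        interior = np.argwhere(depth == depth.max())
    center = interior[rng.integers(0, interior.shape[0])]
    grids = np.mgrid[[slice(0, n) for n in brain.shape]]
    r2 = sum((g - c) ** 2 for g, c in zip(grids, center))
    lesion = (r2 <= radius ** 2) & brain
    if not lesion.any():
        lesion[tuple(center)] = True
    return lesion


def make_noi_atlas(ground_truths: list[GroundTruth], n_templates: int,
                   seed: int = 0, brain_mask: np.ndarray | None = None,
                   gray_matter: np.ndarray | None = None,
                   max_distractor_corr: float = 0.2):
    """Build a network-of-interest template atlas from a cohort's ground truth.

    The first ``k_signal`` templates are the voxelwise-standardised
    group-mean signal maps; the remainder are smooth distractor fields
    regenerated until spatially uncorrelated (|r| < ``max_distractor_corr``)
    with every signal template.
    """
    from .dualreg import NOIAtlas  # local import avoids a module cycle

    k_signal = ground_truths[0].signal_maps.shape[0]
    if n_templates < k_signal:
        raise ValueError(
            f"n_templates={n_templates} < k_signal={k_signal}")
    shape = ground_truths[0].signal_maps.shape[1:]
    if brain_mask is None:
        brain_mask = _brain_mask(shape)
    if gray_matter is None:
        gray_matter = _tissue_masks(brain_mask).gray
    V = int(brain_mask.sum())

    def standardise(grid: np.ndarray) -> np.ndarray:
        vals = grid[brain_mask]
        sd = vals.std()
        out = np.zeros(shape)
        out[brain_mask] = (vals - vals.mean()) / (sd if sd > 0 else 1.0)
        return out

    group_mean = np.mean([gt.signal_maps for gt in ground_truths], axis=0)
    templates = np.zeros((n_templates,) + shape)
    labels = []
    for k in range(k_signal):
        templates[k] = standardise(group_mean[k])
        labels.append(f"network-{k:02d}")

    rng = np.random.default_rng(seed)
    sig_flat = templates[:k_signal][:, brain_mask] if k_signal else \
        np.zeros((0, V))
    for j in range(k_signal, n_templates):
        for _ in range(200):
            cand = standardise(_smooth_field(rng, shape, sigma=2.0) * brain_mask)
            flat = cand[brain_mask]
            if k_signal == 0:
                break
            r = sig_flat @ flat / V  # both standardised -> correlation
            if np.abs(r).max() < max_distractor_corr:
                break
        else:
            raise RuntimeError("could not draw an uncorrelated distractor map")
        templates[j] = cand
        labels.append(f"distractor-{j:02d}")

    return NOIAtlas(templates=templates, labels=tuple(labels),
                    gray_matter=gray_matter, brain_mask=brain_mask)
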