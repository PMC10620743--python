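"""Synthetic multi-subject resting-state datasets with known ground truth.

Generates two-group (HC / ASD) cohorts from k latent spatial sources:
Gaussian blobs with per-subject centroid jitter (intersubject spatial
variability, ISV), group-specific time-course covariance (the planted
functional-network-connectivity structure), group-specific inflation of
across-subject spatial variance on designated sources, and i.i.d. Gaussian
noise. Every downstream stage of the pipeline therefore has a recoverable
ground truth: the base maps, each subject's true maps and time courses,
the mixing structure, and the planted group differences.

The defaults are sized so the full two-method pipeline runs in minutes:
15 + 15 subjects, 8 sources on a 12x12x12 grid, 150 timepoints at TR = 2 s.
Time courses are band-limited (0-0.1 Hz) filtered Gaussian draws rather
than HRF-convolved event trains, so the planted FNC equals the specified
covariance's correlation structure exactly in expectation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .types import ASD, HC, GroupDataset, SubjectScan

logger = logging.getLogger(__name__)

#: default band edge for hemodynamic-like slow fluctuations
LOW_FREQ_CUTOFF_HZ = 0.1


def block_covariance(k: int, blocks, r: float = 0.45) -> np.ndarray:
    """Equicorrelation-block covariance: unit variance, correlation ``r``
    inside each block of ``blocks`` (a partition of range(k)), 0 between."""
    cov = np.eye(k)
    for block in blocks:
        for i in block:
            for j in block:
                if i != j:
                    cov[i, j] = r
    return cov


def _default_cov_hc(k: int) -> np.ndarray:
    half = k // 2
    return block_covariance(k, [range(half), range(half, k)])


def _default_cov_asd(k: int) -> np.ndarray:
    third = max(k // 3, 1)
    blocks = [range(third), range(third, 2 * third), range(2 * third, k)]
    return block_covariance(k, [b for b in blocks if len(b) > 0])


@dataclass
class SimConfig:
    """Study-condition parameters for the synthetic cohort generator.

    isv_sigma is the std of the per-subject blob-centroid jitter in voxel
    units; amp_sigma the fractional per-subject amplitude jitter;
    var_inflation_asd multiplies the across-subject spatial variance of
    ``inflated_sources`` in the ASD group (>= 1).
    """

    n_hc: int = 15
    n_asd: int = 15
    k_sources: int = 8
    grid_shape: tuple = (12, 12, 12)
    n_timepoints: int = 150
    tr_seconds: float = 2.0
    isv_sigma: float = 1.0
    amp_sigma: float = 0.1
    var_inflation_asd: float = 2.0
    inflated_sources: tuple = None  # None -> first min(2, k) sources
    fnc_cov_hc: np.ndarray = None
    fnc_cov_asd: np.ndarray = None
    noise_sigma: float = 0.5
    blob_sigma: float = None  # None -> min(grid)/10
    seed: int = 0

    def __post_init__(self):
        if self.inflated_sources is None:
            self.inflated_sources = tuple(range(min(2, self.k_sources)))
        if self.fnc_cov_hc is None:
            self.fnc_cov_hc = _default_cov_hc(self.k_sources)
        if self.fnc_cov_asd is None:
            self.fnc_cov_asd = _default_cov_asd(self.k_sources)
        self.fnc_cov_hc = np.asarray(self.fnc_cov_hc, dtype=float)
        self.fnc_cov_asd = np.asarray(self.fnc_cov_asd, dtype=float)
        self.grid_shape = tuple(int(g) for g in self.grid_shape)
        self.validate()

    def validate(self):
        if min(self.n_hc, self.n_asd) < 1 or self.k_sources < 1:
            raise ValueError("subject counts and k_sources must be positive")
        if self.k_sources > self.n_timepoints:
            raise ValueError("k_sources must not exceed n_timepoints")
        if int(np.prod(self.grid_shape)) < 10 * self.k_sources:
            raise ValueError("grid volume must be >= 10 * k_sources")
        if self.isv_sigma < 0 or self.amp_sigma < 0 or self.noise_sigma < 0:
            raise ValueError("sigmas must be non-negative")
        if self.var_inflation_asd < 1:
            raise ValueError("var_inflation_asd must be >= 1")
        if not all(0 <= s < self.k_sources for s in self.inflated_sources):
            raise ValueError("inflated_sources out of range")
        for name, cov in (("fnc_cov_hc", self.fnc_cov_hc),
                          ("fnc_cov_asd", self.fnc_cov_asd)):
            k = self.k_sources
            if cov.shape != (k, k):
                raise ValueError(f"{name} must be {k}x{k}")
            if not np.allclose(cov, cov.T):
                raise ValueError(f"{name} must be symmetric")
            if np.linalg.eigvalsh(cov).min() <= 0:
                raise ValueError(f"{name} must be positive definite")

    @property
    def n_subjects(self) -> int:
        return self.n_hc + self.n_asd

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.grid_shape))


@dataclass
class GroundTruth:
    """Latent quantities of a generated cohort: group-level base maps
    (k x V, unit peak), each subject's true maps and time courses, and the
    generating configuration."""

    base_maps: np.ndarray  # k x V
    subject_maps: list  # per subject k x V
    subject_tcs: list  # per subject T x k
    group_labels: list
    blob_centers: np.ndarray = None  # k x 3
    config: SimConfig = None


# ---------------------------------------------------------------------------
# base maps

def _rasterize_blob(center, sigma, grid_shape) -> np.ndarray:
    axes = [np.arange(g, dtype=float) for g in grid_shape]
    zz, yy, xx = np.meshgrid(*axes, indexing="ij")
    d2 = ((zz - center[0]) ** 2 + (yy - center[1]) ** 2 + (xx - center[2]) ** 2)
    blob = np.exp(-d2 / (2.0 * sigma ** 2)).ravel()
    peak = blob.max()
    if peak <= 0:
        raise RuntimeError("degenerate blob")
    return blob / peak


def _spatial_corr(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.linalg.norm(a) * np.linalg.norm(b)
    if denom == 0:
        return 0.0
    return float(a @ b / denom)


def make_base_maps(config: SimConfig, max_retries: int = 500):
    """Place ``k_sources`` Gaussian blobs on the grid so that pairwise
    spatial correlation stays below 0.3; each map has unit peak.

    Returns (maps k x V, centers k x 3, blob sigma). Raises ValueError if
    a non-overlapping placement cannot be found within ``max_retries``
    proposals per source.
    """
    rng = np.random.default_rng(config.seed)
    grid = np.array(config.grid_shape, dtype=float)
    sigma = config.blob_sigma or max(1.0, float(grid.min()) / 10.0)
    margin = 2.0 * sigma

    maps, centers = [], []
    for k in range(config.k_sources):
        placed = False
        for _ in range(max_retries):
            center = rng.uniform(margin, grid - 1 - margin)
            cand = _rasterize_blob(center, sigma, config.grid_shape)
            if all(abs(_spatial_corr(cand, m)) < 0.3 for m in maps):
                maps.append(cand)
                centers.append(center)
                placed = True
                break
        if not placed:
            raise ValueError(
                f"could not place blob {k} with pairwise |r| < 0.3 after "
                f"{max_retries} retries; enlarge the grid or reduce k_sources"
            )
    return np.array(maps), np.array(centers), sigma


# ---------------------------------------------------------------------------
# subject maps

def sample_subject_maps(base_maps, centers, sigma, config: SimConfig, rng):
    """Draw per-subject spatial maps for all subjects.

    Each subject's blob centroid is shifted by N(0, isv_sigma) per axis
    (clamped to the grid, with a warning if a shift would push a blob
    fully off-grid) and its amplitude scaled by 1 + N(0, amp_sigma).
    ASD subjects' deviations from the base map on ``inflated_sources`` are
    scaled by sqrt(var_inflation_asd), which inflates the across-subject
    voxelwise variance of those sources by exactly var_inflation_asd.

    Returns (subject_maps list of k x V, group_labels list).
    """
    grid = np.array(config.grid_shape, dtype=float)
    labels = [HC] * config.n_hc + [ASD] * config.n_asd
    sqrt_inflation = np.sqrt(config.var_inflation_asd)

    subject_maps = []
    for label in labels:
        rows = []
        for k in range(config.k_sources):
            shift = rng.normal(0.0, config.isv_sigma, size=3)
            center = centers[k] + shift
            clamped = np.clip(center, 0.0, grid - 1)
            if np.any(center != clamped):
                if np.any(center < -2 * sigma) or np.any(center > grid - 1 + 2 * sigma):
                    logger.warning(
                        "blob %d shifted fully off-grid; clamped to boundary", k
                    )
                center = clamped
            amp = 1.0 + rng.normal(0.0, config.amp_sigma)
            row = amp * _rasterize_blob(center, sigma, config.grid_shape)
            if label == ASD and k in config.inflated_sources:
                row = base_maps[k] + sqrt_inflation * (row - base_maps[k])
            rows.append(row)
        subject_maps.append(np.array(rows))
    return subject_maps, labels


# ---------------------------------------------------------------------------
# time courses

def lowpass_filter(tcs: np.ndarray, tr_seconds: float,
                   cutoff_hz: float = LOW_FREQ_CUTOFF_HZ) -> np.ndarray:
    """Zero-phase low-pass Butterworth filter along the time axis.

    The output is rescaled by the filter's broadband root-mean-square gain
    so that a unit-variance white input keeps unit variance: the planted
    covariance then sets the scale of the generated sources, not the
    filter's attenuation. The scalar gain is deterministic and shared by
    all columns, so cross-source correlations are untouched.
    """
    nyquist = 0.5 / tr_seconds
    wn = min(cutoff_hz / nyquist, 0.99)
    b, a = signal.butter(4, wn)
    _, h = signal.freqz(b, a, worN=2048)
    # filtfilt applies the filter twice -> power transfer |H|^4
    rms_gain = np.sqrt(np.mean(np.abs(h) ** 4))
    return signal.filtfilt(b, a, tcs, axis=0) / rms_gain


def sample_timecourses(config: SimConfig, group: str, rng,
                       band_limit: bool = True) -> np.ndarray:
    """Draw a T x k time-course matrix from the group's zero-mean
    multivariate normal, then band-limit to 0-0.1 Hz.

    The pre-filter draw's sample covariance converges to the group
    covariance; the shared linear filter preserves the cross-source
    correlation structure in expectation.
    """
    cov = config.fnc_cov_hc if group == HC else config.fnc_cov_asd
    # validated at config construction, but a caller may pass a raw config
    if np.linalg.eigvalsh(cov).min() <= 0:
        raise ValueError("group covariance must be positive definite")
    chol = np.linalg.cholesky(cov)
    tcs = rng.standard_normal((config.n_timepoints, config.k_sources)) @ chol.T
    if band_limit:
        tcs = lowpass_filter(tcs, config.tr_seconds)
    return tcs


def make_behavioral_target(subject_maps, component: int, seed: int = 0,
                           snr: float = 2.0, mode: str = "isv-mode",
                           support_frac: float = 0.05):
    """Synthesize a behavioral score that is a linear function of one
    component's voxels plus Gaussian noise, at std(signal)/std(noise)
    equal to ``snr``.

    mode="isv-mode" (default): the weight vector is the first principal
    axis of the component's z-scored subject maps, so the score tracks
    the dominant mode of intersubject spatial variability — behavior
    rides on how the network is spatially reorganized across subjects.
    mode="random": weights drawn i.i.d. over the component's strongest
    ``support_frac`` voxels; much of such a functional falls outside the
    maps' across-subject variation, making the score largely
    unpredictable — useful as a hard reference condition.

    Returns (target N-vector, weight V-vector).
    """
    raw = np.array([m[component] for m in subject_maps])  # N x V
    maps = (raw - raw.mean(axis=1, keepdims=True)) / raw.std(axis=1, keepdims=True)
    rng = np.random.default_rng(seed)
    if mode == "isv-mode":
        centered = maps - maps.mean(axis=0)
        _, _, vt = np.linalg.svd(centered, full_matrices=False)
        weights = vt[0]
    elif mode == "random":
        mean_map = np.abs(maps).mean(axis=0)
        n_support = max(int(support_frac * maps.shape[1]), 5)
        support = np.argsort(mean_map)[-n_support:]
        weights = np.zeros(maps.shape[1])
        weights[support] = rng.standard_normal(n_support)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    signal_part = maps @ weights
    noise = rng.standard_normal(maps.shape[0])
    noise *= signal_part.std() / (snr * noise.std())
    return signal_part + noise, weights


# ---------------------------------------------------------------------------
# assembly

def _sample_covariates(group: str, rng) -> dict:
    return {
        "age": float(rng.uniform(8.0, 30.0)),
        "sex": int(rng.integers(0, 2)),
        "handedness": float(rng.normal(50.0, 20.0)),
        "score": float(rng.normal(10.0, 3.0) + (2.0 if group == ASD else 0.0)),
    }


def assemble_dataset(config: SimConfig):
    """Generate the full cohort: for each subject,
    data (V x T) = subject_maps.T @ tcs.T + N(0, noise_sigma).

    Returns (GroupDataset, GroundTruth). Identical configs (including seed)
    produce identical datasets.
    """
    rng = np.random.default_rng(config.seed)
    base_maps, centers, sigma = make_base_maps(config)
    subject_maps, labels = sample_subject_maps(base_maps, centers, sigma, config, rng)

    subjects, tcs_list = [], []
    for i, (maps, label) in enumerate(zip(subject_maps, labels)):
        tcs = sample_timecourses(config, label, rng)
        data = maps.T @ tcs.T
        if config.noise_sigma > 0:
            data = data + rng.normal(0.0, config.noise_sigma, size=data.shape)
        subjects.append(SubjectScan(
            subject_id=f"sub-{i:03d}",
            group=label,
            data=data,
            tr_seconds=config.tr_seconds,
            covariates=_sample_covariates(label, rng),
        ))
        tcs_list.append(tcs)

    mask = np.ones(config.grid_shape, dtype=bool)
    dataset = GroupDataset(subjects=subjects, mask=mask, tr_seconds=config.tr_seconds)
    truth = GroundTruth(
        base_maps=base_maps,
        subject_maps=subject_maps,
        subject_tcs=tcs_list,
        group_labels=labels,
        blob_centers=centers,
        config=config,
    )
    return dataset, truth
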