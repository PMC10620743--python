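"""Component screening by spectral quality and cross-method pairing.

Noise components are screened out by the fractional amplitude of
low-frequency fluctuations (fALFF) of their time courses — resting-state
networks concentrate spectral power below ~0.1 Hz while noise components
do not — and components of the two decompositions are paired by the
greedy rule on the spatial-correlation matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal

logger = logging.getLogger(__name__)


@dataclass
class SpectralMetrics:
    component_id: int
    falff: float
    dynamic_range: float


@dataclass
class ComponentPairing:
    """Matched component index pairs (idx_a, idx_b, signed r) between two
    map stacks; in one-to-one mode each index appears at most once per
    side."""

    pairs: list  # list of (idx_a, idx_b, r)
    mode: str  # "one-to-one" | "one-to-many"
    threshold: float

    @property
    def indices_a(self):
        return [p[0] for p in self.pairs]

    @property
    def indices_b(self):
        return [p[1] for p in self.pairs]

    @property
    def correlations(self):
        return [p[2] for p in self.pairs]


def _amplitude_spectrum(tc: np.ndarray, tr_seconds: float):
    tc = np.asarray(tc, dtype=float)
    if tc.ndim != 1 or tc.size < 16:
        raise ValueError("time course must be 1-D with T >= 16")
    if np.all(tc == tc[0]):
        raise ValueError("constant (all-equal) time course")
    demeaned = tc - tc.mean()
    # Hann taper controls spectral leakage of non-bin-aligned oscillations
    amp = np.abs(np.fft.rfft(demeaned * np.hanning(tc.size)))
    freqs = np.fft.rfftfreq(tc.size, d=tr_seconds)
    return freqs, amp


def compute_falff(tc: np.ndarray, tr_seconds: float,
                  low_band=(0.01, 0.08)) -> float:
    """Fraction of the amplitude spectrum (DFT of the demeaned time course)
    falling in ``low_band``, relative to the whole 0-Nyquist range."""
    freqs, amp = _amplitude_spectrum(tc, tr_seconds)
    total = amp.sum()
    if total == 0:
        raise ValueError("zero spectrum")
    in_band = (freqs >= low_band[0]) & (freqs <= low_band[1])
    return float(amp[in_band].sum() / total)


def compute_dynamic_range(tc: np.ndarray, tr_seconds: float) -> float:
    """Spectral dynamic range: difference (log10 scale) between the power
    spectrum's peak and the minimum power at frequencies above the peak.

    The spectrum is a Welch estimate so that broadband (noise) components
    yield a flat spectrum and a value near zero, while genuinely
    oscillatory components yield a large drop after the peak.
    """
    tc = np.asarray(tc, dtype=float)
    if tc.ndim != 1 or tc.size < 16:
        raise ValueError("time course must be 1-D with T >= 16")
    if np.all(tc == tc[0]):
        raise ValueError("constant (all-equal) time course")
    nperseg = min(tc.size, max(32, tc.size // 4))
    freqs, power = signal.welch(tc - tc.mean(), fs=1.0 / tr_seconds,
                                nperseg=nperseg)
    power = power[1:]  # drop DC
    peak = int(np.argmax(power))
    tail = power[peak:]
    floor = max(tail.min(), np.finfo(float).tiny)
    return float(np.log10(power[peak]) - np.log10(floor))


def spectral_metrics(timecourses: np.ndarray, tr_seconds: float) -> list:
    """SpectralMetrics for each column of a T x k time-course matrix."""
    return [
        SpectralMetrics(
            component_id=i,
            falff=compute_falff(timecourses[:, i], tr_seconds),
            dynamic_range=compute_dynamic_range(timecourses[:, i], tr_seconds),
        )
        for i in range(timecourses.shape[1])
    ]


def select_components(metrics: list, falff_min: float = 0.5) -> list:
    """Indices of components with fALFF strictly greater than ``falff_min``,
    in input order."""
    kept = [m.component_id for m in metrics if m.falff > falff_min]
    if not kept:
        logger.warning("no components passed the fALFF > %.2f screen", falff_min)
    return kept


def group_tmap(subject_maps: np.ndarray) -> np.ndarray:
    """Voxelwise one-sample t statistic across subjects (N x V), z-scored
    over voxels. Voxels with zero across-subject variance get t = 0 with a
    warning."""
    maps = np.asarray(subject_maps, dtype=float)
    if maps.ndim != 2 or maps.shape[0] < 2:
        raise ValueError("need an N x V stack with N >= 2")
    n = maps.shape[0]
    mean = maps.mean(axis=0)
    sd = maps.std(axis=0, ddof=1)
    t = np.zeros_like(mean)
    ok = sd > 0
    if not ok.all():
        logger.warning("%d voxels with zero across-subject variance; t set to 0",
                       int((~ok).sum()))
    t[ok] = mean[ok] / (sd[ok] / np.sqrt(n))
    if t.std() == 0:
        raise ValueError("degenerate t-map (constant over voxels)")
    return (t - t.mean()) / t.std()


def spatial_correlation_matrix(maps_a: np.ndarray, maps_b: np.ndarray) -> np.ndarray:
    """Pearson correlation over voxels between every pair of rows."""
    a = np.asarray(maps_a, dtype=float)
    b = np.asarray(maps_b, dtype=float)
    if a.shape[1] != b.shape[1]:
        raise ValueError("map stacks must share the voxel dimension")
    az = (a - a.mean(axis=1, keepdims=True)) / a.std(axis=1, keepdims=True)
    bz = (b - b.mean(axis=1, keepdims=True)) / b.std(axis=1, keepdims=True)
    return az @ bz.T / a.shape[1]


def greedy_pair(maps_a: np.ndarray, maps_b: np.ndarray,
                threshold: float = 0.5, mode: str = "one-to-one") -> ComponentPairing:
    """Pair rows of ``maps_a`` with rows of ``maps_b`` by the greedy rule.

    one-to-one: repeatedly take the globally largest remaining |r| cell of
    the spatial-correlation matrix, record the pair, and delete its row
    and column; stop when the largest remaining |r| <= threshold. Ties
    break to the lowest (row, column) index. one-to-many: each row of
    ``maps_a`` keeps its best column of ``maps_b`` if |r| > threshold.
    Signed correlations are reported; ordering uses |r|.
    """
    maps_a = np.atleast_2d(np.asarray(maps_a, dtype=float))
    maps_b = np.atleast_2d(np.asarray(maps_b, dtype=float))
    if maps_a.size == 0 or maps_b.size == 0:
        return ComponentPairing(pairs=[], mode=mode, threshold=threshold)
    corr = spatial_correlation_matrix(maps_a, maps_b)
    pairs = []
    if mode == "one-to-one":
        work = np.abs(corr).copy()
        while work.size and not np.all(np.isnan(work)):
            if np.nanmax(work) <= threshold:
                break
            flat = np.nanargmax(work)  # first occurrence = lowest (row, col)
            i, j = np.unravel_index(flat, work.shape)
            pairs.append((int(i), int(j), float(corr[i, j])))
            work[i, :] = np.nan
            work[:, j] = np.nan
    elif mode == "one-to-many":
        for i in range(corr.shape[0]):
            j = int(np.argmax(np.abs(corr[i])))
            if abs(corr[i, j]) > threshold:
                pairs.append((i, j, float(corr[i, j])))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    pairs.sort(key=lambda p: (p[0], p[1]))
    return ComponentPairing(pairs=pairs, mode=mode, threshold=threshold)


def pair_to_truth(decomposition, base_maps: np.ndarray,
                  threshold: float = 0.5) -> ComponentPairing:
    """Pair estimated components to ground-truth base maps using the group
    t-map of each component's subject-map stack (one-to-one greedy)."""
    from .decomposition import zscore_maps

    stacked = decomposition.stacked_maps()  # N x k x V
    tmaps = np.array([group_tmap(stacked[:, c, :]) for c in range(stacked.shape[1])])
    return greedy_pair(tmaps, zscore_maps(np.asarray(base_maps, dtype=float)),
                       threshold=threshold)
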