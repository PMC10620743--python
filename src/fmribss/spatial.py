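"""Voxelwise spatial statistics: group mean differences, peak histograms,
variance maps, and the nonparametric variance-difference test.

Group mean differences use a voxelwise two-sample t-test with
Benjamini-Hochberg FDR and 6-connected cluster reporting (both
uncorrected and corrected voxel counts, as in cluster tables). The
intersubject-variability comparison uses across-subject variance maps of
z-scored subject maps: the per-voxel unbiased variance per group, their
difference (HC - ASD), and a paired Wilcoxon signed-rank test across
voxels for a group difference in variance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats

from .network import bh_fdr

logger = logging.getLogger(__name__)


@dataclass
class Cluster:
    voxel_indices: np.ndarray  # indices into the in-mask voxel vector
    size: int
    peak_voxel: int
    peak_t: float


@dataclass
class VoxelStatMap:
    t: np.ndarray
    p: np.ndarray
    q_fdr: np.ndarray
    clusters_uncorrected: list = field(default_factory=list)
    clusters_corrected: list = field(default_factory=list)

    @property
    def n_voxels_uncorrected(self) -> int:
        return int(sum(c.size for c in self.clusters_uncorrected))

    @property
    def n_voxels_corrected(self) -> int:
        return int(sum(c.size for c in self.clusters_corrected))


def _extract_clusters(suprathreshold: np.ndarray, t: np.ndarray,
                      mask: np.ndarray, min_size: int) -> list:
    """Maximal 6-connected clusters of suprathreshold in-mask voxels.

    ``suprathreshold`` and ``t`` are vectors over in-mask voxels;
    ``mask`` is the 3D boolean grid defining the voxel ordering
    (row-major). Without a mask the voxel vector is treated as a line.
    """
    if mask is None:
        volume = suprathreshold[None, None, :]
        tvol = np.zeros_like(volume, dtype=float)
        tvol[0, 0, :] = t
        index_map = np.arange(t.size)[None, None, :]
    else:
        volume = np.zeros(mask.shape, dtype=bool)
        volume[mask] = suprathreshold
        tvol = np.zeros(mask.shape)
        tvol[mask] = t
        index_map = np.full(mask.shape, -1, dtype=int)
        index_map[mask] = np.arange(int(mask.sum()))
    structure = ndimage.generate_binary_structure(3, 1)  # 6-connectivity
    labeled, n_found = ndimage.label(volume, structure=structure)
    clusters = []
    for lab in range(1, n_found + 1):
        where = labeled == lab
        size = int(where.sum())
        if size < min_size:
            continue
        idx = index_map[where]
        tvals = tvol[where]
        peak_local = int(np.argmax(np.abs(tvals)))
        clusters.append(Cluster(
            voxel_indices=np.sort(idx),
            size=size,
            peak_voxel=int(idx[peak_local]),
            peak_t=float(tvals[peak_local]),
        ))
    clusters.sort(key=lambda c: -c.size)
    return clusters


def voxel_group_ttest(maps_a: np.ndarray, maps_b: np.ndarray,
                      alpha: float = 0.05, mask: np.ndarray = None,
                      min_cluster_size: int = 10) -> VoxelStatMap:
    """Voxelwise two-sample t-test between groups (N_a x V vs N_b x V)
    with BH-FDR over in-mask voxels and 6-connected cluster extraction at
    both the uncorrected p < alpha and the FDR-corrected thresholds.

    Voxels with degenerate (zero pooled) variance are excluded from the
    FDR and clusters, with a warning.
    """
    a = np.atleast_2d(np.asarray(maps_a, dtype=float))
    b = np.atleast_2d(np.asarray(maps_b, dtype=float))
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("need at least two subjects per group")
    if a.shape[1] != b.shape[1]:
        raise ValueError("groups must share the voxel dimension")
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = stats.ttest_ind(a, b, axis=0, equal_var=True)
    degenerate = ~np.isfinite(t)
    if degenerate.any():
        logger.warning("%d degenerate-variance voxels excluded",
                       int(degenerate.sum()))
        t = np.where(degenerate, 0.0, t)
        p = np.where(degenerate, 1.0, p)
    q = np.ones_like(p)
    valid = ~degenerate
    if valid.any():
        q[valid], _ = bh_fdr(p[valid], q_level=alpha)
    unc_mask = (p < alpha) & valid
    cor_mask = (q < alpha) & valid
    return VoxelStatMap(
        t=t, p=p, q_fdr=q,
        clusters_uncorrected=_extract_clusters(unc_mask, t, mask, min_cluster_size),
        clusters_corrected=_extract_clusters(cor_mask, t, mask, min_cluster_size),
    )


def peak_histogram(maps_a: np.ndarray, maps_b: np.ndarray, voxel: int,
                   n_bins: int = 10):
    """Per-group histograms of subject amplitudes at one voxel, with
    shared bin edges. Returns (counts_a, counts_b, edges)."""
    va = np.asarray(maps_a, dtype=float)[:, voxel]
    vb = np.asarray(maps_b, dtype=float)[:, voxel]
    lo = min(va.min(), vb.min())
    hi = max(va.max(), vb.max())
    if lo == hi:
        lo, hi = lo - 0.5, hi + 0.5
    edges = np.linspace(lo, hi, n_bins + 1)
    counts_a, _ = np.histogram(va, bins=edges)
    counts_b, _ = np.histogram(vb, bins=edges)
    return counts_a, counts_b, edges


@dataclass
class VarianceMap:
    var_hc: np.ndarray
    var_asd: np.ndarray
    difference: np.ndarray  # HC - ASD


def variance_maps(maps_hc: np.ndarray, maps_asd: np.ndarray) -> VarianceMap:
    """Across-subject unbiased (n-1) voxelwise variance per group and the
    HC - ASD difference map."""
    hc = np.atleast_2d(np.asarray(maps_hc, dtype=float))
    asd = np.atleast_2d(np.asarray(maps_asd, dtype=float))
    if hc.shape[0] < 2 or asd.shape[0] < 2:
        raise ValueError("need at least two subjects per group")
    var_hc = hc.var(axis=0, ddof=1)
    var_asd = asd.var(axis=0, ddof=1)
    return VarianceMap(var_hc=var_hc, var_asd=var_asd,
                       difference=var_hc - var_asd)


def variance_difference_test(var_hc: np.ndarray, var_asd: np.ndarray) -> float:
    """Two-sided Wilcoxon signed-rank test across in-mask voxels pairing
    the two groups' variance values; voxel distributions of variance are
    non-normal, hence the nonparametric choice. Returns the p-value
    (1.0 when all differences are zero)."""
    hc = np.asarray(var_hc, dtype=float)
    asd = np.asarray(var_asd, dtype=float)
    if hc.shape != asd.shape:
        raise ValueError("variance maps must share the mask")
    diffs = hc - asd
    if np.all(diffs == 0):
        return 1.0
    res = stats.wilcoxon(hc, asd, zero_method="wilcox")
    return float(res.pvalue)


def tmap_mask(group_tmap: np.ndarray, z_threshold: float = 1.96) -> np.ndarray:
    """Boolean in-mask vector of voxels with |z| above threshold in a
    z-scored group t-map; the per-network analysis mask."""
    return np.abs(np.asarray(group_tmap, dtype=float)) > z_threshold
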