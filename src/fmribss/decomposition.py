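"""Multi-subject blind source separation: group ICA, GIG-ICA and IVA-GL.

All decompositions use the spatial orientation: components are images
(k x V spatial maps), voxels are samples, and the temporal dimension is
reduced by PCA. Three estimators are provided:

* ``group_ica`` — subject-level PCA, temporal concatenation, group-level
  PCA, Infomax ICA, and least-squares back-reconstruction of subject maps
  and time courses (the reference baseline).
* ``gig_ica`` — group-information-guided ICA: per subject, each component
  maximizes a weighted sum of a negentropy surrogate and the correlation
  with its group-level reference map, one component at a time.
* ``iva_gl`` — independent vector analysis, a joint decomposition across
  subjects minimizing sum_k H(SCV_k) - sum_s log|det W_s| where the k-th
  source component vector (SCV) collects component k across subjects;
  a multivariate Gaussian stage (IVA-G, second-order dependence) is
  followed by a multivariate Laplace refinement (IVA-L, higher-order).

Sign convention everywhere: each map's largest-magnitude voxel is made
positive. Estimated maps are z-scored (mean 0, std 1 over voxels).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .types import GroupDataset

logger = logging.getLogger(__name__)

#: E[log cosh(nu)] for standard normal nu (negentropy surrogate baseline)
GAUSS_LOGCOSH = 0.3745672249144408  # 2/sqrt(2*pi) * integral, precomputed


class ConvergenceError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# PCA whitening

@dataclass
class WhiteningResult:
    """Top-k principal subspace of a (variables x samples) matrix with the
    whitening transform and its pseudo-inverse."""

    reduced: np.ndarray  # k x n_samples, identity covariance
    projection: np.ndarray  # k x n_variables
    back_projection: np.ndarray  # n_variables x k
    explained_variance: np.ndarray  # per-component fractions of total
    mean: np.ndarray  # per-variable mean removed before projection


def pca_whiten(data: np.ndarray, k: int) -> WhiteningResult:
    """Whiten ``data`` (variables x samples) to its top-k principal
    subspace: rows of the result are uncorrelated with unit variance.

    Raises ValueError if ``k`` exceeds the numerical rank.
    """
    data = np.asarray(data, dtype=float)
    m, n = data.shape
    if k < 1 or k > min(m, n):
        raise ValueError(f"k={k} out of range for {m}x{n} data")
    mean = data.mean(axis=1, keepdims=True)
    centered = data - mean
    u, s, _ = np.linalg.svd(centered, full_matrices=False)
    tol = s.max() * max(m, n) * np.finfo(float).eps
    rank = int((s > tol).sum())
    if k > rank:
        raise ValueError(f"k={k} exceeds numerical rank {rank}")
    var = s ** 2 / (n - 1)
    scale = np.sqrt(var[:k])
    projection = (u[:, :k] / scale).T  # k x m
    back_projection = u[:, :k] * scale  # m x k
    reduced = projection @ centered
    return WhiteningResult(
        reduced=reduced,
        projection=projection,
        back_projection=back_projection,
        explained_variance=var[:k] / var.sum(),
        mean=mean.ravel(),
    )


# ---------------------------------------------------------------------------
# map utilities

def fix_sign(maps: np.ndarray) -> np.ndarray:
    """Flip each row so its largest-|value| entry is positive."""
    maps = np.array(maps, dtype=float)
    for row in maps:
        peak = row[np.argmax(np.abs(row))]
        if peak < 0:
            row *= -1.0
    return maps


def zscore_maps(maps: np.ndarray) -> np.ndarray:
    """Z-score each map (row) to mean 0, std 1 over voxels.

    Raises ValueError for a constant (degenerate) map.
    """
    maps = np.asarray(maps, dtype=float)
    std = maps.std(axis=-1, keepdims=True)
    if np.any(std == 0):
        bad = int(np.argmax(std.ravel() == 0))
        raise ValueError(f"component {bad} is constant; cannot z-score")
    return (maps - maps.mean(axis=-1, keepdims=True)) / std


# ---------------------------------------------------------------------------
# Infomax ICA

def infomax_ica(whitened: np.ndarray, seed: int = 0, lr: float = 0.005,
                tol: float = 1e-6, max_iter: int = 1024):
    """Infomax ICA on whitened data (k x M) with the logistic nonlinearity
    and natural-gradient ascent.

    The learning rate anneals down when successive updates oscillate
    (negative cosine) and creeps up on steady progress. Convergence is
    declared when the largest element of the weight update falls below
    ``tol``; non-convergence raises ConvergenceError carrying the final
    gradient norm. Output rows follow the positive-peak sign convention.

    Returns (sources k x M, unmixing k x k).
    """
    z = np.asarray(whitened, dtype=float)
    k, m = z.shape
    if m <= k:
        raise ValueError("need more samples than components")
    rng = np.random.default_rng(seed)
    # random orthogonal init keeps early iterations stable
    w, _ = np.linalg.qr(rng.standard_normal((k, k)))
    eye = np.eye(k)
    prev_update = None
    grad_norm = np.inf
    rate = lr
    for _ in range(max_iter):
        u = w @ z
        y = 1.0 / (1.0 + np.exp(-u))
        grad = eye + (1.0 - 2.0 * y) @ u.T / m
        update = rate * grad @ w
        w = w + update
        grad_norm = float(np.max(np.abs(grad)))
        if prev_update is not None:
            denom = np.linalg.norm(update) * np.linalg.norm(prev_update)
            cosine = float(np.sum(update * prev_update) / denom) if denom else 0.0
            if cosine < -0.2:
                rate *= 0.6
            elif cosine > 0.8:
                rate = min(rate * 1.2, 0.5)
        prev_update = update
        if np.max(np.abs(update)) < tol:
            break
    else:
        raise ConvergenceError(
            f"Infomax did not converge in {max_iter} iterations "
            f"(final gradient norm {grad_norm:.3e})"
        )
    sources = fix_sign(w @ z)
    # re-derive w consistent with the sign fix
    signs = np.sign(np.sum(sources * (w @ z), axis=1))
    w = w * signs[:, None]
    return sources, w


# ---------------------------------------------------------------------------
# Decomposition container

@dataclass
class Decomposition:
    """Per-subject spatial maps (k x V, z-scored) and time courses (T x k)
    for one estimation method at model order k."""

    method: str  # "group-ICA" | "GIG-ICA" | "IVA-GL"
    model_order: int
    spatial_maps: list  # per subject k x V
    timecourses: list  # per subject T x k
    group_maps: np.ndarray = None  # k x V (group-ICA / GIG-ICA reference)
    info: dict = field(default_factory=dict)

    def __post_init__(self):
        shapes = {m.shape for m in self.spatial_maps}
        if len(shapes) > 1:
            raise ValueError("inconsistent spatial map shapes across subjects")

    def stacked_maps(self) -> np.ndarray:
        """N x k x V array of subject maps."""
        return np.array(self.spatial_maps)


def _backproject_subject(data: np.ndarray, maps: np.ndarray):
    """Least-squares time courses and refined maps for one subject given
    spatial maps: data (V x T) ~ maps.T @ tcs.T (dual regression)."""
    tcs, *_ = np.linalg.lstsq(maps.T, data, rcond=None)  # k x T
    tcs = tcs.T  # T x k
    sub_maps, *_ = np.linalg.lstsq(tcs, data.T, rcond=None)  # k x V
    return sub_maps, tcs


def group_ica(dataset: GroupDataset, k: int, seed: int = 0,
              subject_pca_factor: float = 1.5) -> Decomposition:
    """Temporal-concatenation group ICA with Infomax and least-squares
    back-reconstruction (the baseline the guided methods improve on).

    Subject-level PCA keeps ceil(subject_pca_factor * k) components
    (capped by the data's dimensions); group-level PCA reduces the
    concatenation to k before Infomax.
    """
    k1 = int(np.ceil(subject_pca_factor * k))
    reduced_stack = []
    for scan in dataset.subjects:
        x = scan.data.T  # T x V
        k1_s = min(k1, np.linalg.matrix_rank(x))  # noiseless data: rank < 1.5k
        if k1_s < k:
            raise ValueError(
                f"subject {scan.subject_id}: rank {k1_s} below model order {k}"
            )
        reduced_stack.append(pca_whiten(x, k1_s).reduced)
    concat = np.vstack(reduced_stack)  # (N*k1) x V
    group_white = pca_whiten(concat, k)
    sources, unmix = infomax_ica(group_white.reduced, seed=seed)
    group_maps = zscore_maps(fix_sign(sources))

    spatial_maps, timecourses = [], []
    for scan in dataset.subjects:
        sub_maps, tcs = _backproject_subject(scan.data, group_maps)
        spatial_maps.append(zscore_maps(fix_sign(sub_maps)))
        timecourses.append(tcs)
    return Decomposition(
        method="group-ICA", model_order=k,
        spatial_maps=spatial_maps, timecourses=timecourses,
        group_maps=group_maps, info={"seed": seed},
    )


# ---------------------------------------------------------------------------
# GIG-ICA

def _gig_objective_grad(w, z, ref_z, lam):
    """Objective J(w) = lam * (E[G(y)] - E[G(nu)])^2 + (1-lam) * corr(y, ref)
    with y = w^T z, G = log cosh, and its gradient in w."""
    v = z.shape[1]
    y = w @ z
    gy = np.log(np.cosh(y))
    neg_dev = gy.mean() - GAUSS_LOGCOSH
    j_neg = neg_dev ** 2
    grad_neg = 2.0 * neg_dev * (z @ np.tanh(y)) / v

    sy = float(np.sqrt(y @ y / v))
    cross = float(y @ ref_z / v)
    corr = cross / sy  # ref_z has unit variance, y zero mean
    grad_corr = (z @ ref_z) / (v * sy) - corr * (z @ y) / (v * sy ** 2)

    obj = lam * j_neg + (1.0 - lam) * corr
    grad = lam * grad_neg + (1.0 - lam) * grad_corr
    return obj, grad, corr


def _maximize_component(z, ref_z, lam, tol=1e-6, max_iter=512):
    """Gradient ascent on the unit sphere, initialized at the reference's
    projection onto the whitened subspace."""
    v = z.shape[1]
    w = z @ ref_z / v
    norm = np.linalg.norm(w)
    if norm == 0:
        raise ValueError("reference orthogonal to the whitened subspace")
    w = w / norm
    step = 1.0
    obj, grad, corr = _gig_objective_grad(w, z, ref_z, lam)
    for _ in range(max_iter):
        moved = False
        for _ in range(30):
            w_new = w + step * grad
            w_new = w_new / np.linalg.norm(w_new)
            obj_new, grad_new, corr_new = _gig_objective_grad(w_new, z, ref_z, lam)
            if obj_new > obj:
                moved = True
                break
            step *= 0.5
        if not moved:
            break
        delta = np.max(np.abs(w_new - w))
        w, obj, grad, corr = w_new, obj_new, grad_new, corr_new
        step = min(step * 1.3, 10.0)
        if delta < tol:
            break
    return w, corr


def gig_ica(dataset: GroupDataset, group_maps: np.ndarray,
            lambda_weight: float = 0.5, seed: int = 0) -> Decomposition:
    """Group-information-guided ICA: subject-specific components estimated
    one at a time by maximizing
    J(w) = lambda * Jneg(y) + (1 - lambda) * corr(y, reference)
    over unit vectors w in each subject's whitened (spatial) subspace,
    where Jneg is the (E[G(y)] - E[G(nu)])^2 negentropy surrogate with
    G = log cosh.

    References are processed in index order, each initialized at its
    projection; a component whose final reference correlation drops below
    0.2 logs a "reference lost" warning. Subject time courses come from a
    least-squares fit of the final maps.
    """
    refs = zscore_maps(np.asarray(group_maps, dtype=float))
    k = refs.shape[0]
    spatial_maps, timecourses = [], []
    for scan in dataset.subjects:
        white = pca_whiten(scan.data.T, min(k, scan.data.shape[1] - 1))
        z = white.reduced  # k x V, rows uncorrelated unit variance
        sub_rows = []
        for idx in range(k):
            w, corr = _maximize_component(z, refs[idx], lambda_weight)
            if abs(corr) < 0.2:
                logger.warning(
                    "subject %s component %d: reference lost (corr=%.3f)",
                    scan.subject_id, idx, corr,
                )
            y = w @ z
            if corr < 0:
                y = -y
            sub_rows.append(y)
        maps = zscore_maps(fix_sign(np.array(sub_rows)))
        _, tcs = _backproject_subject(scan.data, maps)
        spatial_maps.append(maps)
        timecourses.append(tcs)
    return Decomposition(
        method="GIG-ICA", model_order=k,
        spatial_maps=spatial_maps, timecourses=timecourses,
        group_maps=refs, info={"seed": seed, "lambda": lambda_weight},
    )


# ---------------------------------------------------------------------------
# IVA-GL

def _iva_cost_and_scores(y_stack, prior):
    """Cost contribution of the SCV entropies and the score functions.

    y_stack: N x k x V. Returns (sum of per-SCV entropy terms,
    scores N x k x V such that the relative gradient for subject s is
    (I - scores_s @ y_s.T / V) @ W_s).
    """
    n_subj, k, v = y_stack.shape
    scores = np.empty_like(y_stack)
    cost = 0.0
    eps = 1e-12
    for comp in range(k):
        c = y_stack[:, comp, :]  # N x V, the SCV realizations
        if prior == "gauss":
            sigma = c @ c.T / v + eps * np.eye(n_subj)
            sign, logdet = np.linalg.slogdet(sigma)
            cost += 0.5 * logdet
            scores[:, comp, :] = np.linalg.solve(sigma, c)
        else:  # multivariate Laplace
            r = np.sqrt(np.sum(c ** 2, axis=0) + eps)
            cost += float(np.mean(r))
            scores[:, comp, :] = c / r
    return cost, scores


def _iva_phase(z_list, w_list, prior, lr, tol, max_iter):
    """One IVA optimization phase (Gaussian or Laplace SCV prior) by
    relative-gradient descent with step-halving on cost increase."""
    n_subj = len(z_list)
    k = w_list[0].shape[0]
    v = z_list[0].shape[1]
    eye = np.eye(k)

    def full_cost(ws):
        y = np.stack([w @ z for w, z in zip(ws, z_list)])
        c, scores = _iva_cost_and_scores(y, prior)
        for w in ws:
            _, logdet = np.linalg.slogdet(w)  # log|det W|, sign-free
            c -= logdet
        return c, y, scores

    cost, y, scores = full_cost(w_list)
    rate = lr
    n_halvings = 0
    for iteration in range(max_iter):
        new_ws = []
        max_rel = 0.0
        for s in range(n_subj):
            grad = eye - scores[s] @ y[s].T / v
            update = rate * grad @ w_list[s]
            max_rel = max(max_rel, float(np.linalg.norm(update) /
                                         np.linalg.norm(w_list[s])))
            new_ws.append(w_list[s] + update)
        new_cost, new_y, new_scores = full_cost(new_ws)
        if new_cost > cost + 1e-12:
            rate *= 0.5
            n_halvings += 1
            if rate < 1e-10:
                raise ConvergenceError(
                    f"IVA ({prior}) cost kept increasing after "
                    f"{n_halvings} step halvings at iteration {iteration}"
                )
            continue
        improvement = cost - new_cost
        w_list, cost, y, scores = new_ws, new_cost, new_y, new_scores
        rate = min(rate * 1.05, 1.0)
        if max_rel < tol or improvement < tol * max(1.0, abs(cost)):
            break
    return w_list, cost


def iva_gl(dataset: GroupDataset, k: int, seed: int = 0, lr: float = 0.1,
           tol: float = 1e-6, max_iter: int = 1024) -> Decomposition:
    """IVA-GL: joint decomposition across subjects, Gaussian SCV prior to
    convergence then a unit-variance multivariate-Laplace refinement
    initialized from the Gaussian solution.

    Each subject is whitened to k components internally (spatial
    orientation); one unmixing matrix per subject is estimated jointly so
    component order is aligned across subjects by construction.
    """
    whites = [pca_whiten(scan.data.T, k) for scan in dataset.subjects]
    z_list = [w.reduced for w in whites]
    rng = np.random.default_rng(seed)
    w0, _ = np.linalg.qr(rng.standard_normal((k, k)))
    w_list = [w0.copy() for _ in z_list]

    w_list, cost_g = _iva_phase(z_list, w_list, "gauss", lr, tol, max_iter)
    w_list, cost_l = _iva_phase(z_list, w_list, "laplace", lr, tol, max_iter)

    spatial_maps, timecourses, unmixings = [], [], []
    for scan, white, w in zip(dataset.subjects, whites, w_list):
        y = w @ white.reduced  # k x V
        maps = zscore_maps(fix_sign(y))
        _, tcs = _backproject_subject(scan.data, maps)
        spatial_maps.append(maps)
        timecourses.append(tcs)
        unmixings.append(w @ white.projection)  # k x T total unmixing
    return Decomposition(
        method="IVA-GL", model_order=k,
        spatial_maps=spatial_maps, timecourses=timecourses,
        info={"seed": seed, "cost_gauss": cost_g, "cost_laplace": cost_l,
              "unmixings": unmixings},
    )


# ---------------------------------------------------------------------------
# evaluation

def amari_isi(g: np.ndarray) -> float:
    """Normalized Amari inter-symbol interference of a global k x k matrix;
    0 for a scaled permutation, 1 for maximal interference."""
    a = np.abs(np.asarray(g, dtype=float))
    k = a.shape[0]
    if a.shape != (k, k):
        raise ValueError("global matrix must be square")
    row_max = a.max(axis=1)
    col_max = a.max(axis=0)
    if np.any(row_max == 0) or np.any(col_max == 0):
        raise ValueError("singular global matrix")
    rows = (a / row_max[:, None]).sum(axis=1) - 1.0
    cols = (a / col_max[None, :]).sum(axis=0) - 1.0
    return float((rows.sum() + cols.sum()) / (2.0 * k * (k - 1)))


def joint_isi(estimated_mixings, true_mixings) -> float:
    """Joint Amari index across subjects: the global matrices
    G_s = pinv(estimated_s) @ true_s are averaged in absolute value and the
    Amari ISI of the average is returned. 0 = perfect joint separation
    (component permutations shared across subjects are not penalized)."""
    gs = []
    for est, true in zip(estimated_mixings, true_mixings):
        est = np.asarray(est, dtype=float)
        true = np.asarray(true, dtype=float)
        if est.shape != true.shape:
            raise ValueError("estimated/true mixing shapes differ")
        g = np.linalg.pinv(est) @ true
        gs.append(np.abs(g))
    return amari_isi(np.mean(gs, axis=0))
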