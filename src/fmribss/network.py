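"""Functional network connectivity (FNC) and its group statistics.

Per-subject FNC is the Pearson correlation matrix of paired components'
time courses (Fisher r-to-z transformed for statistics). Community
structure is quantified by signed Louvain modularity (Girvan-Newman Q
with the asymmetric positive/negative weighting appropriate for
correlation networks), group differences by permutation tests and
edge-wise t-tests with Benjamini-Hochberg FDR, and brain-behavior
association by a "boosted" statistic PC + sign(PC) * NMI and by
Shepherd's pi (Spearman correlation after removing bivariate outliers
flagged by bootstrapped Mahalanobis distance).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# FNC construction

@dataclass
class FNCMatrix:
    subject_id: str
    values: np.ndarray  # k x k symmetric, zero diagonal
    scale: str  # "r" | "fisher-z"


def compute_fnc(timecourses: np.ndarray, subject_id: str = "") -> FNCMatrix:
    """Pairwise Pearson correlation between time-course columns (T x k),
    with a zeroed diagonal. A constant column is an error."""
    tcs = np.asarray(timecourses, dtype=float)
    if tcs.ndim != 2 or tcs.shape[0] < 3:
        raise ValueError("need a T x k matrix with T >= 3")
    stds = tcs.std(axis=0)
    if np.any(stds == 0):
        raise ValueError(f"component {int(np.argmax(stds == 0))} has a "
                         "constant time course")
    r = np.corrcoef(tcs, rowvar=False)
    np.fill_diagonal(r, 0.0)
    return FNCMatrix(subject_id=subject_id, values=r, scale="r")


def fisher_z(r):
    """Fisher r-to-z: arctanh(r). Requires |r| < 1; odd in r."""
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) >= 1):
        raise ValueError("|r| must be < 1 for the Fisher transform")
    out = np.arctanh(r)
    return float(out) if out.ndim == 0 else out


def fisher_z_fnc(fnc: FNCMatrix) -> FNCMatrix:
    """Fisher-transform the off-diagonal entries of an r-scale FNC."""
    if fnc.scale != "r":
        raise ValueError("FNC already on fisher-z scale")
    z = np.arctanh(np.clip(fnc.values, -0.999999, 0.999999))
    np.fill_diagonal(z, 0.0)
    return FNCMatrix(subject_id=fnc.subject_id, values=z, scale="fisher-z")


def mean_fnc(fncs: list) -> np.ndarray:
    """Group-mean FNC: average on the Fisher-z scale, then inverse
    transform back to r for display (variance stabilization)."""
    zs = [fisher_z_fnc(f).values if f.scale == "r" else f.values for f in fncs]
    mean_z = np.mean(zs, axis=0)
    out = np.tanh(mean_z)
    np.fill_diagonal(out, 0.0)
    return out


def residualize_covariates(values: np.ndarray, covariates: np.ndarray) -> np.ndarray:
    """Residuals of a least-squares fit of ``values`` (N,) or (N, p) on an
    intercept plus ``covariates`` (N x c). Rank-deficient covariates are an
    error; residuals are orthogonal to the covariates."""
    y = np.asarray(values, dtype=float)
    cov = np.atleast_2d(np.asarray(covariates, dtype=float))
    if cov.shape[0] != y.shape[0]:
        cov = cov.T
    n, c = cov.shape
    if n <= c + 1:
        raise ValueError("need more observations than covariates")
    design = np.column_stack([np.ones(n), cov])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("rank-deficient covariate matrix")
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    return y - design @ beta


# ---------------------------------------------------------------------------
# signed modularity and Louvain

def _split_signs(w):
    wp = np.where(w > 0, w, 0.0)
    wn = np.where(w < 0, -w, 0.0)
    return wp, wn


def modularity_signed(w: np.ndarray, labels, gamma: float = 1.0) -> float:
    """Girvan-Newman modularity Q of a partition of a signed weighted
    network, with the asymmetric positive/negative weighting
    Q = Q+ - (v-/(v+ + v-)) Q-; reduces to standard Newman Q for
    all-positive weights."""
    w = np.asarray(w, dtype=float)
    labels = np.asarray(labels)
    same = labels[:, None] == labels[None, :]

    def one_sign(ws):
        v = ws.sum()
        if v == 0:
            return 0.0, 0.0
        s = ws.sum(axis=1)
        q = ((ws - gamma * np.outer(s, s) / v) * same).sum() / v
        return q, v

    wp, wn = _split_signs(w)
    qp, vp = one_sign(wp)
    qn, vn = one_sign(wn)
    if vp + vn == 0:
        raise ValueError("all-zero connectivity matrix")
    return float(qp - (vn / (vp + vn)) * qn)


@dataclass
class ModularityResult:
    partition: np.ndarray  # community label per node
    q: float
    n_modules: int
    n_repeats: int
    seed: int


def _louvain_local_move(w, gamma, rng):
    """One level of Louvain on a signed matrix: greedy local moving until
    no single-node move improves Q, then return the labels."""
    n = w.shape[0]
    wp, wn = _split_signs(w)
    sp, sn = wp.sum(axis=1), wn.sum(axis=1)
    vp, vn = sp.sum(), sn.sum()
    labels = np.arange(n)
    # community aggregates of strengths
    comm_sp = sp.copy()
    comm_sn = sn.copy()
    scale_n = vn / (vp + vn) if (vp + vn) > 0 else 0.0

    def gain(i, target):
        """Q change of moving node i into community `target` (node i
        currently removed from every community)."""
        in_c = labels == target
        kp = wp[i, in_c].sum()
        kn = wn[i, in_c].sum()
        gp = (2 * kp - 2 * gamma * sp[i] * comm_sp[target] / vp) / vp if vp > 0 else 0.0
        gn = (2 * kn - 2 * gamma * sn[i] * comm_sn[target] / vn) / vn if vn > 0 else 0.0
        return gp - scale_n * gn

    improved = True
    while improved:
        improved = False
        for i in rng.permutation(n):
            current = labels[i]
            labels[i] = -1
            comm_sp[current] -= sp[i]
            comm_sn[current] -= sn[i]
            # candidate communities: neighbors' plus own
            neigh = np.where((wp[i] > 0) | (wn[i] > 0))[0]
            cands = {current} | {int(labels[j]) for j in neigh if labels[j] >= 0}
            best, best_gain = current, gain(i, current)
            for cand in cands:
                g = gain(i, cand)
                if g > best_gain + 1e-14:
                    best, best_gain = cand, g
            labels[i] = best
            comm_sp[best] += sp[i]
            comm_sn[best] += sn[i]
            if best != current:
                improved = True
    return labels


def _aggregate(w, labels):
    comms, inv = np.unique(labels, return_inverse=True)
    k = len(comms)
    agg = np.zeros((k, k))
    for a in range(k):
        for b in range(k):
            agg[a, b] = w[np.ix_(inv == a, inv == b)].sum()
    return agg, inv


def louvain_modularity(w: np.ndarray, gamma: float = 1.0,
                       n_repeats: int = 100, seed: int = 0) -> ModularityResult:
    """Best-of-``n_repeats`` signed Louvain partition of a symmetric
    connectivity matrix; Q is recomputed from the returned partition.
    Singleton communities count toward ``n_modules``."""
    w = np.asarray(w, dtype=float)
    if w.shape[0] != w.shape[1] or not np.allclose(w, w.T):
        raise ValueError("connectivity matrix must be symmetric")
    if np.all(w == 0):
        raise ValueError("all-zero connectivity matrix")
    w = w.copy()
    np.fill_diagonal(w, 0.0)
    rng = np.random.default_rng(seed)
    best_q, best_labels = -np.inf, None
    for _ in range(n_repeats):
        labels = _run_louvain_once(w, gamma, rng)
        q = modularity_signed(w, labels, gamma)
        if q > best_q:
            best_q, best_labels = q, labels
    _, partition = np.unique(best_labels, return_inverse=True)
    return ModularityResult(
        partition=partition, q=float(best_q),
        n_modules=int(partition.max()) + 1,
        n_repeats=n_repeats, seed=seed,
    )


def _run_louvain_once(w, gamma, rng):
    node_map = np.arange(w.shape[0])
    current = w
    while True:
        labels = _louvain_local_move(current, gamma, rng)
        agg, inv = _aggregate(current, labels)
        if agg.shape[0] == current.shape[0]:
            break
        node_map = inv[node_map]
        current = agg
    return node_map


# ---------------------------------------------------------------------------
# group statistics

def permutation_test_group(values_a, values_b, n_perm: int = 10000,
                           paired: bool = False, seed: int = 0) -> float:
    """Two-sided permutation p-value for the observed mean difference:
    label permutation (unpaired) or sign flipping of paired differences.
    p = (1 + #extreme) / (1 + n_perm)."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if n_perm < 100:
        logger.warning("n_perm=%d is small; p-values will be coarse", n_perm)
    rng = np.random.default_rng(seed)
    if paired:
        if a.shape != b.shape:
            raise ValueError("paired test requires equal-length samples")
        d = a - b
        obs = abs(d.mean())
        signs = rng.choice([-1.0, 1.0], size=(n_perm, d.size))
        null = np.abs((signs * d).mean(axis=1))
    else:
        obs = abs(a.mean() - b.mean())
        pooled = np.concatenate([a, b])
        n_a = a.size
        order = np.argsort(rng.random((n_perm, pooled.size)), axis=1)
        shuffled = pooled[order]
        null = np.abs(shuffled[:, :n_a].mean(axis=1) -
                      shuffled[:, n_a:].mean(axis=1))
    return float((1 + (null >= obs - 1e-15).sum()) / (1 + n_perm))


def bh_fdr(pvals, q_level: float = 0.05):
    """Benjamini-Hochberg step-up FDR: (monotone adjusted q-values,
    rejection mask at ``q_level``)."""
    p = np.asarray(pvals, dtype=float)
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, q, *_ = multipletests(p, alpha=q_level, method="fdr_bh")
    return q, reject


@dataclass
class EdgeStats:
    t: np.ndarray
    p: np.ndarray
    q_fdr: np.ndarray
    significant: np.ndarray
    alpha: float


def edge_group_ttest(fnc_a: np.ndarray, fnc_b: np.ndarray,
                     alpha: float = 0.05) -> EdgeStats:
    """Per-edge pooled two-sample t-test between groups (subjects x edges,
    Fisher-z scale) with BH-FDR. Edges with zero pooled variance get p = 1
    with a warning."""
    a = np.atleast_2d(np.asarray(fnc_a, dtype=float))
    b = np.atleast_2d(np.asarray(fnc_b, dtype=float))
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("need at least two subjects per group")
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = stats.ttest_ind(a, b, axis=0, equal_var=True)
    bad = ~np.isfinite(t)
    if bad.any():
        logger.warning("%d edges with zero pooled variance; p set to 1",
                       int(bad.sum()))
        t = np.where(bad, 0.0, t)
        p = np.where(bad, 1.0, p)
    q, reject = bh_fdr(p, q_level=alpha)
    return EdgeStats(t=t, p=p, q_fdr=q, significant=reject, alpha=alpha)


def upper_triangle(values: np.ndarray) -> np.ndarray:
    """Vectorize the strict upper triangle of a k x k matrix."""
    k = values.shape[0]
    iu = np.triu_indices(k, 1)
    return values[iu]


# ---------------------------------------------------------------------------
# association statistics

def normalized_mutual_info(x, y, n_bins: int = None) -> float:
    """NMI between two continuous variables after equal-frequency
    discretization: I(X;Y) / mean(H(X), H(Y)).

    Default n_bins = ceil(sqrt(N/5)), capped at 16.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 10:
        raise ValueError("need at least 10 observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("constant input")
    if n_bins is None:
        n_bins = min(int(np.ceil(np.sqrt(n / 5))), 16)
    n_bins = max(n_bins, 2)

    def discretize(v):
        edges = np.quantile(v, np.linspace(0, 1, n_bins + 1)[1:-1])
        return np.searchsorted(edges, v, side="right")

    xb, yb = discretize(x), discretize(y)
    joint = np.zeros((n_bins, n_bins))
    np.add.at(joint, (xb, yb), 1.0)
    joint /= n
    px = joint.sum(axis=1)
    py = joint.sum(axis=0)
    nz = joint > 0
    mi = float((joint[nz] * np.log(joint[nz] /
                                   np.outer(px, py)[nz])).sum())
    hx = float(stats.entropy(px[px > 0]))
    hy = float(stats.entropy(py[py > 0]))
    denom = 0.5 * (hx + hy)
    if denom == 0:
        raise ValueError("degenerate binning (single occupied bin)")
    return max(mi, 0.0) / denom


def boosted_association(x, y, n_bins: int = None) -> float:
    """PC + sign(PC) * NMI: the Pearson correlation boosted by normalized
    mutual information in its own direction (sign(0) gives 0)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pc = float(stats.pearsonr(x, y).statistic)
    nmi = normalized_mutual_info(x, y, n_bins=n_bins)
    return pc + float(np.sign(pc)) * nmi


def shepherd_pi(x, y, n_boot: int = 200, d2_threshold: float = 6.0,
                seed: int = 0):
    """Shepherd's pi: Spearman correlation after removing bivariate
    outliers flagged by bootstrapped squared Mahalanobis distance.

    Each point's distance from the bivariate mean is averaged over
    ``n_boot`` bootstrap resamples; points with mean squared distance >=
    ``d2_threshold`` are removed. Returns (pi, p, outlier mask). Removing
    more than half the points is an error.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 10:
        raise ValueError("need at least 10 observations")
    rng = np.random.default_rng(seed)
    data = np.column_stack([x, y])
    d2_sum = np.zeros(n)
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        sample = data[idx]
        mean = sample.mean(axis=0)
        cov = np.cov(sample.T)
        try:
            inv = np.linalg.inv(cov)
        except np.linalg.LinAlgError:
            inv = np.linalg.pinv(cov)
        centered = data - mean
        d2_sum += np.einsum("ij,jk,ik->i", centered, inv, centered)
    d2 = d2_sum / n_boot
    outliers = d2 >= d2_threshold
    if outliers.sum() > n / 2:
        raise ValueError("more than half the points flagged as outliers")
    keep = ~outliers
    res = stats.spearmanr(x[keep], y[keep])
    return float(res.statistic), float(res.pvalue), outliers


# ---------------------------------------------------------------------------
# summary-statistic tests (demographic tables)

def ttest_from_summary(n1, m1, s1, n2, m2, s2):
    """Pooled-variance two-sample Student's t from summary statistics;
    two-sided p with df = n1 + n2 - 2."""
    if min(n1, n2) < 2 or min(s1, s2) < 0:
        raise ValueError("need n >= 2 per group and non-negative SDs")
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * s1 ** 2 + (n2 - 1) * s2 ** 2) / df
    if sp2 == 0:
        if m1 == m2:
            return 0.0, 1.0
        raise ValueError("zero pooled variance with unequal means")
    t = (m1 - m2) / np.sqrt(sp2 * (1 / n1 + 1 / n2))
    p = 2 * stats.t.sf(abs(t), df)
    return float(t), float(p)


def chi_square_2x2(a, b, c, d):
    """Pearson chi-square (no continuity correction) on a 2x2 table
    [[a, b], [c, d]]: N(ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d)), p from the
    chi-square distribution with df = 1."""
    counts = np.array([a, b, c, d], dtype=float)
    if np.any(counts < 0) or counts.sum() == 0:
        raise ValueError("counts must be non-negative with positive total")
    n = counts.sum()
    marg = [(a + b), (c + d), (a + c), (b + d)]
    if 0 in marg:
        raise ValueError("zero marginal total")
    chi2 = n * (a * d - b * c) ** 2 / np.prod(marg, dtype=float)
    p = float(stats.chi2.sf(chi2, df=1))
    return float(chi2), p
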