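"""Validation studies exercising the pipeline end to end on synthetic
cohorts with known ground truth.

Each function runs one self-contained study at a documented problem size
and returns plain numbers. They are shared by the test suite and by
``scripts/acceptance.py``, so the reported quantities are always
recomputed from scratch by running the package.
"""

from __future__ import annotations

import logging

import numpy as np

from .decomposition import (gig_ica, group_ica, infomax_ica, iva_gl,
                            joint_isi, pca_whiten, zscore_maps)
from .matching import greedy_pair, group_tmap
from .network import (bh_fdr, chi_square_2x2, compute_fnc, fisher_z_fnc,
                      louvain_modularity, modularity_signed,
                      permutation_test_group)
from .prediction import (permutation_test_prediction, predict_network)
from .spatial import tmap_mask, variance_difference_test, variance_maps
from .synthetic import (SimConfig, assemble_dataset, make_behavioral_target,
                        sample_timecourses)
from .types import ASD, HC

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# worked example: demographic table

def demographics_example():
    """Pearson chi-square (no continuity correction) on the printed
    gender 2x2 table of the study cohort: 65/10 males/females among
    controls vs 76/26 among patients."""
    chi2, p = chi_square_2x2(65, 10, 76, 26)
    return {"chi2": chi2, "p": p}


# ---------------------------------------------------------------------------
# modularity oracle

def _set_partitions(nodes):
    if not nodes:
        yield []
        return
    first, rest = nodes[0], nodes[1:]
    for part in _set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1:]
        yield [[first]] + part


def _exhaustive_q(w):
    n = w.shape[0]
    best = -np.inf
    for part in _set_partitions(list(range(n))):
        labels = np.empty(n, dtype=int)
        for ci, community in enumerate(part):
            labels[community] = ci
        best = max(best, modularity_signed(w, labels))
    return best


def _fixture_graphs(seed=0):
    graphs = {}
    w = np.zeros((6, 6))
    for block in ([0, 1, 2], [3, 4, 5]):
        for i in block:
            for j in block:
                if i != j:
                    w[i, j] = 1.0
    graphs["two_triangles"] = w
    graphs["complete_k4"] = np.ones((4, 4)) - np.eye(4)
    rng = np.random.default_rng(seed)
    for idx in range(4):
        n = int(rng.integers(5, 9))
        g = rng.normal(0, 1, (n, n))
        g = (g + g.T) / 2
        np.fill_diagonal(g, 0)
        graphs[f"signed_random_{idx}"] = g
    return graphs


def modularity_oracle_study(seed=0, n_repeats=100):
    """Best-of-n Louvain Q vs the exhaustive-partition maximum on a fixture
    set of graphs with <= 8 nodes (including two disconnected triangles,
    whose optimum is Q = 0.5 with 2 modules)."""
    graphs = _fixture_graphs(seed)
    max_gap = 0.0
    for name, w in graphs.items():
        best = _exhaustive_q(w)
        got = louvain_modularity(w, n_repeats=n_repeats, seed=seed).q
        max_gap = max(max_gap, abs(best - got))
    res_triangles = louvain_modularity(graphs["two_triangles"],
                                       n_repeats=n_repeats, seed=seed)
    return {
        "max_abs_gap": max_gap,
        "q_two_triangles": res_triangles.q,
        "n_modules_two_triangles": res_triangles.n_modules,
    }


# ---------------------------------------------------------------------------
# FDR oracle and permutation calibration

def _stepup_oracle(pvals, q):
    p = np.asarray(pvals)
    m = p.size
    order = np.argsort(p)
    thresh = q * np.arange(1, m + 1) / m
    below = np.nonzero(p[order] <= thresh)[0]
    reject = np.zeros(m, dtype=bool)
    if below.size:
        reject[order[:below[-1] + 1]] = True
    return reject


def fdr_oracle_study(seed=0, n_vectors=1000):
    """Agreement of bh_fdr with a literal step-up implementation on random
    p-value vectors. Returns the fraction of vectors in full agreement."""
    rng = np.random.default_rng(seed)
    agree = 0
    for _ in range(n_vectors):
        m = int(rng.integers(1, 50))
        p = rng.uniform(size=m) ** rng.uniform(0.5, 3)
        _, reject = bh_fdr(p, q_level=0.05)
        agree += np.array_equal(reject, _stepup_oracle(p, 0.05))
    return {"agreement": agree / n_vectors}


def permutation_calibration_study(seed=0, n_replicates=500, n=15,
                                  n_perm=500, alpha=0.05):
    """Type-I error of the two-sample permutation test under the null."""
    rejections = 0
    for rep in range(n_replicates):
        rng = np.random.default_rng(seed * 100003 + rep)
        a = rng.standard_normal(n)
        b = rng.standard_normal(n)
        p = permutation_test_group(a, b, n_perm=n_perm,
                                   seed=seed * 100003 + rep)
        rejections += p < alpha
    return {"type_one_error": rejections / n_replicates}


# ---------------------------------------------------------------------------
# source recovery

def source_recovery_study(seed=0):
    """Infomax on 3 mixed Laplacian sources (20000 samples) and IVA-GL on
    a 5-subject correlated-source cohort (k=3): minimum best-match |r| and
    the joint Amari ISI."""
    from scipy.optimize import linear_sum_assignment

    rng = np.random.default_rng(seed)
    sources = rng.laplace(size=(3, 20000))
    mixed = rng.standard_normal((3, 3)) @ sources
    est, _ = infomax_ica(pca_whiten(mixed, 3).reduced, seed=seed)
    ez, sz = zscore_maps(est), zscore_maps(sources)
    corr = np.abs(ez @ sz.T / ez.shape[1])
    rows, cols = linear_sum_assignment(-corr)
    min_r = corr[rows, cols].min()

    cfg = SimConfig(n_hc=3, n_asd=2, k_sources=3, grid_shape=(10, 10, 10),
                    n_timepoints=120, isv_sigma=0.5, amp_sigma=0.1,
                    var_inflation_asd=1.0, noise_sigma=0.1, seed=seed)
    dataset, truth = assemble_dataset(cfg)
    dec = iva_gl(dataset, 3, seed=seed)
    est_mixings = [np.linalg.pinv(u) for u in dec.info["unmixings"]]
    isi = joint_isi(est_mixings, truth.subject_tcs)
    return {"infomax_min_match_r": float(min_r), "iva_joint_isi": float(isi)}


# ---------------------------------------------------------------------------
# intersubject-variability comparison (the central study)

def isv_config(seed, isv_sigma=2.0):
    """Study conditions for the ISV comparison: a 25+25 cohort, 4 sources
    of realistic extent (blob sigma 1.75 voxels on a 14-voxel grid,
    matching heavily smoothed fMRI networks), centroid jitter of
    ``isv_sigma`` voxels, and doubled ASD map variance on two designated
    sources."""
    return SimConfig(n_hc=25, n_asd=25, k_sources=4, grid_shape=(14, 14, 14),
                     n_timepoints=150, isv_sigma=isv_sigma, amp_sigma=0.1,
                     var_inflation_asd=2.0, inflated_sources=(0, 1),
                     noise_sigma=0.5, blob_sigma=1.75, seed=seed)


def run_both_methods(dataset, k, seed):
    """Group-ICA references + GIG-ICA and IVA-GL decompositions."""
    baseline = group_ica(dataset, k, seed=seed)
    gig = gig_ica(dataset, baseline.group_maps, seed=seed)
    iva = iva_gl(dataset, k, seed=seed)
    return gig, iva


def match_to_truth(decomposition, base_maps, threshold=0.3):
    """Greedy one-to-one pairing of estimated components (subject-mean
    z-maps) to ground-truth base maps; returns {true_idx: est_idx}."""
    mean_maps = np.mean([zscore_maps(m) for m in decomposition.spatial_maps],
                        axis=0)
    pairing = greedy_pair(mean_maps, zscore_maps(np.asarray(base_maps)),
                          threshold=threshold)
    return {true_idx: est_idx for est_idx, true_idx, _ in pairing.pairs}


def total_subject_map_variance(decomposition):
    """Total across-subject variance of z-scored subject maps — the
    amount of intersubject variability the method's estimates carry."""
    stack = np.array([zscore_maps(m) for m in decomposition.spatial_maps])
    return float(stack.var(axis=0).sum())


def planted_variance_test(decomposition, truth, inflated_sources, groups):
    """Wilcoxon test for ASD-greater map variance on the components
    matched to the inflated sources, within each component's |z| > 1.96
    group-t-map mask (aggregated across the designated sources).

    Returns (p, asd_greater) or (None, None) when no designated source
    was matched."""
    hc = groups == HC
    asd = groups == ASD
    matches = match_to_truth(decomposition, truth.base_maps)
    stacked = decomposition.stacked_maps()
    var_hc_all, var_asd_all = [], []
    for true_idx in inflated_sources:
        if true_idx not in matches:
            continue
        comp = stacked[:, matches[true_idx], :]
        mask = tmap_mask(group_tmap(comp))
        if mask.sum() == 0:
            continue
        vmap = variance_maps(comp[hc][:, mask], comp[asd][:, mask])
        var_hc_all.append(vmap.var_hc)
        var_asd_all.append(vmap.var_asd)
    if not var_hc_all:
        return None, None
    var_hc_all = np.concatenate(var_hc_all)
    var_asd_all = np.concatenate(var_asd_all)
    p = variance_difference_test(var_hc_all, var_asd_all)
    return float(p), bool(var_asd_all.mean() > var_hc_all.mean())


def isv_study(seeds=(0, 1, 2, 3, 4), isv_sigma=2.0):
    """The central comparison: on high-ISV synthetic cohorts, IVA-GL
    should carry more across-subject spatial variance than GIG-ICA, and
    both methods should detect the planted ASD-greater variance."""
    per_seed = []
    for seed in seeds:
        cfg = isv_config(seed, isv_sigma=isv_sigma)
        dataset, truth = assemble_dataset(cfg)
        gig, iva = run_both_methods(dataset, cfg.k_sources, seed)
        groups = dataset.groups
        row = {"seed": seed,
               "var_gig": total_subject_map_variance(gig),
               "var_iva": total_subject_map_variance(iva)}
        for name, dec in (("gig", gig), ("iva", iva)):
            p, asd_greater = planted_variance_test(
                dec, truth, cfg.inflated_sources, groups)
            row[f"p_{name}"] = p
            row[f"asd_greater_{name}"] = asd_greater
        per_seed.append(row)
    ok = [r for r in per_seed if r["p_gig"] is not None
          and r["p_iva"] is not None]
    summary = {
        "n_seeds": len(per_seed),
        "iva_variance_exceeds_gig_fraction": float(np.mean(
            [r["var_iva"] > r["var_gig"] for r in per_seed])),
        "variance_ratio_iva_over_gig_mean": float(np.mean(
            [r["var_iva"] / r["var_gig"] for r in per_seed])),
        "detection_fraction_gig": float(np.mean(
            [r["p_gig"] is not None and r["p_gig"] < 0.05
             and r["asd_greater_gig"] for r in per_seed])),
        "detection_fraction_iva": float(np.mean(
            [r["p_iva"] is not None and r["p_iva"] < 0.05
             and r["asd_greater_iva"] for r in per_seed])),
        "per_seed": per_seed,
    }
    return summary


# ---------------------------------------------------------------------------
# modularity-difference power

def modularity_difference_study(seeds=tuple(range(10)), n_per_group=15,
                                k=8, n_timepoints=150, louvain_repeats=50,
                                n_perm=2000):
    """Power of the paired permutation test to detect the planted 2-block
    (HC) vs 3-block (ASD) FNC structure through per-subject Louvain module
    counts, at n = 15/15 per replicate."""
    detected, qs_hc, qs_asd, nm_hc, nm_asd = [], [], [], [], []
    for seed in seeds:
        cfg = SimConfig(n_hc=n_per_group, n_asd=n_per_group, k_sources=k,
                        n_timepoints=n_timepoints, seed=seed)
        rng = np.random.default_rng(seed)
        counts = {HC: [], ASD: []}
        for group in (HC, ASD):
            for i in range(n_per_group):
                tcs = sample_timecourses(cfg, group, rng)
                z = fisher_z_fnc(compute_fnc(tcs)).values
                mod = louvain_modularity(z, n_repeats=louvain_repeats,
                                         seed=seed + i)
                counts[group].append(mod.n_modules)
                (qs_hc if group == HC else qs_asd).append(mod.q)
        nm_hc.append(np.mean(counts[HC]))
        nm_asd.append(np.mean(counts[ASD]))
        p = permutation_test_group(np.array(counts[HC], float),
                                   np.array(counts[ASD], float),
                                   n_perm=n_perm, paired=True, seed=seed)
        detected.append(p < 0.05)
    return {
        "power": float(np.mean(detected)),
        "mean_n_modules_two_block": float(np.mean(nm_hc)),
        "mean_n_modules_three_block": float(np.mean(nm_asd)),
        "mean_q_two_block": float(np.mean(qs_hc)),
        "mean_q_three_block": float(np.mean(qs_asd)),
    }


# ---------------------------------------------------------------------------
# prediction recovery

def prediction_config(seed):
    """Study conditions for prediction: an 80+80 cohort (sparse-regression
    prediction needs cohort sizes comparable to the ~180-subject study the
    pipeline emulates), 4 well-separated sources, moderate ISV, low scan
    noise (recovery-grade conditions)."""
    return SimConfig(n_hc=80, n_asd=80, k_sources=4, grid_shape=(12, 12, 12),
                     n_timepoints=150, isv_sigma=1.0, amp_sigma=0.1,
                     var_inflation_asd=1.0, noise_sigma=0.1, seed=seed)


def prediction_recovery_study(seed=0, informative_component=2, snr=2.0,
                              n_null_replicates=10):
    """A behavioral target linear in one component's voxels (signal-to-
    noise 2) predicted by CPM + nested-CV LASSO from that component's
    estimated subject maps; plus null calibration on pure-noise feature
    sets of the same cohort size."""
    cfg = prediction_config(seed)
    dataset, truth = assemble_dataset(cfg)
    target, _ = make_behavioral_target(truth.subject_maps,
                                       component=informative_component,
                                       seed=seed, snr=snr)
    baseline = group_ica(dataset, cfg.k_sources, seed=seed)
    gig = gig_ica(dataset, baseline.group_maps, seed=seed)
    matches = match_to_truth(gig, truth.base_maps)
    out = {"r2_informative": None, "perm_p_informative": None}
    if informative_component in matches:
        comp = gig.stacked_maps()[:, matches[informative_component], :]
        # the network's feature set: its subject maps restricted to the
        # |z| > 1.96 voxels of its group t-map
        network_mask = tmap_mask(group_tmap(comp))
        x = comp[:, network_mask]
        res = predict_network(x, target, seed=seed, selection="nested")
        if res is not None:
            out["r2_informative"] = res.r2
            out["rmse_informative"] = res.rmse
            out["perm_p_informative"] = permutation_test_prediction(
                res.observed, res.predictions, seed=seed)
            out["mean_voxels_selected"] = float(np.mean(
                res.n_selected_per_fold))
    # null replicates: pure-noise feature matrices, same machinery
    insignificant = 0
    for rep in range(n_null_replicates):
        rng = np.random.default_rng(seed * 7919 + rep + 1)
        x_null = rng.standard_normal((16, 150))
        y_null = rng.standard_normal(16)
        res = predict_network(x_null, y_null, seed=rep, selection="nested")
        if res is None:
            insignificant += 1
            continue
        p = permutation_test_prediction(res.observed, res.predictions,
                                        seed=rep)
        insignificant += p > 0.05
    out["null_insignificant_fraction"] = insignificant / n_null_replicates
    return out


# ---------------------------------------------------------------------------
# formula worked examples

def formula_examples():
    """Direct formula checks with closed-form expectations."""
    from .network import boosted_association, fisher_z, shepherd_pi
    from scipy import stats as sstats

    out = {"fisher_z_half": float(fisher_z(0.5))}
    # boosted statistic at controlled PC and NMI values: evaluate the
    # formula through the public function on data with known components
    rng = np.random.default_rng(0)
    x = rng.standard_normal(2000)
    out["boosted_identity"] = boosted_association(x, x)
    # Shepherd's pi on a bounded clean cloud equals full-sample Spearman
    gen = np.random.default_rng(1)
    xs = gen.uniform(0, 1, 40)
    ys = xs + gen.uniform(-0.3, 0.3, 40)
    pi, _, outliers = shepherd_pi(xs, ys, seed=0)
    rho = float(sstats.spearmanr(xs, ys).statistic)
    out["shepherd_pi_minus_spearman_clean"] = float(pi - rho)
    out["shepherd_outliers_clean"] = int(outliers.sum())
    return out
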