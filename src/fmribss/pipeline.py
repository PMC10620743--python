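"""End-to-end pipeline: simulate/ingest, decompose with both methods,
screen and pair components, network statistics, spatial statistics, and
prediction, with a JSON run manifest recording configuration, per-stage
outputs with hashes, and wall-clock time.

Stages are idempotent: a stage whose outputs already exist on disk is
skipped on re-run, so deleting one stage's outputs recomputes only that
stage (and the stages after it read from disk as written).
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as fio
from .decomposition import Decomposition, gig_ica, group_ica, iva_gl
from .matching import (SpectralMetrics, greedy_pair, group_tmap,
                       select_components, spectral_metrics)
from .network import (compute_fnc, edge_group_ttest, fisher_z_fnc,
                      louvain_modularity, permutation_test_group,
                      upper_triangle)
from .prediction import permutation_test_prediction, predict_network
from .spatial import variance_difference_test, variance_maps, voxel_group_ttest
from .synthetic import SimConfig, assemble_dataset
from .types import ASD, HC

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Thresholds, seeds and mode flags for a full run."""

    input_dir: str = None  # None -> simulate
    output_dir: str = "fmribss_out"
    model_order: int = 8
    falff_min: float = 0.5
    pair_threshold: float = 0.5
    n_perm: int = 10000
    fdr_q: float = 0.05
    prediction_target: str = "age"
    seed: int = 0
    pooled_selection: bool = False  # select features once on all subjects
    pairing_mode: str = "one-to-one"
    sim: SimConfig = None

    def __post_init__(self):
        if not (0 <= self.falff_min <= 1 and 0 <= self.pair_threshold <= 1
                and 0 < self.fdr_q < 1):
            raise ValueError("thresholds out of range")


@dataclass
class RunManifest:
    config: dict
    stages: dict = field(default_factory=dict)

    def record(self, stage: str, outputs: list, seconds: float):
        self.stages[stage] = {
            "outputs": {str(p): fio.file_hash(p) for p in outputs},
            "seconds": round(seconds, 3),
        }

    def save(self, path):
        fio.write_json({"config": self.config, "stages": self.stages}, path)


def _stage_done(paths) -> bool:
    return all(Path(p).exists() for p in paths)


def _save_decomposition(dec: Decomposition, mask, out: Path, tag: str):
    out.mkdir(parents=True, exist_ok=True)
    np.savez(out / f"{tag}_maps.npz", maps=dec.stacked_maps())
    np.savez(out / f"{tag}_tcs.npz", tcs=np.array(dec.timecourses))
    if dec.group_maps is not None:
        fio.write_maps_nifti(dec.group_maps, mask, out / f"{tag}_group_maps.nii")
    fio.write_json({"method": dec.method, "model_order": dec.model_order,
                    "seed": dec.info.get("seed")}, out / f"{tag}_manifest.json")


def _load_decomposition(out: Path, tag: str, method: str) -> Decomposition:
    maps = np.load(out / f"{tag}_maps.npz")["maps"]
    tcs = np.load(out / f"{tag}_tcs.npz")["tcs"]
    meta = json.loads((out / f"{tag}_manifest.json").read_text())
    return Decomposition(method=method, model_order=meta["model_order"],
                         spatial_maps=list(maps), timecourses=list(tcs),
                         info={"seed": meta.get("seed")})


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Run all stages in order, skipping stages whose outputs exist.
    Returns the manifest (also saved to <output_dir>/manifest.json). A
    failing stage records partial completion before the error propagates."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config={
        k: (v if not isinstance(v, SimConfig) else "SimConfig")
        for k, v in asdict(config).items()
    })
    manifest_path = out / "manifest.json"
    try:
        _run_stages(config, out, manifest)
    finally:
        manifest.save(manifest_path)
    return manifest


def _run_stages(config: PipelineConfig, out: Path, manifest: RunManifest):
    # ---- stage 1: simulate or ingest -------------------------------------
    data_dir = Path(config.input_dir) if config.input_dir else out / "data"
    t0 = time.time()
    if config.input_dir is None and not _stage_done([data_dir / "subjects.tsv"]):
        sim = config.sim or SimConfig(seed=config.seed,
                                      k_sources=config.model_order)
        dataset, truth = assemble_dataset(sim)
        fio.write_dataset(dataset, data_dir)
        fio.write_ground_truth(truth, data_dir)
        manifest.record("simulate", [data_dir / "subjects.tsv"],
                        time.time() - t0)
    dataset = fio.read_dataset(data_dir)
    k = config.model_order

    # ---- stage 2: decomposition ------------------------------------------
    dec_dir = out / "decomposition"
    t0 = time.time()
    tags = {"GIG-ICA": "gig", "IVA-GL": "iva"}
    needed = [dec_dir / f"{tag}_maps.npz" for tag in tags.values()]
    if not _stage_done(needed):
        baseline = group_ica(dataset, k, seed=config.seed)
        gig = gig_ica(dataset, baseline.group_maps, seed=config.seed)
        iva = iva_gl(dataset, k, seed=config.seed)
        iva.info.pop("unmixings", None)
        _save_decomposition(gig, dataset.mask, dec_dir, "gig")
        _save_decomposition(iva, dataset.mask, dec_dir, "iva")
        manifest.record("decompose", needed, time.time() - t0)
    gig = _load_decomposition(dec_dir, "gig", "GIG-ICA")
    iva = _load_decomposition(dec_dir, "iva", "IVA-GL")

    # ---- stage 3: screening + pairing ------------------------------------
    match_dir = out / "matching"
    t0 = time.time()
    pair_path = match_dir / "pairing.tsv"
    if not _stage_done([pair_path]):
        match_dir.mkdir(parents=True, exist_ok=True)
        rows = []
        kept = {}
        for name, dec in (("iva", iva), ("gig", gig)):
            # per-subject spectral metrics, averaged per component (the
            # subject-mean TC cancels uncorrelated fluctuations)
            per_subject = [spectral_metrics(np.asarray(tcs), dataset.tr_seconds)
                           for tcs in dec.timecourses]
            metrics = [
                SpectralMetrics(
                    component_id=c,
                    falff=float(np.mean([m[c].falff for m in per_subject])),
                    dynamic_range=float(np.mean(
                        [m[c].dynamic_range for m in per_subject])),
                )
                for c in range(dec.model_order)
            ]
            kept[name] = select_components(metrics, config.falff_min)
            for m in metrics:
                rows.append({"method": name, "component": m.component_id,
                             "falff": m.falff, "dynamic_range": m.dynamic_range,
                             "kept": m.component_id in kept[name]})
        fio.write_tsv(pd.DataFrame(rows), match_dir / "spectral_metrics.tsv")

        iva_t = np.array([group_tmap(iva.stacked_maps()[:, c, :])
                          for c in kept["iva"]])
        gig_t = np.array([group_tmap(gig.stacked_maps()[:, c, :])
                          for c in kept["gig"]])
        if len(iva_t):
            fio.write_maps_nifti(iva_t, dataset.mask, match_dir / "iva_tmaps.nii")
        if len(gig_t):
            fio.write_maps_nifti(gig_t, dataset.mask, match_dir / "gig_tmaps.nii")
        pairing = greedy_pair(iva_t, gig_t, threshold=config.pair_threshold,
                              mode=config.pairing_mode)
        fio.write_tsv(pd.DataFrame(
            [{"idx_iva": kept["iva"][i], "idx_gig": kept["gig"][j], "r": r}
             for i, j, r in pairing.pairs],
            columns=["idx_iva", "idx_gig", "r"]), pair_path)
        manifest.record("match", [pair_path], time.time() - t0)
    pairing_table = pd.read_csv(pair_path, sep="\t")

    groups = dataset.groups
    hc_idx = np.where(groups == HC)[0]
    asd_idx = np.where(groups == ASD)[0]

    # ---- stage 4: network statistics -------------------------------------
    net_dir = out / "network"
    t0 = time.time()
    net_path = net_dir / "modularity.json"
    if not _stage_done([net_path]) and len(pairing_table) >= 3:
        net_dir.mkdir(parents=True, exist_ok=True)
        results = {}
        edge_rows = []
        for name, dec, col in (("iva", iva, "idx_iva"), ("gig", gig, "idx_gig")):
            comps = pairing_table[col].to_numpy()
            fncs = [compute_fnc(np.asarray(tcs)[:, comps], sid.subject_id)
                    for tcs, sid in zip(dec.timecourses, dataset.subjects)]
            zs = np.array([fisher_z_fnc(f).values for f in fncs])
            mods = [louvain_modularity(z, n_repeats=100, seed=config.seed)
                    for z in zs]
            qs = np.array([m.q for m in mods])
            nmod = np.array([m.n_modules for m in mods], dtype=float)
            results[name] = {
                "q_hc_mean": qs[hc_idx].mean(), "q_hc_std": qs[hc_idx].std(ddof=1),
                "q_asd_mean": qs[asd_idx].mean(),
                "q_asd_std": qs[asd_idx].std(ddof=1),
                "nmod_hc_mean": nmod[hc_idx].mean(),
                "nmod_asd_mean": nmod[asd_idx].mean(),
                "q_group_p": permutation_test_group(
                    qs[hc_idx], qs[asd_idx], n_perm=config.n_perm,
                    seed=config.seed),
                "nmod_group_p": permutation_test_group(
                    nmod[hc_idx], nmod[asd_idx], n_perm=config.n_perm,
                    seed=config.seed),
                "_q": qs.tolist(), "_nmod": nmod.tolist(),
            }
            edges = np.array([upper_triangle(z) for z in zs])
            stats_ = edge_group_ttest(edges[hc_idx], edges[asd_idx],
                                      alpha=config.fdr_q)
            for e in range(edges.shape[1]):
                edge_rows.append({"method": name, "edge": e,
                                  "t": stats_.t[e], "p": stats_.p[e],
                                  "q_fdr": stats_.q_fdr[e],
                                  "significant": bool(stats_.significant[e])})
            np.savez(net_dir / f"{name}_fnc.npz", fnc_z=zs)
        # between-method module-count comparison (paired within group)
        for grp, idx in (("hc", hc_idx), ("asd", asd_idx)):
            results[f"nmod_between_methods_p_{grp}"] = permutation_test_group(
                np.array(results["gig"]["_nmod"])[idx],
                np.array(results["iva"]["_nmod"])[idx],
                n_perm=config.n_perm, paired=True, seed=config.seed)
        fio.write_tsv(pd.DataFrame(edge_rows), net_dir / "edge_stats.tsv")
        fio.write_json(results, net_path)
        manifest.record("network", [net_path], time.time() - t0)

    # ---- stage 5: spatial statistics -------------------------------------
    sp_dir = out / "spatial"
    t0 = time.time()
    sp_path = sp_dir / "variance_tests.tsv"
    if not _stage_done([sp_path]) and len(pairing_table) > 0:
        sp_dir.mkdir(parents=True, exist_ok=True)
        rows = []
        for name, dec, col in (("iva", iva, "idx_iva"), ("gig", gig, "idx_gig")):
            stacked = dec.stacked_maps()
            for comp in pairing_table[col]:
                comp = int(comp)
                maps_hc = stacked[hc_idx, comp, :]
                maps_asd = stacked[asd_idx, comp, :]
                vsm = voxel_group_ttest(maps_hc, maps_asd, alpha=config.fdr_q,
                                        mask=dataset.mask)
                vmap = variance_maps(maps_hc, maps_asd)
                p_var = variance_difference_test(vmap.var_hc, vmap.var_asd)
                rows.append({
                    "method": name, "component": comp,
                    "nov_uncorrected": vsm.n_voxels_uncorrected,
                    "nov_corrected": vsm.n_voxels_corrected,
                    "variance_test_p": p_var,
                    "mean_var_hc": vmap.var_hc.mean(),
                    "mean_var_asd": vmap.var_asd.mean(),
                })
        fio.write_tsv(pd.DataFrame(rows), sp_path)
        manifest.record("spatial", [sp_path], time.time() - t0)

    # ---- stage 6: prediction ---------------------------------------------
    pred_dir = out / "prediction"
    t0 = time.time()
    pred_path = pred_dir / "prediction.tsv"
    if not _stage_done([pred_path]) and len(pairing_table) > 0:
        pred_dir.mkdir(parents=True, exist_ok=True)
        target = np.array([float(s.covariates.get(config.prediction_target,
                                                  np.nan))
                           for s in dataset.subjects])
        covs = np.column_stack([
            [float(s.covariates.get("sex", 0)) for s in dataset.subjects],
            [float(s.covariates.get("handedness", 0)) for s in dataset.subjects],
        ])
        selection = "pooled" if config.pooled_selection else "nested"
        rows = []
        for name, dec, col in (("iva", iva, "idx_iva"), ("gig", gig, "idx_gig")):
            stacked = dec.stacked_maps()
            for comp in pairing_table[col]:
                comp = int(comp)
                res = predict_network(
                    stacked[:, comp, :], target, covariates=covs,
                    seed=config.seed, selection=selection,
                    target_name=config.prediction_target,
                    network_id=f"{name}-{comp}")
                if res is None:
                    continue
                perm_p = permutation_test_prediction(
                    res.observed, res.predictions, seed=config.seed)
                rows.append({"method": name, "component": comp,
                             "r2": res.r2, "rmse": res.rmse,
                             "spearman_rho": res.spearman_rho,
                             "permutation_p": perm_p})
        ranked = pd.DataFrame(rows)
        if len(ranked):
            ranked = ranked.sort_values("r2", ascending=False)
        fio.write_tsv(ranked, pred_path)
        manifest.record("predict", [pred_path], time.time() - t0)
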