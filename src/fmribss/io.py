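"""On-disk formats: NIfTI volumes, tab-separated tables, JSON manifests.

A dataset directory contains one 4D NIfTI per subject, a binary mask
NIfTI, and a ``subjects.tsv`` with columns subject_id, group, age, sex,
handedness, score (extra columns are preserved as covariates). Voxel
ordering is row-major over the mask; TR comes from the NIfTI header
unless the TSV carries a ``tr_seconds`` override column.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .synthetic import GroundTruth, SimConfig
from .types import GroupDataset, SubjectScan

logger = logging.getLogger(__name__)

CORE_COLUMNS = ("subject_id", "group")


def write_dataset(dataset: GroupDataset, out_dir) -> None:
    """Write per-subject 4D NIfTI volumes, the mask, and subjects.tsv."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    mask = dataset.mask
    affine = np.eye(4)
    nib.save(nib.Nifti1Image(mask.astype(np.uint8), affine), out / "mask.nii")
    rows = []
    for scan in dataset.subjects:
        vol = np.zeros(mask.shape + (scan.data.shape[1],), dtype=np.float64)
        vol[mask] = scan.data
        img = nib.Nifti1Image(vol, affine)
        img.header.set_zooms((1.0, 1.0, 1.0, float(scan.tr_seconds)))
        nib.save(img, out / f"{scan.subject_id}.nii")
        rows.append({"subject_id": scan.subject_id, "group": scan.group,
                     **scan.covariates})
    pd.DataFrame(rows).to_csv(out / "subjects.tsv", sep="\t", index=False)


def read_dataset(in_dir) -> GroupDataset:
    """Read a dataset directory written by :func:`write_dataset` (or with
    the same layout). Errors name the offending subject file."""
    src = Path(in_dir)
    table = pd.read_csv(src / "subjects.tsv", sep="\t")
    for col in CORE_COLUMNS:
        if col not in table.columns:
            raise ValueError(f"subjects.tsv missing required column {col!r}")
    mask_img = nib.load(src / "mask.nii")
    mask = np.asarray(mask_img.dataobj).astype(bool)
    subjects = []
    tr = None
    for _, row in table.iterrows():
        path = src / f"{row.subject_id}.nii"
        if not path.exists():
            raise FileNotFoundError(f"missing volume for subject: {path}")
        img = nib.load(path)
        vol = np.asarray(img.dataobj, dtype=float)
        if vol.shape[:3] != mask.shape:
            raise ValueError(
                f"{path.name}: grid {vol.shape[:3]} does not match mask "
                f"{mask.shape}"
            )
        if "tr_seconds" in table.columns:
            tr_s = float(row.tr_seconds)
        else:
            tr_s = float(img.header.get_zooms()[3])
        covariates = {c: row[c] for c in table.columns
                      if c not in CORE_COLUMNS and c != "tr_seconds"}
        subjects.append(SubjectScan(
            subject_id=str(row.subject_id), group=str(row.group),
            data=vol[mask], tr_seconds=tr_s, covariates=covariates,
        ))
        tr = tr_s
    return GroupDataset(subjects=subjects, mask=mask, tr_seconds=tr)


def write_ground_truth(truth: GroundTruth, out_dir) -> None:
    """Serialize ground truth as a JSON descriptor plus a binary array
    bundle (.npz)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = truth.config
    descriptor = {
        "group_labels": list(truth.group_labels),
        "k_sources": int(truth.base_maps.shape[0]),
        "n_voxels": int(truth.base_maps.shape[1]),
        "config": {
            "n_hc": cfg.n_hc, "n_asd": cfg.n_asd, "k_sources": cfg.k_sources,
            "grid_shape": list(cfg.grid_shape),
            "n_timepoints": cfg.n_timepoints, "tr_seconds": cfg.tr_seconds,
            "isv_sigma": cfg.isv_sigma, "amp_sigma": cfg.amp_sigma,
            "var_inflation_asd": cfg.var_inflation_asd,
            "inflated_sources": list(cfg.inflated_sources),
            "noise_sigma": cfg.noise_sigma, "seed": cfg.seed,
        } if cfg is not None else None,
    }
    (out / "ground_truth.json").write_text(json.dumps(descriptor, indent=2))
    np.savez(
        out / "ground_truth.npz",
        base_maps=truth.base_maps,
        subject_maps=np.array(truth.subject_maps),
        subject_tcs=np.array(truth.subject_tcs),
        blob_centers=truth.blob_centers,
        fnc_cov_hc=cfg.fnc_cov_hc if cfg is not None else np.empty(0),
        fnc_cov_asd=cfg.fnc_cov_asd if cfg is not None else np.empty(0),
    )


def read_ground_truth(in_dir) -> GroundTruth:
    src = Path(in_dir)
    descriptor = json.loads((src / "ground_truth.json").read_text())
    arrays = np.load(src / "ground_truth.npz")
    cfg = None
    if descriptor.get("config"):
        c = dict(descriptor["config"])
        c["grid_shape"] = tuple(c["grid_shape"])
        c["inflated_sources"] = tuple(c["inflated_sources"])
        cfg = SimConfig(**c, fnc_cov_hc=arrays["fnc_cov_hc"],
                        fnc_cov_asd=arrays["fnc_cov_asd"])
    return GroundTruth(
        base_maps=arrays["base_maps"],
        subject_maps=list(arrays["subject_maps"]),
        subject_tcs=list(arrays["subject_tcs"]),
        group_labels=descriptor["group_labels"],
        blob_centers=arrays["blob_centers"],
        config=cfg,
    )


def write_maps_nifti(maps: np.ndarray, mask: np.ndarray, path) -> None:
    """Write a k x V map stack as a 4D NIfTI (k volumes)."""
    maps = np.atleast_2d(np.asarray(maps, dtype=float))
    vol = np.zeros(mask.shape + (maps.shape[0],))
    for i, row in enumerate(maps):
        frame = np.zeros(mask.shape)
        frame[mask] = row
        vol[..., i] = frame
    nib.save(nib.Nifti1Image(vol, np.eye(4)), str(path))


def write_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_json_default))


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def file_hash(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()
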