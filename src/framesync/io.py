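"""Dataset directory layout: NIfTI runs, BIDS-style tables, manifest.

One dataset directory holds everything a full analysis needs:

    sub-XX_bold.nii        4D runs (NIfTI-1, affine preserved)
    mask.nii               3D brain mask
    events.tsv             onset, duration, stimulus_id, frame, topic
    sub-XX_nuisance.tsv    six motion-parameter columns
    covariates.csv         participant_id + score columns
    ground_truth.json      generator truth (synthetic datasets only)
    manifest.json          file list with sha256 hashes
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from framesync.preprocess import BoldRun
from framesync.simulate import GroundTruth, SimConfig


def save_run(run: BoldRun, path: str | Path) -> None:
    img = nib.Nifti1Image(run.data.astype(np.float32), run.affine)
    img.header.set_zooms((*img.header.get_zooms()[:3], run.tr_s))
    nib.save(img, str(path))


def load_run(path: str | Path, participant_id: str | None = None) -> BoldRun:
    img = nib.load(str(path))
    tr = float(img.header.get_zooms()[3]) if len(img.header.get_zooms()) > 3 else 1.0
    pid = participant_id or Path(path).name.split("_")[0]
    return BoldRun(
        participant_id=pid,
        data=np.asarray(img.dataobj, dtype=np.float64),
        tr_s=tr,
        affine=np.asarray(img.affine),
        provenance={"source": str(path)},
    )


def save_volume(data: np.ndarray, affine: np.ndarray, path: str | Path) -> None:
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine), str(path))


def load_volume(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    return np.asarray(img.dataobj, dtype=np.float64), np.asarray(img.affine)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _config_json(config: SimConfig) -> dict:
    d = dataclasses.asdict(config)
    d["grid_dims"] = list(d["grid_dims"])
    d["frames"] = list(d["frames"])
    d["topics"] = list(d["topics"])
    if isinstance(d["kappa_by_frame"], dict):
        d["kappa_by_frame"] = dict(d["kappa_by_frame"])
    return d


def write_dataset(
    out_dir: str | Path,
    runs: list[BoldRun],
    events: pd.DataFrame,
    nuisance: dict[str, pd.DataFrame],
    covariates: pd.DataFrame,
    mask: np.ndarray,
    truth: GroundTruth | None = None,
) -> Path:
    """Write a dataset directory with a hash manifest; returns its path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files: list[str] = []

    for run in runs:
        name = f"{run.participant_id}_bold.nii"
        save_run(run, out / name)
        files.append(name)
        nname = f"{run.participant_id}_nuisance.tsv"
        nuisance[run.participant_id].to_csv(out / nname, sep="\t", index=False)
        files.append(nname)

    affine = runs[0].affine if runs else np.eye(4)
    save_volume(mask, affine, out / "mask.nii")
    files.append("mask.nii")
    events.to_csv(out / "events.tsv", sep="\t", index=False)
    files.append("events.tsv")
    covariates.to_csv(out / "covariates.csv", index=False)
    files.append("covariates.csv")

    if truth is not None:
        payload = dict(
            signal_voxel_ids=truth.signal_voxel_ids.tolist(),
            mixing_angles=truth.mixing_angles.to_dict(),
            covariates=truth.covariate_table.reset_index().to_dict(orient="list"),
            config=_config_json(truth.config),
        )
        (out / "ground_truth.json").write_text(json.dumps(payload, indent=1))
        files.append("ground_truth.json")

    manifest = dict(
        files={f: _sha256(out / f) for f in sorted(files)},
        n_participants=len(runs),
    )
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return out


def read_dataset(
    dataset_dir: str | Path,
) -> tuple[list[BoldRun], pd.DataFrame, dict[str, pd.DataFrame], pd.DataFrame, np.ndarray]:
    """Read back (runs, events, nuisance, covariates, mask)."""
    d = Path(dataset_dir)
    manifest = json.loads((d / "manifest.json").read_text())
    run_files = sorted(f for f in manifest["files"] if f.endswith("_bold.nii"))
    runs = [load_run(d / f) for f in run_files]
    nuisance = {
        r.participant_id: pd.read_csv(d / f"{r.participant_id}_nuisance.tsv", sep="\t")
        for r in runs
    }
    events = pd.read_csv(d / "events.tsv", sep="\t")
    covariates = pd.read_csv(d / "covariates.csv")
    mask, _ = load_volume(d / "mask.nii")
    return runs, events, nuisance, covariates, mask.astype(np.uint8)
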