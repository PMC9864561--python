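"""Readers/writers and pipeline configuration.

Array containers round-trip through NumPy ``.npz`` files with named,
self-describing fields; volumetric data use NIfTI (nibabel); tabular
results use CSV with a millisecond time header. Every pipeline output can
carry a JSON provenance sidecar recording stage, parameters, seed and code
version.
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .containers import BetaSet, EpochSet, GazeEpoch, ValidationError
from .decoding import AccuracyMap, TGMatrix, TimeCourse


class SchemaError(ValidationError):
    """A container file is missing a required field."""


def derive_seeds(master_seed: int, n: int) -> list:
    """Independent per-stage substream seeds from one master seed (< 2**31)."""
    state = np.random.SeedSequence(master_seed).generate_state(n)
    return [int(s & 0x7FFFFFFF) for s in state]


# ---------------------------------------------------------------------------
# epoch / gaze / beta containers (npz)

def write_epochs(path, epochs: EpochSet) -> None:
    np.savez_compressed(path, data=epochs.data, category=epochs.category,
                        depiction=epochs.depiction.astype(str),
                        times=epochs.times, srate=epochs.srate)


def _require(npz, fields, path):
    for f in fields:
        if f not in npz:
            raise SchemaError(f"{path}: missing required field {f!r}")


def read_epochs(path) -> EpochSet:
    with np.load(path, allow_pickle=False) as npz:
        _require(npz, ["data", "category", "depiction", "times", "srate"], path)
        return EpochSet(npz["data"], npz["category"], npz["depiction"],
                        npz["times"], float(npz["srate"]))


def write_gaze(path, epochs: list) -> None:
    """Gaze epochs (equal length) with planted-saccade ground truth."""
    x = np.stack([e.x for e in epochs])
    y = np.stack([e.y for e in epochs])
    trial, onset, amp = [], [], []
    for i, e in enumerate(epochs):
        for o, a in e.planted_saccades:
            trial.append(i)
            onset.append(o)
            amp.append(a)
    np.savez_compressed(path, x=x, y=y, srate=epochs[0].srate,
                        planted_trial=np.asarray(trial, int),
                        planted_onset=np.asarray(onset, int),
                        planted_amplitude=np.asarray(amp, float))


def read_gaze(path) -> list:
    with np.load(path, allow_pickle=False) as npz:
        _require(npz, ["x", "y", "srate"], path)
        srate = float(npz["srate"])
        planted = {}
        if "planted_trial" in npz:
            for t, o, a in zip(npz["planted_trial"], npz["planted_onset"],
                               npz["planted_amplitude"]):
                planted.setdefault(int(t), []).append((int(o), float(a)))
        return [GazeEpoch(x, y, srate, planted.get(i, []))
                for i, (x, y) in enumerate(zip(npz["x"], npz["y"]))]


def write_betas(path, betas: BetaSet) -> None:
    np.savez_compressed(path, betas=betas.betas,
                        voxel_coords=betas.voxel_coords,
                        roi_label=np.array(betas.roi_label),
                        condition_ids=betas.condition_ids)


def read_betas(path) -> BetaSet:
    with np.load(path, allow_pickle=False) as npz:
        _require(npz, ["betas", "voxel_coords"], path)
        return BetaSet(npz["betas"], npz["voxel_coords"],
                       roi_label=str(npz["roi_label"]) if "roi_label" in npz else "",
                       condition_ids=npz["condition_ids"]
                       if "condition_ids" in npz else None)


# ---------------------------------------------------------------------------
# NIfTI volumes

def write_volume(path, data: np.ndarray, voxel_size_mm: float = 2.5) -> None:
    """Write a 3-D/4-D array as NIfTI with an isotropic diagonal affine."""
    affine = np.diag([voxel_size_mm] * 3 + [1.0])
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float64), affine),
             str(path))


def read_volume(path, mask_path=None):
    """Read a NIfTI volume; with a mask, return (data, 0-based coords).

    Grid axis order is (x, y, z) as stored; coordinates index the array
    directly — the same convention the searchlight uses.
    """
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if mask_path is None:
        return data
    mask = np.asarray(nib.load(str(mask_path)).dataobj) > 0
    if mask.shape != data.shape[:3]:
        raise ValidationError("mask dimensions do not match volume")
    coords = np.argwhere(mask)
    return data[mask], coords


def write_betas_nifti(out_dir, betas: BetaSet, grid_shape=None,
                      voxel_size_mm: float = 2.5) -> None:
    """Grid-mode BetaSet as one 4-D NIfTI per run plus a binary mask."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if grid_shape is None:
        grid_shape = tuple(betas.voxel_coords.max(axis=0) + 1)
    mask = np.zeros(grid_shape)
    mask[tuple(betas.voxel_coords.T)] = 1.0
    write_volume(out_dir / "mask.nii.gz", mask, voxel_size_mm)
    for r in range(betas.n_runs):
        vol = np.zeros(grid_shape + (betas.n_conditions,))
        vol[tuple(betas.voxel_coords.T)] = betas.betas[r].T
        write_volume(out_dir / f"betas_run-{r + 1:02d}.nii.gz", vol,
                     voxel_size_mm)


def write_accuracy_map(path, amap: AccuracyMap,
                       voxel_size_mm: float = 2.5) -> None:
    vol = amap.to_volume()
    vol[~np.isfinite(vol)] = 0.0
    write_volume(path, vol, voxel_size_mm)


# ---------------------------------------------------------------------------
# tabular results

def write_timecourse_csv(path, tc: TimeCourse | "FusionTimeCourse") -> None:
    pd.DataFrame({"time_ms": tc.times, "value": tc.values}).to_csv(
        path, index=False)


def read_timecourse_csv(path):
    df = pd.read_csv(path)
    return df["time_ms"].to_numpy(), df["value"].to_numpy()


def write_tgm_csv(path, tgm: TGMatrix) -> None:
    pd.DataFrame(tgm.values, index=tgm.times, columns=tgm.times).to_csv(
        path, index_label="train_ms")


def read_events_tsv(path) -> pd.DataFrame:
    """Tab-separated event table with onset, duration, condition columns."""
    df = pd.read_csv(path, sep="\t")
    for col in ("onset", "duration", "condition"):
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")
    return df


# ---------------------------------------------------------------------------
# configuration and provenance

@dataclass
class PipelineConfig:
    """All stage parameters; defaults mirror the emulated study's analysis.

    Round-trips losslessly through YAML; unknown keys are rejected.
    """

    seed: int = 0
    # generator
    n_categories: int = 48
    n_features: int = 100
    n_channels: int = 306
    n_trials_per_cell: int = 24
    shared_fraction: float = 0.5
    noise_sd: float = 1.0
    n_runs: int = 4
    n_subjects: int = 10
    tmin_ms: float = -100.0
    tmax_ms: float = 1000.0
    srate: float = 100.0
    # decoding
    group_size: int = 2
    n_repetitions: int = 5
    svm_c: float = 1.0
    radius_voxels: float = 4.0
    smoothing_fwhm_mm: float = 5.0
    voxel_size_mm: float = 2.5
    # stats
    n_perm: int = 10000
    forming_p: float = 0.001
    alpha: float = 0.05
    n_boot: int = 100000
    # paths
    out_dir: str = "stmvpa_out"

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self),
                                             sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise SchemaError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def write_metadata(path, stage: str, params: dict, seed: int) -> None:
    """JSON provenance sidecar: stage, parameters, seed, code version."""
    meta = {"stage": stage, "parameters": params, "seed": seed,
            "stmvpa_version": __version__}
    Path(path).write_text(json.dumps(meta, indent=2, default=str))
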