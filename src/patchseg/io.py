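"""NIfTI I/O, cohort manifests, and model checkpoints."""
from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .model.network import ConvNet, NetworkSpec
from .model.training import TrainingHistory
from .volume import LabelMap, MpVolume, SEQUENCES

SEQUENCE_FILES = {name: f"{name}.nii" for name in SEQUENCES}
MASK_FILE = "mask.nii"


def _affine(spacing) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    return aff


def save_nifti(arr: np.ndarray, spacing, path) -> None:
    img = nib.Nifti1Image(np.asarray(arr, dtype=np.float32), _affine(spacing))
    img.header.set_zooms(tuple(float(s) for s in spacing))
    nib.save(img, str(path))


def load_nifti(path) -> tuple[np.ndarray, tuple[float, float, float]]:
    img = nib.load(str(path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return np.asarray(img.dataobj, dtype=np.float64), spacing


def write_subject(directory, volume: MpVolume, label: LabelMap | None = None) -> Path:
    """Write one subject's three sequences (and mask) as NIfTI files."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for name, fname in SEQUENCE_FILES.items():
        save_nifti(getattr(volume, name), volume.spacing, directory / fname)
    if label is not None:
        save_nifti(label.mask, volume.spacing, directory / MASK_FILE)
    return directory


def read_subject(directory, subject_id: str | None = None) -> tuple[MpVolume, LabelMap | None]:
    directory = Path(directory)
    seqs = {}
    spacing = None
    for name, fname in SEQUENCE_FILES.items():
        seqs[name], spacing = load_nifti(directory / fname)
    volume = MpVolume(
        **seqs, spacing=spacing, subject_id=subject_id or directory.name
    )
    mask_path = directory / MASK_FILE
    label = None
    if mask_path.exists():
        arr, _ = load_nifti(mask_path)
        label = LabelMap(mask=np.rint(arr).astype(np.uint8))
    return volume, label


def write_manifest(path, rows: list[dict]) -> None:
    """Plain-text cohort manifest: subject_id, directory, split."""
    pd.DataFrame(rows, columns=["subject_id", "directory", "split"]).to_csv(
        path, sep="\t", index=False
    )


def read_manifest(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str)


def save_checkpoint(path, model: ConvNet, history: TrainingHistory | None = None,
                    train_config=None) -> None:
    """Self-describing checkpoint: spec + parameters + history in one file."""
    meta = {
        "spec": asdict(model.spec),
        "patch_edge": model.patch_edge,
        "history": asdict(history) if history is not None else None,
        "train_config": asdict(train_config) if train_config is not None else None,
    }
    arrays = {f"param_{i}": p for i, p in enumerate(model.params())}
    np.savez(path, meta=np.array(json.dumps(meta)), **arrays)


def load_checkpoint(path) -> tuple[ConvNet, dict]:
    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["meta"]))
        spec_dict = meta["spec"]
        for key in ("conv_filters", "conv_kernels"):
            spec_dict[key] = tuple(spec_dict[key])
        spec = NetworkSpec(**spec_dict)
        model = ConvNet(spec, meta["patch_edge"])
        values = [data[f"param_{i}"] for i in range(len(model.params()))]
        model.set_params(values)
    return model, meta


def export_history(path, history: TrainingHistory) -> None:
    history.to_table().to_csv(path, sep="\t", index=False)
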