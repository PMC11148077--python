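"""NIfTI / TSV / dataset-bundle I/O helpers."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd


def save_nifti(data: np.ndarray, affine: np.ndarray, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine), path)
    return path


def load_nifti(path):
    img = nib.load(str(path))
    return np.asarray(img.get_fdata(), dtype=float), img.affine


def write_tsv(df: pd.DataFrame, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)
    return path


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_json(obj, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=_json_default)
    return path


def read_json(path):
    with open(path) as fh:
        return json.load(fh)


def _json_default(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def save_voxel_dataset(path, dataset, behavior: pd.DataFrame,
                       subjects: pd.DataFrame) -> Path:
    """Bundle the PLS inputs: per-condition matrices, voxel index, masks."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    arrays = {f"X_{c}": m for c, m in dataset.matrices.items()}
    np.savez_compressed(
        path, voxel_index=dataset.voxel_index, mask=dataset.mask,
        conditions=np.array(dataset.conditions, dtype=object),
        behavior=behavior.to_numpy(), behavior_columns=np.array(behavior.columns,
                                                                dtype=object),
        subject_id=subjects["subject_id"].to_numpy(dtype=object),
        apoe4=subjects["apoe4"].to_numpy(), **arrays)
    return path


def load_voxel_dataset(path):
    from .prep import VoxelDataset  # local import to avoid cycles

    with np.load(path, allow_pickle=True) as z:
        conditions = tuple(z["conditions"].tolist())
        dataset = VoxelDataset(
            matrices={c: z[f"X_{c}"] for c in conditions},
            voxel_index=z["voxel_index"], mask=z["mask"],
            conditions=conditions)
        behavior = pd.DataFrame(z["behavior"],
                                columns=z["behavior_columns"].tolist())
        meta = pd.DataFrame({"subject_id": z["subject_id"].tolist(),
                             "apoe4": z["apoe4"]})
    return dataset, behavior, meta
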