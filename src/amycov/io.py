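"""File I/O: NIfTI volumes, TSV tables, JSON statistics, YAML configs.

Conventions: GMV stacks are 4-D NIfTI (subject as the 4th axis) with the
brain mask saved alongside as a 3-D uint8 volume; cohort/seed tables are
TSV with a header row; ground truth, fitted models and manifests are JSON.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .synth import GMVStack, GroundTruth, Parcellation

__all__ = [
    "save_stack", "load_stack", "save_volume", "load_volume",
    "save_parcellation", "load_parcellation", "save_table", "load_table",
    "save_json", "load_json", "save_ground_truth", "load_ground_truth",
    "load_config",
]


def save_stack(stack: GMVStack, path: str | Path,
               mask_path: str | Path | None = None) -> None:
    """Write a stack as 4-D NIfTI (and its mask as 3-D uint8 NIfTI)."""
    path = Path(path)
    img = nib.Nifti1Image(np.moveaxis(stack.data, 0, -1), stack.affine)
    img.header.set_xyzt_units("mm")
    nib.save(img, str(path))
    if mask_path is not None:
        save_volume(stack.mask.astype(np.uint8), stack.affine, mask_path)


def load_stack(path: str | Path, mask_path: str | Path,
               subject_ids: list[str] | None = None) -> GMVStack:
    img = nib.load(str(path))
    data = np.moveaxis(np.asarray(img.dataobj, float), -1, 0)
    mask_img = nib.load(str(mask_path))
    mask = np.asarray(mask_img.dataobj) > 0
    ids = subject_ids or [f"sub{k + 1:04d}" for k in range(data.shape[0])]
    return GMVStack(data, mask, img.affine, ids)


def save_volume(volume: np.ndarray, affine: np.ndarray,
                path: str | Path) -> None:
    nib.save(nib.Nifti1Image(np.asarray(volume), affine), str(Path(path)))


def load_volume(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    return np.asarray(img.dataobj), img.affine


def save_parcellation(parc: Parcellation, nifti_path: str | Path,
                      names_path: str | Path) -> None:
    save_volume(parc.labels.astype(np.int32), parc.affine, nifti_path)
    pd.DataFrame(
        {"label": list(parc.names), "name": list(parc.names.values())}
    ).to_csv(names_path, sep="\t", index=False)


def load_parcellation(nifti_path: str | Path,
                      names_path: str | Path) -> Parcellation:
    labels, affine = load_volume(nifti_path)
    table = pd.read_csv(names_path, sep="\t")
    names = dict(zip(table["label"].astype(int), table["name"].astype(str)))
    return Parcellation(labels.astype(np.int32), names, affine)


def save_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)


def load_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


class _NumpyEncoder(json.JSONEncoder):
    def default(self, obj):
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return dataclasses.asdict(obj)
        return super().default(obj)


def save_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, cls=_NumpyEncoder)


def load_json(path: str | Path):
    with open(path) as fh:
        return json.load(fh)


def save_ground_truth(gt: GroundTruth, path: str | Path) -> None:
    save_json(dataclasses.asdict(gt), path)


def load_ground_truth(path: str | Path) -> GroundTruth:
    raw = load_json(path)
    raw["site_additive"] = {int(k): v for k, v in raw["site_additive"].items()}
    raw["site_scale"] = {int(k): v for k, v in raw["site_scale"].items()}
    return GroundTruth(**raw)


def load_config(path: str | Path) -> dict:
    """Load and schema-check a YAML run configuration."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("config must be a YAML mapping")
    return cfg
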