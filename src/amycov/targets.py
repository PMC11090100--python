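"""Target-ROI definition from significance masks and an atlas parcellation.

The selection procedure: (1) binarize each seed's significant voxels,
(2) merge them into a union mask, (3) intersect the union with every atlas
region, (4) compute each region's overlapping ratio
(intersection / region volume), (5) select regions whose ratio and
intersection volume both exceed their thresholds, (6) extract each target
region's mean GMV per subject.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .synth import GMVStack, Parcellation

__all__ = ["OverlapRecord", "TargetROI", "build_union_mask",
           "select_target_rois", "extract_mean_gmv", "overlap_table"]


@dataclass(frozen=True)
class OverlapRecord:
    """Overlap bookkeeping for one atlas region against the union mask."""

    label: int
    name: str
    region_voxels: int
    region_mm3: float
    intersection_voxels: int
    intersection_mm3: float
    ratio: float
    selected: bool


@dataclass
class TargetROI:
    """A selected atlas region with its mask and per-subject mean GMV."""

    label: int
    name: str
    mask: np.ndarray
    mean_gmv: np.ndarray | None = None


def build_union_mask(masks: Sequence[np.ndarray]) -> np.ndarray:
    """Voxelwise OR of per-seed significance masks (identical grids)."""
    if len(masks) == 0:
        raise ValueError("need at least one mask")
    out = np.asarray(masks[0], bool).copy()
    for m in masks[1:]:
        m = np.asarray(m, bool)
        if m.shape != out.shape:
            raise ValueError("masks are on different grids")
        out |= m
    return out


def select_target_rois(union_mask: np.ndarray, parcellation: Parcellation,
                       min_ratio: float = 0.15,
                       min_volume_mm3: float = 1.0,
                       voxel_volume_mm3: float | None = None,
                       ) -> list[OverlapRecord]:
    """Score every atlas region against the union mask.

    A region is selected iff its overlapping ratio exceeds ``min_ratio`` AND
    its intersection volume exceeds ``min_volume_mm3`` (both strict).
    Records are sorted by atlas label.
    """
    if min_ratio < 0 or min_volume_mm3 < 0:
        raise ValueError("thresholds must be non-negative")
    union_mask = np.asarray(union_mask, bool)
    labels = parcellation.labels
    if labels.shape != union_mask.shape:
        raise ValueError("parcellation grid does not match the mask")
    if (labels > 0).sum() == 0:
        raise ValueError("parcellation has no labelled voxels")
    if voxel_volume_mm3 is None:
        voxel_volume_mm3 = float(abs(np.linalg.det(parcellation.affine[:3, :3])))

    max_label = int(labels.max())
    region_counts = np.bincount(labels.ravel(), minlength=max_label + 1)
    inter_counts = np.bincount(labels[union_mask].ravel(),
                               minlength=max_label + 1)
    records = []
    for label in sorted(parcellation.names):
        nvox = int(region_counts[label])
        if nvox == 0:
            continue
        ninter = int(inter_counts[label])
        ratio = ninter / nvox
        inter_mm3 = ninter * voxel_volume_mm3
        records.append(OverlapRecord(
            label=label, name=parcellation.names[label],
            region_voxels=nvox, region_mm3=nvox * voxel_volume_mm3,
            intersection_voxels=ninter, intersection_mm3=inter_mm3,
            ratio=ratio,
            selected=(ratio > min_ratio) and (inter_mm3 > min_volume_mm3),
        ))
    return records


def overlap_table(records: Sequence[OverlapRecord]) -> pd.DataFrame:
    """Overlap records as a DataFrame (TSV-ready)."""
    return pd.DataFrame([r.__dict__ for r in records])


def extract_mean_gmv(stack: GMVStack, roi_mask: np.ndarray,
                     scope: str = "full_region",
                     union_mask: np.ndarray | None = None) -> np.ndarray:
    """Per-subject mean GMV over a target region.

    ``scope="full_region"`` averages over the whole atlas region (restricted
    to the brain mask); ``scope="intersection_only"`` averages only over the
    region's intersection with ``union_mask``.
    """
    if scope not in ("full_region", "intersection_only"):
        raise ValueError("scope must be 'full_region' or 'intersection_only'")
    roi_mask = np.asarray(roi_mask, bool)
    if roi_mask.shape != stack.mask.shape:
        raise ValueError("ROI mask grid does not match the stack")
    sel = roi_mask & stack.mask
    if scope == "intersection_only":
        if union_mask is None:
            raise ValueError("union_mask required for intersection_only scope")
        sel &= np.asarray(union_mask, bool)
    if not sel.any():
        raise ValueError("empty ROI scope: nothing to average")
    return stack.data[:, sel].mean(axis=1)
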