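"""ROI gray-matter volumes from modulated probability maps + a label atlas.

Volumes are sums of modulated voxel values times voxel volume (modulation
makes voxel intensities volume-preserving, so the sum is a volume in mm^3).
No resampling is performed here: maps must already share the atlas grid.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import nibabel as nib
import numpy as np
import pandas as pd

from ._util import ValidationError
from .cohort import ROIVolumeTable

__all__ = ["AtlasParcellation", "load_parcellation", "extract_roi_volumes"]


@dataclass(frozen=True)
class AtlasParcellation:
    """Integer-labeled parcellation on a fixed voxel grid.

    Label 0 is background; ``label_table`` maps every other id to an ROI
    name.  ``voxel_volume`` is |det| of the affine's 3x3 block, in mm^3.
    """

    label_image: np.ndarray
    label_table: dict[int, str]
    affine: np.ndarray
    voxel_volume: float

    @property
    def roi_ids(self) -> list[int]:
        return sorted(self.label_table)

    @property
    def roi_names(self) -> list[str]:
        return [self.label_table[i] for i in self.roi_ids]


def load_parcellation(image_path, label_table_path) -> AtlasParcellation:
    """Load a NIfTI label image and its TSV (id, name) table.

    Labels listed in the table but absent from the image are kept (their
    volumes will be 0) with a warning; non-integer voxel values and
    duplicate ids are errors.
    """
    img = nib.load(str(image_path))
    data = np.asarray(img.get_fdata())
    if not np.allclose(data, np.round(data)):
        raise ValidationError("label image contains non-integer voxel values")
    labels = data.astype(np.int64)
    if np.any(labels < 0):
        raise ValidationError("label image contains negative labels")
    table = pd.read_csv(label_table_path, sep="\t")
    if table.shape[1] < 2:
        raise ValidationError("label table needs (id, name) columns")
    ids = table.iloc[:, 0].astype(int).to_numpy()
    names = table.iloc[:, 1].astype(str).to_numpy()
    if len(set(ids)) != len(ids):
        raise ValidationError("duplicate ids in label table")
    if 0 in ids:
        raise ValidationError("id 0 is reserved for background")
    label_table = dict(zip(ids.tolist(), names.tolist()))
    present = set(np.unique(labels).tolist()) - {0}
    unknown = present - set(label_table)
    if unknown:
        raise ValidationError(f"image labels missing from table: {sorted(unknown)}")
    absent = set(label_table) - present
    if absent:
        warnings.warn(f"table labels absent from image (volume will be 0): "
                      f"{sorted(absent)}", RuntimeWarning, stacklevel=2)
    affine = np.asarray(img.affine)
    if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
        raise ValidationError("atlas affine is singular")
    voxel_volume = float(abs(np.linalg.det(affine[:3, :3])))
    return AtlasParcellation(labels, label_table, affine, voxel_volume)


def extract_roi_volumes(gm_map_paths, atlas: AtlasParcellation,
                        subject_ids=None, groups=None) -> ROIVolumeTable:
    """Per-subject, per-ROI volume = sum of map values over ROI voxels x voxel volume.

    Every map must match the atlas grid and affine exactly; resample
    upstream if they do not.  ``groups`` assigns a group label per subject
    (default ``"control"`` for all).
    """
    gm_map_paths = list(gm_map_paths)
    if not gm_map_paths:
        raise ValidationError("no gray-matter maps given")
    if subject_ids is None:
        subject_ids = [f"sub{i + 1:03d}" for i in range(len(gm_map_paths))]
    if groups is None:
        groups = ["control"] * len(gm_map_paths)
    if not (len(subject_ids) == len(groups) == len(gm_map_paths)):
        raise ValidationError("maps, subject_ids and groups must align")
    ids = atlas.roi_ids
    n_labels = max(ids) + 1
    flat_labels = atlas.label_image.ravel()
    rows = []
    for path in gm_map_paths:
        img = nib.load(str(path))
        if img.shape != atlas.label_image.shape:
            raise ValidationError(
                f"{path}: grid {img.shape} != atlas grid {atlas.label_image.shape}; "
                "resample the map upstream")
        if not np.allclose(img.affine, atlas.affine, atol=1e-6):
            raise ValidationError(f"{path}: affine differs from atlas; resample upstream")
        data = np.asarray(img.get_fdata(), dtype=float)
        if np.any(data < 0):
            raise ValidationError(f"{path}: negative gray-matter values")
        sums = np.bincount(flat_labels, weights=data.ravel(), minlength=n_labels)
        rows.append(sums[ids] * atlas.voxel_volume)
    df = pd.DataFrame({"subject_id": list(subject_ids), "group": list(groups)})
    df[atlas.roi_names] = np.asarray(rows)
    return ROIVolumeTable(df, atlas.roi_names, [])
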