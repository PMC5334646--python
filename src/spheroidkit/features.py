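"""Per-nucleus morphological and intensity features from a label image.

For every labelled nucleus we record: volume (voxels and um^3), centroid,
intensity-weighted centroid, mean/min/max distance of object voxels to the
centroid, number of surface voxels (object voxels with at least one
6-neighbour in the background), bounding box, principal axes and extents
from a PCA of the voxel coordinates, and intensity mean/min/max/sd on the
[0,1]-normalized image.  The normalized distance to the spheroid surface
(``nds``) column is filled later by the geometry stage.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import ndimage

from .io import VoxelImage
from .segmentation import LabelImage

__all__ = ["extract_features", "FEATURE_COLUMNS"]

FEATURE_COLUMNS = [
    "label",
    "volume_voxels",
    "volume_um3",
    "centroid_z", "centroid_y", "centroid_x",
    "weighted_centroid_z", "weighted_centroid_y", "weighted_centroid_x",
    "dist_to_centroid_mean", "dist_to_centroid_min", "dist_to_centroid_max",
    "surface_voxel_count",
    "bbox_min_z", "bbox_min_y", "bbox_min_x",
    "bbox_max_z", "bbox_max_y", "bbox_max_x",
    "extent_1", "extent_2", "extent_3",
    "axis_1_z", "axis_1_y", "axis_1_x",
    "axis_2_z", "axis_2_y", "axis_2_x",
    "axis_3_z", "axis_3_y", "axis_3_x",
    "intensity_mean", "intensity_min", "intensity_max", "intensity_sd",
    "nds",
]


def _surface_voxel_count(obj_mask: np.ndarray) -> int:
    eroded = ndimage.binary_erosion(
        obj_mask, structure=ndimage.generate_binary_structure(3, 1), border_value=0
    )
    return int(obj_mask.sum() - eroded.sum())


def _pca_axes_extents(coords: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Principal directions and peak-to-peak extents of voxel coordinates.

    Zero-variance directions get extent 0; the basis is always completed to
    an orthonormal triple (degenerate flat/linear objects included).
    """
    centered = coords - coords.mean(axis=0)
    if coords.shape[0] == 1:
        return np.eye(3), np.zeros(3)
    cov = centered.T @ centered / coords.shape[0]
    eigval, eigvec = np.linalg.eigh(cov)  # ascending
    order = np.argsort(eigval)[::-1]
    axes = eigvec[:, order].T  # rows = principal axes, descending variance
    proj = centered @ axes.T
    extents = proj.max(axis=0) - proj.min(axis=0)
    return axes, extents


def extract_features(labels: LabelImage, image: VoxelImage) -> pd.DataFrame:
    """Compute the per-nucleus feature table (one row per label)."""
    if labels.labels.shape != image.voxels.shape:
        raise ValueError("label image and intensity image shapes differ")
    lab = labels.labels
    img = image.voxels
    pitch = labels.pitch
    n = labels.n_objects
    if n == 0:
        return pd.DataFrame(columns=FEATURE_COLUMNS)

    objects = ndimage.find_objects(lab, max_label=n)
    rows = []
    for i, sl in enumerate(objects, start=1):
        if sl is None:
            continue
        obj = lab[sl] == i
        vals = img[sl][obj]
        coords = np.argwhere(obj).astype(np.float64)
        offset = np.array([s.start for s in sl], dtype=np.float64)
        coords_global = coords + offset

        vol = coords.shape[0]
        centroid = coords_global.mean(axis=0)
        wsum = vals.sum()
        wcentroid = (coords_global * vals[:, None]).sum(axis=0) / wsum if wsum > 0 else centroid
        d = np.linalg.norm(coords_global - centroid, axis=1)
        axes, extents = _pca_axes_extents(coords_global)
        bbox_min = coords_global.min(axis=0)
        bbox_max = coords_global.max(axis=0)

        rows.append({
            "label": i,
            "volume_voxels": vol,
            "volume_um3": vol * pitch**3,
            "centroid_z": centroid[0], "centroid_y": centroid[1], "centroid_x": centroid[2],
            "weighted_centroid_z": wcentroid[0],
            "weighted_centroid_y": wcentroid[1],
            "weighted_centroid_x": wcentroid[2],
            "dist_to_centroid_mean": d.mean(),
            "dist_to_centroid_min": d.min(),
            "dist_to_centroid_max": d.max(),
            "surface_voxel_count": _surface_voxel_count(obj),
            "bbox_min_z": bbox_min[0], "bbox_min_y": bbox_min[1], "bbox_min_x": bbox_min[2],
            "bbox_max_z": bbox_max[0], "bbox_max_y": bbox_max[1], "bbox_max_x": bbox_max[2],
            "extent_1": extents[0], "extent_2": extents[1], "extent_3": extents[2],
            "axis_1_z": axes[0, 0], "axis_1_y": axes[0, 1], "axis_1_x": axes[0, 2],
            "axis_2_z": axes[1, 0], "axis_2_y": axes[1, 1], "axis_2_x": axes[1, 2],
            "axis_3_z": axes[2, 0], "axis_3_y": axes[2, 1], "axis_3_x": axes[2, 2],
            "intensity_mean": vals.mean(),
            "intensity_min": vals.min(),
            "intensity_max": vals.max(),
            "intensity_sd": vals.std(),
            "nds": np.nan,
        })
    return pd.DataFrame(rows, columns=FEATURE_COLUMNS)
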