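"""Morphometry of segmented structures.

Length and width are operationalized as extents along the structure's
principal component axes (PCA of voxel-centre coordinates), plus one voxel
pitch for the voxel footprint.  Distances are Euclidean minima between
boundary-voxel centres (bias at most one voxel diagonal), in millimetres.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

from .volumes import LabelVolume

__all__ = [
    "principal_dimensions",
    "min_surface_distance",
    "component_census",
    "structure_report",
]


def principal_dimensions(mask: np.ndarray, voxel_pitch_um: float) -> np.ndarray:
    """Extents (mm, sorted descending) along the mask's principal axes.

    Each extent is the range of voxel-centre coordinates projected on a
    principal component axis plus one voxel pitch; for a single voxel all
    extents equal the pitch.  The largest extent is the structure's length,
    the second its width.
    """
    pts = np.argwhere(mask)
    if pts.size == 0:
        raise ValueError("empty mask")
    pitch = voxel_pitch_um / 1000.0
    xyz = pts * pitch
    centred = xyz - xyz.mean(axis=0)
    cov = np.cov(centred.T) if len(xyz) > 1 else np.zeros((3, 3))
    _, axes = np.linalg.eigh(np.atleast_2d(cov))
    proj = centred @ axes
    extents = proj.max(axis=0) - proj.min(axis=0) + pitch
    return np.sort(extents)[::-1]


def _boundary(mask: np.ndarray) -> np.ndarray:
    return mask & ~ndimage.binary_erosion(mask)


def min_surface_distance(mask_a, mask_b, voxel_pitch_um: float,
                         points_b_mm: np.ndarray | None = None):
    """Minimum distance (mm) between two structures, with the realizing pair.

    ``mask_b`` may be None if ``points_b_mm`` gives landmark points in mm
    (voxel-grid coordinates, origin at voxel (0,0,0) centre).  Distances are
    between boundary-voxel centres; intersecting masks give 0.  Returns
    ``(distance_mm, point_a_mm, point_b_mm)``.
    """
    pitch = voxel_pitch_um / 1000.0
    if not np.any(mask_a):
        raise ValueError("empty mask")
    if points_b_mm is None:
        if not np.any(mask_b):
            raise ValueError("empty mask")
        if np.any(mask_a & mask_b):
            p = np.argwhere(mask_a & mask_b)[0] * pitch
            return 0.0, p, p
        pts_b = np.argwhere(_boundary(mask_b)) * pitch
    else:
        pts_b = np.asarray(points_b_mm, dtype=float).reshape(-1, 3)
        if pts_b.size == 0:
            raise ValueError("no landmark points")
    pts_a = np.argwhere(_boundary(mask_a)) * pitch
    tree = cKDTree(pts_b)
    d, j = tree.query(pts_a)
    i = int(np.argmin(d))
    return float(d[i]), pts_a[i], pts_b[j[i]]


def component_census(labels: LabelVolume) -> pd.DataFrame:
    """Per-structure voxel counts, volumes and connected components.

    Volume is voxel count x pitch^3 (mm^3); components use 26-connectivity
    (consistent with the segmentation's region growing).  Labels absent from
    the data yield rows with zeros.
    """
    pitch = labels.pitch_mm
    struct = ndimage.generate_binary_structure(3, 3)
    rows = []
    for lab, name in sorted(labels.legend.items()):
        mask = labels.labels == lab
        n_vox = int(mask.sum())
        n_comp = int(ndimage.label(mask, structure=struct)[1]) if n_vox else 0
        row = {"label": lab, "structure": name, "voxels": n_vox,
               "volume_mm3": n_vox * pitch ** 3, "components": n_comp}
        if n_vox:
            ext = principal_dimensions(mask, labels.voxel_pitch_um)
            row.update(length_mm=float(ext[0]), width_mm=float(ext[1]),
                       depth_mm=float(ext[2]))
        else:
            row.update(length_mm=0.0, width_mm=0.0, depth_mm=0.0)
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class StructurePair:
    a: str
    b: str
    distance_mm: float
    point_a_mm: tuple[float, float, float]
    point_b_mm: tuple[float, float, float]


def structure_report(labels: LabelVolume,
                     pairs: list[tuple[str, str]] = (),
                     landmarks: dict[str, np.ndarray] | None = None,
                     landmark_pairs: list[tuple[str, str]] = ()):
    """Full morphometry: census plus minimum distances.

    ``pairs`` are (structure, structure) name pairs; ``landmark_pairs`` are
    (structure, landmark) pairs against the ``landmarks`` point sets (mm).
    Returns ``(census DataFrame, list of StructurePair)``.
    """
    census = component_census(labels)
    out = []
    for a, b in pairs:
        d, pa, pb = min_surface_distance(labels.mask(a), labels.mask(b),
                                         labels.voxel_pitch_um)
        out.append(StructurePair(a, b, d, tuple(pa), tuple(pb)))
    for a, lm in landmark_pairs:
        d, pa, pb = min_surface_distance(labels.mask(a), None,
                                         labels.voxel_pitch_um,
                                         points_b_mm=landmarks[lm])
        out.append(StructurePair(a, lm, d, tuple(pa), tuple(pb)))
    return census, out
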