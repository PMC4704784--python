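"""Centrosome detection from the gamma-tubulin channel.

A centrosome is a 3-D connected component of at least ``min_voxels`` voxels
whose gamma-tubulin intensity is at or above a minimum threshold, inside the
ROI.  Its center point is the centroid of the regional maxima of the
Euclidean distance transform of the component (distance to background,
computed with the physical, anisotropic voxel spacing) - i.e. the deepest
interior of the blob rather than an intensity-weighted centroid, which makes
the center robust to asymmetric staining halos.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.morphology import local_maxima

_STRUCTS = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


@dataclass
class Centrosome:
    """A detected gamma-tubulin punctum."""

    voxels: np.ndarray  # (N, 3) array of (z, y, x) indices
    center_um: tuple[float, float, float]
    size_voxels: int
    peak_intensity: float
    touches_border: bool = False

    @property
    def first_voxel(self) -> tuple[int, int, int]:
        return tuple(self.voxels[0])


def component_center(
    voxels: np.ndarray, voxel_size: tuple[float, float, float]
) -> tuple[float, float, float]:
    """Center of a connected voxel component in micrometres.

    The component mask is embedded in a one-voxel background pad, its
    anisotropic Euclidean distance transform taken, and the centroid of the
    regional-maxima voxel set returned (plateaus contribute all their
    voxels, which makes ties deterministic).
    """
    voxels = np.asarray(voxels)
    lo = voxels.min(axis=0)
    hi = voxels.max(axis=0)
    box = np.zeros(hi - lo + 3, dtype=bool)  # pad by 1 so EDT sees background
    box[tuple((voxels - lo + 1).T)] = True
    edt = ndimage.distance_transform_edt(box, sampling=voxel_size)
    maxima = local_maxima(edt, connectivity=3, allow_borders=True) & box
    coords = np.argwhere(maxima) + lo - 1
    center_idx = coords.mean(axis=0)
    return tuple(float(c * s) for c, s in zip(center_idx, voxel_size))


def detect_centrosomes(
    tub_channel: np.ndarray,
    roi_mask: np.ndarray,
    t_tub_min: float,
    min_voxels: int = 8,
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0),
    connectivity: int = 26,
) -> list[Centrosome]:
    """All sufficiently large bright gamma-tubulin components inside the ROI.

    Returns centrosomes sorted by descending size, ties broken by ascending
    (z, y, x) of the first voxel in scan order.  An empty list is a valid
    result.  Components touching the ROI boundary (or the volume edge) are
    kept but flagged via ``touches_border``.
    """
    bright = roi_mask & (tub_channel >= t_tub_min)
    labels, n = ndimage.label(bright, structure=_STRUCTS[connectivity])
    out: list[Centrosome] = []
    for lab in range(1, n + 1):
        comp = labels == lab
        voxels = np.argwhere(comp)
        if len(voxels) < min_voxels:
            continue
        dilated = ndimage.binary_dilation(comp, structure=_STRUCTS[6])
        touches = bool(np.any(dilated & ~roi_mask)) or _on_volume_edge(voxels, comp.shape)
        out.append(
            Centrosome(
                voxels=voxels,
                center_um=component_center(voxels, voxel_size),
                size_voxels=len(voxels),
                peak_intensity=float(tub_channel[comp].max()),
                touches_border=touches,
            )
        )
    out.sort(key=lambda c: (-c.size_voxels, c.first_voxel))
    return out


def _on_volume_edge(voxels: np.ndarray, shape: tuple[int, int, int]) -> bool:
    return bool(
        np.any(voxels == 0) or np.any(voxels == np.asarray(shape) - 1)
    )
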