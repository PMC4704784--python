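"""Nuclear / cytoplasmic segmentation inside an ROI.

The nucleus is defined purely by thresholding: a voxel is nuclear iff it lies
in the ROI, its DAPI intensity is at or above a user-specified threshold, and
its gamma-tubulin intensity is *below* a background threshold (diffuse
cytoplasmic gamma-tubulin staining is absent from the nucleus, which makes it
a useful second gate against DAPI bleed-through).  Cytoplasm is the set
difference ROI minus nucleus, so the two masks always partition the ROI.

No morphological clean-up is applied by default; an optional hole fill is
available for noisy data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu, threshold_isodata

from .errors import DegenerateInputError, EmptyInputError
from .stack import VolumeStack


@dataclass
class RegionMasks:
    """Disjoint nuclear and cytoplasmic masks partitioning an ROI."""

    nuclear: np.ndarray
    cytoplasm: np.ndarray
    roi: np.ndarray

    def __post_init__(self) -> None:
        assert not np.any(self.nuclear & self.cytoplasm)
        assert np.array_equal(self.nuclear | self.cytoplasm, self.roi)


def nuclear_mask(
    stack: VolumeStack,
    roi_mask: np.ndarray,
    t_dapi: float,
    t_tub_low: float,
    fill_holes: bool = False,
) -> np.ndarray:
    """Voxels in the ROI with DAPI >= ``t_dapi`` and gamma-tubulin < ``t_tub_low``."""
    if not roi_mask.any():
        raise EmptyInputError("ROI mask is empty")
    dapi = stack.channel("dapi")
    tub = stack.channel("gamma_tubulin")
    mask = roi_mask & (dapi >= t_dapi) & (tub < t_tub_low)
    if fill_holes:
        mask = ndimage.binary_fill_holes(mask) & roi_mask
    return mask


def cytoplasm_mask(roi_mask: np.ndarray, nuclear: np.ndarray) -> np.ndarray:
    """Set difference ROI minus nucleus."""
    if np.any(nuclear & ~roi_mask):
        raise EmptyInputError("nuclear mask is not a subset of the ROI mask")
    return roi_mask & ~nuclear


def segment(
    stack: VolumeStack,
    roi_mask: np.ndarray,
    t_dapi: float,
    t_tub_low: float,
    fill_holes: bool = False,
) -> RegionMasks:
    nuc = nuclear_mask(stack, roi_mask, t_dapi, t_tub_low, fill_holes=fill_holes)
    return RegionMasks(nuclear=nuc, cytoplasm=cytoplasm_mask(roi_mask, nuc), roi=roi_mask)


def auto_threshold(values: np.ndarray, method: str = "otsu") -> float:
    """Histogram-based threshold over the given intensity sample.

    Offered as a convenience for generating starting thresholds; the measured
    analyses use explicit user-specified values.  ``otsu`` maximizes
    between-class variance; ``isodata`` iterates the two-class midpoint.
    """
    values = np.asarray(values).ravel()
    if values.size == 0:
        raise EmptyInputError("cannot threshold an empty sample")
    if np.all(values == values.flat[0]):
        raise DegenerateInputError("constant intensities admit no threshold")
    if method == "otsu":
        return float(threshold_otsu(values))
    if method == "isodata":
        return float(threshold_isodata(values))
    raise ValueError(f"unknown threshold method {method!r}")
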