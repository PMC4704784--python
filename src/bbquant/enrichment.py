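"""Regional enrichment of an experimental stain around the centrosome.

This is the core measurement: cytoplasm is partitioned by physical distance
to centrosome center(s) into *centrosome-adjacent* (within the inner sphere
radius), *centrosome-nonadjacent* (beyond the outer radius) and an unassigned
buffer *shell* in between.  Mean raw intensity of the experimental channel is
taken over the nuclear, adjacent and nonadjacent regions; the nuclear mean is
subtracted from both cytoplasmic means as a per-stack background normalization,
and fold enrichment is the ratio of the two normalized means.

Two modes mirror the two biological settings:

* ``cleft`` - one pachytene/early-diplotene oocyte per ROI; a single
  centrosome (the largest component if several qualify) seeds spheres of
  4.8 / 6.0 um, capturing in-cleft vs non-cleft cytoplasm.
* ``nest`` - a whole zygotene nest per ROI, measured in bulk; every detected
  centrosome seeds spheres of 1.2 / 2.4 um.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .centrosomes import Centrosome, detect_centrosomes
from .config import AnalysisConfig
from .errors import EmptyInputError
from .roi import RoiUnit, rasterize_unit
from .segmentation import RegionMasks, segment
from .stack import VolumeStack

logger = logging.getLogger(__name__)

#: QC flags attached to per-unit results.
QC_NO_CENTROSOME = "no_centrosome"
QC_MULTIPLE_CENTROSOMES = "multiple_centrosomes"
QC_UNDEFINED_FOLD = "undefined_fold"
QC_BORDER_TOUCHING = "border_touching"
QC_EMPTY_REGION = "empty_region"
QC_NEGATIVE_NORM = "negative_normalized_intensity"
QC_KIND_MISMATCH = "unit_kind_mismatch"


@dataclass
class RegionPartition:
    """Disjoint distance-based split of the cytoplasm."""

    adjacent: np.ndarray
    shell: np.ndarray
    nonadjacent: np.ndarray
    centers_used: list[tuple[float, float, float]]
    r_adjacent: float
    r_nonadjacent: float


@dataclass
class EnrichmentResult:
    """Per-unit regional means and fold enrichment."""

    unit_id: str
    mode: str
    n_centrosomes: int = 0
    mean_nuclear: float | None = None
    mean_adjacent: float | None = None
    mean_nonadjacent: float | None = None
    norm_adjacent: float | None = None
    norm_nonadjacent: float | None = None
    fold: float | None = None
    qc_flags: set[str] = field(default_factory=set)

    @property
    def ok(self) -> bool:
        return self.fold is not None


def min_distance_field(
    grid_shape: tuple[int, int, int],
    centers: list[tuple[float, float, float]],
    voxel_size: tuple[float, float, float],
) -> np.ndarray:
    """Per-voxel minimum physical distance (um) from voxel centers to any point."""
    dz, dy, dx = voxel_size
    zz = np.arange(grid_shape[0])[:, None, None] * dz
    yy = np.arange(grid_shape[1])[None, :, None] * dy
    xx = np.arange(grid_shape[2])[None, None, :] * dx
    dmin = None
    for cz, cy, cx in centers:
        d2 = (zz - cz) ** 2 + (yy - cy) ** 2 + (xx - cx) ** 2
        dmin = d2 if dmin is None else np.minimum(dmin, d2)
    return np.sqrt(dmin)


def partition_cytoplasm(
    cytoplasm: np.ndarray,
    centers: list[tuple[float, float, float]],
    r_adjacent: float,
    r_nonadjacent: float,
    voxel_size: tuple[float, float, float],
) -> RegionPartition:
    """Classify every cytoplasmic voxel by its distance to the nearest center.

    adjacent: d <= r_adjacent; nonadjacent: d > r_nonadjacent; the shell in
    between is retained but belongs to neither measured region.
    """
    if not centers:
        raise EmptyInputError("partition requires at least one centrosome center")
    if not r_adjacent < r_nonadjacent:
        raise ValueError("r_adjacent must be < r_nonadjacent")
    d = min_distance_field(cytoplasm.shape, centers, voxel_size)
    adjacent = cytoplasm & (d <= r_adjacent)
    nonadjacent = cytoplasm & (d > r_nonadjacent)
    shell = cytoplasm & ~adjacent & ~nonadjacent
    return RegionPartition(
        adjacent=adjacent,
        shell=shell,
        nonadjacent=nonadjacent,
        centers_used=list(centers),
        r_adjacent=r_adjacent,
        r_nonadjacent=r_nonadjacent,
    )


def regional_means(
    experimental: np.ndarray, masks: RegionMasks, partition: RegionPartition
) -> tuple[float, float, float]:
    """Mean raw intensity over (nuclear, adjacent, nonadjacent) regions."""
    for name, region in (
        ("nuclear", masks.nuclear),
        ("adjacent", partition.adjacent),
        ("nonadjacent", partition.nonadjacent),
    ):
        if not region.any():
            raise EmptyInputError(f"{name} region is empty")
    return (
        float(experimental[masks.nuclear].mean()),
        float(experimental[partition.adjacent].mean()),
        float(experimental[partition.nonadjacent].mean()),
    )


def fold_enrichment(
    mean_adjacent: float, mean_nonadjacent: float, mean_nuclear: float
) -> float | None:
    """(adjacent - nuclear) / (nonadjacent - nuclear); None if denominator <= 0."""
    denom = mean_nonadjacent - mean_nuclear
    if denom <= 0:
        return None
    return (mean_adjacent - mean_nuclear) / denom


def _analyze(
    stack: VolumeStack, unit: RoiUnit, config: AnalysisConfig
) -> EnrichmentResult:
    result = EnrichmentResult(unit_id=unit.name, mode=config.mode)
    roi_mask = rasterize_unit(unit, stack.shape)
    masks = segment(stack, roi_mask, config.t_dapi, config.t_tub_low)
    found = detect_centrosomes(
        stack.channel("gamma_tubulin"),
        roi_mask,
        config.t_tub_min,
        min_voxels=config.min_centrosome_voxels,
        voxel_size=stack.voxel_size,
        connectivity=config.connectivity,
    )
    result.n_centrosomes = len(found)
    if not found:
        result.qc_flags.add(QC_NO_CENTROSOME)
        logger.warning("unit %s: no centrosome detected; unit skipped", unit.name)
        return result
    if any(c.touches_border for c in found):
        result.qc_flags.add(QC_BORDER_TOUCHING)

    if config.mode == "cleft":
        if len(found) > 1:
            result.qc_flags.add(QC_MULTIPLE_CENTROSOMES)
            logger.warning(
                "unit %s: %d centrosomes detected in cleft mode; using the largest",
                unit.name,
                len(found),
            )
        centers = [found[0].center_um]
    else:
        centers = [c.center_um for c in found]

    partition = partition_cytoplasm(
        masks.cytoplasm, centers, config.r_adjacent, config.r_nonadjacent, stack.voxel_size
    )
    try:
        mn, ma, mna = regional_means(stack.channel("experimental"), masks, partition)
    except EmptyInputError:
        result.qc_flags.add(QC_EMPTY_REGION)
        logger.warning("unit %s: an analysis region is empty; unit skipped", unit.name)
        return result

    result.mean_nuclear, result.mean_adjacent, result.mean_nonadjacent = mn, ma, mna
    result.norm_adjacent = ma - mn
    result.norm_nonadjacent = mna - mn
    if result.norm_adjacent < 0 or result.norm_nonadjacent < 0:
        result.qc_flags.add(QC_NEGATIVE_NORM)
    result.fold = fold_enrichment(ma, mna, mn)
    if result.fold is None:
        result.qc_flags.add(QC_UNDEFINED_FOLD)
    return result


def analyze_cleft(stack: VolumeStack, unit: RoiUnit, config: AnalysisConfig) -> EnrichmentResult:
    """Single-oocyte cleft analysis (one centrosome, 4.8 / 6.0 um spheres)."""
    if config.mode != "cleft":
        raise ValueError("analyze_cleft requires config.mode == 'cleft'")
    return _analyze(stack, unit, config)


def analyze_nest(stack: VolumeStack, unit: RoiUnit, config: AnalysisConfig) -> EnrichmentResult:
    """Bulk nest analysis (all centrosomes seed spheres, 1.2 / 2.4 um)."""
    if config.mode != "nest":
        raise ValueError("analyze_nest requires config.mode == 'nest'")
    return _analyze(stack, unit, config)


def group_fold(results: list[EnrichmentResult]) -> float:
    """Average fold enrichment over units with a defined fold."""
    folds = [r.fold for r in results if r.fold is not None]
    if not folds:
        raise EmptyInputError("no unit has a defined fold")
    return float(np.mean(folds))
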