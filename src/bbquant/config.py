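"""Run configuration for the cleft / nest enrichment analyses."""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

from .errors import ConfigurationError

#: Default sphere radii (inner, outer) in micrometres per analysis mode.
#: Cleft mode measures single pachytene/early-diplotene oocytes (17-25 um);
#: nest mode measures whole zygotene nests of ~12 um cells in bulk.
MODE_RADII = {"cleft": (4.8, 6.0), "nest": (1.2, 2.4)}


@dataclass
class AnalysisConfig:
    """Thresholds, radii and options for one analysis run.

    Attributes
    ----------
    mode:
        ``"cleft"`` (single oocyte, one centrosome) or ``"nest"`` (bulk
        cytoplasm, all centrosomes seed spheres).
    t_dapi:
        Minimum DAPI intensity for a voxel to count as nuclear.
    t_tub_low:
        Maximum gamma-tubulin intensity for a nuclear voxel (cytoplasmic
        background staining is absent from the nucleus).
    t_tub_min:
        Minimum gamma-tubulin intensity for centrosome voxels; must exceed
        ``t_tub_low``.
    min_centrosome_voxels:
        Minimum connected-component size for a centrosome (default 8).
    r_adjacent, r_nonadjacent:
        Sphere radii in micrometres; ``None`` selects the mode defaults
        (4.8 / 6.0 for cleft, 1.2 / 2.4 for nest).
    connectivity:
        3-D voxel connectivity for component labelling (6, 18 or 26).
    """

    mode: str
    t_dapi: float
    t_tub_low: float
    t_tub_min: float
    min_centrosome_voxels: int = 8
    r_adjacent: float | None = None
    r_nonadjacent: float | None = None
    connectivity: int = 26
    rng_seed: int = 0
    threshold_method: str = "manual"

    def __post_init__(self) -> None:
        if self.mode not in MODE_RADII:
            raise ConfigurationError(f"mode must be one of {sorted(MODE_RADII)}, got {self.mode!r}")
        if self.r_adjacent is None:
            self.r_adjacent = MODE_RADII[self.mode][0]
        if self.r_nonadjacent is None:
            self.r_nonadjacent = MODE_RADII[self.mode][1]
        if not self.r_adjacent < self.r_nonadjacent:
            raise ConfigurationError(
                f"r_adjacent ({self.r_adjacent}) must be < r_nonadjacent ({self.r_nonadjacent})"
            )
        if self.min_centrosome_voxels < 1:
            raise ConfigurationError("min_centrosome_voxels must be >= 1")
        if self.t_tub_min <= self.t_tub_low:
            raise ConfigurationError(
                "centrosome threshold t_tub_min must exceed the nuclear-exclusion "
                "background threshold t_tub_low"
            )
        if self.connectivity not in (6, 18, 26):
            raise ConfigurationError("connectivity must be 6, 18 or 26")
        if self.threshold_method not in ("manual", "automatic"):
            raise ConfigurationError("threshold_method must be 'manual' or 'automatic'")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        return cls(**d)

    @classmethod
    def from_json(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))
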