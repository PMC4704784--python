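"""Synthetic ovary image generator with known ground truth.

Renders multi-channel 3-D stacks that emulate confocal acquisitions of early
zebrafish oocytes, so that every stage of the measurement pipeline can be
verified against a generative truth:

* ``oocyte_cleft`` - one pachytene/early-diplotene oocyte (17-25 um
  diameter, default 20): spherical cell, DAPI-positive nucleus with a
  spherical-cap indentation (the nuclear cleft), a compact gamma-tubulin
  punctum in the cleft pocket, and an experimental channel enriched around
  the punctum by a known factor.
* ``uniform_control`` - same geometry, enrichment factor forced to 1.
* ``nest`` - a tightly packed nest of mid-zygotene cells (~12 um), each with
  a spherical nucleus and one perinuclear centrosome; the experimental
  channel is enriched around every punctum; one ROI encloses the whole nest
  and the interstitial space is rendered as bulk cytoplasm, mirroring nests
  in which cell boundaries are invisible and cytoplasm is measured in bulk.
* ``dispersed_control`` - a nest whose experimental channel is spatially
  uniform over the cytoplasm (microtubule-depolymerized-like dispersion).

The enrichment field around a centrosome center at distance ``d`` is

    I(d) = offset + base * (1 + (factor - 1) * G(d)),
    G(d) = exp(-max(0, d - r_core)^2 / (2 * sigma^2))

i.e. a flat core of radius ``r_core`` (matching the analysis inner sphere)
with a Gaussian shoulder of scale ``sigma``.  With this shape the generative
``factor`` is exactly the contrast between core and far-field cytoplasm, so
the measured fold has a well-defined truth to recover; a soft shoulder still
exercises the buffer shell.  The nuclear experimental intensity equals the
cytoplasmic ``offset``, matching the role of the nuclear mean as a
background estimate.

Noise model: per-voxel Poisson (shot noise) followed by additive Gaussian
read noise, then 12-bit clipping and quantization.  All randomness comes
from a single ``numpy`` Generator seeded per stack, with draws in a fixed,
documented order (geometry first, then noise per channel in the order
experimental, gamma_tubulin, dapi), so stacks are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import shapely
from shapely.geometry import MultiPoint

from .config import AnalysisConfig
from .errors import ConfigurationError
from .roi import RoiSet, RoiUnit
from .stack import VolumeStack

MODES = ("oocyte_cleft", "uniform_control", "nest", "dispersed_control")

#: Enrichment-field geometry defaults per analysis scale (um).
_CORE_RADIUS = {"cleft": 4.8, "nest": 1.2}
_SHOULDER_SIGMA = {"cleft": 0.6, "nest": 0.4}

#: Analysis thresholds appropriate for the default rendering intensities.
DEFAULT_THRESHOLDS = {"t_dapi": 700.0, "t_tub_low": 45.0, "t_tub_min": 1000.0}


def default_config(mode: str, **overrides) -> AnalysisConfig:
    """An :class:`AnalysisConfig` matched to the generator's intensity scales."""
    kwargs = dict(mode=mode, **DEFAULT_THRESHOLDS)
    kwargs.update(overrides)
    return AnalysisConfig(**kwargs)


@dataclass
class SyntheticSpec:
    """Rendering parameters; defaults are the stage-appropriate conditions.

    ``cell_diameter_um`` defaults to 20 (cleft-stage oocytes span 17-25 um)
    for single-oocyte modes and 12 (mid-zygotene) for nest modes.
    """

    mode: str = "oocyte_cleft"
    n_cells: int = 1
    cell_diameter_um: float | None = None
    nucleus_fraction: float = 0.45
    cleft_depth_um: float = 3.0
    enrichment_factor: float = 2.0
    enrichment_radius_um: float | None = None
    enrichment_sigma_um: float | None = None
    base_intensity: float = 300.0
    offset_intensity: float = 40.0
    punctum_intensity: float = 3000.0
    punctum_radius_um: float = 0.6
    dapi_intensity: float = 2200.0
    dapi_cytoplasm: float = 30.0
    tub_background: float = 90.0
    tub_nuclear: float = 10.0
    exterior_intensity: float = 5.0
    noise_poisson: bool = True
    noise_gaussian_sd: float = 6.0
    voxel_size: tuple[float, float, float] = (0.53, 0.25, 0.25)
    bit_depth: int = 12
    n_missing_centrosomes: int = 0
    follicle_cells: int = 0

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ConfigurationError(f"mode must be one of {MODES}, got {self.mode!r}")
        scale = "nest" if self.is_nest else "cleft"
        if self.cell_diameter_um is None:
            self.cell_diameter_um = 12.0 if self.is_nest else 20.0
        if self.enrichment_radius_um is None:
            self.enrichment_radius_um = _CORE_RADIUS[scale]
        if self.enrichment_sigma_um is None:
            self.enrichment_sigma_um = _SHOULDER_SIGMA[scale]
        if self.cell_diameter_um <= 0:
            raise ConfigurationError("cell_diameter_um must be positive")
        if self.enrichment_factor < 0:
            raise ConfigurationError("enrichment_factor must be >= 0")
        if self.is_nest and self.n_cells < 2:
            raise ConfigurationError("nest modes require n_cells >= 2")
        if self.voxel_size[1] != self.voxel_size[2]:
            raise ConfigurationError("xy pixels must be square (dy == dx)")

    @property
    def is_nest(self) -> bool:
        return self.mode in ("nest", "dispersed_control")

    @property
    def effective_factor(self) -> float:
        if self.mode in ("uniform_control", "dispersed_control"):
            return 1.0
        return self.enrichment_factor


@dataclass
class CellTruth:
    center_um: tuple[float, float, float]
    radius_um: float
    centrosome_center_um: tuple[float, float, float] | None
    enrichment_factor: float
    has_punctum: bool


@dataclass
class GroundTruth:
    """Generative truth for one rendered stack."""

    cells: list[CellTruth]
    nucleus_labels: np.ndarray  # 0 = background, i = nucleus of cells[i-1]
    clean_experimental: np.ndarray  # pre-noise experimental channel
    enrichment_factor: float


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------

def _coordinate_grids(shape, voxel_size):
    dz, dy, dx = voxel_size
    zz = np.arange(shape[0])[:, None, None] * dz
    yy = np.arange(shape[1])[None, :, None] * dy
    xx = np.arange(shape[2])[None, None, :] * dx
    return zz, yy, xx


def _dist(zz, yy, xx, center):
    cz, cy, cx = center
    return np.sqrt((zz - cz) ** 2 + (yy - cy) ** 2 + (xx - cx) ** 2)


def _circle_polygon(cx_px, cy_px, r_px, n_vertices=64):
    theta = np.linspace(0.0, 2.0 * np.pi, n_vertices, endpoint=False)
    return np.stack([cx_px + r_px * np.cos(theta), cy_px + r_px * np.sin(theta)], axis=1)


def _enrichment_profile(d, factor, r_core, sigma):
    shoulder = np.maximum(d - r_core, 0.0)
    g = np.exp(-(shoulder**2) / (2.0 * sigma**2))
    return 1.0 + (factor - 1.0) * g


def _apply_noise(channels, spec: SyntheticSpec, rng: np.random.Generator):
    """Poisson then Gaussian noise, clip to bit depth, quantize to uint16."""
    out = []
    vmax = 2**spec.bit_depth - 1
    for img in channels:  # fixed order: experimental, gamma_tubulin, dapi
        noisy = img.astype(float)
        if spec.noise_poisson:
            noisy = rng.poisson(np.maximum(noisy, 0.0)).astype(float)
        if spec.noise_gaussian_sd > 0:
            noisy = noisy + rng.normal(0.0, spec.noise_gaussian_sd, size=noisy.shape)
        out.append(np.clip(np.rint(noisy), 0, vmax).astype(np.uint16))
    return out


def _random_unit_vector(rng):
    v = rng.normal(size=3)
    n = np.linalg.norm(v)
    while n < 1e-9:
        v = rng.normal(size=3)
        n = np.linalg.norm(v)
    return v / n


# ---------------------------------------------------------------------------
# single oocyte
# ---------------------------------------------------------------------------

def generate_oocyte(spec: SyntheticSpec, seed: int = 0):
    """Render one cleft-stage oocyte; returns ``(stack, rois, truth)``."""
    if not spec.is_nest and spec.n_cells != 1:
        raise ConfigurationError("single-oocyte modes render exactly one cell")
    if spec.is_nest:
        raise ConfigurationError("use generate_nest for nest modes")
    rng = np.random.default_rng(seed)
    dz, dy, dx = spec.voxel_size
    R = spec.cell_diameter_um / 2.0
    margin = 1.0
    extent = 2 * (R + margin)
    shape = (
        int(np.ceil(extent / dz)) + 1,
        int(np.ceil(extent / dy)) + 1,
        int(np.ceil(extent / dx)) + 1,
    )
    if max(shape) > 512:
        raise ConfigurationError(f"cell of {spec.cell_diameter_um} um needs grid {shape}; too large")
    center = tuple(((n - 1) / 2.0) * s for n, s in zip(shape, spec.voxel_size))
    zz, yy, xx = _coordinate_grids(shape, spec.voxel_size)

    axis = _random_unit_vector(rng)  # cleft / centrosome axis
    cell = _dist(zz, yy, xx, center) <= R
    nuc_r = spec.nucleus_fraction * R
    depth = min(spec.cleft_depth_um, 1.6 * nuc_r)  # keep the indentation a cap
    nucleus = _dist(zz, yy, xx, center) <= nuc_r
    if depth > 0:
        indenter_center = tuple(c + a * (2 * nuc_r - depth) for c, a in zip(center, axis))
        nucleus &= _dist(zz, yy, xx, indenter_center) > nuc_r
        centro_offset = nuc_r - depth / 2.0
    else:
        centro_offset = nuc_r + spec.punctum_radius_um + 0.3
    centrosome = tuple(c + a * centro_offset for c, a in zip(center, axis))

    punctum = (_dist(zz, yy, xx, centrosome) <= spec.punctum_radius_um) & cell & ~nucleus
    cytoplasm = cell & ~nucleus

    factor = spec.effective_factor
    d_centro = _dist(zz, yy, xx, centrosome)
    profile = _enrichment_profile(
        d_centro, factor, spec.enrichment_radius_um, spec.enrichment_sigma_um
    )

    exp = np.full(shape, spec.exterior_intensity)
    exp[cytoplasm] = spec.offset_intensity + spec.base_intensity * profile[cytoplasm]
    exp[nucleus] = spec.offset_intensity
    dapi = np.full(shape, spec.exterior_intensity)
    dapi[cytoplasm] = spec.dapi_cytoplasm
    dapi[nucleus] = spec.dapi_intensity
    tub = np.full(shape, spec.exterior_intensity)
    tub[cytoplasm] = spec.tub_background
    tub[nucleus] = spec.tub_nuclear
    tub[punctum] = spec.punctum_intensity

    clean_exp = exp.copy()
    exp_n, tub_n, dapi_n = _apply_noise([exp, tub, dapi], spec, rng)
    stack = VolumeStack(
        np.stack([exp_n, tub_n, dapi_n]),
        {"experimental": 0, "gamma_tubulin": 1, "dapi": 2},
        spec.voxel_size,
        bit_depth=spec.bit_depth,
    )

    polygons = []
    for z in range(shape[0]):
        h = z * dz - center[0]
        if abs(h) >= R:
            continue
        r_z = np.sqrt(R**2 - h**2)
        if r_z < 3 * dx:
            continue
        polygons.append((z, _circle_polygon(center[2] / dx, center[1] / dy, r_z / dx)))
    rois = RoiSet([RoiUnit(name="oocyte_1", kind="oocyte", polygons=polygons)])

    labels = np.zeros(shape, dtype=np.uint8)
    labels[nucleus] = 1
    truth = GroundTruth(
        cells=[CellTruth(center, R, centrosome, factor, True)],
        nucleus_labels=labels,
        clean_experimental=clean_exp,
        enrichment_factor=factor,
    )
    return stack, rois, truth


# ---------------------------------------------------------------------------
# nest
# ---------------------------------------------------------------------------

def _pack_nest_centers(spec: SyntheticSpec, rng: np.random.Generator):
    """Tightly packed xy positions (two staggered rows) with small jitter."""
    D = spec.cell_diameter_um
    spacing = 0.98 * D
    n = spec.n_cells
    per_row = int(np.ceil(n / 2)) if n > 2 else n
    positions = []
    for attempt in range(50):
        positions = []
        i = 0
        row = 0
        while i < n:
            in_row = min(per_row, n - i)
            x_shift = (spacing / 2.0) * (row % 2)
            for k in range(in_row):
                jitter = rng.uniform(-0.15, 0.15, size=2)
                positions.append(
                    (k * spacing + x_shift + jitter[0], row * spacing * 0.87 + jitter[1])
                )
                i += 1
            row += 1
        pts = np.asarray(positions)
        dists = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
        np.fill_diagonal(dists, np.inf)
        if dists.min() >= 0.9 * D:
            return pts
    raise ConfigurationError("failed to pack nest cells without overlap; try another seed")


def generate_nest(spec: SyntheticSpec, seed: int = 0):
    """Render a packed nest of zygotene cells; returns ``(stack, rois, truth)``."""
    if not spec.is_nest:
        raise ConfigurationError("use generate_oocyte for single-oocyte modes")
    rng = np.random.default_rng(seed)
    dz, dy, dx = spec.voxel_size
    D = spec.cell_diameter_um
    R = D / 2.0
    margin = 1.0

    xy = _pack_nest_centers(spec, rng)
    x0, y0 = xy[:, 0].min() - R - margin, xy[:, 1].min() - R - margin
    x1, y1 = xy[:, 0].max() + R + margin, xy[:, 1].max() + R + margin
    z_extent = D + 2 * margin
    shape = (
        int(np.ceil(z_extent / dz)) + 1,
        int(np.ceil((y1 - y0) / dy)) + 1,
        int(np.ceil((x1 - x0) / dx)) + 1,
    )
    if max(shape) > 1024:
        raise ConfigurationError(f"nest grid {shape} too large")
    cz = ((shape[0] - 1) / 2.0) * dz
    centers = [(cz, y - y0, x - x0) for x, y in xy]  # (z, y, x) in um
    zz, yy, xx = _coordinate_grids(shape, spec.voxel_size)

    # ROI: per-slice convex hull of the cells' circular cross sections.
    polygons = []
    for z in range(shape[0]):
        h = z * dz - cz
        if abs(h) >= R:
            continue
        r_z = np.sqrt(R**2 - h**2)
        if r_z < 3 * dx:
            continue
        pts = []
        for _, cy_um, cx_um in centers:
            circ = _circle_polygon(cx_um / dx, cy_um / dy, r_z / dx, n_vertices=32)
            pts.extend(circ.tolist())
        hull = MultiPoint(pts).convex_hull
        verts = np.asarray(hull.exterior.coords)[:-1]
        polygons.append((z, verts))
    unit = RoiUnit(name="nest_1", kind="nest", polygons=polygons)
    rois = RoiSet([unit])

    from .roi import rasterize_unit  # local import to avoid cycle at module load

    domain = rasterize_unit(unit, shape)

    nuc_r = spec.nucleus_fraction * R
    labels = np.zeros(shape, dtype=np.uint8)
    nuclei = np.zeros(shape, dtype=bool)
    for i, c in enumerate(centers, start=1):
        ball = _dist(zz, yy, xx, c) <= nuc_r
        nuclei |= ball
        labels[ball] = i

    factor = spec.effective_factor
    cells: list[CellTruth] = []
    puncta = np.zeros(shape, dtype=bool)
    centro_centers = []
    for i, c in enumerate(centers):
        has_punctum = i >= spec.n_missing_centrosomes
        centro = _place_perinuclear_centrosome(
            c, nuc_r, spec, rng, domain, nuclei, zz, yy, xx
        )
        if has_punctum:
            puncta |= (_dist(zz, yy, xx, centro) <= spec.punctum_radius_um) & domain & ~nuclei
        centro_centers.append(centro)
        cells.append(CellTruth(tuple(c), R, tuple(centro), factor, has_punctum))

    cytoplasm = domain & ~nuclei
    if factor != 1.0:
        dmin = None
        for centro in centro_centers:
            d = _dist(zz, yy, xx, centro)
            dmin = d if dmin is None else np.minimum(dmin, d)
        profile = _enrichment_profile(
            dmin, factor, spec.enrichment_radius_um, spec.enrichment_sigma_um
        )
    else:
        profile = np.ones(shape)

    exp = np.full(shape, spec.exterior_intensity)
    exp[cytoplasm] = spec.offset_intensity + spec.base_intensity * profile[cytoplasm]
    exp[nuclei] = spec.offset_intensity
    dapi = np.full(shape, spec.exterior_intensity)
    dapi[cytoplasm] = spec.dapi_cytoplasm
    dapi[nuclei] = spec.dapi_intensity
    tub = np.full(shape, spec.exterior_intensity)
    tub[cytoplasm] = spec.tub_background
    tub[nuclei] = spec.tub_nuclear
    tub[puncta] = spec.punctum_intensity

    if spec.follicle_cells:
        _add_follicle_nuclei(dapi, spec, rng, domain, zz, yy, xx, centers, R)

    clean_exp = exp.copy()
    exp_n, tub_n, dapi_n = _apply_noise([exp, tub, dapi], spec, rng)
    stack = VolumeStack(
        np.stack([exp_n, tub_n, dapi_n]),
        {"experimental": 0, "gamma_tubulin": 1, "dapi": 2},
        spec.voxel_size,
        bit_depth=spec.bit_depth,
    )
    truth = GroundTruth(
        cells=cells,
        nucleus_labels=labels,
        clean_experimental=clean_exp,
        enrichment_factor=factor,
    )
    return stack, rois, truth


def _place_perinuclear_centrosome(cell_center, nuc_r, spec, rng, domain, nuclei, zz, yy, xx):
    """A punctum center just outside the nucleus, fully inside the nest domain."""
    gap = 0.8
    r_p = spec.punctum_radius_um
    for _ in range(20):
        u = _random_unit_vector(rng)
        cand = tuple(c + ui * (nuc_r + gap) for c, ui in zip(cell_center, u))
        if _ball_ok(cand, r_p, domain, nuclei, spec.voxel_size):
            return cand
    # fall back to an in-plane direction toward the domain interior
    u = np.array([0.0, 0.0, 1.0])
    return tuple(c + ui * (nuc_r + gap) for c, ui in zip(cell_center, u))


def _ball_ok(center, radius, domain, nuclei, voxel_size):
    dz, dy, dx = voxel_size
    z0 = int(round(center[0] / dz))
    y0 = int(round(center[1] / dy))
    x0 = int(round(center[2] / dx))
    rz, ry, rx = int(np.ceil(radius / dz)) + 1, int(np.ceil(radius / dy)) + 1, int(np.ceil(radius / dx)) + 1
    sl = (
        slice(max(z0 - rz, 0), z0 + rz + 1),
        slice(max(y0 - ry, 0), y0 + ry + 1),
        slice(max(x0 - rx, 0), x0 + rx + 1),
    )
    box_d = domain[sl]
    box_n = nuclei[sl]
    if box_d.size == 0:
        return False
    zzb = (np.arange(sl[0].start, sl[0].start + box_d.shape[0])[:, None, None]) * dz
    yyb = (np.arange(sl[1].start, sl[1].start + box_d.shape[1])[None, :, None]) * dy
    xxb = (np.arange(sl[2].start, sl[2].start + box_d.shape[2])[None, None, :]) * dx
    ball = (
        (zzb - center[0]) ** 2 + (yyb - center[1]) ** 2 + (xxb - center[2]) ** 2
    ) <= radius**2
    if not ball.any():
        return False
    return bool(np.all(box_d[ball]) and not np.any(box_n[ball]))


def _add_follicle_nuclei(dapi, spec, rng, domain, zz, yy, xx, centers, R):
    """Small DAPI-only somatic nuclei scattered at the nest periphery."""
    ys = [c[1] for c in centers]
    xs = [c[2] for c in centers]
    cz = centers[0][0]
    cy, cx = float(np.mean(ys)), float(np.mean(xs))
    for _ in range(spec.follicle_cells):
        theta = rng.uniform(0, 2 * np.pi)
        rad = max(np.ptp(xs), np.ptp(ys)) / 2 + R + 1.5
        pos = (cz + rng.uniform(-2, 2), cy + rad * np.sin(theta), cx + rad * np.cos(theta))
        ball = _dist(zz, yy, xx, pos) <= 1.5
        dapi[ball & ~domain] = spec.dapi_intensity


# ---------------------------------------------------------------------------
# colocalization test pairs
# ---------------------------------------------------------------------------

def generate_coloc_pair(
    overlap_fraction: float,
    n_puncta: int = 40,
    size: int = 128,
    spot_sigma_px: float = 1.8,
    amplitude: float = 800.0,
    offset: float = 20.0,
    noise_sd: float = 4.0,
    seed: int = 0,
):
    """Two punctate 2-D channels sharing a fraction of their spot positions.

    Returns ``(ch1, ch2, mask, truth)`` where ``mask`` is a circular
    analysis region and ``truth`` records the spot positions.  Non-shared
    spots of the second channel are kept at least 5 sigma away from every
    first-channel spot so that ``overlap_fraction = 0`` yields genuinely
    disjoint signals.
    """
    if not 0.0 <= overlap_fraction <= 1.0:
        raise ValueError("overlap_fraction must be within [0, 1]")
    rng = np.random.default_rng(seed)
    yy, xx = np.mgrid[0:size, 0:size]
    center = (size - 1) / 2.0
    mask = (yy - center) ** 2 + (xx - center) ** 2 <= (0.45 * size) ** 2

    def sample_position():
        while True:
            p = rng.uniform(0.1 * size, 0.9 * size, size=2)
            if mask[int(p[0]), int(p[1])]:
                return p

    pos1 = np.array([sample_position() for _ in range(n_puncta)])
    n_shared = int(round(overlap_fraction * n_puncta))
    pos2 = list(pos1[:n_shared])
    min_sep = 5.0 * spot_sigma_px
    while len(pos2) < n_puncta:
        p = sample_position()
        if np.all(np.sqrt(((pos1 - p) ** 2).sum(1)) >= min_sep):
            pos2.append(p)
    pos2 = np.asarray(pos2)

    def render(positions):
        img = np.full((size, size), offset)
        for py, px in positions:
            img += amplitude * np.exp(
                -((yy - py) ** 2 + (xx - px) ** 2) / (2 * spot_sigma_px**2)
            )
        img = img + rng.normal(0.0, noise_sd, size=img.shape)
        return np.clip(np.rint(img), 0, 4095).astype(np.uint16)

    ch1 = render(pos1)
    ch2 = render(pos2)
    truth = {"positions_1": pos1, "positions_2": pos2, "n_shared": n_shared}
    return ch1, ch2, mask, truth
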