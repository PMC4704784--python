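"""Independent brute-force oracles for the core voxel operations.

Everything here is deliberately naive (pure-Python loops, exhaustive
enumeration, math.fsum) and shares no code with the package implementation,
so agreement is meaningful.
"""

from __future__ import annotations

import math
from collections import deque

import numpy as np


def point_in_polygon(x: float, y: float, verts) -> bool:
    """Even-odd ray-crossing test."""
    inside = False
    n = len(verts)
    j = n - 1
    for i in range(n):
        xi, yi = verts[i]
        xj, yj = verts[j]
        if (yi > y) != (yj > y) and x < (xj - xi) * (y - yi) / (yj - yi) + xi:
            inside = not inside
        j = i
    return inside


def rasterize_oracle(polygons, grid_shape):
    """Per-voxel even-odd rasterization of (slice, vertices) polygons."""
    mask = np.zeros(grid_shape, dtype=bool)
    for z, verts in polygons:
        for y in range(grid_shape[1]):
            for x in range(grid_shape[2]):
                if point_in_polygon(float(x), float(y), verts):
                    mask[z, y, x] = True
    return mask


def nuclear_mask_oracle(dapi, tub, roi, t_dapi, t_tub_low):
    out = np.zeros(roi.shape, dtype=bool)
    for idx in np.ndindex(roi.shape):
        out[idx] = bool(roi[idx]) and dapi[idx] >= t_dapi and tub[idx] < t_tub_low
    return out


def _neighbors(connectivity):
    offs = []
    for dz in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                if (dz, dy, dx) == (0, 0, 0):
                    continue
                order = abs(dz) + abs(dy) + abs(dx)
                if connectivity == 6 and order > 1:
                    continue
                if connectivity == 18 and order > 2:
                    continue
                offs.append((dz, dy, dx))
    return offs


def flood_fill_components(mask, connectivity=26):
    """Connected components by BFS flood fill; returns list of voxel-index sets."""
    offs = _neighbors(connectivity)
    seen = np.zeros(mask.shape, dtype=bool)
    comps = []
    for start in np.ndindex(mask.shape):
        if not mask[start] or seen[start]:
            continue
        comp = set()
        queue = deque([start])
        seen[start] = True
        while queue:
            z, y, x = queue.popleft()
            comp.add((z, y, x))
            for dz, dy, dx in offs:
                nz, ny, nx = z + dz, y + dy, x + dx
                if (
                    0 <= nz < mask.shape[0]
                    and 0 <= ny < mask.shape[1]
                    and 0 <= nx < mask.shape[2]
                    and mask[nz, ny, nx]
                    and not seen[nz, ny, nx]
                ):
                    seen[nz, ny, nx] = True
                    queue.append((nz, ny, nx))
        comps.append(frozenset(comp))
    return comps


def edt_oracle(mask, voxel_size):
    """Exhaustive Euclidean distance transform: per foreground voxel, the
    minimum physical distance to any background voxel (in a 1-voxel pad)."""
    dz, dy, dx = voxel_size
    padded = np.pad(mask, 1)
    bg = [tuple(i) for i in np.argwhere(~padded)]
    out = np.zeros(padded.shape)
    for idx in np.argwhere(padded):
        z, y, x = idx
        out[z, y, x] = min(
            math.sqrt(((z - bz) * dz) ** 2 + ((y - by) * dy) ** 2 + ((x - bx) * dx) ** 2)
            for bz, by, bx in bg
        )
    return out  # padded by 1 on each side


def regional_maxima_oracle(values, support):
    """Regional maxima of ``values`` over ``support``: connected equal-value
    plateaus (26-connectivity) with no strictly greater 26-neighbor."""
    offs = _neighbors(26)
    shape = values.shape
    maxima = np.zeros(shape, dtype=bool)
    seen = np.zeros(shape, dtype=bool)
    for start in np.ndindex(shape):
        if not support[start] or seen[start]:
            continue
        level = values[start]
        plateau = []
        is_max = True
        queue = deque([start])
        seen[start] = True
        while queue:
            z, y, x = queue.popleft()
            plateau.append((z, y, x))
            for dz, dy, dx in offs:
                nz, ny, nx = z + dz, y + dy, x + dx
                if not (0 <= nz < shape[0] and 0 <= ny < shape[1] and 0 <= nx < shape[2]):
                    continue
                v = values[nz, ny, nx]
                if v > level:
                    is_max = False
                elif v == level and support[nz, ny, nx] and not seen[nz, ny, nx]:
                    seen[nz, ny, nx] = True
                    queue.append((nz, ny, nx))
        if is_max:
            for p in plateau:
                maxima[p] = True
    return maxima


def partition_oracle(cytoplasm, centers, r_adj, r_non, voxel_size):
    dz, dy, dx = voxel_size
    adj = np.zeros(cytoplasm.shape, dtype=bool)
    shell = np.zeros(cytoplasm.shape, dtype=bool)
    non = np.zeros(cytoplasm.shape, dtype=bool)
    for idx in np.argwhere(cytoplasm):
        z, y, x = idx
        d = min(
            math.sqrt((z * dz - cz) ** 2 + (y * dy - cy) ** 2 + (x * dx - cx) ** 2)
            for cz, cy, cx in centers
        )
        if d <= r_adj:
            adj[z, y, x] = True
        elif d > r_non:
            non[z, y, x] = True
        else:
            shell[z, y, x] = True
    return adj, shell, non


def pearson_oracle(ch1, ch2, mask):
    a = [float(v) for v in np.asarray(ch1)[mask]]
    b = [float(v) for v in np.asarray(ch2)[mask]]
    n = len(a)
    ma = math.fsum(a) / n
    mb = math.fsum(b) / n
    cov = math.fsum((x - ma) * (y - mb) for x, y in zip(a, b))
    va = math.fsum((x - ma) ** 2 for x in a)
    vb = math.fsum((y - mb) ** 2 for y in b)
    return cov / math.sqrt(va * vb)


def manders_oracle(ch1, ch2, mask, t1, t2):
    a = np.asarray(ch1, dtype=float)[mask]
    b = np.asarray(ch2, dtype=float)[mask]
    num1 = math.fsum(x for x, y in zip(a, b) if x > t1 and y > t2)
    den1 = math.fsum(x for x in a if x > t1)
    num2 = math.fsum(y for x, y in zip(a, b) if x > t1 and y > t2)
    den2 = math.fsum(y for y in b if y > t2)
    return num1 / den1, num2 / den2


def mean_oracle(values) -> float:
    values = [float(v) for v in values]
    return math.fsum(values) / len(values)
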