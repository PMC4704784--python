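"""Multi-channel 3-D image stacks with physical voxel geometry.

A :class:`VolumeStack` holds one intensity grid per fluorescence channel,
indexed by *role* (``experimental``, ``gamma_tubulin``, ``dapi``, ...) so the
analysis code never hard-codes channel order.  Voxel size is carried as
``(dz, dy, dx)`` metadata in micrometres and honoured by every
physical-distance computation downstream; nothing is ever resampled, because
voxel *counts* (e.g. the >=8-voxel centrosome rule) must stay meaningful on
the acquired grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import tifffile

from .errors import ConfigurationError, FormatError

#: Channel roles with dedicated semantics in the pipeline.
KNOWN_ROLES = ("experimental", "gamma_tubulin", "dapi")


@dataclass
class VolumeStack:
    """A multi-channel 3-D intensity volume.

    Parameters
    ----------
    data:
        Array of shape ``(C, Z, Y, X)`` with non-negative integer intensities.
    channel_roles:
        Mapping from role name to channel index.
    voxel_size:
        Physical voxel dimensions ``(dz, dy, dx)`` in micrometres.
    bit_depth:
        Acquisition bit depth; intensities must fit in ``[0, 2**bit_depth - 1]``.
    """

    data: np.ndarray
    channel_roles: dict[str, int]
    voxel_size: tuple[float, float, float]
    bit_depth: int = 12

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise FormatError(f"expected (C, Z, Y, X) data, got shape {self.data.shape}")
        n_channels = self.data.shape[0]
        for role, idx in self.channel_roles.items():
            if not 0 <= idx < n_channels:
                raise ConfigurationError(
                    f"role {role!r} maps to channel {idx}, but the stack has "
                    f"{n_channels} channel(s)"
                )
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise ConfigurationError(f"voxel_size must be 3 positive values, got {self.voxel_size}")
        if self.data.min() < 0 or self.data.max() > 2**self.bit_depth - 1:
            raise FormatError(
                f"intensities outside [0, {2**self.bit_depth - 1}] for bit depth {self.bit_depth}"
            )

    @property
    def shape(self) -> tuple[int, int, int]:
        """Grid shape ``(Z, Y, X)`` shared by all channels."""
        return self.data.shape[1:]

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    def channel(self, role: str) -> np.ndarray:
        """Return the 3-D intensity grid for a channel role."""
        try:
            return self.data[self.channel_roles[role]]
        except KeyError:
            raise ConfigurationError(
                f"stack has no channel with role {role!r}; available: "
                f"{sorted(self.channel_roles)}"
            ) from None


def save_stack(stack: VolumeStack, path) -> None:
    """Write a stack as an ImageJ-style ZCYX hyperstack TIFF.

    Voxel size is stored in the ImageJ ``spacing`` metadata (z) and the TIFF
    resolution tags (x, y) so that :func:`load_stack` round-trips it.
    """
    dz, dy, dx = stack.voxel_size
    data = np.ascontiguousarray(np.moveaxis(stack.data, 0, 1))  # (Z, C, Y, X)
    tifffile.imwrite(
        path,
        data.astype(np.uint16),
        imagej=True,
        resolution=(1.0 / dx, 1.0 / dy),
        metadata={"axes": "ZCYX", "spacing": dz, "unit": "um"},
    )


def load_stack(
    path,
    channel_roles: dict[str, int],
    voxel_size: tuple[float, float, float] | None = None,
    bit_depth: int = 12,
) -> VolumeStack:
    """Read a multi-channel TIFF into a :class:`VolumeStack`.

    Accepts ImageJ hyperstacks (any permutation of ``CZYX`` axes) and bare
    3-D/2-D TIFFs.  For a bare 3-D file the leading axis is interpreted as
    channels when the number of requested roles matches it, otherwise as z
    with a single channel.  ``voxel_size`` overrides any metadata; if omitted
    it is recovered from ImageJ spacing + resolution tags.
    """
    with tifffile.TiffFile(path) as tif:
        series = tif.series[0]
        arr = series.asarray()
        axes = series.axes  # e.g. 'ZCYX', 'CYX', 'ZYX', 'YX'
        meta_voxel = _voxel_size_from_metadata(tif)

    axes = axes.replace("S", "C").replace("Q", "Z").replace("I", "Z")
    if set(axes) - set("CZYX"):
        raise FormatError(f"unsupported TIFF axes {axes!r}")
    if arr.ndim == 2:
        arr = arr[None, None]
    elif arr.ndim == 3:
        if "C" in axes:
            arr = arr[:, None]  # (C, 1, Y, X)
        elif len(channel_roles) > 1:
            if arr.shape[0] == len(channel_roles):
                arr = arr[:, None]
            else:
                raise ConfigurationError(
                    f"{len(channel_roles)} channel roles requested but the file "
                    f"has {arr.shape[0]} page(s) and no channel axis"
                )
        else:
            arr = arr[None]  # (1, Z, Y, X)
    elif arr.ndim == 4:
        order = [axes.index(a) for a in "CZYX"]
        arr = np.transpose(arr, order)
    else:
        raise FormatError(f"cannot interpret TIFF with {arr.ndim} dimensions")

    if voxel_size is None:
        if meta_voxel is None:
            raise ConfigurationError(
                "voxel_size not given and not recoverable from TIFF metadata"
            )
        voxel_size = meta_voxel
    return VolumeStack(arr, dict(channel_roles), voxel_size, bit_depth=bit_depth)


def _voxel_size_from_metadata(tif: tifffile.TiffFile):
    meta = tif.imagej_metadata or {}
    dz = meta.get("spacing")
    page = tif.pages[0]
    xres = page.tags.get("XResolution")
    yres = page.tags.get("YResolution")
    if dz is None or xres is None or yres is None:
        return None
    xr = xres.value[0] / xres.value[1]
    yr = yres.value[0] / yres.value[1]
    if xr <= 0 or yr <= 0:
        return None
    return (float(dz), 1.0 / yr, 1.0 / xr)
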