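"""Confocal z-stack container and TIFF round-trip.

A stack is a single-channel voxel grid with the Z (optical section) axis
leading, plus the two physical scales every downstream measurement needs:
the XY pixel size and the Z section thickness, both in micrometres.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile

__all__ = ["ConfocalStack", "read_stack", "write_stack"]

#: XY pixel size (µm) of the study's standardized confocal zoom.
DEFAULT_PIXEL_SIZE_XY = 0.054
#: Z section thickness (µm); a typical confocal step for whole-oocyte karyosomes.
DEFAULT_SECTION_THICKNESS_Z = 0.5


@dataclass
class ConfocalStack:
    """Single-channel 3D intensity grid (sections x rows x cols)."""

    data: np.ndarray
    pixel_size_xy: float = DEFAULT_PIXEL_SIZE_XY
    section_thickness_z: float = DEFAULT_SECTION_THICKNESS_Z

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(
                f"stack must be 3D (sections, rows, cols); got shape {self.data.shape}"
            )
        if min(self.data.shape) < 1:
            raise ValueError(f"all stack dimensions must be >= 1; got {self.data.shape}")
        if self.pixel_size_xy <= 0:
            raise ValueError("pixel_size_xy must be > 0")
        if self.section_thickness_z <= 0:
            raise ValueError("section_thickness_z must be > 0")

    @property
    def n_sections(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_diagonal(self) -> float:
        """Length (µm) of one voxel's space diagonal — the natural localization scale."""
        return float(
            np.sqrt(2 * self.pixel_size_xy**2 + self.section_thickness_z**2)
        )


def write_stack(path: str | Path, stack: ConfocalStack) -> Path:
    """Write a stack as a multi-page grayscale TIFF (16-bit unsigned).

    The physical scales are stored in the TIFF ImageDescription as JSON so
    a later :func:`read_stack` recovers them without external config.
    Intensities are rounded and clipped into the uint16 range.
    """
    path = Path(path)
    data = np.clip(np.rint(stack.data), 0, np.iinfo(np.uint16).max).astype(np.uint16)
    meta = {
        "pixel_size_xy_um": stack.pixel_size_xy,
        "section_thickness_z_um": stack.section_thickness_z,
        "axes": "ZYX",
    }
    tifffile.imwrite(path, data, photometric="minisblack", description=json.dumps(meta))
    return path


def read_stack(
    path: str | Path,
    pixel_size_xy: float | None = None,
    section_thickness_z: float | None = None,
) -> ConfocalStack:
    """Read a single-channel multi-page TIFF into a :class:`ConfocalStack`.

    Scales are taken from the arguments when given, else from the JSON
    metadata written by :func:`write_stack`, else from the package defaults.

    Raises
    ------
    FileNotFoundError
        If ``path`` does not exist.
    ValueError
        For multichannel (e.g. RGB) input or an empty file.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"stack file not found: {path}")
    with tifffile.TiffFile(path) as tif:
        if len(tif.pages) == 0:
            raise ValueError(f"{path}: TIFF contains zero pages")
        data = tif.asarray()
        desc = tif.pages[0].description
    if data.ndim == 2:
        data = data[np.newaxis]
    if data.ndim != 3:
        raise ValueError(
            f"{path}: expected a single-channel stack, got array of shape {data.shape} "
            "(multichannel/RGB input is not supported; split channels first)"
        )
    # A trailing small axis is an RGB(A) sample axis, not a column axis.
    if data.shape[-1] in (3, 4) and data.dtype == np.uint8:
        raise ValueError(
            f"{path}: image appears to be RGB(A) ({data.shape[-1]} samples per pixel); "
            "a single grayscale channel is required"
        )
    meta = {}
    if desc:
        try:
            meta = json.loads(desc)
        except (json.JSONDecodeError, TypeError):
            meta = {}
    px = pixel_size_xy if pixel_size_xy is not None else meta.get(
        "pixel_size_xy_um", DEFAULT_PIXEL_SIZE_XY
    )
    dz = section_thickness_z if section_thickness_z is not None else meta.get(
        "section_thickness_z_um", DEFAULT_SECTION_THICKNESS_Z
    )
    return ConfocalStack(data, pixel_size_xy=px, section_thickness_z=dz)
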