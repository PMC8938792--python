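"""Voxel-grid containers shared by the generator and the scorer.

A :class:`Volume` is a 3D intensity grid on a Hounsfield-unit-like
scale; a :class:`LabelMap` is an integer class grid aligned to it.
Both carry per-axis voxel spacing in mm and an RAS-style orientation
tag (one character per array axis from {R,L,A,P,S,I}) identifying which
axis runs right/left, anterior/posterior and superior/inferior.
NIfTI (.nii.gz) is the on-disk format, via nibabel.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = ["Volume", "LabelMap", "save_nifti", "load_volume", "load_labelmap"]

_VALID_AXES = set("RLAPSI")


def _check_orientation(orientation: str | None) -> None:
    if orientation is None:
        raise ValueError("orientation tag is missing")
    if (len(orientation) != 3 or set(orientation) - _VALID_AXES
            or len({c.translate(str.maketrans("LPI", "RAS")) for c in orientation}) != 3):
        raise ValueError(f"invalid orientation tag {orientation!r}")


@dataclass
class _Grid:
    data: np.ndarray
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    orientation: str | None = "RAS"

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("grid data must be 3D")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if len(self.spacing_mm) != 3 or any(s <= 0 for s in self.spacing_mm):
            raise ValueError("spacing_mm must be three positive values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing_mm))

    @property
    def voxel_volume_ml(self) -> float:
        return self.voxel_volume_mm3 / 1000.0

    def axis_of(self, direction: str) -> int:
        """Array axis running along ``direction`` (or its opposite)."""
        _check_orientation(self.orientation)
        flip = {"L": "R", "P": "A", "I": "S"}
        want = flip.get(direction, direction)
        for i, c in enumerate(self.orientation):
            if flip.get(c, c) == want:
                return i
        raise ValueError(f"no axis along {direction!r} in {self.orientation!r}")

    @property
    def coronal_axis(self) -> int:
        """Axis perpendicular to the coronal plane (anteroposterior)."""
        return self.axis_of("A")


class Volume(_Grid):
    pass


class LabelMap(_Grid):
    def __post_init__(self):
        super().__post_init__()
        if not np.issubdtype(self.data.dtype, np.integer):
            raise ValueError("label map must be integer-typed")


def _affine(grid: _Grid) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = grid.spacing_mm
    return aff


def save_nifti(grid: _Grid, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    data = grid.data
    if isinstance(grid, LabelMap):
        data = data.astype(np.int16)
    img = nib.Nifti1Image(np.asarray(data), _affine(grid))
    img.header.set_zooms(grid.spacing_mm)
    if grid.orientation:
        img.header["descrip"] = f"orientation={grid.orientation}".encode()
    nib.save(img, str(path))
    return path


def _load(path: str | Path) -> tuple[np.ndarray, tuple, str | None]:
    img = nib.load(str(path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    descrip = img.header["descrip"].tobytes().decode(errors="ignore").rstrip("\x00")
    orientation = None
    if "orientation=" in descrip:
        orientation = descrip.split("orientation=")[1][:3]
    return np.asarray(img.dataobj), spacing, orientation


def load_volume(path: str | Path) -> Volume:
    data, spacing, orientation = _load(path)
    return Volume(data.astype(np.float32), spacing, orientation or "RAS")


def load_labelmap(path: str | Path) -> LabelMap:
    data, spacing, orientation = _load(path)
    return LabelMap(np.rint(data).astype(np.int16), spacing, orientation or "RAS")
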