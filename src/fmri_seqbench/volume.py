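"""Volumetric containers: 4D BOLD series and 3D statistic maps.

Geometry is deliberately minimal: isotropic voxel size with an identity
orientation (no oblique affines), since the benchmark operates entirely in
voxel space and never needs real-world registration.  NIfTI-1 round-trips
are provided through :mod:`nibabel`.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = ["Volume4D", "StatMap"]

_STAT_KINDS = ("tsnr", "t", "p", "beta", "probability", "other")


def _affine(voxel_size_mm: float) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0] = aff[1, 1] = aff[2, 2] = float(voxel_size_mm)
    return aff


@dataclass
class Volume4D:
    """A voxel grid x time BOLD series.

    Parameters
    ----------
    data
        Array of shape ``(nx, ny, nz, nt)``; finite values.
    tr
        Repetition time in seconds (> 0).
    voxel_size_mm
        Isotropic voxel edge length in millimetres.
    mask
        Optional boolean brain mask on the spatial grid.
    """

    data: np.ndarray
    tr: float
    voxel_size_mm: float = 2.0
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 4:
            raise ValueError(f"expected 4D data, got shape {self.data.shape}")
        if self.tr <= 0:
            raise ValueError("TR must be positive")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("non-finite values in 4D data")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.shape3d:
                raise ValueError("mask shape does not match spatial grid")

    @property
    def shape3d(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]

    @property
    def frame_times(self) -> np.ndarray:
        """Acquisition time of each volume, ``t_i = i * TR`` seconds."""
        return np.arange(self.n_volumes) * self.tr

    def timeseries(self, mask: np.ndarray | None = None) -> np.ndarray:
        """Return a ``(n_voxels, nt)`` view of the series inside *mask*."""
        m = self.mask if mask is None else np.asarray(mask, dtype=bool)
        if m is None:
            return self.data.reshape(-1, self.n_volumes)
        return self.data[m]

    def to_nifti(self) -> nib.Nifti1Image:
        img = nib.Nifti1Image(self.data.astype(np.float32), _affine(self.voxel_size_mm))
        img.header.set_zooms((self.voxel_size_mm,) * 3 + (self.tr,))
        return img

    def save(self, path: str | Path) -> None:
        nib.save(self.to_nifti(), str(path))

    @classmethod
    def from_nifti(cls, path: str | Path, tr: float | None = None) -> "Volume4D":
        img = nib.load(str(path))
        zooms = img.header.get_zooms()
        if tr is None:
            tr = float(zooms[3]) if len(zooms) > 3 and zooms[3] > 0 else 1.0
        return cls(
            data=np.asarray(img.dataobj, dtype=np.float64),
            tr=tr,
            voxel_size_mm=float(zooms[0]),
        )


@dataclass
class StatMap:
    """Per-voxel scalar statistic on a :class:`Volume4D` grid.

    Undefined voxels (e.g. zero temporal variance for tSNR) are carried as
    NaN.  ``kind`` records what the values are; ``dof`` accompanies t- and
    p-maps.
    """

    data: np.ndarray
    kind: str
    voxel_size_mm: float = 2.0
    dof: float | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim > 3:
            raise ValueError(f"expected <=3D statistic map, got shape {self.data.shape}")
        if self.kind not in _STAT_KINDS:
            raise ValueError(f"unknown statistic kind {self.kind!r}")
        if self.kind in ("t", "p") and self.dof is None:
            raise ValueError(f"{self.kind}-maps require degrees of freedom")
        finite = self.data[np.isfinite(self.data)]
        if self.kind == "p" and finite.size and (finite.min() < 0 or finite.max() > 1):
            raise ValueError("p-values outside [0, 1]")
        if self.kind == "tsnr" and finite.size and finite.min() < 0:
            raise ValueError("negative tSNR")

    @property
    def defined(self) -> np.ndarray:
        return np.isfinite(self.data)

    def to_nifti(self) -> nib.Nifti1Image:
        if self.data.ndim != 3:
            raise ValueError("only 3D statistic maps can be written as NIfTI")
        return nib.Nifti1Image(
            self.data.astype(np.float32), _affine(self.voxel_size_mm)
        )

    def save(self, path: str | Path) -> None:
        nib.save(self.to_nifti(), str(path))

    @classmethod
    def from_nifti(cls, path: str | Path, kind: str, dof: float | None = None) -> "StatMap":
        img = nib.load(str(path))
        return cls(
            data=np.asarray(img.dataobj, dtype=np.float64),
            kind=kind,
            voxel_size_mm=float(img.header.get_zooms()[0]),
            dof=dof,
        )


def save_mask(mask: np.ndarray, voxel_size_mm: float, path: str | Path) -> None:
    """Write a binary mask as uint8 NIfTI-1."""
    img = nib.Nifti1Image(np.asarray(mask, dtype=np.uint8), _affine(voxel_size_mm))
    nib.save(img, str(path))


def load_mask(path: str | Path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).dataobj) > 0
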