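"""NIfTI input/output and the core in-memory containers.

Volumes are kept in the voxel grid of the file they came from: no resampling
or reorientation is performed (registration is upstream preprocessing), and
the NIfTI affine travels with every array so outputs land in the same space.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

from .params import AcquisitionParams


@dataclass
class EchoSeries:
    """One echo's 4D dynamic signal grid (x, y, z, t)."""

    voxels: np.ndarray
    affine: np.ndarray
    te: float

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=float)
        if self.voxels.ndim != 4:
            raise ValueError(f"EchoSeries requires a 4D grid, got {self.voxels.ndim}D")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.voxels.shape

    @property
    def n_timepoints(self) -> int:
        return self.voxels.shape[3]


@dataclass
class MaskSet:
    """Brain / lesion / input-function ROI masks sharing one geometry."""

    brain: np.ndarray
    aif_roi: np.ndarray | None = None
    lesion: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.brain = np.asarray(self.brain, dtype=bool)
        for name in ("aif_roi", "lesion"):
            m = getattr(self, name)
            if m is not None:
                m = np.asarray(m, dtype=bool)
                if m.shape != self.brain.shape:
                    raise ValueError(f"{name} shape {m.shape} != brain {self.brain.shape}")
                setattr(self, name, m)
        if self.lesion is not None and np.any(self.lesion & ~self.brain):
            raise ValueError("lesion mask extends outside the brain mask")


def read_echo_series(path: str | Path, params: AcquisitionParams, te: float) -> EchoSeries:
    """Load a 4D dynamic NIfTI as an EchoSeries; no rescaling applied."""
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(), dtype=float)
    if data.ndim != 4:
        raise ValueError(
            f"{path}: expected a 4D volume, got {data.ndim} axes {data.shape}"
        )
    if data.shape[3] != params.n_timepoints:
        raise ValueError(
            f"{path}: time axis has {data.shape[3]} frames, "
            f"acquisition expects {params.n_timepoints}"
        )
    n_bad = int((~np.isfinite(data)).sum())
    if n_bad:
        raise ValueError(f"{path}: {n_bad} non-finite voxels")
    return EchoSeries(voxels=data, affine=img.affine, te=te)


def split_dual_echo(
    path: str | Path, params: AcquisitionParams
) -> tuple[EchoSeries, EchoSeries]:
    """Split a single 5D NIfTI (echo as 5th dimension) into the two echoes."""
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(), dtype=float)
    if data.ndim != 5 or data.shape[4] < 2:
        raise ValueError(f"{path}: expected 5D with >= 2 echoes, got {data.shape}")
    if data.shape[3] != params.n_timepoints:
        raise ValueError(
            f"{path}: time axis has {data.shape[3]} frames, "
            f"acquisition expects {params.n_timepoints}"
        )
    return (
        EchoSeries(voxels=data[..., 0], affine=img.affine, te=params.te1),
        EchoSeries(voxels=data[..., 1], affine=img.affine, te=params.te2),
    )


def read_mask(path: str | Path, reference_shape: tuple[int, ...] | None = None) -> np.ndarray:
    """Load a 3D mask; nonzero voxels are True."""
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata())
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D mask, got {data.ndim} axes")
    if reference_shape is not None and data.shape != tuple(reference_shape):
        raise ValueError(f"{path}: mask shape {data.shape} != volume {reference_shape}")
    return data > 0


def write_quant_map(map3d: np.ndarray, affine: np.ndarray, path: str | Path) -> None:
    """Write a 3D map as NIfTI; undefined voxels stay NaN."""
    map3d = np.asarray(map3d, dtype=np.float64)
    if map3d.ndim != 3:
        raise ValueError(f"expected a 3D map, got {map3d.ndim} axes")
    img = nib.Nifti1Image(map3d, np.asarray(affine, dtype=float))
    nib.save(img, str(path))


def write_series(voxels: np.ndarray, affine: np.ndarray, path: str | Path) -> None:
    """Write a 3D/4D array as NIfTI (used by the phantom generator)."""
    img = nib.Nifti1Image(np.asarray(voxels, dtype=np.float64), np.asarray(affine, float))
    nib.save(img, str(path))
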