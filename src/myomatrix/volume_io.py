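"""Volumetric image I/O, reorientation, and binning.

All volumes carry a :class:`VoxelGrid` describing voxel counts and physical
voxel size in nanometres. The internal coordinate convention is 0-based
``(long, row, col)`` with the muscle's longitudinal axis always stored as
axis 0, so slicing along axis 0 yields muscle cross-sections.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal, Sequence, Union

import h5py
import numpy as np
import tifffile

__all__ = [
    "VoxelGrid",
    "LabeledVolume",
    "MaskVolume",
    "ProbabilityVolume",
    "Volume",
    "read_volume",
    "write_volume",
    "reorient_longitudinal",
    "bin_volume",
]

VolumeKind = Literal["labels", "mask", "probability", "auto"]
FileFormat = Literal["tiff_stack", "hdf5"]

STRUCTURE_NAMES = ("contractile", "mitochondria", "SRT", "cell", "other")


class VolumeError(ValueError):
    """Raised on invalid volume data or metadata."""


@dataclass(frozen=True)
class VoxelGrid:
    """Voxel counts and spacing of a reoriented volume.

    ``shape`` is ``(n_long, n_row, n_col)`` and ``voxel_size`` is
    ``(dz, dy, dx)`` in nm. Axis 0 is the longitudinal (muscle) axis.
    """

    shape: tuple[int, int, int]
    voxel_size: tuple[float, float, float]
    longitudinal_axis: int = 0

    def __post_init__(self):
        if len(self.shape) != 3 or any(int(s) < 1 for s in self.shape):
            raise VolumeError(f"grid shape must be 3 positive ints, got {self.shape}")
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise VolumeError(f"voxel sizes must be > 0, got {self.voxel_size}")
        if self.longitudinal_axis != 0:
            raise VolumeError("internal convention: longitudinal axis is always 0")
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        object.__setattr__(self, "voxel_size", tuple(float(v) for v in self.voxel_size))


@dataclass
class _BaseVolume:
    grid: VoxelGrid
    data: np.ndarray

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise VolumeError(f"volume data must be 3D, got ndim={self.data.ndim}")
        if tuple(self.data.shape) != self.grid.shape:
            raise VolumeError(
                f"data shape {self.data.shape} != grid shape {self.grid.shape}"
            )


@dataclass
class LabeledVolume(_BaseVolume):
    """Integer-labeled volume; 0 is background, each segment a unique label."""

    def __post_init__(self):
        super().__post_init__()
        if not np.issubdtype(self.data.dtype, np.integer):
            raise VolumeError("labeled volume requires an integer dtype")
        if self.data.size and int(self.data.min()) < 0:
            raise VolumeError("negative labels are not allowed")

    @property
    def label_set(self) -> set[int]:
        labels = np.unique(self.data)
        return {int(l) for l in labels if l > 0}


@dataclass
class MaskVolume(_BaseVolume):
    """Binary structure mask (values in {0, 1})."""

    structure_name: str = "other"

    def __post_init__(self):
        super().__post_init__()
        if self.structure_name not in STRUCTURE_NAMES:
            raise VolumeError(
                f"structure_name must be one of {STRUCTURE_NAMES}, got {self.structure_name!r}"
            )
        vals = np.unique(self.data)
        if not np.isin(vals, (0, 1)).all():
            raise VolumeError("mask values must be in {0, 1}")
        self.data = self.data.astype(np.uint8)

    @property
    def voxel_count(self) -> int:
        return int(self.data.sum())


@dataclass
class ProbabilityVolume(_BaseVolume):
    """Per-voxel class probability in [0, 1]."""

    def __post_init__(self):
        super().__post_init__()
        self.data = self.data.astype(np.float64)
        if self.data.size and (self.data.min() < 0 or self.data.max() > 1):
            raise VolumeError("probability values must lie in [0, 1]")


Volume = Union[LabeledVolume, MaskVolume, ProbabilityVolume]


def _wrap(data: np.ndarray, voxel_size, kind: VolumeKind, structure_name: str) -> Volume:
    grid = VoxelGrid(tuple(data.shape), tuple(voxel_size))
    if kind == "auto":
        kind = "labels" if np.issubdtype(data.dtype, np.integer) else "probability"
    if kind == "labels":
        if not np.issubdtype(data.dtype, np.integer):
            raise VolumeError("label volume requires integer data")
        return LabeledVolume(grid, data)
    if kind == "mask":
        return MaskVolume(grid, (np.asarray(data) != 0).astype(np.uint8), structure_name)
    if kind == "probability":
        if data.dtype == np.uint8:
            data = data.astype(np.float64) / 255.0  # 8-bit probability convention
        return ProbabilityVolume(grid, np.asarray(data, dtype=np.float64))
    raise VolumeError(f"unknown volume kind {kind!r}")


def read_volume(
    path: str | os.PathLike,
    format: FileFormat | None = None,
    voxel_size: Sequence[float] = (10.0, 10.0, 10.0),
    kind: VolumeKind = "auto",
    dataset: str = "labels",
    structure_name: str = "other",
) -> Volume:
    """Read a 3D volume from a multi-page TIFF stack or an HDF5 dataset.

    Integer data yields a :class:`LabeledVolume` (or :class:`MaskVolume` with
    ``kind="mask"``); float or 8-bit probability data (``kind="probability"``,
    rescaled by 1/255) yields a :class:`ProbabilityVolume`.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"cannot read volume: no such file {path}")
    if format is None:
        format = "hdf5" if path.suffix in (".h5", ".hdf5") else "tiff_stack"
    if format == "tiff_stack":
        try:
            data = tifffile.imread(path)
        except Exception as exc:  # pragma: no cover - backend specific
            raise IOError(f"unreadable TIFF file {path}: {exc}") from exc
    elif format == "hdf5":
        try:
            with h5py.File(path, "r") as fh:
                if dataset not in fh:
                    raise IOError(f"HDF5 file {path} has no dataset {dataset!r}")
                data = fh[dataset][()]
                if "voxel_size_nm" in fh[dataset].attrs:
                    voxel_size = tuple(fh[dataset].attrs["voxel_size_nm"])
        except OSError as exc:
            raise IOError(f"unreadable HDF5 file {path}: {exc}") from exc
    else:
        raise VolumeError(f"unknown format {format!r}")
    data = np.asarray(data)
    if data.ndim == 2:
        raise VolumeError(f"{path} holds a 2D image; a 3D volume is required")
    if data.ndim != 3:
        raise VolumeError(f"{path} has ndim={data.ndim}; a 3D volume is required")
    return _wrap(data, voxel_size, kind, structure_name)


def write_volume(
    vol: Volume, path: str | os.PathLike, format: FileFormat | None = None,
    dataset: str = "labels",
) -> Path:
    """Write a volume to disk; ``read_volume`` round-trips data and metadata.

    Probabilities written to TIFF are quantized to 8-bit (nearest 1/255);
    HDF5 keeps float probabilities exact and stores voxel size as an
    attribute on the dataset.
    """
    path = Path(path)
    if format is None:
        format = "hdf5" if path.suffix in (".h5", ".hdf5") else "tiff_stack"
    data = vol.data
    if isinstance(vol, ProbabilityVolume) and format == "tiff_stack":
        data = np.round(data * 255.0).astype(np.uint8)
    try:
        if format == "tiff_stack":
            tifffile.imwrite(path, data, photometric="minisblack")
        elif format == "hdf5":
            with h5py.File(path, "w") as fh:
                ds = fh.create_dataset(dataset, data=data)
                ds.attrs["voxel_size_nm"] = np.asarray(vol.grid.voxel_size)
        else:
            raise VolumeError(f"unknown format {format!r}")
    except OSError as exc:
        raise IOError(f"cannot write volume to {path}: {exc}") from exc
    return path


def reorient_longitudinal(
    vol: Volume, long_axis: int, flip: Sequence[bool] = (False, False, False)
) -> Volume:
    """Permute axes so ``long_axis`` becomes axis 0, with optional flips.

    A pure axis permutation plus per-axis flips; no resampling, so the
    multiset of voxel values is preserved exactly. Voxel sizes are permuted
    accordingly. Applying the inverse parameters restores the original.
    """
    if long_axis not in (0, 1, 2):
        raise VolumeError(f"long_axis must be 0, 1 or 2, got {long_axis}")
    order = (long_axis,) + tuple(a for a in range(3) if a != long_axis)
    data = np.transpose(vol.data, order)
    for axis, f in enumerate(flip):
        if f:
            data = np.flip(data, axis=axis)
    data = np.ascontiguousarray(data)
    grid = VoxelGrid(
        tuple(data.shape), tuple(vol.grid.voxel_size[a] for a in order)
    )
    out = replace(vol, grid=grid, data=data)
    return out


def _block_view_pad(data: np.ndarray, factors, pad_value) -> np.ndarray:
    """Pad up to a multiple of the factors and return a 6D block view."""
    pads = [(0, (-data.shape[a]) % factors[a]) for a in range(3)]
    padded = np.pad(data, pads, mode="constant", constant_values=pad_value)
    f0, f1, f2 = factors
    n0, n1, n2 = (padded.shape[a] // factors[a] for a in range(3))
    return (
        padded.reshape(n0, f0, n1, f1, n2, f2).transpose(0, 2, 4, 1, 3, 5)
        .reshape(n0, n1, n2, f0 * f1 * f2)
    )


def _modal_labels(blocks: np.ndarray) -> np.ndarray:
    """Per-block modal positive label (ties -> smallest label); 0 if empty."""
    out = np.zeros(blocks.shape[:3], dtype=blocks.dtype)
    fg = blocks.max(axis=3) > 0
    for idx in np.argwhere(fg):
        block = blocks[tuple(idx)]
        block = block[block > 0]
        counts = np.bincount(block)
        out[tuple(idx)] = np.argmax(counts)  # argmax returns smallest on ties
    return out


def bin_volume(vol: Volume, factor: int | Sequence[int], reducer: str | None = None) -> Volume:
    """Downsample by integer factors per axis.

    Labels are reduced per block by the modal positive label (background only
    if the block is empty), masks by max, probabilities by mean over the
    in-bounds voxels. Output shape is ``ceil(shape / factor)`` and voxel
    sizes are multiplied by the factors.
    """
    if np.isscalar(factor):
        factor = (int(factor),) * 3
    factors = tuple(int(f) for f in factor)
    if len(factors) != 3 or any(f < 1 for f in factors):
        raise VolumeError(f"bin factors must be >= 1 per axis, got {factor}")
    if reducer is None:
        reducer = {
            LabeledVolume: "mode_label", MaskVolume: "max", ProbabilityVolume: "mean"
        }[type(vol)]
    grid = VoxelGrid(
        tuple(-(-s // f) for s, f in zip(vol.grid.shape, factors)),
        tuple(v * f for v, f in zip(vol.grid.voxel_size, factors)),
    )
    if reducer == "mode_label":
        data = _modal_labels(_block_view_pad(vol.data, factors, 0))
    elif reducer == "max":
        data = _block_view_pad(vol.data, factors, 0).max(axis=3)
    elif reducer == "mean":
        blocks = _block_view_pad(vol.data.astype(float), factors, np.nan)
        data = np.nanmean(blocks, axis=3)
    else:
        raise VolumeError(f"unknown reducer {reducer!r}")
    return replace(vol, grid=grid, data=data)
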