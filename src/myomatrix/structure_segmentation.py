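"""Probability-map post-processing and cellular volume-fraction composition."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.morphology import disk

from .volume_io import MaskVolume, ProbabilityVolume, VolumeError, replace

__all__ = [
    "VolumeFractionReport",
    "threshold_probability",
    "remove_outliers",
    "resolve_structure_overlaps",
    "volume_fractions",
]

STRUCTURE_PRIORITY = ("contractile", "mitochondria", "SRT")


@dataclass(frozen=True)
class VolumeFractionReport:
    """Percent of cell volume occupied by each structure class.

    Percentages close to 100: ``contractile + mitochondria + SRT + other``
    sums to 100 exactly.
    """

    cell_voxels: int
    voxel_counts: dict[str, int]
    percents: dict[str, float]
    other_percent: float

    def __post_init__(self):
        total = sum(self.percents.values()) + self.other_percent
        if abs(total - 100.0) > 1e-9:
            raise VolumeError(f"volume fractions must close to 100, got {total}")

    def as_dict(self) -> dict[str, float]:
        out = {f"{k}_percent": v for k, v in self.percents.items()}
        out["other_percent"] = self.other_percent
        out["cell_voxels"] = self.cell_voxels
        return out


def threshold_probability(
    prob: ProbabilityVolume, threshold: float = 0.5, structure_name: str = "other"
) -> MaskVolume:
    """Binarize a probability volume: foreground iff value >= threshold."""
    if not 0.0 <= threshold <= 1.0:
        raise VolumeError(f"threshold must lie in [0, 1], got {threshold}")
    return MaskVolume(prob.grid, (prob.data >= threshold).astype(np.uint8), structure_name)


def remove_outliers(vol, radius: int = 3, k_sd: float = 2.0):
    """Median-replace per-slice outliers, as a despeckling filter.

    In every cross-sectional slice, a voxel deviating from the median of its
    radius-``radius`` disk neighborhood by more than ``k_sd`` times the
    slice's global standard deviation is replaced by that median. Uniform
    slices are untouched; on binary masks this removes specks smaller than
    the neighborhood scale.
    """
    if radius < 1:
        raise VolumeError(f"radius must be >= 1, got {radius}")
    if k_sd <= 0:
        raise VolumeError(f"k_sd must be > 0, got {k_sd}")
    if 2 * radius + 1 > min(vol.grid.shape[1], vol.grid.shape[2]):
        raise VolumeError(f"radius {radius} exceeds slice extent {vol.grid.shape[1:]}")
    footprint = disk(radius)
    data = vol.data.astype(np.float64, copy=True)
    for z in range(data.shape[0]):
        sl = data[z]
        sd = sl.std()
        med = ndimage.median_filter(sl, footprint=footprint, mode="reflect")
        bad = np.abs(sl - med) > k_sd * sd
        sl[bad] = med[bad]
    if isinstance(vol, MaskVolume):
        return replace(vol, data=(data >= 0.5).astype(np.uint8))
    return replace(vol, data=data)


def resolve_structure_overlaps(
    probs: dict[str, ProbabilityVolume], threshold: float = 0.5
) -> dict[str, MaskVolume]:
    """Assign each voxel to its max-probability class, so masks are disjoint.

    Ties are broken by the fixed priority contractile > mitochondria > SRT.
    Voxels whose winning probability is below ``threshold`` belong to no
    structure.
    """
    names = [n for n in STRUCTURE_PRIORITY if n in probs]
    if not names:
        raise VolumeError("no known structure probabilities given")
    stack = np.stack([probs[n].data for n in names])
    winner = np.argmax(stack, axis=0)  # first (highest-priority) wins ties
    fg = stack.max(axis=0) >= threshold
    out = {}
    for i, name in enumerate(names):
        mname = "mitochondria" if name == "mitochondria" else name
        out[name] = MaskVolume(
            probs[name].grid,
            ((winner == i) & fg).astype(np.uint8),
            mname if mname in ("contractile", "mitochondria", "SRT") else "other",
        )
    return out


def volume_fractions(
    structures: dict[str, MaskVolume], cell: MaskVolume
) -> VolumeFractionReport:
    """Percent of the cell volume occupied by each structure mask.

    ``percent = 100 * |structure & cell| / |cell|``; the remainder is
    reported as ``other``. Structure masks must be pairwise disjoint.
    """
    cell_data = cell.data.astype(bool)
    n_cell = int(cell_data.sum())
    if n_cell == 0:
        raise VolumeError("cell mask is empty")
    for name, m in structures.items():
        if m.grid.shape != cell.grid.shape:
            raise VolumeError(f"structure {name!r} grid differs from cell grid")
    stack = np.stack([m.data.astype(bool) for m in structures.values()])
    n_overlap = int((stack.sum(axis=0) > 1).sum())
    if n_overlap:
        raise VolumeError(
            f"{n_overlap} voxels are claimed by more than one structure mask"
        )
    counts = {
        name: int((m.data.astype(bool) & cell_data).sum())
        for name, m in structures.items()
    }
    percents = {name: 100.0 * c / n_cell for name, c in counts.items()}
    other = 100.0 - sum(percents.values())
    return VolumeFractionReport(n_cell, counts, percents, other)
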