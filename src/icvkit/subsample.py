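"""Voxel-count ICV and the interleaved slice-subsampling estimator.

The reference ("every slice") ICV is the number of occupied voxels times
the voxel volume.  The subsampled estimate with sampling period ``m`` keeps
every m-th slice starting ``start_offset`` slices after the first occupied
slice and multiplies the summed slice volumes by ``m`` — the Cavalieri
estimator for equally spaced parallel sections.  All estimates are computed
from integer slice voxel counts, so the m = 1 estimate is bit-equal to the
reference and averaging over all start offsets recovers it exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .phantom import MaskVolume

__all__ = [
    "SubsampleEstimate",
    "icv_from_mask",
    "slice_counts",
    "slice_areas",
    "subsample_icv",
    "subsample_counts",
    "period_mm",
]


@dataclass(frozen=True)
class SubsampleEstimate:
    """One subsampled ICV estimate.

    ``period_mm`` is the sampling period expressed in millimetres
    (m x slice spacing), the unit in which protocol guidelines are stated
    so they transfer across acquisitions with different slice spacing.
    """

    period_slices: int
    period_mm: float
    start_offset: int
    icv_l: float

    def __post_init__(self) -> None:
        if self.period_slices < 1:
            raise ValueError("period_slices must be >= 1")
        if not 0 <= self.start_offset < self.period_slices:
            raise ValueError("start_offset must lie in [0, period_slices)")
        if self.icv_l < 0:
            raise ValueError("icv_l must be >= 0")


def icv_from_mask(mask: MaskVolume) -> float:
    """Reference ICV: occupied voxel count x voxel volume, in litres."""
    return mask.volume_l()


def slice_counts(mask: MaskVolume, slice_axis: int | None = None) -> np.ndarray:
    """Occupied-voxel count per slice along ``slice_axis`` (int64 array)."""
    axis = mask.slice_axis if slice_axis is None else slice_axis
    if axis not in (0, 1, 2):
        raise ValueError("slice_axis must be 0, 1 or 2")
    other = tuple(i for i in range(3) if i != axis)
    return mask.occupancy.sum(axis=other, dtype=np.int64)


def slice_areas(mask: MaskVolume, slice_axis: int | None = None) -> np.ndarray:
    """Traced area per slice in mm^2 (voxel count x in-plane voxel area)."""
    axis = mask.slice_axis if slice_axis is None else slice_axis
    counts = slice_counts(mask, axis)
    inplane = [s for i, s in enumerate(mask.spacing) if i != axis]
    return counts * (inplane[0] * inplane[1])


def subsample_counts(counts: np.ndarray, m: int, start_offset: int) -> int:
    """Summed voxel count over the sampled slices (exact integer arithmetic).

    Sampled slices are ``f + start_offset, f + start_offset + m, ...`` up to
    the last occupied slice, where ``f`` is the first occupied slice.
    """
    if m < 1:
        raise ValueError("sampling period m must be >= 1")
    if not 0 <= start_offset < m:
        raise ValueError("start_offset must lie in [0, m)")
    counts = np.asarray(counts)
    nz = np.flatnonzero(counts)
    if nz.size == 0:
        raise ValueError("mask is empty: no occupied slice to anchor the subset")
    f, l = int(nz[0]), int(nz[-1])
    return int(counts[f + start_offset : l + 1 : m].sum(dtype=np.int64))


def subsample_icv(
    mask: MaskVolume,
    slice_axis: int | None = None,
    m: int = 1,
    start_offset: int = 0,
) -> SubsampleEstimate:
    """Interleaved slice-sampling ICV estimate with period ``m``.

    icv = m x sum(sampled slice areas) x slice spacing / 1e6 litres.  With
    ``m = 1`` and ``start_offset = 0`` this equals :func:`icv_from_mask`
    bit-exactly.
    """
    axis = mask.slice_axis if slice_axis is None else slice_axis
    counts = slice_counts(mask, axis)
    total = subsample_counts(counts, m, start_offset)
    sx, sy, sz = mask.spacing
    icv_l = m * total * (sx * sy * sz) / 1e6
    return SubsampleEstimate(
        period_slices=m,
        period_mm=period_mm(m, mask.spacing[axis]),
        start_offset=start_offset,
        icv_l=icv_l,
    )


def period_mm(m: int, slice_spacing: float) -> float:
    """Sampling period in millimetres: m x slice spacing."""
    if m < 1:
        raise ValueError("sampling period m must be >= 1")
    if slice_spacing <= 0:
        raise ValueError("slice spacing must be > 0")
    return m * slice_spacing
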