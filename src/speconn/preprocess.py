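"""Intensity normalization across z-slices.

Confocal stacks lose signal with depth; before tracing or segmenting, each
z-plane's intensity distribution is matched onto a single high-SnR reference
plane.  Matching is per channel and purely monotone (empirical-CDF mapping),
so rank order within a plane is preserved and the reference plane itself is a
fixed point.
"""

from __future__ import annotations

import numpy as np

from .types import ValidationError, VoxelGrid

__all__ = ["histogram_match_z", "match_plane"]


def match_plane(source: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Exact empirical-quantile mapping of ``source`` onto ``reference``.

    Each unique source value maps to the reference value at the same
    empirical quantile (linear interpolation between reference order
    statistics).  Monotone by construction; ties in the source stay tied.
    """
    src = np.asarray(source, dtype=float)
    ref = np.asarray(reference, dtype=float)
    src_vals, src_inverse, src_counts = np.unique(
        src.ravel(), return_inverse=True, return_counts=True
    )
    ref_sorted = np.sort(ref.ravel())
    # quantile of each unique source value = upper CDF of its value class
    src_q = np.cumsum(src_counts) / src.size
    ref_q = (np.arange(ref_sorted.size) + 1) / ref_sorted.size
    mapped = np.interp(src_q, ref_q, ref_sorted)
    return mapped[src_inverse].reshape(src.shape)


def histogram_match_z(grid: VoxelGrid, channel: str, reference_z: int) -> VoxelGrid:
    """Match every z-plane of ``channel`` onto the plane at ``reference_z``.

    Returns a new grid; other channels are copied untouched.  The reference
    plane is returned unchanged, and each plane's voxel count and rank order
    are preserved.

    Raises
    ------
    ValidationError
        If ``reference_z`` is out of range or the reference plane is constant
        (a degenerate matching target).
    """
    nz = grid.shape[0]
    if not (0 <= reference_z < nz):
        raise ValidationError(f"reference_z={reference_z} outside [0, {nz})")
    ch = grid.channel(channel)
    ref = ch[reference_z]
    if np.ptp(ref) == 0:
        raise ValidationError("reference plane is constant; histogram matching is degenerate")
    out = grid.copy()
    out_ch = out.data[grid.channels.index(channel)]
    for z in range(nz):
        if z == reference_z:
            out_ch[z] = ref
        else:
            out_ch[z] = match_plane(ch[z], ref)
    return out
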