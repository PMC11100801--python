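"""2D Sholl analysis and basic size measures.

The Sholl procedure follows the classical recipe: reduce the binarized
cell to a one-pixel-wide medial skeleton, draw concentric rings around
the soma centre at fixed spacing, and count, for each ring, the number of
distinct process crossings.

A "crossing" is a connected run of skeleton pixels on the ring band
(8-connectivity), so a process thicker than one pixel, or one crossing
the ring obliquely, still counts once.  The ring band has a half-width of
0.75 pixels: an 8-connected path heading outward advances its radial
distance by at most sqrt(2) pixels per step, so every crossing path is
guaranteed to deposit at least one pixel in a band of width 1.5 pixels —
no crossing can tunnel through between samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.morphology import skeletonize as _skimage_skeletonize

from .io_core import BinaryMask

__all__ = ["ShollProfile", "skeletonize_cell", "sholl_profile", "cell_volume"]

_STRUCT8 = np.ones((3, 3), dtype=bool)


@dataclass
class ShollProfile:
    """Ring radii (µm, strictly increasing) and crossing counts for one cell."""

    ring_radii: np.ndarray
    intersections: np.ndarray
    ring_spacing: float
    max_radius: float
    cell_id: int | None = None
    clipped: np.ndarray = field(default=None)  # per-ring: ring leaves the image

    def __post_init__(self) -> None:
        self.ring_radii = np.asarray(self.ring_radii, dtype=float)
        self.intersections = np.asarray(self.intersections, dtype=int)
        if self.ring_radii.size != self.intersections.size:
            raise ValueError("radii and intersections length mismatch")
        if self.ring_radii.size and np.any(np.diff(self.ring_radii) <= 0):
            raise ValueError("ring radii must be strictly increasing")
        if np.any(self.intersections < 0):
            raise ValueError("intersections must be non-negative")
        if self.clipped is None:
            self.clipped = np.zeros(self.ring_radii.size, dtype=bool)


def skeletonize_cell(mask2d: BinaryMask) -> BinaryMask:
    """Topology-preserving one-pixel-wide skeleton of a 2D cell mask."""
    if mask2d.data.shape[0] != 1:
        raise ValueError("skeletonize_cell expects a 2D (z=1) mask; project first")
    if mask2d.voxel_count == 0:
        raise ValueError("cannot skeletonize an empty mask")
    skel = _skimage_skeletonize(mask2d.data[0])
    return BinaryMask(skel[None], mask2d.voxel_size)


def sholl_profile(
    skeleton: BinaryMask,
    soma_center_um: tuple[float, float],
    ring_spacing_um: float = 1.0,
    max_radius_um: float | None = None,
    start_radius_um: float | None = None,
    cell_id: int | None = None,
) -> ShollProfile:
    """Count skeleton crossings on concentric rings around the soma.

    Parameters
    ----------
    soma_center_um:
        ``(y, x)`` position of the soma centre in µm (voxel-centre
        convention, i.e. pixel index × pixel size).
    ring_spacing_um:
        Arithmetic spacing between rings; default 1 µm.
    start_radius_um:
        First ring radius.  Defaults to one spacing — by convention there
        are no crossings *inside* the soma, so callers normally pass
        ``soma_radius + spacing``.
    max_radius_um:
        Last ring radius; defaults to the largest distance from the soma
        centre to an image corner (covers the whole cell).

    Rings that leave the image bounds are still measured on the part
    inside, and flagged in ``profile.clipped`` rather than silently
    truncated.
    """
    if ring_spacing_um <= 0:
        raise ValueError("ring_spacing must be positive")
    if skeleton.data.shape[0] != 1:
        raise ValueError("sholl_profile expects a 2D (z=1) skeleton")
    _, dy, dx = skeleton.voxel_size
    grid = skeleton.data[0]
    ny, nx = grid.shape
    cy, cx = (float(v) for v in soma_center_um)
    if not (0 <= cy <= (ny - 1) * dy and 0 <= cx <= (nx - 1) * dx):
        raise ValueError(f"soma centre {soma_center_um} outside image")

    yy = np.arange(ny) * dy - cy
    xx = np.arange(nx) * dx - cx
    dist = np.sqrt(yy[:, None] ** 2 + xx[None, :] ** 2)

    # farthest corner distance
    corner = max(
        np.hypot(cy - 0, cx - 0),
        np.hypot(cy - 0, cx - (nx - 1) * dx),
        np.hypot(cy - (ny - 1) * dy, cx - 0),
        np.hypot(cy - (ny - 1) * dy, cx - (nx - 1) * dx),
    )
    if max_radius_um is None:
        max_radius_um = corner
    if start_radius_um is None:
        start_radius_um = ring_spacing_um
    radii = np.arange(start_radius_um, max_radius_um + 1e-9, ring_spacing_um)

    # nearest border distance: rings beyond this are clipped by the frame
    border = min(cy, cx, (ny - 1) * dy - cy, (nx - 1) * dx - cx)

    half_band = 0.75 * max(dy, dx)
    counts = np.empty(radii.size, dtype=int)
    clipped = np.empty(radii.size, dtype=bool)
    for i, r in enumerate(radii):
        band = (np.abs(dist - r) <= half_band) & grid
        _, n = ndimage.label(band, structure=_STRUCT8)
        counts[i] = n
        clipped[i] = r + half_band > border
    return ShollProfile(
        radii, counts, ring_spacing_um, float(radii[-1]) if radii.size else 0.0,
        cell_id=cell_id, clipped=clipped,
    )


def cell_volume(mask: BinaryMask) -> float:
    """Volume in µm³: true-voxel count × voxel volume.  Nothing more."""
    return mask.volume_um3
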