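"""Pre/post synaptic puncta detection and colocalization counting.

A synapse is scored where a presynaptic punctum (e.g. VGlut2) and a
postsynaptic punctum (e.g. PSD95) colocalize.  Two criteria are offered:

* ``overlap`` (default) — the two puncta share at least one voxel;
* ``("centroid", r)`` — centroid distance at most ``r`` µm.

Matching is one-to-one and greedy: pairs are consumed best-first
(largest voxel overlap, or smallest centroid distance), each punctum used
at most once, ties broken by lower punctum index so results are
deterministic.  One-to-one matching prevents a single large punctum from
counting as several synapses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial.distance import cdist

from .io_core import RunManifest, VolumeImage
from .segmentation import LabeledObjects, label_objects, threshold_channel

__all__ = ["PunctaSet", "ColocResult", "detect_puncta", "count_colocalized"]


@dataclass
class PunctaSet:
    """Detected puncta of one channel: centroids, sizes, intensities.

    Keeps the label grid so the voxel-overlap criterion can be evaluated
    exactly rather than from centroid geometry.
    """

    channel: str
    centroids_um: np.ndarray  # (n, 3) µm
    voxel_counts: np.ndarray  # (n,)
    mean_intensities: np.ndarray  # (n,)
    labels: np.ndarray  # (z, y, x) int grid, 0 background
    voxel_size: tuple[float, float, float]

    @property
    def n(self) -> int:
        return len(self.voxel_counts)


@dataclass
class ColocResult:
    """Colocalization counts and density for one field."""

    n_pre: int
    n_post: int
    n_colocalized: int
    criterion: str
    density_per_100um2: float | None = None
    pairs: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.n_colocalized > min(self.n_pre, self.n_post):
            raise ValueError("colocalized count cannot exceed either channel's count")


def detect_puncta(
    volume: VolumeImage,
    channel: str,
    threshold_method: str | tuple[str, float] = "robust",
    size_window: tuple[int, int] = (1, 200),
    manifest: RunManifest | None = None,
) -> PunctaSet:
    """Threshold one channel and keep connected components in the size window.

    Components larger than the window (out-of-focus blobs, aggregates)
    are rejected and logged; the robust background threshold is the
    default because synaptic puncta occupy far too little of the image
    for a bimodal threshold criterion.
    """
    lo, hi = size_window
    if not lo < hi:
        raise ValueError(f"size window min must be < max, got {size_window}")
    mask = threshold_channel(volume, channel, method=threshold_method, manifest=manifest)
    objs: LabeledObjects = label_objects(mask, min_voxels=lo, manifest=manifest)
    keep = objs.voxel_counts <= hi
    n_rejected = int((~keep).sum())
    if n_rejected and manifest is not None:
        manifest.log_filtered(
            "punctum above size window", channel=channel, n_removed=n_rejected
        )
    remap = np.zeros(objs.n_objects + 1, dtype=objs.labels.dtype)
    remap[1:][keep] = np.arange(1, int(keep.sum()) + 1)
    img = volume.channel(channel)
    labels = remap[objs.labels]
    kept_ids = np.arange(1, int(keep.sum()) + 1)
    means = (
        ndimage.mean(img, labels, kept_ids) if kept_ids.size else np.zeros(0)
    )
    return PunctaSet(
        channel=str(channel),
        centroids_um=objs.centroids_um[keep],
        voxel_counts=objs.voxel_counts[keep],
        mean_intensities=np.atleast_1d(means),
        labels=labels,
        voxel_size=volume.voxel_size,
    )


def _greedy_match(scores: list[tuple[float, int, int]]) -> list[tuple[int, int]]:
    """Consume candidate pairs best-first (score ascending, then pre index,
    then post index), each punctum at most once."""
    pairs = []
    used_pre: set[int] = set()
    used_post: set[int] = set()
    for _, i, j in sorted(scores):
        if i in used_pre or j in used_post:
            continue
        used_pre.add(i)
        used_post.add(j)
        pairs.append((i, j))
    return pairs


def count_colocalized(
    pre: PunctaSet,
    post: PunctaSet,
    criterion: str | tuple[str, float] = "overlap",
    field_area_um2: float | None = None,
) -> ColocResult:
    """Count colocalized pre/post puncta under the chosen criterion.

    Symmetric in its two arguments, and (for the centroid criterion)
    monotone in the radius: enlarging ``r`` never loses pairs.
    """
    if pre.labels.shape != post.labels.shape:
        raise ValueError("puncta sets must come from the same image frame")
    scores: list[tuple[float, int, int]] = []
    if criterion == "overlap":
        both = (pre.labels > 0) & (post.labels > 0)
        if both.any():
            pl = pre.labels[both]
            ql = post.labels[both]
            pair_ids, overlap_counts = np.unique(
                pl.astype(np.int64) * (post.n + 1) + ql, return_counts=True
            )
            for pid, cnt in zip(pair_ids, overlap_counts):
                i = int(pid // (post.n + 1)) - 1
                j = int(pid % (post.n + 1)) - 1
                scores.append((-float(cnt), i, j))
        crit_label = "overlap"
    elif isinstance(criterion, tuple) and criterion[0] == "centroid":
        r = float(criterion[1])
        if r < 0:
            raise ValueError("centroid radius must be non-negative")
        if pre.n and post.n:
            d = cdist(pre.centroids_um, post.centroids_um)
            for i, j in zip(*np.nonzero(d <= r)):
                scores.append((float(d[i, j]), int(i), int(j)))
        crit_label = f"centroid:{r}"
    else:
        raise ValueError(f"unknown criterion {criterion!r}")
    pairs = _greedy_match(scores)
    density = None
    if field_area_um2 is not None:
        if field_area_um2 <= 0:
            raise ValueError("field area must be positive")
        density = 100.0 * len(pairs) / field_area_um2
    return ColocResult(
        n_pre=pre.n,
        n_post=post.n,
        n_colocalized=len(pairs),
        criterion=crit_label,
        density_per_100um2=density,
        pairs=pairs,
    )
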