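"""Single-cell RNA-FISH scoring.

Nuclei are segmented from the DAPI channel; each FISH punctum (a small
bright object in a probe channel) is assigned to the nucleus containing
its centroid.  Per cell the pipeline derives:

* a neuronal type call — glutamatergic vs GABAergic — from the margin
  between excitatory-marker (VGlut1) and inhibitory-marker (Gad2) puncta
  counts; cells without a clear margin are "ambiguous" and excluded from
  type averages (but logged, never silently dropped);
* an activity call — Fos+/Fos− — from the Fos puncta count against a
  base threshold of 6 puncta scaled linearly by the cell's nucleus
  volume relative to the field median ("adjusted for cell size"), with
  strict inequality: exactly the adjusted threshold is Fos−;
* a target (IL34) expression density — puncta per µm³ of DAPI volume —
  averaged per (animal, type) so the animal is the statistical unit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_core import RunManifest, VolumeImage, logger
from .segmentation import LabeledObjects, label_objects, threshold_channel

__all__ = [
    "FishCellRecord",
    "segment_nuclei",
    "detect_fish_puncta",
    "assign_puncta",
    "call_cell_type",
    "call_fos_state",
    "il34_by_type",
    "quantify_field",
]

GLUT = "glutamatergic"
GABA = "GABAergic"
AMBIGUOUS = "ambiguous"


@dataclass
class FishCellRecord:
    """Per-nucleus puncta counts, volume, and derived calls."""

    nucleus_id: int
    dapi_volume_um3: float
    vglut1_count: int
    gad2_count: int
    il34_count: int
    fos_count: int | None
    cell_type: str
    fos_state: str | None
    il34_density: float  # puncta per µm³ DAPI volume
    animal_id: str | None = None


def segment_nuclei(
    volume: VolumeImage,
    channel: str = "DAPI",
    min_voxels: int | None = None,
    manifest: RunManifest | None = None,
) -> LabeledObjects:
    """Threshold the DAPI channel and label size-filtered nuclei.

    Uses the robust background threshold rather than a bimodal criterion:
    it degrades gracefully on fields with few or no nuclei (a noise-only
    image yields isolated voxels that the size filter removes), whereas a
    bimodal threshold on such an image splits the noise itself.
    """
    mask = threshold_channel(volume, channel, method="robust", manifest=manifest)
    return label_objects(mask, min_voxels=min_voxels, manifest=manifest)


def detect_fish_puncta(
    volume: VolumeImage,
    channel: str,
    size_window: tuple[int, int] = (1, 30),
    manifest: RunManifest | None = None,
) -> LabeledObjects:
    """Detect FISH puncta as small bright objects in one probe channel.

    Uses the robust background threshold (puncta channels are far too
    sparse for Otsu) and keeps components within the voxel-count window;
    larger blobs are rejected and logged.
    """
    lo, hi = size_window
    if not lo < hi:
        raise ValueError(f"size window min must be < max, got {size_window}")
    mask = threshold_channel(volume, channel, method="robust", manifest=manifest)
    objs = label_objects(mask, min_voxels=lo, manifest=manifest)
    too_big = np.flatnonzero(objs.voxel_counts > hi)
    if too_big.size:
        if manifest is not None:
            manifest.log_filtered(
                "punctum above size window", channel=channel, n_removed=int(too_big.size)
            )
        keep = objs.voxel_counts <= hi
        # rebuild with oversized labels zeroed, keeping ids contiguous
        remap = np.zeros(objs.n_objects + 1, dtype=objs.labels.dtype)
        remap[1:][keep] = np.arange(1, int(keep.sum()) + 1)
        objs = LabeledObjects(
            remap[objs.labels],
            objs.voxel_size,
            objs.voxel_counts[keep],
            objs.centroids_um[keep],
            [b for b, k in zip(objs.bboxes, keep) if k],
            meta=dict(objs.meta),
        )
    return objs


def assign_puncta(
    puncta: LabeledObjects, nuclei: LabeledObjects
) -> tuple[np.ndarray, int]:
    """Count puncta per nucleus by centroid containment.

    A punctum belongs to the nucleus whose mask contains its centroid
    voxel; puncta over background are tallied separately.  Returns
    ``(counts, n_unassigned)`` with ``counts[k]`` the count for nucleus
    label ``k+1``; ``counts.sum() + n_unassigned`` equals the number of
    detected puncta.
    """
    counts = np.zeros(nuclei.n_objects, dtype=int)
    unassigned = 0
    vox = np.asarray(nuclei.voxel_size)
    shape = nuclei.labels.shape
    for centroid in puncta.centroids_um:
        idx = np.clip(np.rint(centroid / vox).astype(int), 0, np.array(shape) - 1)
        label = nuclei.labels[tuple(idx)]
        if label == 0:
            unassigned += 1
        else:
            counts[label - 1] += 1
    return counts, unassigned


def call_cell_type(vglut1_count: int, gad2_count: int, min_margin: int = 3) -> str:
    """Type call from the margin between excitatory and inhibitory markers.

    Glutamatergic if VGlut1 exceeds Gad2 by at least ``min_margin``
    puncta, GABAergic for the reverse, ambiguous otherwise.
    """
    if min_margin < 1:
        raise ValueError("min_margin must be >= 1")
    if vglut1_count >= gad2_count + min_margin:
        return GLUT
    if gad2_count >= vglut1_count + min_margin:
        return GABA
    return AMBIGUOUS


def call_fos_state(
    fos_count: int,
    dapi_volume: float,
    median_volume: float,
    base_threshold: float = 6.0,
) -> str:
    """Fos+ iff the count strictly exceeds the size-adjusted threshold.

    The base threshold (6 puncta) scales linearly with nucleus volume
    relative to the field median, so a cell twice the median size needs
    more than 12 puncta.  Strict inequality: a median-size cell with
    exactly 6 puncta is Fos−.
    """
    if median_volume <= 0:
        raise ValueError("median_volume must be positive")
    if dapi_volume < 0 or fos_count < 0:
        raise ValueError("counts and volumes must be non-negative")
    adjusted = base_threshold * (dapi_volume / median_volume)
    return "Fos+" if fos_count > adjusted else "Fos-"


def quantify_field(
    volume: VolumeImage,
    channels: dict[str, str] | None = None,
    min_margin: int = 3,
    fos_base_threshold: float = 6.0,
    animal_id: str | None = None,
    size_window: tuple[int, int] = (1, 30),
    manifest: RunManifest | None = None,
) -> pd.DataFrame:
    """Full per-cell scoring of one FISH field.

    ``channels`` maps roles to channel names, defaulting to
    ``{"dapi": "DAPI", "vglut1": "VGlut1", "gad2": "Gad2", "il34": "IL34"}``
    with an optional ``"fos"`` entry; the Fos call is skipped when no Fos
    channel is present.
    """
    ch = {"dapi": "DAPI", "vglut1": "VGlut1", "gad2": "Gad2", "il34": "IL34"}
    if channels:
        ch.update(channels)
    nuclei = segment_nuclei(volume, ch["dapi"], manifest=manifest)
    if nuclei.n_objects == 0:
        return pd.DataFrame()
    vols = nuclei.volumes_um3

    def counts_for(role: str) -> tuple[np.ndarray, int]:
        puncta = detect_fish_puncta(
            volume, ch[role], size_window=size_window, manifest=manifest
        )
        return assign_puncta(puncta, nuclei)

    vglut1, _ = counts_for("vglut1")
    gad2, _ = counts_for("gad2")
    il34, _ = counts_for("il34")
    fos = counts_for("fos")[0] if "fos" in ch else None
    median_vol = float(np.median(vols))

    records = []
    n_ambiguous = 0
    for i in range(nuclei.n_objects):
        ctype = call_cell_type(int(vglut1[i]), int(gad2[i]), min_margin)
        n_ambiguous += ctype == AMBIGUOUS
        records.append(
            FishCellRecord(
                nucleus_id=i + 1,
                dapi_volume_um3=float(vols[i]),
                vglut1_count=int(vglut1[i]),
                gad2_count=int(gad2[i]),
                il34_count=int(il34[i]),
                fos_count=int(fos[i]) if fos is not None else None,
                cell_type=ctype,
                fos_state=(
                    call_fos_state(int(fos[i]), float(vols[i]), median_vol,
                                   fos_base_threshold)
                    if fos is not None else None
                ),
                il34_density=float(il34[i] / vols[i]),
                animal_id=animal_id,
            )
        )
    if n_ambiguous:
        logger.info(
            "quantify_field: %d/%d cells ambiguous (margin < %d)",
            n_ambiguous, nuclei.n_objects, min_margin,
        )
    return pd.DataFrame([vars(r) for r in records])


def il34_by_type(
    records: pd.DataFrame,
    by_fos: bool = False,
) -> pd.DataFrame:
    """Mean IL34 density per (animal, cell type[, Fos state]).

    Ambiguous cells are excluded from the averages (their count is
    reported via the log); every stratum row carries the contributing
    cell n.  Empty strata are simply absent.
    """
    if records.empty:
        return pd.DataFrame(columns=["animal_id", "cell_type", "mean_il34_density", "n_cells"])
    typed = records[records.cell_type != AMBIGUOUS]
    n_excl = len(records) - len(typed)
    if n_excl:
        logger.info("il34_by_type: excluded %d ambiguous cells from averages", n_excl)
    keys = ["animal_id", "cell_type"] + (["fos_state"] if by_fos else [])
    out = (
        typed.groupby(keys, dropna=False)
        .agg(mean_il34_density=("il34_density", "mean"), n_cells=("il34_density", "size"))
        .reset_index()
    )
    return out
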