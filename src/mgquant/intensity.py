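"""Masked mean-gray-value quantification and Hi/Mid/Lo marker binning.

Per-cell marker expression (TMEM119, CD68) is measured as the mean gray
value (MGV) inside the cell's Iba1 mask, normalized to the same cell's
Iba1 MGV (division by default; subtraction available), and binned into
Lo / Mid / Hi states using cutoffs derived once from the pooled
all-animal distribution — never per experimental group, which would
manufacture circular group differences.

Two cutoff rules are provided:

* ``tertile`` — 33.3/66.7 percentiles of the pooled values (default;
  order-statistic based, always defined, permutation invariant);
* ``valley`` — the two deepest antimodes of a kernel-smoothed histogram,
  for data with visibly multimodal expression.

Animal-level summaries report the percentage of that animal's sampled
cells in each joint (CD68 class × TMEM class) category; the nominal
sampling plan is 12 cells per animal (4 cells × 3 images) and is enforced
in strict mode.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd
from scipy.signal import argrelmin
from scipy.stats import gaussian_kde

from .io_core import BinaryMask, logger
from .segmentation import CellObject

__all__ = [
    "IntensityRecord",
    "CutoffSet",
    "masked_mean_gray",
    "measure_cell_markers",
    "derive_cutoffs",
    "classify_value",
    "classify_cells",
    "animal_percentages",
    "CLASSES",
]

CLASSES = ("Lo", "Mid", "Hi")
#: cells high in the lysosomal marker but low in the homeostatic marker
PHAGOCYTIC_NON_HOMEOSTATIC = ("Hi", "Lo")  # (cd68_class, tmem_class)


def masked_mean_gray(image_channel: np.ndarray, mask: BinaryMask) -> float:
    """Arithmetic mean intensity over the mask's true voxels."""
    img = np.asarray(image_channel)
    if img.ndim == 2:
        img = img[None]
    if img.shape != mask.data.shape:
        raise ValueError(f"shape mismatch: image {img.shape} vs mask {mask.data.shape}")
    if mask.voxel_count == 0:
        raise ValueError("empty mask: mean gray value undefined")
    return float(img[mask.data].mean())


@dataclass
class IntensityRecord:
    """Per-cell marker intensities, Iba1-normalized values, and classes."""

    cell_id: int
    iba1_mgv: float
    tmem_mgv: float
    cd68_mgv: float
    tmem_norm: float
    cd68_norm: float
    animal_id: str | None = None
    image_id: str | None = None
    tmem_class: str | None = None
    cd68_class: str | None = None

    @property
    def phagocytic_non_homeostatic(self) -> bool:
        """CD68-high, TMEM119-low phenotype flag (requires classes set)."""
        return (self.cd68_class, self.tmem_class) == PHAGOCYTIC_NON_HOMEOSTATIC


def measure_cell_markers(
    cells: list[CellObject],
    iba1: np.ndarray,
    tmem: np.ndarray,
    cd68: np.ndarray,
    normalization: str = "divide",
) -> list[IntensityRecord]:
    """MGV of each marker within each cell's mask, normalized to Iba1.

    ``normalization`` is ``"divide"`` (marker MGV / Iba1 MGV, default) or
    ``"subtract"`` (marker MGV − Iba1 MGV).
    """
    if normalization not in ("divide", "subtract"):
        raise ValueError(f"unknown normalization {normalization!r}")
    records = []
    for cell in cells:
        sub = cell.bbox
        i = masked_mean_gray(np.asarray(iba1)[sub], cell.mask)
        t = masked_mean_gray(np.asarray(tmem)[sub], cell.mask)
        c = masked_mean_gray(np.asarray(cd68)[sub], cell.mask)
        if normalization == "divide":
            if i <= 0:
                raise ValueError(f"cell {cell.cell_id}: Iba1 MGV must be > 0 to divide")
            tn, cn = t / i, c / i
        else:
            tn, cn = t - i, c - i
        records.append(
            IntensityRecord(
                cell_id=cell.cell_id,
                iba1_mgv=i, tmem_mgv=t, cd68_mgv=c,
                tmem_norm=tn, cd68_norm=cn,
                animal_id=cell.animal_id, image_id=cell.image_id,
            )
        )
    return records


@dataclass
class CutoffSet:
    """Lower/upper class boundaries on the normalized scale, with provenance."""

    lower: float
    upper: float
    derivation_rule: str
    source_population_size: int
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.lower < self.upper:
            raise ValueError(f"cutoffs must satisfy lower < upper, got {self}")


def derive_cutoffs(
    normalized_values,
    rule: str = "tertile",
    kde_bandwidth: float | str = "scott",
    grid_size: int = 512,
) -> CutoffSet:
    """Derive Lo/Mid/Hi boundaries from a pooled value distribution.

    ``tertile``: boundaries at the 33.3rd and 66.7th percentiles.
    ``valley``: Gaussian-KDE smooth the histogram and place boundaries at
    the two deepest interior local minima (antimodes).  Requires the
    smoothed density to actually have two antimodes; otherwise an error
    asks the caller to fall back to tertiles.
    """
    values = np.asarray(list(normalized_values), dtype=float)
    if values.size < 9:
        raise ValueError(f"need >= 9 values to derive 3-class cutoffs, got {values.size}")
    if not np.all(np.isfinite(values)):
        raise ValueError("values must be finite")
    if values.max() == values.min():
        raise ValueError("all values identical: no separation to derive cutoffs")
    if rule == "tertile":
        lower, upper = np.percentile(values, [100 / 3, 200 / 3])
        return CutoffSet(float(lower), float(upper), "tertile", values.size)
    if rule == "valley":
        kde = gaussian_kde(values, bw_method=kde_bandwidth)
        pad = 0.05 * (values.max() - values.min())
        grid = np.linspace(values.min() - pad, values.max() + pad, grid_size)
        dens = kde(grid)
        minima = argrelmin(dens)[0]
        if minima.size < 2:
            raise ValueError(
                "valley rule needs >= 2 antimodes in the smoothed histogram; "
                f"found {minima.size} — use rule='tertile'"
            )
        deepest = minima[np.argsort(dens[minima])[:2]]
        lower, upper = sorted(grid[deepest])
        return CutoffSet(
            float(lower), float(upper), "valley", values.size,
            extra={"bandwidth": kde.factor, "grid_size": grid_size},
        )
    raise ValueError(f"unknown cutoff rule {rule!r}")


def classify_value(value: float, cutoffs: CutoffSet) -> str:
    """Lo below the lower bound, Hi above the upper, Mid otherwise.

    Values exactly on a boundary tie inward to Mid.
    """
    if value < cutoffs.lower:
        return "Lo"
    if value > cutoffs.upper:
        return "Hi"
    return "Mid"


def classify_cells(
    records: list[IntensityRecord],
    tmem_cutoffs: CutoffSet,
    cd68_cutoffs: CutoffSet,
) -> list[IntensityRecord]:
    """Assign per-marker classes in place and return the records.

    A total function: every cell receives exactly one class per marker.
    """
    for r in records:
        r.tmem_class = classify_value(r.tmem_norm, tmem_cutoffs)
        r.cd68_class = classify_value(r.cd68_norm, cd68_cutoffs)
    return records


def animal_percentages(
    records: list[IntensityRecord],
    cells_per_animal: int = 12,
    strict: bool = True,
) -> pd.DataFrame:
    """Per-animal percentages of cells in each joint (CD68 × TMEM) category.

    The nominal design samples ``cells_per_animal`` (12 = 4 cells × 3
    images) cells per animal.  In strict mode an animal with any other
    cell count is an error; in relaxed mode it is a logged warning and
    the available n is used as the denominator.  Returns one row per
    animal with the 9 joint percentages plus the 3+3 per-marker marginal
    percentages (each marginal set sums to 100 exactly).
    """
    if any(r.tmem_class is None or r.cd68_class is None for r in records):
        raise ValueError("classify_cells must run before animal_percentages")
    df = pd.DataFrame(
        {
            "animal_id": [r.animal_id for r in records],
            "tmem_class": [r.tmem_class for r in records],
            "cd68_class": [r.cd68_class for r in records],
        }
    )
    rows = []
    for animal, grp in df.groupby("animal_id", sort=True):
        n = len(grp)
        if n != cells_per_animal:
            msg = (
                f"animal {animal}: {n} cells, sampling plan expects "
                f"{cells_per_animal} (4 cells x 3 images)"
            )
            if strict:
                raise ValueError(msg + "; pass strict=False to override")
            logger.warning("%s; using n=%d", msg, n)
        row: dict = {"animal_id": animal, "n_cells": n}
        for cd, tm in product(CLASSES, CLASSES):
            pct = 100.0 * ((grp.cd68_class == cd) & (grp.tmem_class == tm)).sum() / n
            row[f"pct_CD68{cd}_TMEM{tm}"] = pct
        for cls in CLASSES:
            row[f"pct_CD68{cls}"] = 100.0 * (grp.cd68_class == cls).sum() / n
            row[f"pct_TMEM{cls}"] = 100.0 * (grp.tmem_class == cls).sum() / n
        rows.append(row)
    return pd.DataFrame(rows)
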