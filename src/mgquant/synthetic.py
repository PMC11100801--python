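"""Seeded synthetic-microscopy generators with voxel-exact ground truth.

Every input the pipeline consumes can be generated here as a phantom with
the truth attached, so each analysis stage can be validated by recovery:
run the stage on a generated field and compare its output to what was
planted.

The phantoms emulate the imaging designs the pipeline targets:

* ``generate_microglia_volume`` — sparse branched cells (spherical soma +
  persistent-random-walk processes) on a dark background, with lysosomal
  blobs nested inside cells and synaptic puncta partly nested inside
  lysosomes at a controlled engulfed fraction.  Channels: Iba1, CD68,
  VGlut2, TMEM119.
* ``generate_fish_field`` — nucleus fields with per-cell puncta counts
  drawn from cell-type-dependent negative-binomial distributions
  (excitatory target mean defaults to 2× inhibitory).  Channels: DAPI,
  VGlut1, Gad2, IL34.
* ``generate_synapse_field`` — pre/post puncta with a controlled
  colocalized fraction.
* ``generate_sholl_phantom`` — a k-arm star whose ring-intersection
  profile is known analytically.
* ``generate_assay_table`` — Ct pairs and ELISA rows with known fold
  changes.

Intensity model: piecewise-constant foreground/background plus additive
Gaussian noise, clipped at zero.  At the default levels (background 10,
foreground 100, sd 5) the classes are separated by 18 noise sd, so
threshold-based recovery is essentially exact and recovery tests measure
the geometry of the pipeline, not the luck of the noise draw.

Determinism: each generator draws from one RNG stream derived from
``(seed, stage-name)``, so a given config reproduces its output
bit-exactly and the stages are independently reproducible.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field as dc_field
from typing import Any, Mapping

import numpy as np
import pandas as pd

from .io_core import VolumeImage

__all__ = [
    "GeneratorConfig",
    "GroundTruth",
    "FieldTooCrowdedError",
    "generate_microglia_volume",
    "generate_fish_field",
    "generate_synapse_field",
    "generate_sholl_phantom",
    "generate_assay_table",
    "generate_intensity_population",
    "generate_animal_summaries",
    "engulfment_config",
    "counting_config",
    "fish_config",
    "synapse_config",
]


class FieldTooCrowdedError(RuntimeError):
    """Raised when the requested cells cannot be placed at the required
    pairwise separation within the given field after bounded retries."""


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """One independent, reproducible RNG stream per (seed, stage)."""
    digest = hashlib.sha256(stage.encode()).digest()
    stage_int = int.from_bytes(digest[:4], "little")
    return np.random.default_rng(np.random.SeedSequence([int(seed), stage_int]))


_DEFAULT_FISH_MEANS: dict[str, dict[str, float]] = {
    "glutamatergic": {"VGlut1": 10.0, "Gad2": 0.5, "IL34": 10.0},
    "GABAergic": {"VGlut1": 0.5, "Gad2": 10.0, "IL34": 5.0},
}

#: TMEM119 expression multipliers for the three planted cell states
_TMEM_LEVELS = {"Lo": 0.25, "Mid": 0.55, "Hi": 1.0}


@dataclass
class GeneratorConfig:
    """Parameters shared by the field generators.

    Lengths in µm, intensities in arbitrary units.  ``field_shape`` may
    be None, in which case the field is sized automatically so that
    ``n_cells`` fit at the enforced separation (auto-sizing cannot fail;
    an explicit too-small shape raises :class:`FieldTooCrowdedError`).
    """

    seed: int = 0
    field_shape: tuple[int, int, int] | None = None  # (z, y, x) voxels
    voxel_size: tuple[float, float, float] = (0.33, 0.1, 0.1)  # µm
    n_cells: int = 10
    soma_radius: float = 2.0
    n_processes_per_cell: int = 4
    process_length: float = 6.0
    process_radius: float = 0.3
    lysosome_fraction: float = 0.05
    lysosome_radius: float = 0.5
    n_synaptic_puncta: int = 60
    engulfed_fraction: float = 0.25
    coloc_probability: float = 0.5
    puncta_radius_px: float = 1.5
    background_level: float = 10.0
    foreground_level: float = 100.0
    noise_sd: float = 5.0
    fish_type_means: Mapping[str, Mapping[str, float]] = dc_field(
        default_factory=lambda: {k: dict(v) for k, v in _DEFAULT_FISH_MEANS.items()}
    )
    fish_dispersion: float = 10.0  # NB size parameter; np.inf -> Poisson

    def __post_init__(self) -> None:
        for name in ("lysosome_fraction", "engulfed_fraction", "coloc_probability"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in (
            "soma_radius", "process_length", "process_radius",
            "lysosome_radius", "puncta_radius_px", "foreground_level",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel sizes must be positive")
        if self.n_cells < 0 or self.n_synaptic_puncta < 0:
            raise ValueError("counts must be non-negative")
        if self.noise_sd < 0 or self.background_level < 0:
            raise ValueError("background and noise must be non-negative")
        if self.fish_dispersion <= 0:
            raise ValueError("fish_dispersion must be positive")
        for ctype, means in self.fish_type_means.items():
            for chan, mu in means.items():
                if mu <= 0:
                    raise ValueError(
                        f"fish mean for ({ctype}, {chan}) must be > 0, got {mu}"
                    )

    @property
    def min_separation(self) -> float:
        """Enforced pairwise soma separation (µm): cells are confined to a
        ball of radius soma_radius + process_length, so twice that (plus a
        1 µm guard) guarantees disjoint cell masks.  Never below the
        4×soma_radius floor."""
        return max(
            4.0 * self.soma_radius,
            2.0 * (self.soma_radius + self.process_length) + 1.0,
        )


def engulfment_config(seed: int = 0, **kw: Any) -> GeneratorConfig:
    """High-resolution 3D geometry (60×/0.33 µm steps, 0.1 µm in plane)."""
    kw.setdefault("voxel_size", (0.33, 0.1, 0.1))
    kw.setdefault("n_cells", 10)
    return GeneratorConfig(seed=seed, **kw)


def counting_config(n_cells: int, seed: int = 0, **kw: Any) -> GeneratorConfig:
    """Low-magnification counting geometry (20×/1 µm steps, 0.3 µm in plane)."""
    kw.setdefault("voxel_size", (1.0, 0.3, 0.3))
    kw.setdefault("process_length", 4.0)
    kw.setdefault("lysosome_fraction", 0.0)
    kw.setdefault("n_synaptic_puncta", 0)
    return GeneratorConfig(seed=seed, n_cells=n_cells, **kw)


def fish_config(seed: int = 0, n_cells: int = 400, **kw: Any) -> GeneratorConfig:
    """FISH geometry: 0.33 µm steps, 0.2 µm in plane; soma_radius is the
    nucleus radius."""
    kw.setdefault("voxel_size", (0.33, 0.2, 0.2))
    kw.setdefault("soma_radius", 3.0)
    kw.setdefault("puncta_radius_px", 1.2)
    return GeneratorConfig(seed=seed, n_cells=n_cells, **kw)


def synapse_config(seed: int = 0, n_synaptic_puncta: int = 200, **kw: Any) -> GeneratorConfig:
    """Planar synaptic-puncta field at 0.1 µm pixels."""
    kw.setdefault("voxel_size", (0.33, 0.1, 0.1))
    return GeneratorConfig(seed=seed, n_synaptic_puncta=n_synaptic_puncta, **kw)


@dataclass
class GroundTruth:
    """Generator-side truth for recovery tests.

    All volumes are derived from the emitted label/mask grids by voxel
    counting at generation time, so re-counting those grids reproduces
    the recorded values exactly.
    """

    n_cells: int = 0
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    per_cell_true_volume: np.ndarray = dc_field(default_factory=lambda: np.zeros(0))
    per_cell_true_lysosome_volume: np.ndarray = dc_field(default_factory=lambda: np.zeros(0))
    per_cell_true_engulfed_volume: np.ndarray = dc_field(default_factory=lambda: np.zeros(0))
    per_cell_class_label: list[str] = dc_field(default_factory=list)
    per_cell_type: list[str] = dc_field(default_factory=list)
    per_cell_true_puncta: dict[str, np.ndarray] = dc_field(default_factory=dict)
    colocalized_pair_count: int = 0
    soma_centers_um: np.ndarray = dc_field(default_factory=lambda: np.zeros((0, 3)))
    cell_labels: np.ndarray | None = None  # (z,y,x), 0 background, 1..n cells
    lysosome_mask: np.ndarray | None = None
    synaptic_mask: np.ndarray | None = None
    puncta_centroids_um: np.ndarray | None = None
    puncta_engulfed: np.ndarray | None = None
    extra: dict[str, Any] = dc_field(default_factory=dict)

    def validate(self) -> None:
        eps = 1e-9
        if not (
            np.all(self.per_cell_true_engulfed_volume
                   <= self.per_cell_true_lysosome_volume + eps)
            and np.all(self.per_cell_true_lysosome_volume
                       <= self.per_cell_true_volume + eps)
        ):
            raise AssertionError("truth nesting violated: engulfed <= lysosome <= cell")
        if self.per_cell_class_label and len(self.per_cell_class_label) != self.n_cells:
            raise AssertionError("class labels must cover every generated cell")


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------


def _paint_ellipsoid(
    grid: np.ndarray,
    center_um: np.ndarray,
    radii_um: np.ndarray,
    voxel_size: np.ndarray,
    value: int | bool = True,
) -> None:
    """Set voxels whose centres lie within the physical ellipsoid."""
    lo = np.maximum(0, np.floor((center_um - radii_um) / voxel_size).astype(int))
    hi = np.minimum(
        np.array(grid.shape) - 1,
        np.ceil((center_um + radii_um) / voxel_size).astype(int),
    )
    if np.any(hi < lo):
        return
    axes = [np.arange(l, h + 1) for l, h in zip(lo, hi)]
    zz, yy, xx = np.meshgrid(*axes, indexing="ij")
    d2 = (
        ((zz * voxel_size[0] - center_um[0]) / radii_um[0]) ** 2
        + ((yy * voxel_size[1] - center_um[1]) / radii_um[1]) ** 2
        + ((xx * voxel_size[2] - center_um[2]) / radii_um[2]) ** 2
    )
    sub = grid[lo[0] : hi[0] + 1, lo[1] : hi[1] + 1, lo[2] : hi[2] + 1]
    sub[d2 <= 1.0] = value


def _jittered_grid_sites(
    rng: np.random.Generator,
    n: int,
    sep: float,
    margin: float,
) -> tuple[np.ndarray, float]:
    """``n`` random (y, x) positions with pairwise distance >= ``sep``.

    Sites sit on a square grid of pitch ``1.2 * sep`` jittered by up to
    ±0.1·sep per axis, which preserves the separation guarantee while
    randomizing positions; the required field side (µm) is returned.
    """
    pitch = 1.2 * sep
    jit = 0.1 * sep
    cols = int(np.ceil(np.sqrt(max(n, 1))))
    rows = int(np.ceil(max(n, 1) / cols))
    side = max(rows, cols) * pitch + 2 * margin
    sites = []
    for r in range(rows):
        for c in range(cols):
            sites.append(
                (
                    margin + (r + 0.5) * pitch,
                    margin + (c + 0.5) * pitch,
                )
            )
    sites_arr = np.asarray(sites)
    chosen = rng.choice(len(sites_arr), size=n, replace=False) if n else np.zeros(0, int)
    pos = sites_arr[chosen] + rng.uniform(-jit, jit, size=(n, 2))
    return pos, side


def _dart_throw_sites(
    rng: np.random.Generator,
    n: int,
    sep: float,
    margin: float,
    extent_yx: tuple[float, float],
    max_tries_per_cell: int = 200,
) -> np.ndarray:
    """Rejection-sample ``n`` (y, x) positions at min distance ``sep`` in a
    fixed extent; raises :class:`FieldTooCrowdedError` on failure."""
    ey, ex = extent_yx
    if ey - 2 * margin <= 0 or ex - 2 * margin <= 0:
        raise FieldTooCrowdedError("field smaller than placement margin")
    placed: list[np.ndarray] = []
    for _ in range(n):
        for _try in range(max_tries_per_cell):
            cand = np.array(
                [rng.uniform(margin, ey - margin), rng.uniform(margin, ex - margin)]
            )
            if all(np.linalg.norm(cand - p) >= sep for p in placed):
                placed.append(cand)
                break
        else:
            raise FieldTooCrowdedError(
                f"could not place cell {len(placed) + 1}/{n} at separation "
                f"{sep:.1f} µm after {max_tries_per_cell} tries: field too crowded"
            )
    return np.asarray(placed).reshape(n, 2)


def _place_cells_yx(
    cfg: GeneratorConfig, rng: np.random.Generator, sep: float, margin: float
) -> tuple[np.ndarray, tuple[int, int, int]]:
    """Soma (y, x) positions plus the final field shape in voxels."""
    dz, dy, dx = cfg.voxel_size
    if cfg.field_shape is not None:
        nz, ny, nx = cfg.field_shape
        pos = _dart_throw_sites(
            rng, cfg.n_cells, sep, margin, ((ny - 1) * dy, (nx - 1) * dx)
        )
        return pos, (nz, ny, nx)
    pos, side = _jittered_grid_sites(rng, cfg.n_cells, sep, margin)
    ny = nx = int(np.ceil(side / dy)) + 1
    z_extent = 2.0 * cfg.soma_radius + 2.0
    nz = max(1, int(np.ceil(z_extent / dz)) + 1)
    return pos, (nz, ny, nx)


def _noisy_channels(
    rng: np.random.Generator,
    cfg: GeneratorConfig,
    foreground: list[np.ndarray],
) -> np.ndarray:
    """Stack piecewise-constant foreground maps into noisy channels.

    All arithmetic stays in float32; the noise draw order is fixed so a
    given config reproduces the volume bit-exactly.
    """
    out = np.empty((len(foreground), *foreground[0].shape), dtype=np.float32)
    for i, fg in enumerate(foreground):
        ch = out[i]
        if cfg.noise_sd > 0:
            rng.standard_normal(size=ch.shape, dtype=np.float32, out=ch)
            ch *= np.float32(cfg.noise_sd)
        else:
            ch.fill(0.0)
        ch += np.float32(cfg.background_level)
        ch += fg.astype(np.float32, copy=False)
        np.clip(ch, 0.0, None, out=ch)
    return out


# ---------------------------------------------------------------------------
# microglia engulfment / counting phantom
# ---------------------------------------------------------------------------


def generate_microglia_volume(cfg: GeneratorConfig) -> tuple[VolumeImage, GroundTruth]:
    """Branched-cell phantom with nested lysosomes and synaptic puncta.

    Returns a 4-channel volume (Iba1, CD68, VGlut2, TMEM119) and truth
    holding the cell label grid, the lysosome and synaptic masks, and
    voxel-exact per-cell volumes.  Exactly
    ``round(engulfed_fraction * n_synaptic_puncta)`` puncta are centred
    inside lysosomes; the remainder lie on the background, clear of any
    cell.
    """
    rng = stage_rng(cfg.seed, "microglia")
    dzyx = np.asarray(cfg.voxel_size)
    reach = cfg.soma_radius + cfg.process_length
    sep = cfg.min_separation
    margin = reach + 1.0
    pos_yx, shape = _place_cells_yx(cfg, rng, sep, margin)
    nz, ny, nx = shape
    zc = (nz - 1) * dzyx[0] / 2.0

    cell_labels = np.zeros(shape, dtype=np.int16)
    centers = np.zeros((cfg.n_cells, 3))
    class_labels: list[str] = []
    step = min(dzyx[1], dzyx[2]) * 2.5
    for k in range(cfg.n_cells):
        c = np.array([zc, pos_yx[k, 0], pos_yx[k, 1]])
        centers[k] = c
        _paint_ellipsoid(cell_labels, c, np.full(3, cfg.soma_radius), dzyx, k + 1)
        class_labels.append(rng.choice(["Lo", "Mid", "Hi"]))
        for _ in range(cfg.n_processes_per_cell):
            d = rng.normal(size=3)
            d[0] *= 0.25  # keep processes mostly in-plane, as in thin stacks
            d /= np.linalg.norm(d)
            p = c + cfg.soma_radius * d
            n_steps = int(cfg.process_length / step) + 1
            for _s in range(n_steps):
                d = d + rng.normal(scale=0.25, size=3) * np.array([0.25, 1.0, 1.0])
                d /= np.linalg.norm(d)
                p = p + step * d
                if np.linalg.norm(p - c) > reach:
                    break
                _paint_ellipsoid(
                    cell_labels, p,
                    np.array([max(cfg.process_radius, dzyx[0] * 0.51),
                              cfg.process_radius, cfg.process_radius]),
                    dzyx, k + 1,
                )

    cell_counts = np.bincount(cell_labels.ravel(), minlength=cfg.n_cells + 1)[1:]

    # lysosomes: blobs nested inside each cell until the target fraction;
    # all work happens inside the cell's bounding box
    from scipy import ndimage as _ndi

    lysosome = np.zeros(shape, dtype=bool)
    lys_radii = np.array(
        [max(cfg.lysosome_radius, dzyx[0] * 0.51), cfg.lysosome_radius, cfg.lysosome_radius]
    )
    cell_bboxes = _ndi.find_objects(cell_labels) if cfg.n_cells else []
    for k in range(cfg.n_cells):
        target = int(round(cfg.lysosome_fraction * cell_counts[k]))
        if target == 0:
            continue
        bbox = cell_bboxes[k]
        local_cell = cell_labels[bbox] == k + 1
        cell_vox = np.argwhere(local_cell)
        blob = np.zeros(local_cell.shape, dtype=bool)
        for _ in range(200):
            if np.count_nonzero(blob) >= target:
                break
            seed_vox = cell_vox[rng.integers(len(cell_vox))]
            _paint_ellipsoid(blob, seed_vox * dzyx, lys_radii, dzyx, True)
            blob &= local_cell  # lysosomes never leave the cell
        lysosome[bbox] |= blob

    # synaptic puncta: engulfed ones centred on lysosome voxels
    n_eng = int(round(cfg.engulfed_fraction * cfg.n_synaptic_puncta))
    synaptic = np.zeros(shape, dtype=bool)
    punc_radii = np.array(
        [dzyx[0] * 1.01, cfg.puncta_radius_px * dzyx[1], cfg.puncta_radius_px * dzyx[2]]
    )
    centroids: list[np.ndarray] = []
    engulfed_flags: list[bool] = []
    lys_vox = np.argwhere(lysosome)
    if n_eng > 0 and len(lys_vox) == 0:
        raise ValueError(
            "engulfed_fraction > 0 requires lysosome_fraction > 0 and n_cells > 0"
        )
    for _ in range(n_eng):
        v = lys_vox[rng.integers(len(lys_vox))]
        cu = v * dzyx
        _paint_ellipsoid(synaptic, cu, punc_radii, dzyx, True)
        centroids.append(cu)
        engulfed_flags.append(True)
    n_bg = cfg.n_synaptic_puncta - n_eng
    for _ in range(n_bg):
        for _try in range(1000):
            cu = np.array(
                [
                    rng.uniform(0, (nz - 1) * dzyx[0]),
                    rng.uniform(0, (ny - 1) * dzyx[1]),
                    rng.uniform(0, (nx - 1) * dzyx[2]),
                ]
            )
            if cfg.n_cells == 0 or np.min(
                np.linalg.norm(centers - cu, axis=1)
            ) > reach + 1.0:
                break
        else:  # pragma: no cover - background always exists at enforced sizes
            raise FieldTooCrowdedError("no background room for synaptic puncta")
        _paint_ellipsoid(synaptic, cu, punc_radii, dzyx, True)
        centroids.append(cu)
        engulfed_flags.append(False)

    lys_counts = np.bincount(
        cell_labels[lysosome].ravel(), minlength=cfg.n_cells + 1
    )[1:]
    eng_counts = np.bincount(
        cell_labels[lysosome & synaptic].ravel(), minlength=cfg.n_cells + 1
    )[1:]

    fg = np.float32(cfg.foreground_level - cfg.background_level)
    tmem_fg = (
        np.array([0.0] + [_TMEM_LEVELS[c] for c in class_labels]) * fg
    ).astype(np.float32)
    channels = _noisy_channels(
        rng,
        cfg,
        [
            (cell_labels > 0).astype(np.float32) * fg,
            lysosome.astype(np.float32) * fg,
            synaptic.astype(np.float32) * fg,
            tmem_fg[cell_labels],
        ],
    )
    volume = VolumeImage(
        channels, cfg.voxel_size, ("Iba1", "CD68", "VGlut2", "TMEM119")
    )
    voxvol = float(np.prod(dzyx))
    truth = GroundTruth(
        n_cells=cfg.n_cells,
        voxel_size=cfg.voxel_size,
        per_cell_true_volume=cell_counts * voxvol,
        per_cell_true_lysosome_volume=lys_counts * voxvol,
        per_cell_true_engulfed_volume=eng_counts * voxvol,
        per_cell_class_label=class_labels,
        soma_centers_um=centers,
        cell_labels=cell_labels,
        lysosome_mask=lysosome,
        synaptic_mask=synaptic,
        puncta_centroids_um=np.asarray(centroids).reshape(-1, 3),
        puncta_engulfed=np.asarray(engulfed_flags, dtype=bool),
        extra={"n_engulfed_puncta": n_eng},
    )
    truth.validate()
    return volume, truth


# ---------------------------------------------------------------------------
# FISH phantom
# ---------------------------------------------------------------------------


def _nb_counts(
    rng: np.random.Generator, mean: float, dispersion: float, n: int
) -> np.ndarray:
    """Overdispersed counts: NB with var = mean + mean²/dispersion;
    dispersion = inf gives the Poisson limit."""
    if not np.isfinite(dispersion):
        return rng.poisson(mean, size=n)
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p, size=n)


def generate_fish_field(cfg: GeneratorConfig) -> tuple[VolumeImage, GroundTruth]:
    """Nucleus field with per-cell, type-dependent puncta counts.

    Cell types alternate so the field carries ``n_cells // 2`` of each;
    puncta are placed wholly inside their nucleus with same-channel
    centroid separation enforced, so centroid assignment and component
    counting recover the planted counts.
    """
    required = {"glutamatergic", "GABAergic"}
    if not required <= set(cfg.fish_type_means):
        raise ValueError(f"fish_type_means must include {sorted(required)}")
    rng = stage_rng(cfg.seed, "fish")
    dzyx = np.asarray(cfg.voxel_size)
    r_nuc = cfg.soma_radius
    sep = max(2.0 * (1.1 * r_nuc) + 0.8, 4.0 * r_nuc * 0.55)
    margin = 1.2 * r_nuc + 0.5
    pos_yx, shape = _place_cells_yx(cfg, rng, sep, margin)
    nz, ny, nx = shape
    zc = (nz - 1) * dzyx[0] / 2.0

    types = ["glutamatergic", "GABAergic"] * (cfg.n_cells // 2 + 1)
    types = types[: cfg.n_cells]
    rng.shuffle(types)

    nucleus_labels = np.zeros(shape, dtype=np.int32)
    radii = rng.uniform(0.9 * r_nuc, 1.1 * r_nuc, size=cfg.n_cells)
    centers = np.zeros((cfg.n_cells, 3))
    for k in range(cfg.n_cells):
        c = np.array([zc, pos_yx[k, 0], pos_yx[k, 1]])
        centers[k] = c
        _paint_ellipsoid(nucleus_labels, c, np.full(3, radii[k]), dzyx, k + 1)
    nuc_counts = np.bincount(nucleus_labels.ravel(), minlength=cfg.n_cells + 1)[1:]

    channels = ["VGlut1", "Gad2", "IL34"]
    counts = {
        ch: np.array(
            [
                _nb_counts(rng, cfg.fish_type_means[types[k]][ch], cfg.fish_dispersion, 1)[0]
                for k in range(cfg.n_cells)
            ],
            dtype=int,
        )
        for ch in channels
    }

    punc_r_um = cfg.puncta_radius_px * float(min(dzyx[1], dzyx[2]))
    punc_radii = np.array([dzyx[0] * 1.01, punc_r_um, punc_r_um])
    # jittered anisotropic lattice of candidate sites inside each nucleus:
    # the per-axis pitch leaves two clear voxels between painted balls even
    # under 26-connectivity, so same-channel puncta can never blend into
    # one detected object
    pitch_vec = 1.25 * (2.0 * punc_radii + 2.0 * dzyx)
    masks = {ch: np.zeros(shape, dtype=bool) for ch in channels}
    for k in range(cfg.n_cells):
        allowed_r = max(radii[k] - punc_r_um - float(dzyx[0]), 0.3)
        ms = np.floor(allowed_r / pitch_vec).astype(int)
        offs = [np.arange(-m, m + 1) * p for m, p in zip(ms, pitch_vec)]
        zz, yy, xx = np.meshgrid(*offs, indexing="ij")
        lattice = np.stack([zz, yy, xx], axis=-1).reshape(-1, 3)
        lattice = lattice[np.linalg.norm(lattice, axis=1) <= allowed_r]
        if len(lattice) == 0:
            lattice = np.zeros((1, 3))
        for ch in channels:
            want = int(counts[ch][k])
            if want > len(lattice):
                # nucleus at capacity: cap the planted count; truth records
                # what was actually placed
                counts[ch][k] = want = len(lattice)
            chosen = lattice[rng.choice(len(lattice), size=want, replace=False)]
            jitter = rng.uniform(-0.1, 0.1, size=(want, 3)) * pitch_vec
            for cand in centers[k] + chosen + jitter:
                _paint_ellipsoid(masks[ch], cand, punc_radii, dzyx, True)

    fg = np.float32(cfg.foreground_level - cfg.background_level)
    data = _noisy_channels(
        rng, cfg,
        [(nucleus_labels > 0).astype(np.float32) * fg]
        + [masks[ch].astype(np.float32) * fg for ch in channels],
    )
    volume = VolumeImage(data, cfg.voxel_size, ("DAPI", "VGlut1", "Gad2", "IL34"))
    voxvol = float(np.prod(dzyx))
    truth = GroundTruth(
        n_cells=cfg.n_cells,
        voxel_size=cfg.voxel_size,
        per_cell_true_volume=nuc_counts * voxvol,
        per_cell_true_lysosome_volume=np.zeros(cfg.n_cells),
        per_cell_true_engulfed_volume=np.zeros(cfg.n_cells),
        per_cell_type=list(types),
        per_cell_true_puncta={ch: counts[ch].copy() for ch in channels},
        soma_centers_um=centers,
        cell_labels=nucleus_labels,
        extra={"nucleus_radii_um": radii},
    )
    truth.validate()
    return volume, truth


# ---------------------------------------------------------------------------
# synaptic colocalization phantom
# ---------------------------------------------------------------------------


def generate_synapse_field(cfg: GeneratorConfig) -> tuple[VolumeImage, GroundTruth]:
    """Planar pre/post puncta field with a controlled colocalized fraction.

    ``round(coloc_probability * n)`` pre/post pairs are placed sharing
    voxels (centroid offset below half a punctum radius); all remaining
    puncta sit on their own sites with all-pairs separation enforced, so
    the planted pair count is exactly the number of truly colocalized
    pairs under both the overlap and small-radius centroid criteria.
    """
    rng = stage_rng(cfg.seed, "synapse")
    dzyx = np.asarray(cfg.voxel_size)
    n = cfg.n_synaptic_puncta
    n_coloc = int(round(cfg.coloc_probability * n))
    n_sites = n_coloc + 2 * (n - n_coloc)
    punc_r_um = cfg.puncta_radius_px * float(min(dzyx[1], dzyx[2]))
    sep = 4.0 * punc_r_um + 1.0

    if cfg.field_shape is not None:
        nz, ny, nx = cfg.field_shape
        sites = _dart_throw_sites(
            rng, n_sites, sep, punc_r_um + 0.2, ((ny - 1) * dzyx[1], (nx - 1) * dzyx[2])
        )
    else:
        sites, side = _jittered_grid_sites(rng, n_sites, sep, punc_r_um + 0.5)
        ny = nx = int(np.ceil(side / dzyx[1])) + 1
        nz = 1
    shape = (nz, ny, nx)
    zc = (nz - 1) * dzyx[0] / 2.0

    pre = np.zeros(shape, dtype=bool)
    post = np.zeros(shape, dtype=bool)
    punc_radii = np.array([dzyx[0] * 1.01, punc_r_um, punc_r_um])
    order = rng.permutation(n_sites)
    pre_centroids, post_centroids = [], []
    for i in range(n_coloc):
        c = np.array([zc, *sites[order[i]]])
        off = rng.uniform(-0.4 * punc_r_um, 0.4 * punc_r_um, size=2)
        _paint_ellipsoid(pre, c, punc_radii, dzyx, True)
        _paint_ellipsoid(post, c + np.array([0.0, *off]), punc_radii, dzyx, True)
        pre_centroids.append(c)
        post_centroids.append(c + np.array([0.0, *off]))
    cursor = n_coloc
    for _ in range(n - n_coloc):
        c = np.array([zc, *sites[order[cursor]]])
        _paint_ellipsoid(pre, c, punc_radii, dzyx, True)
        pre_centroids.append(c)
        cursor += 1
    for _ in range(n - n_coloc):
        c = np.array([zc, *sites[order[cursor]]])
        _paint_ellipsoid(post, c, punc_radii, dzyx, True)
        post_centroids.append(c)
        cursor += 1

    fg = np.float32(cfg.foreground_level - cfg.background_level)
    data = _noisy_channels(
        rng, cfg, [pre.astype(np.float32) * fg, post.astype(np.float32) * fg]
    )
    volume = VolumeImage(data, cfg.voxel_size, ("VGlut2", "PSD95"))
    truth = GroundTruth(
        n_cells=0,
        voxel_size=cfg.voxel_size,
        colocalized_pair_count=n_coloc,
        extra={
            "n_pre": n,
            "n_post": n,
            "pre_centroids_um": np.asarray(pre_centroids).reshape(-1, 3),
            "post_centroids_um": np.asarray(post_centroids).reshape(-1, 3),
            "pre_mask": pre,
            "post_mask": post,
        },
    )
    return volume, truth


# ---------------------------------------------------------------------------
# Sholl star phantom
# ---------------------------------------------------------------------------


def generate_sholl_phantom(
    n_arms: int,
    arm_length_um: float,
    pixel_size_um: float,
    soma_radius_um: float = 3.0,
    angles_rad: np.ndarray | None = None,
    seed: int | None = None,
) -> tuple[VolumeImage, GroundTruth]:
    """Binary k-arm star: a filled soma disc with straight one-pixel rays.

    Every ring with radius strictly between the soma edge and the arm
    tips crosses each arm exactly once, so the expected profile is
    ``n_arms`` there and 0 beyond.  Angles default to an even spread,
    randomly rotated when ``seed`` is given.
    """
    from skimage.draw import line as _draw_line

    if n_arms < 1:
        raise ValueError("n_arms must be >= 1")
    if arm_length_um <= soma_radius_um:
        raise ValueError("arms must extend beyond the soma")
    if angles_rad is None:
        offset = 0.0
        if seed is not None:
            offset = float(stage_rng(seed, "sholl").uniform(0, 2 * np.pi))
        angles_rad = offset + np.arange(n_arms) * (2 * np.pi / n_arms)
    angles_rad = np.asarray(angles_rad, dtype=float)
    if angles_rad.size != n_arms:
        raise ValueError("need one angle per arm")
    if n_arms > 1:
        wrapped = np.sort(np.mod(angles_rad, 2 * np.pi))
        gaps = np.diff(np.concatenate([wrapped, [wrapped[0] + 2 * np.pi]]))
        if np.min(gaps) < 1e-6:
            raise ValueError("arm angles must be distinct")

    arm_px = arm_length_um / pixel_size_um
    half = int(np.ceil(arm_px)) + 3
    side = 2 * half + 1
    img = np.zeros((side, side), dtype=bool)
    cy = cx = half
    yy, xx = np.mgrid[0:side, 0:side]
    img[(yy - cy) ** 2 + (xx - cx) ** 2 <= (soma_radius_um / pixel_size_um) ** 2] = True
    for a in angles_rad:
        ey = int(round(cy + arm_px * np.sin(a)))
        ex = int(round(cx + arm_px * np.cos(a)))
        if not (0 <= ey < side and 0 <= ex < side):
            raise ValueError("arm exceeds the field")
        rr, cc = _draw_line(cy, cx, ey, ex)
        img[rr, cc] = True

    volume = VolumeImage(
        img[None, None].astype(np.float32) * 100.0,
        (1.0, pixel_size_um, pixel_size_um),
        ("Iba1",),
    )
    truth = GroundTruth(
        n_cells=1,
        voxel_size=(1.0, pixel_size_um, pixel_size_um),
        soma_centers_um=np.array([[0.0, cy * pixel_size_um, cx * pixel_size_um]]),
        extra={
            "n_arms": n_arms,
            "arm_length_um": arm_length_um,
            "soma_radius_um": soma_radius_um,
            "angles_rad": angles_rad,
        },
    )
    return volume, truth


# ---------------------------------------------------------------------------
# tabular generators
# ---------------------------------------------------------------------------


def generate_assay_table(
    seed: int = 0,
    group_fold_changes: Mapping[str, float] | None = None,
    n_per_group: int = 6,
    ct_noise_sd: float = 0.15,
    reference_ct_mean: float = 15.0,
    control_dct: float = 10.0,
    elisa_base_pg_per_ml: float = 50.0,
    protein_mg_per_ml: float = 2.0,
    elisa_cv: float = 0.1,
) -> tuple[pd.DataFrame, dict[str, Any]]:
    """Ct pairs and ELISA rows for groups with known fold changes.

    The first-listed group is the control (fold change 1 by definition);
    a true fold change ``f`` shifts the target Ct by ``-log2(f)``.  With
    ``ct_noise_sd = 0`` the 2^-ddCt pipeline recovers the fold changes
    exactly.
    """
    if group_fold_changes is None:
        group_fold_changes = {"control": 1.0, "treated": 4.0}
    rng = stage_rng(seed, "assay")
    rows = []
    for group, fold in group_fold_changes.items():
        dct = control_dct - np.log2(fold)
        for i in range(n_per_group):
            ct_ref = reference_ct_mean + rng.normal(0, ct_noise_sd)
            ct_tgt = ct_ref + dct + rng.normal(0, ct_noise_sd)
            conc = elisa_base_pg_per_ml * fold * float(
                np.exp(rng.normal(0, elisa_cv)) if elisa_cv > 0 else 1.0
            )
            rows.append(
                {
                    "sample_id": f"{group}_{i}",
                    "group": group,
                    "sex": "F" if i % 2 else "M",
                    "ct_target": ct_tgt,
                    "ct_reference": ct_ref,
                    "elisa_pg_per_ml": conc,
                    "total_protein_mg_per_ml": protein_mg_per_ml,
                }
            )
    truth = {
        "fold_changes": dict(group_fold_changes),
        "control_group": next(iter(group_fold_changes)),
        "control_dct": control_dct,
    }
    return pd.DataFrame(rows), truth


def generate_intensity_population(
    seed: int = 0,
    means: tuple[float, float, float] = (1.0, 5.0, 9.0),
    sds: tuple[float, float, float] = (0.2, 0.2, 0.2),
    n_per_class: int = 60,
) -> pd.DataFrame:
    """Normalized marker values from a labelled 3-component mixture.

    Used to validate the Lo/Mid/Hi cutoff rules against known class
    membership; classes are emitted in Lo/Mid/Hi order of their means.
    """
    order = np.argsort(means)
    rng = stage_rng(seed, "mixture")
    rows = []
    for cls, idx in zip(("Lo", "Mid", "Hi"), order):
        vals = rng.normal(means[idx], sds[idx], size=n_per_class)
        rows.extend({"value": float(v), "true_class": cls} for v in vals)
    df = pd.DataFrame(rows)
    return df.sample(frac=1.0, random_state=int(seed) % (2**32)).reset_index(drop=True)


def generate_animal_summaries(
    seed: int = 0,
    group_means: Mapping[str, float] | None = None,
    n_per_group: int = 6,
    cv: float = 0.3,
    sex_effect: float = 0.0,
    measure: str = "engulfed_norm",
) -> pd.DataFrame:
    """Animal-level summaries with lognormal between-animal variation.

    Each animal's mean is ``group_mean × exp(N(0, cv)) × (1 + sex_effect
    for females)``; sexes are balanced within group.  ``cv`` defaults to
    0.3, a typical between-animal coefficient of variation for imaging
    endpoints.
    """
    if group_means is None:
        group_means = {"control": 1.0, "treated": 2.0}
    rng = stage_rng(seed, "animals")
    rows = []
    for group, mu in group_means.items():
        for i in range(n_per_group):
            sex = "F" if i % 2 else "M"
            val = mu * float(np.exp(rng.normal(0, cv)))
            if sex == "F":
                val *= 1.0 + sex_effect
            rows.append(
                {"animal_id": f"{group}_{i}", "group": group, "sex": sex, measure: val}
            )
    return pd.DataFrame(rows)
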