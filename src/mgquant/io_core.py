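"""Shared image data model, TIFF I/O, and run-manifest plumbing.

Every imaging stage in the pipeline operates on :class:`VolumeImage`
(a ``(channel, z, y, x)`` intensity grid with physical voxel sizes in
micrometres) and :class:`BinaryMask` (a boolean grid on the same
``(z, y, x)`` lattice).  Conventions, stated once:

* coordinates are 0-based ``(z, y, x)``; the physical position of a voxel
  is ``index * voxel_size`` at the voxel centre;
* all reported volumes are in µm³ and lengths in µm; raw voxel counts are
  carried alongside for auditability;
* 2D images are volumes with a singleton z axis.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import tifffile

logger = logging.getLogger("mgquant")

__all__ = [
    "VolumeImage",
    "BinaryMask",
    "RunManifest",
    "read_volume",
    "write_volume",
    "max_intensity_projection",
]


def _as_triple(value: Sequence[float], name: str) -> tuple[float, float, float]:
    t = tuple(float(v) for v in value)
    if len(t) != 3:
        raise ValueError(f"{name} must have 3 entries (dz, dy, dx), got {len(t)}")
    if any(v <= 0 for v in t):
        raise ValueError(f"{name} must be strictly positive, got {t}")
    return t  # type: ignore[return-value]


@dataclass
class VolumeImage:
    """Multi-channel intensity volume with physical voxel sizes.

    Parameters
    ----------
    data:
        Array indexed ``(channel, z, y, x)``; z may be 1 for planar images.
    voxel_size:
        ``(dz, dy, dx)`` in µm per voxel, all strictly positive.
    channel_names:
        One unique label per channel.
    """

    data: np.ndarray
    voxel_size: tuple[float, float, float]
    channel_names: tuple[str, ...]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError(
                f"data must be (channel, z, y, x); got {self.data.ndim} axes"
            )
        self.voxel_size = _as_triple(self.voxel_size, "voxel_size")
        self.channel_names = tuple(str(c) for c in self.channel_names)
        if len(self.channel_names) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channel_names)} channel names for "
                f"{self.data.shape[0]} channels"
            )
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError(f"channel names not unique: {self.channel_names}")
        if np.issubdtype(self.data.dtype, np.floating):
            if not np.all(np.isfinite(self.data)):
                raise ValueError("intensities must be finite")
            if np.any(self.data < 0):
                raise ValueError("intensities must be non-negative")

    @property
    def shape_zyx(self) -> tuple[int, int, int]:
        return self.data.shape[1:]

    @property
    def voxel_volume_um3(self) -> float:
        dz, dy, dx = self.voxel_size
        return dz * dy * dx

    def channel_index(self, channel: str | int) -> int:
        if isinstance(channel, (int, np.integer)):
            if not 0 <= channel < self.data.shape[0]:
                raise KeyError(f"channel index {channel} out of range")
            return int(channel)
        try:
            return self.channel_names.index(channel)
        except ValueError:
            raise KeyError(
                f"unknown channel {channel!r}; have {self.channel_names}"
            ) from None

    def channel(self, channel: str | int) -> np.ndarray:
        """Return the (z, y, x) intensity grid of one channel."""
        return self.data[self.channel_index(channel)]


@dataclass
class BinaryMask:
    """Boolean grid on the (z, y, x) lattice of a parent volume.

    ``volume_um3`` is always the true-voxel count times the voxel volume;
    no smoothing or mesh estimation is applied anywhere in the pipeline.
    """

    data: np.ndarray
    voxel_size: tuple[float, float, float]
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim == 2:
            self.data = self.data[None]
        if self.data.ndim != 3:
            raise ValueError(f"mask must be (z, y, x); got {self.data.ndim} axes")
        self.data = self.data.astype(bool)
        self.voxel_size = _as_triple(self.voxel_size, "voxel_size")

    @property
    def voxel_count(self) -> int:
        return int(self.data.sum())

    @property
    def voxel_volume_um3(self) -> float:
        dz, dy, dx = self.voxel_size
        return dz * dy * dx

    @property
    def volume_um3(self) -> float:
        return self.voxel_count * self.voxel_volume_um3

    def same_lattice(self, other: "BinaryMask") -> bool:
        return (
            self.data.shape == other.data.shape
            and self.voxel_size == other.voxel_size
        )


@dataclass
class RunManifest:
    """Provenance record written next to every stage output.

    Collects the seed, configuration hash, package version, and any
    parameters a stage chose at run time (e.g. the threshold Otsu picked),
    so a result table can always be traced back to its inputs.
    """

    stage: str
    seed: int | None = None
    config: dict[str, Any] = field(default_factory=dict)
    chosen: dict[str, Any] = field(default_factory=dict)
    filtered: list[dict[str, Any]] = field(default_factory=list)

    def record(self, key: str, value: Any) -> None:
        self.chosen[key] = value
        logger.info("%s: %s = %r", self.stage, key, value)

    def log_filtered(self, reason: str, **info: Any) -> None:
        """No silent row drops: every filtered unit is logged with a reason."""
        entry = {"reason": reason, **info}
        self.filtered.append(entry)
        logger.info("%s: filtered %s", self.stage, entry)

    def to_dict(self) -> dict[str, Any]:
        from . import __version__

        cfg_json = json.dumps(self.config, sort_keys=True, default=str)
        return {
            "stage": self.stage,
            "seed": self.seed,
            "version": __version__,
            "config": self.config,
            "config_hash": hashlib.sha256(cfg_json.encode()).hexdigest()[:16],
            "chosen": self.chosen,
            "filtered": self.filtered,
        }

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, default=str))


# ---------------------------------------------------------------------------
# TIFF I/O
#
# Volumes are written as plain multi-page TIFF with a JSON image description
# carrying the axis layout, voxel size and channel names.  Reading falls back
# to shape heuristics (2D -> one channel, one slice) when the sidecar
# metadata is absent, but never invents a voxel size.
# ---------------------------------------------------------------------------

_DESC_KEY = "mgquant"


def write_volume(path: str | Path, volume: VolumeImage) -> None:
    """Write a volume as multi-page TIFF with JSON metadata in the description."""
    # the top-level "shape" key doubles as tifffile's own shaped-series
    # metadata, so tif.asarray() reconstructs the 4D array directly
    desc = json.dumps(
        {
            "shape": list(volume.data.shape),
            _DESC_KEY: {
                "shape": list(volume.data.shape),
                "axes": "CZYX",
                "voxel_size_um": list(volume.voxel_size),
                "channel_names": list(volume.channel_names),
            },
        }
    )
    pages = volume.data.reshape(-1, *volume.data.shape[2:])
    tifffile.imwrite(str(path), pages, description=desc, photometric="minisblack")


def read_volume(
    path: str | Path,
    voxel_size_override: Sequence[float] | None = None,
    channel_names: Sequence[str] | None = None,
) -> VolumeImage:
    """Read a TIFF into a :class:`VolumeImage` with axes ``(channel, z, y, x)``.

    Files written by :func:`write_volume` round-trip bit-exactly.  For
    foreign TIFFs the array is normalized as ``2D -> (1, 1, Y, X)`` and
    ``3D -> (1, Z, Y, X)``, and a voxel size must be supplied via
    ``voxel_size_override`` — a missing voxel size is an error, never a
    silent default.  When both file metadata and an override are present
    the override wins and a warning is logged.
    """
    path = Path(path)
    with tifffile.TiffFile(str(path)) as tif:
        arr = tif.asarray()
        meta = None
        desc = tif.pages[0].description
        if desc:
            try:
                parsed = json.loads(desc)
                meta = parsed.get(_DESC_KEY)
            except (json.JSONDecodeError, AttributeError):
                meta = None

    names = list(channel_names) if channel_names is not None else None
    voxel_size = None
    if meta is not None:
        arr = arr.reshape(meta["shape"])
        voxel_size = tuple(meta["voxel_size_um"])
        if names is None:
            names = list(meta["channel_names"])
    else:
        if arr.ndim == 2:
            arr = arr[None, None]
        elif arr.ndim == 3:
            arr = arr[None]
        elif arr.ndim != 4:
            raise ValueError(f"cannot normalize TIFF with {arr.ndim} axes")

    if voxel_size_override is not None:
        override = _as_triple(voxel_size_override, "voxel_size_override")
        if voxel_size is not None and tuple(voxel_size) != override:
            logger.warning(
                "voxel size override %s supersedes file metadata %s for %s",
                override,
                voxel_size,
                path.name,
            )
        voxel_size = override
    if voxel_size is None:
        raise ValueError(
            f"{path}: no voxel size in metadata and no override given; "
            "pass voxel_size_override=(dz, dy, dx) in µm"
        )
    if names is None:
        names = [f"ch{i}" for i in range(arr.shape[0])]
    return VolumeImage(arr, tuple(voxel_size), tuple(names))


def max_intensity_projection(
    volume: VolumeImage, channel: str | int | None = None
) -> VolumeImage:
    """Maximum-intensity projection over z, returning a z=1 volume.

    Idempotent on planar input.  If ``channel`` is given the output holds
    that single channel; otherwise all channels are projected.
    """
    if channel is None:
        data = volume.data
        names = volume.channel_names
    else:
        idx = volume.channel_index(channel)
        data = volume.data[idx : idx + 1]
        names = (volume.channel_names[idx],)
    return VolumeImage(data.max(axis=1, keepdims=True), volume.voxel_size, names)
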