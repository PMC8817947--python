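"""Pixel-aligned multi-channel image stacks and their preprocessing.

A stack bundles the three RGB channels and six narrow spectral bands
(490, 550, 680, 720, 800 and 900 nm) as 8-bit grids aligned pixel to
pixel, together with the acquisition metadata (days after sowing,
irradiance, sun zenith angle) that downstream features consume.
Registration across cameras is assumed done upstream; the only
preprocessing offered here is a small per-channel box blur that damps
residual registration errors.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import imageio.v3 as iio
import numpy as np
import tifffile

#: Canonical channel order used everywhere (tables, multi-page TIFFs).
CHANNEL_NAMES = ("R", "G", "B", "b490", "b550", "b680", "b720", "b800", "b900")

#: Narrow-band channels, by center wavelength.
BAND_NAMES = ("b490", "b550", "b680", "b720", "b800", "b900")


@dataclass(frozen=True)
class AcquisitionMeta:
    """Per-acquisition context attached to a stack.

    Parameters
    ----------
    days_after_sowing : int
        Phenology clock (DAS), days since sowing, >= 0.
    irradiance_E : float
        Solar irradiance at capture time, W/m^2, >= 0.
    zenith_z : float
        Sun zenith angle in degrees, in [0, 90).
    """

    days_after_sowing: int
    irradiance_E: float
    zenith_z: float
    trial_id: str = ""
    plot_id: str = ""
    date: str = ""

    def __post_init__(self) -> None:
        if self.days_after_sowing < 0:
            raise ValueError("days_after_sowing must be >= 0")
        if self.irradiance_E < 0:
            raise ValueError("irradiance_E must be >= 0")
        if not (0 <= self.zenith_z < 90):
            raise ValueError("zenith_z must lie in [0, 90) degrees")


@dataclass
class MultiChannelImage:
    """Nine named 8-bit channels sharing one pixel grid, plus metadata."""

    channels: dict[str, np.ndarray]
    meta: AcquisitionMeta
    image_id: str = ""

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("at least one channel required")
        shapes = set()
        for name, grid in self.channels.items():
            if name not in CHANNEL_NAMES:
                raise ValueError(f"unknown channel name {name!r}")
            grid = np.asarray(grid)
            if grid.ndim != 2:
                raise ValueError(f"channel {name!r} is not a 2-D grid")
            if grid.dtype != np.uint8:
                raise TypeError(
                    f"channel {name!r} has dtype {grid.dtype}; stacks are 8-bit "
                    "and inputs are refused rather than rescaled"
                )
            self.channels[name] = grid
            shapes.add(grid.shape)
        if len(shapes) != 1:
            raise ValueError(f"channel dimension mismatch: {sorted(shapes)}")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    @property
    def height(self) -> int:
        return self.shape[0]

    @property
    def width(self) -> int:
        return self.shape[1]

    def rgb(self) -> np.ndarray:
        """H x W x 3 uint8 composite of the R, G, B channels."""
        return np.stack([self.channels[c] for c in ("R", "G", "B")], axis=-1)


def load_stack(
    channel_paths: Mapping[str, str | Path],
    meta: AcquisitionMeta,
    image_id: str = "",
) -> MultiChannelImage:
    """Read one 8-bit grayscale file per channel into a stack.

    Refuses missing files, non-2-D or non-8-bit images, and channels
    whose dimensions disagree (alignment is assumed done upstream).
    """
    channels: dict[str, np.ndarray] = {}
    for name, path in channel_paths.items():
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(f"channel {name!r}: {path}")
        arr = np.asarray(iio.imread(path))
        if arr.ndim == 3 and arr.shape[2] == 1:
            arr = arr[:, :, 0]
        if arr.ndim != 2:
            raise ValueError(f"channel {name!r} in {path} is not single-plane grayscale")
        if arr.dtype != np.uint8:
            raise TypeError(f"channel {name!r} in {path} is not 8-bit (dtype {arr.dtype})")
        channels[name] = arr
    return MultiChannelImage(channels=channels, meta=meta, image_id=image_id)


def write_stack(img: MultiChannelImage, out_dir: str | Path, fmt: str = "png") -> dict[str, Path]:
    """Write one 8-bit grayscale file per channel; returns name -> path.

    PNG and TIFF both round-trip bit-exactly through :func:`load_stack`.
    """
    if fmt not in ("png", "tif", "tiff"):
        raise ValueError(f"unsupported format {fmt!r}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    stem = img.image_id or "stack"
    for name in CHANNEL_NAMES:
        if name not in img.channels:
            continue
        path = out_dir / f"{stem}_{name}.{fmt}"
        if fmt == "png":
            iio.imwrite(path, img.channels[name])
        else:
            tifffile.imwrite(path, img.channels[name])
        paths[name] = path
    return paths


def write_sidecar(rows: list[dict], path: str | Path) -> None:
    """Write the plain-text metadata sidecar (plot_id, date, DAS, E, z...)."""
    path = Path(path)
    fieldnames = ["image_id", "trial_id", "plot_id", "date", "DAS", "E", "z"]
    extra = [k for k in rows[0] if k not in fieldnames] if rows else []
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=fieldnames + extra)
        writer.writeheader()
        writer.writerows(rows)


def read_sidecar(path: str | Path) -> list[dict]:
    with open(path, newline="") as fh:
        return list(csv.DictReader(fh))


def meta_from_sidecar_row(row: Mapping[str, str]) -> AcquisitionMeta:
    return AcquisitionMeta(
        days_after_sowing=int(row["DAS"]),
        irradiance_E=float(row["E"]),
        zenith_z=float(row["z"]),
        trial_id=row.get("trial_id", ""),
        plot_id=row.get("plot_id", ""),
        date=row.get("date", ""),
    )


def _box_blur_u8(grid: np.ndarray, k: int) -> np.ndarray:
    # Mean filter with reflected borders; round-half-up keeps 8-bit range.
    from scipy.ndimage import uniform_filter

    acc = uniform_filter(grid.astype(np.float64), size=k, mode="reflect")
    return np.clip(np.floor(acc + 0.5), 0, 255).astype(np.uint8)


def blur_channels(img: MultiChannelImage, kernel_px: int = 3) -> MultiChannelImage:
    """Box-blur every channel independently with a kernel_px x kernel_px mean.

    kernel_px must be odd and >= 1; kernel_px=1 is the identity. The blur
    exists only to damp small registration errors, so any small low-pass
    suffices; the mean filter keeps the operation linear and cheap.
    """
    if kernel_px < 1 or kernel_px % 2 == 0:
        raise ValueError("kernel_px must be a positive odd integer")
    if kernel_px == 1:
        return MultiChannelImage(
            channels={k: v.copy() for k, v in img.channels.items()},
            meta=img.meta,
            image_id=img.image_id,
        )
    return MultiChannelImage(
        channels={k: _box_blur_u8(v, kernel_px) for k, v in img.channels.items()},
        meta=img.meta,
        image_id=img.image_id,
    )
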