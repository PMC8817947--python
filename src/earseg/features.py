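"""Per-superpixel feature vectors: band means, color transforms, vegetation indices.

Each plant-eligible superpixel yields 29 features: the mean 8-bit
intensity of the six narrow bands, normalized rgb chromaticity and HSV
of the mean RGB color, fifteen vegetation indices evaluated on the
superpixel-mean band values, and two scene-level features — days after
sowing (DAS) and the cloudiness index (CT) — that encode growth stage
and illumination. Indices are computed means-first (index of the mean,
not mean of per-pixel indices); band intensities act as reflectance
proxies on a [0, 1] scale for indices with additive constants, since
no radiometric calibration is performed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Mapping

import numpy as np
import pandas as pd
from matplotlib.colors import rgb_to_hsv

from earseg.illumination import CloudinessIndex
from earseg.image_stack import BAND_NAMES, MultiChannelImage
from earseg.superpixels import SuperpixelMap

logger = logging.getLogger(__name__)

_EPS = 0.0  # exact-zero denominators are mapped to 0 with a flag, not nudged


def _safe_div(num: float, den: float, flags: list[str] | None, name: str) -> float:
    if den == 0:
        if flags is not None:
            flags.append(name)
        return 0.0
    return num / den


def _make_default_registry() -> "IndexRegistry":
    """Named vegetation indices over [0,1]-scaled band means and rgb chromaticity.

    The first ten are the indices the selection study names (SR, NDVI,
    NDRE, GNDVI, RDVI, OSAVI, TCARI, CIRE, VARI, mNDblue) with their
    standard literature formulas; the last five fill the registry with
    common NIR/visible indices and are freely replaceable — the
    registry is configuration, not code.
    """
    f: dict[str, Callable] = {}
    f["SR"] = lambda e, fl: _safe_div(e["n800"], e["n680"], fl, "SR")
    f["NDVI"] = lambda e, fl: _safe_div(e["n800"] - e["n680"], e["n800"] + e["n680"], fl, "NDVI")
    f["NDRE"] = lambda e, fl: _safe_div(e["n800"] - e["n720"], e["n800"] + e["n720"], fl, "NDRE")
    f["GNDVI"] = lambda e, fl: _safe_div(e["n800"] - e["n550"], e["n800"] + e["n550"], fl, "GNDVI")
    f["RDVI"] = lambda e, fl: _safe_div(
        e["n800"] - e["n680"], float(np.sqrt(e["n800"] + e["n680"])) if e["n800"] + e["n680"] > 0 else 0.0,
        fl, "RDVI",
    )
    f["OSAVI"] = lambda e, fl: _safe_div(
        1.16 * (e["n800"] - e["n680"]), e["n800"] + e["n680"] + 0.16, fl, "OSAVI"
    )
    f["TCARI"] = lambda e, fl: 3.0 * (
        (e["n720"] - e["n680"])
        - 0.2 * (e["n720"] - e["n550"]) * _safe_div(e["n720"], e["n680"], fl, "TCARI")
    )
    f["CIRE"] = lambda e, fl: _safe_div(e["n800"], e["n720"], fl, "CIRE") - 1.0
    f["VARI"] = lambda e, fl: _safe_div(e["g"] - e["r"], e["g"] + e["r"] - e["b"], fl, "VARI")
    f["mNDblue"] = lambda e, fl: _safe_div(
        e["n490"] - e["n800"], e["n490"] + e["n800"], fl, "mNDblue"
    )
    # replaceable extras
    f["GRVI"] = lambda e, fl: _safe_div(e["n800"], e["n550"], fl, "GRVI")
    f["EVI2"] = lambda e, fl: _safe_div(
        2.5 * (e["n800"] - e["n680"]), e["n800"] + 2.4 * e["n680"] + 1.0, fl, "EVI2"
    )
    f["MCARI"] = lambda e, fl: (
        (e["n720"] - e["n680"]) - 0.2 * (e["n720"] - e["n550"])
    ) * _safe_div(e["n720"], e["n680"], fl, "MCARI")
    f["ExG"] = lambda e, fl: 2.0 * e["g"] - e["r"] - e["b"]
    f["GLI"] = lambda e, fl: _safe_div(
        2.0 * e["g"] - e["r"] - e["b"], 2.0 * e["g"] + e["r"] + e["b"], fl, "GLI"
    )
    return IndexRegistry(entries=list(f.items()))


@dataclass
class IndexRegistry:
    """Ordered (name, formula) pairs; formulas see scaled band means and rgb."""

    entries: list[tuple[str, Callable]]

    def __post_init__(self) -> None:
        names = [n for n, _ in self.entries]
        if len(set(names)) != len(names):
            raise ValueError("index names must be unique")

    @property
    def names(self) -> list[str]:
        return [n for n, _ in self.entries]

    def __len__(self) -> int:
        return len(self.entries)


DEFAULT_REGISTRY = _make_default_registry()

#: Fixed column order of the 29-feature table.
FEATURE_COLUMNS = (
    ["m490", "m550", "m680", "m720", "m800", "m900"]
    + ["r", "g", "b", "hue", "saturation", "value"]
    + DEFAULT_REGISTRY.names
    + ["das", "ct"]
)

KEY_COLUMNS = ("image_id", "superpixel")


def superpixel_band_means(
    img: MultiChannelImage, sp: SuperpixelMap, label: int
) -> dict[str, float]:
    """Arithmetic mean of every channel over one region's pixels."""
    region = sp.labels == label
    n = int(region.sum())
    if n == 0:
        raise ValueError(f"superpixel {label} is empty")
    return {name: float(grid[region].mean()) for name, grid in img.channels.items()}


def color_features(R: float, G: float, B: float) -> dict[str, float]:
    """Normalized rgb chromaticity and HSV from mean RGB in [0, 255].

    The black point R=G=B=0 maps to r=g=b=1/3 and hue=0 by convention.
    """
    total = R + G + B
    if total > 0:
        r, g, b = R / total, G / total, B / total
    else:
        r = g = b = 1.0 / 3.0
    hsv = rgb_to_hsv(np.array([R, G, B]) / 255.0)
    return {
        "r": r,
        "g": g,
        "b": b,
        "hue": float(hsv[0]),
        "saturation": float(hsv[1]),
        "value": float(hsv[2]),
    }


def vegetation_indices(
    band_means: Mapping[str, float],
    color_means: Mapping[str, float],
    registry: IndexRegistry = DEFAULT_REGISTRY,
    flags: list[str] | None = None,
) -> dict[str, float]:
    """Evaluate every registry formula on superpixel-mean values.

    Band means (8-bit) are scaled to [0, 1] reflectance proxies before
    evaluation; zero denominators yield 0 with the index name appended
    to ``flags``.
    """
    env = {f"n{w}": band_means[f"b{w}"] / 255.0 for w in (490, 550, 680, 720, 800, 900)}
    env.update({k: color_means[k] for k in ("r", "g", "b")})
    return {name: float(fn(env, flags)) for name, fn in registry.entries}


def eligible_superpixels(
    sp: SuperpixelMap, plant_mask: np.ndarray, min_plant_fraction: float = 0.5
) -> np.ndarray:
    """Labels whose plant-pixel fraction exceeds the (majority) cutoff."""
    counts = np.bincount(sp.labels.ravel(), minlength=sp.n_regions)
    plant = np.bincount(
        sp.labels.ravel(), weights=plant_mask.ravel().astype(np.float64), minlength=sp.n_regions
    )
    return np.nonzero(plant > min_plant_fraction * counts)[0]


def build_feature_table(
    img: MultiChannelImage,
    sp: SuperpixelMap,
    plant_mask: np.ndarray,
    ct: CloudinessIndex | float,
    registry: IndexRegistry = DEFAULT_REGISTRY,
    min_plant_fraction: float = 0.5,
) -> pd.DataFrame:
    """One 29-feature row per plant-eligible superpixel.

    A superpixel is eligible when the majority of its pixels are plant
    under ``plant_mask``. Rows are keyed by (image_id, superpixel);
    ``das`` and ``ct`` are constant within an image.
    """
    ct_value = ct.value if isinstance(ct, CloudinessIndex) else float(ct)
    labels_flat = sp.labels.ravel()
    counts = np.bincount(labels_flat, minlength=sp.n_regions).astype(np.float64)
    means = {
        name: np.bincount(labels_flat, weights=grid.ravel().astype(np.float64),
                          minlength=sp.n_regions) / counts
        for name, grid in img.channels.items()
    }
    keep = eligible_superpixels(sp, plant_mask, min_plant_fraction)
    if keep.size == 0:
        raise ValueError(f"image {img.image_id!r}: no plant-eligible superpixels")
    flags: list[str] = []
    rows = []
    for label in keep:
        band_means = {name: float(means[name][label]) for name in BAND_NAMES}
        col = color_features(
            float(means["R"][label]), float(means["G"][label]), float(means["B"][label])
        )
        vi = vegetation_indices(band_means, col, registry, flags)
        row = {"image_id": img.image_id, "superpixel": int(label)}
        row.update({f"m{w}": band_means[f"b{w}"] for w in (490, 550, 680, 720, 800, 900)})
        row.update(col)
        row.update(vi)
        row["das"] = float(img.meta.days_after_sowing)
        row["ct"] = ct_value
        rows.append(row)
    if flags:
        logger.info("image %s: %d zero-denominator index evaluations set to 0",
                    img.image_id, len(flags))
    table = pd.DataFrame(rows, columns=list(KEY_COLUMNS) + FEATURE_COLUMNS)
    return table


def write_feature_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


def read_feature_table(path) -> pd.DataFrame:
    return pd.read_csv(path)
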