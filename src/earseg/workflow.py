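"""Batch helpers tying scenes to labelled tables and scored masks.

These are the steps shared by the command-line interface, the test
suite and the reproduction script: derive labelled superpixel feature
tables from scenes with known (or hand-brushed) region labels, and
score predicted masks against pixel annotations.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from earseg.annotation import (
    EAR_REGION,
    LEAF_REGION,
    UNLABELLED,
    pixel_grid_sample,
    regions_to_superpixel_labels,
)
from earseg.features import DEFAULT_REGISTRY, IndexRegistry, build_feature_table
from earseg.illumination import cloudiness_index
from earseg.image_stack import (
    MultiChannelImage,
    blur_channels,
    load_stack,
    meta_from_sidecar_row,
    read_sidecar,
)
from earseg.pipeline import MASK_EAR, MASK_LEAF
from earseg.soil_mask import soil_plant_mask
from earseg.superpixels import SlicParams, compute_superpixels


def regions_from_truth(truth_mask: np.ndarray, erosion_radius: int = 4) -> np.ndarray:
    """Ternary truth mask -> brush-region grid (ear=1, leaf=2, soil unlabelled).

    Each class region is eroded before use, mimicking an operator who
    paints strokes inside organs and stays clear of boundaries; without
    the erosion every boundary superpixel would carry labels of both
    classes and be discarded as mixed.
    """
    from skimage.morphology import disk, erosion

    regions = np.full(truth_mask.shape, UNLABELLED, dtype=np.uint8)
    selem = disk(erosion_radius) if erosion_radius > 0 else None
    for value, region_label in ((MASK_EAR, EAR_REGION), (MASK_LEAF, LEAF_REGION)):
        sel = truth_mask == value
        if selem is not None:
            sel = erosion(sel, selem)
        regions[sel] = region_label
    return regions


def labelled_feature_table(
    img: MultiChannelImage,
    regions: np.ndarray,
    slic_params: SlicParams | None = None,
    blur_kernel_px: int = 3,
    registry: IndexRegistry = DEFAULT_REGISTRY,
    scale_segments: bool = True,
    min_plant_fraction: float = 0.5,
) -> pd.DataFrame:
    """Feature table for one stack with a ``class`` column from brush regions.

    Only plant-eligible superpixels that received an ear/leaf label
    under the conversion rules are kept.
    """
    img = blur_channels(img, blur_kernel_px)
    ct = cloudiness_index(img.meta.irradiance_E, img.meta.zenith_z)
    plant = soil_plant_mask(img, ct)
    params = slic_params or SlicParams()
    if scale_segments:
        params = params.scaled_to(img.height, img.width)
    sp = compute_superpixels(img, params)
    table = build_feature_table(img, sp, plant, ct, registry,
                                min_plant_fraction=min_plant_fraction)
    labelset = regions_to_superpixel_labels(regions, sp)
    table["class"] = table["superpixel"].map(labelset.labels)
    return table.dropna(subset=["class"]).reset_index(drop=True)


def load_experiment_stacks(exp_dir: str | Path) -> list[dict]:
    """Read a simulated (or equivalently laid out) experiment directory."""
    exp_dir = Path(exp_dir)
    records = []
    for row in read_sidecar(exp_dir / "sidecar.csv"):
        image_id = row["image_id"]
        paths = {
            name: exp_dir / "stacks" / f"{image_id}_{name}.png"
            for name in ("R", "G", "B", "b490", "b550", "b680", "b720", "b800", "b900")
        }
        img = load_stack(paths, meta_from_sidecar_row(row), image_id=image_id)
        rec = {"image": img, "meta_row": row}
        truth_path = exp_dir / "truth" / f"{image_id}_mask.png"
        if truth_path.exists():
            import imageio.v3 as iio

            rec["truth_mask"] = np.asarray(iio.imread(truth_path))
        records.append(rec)
    return records


def grid_truth_annotations(truth_mask: np.ndarray, image_id: str,
                           n_points: int = 18, n_rows: int = 3):
    """Ground-truth pixel-grid annotations for a scene with known truth."""
    from earseg.synthetic import GroundTruth, truth_annotations

    coords = pixel_grid_sample(truth_mask.shape[0], truth_mask.shape[1],
                               n_points=n_points, n_rows=n_rows)
    truth = GroundTruth(mask=truth_mask, instances=np.zeros_like(truth_mask, dtype=np.int32))
    return truth_annotations(truth, coords, image_id)
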