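"""End-to-end segmentation: stack in, ternary soil/leaf/ear mask out.

Chains the stages: per-channel blur, cloudiness index from the
metadata, automatic soil masking, SLIC on the RGB composite, feature
extraction for plant-majority superpixels, classifier prediction, and
mask assembly. Soil pixels keep the soil class regardless of their
superpixel; plant pixels inherit the ear/leaf class predicted for
their superpixel (plant pixels whose superpixel was not eligible for
classification default to leaf).
"""

from __future__ import annotations

import numpy as np

from earseg.classification import ScalerParams, predict
from earseg.features import IndexRegistry, DEFAULT_REGISTRY, build_feature_table
from earseg.illumination import cloudiness_index
from earseg.image_stack import MultiChannelImage, blur_channels
from earseg.soil_mask import soil_plant_mask
from earseg.superpixels import SlicParams, compute_superpixels

MASK_SOIL, MASK_LEAF, MASK_EAR = 0, 1, 2


def segment_image(
    img: MultiChannelImage,
    model,
    scaler: ScalerParams,
    feature_columns: list[str],
    slic_params: SlicParams | None = None,
    blur_kernel_px: int = 3,
    registry: IndexRegistry = DEFAULT_REGISTRY,
    scale_segments: bool = True,
) -> np.ndarray:
    """Run the full pipeline on one stack; returns the ternary mask."""
    img = blur_channels(img, blur_kernel_px)
    ct = cloudiness_index(img.meta.irradiance_E, img.meta.zenith_z)
    plant = soil_plant_mask(img, ct)
    params = slic_params or SlicParams()
    if scale_segments:
        params = params.scaled_to(img.height, img.width)
    sp = compute_superpixels(img, params)
    mask = np.where(plant == 1, MASK_LEAF, MASK_SOIL).astype(np.uint8)
    try:
        table = build_feature_table(img, sp, plant, ct, registry)
    except ValueError:
        return mask  # no plant-eligible superpixels: nothing to classify
    scaled = scaler.transform(table)
    classes = predict(model, scaled, feature_columns)
    ear_labels = table.loc[classes == "ear", "superpixel"].to_numpy()
    ear_region = np.isin(sp.labels, ear_labels)
    mask[ear_region & (plant == 1)] = MASK_EAR
    return mask
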