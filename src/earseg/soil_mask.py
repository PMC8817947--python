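"""Soil / plant separation by NIR histogram-valley thresholding.

Plants reflect strongly at 800 nm while bare soil does not, so the
800 nm histogram of a canopy frame is bimodal and the first valley
between the soil mode and the plant mode is an automatic per-image
threshold. Under strong direct sunlight, brightly lit soil and deeply
shaded low leaves can overlap in NIR; a second threshold on the
490 nm (blue) channel then rescues shaded leaves (soil stays bright in
blue, shaded vegetation does not) for the low-NIR pixel population.
The blue step only ever flips soil -> plant.
"""

from __future__ import annotations

import logging

import numpy as np
from skimage.filters import threshold_otsu

from earseg.illumination import CloudinessIndex, is_direct_sun
from earseg.image_stack import MultiChannelImage

logger = logging.getLogger(__name__)

#: Threshold used when a histogram has no interior valley.
FALLBACK_THRESHOLD = 128


class DegenerateHistogramError(ValueError):
    """Raised when a histogram has no interior local minimum."""


def _smooth_histogram(hist: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return hist.astype(np.float64)
    kernel = np.ones(window) / window
    # reflect padding keeps the end bins unbiased
    padded = np.pad(hist.astype(np.float64), window // 2, mode="reflect")
    return np.convolve(padded, kernel, mode="valid")


def first_local_minimum_threshold(
    channel: np.ndarray,
    smooth_window: int = 5,
    peak_fraction: float = 0.05,
    depth_fraction: float = 0.5,
) -> int:
    """Smallest intensity t that is a true valley of the smoothed histogram.

    A valley satisfies h(t) <= h(t-1), h(t) <= h(t+1), and separates two
    real modes: it is preceded by a mode of at least ``peak_fraction``
    of the histogram maximum (rejects noise dips in the dark tail), and
    h(t) lies below ``depth_fraction`` of both flanking maxima (rejects
    shallow dips riding on top of a single mode and the bright tail).
    Pixels with value > t belong to the plant class. Raises
    :class:`DegenerateHistogramError` when no valley exists (e.g. a
    single-class image); callers fall back to a configured constant.
    """
    channel = np.asarray(channel)
    if channel.size == 0:
        raise ValueError("empty channel")
    hist = np.bincount(channel.ravel(), minlength=256)[:256]
    h = _smooth_histogram(hist, smooth_window)
    later_max = np.maximum.accumulate(h[::-1])[::-1]  # max of h[t:]
    earlier_max = np.maximum.accumulate(h)            # max of h[:t+1]
    min_peak = peak_fraction * h.max()
    for t in range(1, 255):
        if (
            h[t] <= h[t - 1]
            and h[t] <= h[t + 1]
            and earlier_max[t - 1] >= min_peak             # a real mode precedes
            and h[t] < depth_fraction * earlier_max[t - 1]  # genuinely below it
            and h[t] < depth_fraction * later_max[t + 1]    # and a mode follows
        ):
            return t
    raise DegenerateHistogramError("histogram has no interior valley")


def soil_plant_mask(
    img: MultiChannelImage,
    ct: CloudinessIndex | float,
    *,
    smooth_window: int = 5,
    low_nir_band: int = 0,
    blue_threshold: int | None = None,
    fallback_threshold: int = FALLBACK_THRESHOLD,
    direct_sun_cutoff: float = 0.90,
) -> np.ndarray:
    """Binary mask (soil=0, plant=1) from the 800 nm channel.

    Pixels with b800 above the automatic valley threshold are plant.
    Under direct sun (``is_direct_sun(ct)``), pixels at or below the
    threshold (plus an optional ``low_nir_band`` margin) are
    re-examined: those darker than the blue threshold in b490 are
    reassigned to plant as shaded low leaves. ``blue_threshold=None``
    computes Otsu's threshold over that low-NIR population.
    """
    nir = img.channels["b800"]
    try:
        t_nir = first_local_minimum_threshold(nir, smooth_window)
    except DegenerateHistogramError:
        t_nir = fallback_threshold
        logger.info("image %s: degenerate NIR histogram, fallback threshold %d",
                    img.image_id, t_nir)
    mask = (nir > t_nir).astype(np.uint8)

    if is_direct_sun(ct, direct_sun_cutoff):
        if "b490" not in img.channels:
            raise ValueError("b490 channel required for direct-sun refinement")
        blue = img.channels["b490"]
        low_nir = nir <= t_nir + low_nir_band
        candidates = low_nir & (mask == 0)
        if candidates.any():
            if blue_threshold is None:
                vals = blue[candidates]
                if vals.min() == vals.max():
                    t_blue = int(vals.min())  # uniform population: nothing to split
                else:
                    t_blue = int(threshold_otsu(vals))
            else:
                t_blue = int(blue_threshold)
            # shaded leaves are dark in blue; sunlit soil stays bright
            mask[candidates & (blue < t_blue)] = 1
            logger.info("image %s: t_nir=%d t_blue=%d (direct sun)",
                        img.image_id, t_nir, t_blue)
    else:
        logger.info("image %s: t_nir=%d (diffuse)", img.image_id, t_nir)
    return mask
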