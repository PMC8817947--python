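"""Cloudiness index from incident-light-sensor measurements.

The index compares the measured solar irradiance E with the clear-sky
expectation E0*cos(z), where E0 = 1360 W/m^2 is the solar constant and
z the sun zenith angle:

    CT = 1 - E / (E0 * cos z)

Clear sky gives E close to E0*cos(z) and CT near 0; overcast sky gives
small E and CT near 1. CT can be slightly negative under cloud-edge
irradiance enhancement; negative values are meaningful and retained.
The index decides whether the soil mask needs its direct-sun
blue-channel refinement step.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

#: Solar constant, W/m^2.
E0 = 1360.0

#: Empirical cutoff separating direct-sun from diffuse illumination.
DIRECT_SUN_CUTOFF = 0.90


@dataclass(frozen=True)
class CloudinessIndex:
    value: float
    E: float
    z: float


def cloudiness_index(E: float, z: float) -> CloudinessIndex:
    """CT = 1 - E/(E0*cos z); z in degrees, E in W/m^2.

    Raises ValueError for z >= 90 degrees (the geometry makes the
    clear-sky expectation non-positive and the index undefined).
    """
    if E < 0:
        raise ValueError("irradiance E must be >= 0")
    if not (0 <= z < 90):
        raise ValueError("zenith angle must lie in [0, 90) degrees")
    value = 1.0 - E / (E0 * math.cos(math.radians(z)))
    return CloudinessIndex(value=value, E=E, z=z)


def is_direct_sun(ct: CloudinessIndex | float, cutoff: float = DIRECT_SUN_CUTOFF) -> bool:
    """True when illumination is dominated by direct sunlight.

    Direct sun means large E, hence CT well below 1; the scene then
    casts hard shadows and the soil mask needs the second (blue
    channel) thresholding step. The boundary CT == cutoff counts as
    not-direct (strict inequality).
    """
    if not (0 < cutoff <= 1):
        raise ValueError("cutoff must lie in (0, 1]")
    value = ct.value if isinstance(ct, CloudinessIndex) else float(ct)
    return value < cutoff
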