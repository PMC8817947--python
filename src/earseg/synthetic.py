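"""Synthetic wheat canopy scenes with exact soil/leaf/ear ground truth.

The generator renders nadir views of a crude but statistically
controllable canopy: a soil background, overlapping elongated leaf
blobs, and ellipse-with-awn ear blobs drawn on top. Every class has a
per-channel spectral signature (mean and sd on the 8-bit scale) chosen
so the phenomena the pipeline exploits are present: soil is dark at
800 nm while vegetation is bright (the NIR valley threshold), and ears
are brighter and yellow-shifted relative to leaves (the HSV "value"
separation). A ``stage_similarity`` dial pulls the ear signature
toward the leaf signature, emulating the heading stage where ears and
leaves are nearly the same color. Each organ instance additionally
carries its own per-channel mean offset, emulating pose and lighting
differences between organs; this is what gives superpixel means a
realistic within-class spread. ``illumination="direct"`` casts hard
shadows on the canopy (attenuated per wavelength — shadows keep
blue-rich skylight) and sweeps the soil through a sun-fleck/penumbra
brightness continuum, reproducing the shaded-leaf / bright-soil NIR
confusion that the blue-channel refinement targets. Geometry is
deliberately simple — realism is not the goal, controllable structure
is.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.draw import ellipse as draw_ellipse
from skimage.draw import line as draw_line

from earseg.illumination import E0
from earseg.image_stack import CHANNEL_NAMES, AcquisitionMeta, MultiChannelImage, write_stack

MASK_SOIL, MASK_LEAF, MASK_EAR = 0, 1, 2

#: Fraction of light a shadowed surface keeps from blue-rich diffuse
#: skylight, per channel. Shadows are not black: they are lit by the sky,
#: which is much stronger in blue than in red/NIR. This is what makes the
#: 490 nm channel able to tell shaded soil (stays fairly bright in blue)
#: from shaded leaves (absorb blue strongly).
SKYLIGHT_WEIGHT = {
    "R": 0.10, "G": 0.22, "B": 0.45,
    "b490": 0.45, "b550": 0.22, "b680": 0.08,
    "b720": 0.06, "b800": 0.05, "b900": 0.05,
}

#: Default class signatures: channel -> (mean, sd), 8-bit scale.
SOIL_SIGNATURE = {
    "R": (120, 8), "G": (100, 8), "B": (90, 8),
    "b490": (110, 8), "b550": (110, 8), "b680": (120, 8),
    "b720": (100, 8), "b800": (40, 6), "b900": (45, 6),
}
LEAF_SIGNATURE = {
    "R": (60, 10), "G": (120, 10), "B": (40, 8),
    "b490": (30, 6), "b550": (90, 8), "b680": (35, 6),
    "b720": (120, 10), "b800": (190, 10), "b900": (180, 10),
}
EAR_SIGNATURE = {
    "R": (210, 10), "G": (185, 10), "B": (95, 8),
    "b490": (45, 6), "b550": (150, 8), "b680": (140, 8),
    "b720": (170, 10), "b800": (205, 10), "b900": (195, 10),
}


@dataclass(frozen=True)
class SceneParams:
    """Controls for one rendered scene; all randomness flows from ``seed``."""

    height: int = 512
    width: int = 512
    ear_fraction: float = 0.10
    n_ears: int | None = None
    leaf_cover: float = 0.45
    stage_similarity: float = 0.0
    illumination: str = "diffuse"  # "diffuse" | "direct"
    shadow_fraction: float = 0.35
    shadow_factor: float = 0.15
    sunlit_soil_gain: float = 1.3
    #: sd of the per-organ spectral offset (each leaf/ear instance gets its
    #: own per-channel mean shift, emulating pose and lighting variation
    #: between organs; without it superpixel means are noise-free and the
    #: ear/leaf classes never overlap, even at full stage similarity)
    organ_level_sd: float = 15.0
    noise_sd: float = 0.0
    soil_signature: dict = field(default_factory=lambda: dict(SOIL_SIGNATURE))
    leaf_signature: dict = field(default_factory=lambda: dict(LEAF_SIGNATURE))
    ear_signature: dict = field(default_factory=lambda: dict(EAR_SIGNATURE))
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.ear_fraction <= 1 and 0 <= self.leaf_cover <= 1):
            raise ValueError("fractions must lie in [0, 1]")
        if not (0 <= self.stage_similarity <= 1):
            raise ValueError("stage_similarity must lie in [0, 1]")
        if self.illumination not in ("diffuse", "direct"):
            raise ValueError("illumination must be 'diffuse' or 'direct'")
        for sig in (self.soil_signature, self.leaf_signature, self.ear_signature):
            for ch, (m, s) in sig.items():
                if not (0 <= m <= 255):
                    raise ValueError(f"signature mean for {ch} outside [0, 255]")
        if self.ear_fraction > 0.5:
            raise ValueError("ear_fraction above 0.5 is infeasible for a canopy scene")


@dataclass
class GroundTruth:
    """Per-pixel class mask plus per-ear instance labels (0 = not an ear)."""

    mask: np.ndarray
    instances: np.ndarray
    shadow: np.ndarray | None = None

    @property
    def ear_ratio(self) -> float:
        return float(np.mean(self.mask == MASK_EAR))


def _scatter_leaves(mask: np.ndarray, organs: np.ndarray, params: SceneParams,
                    rng: np.random.Generator, first_organ_id: int) -> int:
    """Overlapping elongated leaf blobs; returns the next free organ id."""
    h, w = mask.shape
    scale = np.sqrt(h * w) / 512.0
    target = params.leaf_cover
    organ_id = first_organ_id
    for _ in range(20000):
        if np.mean(mask == MASK_LEAF) >= target:
            break
        r, c = rng.integers(0, h), rng.integers(0, w)
        length = rng.uniform(25, 60) * scale
        width_ = rng.uniform(5, 12) * scale
        rot = rng.uniform(-np.pi, np.pi)
        rr, cc = draw_ellipse(r, c, length, width_, shape=mask.shape, rotation=rot)
        mask[rr, cc] = MASK_LEAF
        organs[rr, cc] = organ_id
        organ_id += 1
    return organ_id


def _draw_ear(mask: np.ndarray, instances: np.ndarray, organs: np.ndarray,
              ear_id: int, organ_id: int, params: SceneParams,
              rng: np.random.Generator) -> bool:
    """Place one ear; returns False (no draw) if it would bury an earlier ear."""
    h, w = mask.shape
    scale = np.sqrt(h * w) / 512.0
    r_rad = rng.uniform(44, 58) * scale
    c_rad = rng.uniform(20, 27) * scale
    # keep ears wholly in frame so every instance is a full blob
    m = int(np.ceil(r_rad)) + 1
    r = rng.integers(min(m, h // 2), max(h - m, h // 2) + 1)
    c = rng.integers(min(m, w // 2), max(w - m, w // 2) + 1)
    rot = rng.uniform(-np.pi, np.pi)
    rr, cc = draw_ellipse(r, c, r_rad, c_rad, shape=mask.shape, rotation=rot)
    if rr.size == 0 or np.mean(mask[rr, cc] == MASK_EAR) > 0.10:
        return False
    mask[rr, cc] = MASK_EAR
    instances[rr, cc] = ear_id
    organs[rr, cc] = organ_id
    # awns: short bristle lines fanning out from the ear tip
    tip_r = int(np.clip(r - r_rad * np.cos(rot), 0, h - 1))
    tip_c = int(np.clip(c + r_rad * np.sin(rot), 0, w - 1))
    for _ in range(3):
        ang = rot + rng.uniform(-0.5, 0.5)
        end_r = int(np.clip(tip_r - 10 * scale * np.cos(ang), 0, h - 1))
        end_c = int(np.clip(tip_c + 10 * scale * np.sin(ang), 0, w - 1))
        lr, lc = draw_line(tip_r, tip_c, end_r, end_c)
        keep = mask[lr, lc] != MASK_EAR
        mask[lr[keep], lc[keep]] = MASK_EAR
        instances[lr[keep], lc[keep]] = ear_id
        organs[lr[keep], lc[keep]] = organ_id
    return True


def generate_canopy(
    params: SceneParams,
    meta: AcquisitionMeta | None = None,
    image_id: str = "synthetic",
) -> tuple[MultiChannelImage, GroundTruth]:
    """Render one scene; bit-identical for identical params (incl. seed)."""
    rng = np.random.default_rng(params.seed)
    h, w = params.height, params.width
    mask = np.full((h, w), MASK_SOIL, dtype=np.uint8)
    instances = np.zeros((h, w), dtype=np.int32)
    organs = np.zeros((h, w), dtype=np.int32)  # 0 = soil

    next_organ = _scatter_leaves(mask, organs, params, rng, first_organ_id=1)

    ear_id = 0
    if params.n_ears is not None:
        placed, attempts = 0, 0
        while placed < params.n_ears:
            attempts += 1
            if attempts > 1000 * params.n_ears:
                raise ValueError("could not place the requested number of ears")
            if _draw_ear(mask, instances, organs, ear_id + 1, next_organ, params, rng):
                ear_id += 1
                next_organ += 1
                placed += 1
    else:
        for _ in range(200000):
            if np.mean(mask == MASK_EAR) >= params.ear_fraction:
                break
            if _draw_ear(mask, instances, organs, ear_id + 1, next_organ, params, rng):
                ear_id += 1
                next_organ += 1
        else:
            raise ValueError("could not reach requested ear_fraction")

    s = params.stage_similarity
    ear_sig = {
        ch: ((1 - s) * params.ear_signature[ch][0] + s * params.leaf_signature[ch][0],
             (1 - s) * params.ear_signature[ch][1] + s * params.leaf_signature[ch][1])
        for ch in params.ear_signature
    }
    signatures = {MASK_SOIL: params.soil_signature,
                  MASK_LEAF: params.leaf_signature,
                  MASK_EAR: ear_sig}

    shadow = None
    soil_gain = None
    if params.illumination == "direct":
        # cast shadows on the canopy: binary field from smoothed noise
        field_ = gaussian_filter(rng.standard_normal((h, w)), sigma=max(4, h // 32))
        shadow = field_ < np.quantile(field_, params.shadow_fraction)
        # the ground sees a continuum from sun flecks to penumbra, which
        # keeps the soil side of the NIR histogram one broad mode
        gfield = gaussian_filter(rng.standard_normal((h, w)), sigma=max(4, h // 32))
        soil_gain = (gfield - gfield.min()) / (gfield.max() - gfield.min() + 1e-12)

    # per-organ spectral offsets: one per-channel mean shift per blob
    organ_offsets = rng.normal(0.0, params.organ_level_sd,
                               size=(next_organ, len(CHANNEL_NAMES)))
    organ_offsets[0, :] = 0.0  # soil has no organ identity

    channels: dict[str, np.ndarray] = {}
    for ci, ch in enumerate(CHANNEL_NAMES):
        grid = np.empty((h, w), dtype=np.float64)
        for cls, sig in signatures.items():
            sel = mask == cls
            m, sd = sig[ch]
            grid[sel] = m + rng.standard_normal(int(sel.sum())) * sd
        grid += organ_offsets[organs, ci]
        if params.noise_sd > 0:
            grid += rng.standard_normal((h, w)) * params.noise_sd
        if shadow is not None:
            # shadowed surfaces keep skylight, which is blue-rich
            f_ch = params.shadow_factor + (1 - params.shadow_factor) * SKYLIGHT_WEIGHT[ch]
            veg = mask != MASK_SOIL
            grid[shadow & veg] *= f_ch
            soil = ~veg
            gain_ch = f_ch + (params.sunlit_soil_gain - f_ch) * soil_gain[soil]
            grid[soil] *= gain_ch
        channels[ch] = np.clip(np.floor(grid + 0.5), 0, 255).astype(np.uint8)

    if meta is None:
        if params.illumination == "direct":
            E, z = 0.95 * E0 * np.cos(np.radians(30.0)), 30.0
        else:
            E, z = 80.0, 30.0
        meta = AcquisitionMeta(days_after_sowing=240, irradiance_E=float(E), zenith_z=z)
    img = MultiChannelImage(channels=channels, meta=meta, image_id=image_id)
    return img, GroundTruth(mask=mask, instances=instances, shadow=shadow)


def _ear_fraction_schedule(date_idx: int, n_dates: int, nitrogen: float,
                           max_nitrogen: float) -> float:
    """Ear cover grows over the season and with nitrogen input."""
    base = 0.05 + (0.15 * date_idx / max(1, n_dates - 1))
    n_mult = 0.4 + 0.6 * (nitrogen / max_nitrogen if max_nitrogen > 0 else 1.0)
    return base * n_mult


def generate_experiment(
    n_dates: int,
    n_plots: int,
    nitrogen_levels: list[float] | None = None,
    seed: int = 0,
    height: int = 512,
    width: int = 512,
    stage_similarity_start: float = 0.8,
    out_dir: str | Path | None = None,
) -> list[dict]:
    """A multi-date, multi-plot trial with known truth and a metadata sidecar.

    Plots cycle through the nitrogen levels; ear cover increases with
    date index and nitrogen input, and stage similarity decreases over
    the season (ears green at heading, yellow at maturity). Every other
    plot is imaged under direct sun. Returns one record per image with
    keys ``image``, ``truth``, ``meta_row``, ``params``; when
    ``out_dir`` is given the stacks and sidecar CSV are also written.
    """
    if n_dates <= 0 or n_plots <= 0:
        raise ValueError("counts must be positive")
    if nitrogen_levels is None:
        nitrogen_levels = [0.0, 60.0, 120.0, 180.0]
    max_n = max(nitrogen_levels)
    records: list[dict] = []
    sidecar_rows: list[dict] = []
    for d in range(n_dates):
        das = 230 + 7 * d
        date = f"2021-05-{1 + d:02d}" if d < 30 else f"2021-06-{d - 29:02d}"
        for p in range(n_plots):
            nitrogen = nitrogen_levels[p % len(nitrogen_levels)]
            direct = p % 2 == 1
            if direct:
                E, z = 0.95 * E0 * np.cos(np.radians(30.0)), 30.0
            else:
                E, z = 80.0, 30.0
            sim = stage_similarity_start * (1 - d / max(1, n_dates - 1))
            image_id = f"d{d}_p{p}"
            params = SceneParams(
                height=height, width=width,
                ear_fraction=_ear_fraction_schedule(d, n_dates, nitrogen, max_n),
                stage_similarity=sim,
                illumination="direct" if direct else "diffuse",
                seed=int((seed * 1000003 + d * 101 + p) % (2**31)),
            )
            meta = AcquisitionMeta(days_after_sowing=das, irradiance_E=float(E),
                                   zenith_z=z, plot_id=f"plot{p}", date=date,
                                   trial_id="synthetic")
            img, truth = generate_canopy(params, meta=meta, image_id=image_id)
            row = {"image_id": image_id, "trial_id": "synthetic", "plot_id": f"plot{p}",
                   "date": date, "DAS": das, "E": float(E), "z": z,
                   "nitrogen": nitrogen, "stage_similarity": sim,
                   "ear_fraction_target": params.ear_fraction}
            records.append({"image": img, "truth": truth, "meta_row": row,
                            "params": params})
            sidecar_rows.append(row)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for rec in records:
            write_stack(rec["image"], out_dir / "stacks")
        # truth masks as compact PNGs (values 0/1/2)
        import imageio.v3 as iio

        truth_dir = out_dir / "truth"
        truth_dir.mkdir(exist_ok=True)
        for rec in records:
            iio.imwrite(truth_dir / f"{rec['image'].image_id}_mask.png",
                        rec["truth"].mask)
        with open(out_dir / "sidecar.csv", "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=list(sidecar_rows[0]))
            writer.writeheader()
            writer.writerows(sidecar_rows)
    return records


def truth_annotations(truth: GroundTruth, coordinates, image_id: str,
                      operator: str = "truth"):
    """Pixel annotations read off the ground-truth mask (no uncertainty)."""
    from earseg.annotation import CLS_BACKGROUND, CLS_EAR, PixelAnnotation

    return [
        PixelAnnotation(
            row=r, col=c,
            cls=CLS_EAR if truth.mask[r, c] == MASK_EAR else CLS_BACKGROUND,
            operator=operator, image_id=image_id,
        )
        for r, c in coordinates
    ]
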