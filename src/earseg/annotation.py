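"""Annotation handling: brush regions to superpixel labels, pixel-grid sampling.

Training labels come from hand-drawn brush regions (ear / leaf strokes
on the RGB view) which are converted to superpixel class labels:
a superpixel takes a class when at least 10% of its pixels carry that
class's label and no pixels of the other class are present; superpixels
touched by both classes, or with fewer than two labelled pixels, are
discarded. Evaluation ground truth instead comes from a sparse
deterministic pixel grid (18 pixels in 3 rows per frame) annotated by
an operator into background / ear / uncertain.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from earseg.image_stack import MultiChannelImage
from earseg.superpixels import SuperpixelMap

# brush-region label values
UNLABELLED, EAR_REGION, LEAF_REGION = 0, 1, 2

# pixel-annotation classes
CLS_BACKGROUND, CLS_EAR, CLS_UNCERTAIN = 1, 2, 3


@dataclass(frozen=True)
class PixelAnnotation:
    row: int
    col: int
    cls: int
    operator: str
    image_id: str

    def __post_init__(self) -> None:
        if self.cls not in (CLS_BACKGROUND, CLS_EAR, CLS_UNCERTAIN):
            raise ValueError(f"class must be 1, 2 or 3, got {self.cls}")


@dataclass
class SuperpixelLabelSet:
    """Outcome of the brush-region conversion for one frame."""

    labels: dict[int, str]                      # superpixel -> "ear" | "leaf"
    discarded: list[tuple[int, str]]            # (superpixel, "mixed" | "too_few")
    ignored: list[int] = field(default_factory=list)  # fully unlabelled

    def __post_init__(self) -> None:
        if set(self.labels) & {s for s, _ in self.discarded}:
            raise ValueError("labelled and discarded sets overlap")

    @property
    def discard_fraction(self) -> float:
        """Fraction of labelled-touched superpixels that were discarded."""
        n_touched = len(self.labels) + len(self.discarded)
        return len(self.discarded) / n_touched if n_touched else 0.0


def regions_to_superpixel_labels(
    regions: np.ndarray,
    sp: SuperpixelMap,
    min_fraction: float = 0.10,
    min_labelled_pixels: int = 2,
) -> SuperpixelLabelSet:
    """Convert a brush-region label grid {0,1,2} to superpixel classes.

    Rules, applied per superpixel over its labelled pixels:

    * pixels of both classes present -> discarded (``mixed``);
    * fewer than ``min_labelled_pixels`` labelled pixels -> discarded
      (``too_few``);
    * one class covering >= ``min_fraction`` of the superpixel's total
      pixel count -> that class; below the fraction the superpixel is
      ignored, as are fully unlabelled ones.
    """
    regions = np.asarray(regions)
    if regions.shape != sp.labels.shape:
        raise ValueError("region grid and superpixel map dimensions differ")
    if not np.isin(regions, (UNLABELLED, EAR_REGION, LEAF_REGION)).all():
        raise ValueError("region values must be in {0, 1, 2}")

    flat = sp.labels.ravel()
    total = np.bincount(flat, minlength=sp.n_regions)
    n_ear = np.bincount(flat, weights=(regions.ravel() == EAR_REGION), minlength=sp.n_regions)
    n_leaf = np.bincount(flat, weights=(regions.ravel() == LEAF_REGION), minlength=sp.n_regions)

    labels: dict[int, str] = {}
    discarded: list[tuple[int, str]] = []
    ignored: list[int] = []
    for s in range(sp.n_regions):
        ne, nl = int(n_ear[s]), int(n_leaf[s])
        if ne == 0 and nl == 0:
            ignored.append(s)
            continue
        if ne > 0 and nl > 0:
            discarded.append((s, "mixed"))
            continue
        if ne + nl < min_labelled_pixels:
            discarded.append((s, "too_few"))
            continue
        cls, count = ("ear", ne) if ne > 0 else ("leaf", nl)
        if count >= min_fraction * total[s]:
            labels[s] = cls
        else:
            ignored.append(s)
    return SuperpixelLabelSet(labels=labels, discarded=discarded, ignored=ignored)


def split_dataset(
    table: pd.DataFrame,
    train_fraction: float = 0.80,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Randomize labelled rows and split round(n*train_fraction) / rest."""
    n = len(table)
    if n < 5:
        raise ValueError("need at least 5 labelled rows to split")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    n_train = round(n * train_fraction)
    return (
        table.iloc[order[:n_train]].reset_index(drop=True),
        table.iloc[order[n_train:]].reset_index(drop=True),
    )


def pixel_grid_sample(
    height: int,
    width: int,
    n_points: int = 18,
    n_rows: int = 3,
    margin_fraction: float = 0.05,
) -> list[tuple[int, int]]:
    """Deterministic evaluation grid: n_rows rows, evenly spaced columns.

    Rows and columns are placed at the centers of equal subdivisions of
    the in-margin area, so the 18-point default yields 3 rows of 6.
    """
    if n_points % n_rows != 0:
        raise ValueError("n_points must be divisible by n_rows")
    n_cols = n_points // n_rows
    r0, r1 = margin_fraction * height, (1 - margin_fraction) * height
    c0, c1 = margin_fraction * width, (1 - margin_fraction) * width
    if r1 - r0 < n_rows or c1 - c0 < n_cols:
        raise ValueError("image too small for the requested grid")
    rows = [int(r0 + (r1 - r0) * (i + 0.5) / n_rows) for i in range(n_rows)]
    cols = [int(c0 + (c1 - c0) * (j + 0.5) / n_cols) for j in range(n_cols)]
    return [(r, c) for r in rows for c in cols]


def annotate_pixels(
    img: MultiChannelImage,
    coordinates: Sequence[tuple[int, int]],
    operator: str,
    responder: Callable[[np.ndarray, tuple[int, int]], int],
    out_csv: str | Path | None = None,
    zoom_half_size: int = 25,
) -> list[PixelAnnotation]:
    """Collect one three-way class decision per coordinate.

    ``responder`` receives a zoomed RGB crop centered on the pixel and
    the coordinate, and returns 1 (background), 2 (ear) or 3
    (uncertain) — in production an interactive prompt, in tests a
    scripted function. Records are appended to ``out_csv`` as they are
    made, so an aborted session leaves a resumable partial file.
    """
    h, w = img.shape
    rgb = img.rgb()
    records: list[PixelAnnotation] = []
    writer = fh = None
    if out_csv is not None:
        out_csv = Path(out_csv)
        new = not out_csv.exists()
        fh = open(out_csv, "a", newline="")
        writer = csv.writer(fh)
        if new:
            writer.writerow(["image_id", "row", "col", "class", "operator"])
    try:
        for r, c in coordinates:
            if not (0 <= r < h and 0 <= c < w):
                raise ValueError(f"coordinate ({r}, {c}) outside {h}x{w} image")
            crop = rgb[
                max(0, r - zoom_half_size) : r + zoom_half_size + 1,
                max(0, c - zoom_half_size) : c + zoom_half_size + 1,
            ]
            cls = int(responder(crop, (r, c)))
            ann = PixelAnnotation(row=r, col=c, cls=cls, operator=operator,
                                  image_id=img.image_id)
            records.append(ann)
            if writer is not None:
                writer.writerow([ann.image_id, ann.row, ann.col, ann.cls, ann.operator])
                fh.flush()
    finally:
        if fh is not None:
            fh.close()
    return records


def annotations_to_frame(annotations: Iterable[PixelAnnotation]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"image_id": a.image_id, "row": a.row, "col": a.col,
             "class": a.cls, "operator": a.operator}
            for a in annotations
        ]
    )


def read_annotations(path: str | Path) -> list[PixelAnnotation]:
    frame = pd.read_csv(path)
    return [
        PixelAnnotation(row=int(r.row), col=int(r.col), cls=int(r["class"]),
                        operator=str(r.operator), image_id=str(r.image_id))
        for _, r in frame.iterrows()
    ]
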