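"""Pixel-level evaluation of predicted ternary masks.

The predicted mask assigns every pixel to soil (0), leaf (1) or ear
(2). Ground truth is the sparse pixel-grid annotation, where soil and
leaf merge into one "background" class to match the operator's
three-button protocol (background / ear / uncertain). Uncertain
annotations are discarded before any metric. Metrics are the usual
confusion-table quantities with ear as the positive class, Cohen's
kappa for inter-annotator agreement, and the ear ratio (fraction of
ear pixels) as a proxy for ear prominence.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from earseg.annotation import CLS_BACKGROUND, CLS_EAR, CLS_UNCERTAIN, PixelAnnotation

# ternary mask values
MASK_SOIL, MASK_LEAF, MASK_EAR = 0, 1, 2


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.tp + other.tp, self.tn + other.tn,
                               self.fp + other.fp, self.fn + other.fn)


@dataclass(frozen=True)
class AgreementResult:
    kappa: float
    p_o: float
    p_e: float
    n_used: int
    n_discarded: int


def confusion_from_annotations(
    mask: np.ndarray, annotations: Sequence[PixelAnnotation]
) -> ConfusionCounts:
    """Tally the annotated pixels against the predicted mask.

    Predicted ear (mask value 2) is the positive class; predicted soil
    and leaf both count as background. Uncertain annotations are
    excluded; if nothing remains the metrics are undefined and a
    ValueError is raised.
    """
    h, w = mask.shape
    tp = tn = fp = fn = 0
    n_used = 0
    for a in annotations:
        if not (0 <= a.row < h and 0 <= a.col < w):
            raise ValueError(f"annotation at ({a.row}, {a.col}) outside {h}x{w} mask")
        if a.cls == CLS_UNCERTAIN:
            continue
        n_used += 1
        pred_ear = mask[a.row, a.col] == MASK_EAR
        true_ear = a.cls == CLS_EAR
        if pred_ear and true_ear:
            tp += 1
        elif pred_ear and not true_ear:
            fp += 1
        elif not pred_ear and true_ear:
            fn += 1
        else:
            tn += 1
    if n_used == 0:
        raise ValueError("all annotations uncertain: metrics undefined")
    return ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)


def precision_recall_f1(c: ConfusionCounts) -> tuple[float, float, float]:
    """precision = tp/(tp+fp); recall = tp/(tp+fn); F1 their harmonic mean."""
    if c.tp + c.fp == 0 or c.tp + c.fn == 0:
        raise ValueError("precision/recall undefined: empty denominator")
    precision = c.tp / (c.tp + c.fp)
    recall = c.tp / (c.tp + c.fn)
    f1 = 0.0 if precision + recall == 0 else 2 * precision * recall / (precision + recall)
    return precision, recall, f1


def cohens_kappa(
    a: Sequence[PixelAnnotation], b: Sequence[PixelAnnotation]
) -> AgreementResult:
    """Chance-corrected two-class agreement between two annotators.

    Annotations are matched on (image_id, row, col); pairs where either
    label is uncertain are discarded. p_e uses each annotator's own
    marginal label frequencies (the standard Cohen definition). If both
    annotators are constant and identical, p_e = 1 and kappa is defined
    as 1 by convention.
    """
    index_b = {(x.image_id, x.row, x.col): x.cls for x in b}
    pairs = []
    n_discarded = 0
    for x in a:
        key = (x.image_id, x.row, x.col)
        if key not in index_b:
            raise ValueError(f"coordinate {key} not annotated by both operators")
        cb = index_b[key]
        if x.cls == CLS_UNCERTAIN or cb == CLS_UNCERTAIN:
            n_discarded += 1
            continue
        pairs.append((x.cls, cb))
    if not pairs:
        raise ValueError("no usable annotation pairs")
    n = len(pairs)
    p_o = sum(1 for ca, cb in pairs if ca == cb) / n
    ma = Counter(ca for ca, _ in pairs)
    mb = Counter(cb for _, cb in pairs)
    p_e = sum(ma[k] * mb[k] for k in (CLS_BACKGROUND, CLS_EAR)) / (n * n)
    if p_e == 1.0:
        kappa = 1.0
    else:
        kappa = (p_o - p_e) / (1 - p_e)
    return AgreementResult(kappa=kappa, p_o=p_o, p_e=p_e,
                           n_used=n, n_discarded=n_discarded)


def ear_ratio(source: np.ndarray | Sequence[PixelAnnotation]) -> float:
    """Fraction of ear pixels among evaluated pixels.

    For a ternary mask: ear pixels / all pixels. For annotations: ear
    count / (ear + background), after discarding uncertain labels.
    """
    if isinstance(source, np.ndarray):
        if source.size == 0:
            raise ValueError("empty mask")
        return float(np.mean(source == MASK_EAR))
    counts = Counter(a.cls for a in source)
    used = counts[CLS_BACKGROUND] + counts[CLS_EAR]
    if used == 0:
        raise ValueError("no certain annotations")
    return counts[CLS_EAR] / used


def aggregate_by_group(
    records: Iterable[Mapping],
    group_key: str,
) -> pd.DataFrame:
    """Pool confusion counts per group, then compute metrics once per group.

    ``records`` are mappings with the group column plus tp/tn/fp/fn
    (e.g. one per image). Counts are summed within a group before the
    F1 family is computed, so sparsely annotated images do not carry
    disproportionate weight.
    """
    frame = pd.DataFrame(list(records))
    if frame.empty:
        raise ValueError("no records to aggregate")
    rows = []
    for key, grp in frame.groupby(group_key, sort=True):
        c = ConfusionCounts(int(grp["tp"].sum()), int(grp["tn"].sum()),
                            int(grp["fp"].sum()), int(grp["fn"].sum()))
        try:
            precision, recall, f1 = precision_recall_f1(c)
        except ValueError:
            # a sparsely annotated group can miss the positive class entirely
            precision = recall = f1 = float("nan")
        rows.append({
            group_key: key, "tp": c.tp, "tn": c.tn, "fp": c.fp, "fn": c.fn,
            "n_pixels": c.total, "precision": precision, "recall": recall,
            "f1": f1, "ear_ratio": (c.tp + c.fn) / c.total,
        })
    return pd.DataFrame(rows)


def plot_metric_curve(table: pd.DataFrame, x: str, y: str, out_path,
                      hue: str | None = None) -> None:
    """Line plot of a metric over a grouping axis (e.g. F1 over date)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    if hue is None:
        ax.plot(table[x], table[y], marker="o")
    else:
        for key, grp in table.groupby(hue):
            ax.plot(grp[x], grp[y], marker="o", label=str(key))
        ax.legend(title=hue)
    ax.set_xlabel(x)
    ax.set_ylabel(y)
    fig.tight_layout()
    fig.savefig(out_path)
    plt.close(fig)
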