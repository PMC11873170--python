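"""Evaluation metrics.

Classification: accuracy, per-class (one-vs-rest) precision and recall,
macro-averaged F1, and the 3x3 confusion matrix.

Segmentation: per-image IoU averaged over the two classes (background and
tongue), the foreground Dice coefficient 2TP/(FN+2TP+FP), and the symmetric
Hausdorff distance between foreground boundaries; dataset values are means
over images. The Hausdorff distance has a brute-force O(|A|x|B|) reference and
a distance-transform fast path that agree exactly on integer pixel grids.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial.distance import cdist

__all__ = [
    "ClsReport", "SegReport", "cls_metrics", "seg_metrics",
    "hausdorff", "hausdorff_masks", "boundary_points",
]

_CROSS = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


# --------------------------------------------------------------------- reports
@dataclass
class ClsReport:
    accuracy: float
    f1: float
    precision: list            # per class
    recall: list               # per class
    confusion: np.ndarray      # 3x3, rows = truth, cols = prediction

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "f1": self.f1,
            "precision": list(self.precision),
            "recall": list(self.recall),
            "confusion": self.confusion.tolist(),
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, **kwargs)


@dataclass
class SegReport:
    miou: float
    dice: float
    mhd: float
    per_image: list = field(default_factory=list)   # (iou, dice, hd) triples

    def to_dict(self) -> dict:
        return {
            "miou": self.miou,
            "dice": self.dice,
            "mhd": self.mhd,
            "per_image": [list(t) for t in self.per_image],
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, **kwargs)


# ---------------------------------------------------------------- classification
def cls_metrics(pred, truth, n_classes: int = 3) -> ClsReport:
    """Accuracy, one-vs-rest precision/recall, macro F1, confusion matrix.

    Zero-division (a class never predicted or never present) yields 0 for the
    affected precision/recall/F1 with a warning, never an exception.
    """
    pred = np.asarray(pred, dtype=np.int64)
    truth = np.asarray(truth, dtype=np.int64)
    if pred.shape != truth.shape:
        raise ValueError(f"pred {pred.shape} and truth {truth.shape} differ in length")
    if pred.size and not (np.isin(pred, range(n_classes)).all()
                          and np.isin(truth, range(n_classes)).all()):
        raise ValueError(f"labels must lie in [0, {n_classes})")
    confusion = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(confusion, (truth, pred), 1)
    accuracy = float(np.trace(confusion)) / max(1, confusion.sum())
    precision, recall, f1 = [], [], []
    for c in range(n_classes):
        tp = confusion[c, c]
        fp = confusion[:, c].sum() - tp
        fn = confusion[c, :].sum() - tp
        p = _safe_div(tp, tp + fp, f"class {c} never predicted")
        r = _safe_div(tp, tp + fn, f"class {c} never present")
        precision.append(p)
        recall.append(r)
        f1.append(_safe_div(2 * p * r, p + r, f"class {c} degenerate F1"))
    return ClsReport(accuracy=accuracy, f1=float(np.mean(f1)),
                     precision=precision, recall=recall, confusion=confusion)


def _safe_div(num, den, what: str) -> float:
    if den == 0:
        warnings.warn(f"zero division in metric ({what}); reporting 0", stacklevel=3)
        return 0.0
    return float(num) / float(den)


# ----------------------------------------------------------------- segmentation
def boundary_points(mask: np.ndarray) -> np.ndarray:
    """Boundary of a binary mask: foreground minus its 4-connected erosion."""
    mask = np.asarray(mask, dtype=bool)
    eroded = ndimage.binary_erosion(mask, structure=_CROSS, border_value=0)
    return np.argwhere(mask & ~eroded)


def hausdorff(a: np.ndarray, b: np.ndarray) -> float:
    """Symmetric Hausdorff distance between two nonempty point sets.

    Brute force: max over both directed sup-inf distances, Euclidean metric.
    """
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    if a.size == 0 or b.size == 0:
        raise ValueError("hausdorff distance of an empty point set is undefined")
    d = cdist(a, b)
    return float(max(d.min(axis=1).max(), d.min(axis=0).max()))


def hausdorff_masks(pred: np.ndarray, truth: np.ndarray) -> float:
    """Fast path: boundary Hausdorff via exact Euclidean distance transforms."""
    pa = boundary_points(pred)
    pb = boundary_points(truth)
    if len(pa) == 0 or len(pb) == 0:
        raise ValueError("hausdorff distance of an empty boundary is undefined")
    dt_b = ndimage.distance_transform_edt(~_points_to_mask(pb, truth.shape))
    dt_a = ndimage.distance_transform_edt(~_points_to_mask(pa, pred.shape))
    d_ab = dt_b[pa[:, 0], pa[:, 1]].max()
    d_ba = dt_a[pb[:, 0], pb[:, 1]].max()
    return float(max(d_ab, d_ba))


def _points_to_mask(points: np.ndarray, shape) -> np.ndarray:
    m = np.zeros(shape, dtype=bool)
    m[points[:, 0], points[:, 1]] = True
    return m


def _image_metrics(pred: np.ndarray, truth: np.ndarray,
                   hd_variant: str) -> tuple[float, float, float]:
    pred = np.asarray(pred).astype(bool)
    truth = np.asarray(truth).astype(bool)
    if pred.shape != truth.shape:
        raise ValueError(f"mask shapes differ: {pred.shape} vs {truth.shape}")
    diag = float(np.hypot(*pred.shape))
    tp = int((pred & truth).sum())
    fp = int((pred & ~truth).sum())
    fn = int((~pred & truth).sum())
    tn = int((~pred & ~truth).sum())
    if not pred.any() and not truth.any():
        # degenerate: both empty -> perfect by policy
        return 1.0, 1.0, 0.0
    if pred.any() != truth.any():
        # degenerate: exactly one empty
        iou_fg = 0.0
        iou_bg = tn / (tn + fp + fn) if (tn + fp + fn) else 0.0
        return 0.5 * (iou_fg + iou_bg), 0.0, diag
    iou_fg = tp / (fn + tp + fp)
    iou_bg = tn / (fp + tn + fn)       # background class: its TP is TN
    miou = 0.5 * (iou_fg + iou_bg)
    dice = 2 * tp / (fn + 2 * tp + fp)
    if hd_variant == "max":
        hd = hausdorff_masks(pred, truth)
    elif hd_variant == "average":
        pa, pb = boundary_points(pred), boundary_points(truth)
        d = cdist(pa.astype(float), pb.astype(float))
        hd = 0.5 * float(d.min(axis=1).mean() + d.min(axis=0).mean())
    else:
        raise ValueError(f"unknown hd_variant {hd_variant!r}")
    return miou, dice, hd


def seg_metrics(pred_masks, truth_masks, hd_variant: str = "max") -> SegReport:
    """Dataset segmentation report: per-image metrics averaged over images."""
    if len(pred_masks) != len(truth_masks):
        raise ValueError("pred and truth mask lists differ in length")
    per_image = [_image_metrics(p, t, hd_variant)
                 for p, t in zip(pred_masks, truth_masks)]
    arr = np.array(per_image, dtype=float)
    return SegReport(miou=float(arr[:, 0].mean()),
                     dice=float(arr[:, 1].mean()),
                     mhd=float(arr[:, 2].mean()),
                     per_image=per_image)


def confusion_to_csv(confusion: np.ndarray, path) -> None:
    """Write a confusion matrix as CSV with class-name headers."""
    import pandas as pd

    names = ["thin", "normal", "bulgy"][: confusion.shape[0]]
    pd.DataFrame(confusion, index=names, columns=names).to_csv(path)


def confusion_heatmap(confusion: np.ndarray, path) -> None:
    """Render a confusion-matrix heat map PNG (requires matplotlib)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    names = ["thin", "normal", "bulgy"][: confusion.shape[0]]
    fig, ax = plt.subplots(figsize=(4, 3.5))
    im = ax.imshow(confusion, cmap="Blues")
    for (i, j), v in np.ndenumerate(confusion):
        ax.text(j, i, str(v), ha="center", va="center")
    ax.set_xticks(range(len(names)), names)
    ax.set_yticks(range(len(names)), names)
    ax.set_xlabel("predicted")
    ax.set_ylabel("true")
    fig.colorbar(im)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
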