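"""Empirical ROC over the degree of encasement, Youden cutoff, confusion metrics.

The classifier is the single score "degree of encasement": a lesion is
predicted malignant when its degree is at or above the cutoff.  Candidate
cutoffs are the distinct observed degrees plus a +inf sentinel (the
all-negative operating point), so the published best cutoff is always an
observed degree.  AUC is the trapezoidal area of the empirical curve, which
coincides with the Mann-Whitney U statistic scaled by n1*n0 (ties counted
half).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "RocCurve",
    "ConfusionMetrics",
    "empirical_roc",
    "youden_cutoff",
    "confusion_metrics",
    "plot_roc",
]


@dataclass(frozen=True)
class RocCurve:
    """Empirical operating points (cutoff, sensitivity, 1-specificity), AUC,
    and the Youden-optimal cutoff."""

    operating_points: tuple[tuple[float, float, float], ...]
    auc: float
    best_cutoff: float
    youden_j: float


@dataclass(frozen=True)
class ConfusionMetrics:
    """Confusion counts and rates (percent) at one cutoff.

    Rates are None when their denominator is zero (e.g. PPV with no
    predicted positives), never a division failure.
    """

    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float | None
    specificity: float | None
    ppv: float | None
    npv: float | None


def _check_inputs(degrees, labels) -> tuple[np.ndarray, np.ndarray]:
    d = np.asarray(degrees, dtype=float)
    y = np.asarray(labels)
    if d.shape != y.shape or d.ndim != 1:
        raise ValueError("degrees and labels must be 1-d and the same length")
    if y.dtype.kind in "US":
        y = (y == "malignant").astype(int)
    y = y.astype(int)
    return d, y


def _point(d: np.ndarray, y: np.ndarray, cutoff: float) -> tuple[float, float]:
    pred = d >= cutoff
    tp = int(np.sum(pred & (y == 1)))
    fp = int(np.sum(pred & (y == 0)))
    n1 = int(np.sum(y == 1))
    n0 = int(np.sum(y == 0))
    return tp / n1, fp / n0


def empirical_roc(degrees, labels) -> RocCurve:
    """Empirical ROC of degree-of-encasement against malignancy.

    ``labels`` may be 0/1 (1 = malignant) or the strings "benign"/"malignant".
    """
    d, y = _check_inputs(degrees, labels)
    n1 = int(np.sum(y == 1))
    n0 = int(np.sum(y == 0))
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")

    cutoffs = sorted(set(d.tolist())) + [math.inf]
    points = []
    for c in cutoffs:
        sens, fpr = _point(d, y, c)
        points.append((c, sens, fpr))

    # trapezoid over (fpr, tpr), ordered by increasing fpr
    fprs = np.array([p[2] for p in points][::-1])
    tprs = np.array([p[1] for p in points][::-1])
    auc = float(np.trapezoid(tprs, fprs))

    best, j = youden_from_points(points)
    return RocCurve(operating_points=tuple(points), auc=auc,
                    best_cutoff=best, youden_j=j)


def youden_from_points(points) -> tuple[float, float]:
    best_cutoff, best_j, best_sens = None, -math.inf, -1.0
    for c, sens, fpr in points:
        if not math.isfinite(c):
            continue
        j = sens - fpr  # sensitivity + specificity - 1
        # ties break toward higher sensitivity, then lower cutoff
        if (j > best_j + 1e-12
                or (abs(j - best_j) <= 1e-12 and sens > best_sens + 1e-12)
                or (abs(j - best_j) <= 1e-12 and abs(sens - best_sens) <= 1e-12
                    and c < best_cutoff)):
            best_cutoff, best_j, best_sens = c, j, sens
    return float(best_cutoff), float(best_j)


def youden_cutoff(roc: RocCurve) -> float:
    """Cutoff maximizing Youden's J = sensitivity + specificity - 1."""
    return youden_from_points(roc.operating_points)[0]


def closest_to_corner_cutoff(roc: RocCurve) -> float:
    """Alternative criterion: cutoff closest to the (0, 1) corner."""
    best_cutoff, best_d = None, math.inf
    for c, sens, fpr in roc.operating_points:
        if not math.isfinite(c):
            continue
        dist = math.hypot(fpr, 1.0 - sens)
        if dist < best_d - 1e-12 or (abs(dist - best_d) <= 1e-12 and c < best_cutoff):
            best_cutoff, best_d = c, dist
    return float(best_cutoff)


def confusion_metrics(degrees, labels, cutoff: float) -> ConfusionMetrics:
    """Confusion counts and percent rates at ``cutoff`` (malignant iff >=)."""
    if not math.isfinite(cutoff):
        raise ValueError("cutoff must be finite")
    d, y = _check_inputs(degrees, labels)
    pred = d >= cutoff
    tp = int(np.sum(pred & (y == 1)))
    fp = int(np.sum(pred & (y == 0)))
    fn = int(np.sum(~pred & (y == 1)))
    tn = int(np.sum(~pred & (y == 0)))

    def rate(num: int, den: int) -> float | None:
        return 100.0 * num / den if den else None

    return ConfusionMetrics(
        tp=tp, fp=fp, tn=tn, fn=fn,
        sensitivity=rate(tp, tp + fn),
        specificity=rate(tn, tn + fp),
        ppv=rate(tp, tp + fp),
        npv=rate(tn, tn + fn),
    )


def plot_roc(roc: RocCurve, path: str, label_cutoffs: bool = True) -> None:
    """Export the ROC curve as SVG/PNG (cosmetic; requires matplotlib)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fprs = [p[2] for p in roc.operating_points][::-1]
    tprs = [p[1] for p in roc.operating_points][::-1]
    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    ax.plot(fprs, tprs, marker="o", lw=1.2, ms=3)
    ax.plot([0, 1], [0, 1], ls="--", c="grey", lw=0.8)
    if label_cutoffs:
        for c, sens, fpr in roc.operating_points:
            if math.isfinite(c):
                ax.annotate(f"{c:.1f}", (fpr, sens), fontsize=6,
                            xytext=(3, 3), textcoords="offset points")
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.set_title(f"AUC = {roc.auc:.3f}, best cutoff {roc.best_cutoff:.1f}%")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
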