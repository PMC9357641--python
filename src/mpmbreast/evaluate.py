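"""Evaluation statistics: tile confusion matrix, malignant probability,
ROC/AUC, Mann-Whitney U, and Cohen's kappa.

Conventions: a nonblank tile is predicted positive iff its classifier
score reaches the tile cutoff (default 0.5); blank tiles are always
predicted negative.  The per-image "malignant probability" is the fraction
of positive tiles among the image's 64 tiles (blanks included in the
denominator); an image is called malignant iff that fraction reaches the
verdict threshold (default 0.0625, i.e. 4 of 64 tiles).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import DataError, GeometryError, InvalidConfigError

__all__ = [
    "ConfusionMatrix",
    "ImageVerdict",
    "VerdictConfig",
    "AgreementTable",
    "tile_outcomes",
    "matrix_metrics",
    "malignant_probability",
    "image_level_rates",
    "roc_curve",
    "mann_whitney_u",
    "cohens_kappa",
]

#: Marker for metrics whose denominator is zero.
UNDEFINED = float("nan")

TILE_CUTOFF = 0.5


@dataclass(frozen=True)
class ConfusionMatrix:
    """Tile-level TP/FP/FN/TN counts (positive = cancer)."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise InvalidConfigError("confusion-matrix counts must be >= 0")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass
class ImageVerdict:
    """Per-image malignant-probability decision against ground truth."""

    image_id: str
    malignant_probability: float
    predicted_class: str  # "malignant" | "nonmalignant"
    truth_class: str  # "cancerous" | "normal"


@dataclass(frozen=True)
class VerdictConfig:
    """Image-level decision rule: malignant iff probability >= threshold."""

    threshold: float = 0.0625
    strict: bool = False  # True: use > instead of >=

    def __post_init__(self) -> None:
        if not 0.0 < self.threshold < 1.0:
            raise InvalidConfigError("verdict threshold must be in (0, 1)")

    def is_malignant(self, probability: float) -> bool:
        if self.strict:
            return probability > self.threshold
        return probability >= self.threshold


@dataclass(frozen=True)
class AgreementTable:
    """2 x 2 rater agreement counts: rows rater 1, columns rater 2."""

    counts: tuple[tuple[int, int], tuple[int, int]]

    def __post_init__(self) -> None:
        flat = [c for row in self.counts for c in row]
        if any(c < 0 for c in flat):
            raise InvalidConfigError("agreement counts must be >= 0")
        if sum(flat) == 0:
            raise InvalidConfigError("agreement table must have observations")

    @property
    def total(self) -> int:
        return sum(c for row in self.counts for c in row)


def tile_outcomes(tiles, tile_cutoff: float = TILE_CUTOFF) -> ConfusionMatrix:
    """Tally the tile confusion matrix over a cohort.

    ``tiles`` is an iterable of objects (or dicts) with ``truth_label``
    ("cancer"/"no_cancer"), ``is_blank``, and ``score``.  Predicted
    positive = nonblank with score >= cutoff; blank tiles and sub-cutoff
    nonblank tiles are predicted negative.
    """
    tp = fp = fn = tn = 0
    for t in tiles:
        get = t.get if isinstance(t, dict) else lambda k, _t=t: getattr(_t, k)
        truth = get("truth_label")
        if truth not in ("cancer", "no_cancer"):
            raise DataError(f"tile missing truth label (got {truth!r})")
        blank = bool(get("is_blank"))
        score = get("score")
        if not blank and score is None:
            raise DataError("nonblank tile missing classifier score")
        positive = (not blank) and score >= tile_cutoff
        if truth == "cancer":
            tp, fn = tp + positive, fn + (not positive)
        else:
            fp, tn = fp + positive, tn + (not positive)
    return ConfusionMatrix(tp, fp, fn, tn)


def matrix_metrics(cm: ConfusionMatrix) -> tuple[float, float, float, float]:
    """(accuracy, precision, recall, F-measure); NaN marks a zero denominator."""
    accuracy = (cm.tp + cm.tn) / cm.total if cm.total else UNDEFINED
    precision = cm.tp / (cm.tp + cm.fp) if (cm.tp + cm.fp) else UNDEFINED
    recall = cm.tp / (cm.tp + cm.fn) if (cm.tp + cm.fn) else UNDEFINED
    if math.isnan(precision) or math.isnan(recall) or precision + recall == 0:
        f = UNDEFINED
    else:
        f = 2.0 * precision * recall / (precision + recall)
    return accuracy, precision, recall, f


def malignant_probability(tiles, expected_tiles: int = 64) -> float:
    """Fraction of predicted-positive tiles in one image.

    ``tiles`` may be Tile-like records (scored via the 0.5 cutoff, blanks
    negative) or booleans.  Blank tiles stay in the denominator: the ratio
    is over all tiles of the captured image.
    """
    tiles = list(tiles)
    if len(tiles) != expected_tiles:
        raise GeometryError(f"expected {expected_tiles} tiles, got {len(tiles)}")
    pos = 0
    for t in tiles:
        if isinstance(t, (bool, np.bool_)):
            pos += bool(t)
        else:
            get = t.get if isinstance(t, dict) else lambda k, _t=t: getattr(_t, k)
            pos += (not get("is_blank")) and get("score") is not None and get(
                "score"
            ) >= TILE_CUTOFF
    return pos / len(tiles)


def image_level_rates(verdicts: list[ImageVerdict]) -> tuple[float, float]:
    """(sensitivity, specificity) of the malignant/nonmalignant calls."""
    n_cancer = sum(v.truth_class == "cancerous" for v in verdicts)
    n_normal = sum(v.truth_class == "normal" for v in verdicts)
    tp = sum(
        v.truth_class == "cancerous" and v.predicted_class == "malignant" for v in verdicts
    )
    tn = sum(
        v.truth_class == "normal" and v.predicted_class == "nonmalignant" for v in verdicts
    )
    sensitivity = tp / n_cancer if n_cancer else UNDEFINED
    specificity = tn / n_normal if n_normal else UNDEFINED
    return sensitivity, specificity


def roc_curve(
    verdicts: list[ImageVerdict], n_tiles: int = 64
) -> tuple[list[tuple[float, float]], float]:
    """ROC of malignant probability over the achievable threshold grid.

    Thresholds sweep {0, 1/n, ..., n/n, 1+}; an image is called malignant
    at threshold t iff its probability >= t.  Returns ((FPR, TPR) points
    ordered by increasing FPR, trapezoid AUC).  Single-class input yields
    an undefined (NaN) AUC.
    """
    scores = np.array([v.malignant_probability for v in verdicts], dtype=float)
    truth = np.array([v.truth_class == "cancerous" for v in verdicts])
    n_pos, n_neg = int(truth.sum()), int((~truth).sum())
    thresholds = np.concatenate([np.arange(n_tiles + 1) / n_tiles, [1.0 + 1.0 / n_tiles]])
    points = []
    for t in thresholds[::-1]:  # descending: (0,0) first
        called = scores >= t
        tpr = called[truth].mean() if n_pos else UNDEFINED
        fpr = called[~truth].mean() if n_neg else UNDEFINED
        points.append((float(fpr), float(tpr)))
    if n_pos == 0 or n_neg == 0:
        return points, UNDEFINED
    fprs = np.array([p[0] for p in points])
    tprs = np.array([p[1] for p in points])
    auc = float(np.trapezoid(tprs, fprs))
    return points, auc


def mann_whitney_u(group1, group2) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Exact enumeration for combined n <= 20 without ties; tie-corrected
    normal approximation otherwise.  Returns (U of group1, p value).
    All-tied input yields p = 1.
    """
    from scipy import stats

    g1 = np.asarray(group1, dtype=float)
    g2 = np.asarray(group2, dtype=float)
    if len(g1) == 0 or len(g2) == 0:
        raise InvalidConfigError("both groups must be nonempty")
    combined = np.concatenate([g1, g2])
    if np.all(combined == combined[0]):
        return len(g1) * len(g2) / 2.0, 1.0
    has_ties = len(np.unique(combined)) < len(combined)
    if len(combined) <= 20 and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(g1, g2, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def cohens_kappa(table: AgreementTable) -> float:
    """Chance-corrected agreement kappa = (p_o - p_e) / (1 - p_e).

    If chance agreement p_e = 1: kappa is 1 when observed agreement is
    also perfect, otherwise undefined (NaN).
    """
    c = np.asarray(table.counts, dtype=float)
    n = c.sum()
    p_o = np.trace(c) / n
    p_e = float(np.sum(c.sum(axis=0) * c.sum(axis=1)) / n**2)
    if p_e == 1.0:
        return 1.0 if p_o == 1.0 else UNDEFINED
    return float((p_o - p_e) / (1.0 - p_e))


def save_roc_plot(points, auc: float, path) -> None:
    """Write the ROC curve as an SVG/PNG figure."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fpr = [p[0] for p in points]
    tpr = [p[1] for p in points]
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.plot(fpr, tpr, marker=".", color="tab:red")
    ax.plot([0, 1], [0, 1], ls="--", color="gray", lw=0.8)
    ax.set_xlabel("False positive rate")
    ax.set_ylabel("True positive rate")
    ax.set_title(f"Malignant probability ROC (AUC = {auc:.3f})")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
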