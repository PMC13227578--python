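"""Classification report, regression errors, residual densities, confidence
intervals and effect sizes.

The per-class precision/recall/F1 counting, Cohen's kappa, the
normal-approximation confidence interval and both Cohen's d conventions are
implemented directly from their defining formulas; the test suite
cross-checks them against scikit-learn and scipy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "confusion_matrix",
    "ClassificationReport",
    "classification_report",
    "regression_metrics",
    "residual_density",
    "confidence_interval",
    "cohens_d",
    "percent_change",
    "augmentation_ab_report",
]


def confusion_matrix(
    y_true: np.ndarray, y_pred: np.ndarray, n_classes: int | None = None
) -> np.ndarray:
    """C×C count matrix, rows = true class, columns = predicted class."""
    yt = np.asarray(y_true, dtype=int)
    yp = np.asarray(y_pred, dtype=int)
    if yt.size == 0 or yt.shape != yp.shape:
        raise ValueError("y_true and y_pred must be equal-length and non-empty")
    c = n_classes or int(max(yt.max(), yp.max())) + 1
    cm = np.zeros((c, c), dtype=int)
    np.add.at(cm, (yt, yp), 1)
    return cm


@dataclass
class ClassificationReport:
    """Per-class and aggregate classification metrics.

    ``zero_division_flags`` lists classes that were never predicted, whose
    precision is reported as 0 by convention rather than raising.
    """

    precision: np.ndarray
    recall: np.ndarray
    f1: np.ndarray
    support: np.ndarray
    accuracy: float
    weighted_precision: float
    weighted_recall: float
    weighted_f1: float
    macro_precision: float
    macro_recall: float
    macro_f1: float
    cohen_kappa: float
    zero_division_flags: list[int] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "class": i,
                "precision": self.precision[i],
                "recall": self.recall[i],
                "f1": self.f1[i],
                "support": int(self.support[i]),
            }
            for i in range(len(self.support))
        ]
        return pd.DataFrame(rows)


def classification_report(
    y_true: np.ndarray, y_pred: np.ndarray, n_classes: int | None = None
) -> ClassificationReport:
    """Precision TP/(TP+FP), recall TP/(TP+FN), F1, support-weighted and
    macro averages, accuracy and Cohen's kappa
    κ = (p_o − p_e)/(1 − p_e) with p_e from the marginal products."""
    cm = confusion_matrix(y_true, y_pred, n_classes)
    total = cm.sum()
    tp = np.diag(cm).astype(float)
    pred_tot = cm.sum(0).astype(float)
    true_tot = cm.sum(1).astype(float)

    flags = [int(i) for i in np.nonzero(pred_tot == 0)[0]]
    with np.errstate(divide="ignore", invalid="ignore"):
        precision = np.where(pred_tot > 0, tp / np.maximum(pred_tot, 1), 0.0)
        recall = np.where(true_tot > 0, tp / np.maximum(true_tot, 1), 0.0)
        denom = precision + recall
        f1 = np.where(denom > 0, 2 * precision * recall / np.maximum(denom, 1e-300), 0.0)

    support = true_tot
    w = support / total
    accuracy = float(tp.sum() / total)
    p_o = accuracy
    p_e = float((true_tot * pred_tot).sum() / total**2)
    kappa = 1.0 if p_e == 1.0 else (p_o - p_e) / (1.0 - p_e)

    return ClassificationReport(
        precision=precision,
        recall=recall,
        f1=f1,
        support=support.astype(int),
        accuracy=accuracy,
        weighted_precision=float((w * precision).sum()),
        weighted_recall=float((w * recall).sum()),
        weighted_f1=float((w * f1).sum()),
        macro_precision=float(precision.mean()),
        macro_recall=float(recall.mean()),
        macro_f1=float(f1.mean()),
        cohen_kappa=float(kappa),
        zero_division_flags=flags,
    )


def regression_metrics(predicted: np.ndarray, actual: np.ndarray) -> tuple[float, float]:
    """(MAE, RMSE) of severity predictions; RMSE ≥ MAE always."""
    pred = np.atleast_1d(np.asarray(predicted, dtype=np.float64))
    act = np.atleast_1d(np.asarray(actual, dtype=np.float64))
    if pred.size == 0 or pred.shape != act.shape:
        raise ValueError("inputs must be equal-length and non-empty")
    resid = pred - act
    return float(np.mean(np.abs(resid))), float(np.sqrt(np.mean(resid**2)))


def residual_density(
    before: np.ndarray, after: np.ndarray, grid_size: int = 256
) -> dict:
    """Gaussian KDEs of two residual samples on a shared grid, with spread
    summaries.  ``after_narrower`` reports whether the post-condition sample
    has a smaller SD — a finding, not an assumption."""
    b = np.asarray(before, dtype=np.float64).ravel()
    a = np.asarray(after, dtype=np.float64).ravel()
    if b.size == 0 or a.size == 0:
        raise ValueError("both residual samples must be non-empty")
    lo = min(b.min(), a.min())
    hi = max(b.max(), a.max())
    pad = 0.2 * max(hi - lo, 1e-12)
    grid = np.linspace(lo - pad, hi + pad, grid_size)

    def _kde(x: np.ndarray) -> np.ndarray:
        if np.ptp(x) == 0:  # degenerate sample: spike approximated by narrow normal
            return sps.norm.pdf(grid, loc=x[0], scale=max(1e-6, 1e-3 * (pad or 1)))
        return sps.gaussian_kde(x)(grid)

    sd_b, sd_a = float(np.std(b, ddof=1 if b.size > 1 else 0)), float(
        np.std(a, ddof=1 if a.size > 1 else 0)
    )
    return {
        "grid": grid,
        "before_density": _kde(b),
        "after_density": _kde(a),
        "before_sd": sd_b,
        "after_sd": sd_a,
        "before_iqr": float(np.subtract(*np.percentile(b, [75, 25]))),
        "after_iqr": float(np.subtract(*np.percentile(a, [75, 25]))),
        "after_narrower": bool(sd_a < sd_b),
    }


def confidence_interval(
    mean: float, sd: float, n: int, level: float = 0.95
) -> tuple[float, float]:
    """Normal-approximation interval mean ± z·sd/√n at the given level."""
    if sd < 0:
        raise ValueError("sd must be >= 0")
    if n < 2:
        raise ValueError("n must be >= 2")
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    z = sps.norm.ppf(0.5 + level / 2.0)
    half = z * sd / np.sqrt(n)
    return float(mean - half), float(mean + half)


def cohens_d(
    mean1: float, sd1: float, mean2: float, sd2: float, method: str = "mean_sd"
) -> float:
    """Standardized mean difference (m2 − m1)/s.

    ``method='pooled'`` uses s = √((sd1² + sd2²)/2); ``method='mean_sd'``
    (default) uses the mean of the two SDs, s = (sd1 + sd2)/2.
    """
    if sd1 < 0 or sd2 < 0:
        raise ValueError("standard deviations must be >= 0")
    if method == "pooled":
        denom = np.sqrt((sd1**2 + sd2**2) / 2.0)
    elif method == "mean_sd":
        denom = (sd1 + sd2) / 2.0
    else:
        raise ValueError(f"unknown method {method!r}")
    if denom == 0:
        raise ValueError("both SDs are zero; effect size undefined")
    return float((mean2 - mean1) / denom)


def percent_change(before: float, after: float, ndigits: int | None = 2):
    """100·(after − before)/before; returns NaN when before is 0 (flagged in
    batch reports rather than raised)."""
    if before == 0:
        return float("nan")
    val = 100.0 * (after - before) / before
    return round(val, ndigits) if ndigits is not None else val


def augmentation_ab_report(
    metrics_a: dict[str, float],
    metrics_b: dict[str, float],
    *,
    sds: dict[str, tuple[float, float]] | None = None,
    n_runs: int | None = None,
    labels: tuple[str, str] = ("original", "augmented"),
) -> pd.DataFrame:
    """A/B comparison of two training conditions (e.g. original vs augmented
    data): per metric the two values, percent change, and optionally a 95% CI
    per condition and Cohen's d when per-metric SDs (and n) are supplied."""
    if set(metrics_a) != set(metrics_b):
        raise ValueError("metric keys differ between the two conditions")
    rows = []
    for key in metrics_a:
        a, b = metrics_a[key], metrics_b[key]
        row = {
            "metric": key,
            labels[0]: a,
            labels[1]: b,
            "percent_change": percent_change(a, b),
            "undefined_change": a == 0,
        }
        if sds is not None and key in sds:
            sd_a, sd_b = sds[key]
            if not (sd_a == 0 and sd_b == 0):
                row["cohens_d"] = round(cohens_d(a, sd_a, b, sd_b), 2)
            if n_runs is not None and n_runs >= 2:
                row[f"{labels[0]}_ci95"] = confidence_interval(a, sd_a, n_runs)
                row[f"{labels[1]}_ci95"] = confidence_interval(b, sd_b, n_runs)
        rows.append(row)
    return pd.DataFrame(rows)
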