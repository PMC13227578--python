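"""Attention-map extraction and spatial-alignment metrics.

Token attention is turned into a pixel saliency map by attention rollout
(multiplying head-averaged, identity-augmented, renormalized per-layer
attention matrices) and nearest-neighbour upsampling to image resolution.
Maps are scored against binary expert-style annotation masks with:

* CoG Shift — Euclidean distance between the map's intensity-weighted
  centroid and the mask centroid, in pixels;
* AFR — percentage of the thresholded attention area inside the mask;
* WRS — attention-mass-weighted Gaussian kernel of distance to the mask
  centroid, normalized to (0, 1];
* AED — percentage of total attention energy outside the mask;
* ODM — mean attention/mask IoU over a sequence of frames;

plus the standard IoU and Dice coefficients.
"""

from __future__ import annotations

import numpy as np
from matplotlib import colormaps

from . import model as M
from .model import ViTConfig

__all__ = [
    "extract_attention_map",
    "rollout",
    "mask_centroid",
    "map_centroid",
    "cog_shift",
    "afr",
    "threshold_attention",
    "wrs",
    "aed",
    "iou_dsc",
    "odm",
    "render_overlay",
    "attention_improvement_table",
    "evaluate_attention",
]


class DegenerateInputError(ValueError):
    """Raised when a metric is undefined (empty mask, zero-energy map)."""


# ---------------------------------------------------------------------------
# extraction


def rollout(attn_layers: list[np.ndarray]) -> np.ndarray:
    """Attention rollout over per-layer (heads, N, N) weight stacks.

    Each layer's head-averaged matrix gets an identity residual, is
    renormalized to row-stochastic form, and the matrices are multiplied from
    first to last layer.  An empty list yields the identity (uniform saliency
    after pooling).
    """
    r = None
    for a in attn_layers:
        a = np.asarray(a, dtype=np.float64)
        if a.ndim == 3:  # (heads, N, N)
            a = a.mean(0)
        n = a.shape[0]
        a_hat = a + np.eye(n)
        a_hat /= a_hat.sum(-1, keepdims=True)
        r = a_hat if r is None else a_hat @ r
    return r if r is not None else np.empty((0, 0))


def extract_attention_map(
    params: dict[str, np.ndarray], img: np.ndarray, config: ViTConfig
) -> np.ndarray:
    """Pixel-level saliency for one image, normalized to total energy 1.

    Runs the model, rolls out the per-layer attention, averages the rollout
    over query tokens (matching the mean pooling of the model head) to get a
    per-token importance, and upsamples the patch grid to H×W by
    nearest-neighbour replication.  A depth-0 (or attention-free) model
    yields the uniform map.
    """
    out = M.forward(params, img, config)
    rows, cols = config.grid
    n = rows * cols
    layers = [a[0] for a in out.attention_maps]  # strip batch axis
    if not layers:
        token_imp = np.full(n, 1.0 / n)
    else:
        r = rollout(layers)
        token_imp = r.mean(0)  # importance of each input token
    grid = token_imp.reshape(rows, cols)
    p = config.patch_size
    pixel_map = np.kron(grid, np.ones((p, p)))
    return pixel_map / pixel_map.sum()


# ---------------------------------------------------------------------------
# centroids and metrics


def _check_map(att: np.ndarray) -> np.ndarray:
    a = np.asarray(att, dtype=np.float64)
    if a.ndim != 2 or np.any(a < 0):
        raise ValueError("attention map must be a nonnegative 2-D grid")
    if a.sum() <= 0:
        raise DegenerateInputError("attention map has zero total energy")
    return a


def _check_mask(mask: np.ndarray) -> np.ndarray:
    m = np.asarray(mask).astype(bool)
    if m.ndim != 2:
        raise ValueError("mask must be 2-D")
    if not m.any():
        raise DegenerateInputError("annotation mask is empty")
    return m


def map_centroid(att: np.ndarray) -> tuple[float, float]:
    """Intensity-weighted centroid (row, col) of a nonnegative map."""
    a = _check_map(att)
    rr, cc = np.mgrid[0 : a.shape[0], 0 : a.shape[1]]
    total = a.sum()
    return float((a * rr).sum() / total), float((a * cc).sum() / total)


def mask_centroid(mask: np.ndarray) -> tuple[float, float]:
    """Unweighted centroid (row, col) of a non-empty binary mask."""
    m = _check_mask(mask)
    rr, cc = np.nonzero(m)
    return float(rr.mean()), float(cc.mean())


def cog_shift(att: np.ndarray, mask: np.ndarray) -> float:
    """Center-of-gravity shift: Euclidean distance in pixels between the
    attention centroid and the annotation centroid."""
    ar, ac = map_centroid(att)
    mr, mc = mask_centroid(mask)
    return float(np.hypot(ar - mr, ac - mc))


def threshold_attention(att: np.ndarray, area_quantile: float = 0.9) -> np.ndarray:
    """Binarize a map by keeping pixels above the given weight quantile
    (default: the top 10% of pixels by weight)."""
    a = _check_map(att)
    if not 0.0 <= area_quantile < 1.0:
        raise ValueError("area_quantile must be in [0, 1)")
    thr = np.quantile(a, area_quantile)
    binar = a > thr
    if not binar.any():  # ties at the threshold (e.g. uniform maps)
        binar = a >= thr
    return binar


def afr(att: np.ndarray, mask: np.ndarray, area_quantile: float = 0.9) -> float:
    """Attention Focus Ratio: percentage of the thresholded attention area
    that overlaps the annotated region."""
    m = _check_mask(mask)
    region = threshold_attention(att, area_quantile)
    if not region.any():
        raise DegenerateInputError("thresholding left an empty attention area")
    return float(100.0 * np.logical_and(region, m).sum() / region.sum())


def wrs(att: np.ndarray, mask: np.ndarray, sigma: float | None = None) -> float:
    """Weighted Relevance Score in (0, 1].

    Attention-mass-weighted mean of exp(−d²/(2σ²)) where d is the distance to
    the mask centroid and σ defaults to the mask's equivalent circle radius
    √(|R|/π), so a map fully concentrated on the centroid scores 1.
    """
    a = _check_map(att)
    m = _check_mask(mask)
    if a.shape != m.shape:
        raise ValueError("map and mask shapes differ")
    if sigma is None:
        sigma = float(np.sqrt(m.sum() / np.pi))
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    cr, cc = mask_centroid(m)
    rr, cc_grid = np.mgrid[0 : a.shape[0], 0 : a.shape[1]]
    d2 = (rr - cr) ** 2 + (cc_grid - cc) ** 2
    kernel = np.exp(-d2 / (2.0 * sigma**2))
    return float((a * kernel).sum() / a.sum())


def aed(att: np.ndarray, mask: np.ndarray) -> float:
    """Attention Energy Distribution: percent of total attention energy
    falling outside the annotated region (0 = perfectly focused)."""
    a = _check_map(att)
    m = np.asarray(mask).astype(bool)
    if a.shape != m.shape:
        raise ValueError("map and mask shapes differ")
    return float(100.0 * a[~m].sum() / a.sum())


def iou_dsc(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """IoU and Dice coefficients (percent) between two binary regions.

    Two empty regions agree perfectly and return (100, 100) by convention.
    """
    aa = np.asarray(a).astype(bool)
    bb = np.asarray(b).astype(bool)
    if aa.shape != bb.shape:
        raise ValueError("region shapes differ")
    inter = np.logical_and(aa, bb).sum()
    union = np.logical_or(aa, bb).sum()
    if union == 0:
        return 100.0, 100.0
    iou = 100.0 * inter / union
    dsc = 100.0 * 2.0 * inter / (aa.sum() + bb.sum())
    return float(iou), float(dsc)


def odm(
    att_sequence: list[np.ndarray],
    ann_sequence: list[np.ndarray],
    area_quantile: float = 0.9,
    *,
    frame_to_frame: bool = False,
) -> float:
    """Overlap Dynamics Metric: mean IoU (percent) between the thresholded
    attention map and its mask across a sequence of frames.

    With ``frame_to_frame=True`` the alternative reading is used: mean IoU of
    consecutive thresholded attention maps.
    """
    if len(att_sequence) == 0 or (
        not frame_to_frame and len(att_sequence) != len(ann_sequence)
    ):
        raise ValueError("sequences must be non-empty and equal-length")
    if frame_to_frame:
        bins = [threshold_attention(a, area_quantile) for a in att_sequence]
        if len(bins) < 2:
            return 100.0
        return float(
            np.mean([iou_dsc(bins[i], bins[i + 1])[0] for i in range(len(bins) - 1)])
        )
    ious = [
        iou_dsc(threshold_attention(a, area_quantile), m)[0]
        for a, m in zip(att_sequence, ann_sequence)
    ]
    return float(np.mean(ious))


# ---------------------------------------------------------------------------
# overlay and reporting


def render_overlay(
    img: np.ndarray, att: np.ndarray, alpha: float = 0.5, cmap: str = "jet"
) -> np.ndarray:
    """Alpha-blend a min-max-normalized attention map (blue→red colormap)
    onto a grayscale image; returns an (H, W, 3) float array in [0, 1]."""
    gray = np.asarray(img, dtype=np.float64)
    a = np.asarray(att, dtype=np.float64)
    if gray.shape != a.shape:
        raise ValueError("image and attention map shapes differ")
    span = a.max() - a.min()
    norm = (a - a.min()) / span if span > 0 else np.zeros_like(a)
    colors = colormaps[cmap](norm)[..., :3]
    base = np.repeat(np.clip(gray, 0, 1)[..., None], 3, axis=2)
    return (1 - alpha) * base + alpha * colors


def evaluate_attention(
    att: np.ndarray, mask: np.ndarray, area_quantile: float = 0.9
) -> dict[str, float]:
    """All alignment metrics for one (map, mask) pair."""
    region = threshold_attention(att, area_quantile)
    iou, dsc = iou_dsc(region, np.asarray(mask).astype(bool))
    return {
        "cog_shift": cog_shift(att, mask),
        "afr": afr(att, mask, area_quantile),
        "wrs": wrs(att, mask),
        "aed": aed(att, mask),
        "iou": iou,
        "dsc": dsc,
    }


def attention_improvement_table(before: dict, after: dict) -> "pd.DataFrame":
    """Percent improvement per metric per class between two evaluation
    snapshots: 100·(after − before)/before, rounded to 1 decimal.

    ``before``/``after`` map class name → {metric → value}; a zero "before"
    value yields NaN with an ``undefined`` flag rather than an error.
    """
    import pandas as pd

    if set(before) != set(after):
        raise ValueError("before/after class keys differ")
    rows = []
    for cls in before:
        if set(before[cls]) != set(after[cls]):
            raise ValueError(f"metric keys differ for class {cls!r}")
        for metric, b in before[cls].items():
            a = after[cls][metric]
            if b == 0:
                rows.append(
                    {"class": cls, "metric": metric, "before": b, "after": a,
                     "improvement_pct": np.nan, "undefined": True}
                )
            else:
                rows.append(
                    {"class": cls, "metric": metric, "before": b, "after": a,
                     "improvement_pct": round(100.0 * (a - b) / b, 1),
                     "undefined": False}
                )
    return pd.DataFrame(rows)
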