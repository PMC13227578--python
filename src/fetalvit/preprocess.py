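"""Image preprocessing: resizing, min-max normalization, and seeded augmentation.

All functions operate on 2-D ``float64`` NumPy arrays (row-major, origin at the
top-left, pixel centers at integer coordinates).  Raw images may live on any
intensity scale (e.g. [0, 255] for 8-bit PNG); :func:`normalize_image` maps them
to [0, 1], which is the range the augmentation operators and the transformer
expect.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage


class DegenerateImageError(ValueError):
    """Raised when an operation is undefined for the given image (e.g. constant)."""


@dataclass(frozen=True)
class AugmentSpec:
    """Parameters of the stochastic augmentation pipeline.

    Defaults are the example parameters of the augmentation protocol:
    rotation up to ±20°, horizontal flip with probability 0.5, zoom factor 1.1
    (cropped back to the input size), shift of (+10, −5) pixels, brightness
    ×1.2 and contrast ×1.5.  ``deterministic=True`` applies the rotation at
    the fixed angle ``rotation_deg`` and the flip whenever ``hflip_prob > 0.5``
    instead of sampling.
    """

    rotation_deg: float = 20.0
    hflip_prob: float = 0.5
    zoom_factor: float = 1.1
    shift_x: int = 10
    shift_y: int = -5
    brightness: float = 1.2
    contrast: float = 1.5
    seed: int = 0
    deterministic: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.hflip_prob <= 1.0:
            raise ValueError(f"hflip_prob must be in [0, 1], got {self.hflip_prob}")
        if self.zoom_factor <= 0:
            raise ValueError(f"zoom_factor must be > 0, got {self.zoom_factor}")
        if self.brightness <= 0 or self.contrast <= 0:
            raise ValueError("brightness and contrast factors must be positive")


def _as_image(img: np.ndarray) -> np.ndarray:
    arr = np.asarray(img, dtype=np.float64)
    if arr.ndim != 2 or arr.shape[0] < 1 or arr.shape[1] < 1:
        raise ValueError(f"expected a 2-D image, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError("image contains non-finite intensities")
    return arr


def resize_image(
    img: np.ndarray, target_h: int, target_w: int, *, order: int = 1
) -> np.ndarray:
    """Resample ``img`` to ``(target_h, target_w)``.

    Bilinear by default (``order=1``); ``order=0`` gives nearest-neighbour.
    Pixel centers are aligned so that resizing an image to its own shape is
    the identity, and borders are handled by reflection.
    """
    arr = _as_image(img)
    if target_h < 1 or target_w < 1:
        raise ValueError("target dimensions must be >= 1")
    h, w = arr.shape
    if (target_h, target_w) == (h, w):
        return arr.copy()
    # Center-aligned sampling grid: dst pixel i samples src at (i+0.5)*s - 0.5.
    rows = (np.arange(target_h) + 0.5) * (h / target_h) - 0.5
    cols = (np.arange(target_w) + 0.5) * (w / target_w) - 0.5
    rr, cc = np.meshgrid(rows, cols, indexing="ij")
    return ndimage.map_coordinates(
        arr, [rr, cc], order=order, mode="reflect", prefilter=False
    )


def normalize_image(img: np.ndarray) -> np.ndarray:
    """Min-max normalize to [0, 1]: (I − min I) / (max I − min I).

    Raises :class:`DegenerateImageError` for constant images, whose range is
    zero and for which the rescaling is undefined.
    """
    arr = _as_image(img)
    lo, hi = float(arr.min()), float(arr.max())
    if hi == lo:
        raise DegenerateImageError("cannot normalize a constant image (max == min)")
    return (arr - lo) / (hi - lo)


def _zoom(arr: np.ndarray, z: float) -> np.ndarray:
    """Zoom by factor ``z`` and return an image of the original shape.

    ``z > 1`` resamples onto a larger canvas (e.g. 256→282 for z=1.1) and
    center-crops back; ``z < 1`` shrinks and zero-pads symmetrically.
    """
    h, w = arr.shape
    zh, zw = max(1, round(h * z)), max(1, round(w * z))
    big = resize_image(arr, zh, zw)
    if zh >= h and zw >= w:
        r0, c0 = (zh - h) // 2, (zw - w) // 2
        return big[r0 : r0 + h, c0 : c0 + w]
    out = np.zeros((h, w), dtype=arr.dtype)
    r0, c0 = (h - zh) // 2, (w - zw) // 2
    out[r0 : r0 + zh, c0 : c0 + zw] = big
    return out


def adjust_brightness(arr: np.ndarray, beta: float) -> np.ndarray:
    """Scale intensities by ``beta`` and clip to [0, 1]."""
    return np.clip(arr * beta, 0.0, 1.0)


def adjust_contrast(arr: np.ndarray, gamma_c: float) -> np.ndarray:
    """Stretch intensities about the image mean by ``gamma_c``, clipped to [0, 1]."""
    m = arr.mean()
    return np.clip((arr - m) * gamma_c + m, 0.0, 1.0)


def augment_image(img: np.ndarray, spec: AugmentSpec) -> np.ndarray:
    """Apply the augmentation pipeline: rotation, horizontal flip, zoom,
    shift, brightness, contrast.

    The input must already be normalized to [0, 1].  Output has the same
    shape, lies in [0, 1], and is a deterministic function of ``spec``
    (including its seed).
    """
    arr = _as_image(img)
    if arr.min() < -1e-9 or arr.max() > 1 + 1e-9:
        raise ValueError("augment_image expects an image normalized to [0, 1]")
    rng = np.random.default_rng(spec.seed)

    if spec.deterministic:
        angle = spec.rotation_deg
        do_flip = spec.hflip_prob > 0.5
    else:
        angle = rng.uniform(-spec.rotation_deg, spec.rotation_deg)
        do_flip = rng.random() < spec.hflip_prob

    out = arr
    if angle != 0.0:
        out = ndimage.rotate(
            out, angle, reshape=False, order=1, mode="reflect", prefilter=False
        )
    if do_flip:
        out = out[:, ::-1]
    if spec.zoom_factor != 1.0:
        out = _zoom(out, spec.zoom_factor)
    if spec.shift_x or spec.shift_y:
        # +x shifts right (columns), +y shifts down (rows); vacated pixels are 0.
        out = ndimage.shift(
            out,
            (spec.shift_y, spec.shift_x),
            order=0,
            mode="constant",
            cval=0.0,
        )
    out = adjust_brightness(out, spec.brightness)
    out = adjust_contrast(out, spec.contrast)
    return np.clip(out, 0.0, 1.0)


def expand_dataset(
    images: list[np.ndarray],
    *,
    factor: int = 5,
    base_spec: AugmentSpec | None = None,
    seed: int = 0,
) -> list[np.ndarray]:
    """Expand a normalized image list by augmentation.

    Each source image contributes itself plus ``factor − 1`` augmented copies
    (so 500 images become 2500 at the default factor of 5), each drawn with an
    independent sub-seed.
    """
    if factor < 1:
        raise ValueError("factor must be >= 1")
    base = base_spec or AugmentSpec()
    rng = np.random.default_rng(seed)
    out: list[np.ndarray] = []
    for img in images:
        out.append(np.asarray(img, dtype=np.float64))
        for _ in range(factor - 1):
            sub = int(rng.integers(0, 2**31 - 1))
            spec = AugmentSpec(
                rotation_deg=base.rotation_deg,
                hflip_prob=base.hflip_prob,
                zoom_factor=base.zoom_factor,
                shift_x=base.shift_x,
                shift_y=base.shift_y,
                brightness=base.brightness,
                contrast=base.contrast,
                seed=sub,
                deterministic=False,
            )
            out.append(augment_image(img, spec))
    return out
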