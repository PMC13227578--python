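"""Synthetic ultrasound-style phantom generator.

Emulates a fetal-ultrasound dataset for which no public accession exists:
fan-shaped (sector) grayscale images with multiplicative Rayleigh speckle over
a smooth tissue texture, four health classes (healthy/mild/moderate/severe), a
continuous severity score in [0, 3], and exact per-image anomaly masks.
Non-healthy phantoms contain 1–3 bright elliptical lesions whose area and
contrast grow monotonically with severity, so classifiers and the severity
head have learnable signal and attention metrics have ground truth.

This is a first-order speckle approximation (multiplicative Rayleigh noise),
not a physical acoustics simulation, and makes no claim of anatomical realism.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "CLASS_NAMES",
    "SEVERITY_BANDS",
    "PhantomSpec",
    "Sample",
    "fan_mask",
    "rayleigh_speckle",
    "generate_phantom",
    "generate_samples",
    "generate_dataset",
    "plant_attention_target",
]

CLASS_NAMES = ("healthy", "mild", "moderate", "severe")
#: severity band per class, width ≈ 1 on a [0, 3] scale
SEVERITY_BANDS = {
    "healthy": (0.0, 0.5),
    "mild": (0.5, 1.5),
    "moderate": (1.5, 2.5),
    "severe": (2.5, 3.0),
}
_LESION_COUNT = {"healthy": 0, "mild": 1, "moderate": 2, "severe": 3}


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one phantom draw.

    ``severity=None`` draws uniformly from the class band; an explicit value
    must lie inside the band for its class.
    """

    height: int = 64
    width: int = 64
    class_label: str = "healthy"
    severity: float | None = None
    lesion_base_radius: float = 0.055  # fraction of min(H, W)
    lesion_contrast: float = 0.3  # added brightness per unit severity factor
    speckle_scale: float = 1.0  # multiplier on the Rayleigh scale
    texture_strength: float = 0.15  # amplitude of the smooth tissue field
    fan_angle_deg: float = 60.0  # full sector angle, apex at top-center
    seed: int = 0

    def __post_init__(self) -> None:
        if self.class_label not in CLASS_NAMES:
            raise ValueError(f"unknown class {self.class_label!r}")
        if self.severity is not None:
            lo, hi = SEVERITY_BANDS[self.class_label]
            if not lo <= self.severity <= hi:
                raise ValueError(
                    f"severity {self.severity} outside band {lo}–{hi}"
                    f" for class {self.class_label!r}"
                )
        if self.height < 8 or self.width < 8:
            raise ValueError("phantom must be at least 8×8")


@dataclass
class Sample:
    """One dataset record: image, labels, anomaly mask."""

    image: np.ndarray  # (H, W) in [0, 1]
    class_index: int
    class_name: str
    severity: float
    mask: np.ndarray  # (H, W) bool


def fan_mask(h: int, w: int, angle_deg: float = 60.0) -> np.ndarray:
    """Boolean sector mask: apex at top-center, opening downward."""
    rr, cc = np.mgrid[0:h, 0:w]
    dx = cc - (w - 1) / 2.0
    dy = rr.astype(float)
    theta = np.degrees(np.arctan2(dx, dy + 1e-9))
    radius = np.hypot(dx, dy)
    return (np.abs(theta) <= angle_deg / 2.0) & (radius <= 0.98 * h)


def rayleigh_speckle(
    shape: tuple[int, int], rng: np.random.Generator, scale: float = 1.0
) -> np.ndarray:
    """Multiplicative Rayleigh speckle field with unit mean (before ``scale``)."""
    sigma = np.sqrt(2.0 / np.pi)  # Rayleigh mean = sigma·√(π/2) = 1
    return scale * rng.rayleigh(sigma, size=shape)


def _ellipse(
    h: int, w: int, center: tuple[float, float], a: float, b: float, phi: float
) -> np.ndarray:
    rr, cc = np.mgrid[0:h, 0:w]
    dy = rr - center[0]
    dx = cc - center[1]
    u = dy * np.cos(phi) + dx * np.sin(phi)
    v = -dy * np.sin(phi) + dx * np.cos(phi)
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def generate_phantom(spec: PhantomSpec) -> Sample:
    """Draw one phantom; bit-identical for identical specs."""
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height, spec.width
    fan = fan_mask(h, w, spec.fan_angle_deg)

    lo, hi = SEVERITY_BANDS[spec.class_label]
    severity = (
        float(rng.uniform(lo, hi)) if spec.severity is None else float(spec.severity)
    )

    # smooth tissue texture
    base = np.full((h, w), 0.5)
    if spec.texture_strength > 0:
        field = ndimage.gaussian_filter(rng.normal(size=(h, w)), sigma=h / 10.0)
        amp = np.abs(field).max() or 1.0
        base = base + spec.texture_strength * field / amp

    # lesions: count fixed by class, size/contrast monotone in severity
    mask = np.zeros((h, w), dtype=bool)
    n_lesions = _LESION_COUNT[spec.class_label]
    size_factor = 0.6 + 0.45 * severity
    contrast = spec.lesion_contrast * (0.5 + 0.5 * severity)
    inside = np.argwhere(ndimage.binary_erosion(fan, iterations=4))
    for _ in range(n_lesions):
        center = inside[rng.integers(0, len(inside))].astype(float)
        r0 = spec.lesion_base_radius * min(h, w) * size_factor
        a = r0 * rng.uniform(0.85, 1.15)
        b = r0 * rng.uniform(0.85, 1.15)
        phi = rng.uniform(0, np.pi)
        mask |= _ellipse(h, w, (center[0], center[1]), a, b, phi)
    mask &= fan
    img = base + contrast * mask

    img = img * rayleigh_speckle((h, w), rng, spec.speckle_scale)
    img = np.where(fan, img, 0.0)
    # min-max normalize to [0, 1]
    span = img.max() - img.min()
    img = (img - img.min()) / (span if span > 0 else 1.0)

    return Sample(
        image=img,
        class_index=CLASS_NAMES.index(spec.class_label),
        class_name=spec.class_label,
        severity=severity,
        mask=mask,
    )


def generate_samples(
    n: int,
    class_proportions: dict[str, float] | None = None,
    seed: int = 0,
    **spec_kwargs,
) -> list[Sample]:
    """Draw ``n`` phantoms in memory with the requested class mix
    (default: balanced across the four classes)."""
    props = class_proportions or {c: 0.25 for c in CLASS_NAMES}
    if abs(sum(props.values()) - 1.0) > 1e-9:
        raise ValueError("class proportions must sum to 1")
    counts = {c: int(round(n * p)) for c, p in props.items()}
    # fix rounding drift on the largest class
    drift = n - sum(counts.values())
    counts[max(counts, key=counts.get)] += drift

    rng = np.random.default_rng(seed)
    samples: list[Sample] = []
    for cls in CLASS_NAMES:
        for _ in range(counts.get(cls, 0)):
            sub = int(rng.integers(0, 2**31 - 1))
            samples.append(
                generate_phantom(
                    PhantomSpec(class_label=cls, seed=sub, **spec_kwargs)
                )
            )
    perm = np.random.default_rng(seed + 1).permutation(len(samples))
    return [samples[i] for i in perm]


def generate_dataset(
    out_dir: str | Path,
    n: int = 500,
    class_proportions: dict[str, float] | None = None,
    seed: int = 0,
    split_fractions: tuple[float, float, float] = (0.7, 0.15, 0.15),
    **spec_kwargs,
) -> pd.DataFrame:
    """Write ``n`` phantoms as 8-bit PNGs with masks, a manifest CSV
    (path, class, severity, mask_path, split) with stratified train/val/test
    tags, and a JSON sidecar echoing the generation parameters."""
    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "masks").mkdir(parents=True, exist_ok=True)
    samples = generate_samples(n, class_proportions, seed, **spec_kwargs)

    # stratified split tags
    split_of: dict[int, str] = {}
    rng = np.random.default_rng(seed + 2)
    for ci in range(len(CLASS_NAMES)):
        idx = [i for i, s in enumerate(samples) if s.class_index == ci]
        idx = list(rng.permutation(idx))
        n_tr = int(round(split_fractions[0] * len(idx)))
        n_va = int(round(split_fractions[1] * len(idx)))
        for j, i in enumerate(idx):
            split_of[i] = "train" if j < n_tr else ("val" if j < n_tr + n_va else "test")

    records = []
    for i, s in enumerate(samples):
        img_path = out / "images" / f"phantom_{i:05d}.png"
        mask_path = out / "masks" / f"phantom_{i:05d}_mask.png"
        iio.imwrite(img_path, np.round(s.image * 255).astype(np.uint8))
        iio.imwrite(mask_path, (s.mask * 255).astype(np.uint8))
        records.append(
            {
                "path": str(img_path.relative_to(out)),
                "class": s.class_index,
                "severity": s.severity,
                "mask_path": str(mask_path.relative_to(out)),
                "split": split_of[i],
            }
        )
    manifest = pd.DataFrame(records)
    manifest.to_csv(out / "manifest.csv", index=False)
    sidecar = {
        "n": n,
        "seed": seed,
        "class_proportions": class_proportions or {c: 0.25 for c in CLASS_NAMES},
        "split_fractions": list(split_fractions),
        "spec_defaults": asdict(PhantomSpec()),
        "spec_overrides": spec_kwargs,
    }
    (out / "generation.json").write_text(json.dumps(sidecar, indent=2))
    return manifest


def plant_attention_target(
    mask: np.ndarray, sharpness: float
) -> np.ndarray:
    """Attention map with a known analytic energy split for metric tests.

    map ∝ uniform + sharpness · mask/|mask|, normalized to total energy 1, so
    the energy inside the mask is (|R|/(H·W) + s)/(1 + s): sharpness 0 gives
    the uniform map, sharpness → ∞ drives AED → 0 and AFR → 100.  An empty
    mask yields the uniform map.
    """
    if sharpness < 0:
        raise ValueError("sharpness must be >= 0")
    m = np.asarray(mask).astype(bool)
    h, w = m.shape
    att = np.full((h, w), 1.0 / (h * w))
    if m.any() and sharpness > 0:
        att = att + sharpness * m / m.sum()
    return att / att.sum()
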