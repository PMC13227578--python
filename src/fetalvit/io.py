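"""Dataset manifests, grayscale image files, and model checkpoints."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .model import ViTConfig

__all__ = [
    "ManifestError",
    "SampleStub",
    "read_image",
    "write_image",
    "read_manifest",
    "write_manifest",
    "load_split",
    "save_checkpoint",
    "load_checkpoint",
    "provenance_record",
]

MANIFEST_COLUMNS = ("path", "class", "severity", "mask_path", "split")


class ManifestError(IOError):
    """Malformed manifest; the message carries the row number when known."""


@dataclass
class SampleStub:
    """One manifest row; the image is loaded on demand."""

    path: str
    class_index: int
    severity: float
    mask_path: str | None
    split: str


def read_image(path: str | Path) -> np.ndarray:
    """Read an 8- or 16-bit grayscale PNG/TIFF as float64 in [0, 1]."""
    arr = np.asarray(iio.imread(path))
    if arr.ndim == 3:  # collapse accidental channel axis
        arr = arr.mean(axis=2)
    if arr.dtype == np.uint8:
        return arr.astype(np.float64) / 255.0
    if arr.dtype == np.uint16:
        return arr.astype(np.float64) / 65535.0
    return arr.astype(np.float64)


def write_image(path: str | Path, img: np.ndarray, *, bits: int = 8) -> None:
    """Write a [0, 1] float image as an 8- or 16-bit grayscale PNG/TIFF."""
    arr = np.clip(np.asarray(img, dtype=np.float64), 0.0, 1.0)
    if bits == 8:
        iio.imwrite(path, np.round(arr * 255).astype(np.uint8))
    elif bits == 16:
        iio.imwrite(path, np.round(arr * 65535).astype(np.uint16))
    else:
        raise ValueError("bits must be 8 or 16")


def read_manifest(path: str | Path) -> list[SampleStub]:
    """Parse a manifest CSV (path, class, severity, mask_path, split).

    Class indices are 0-based; a missing mask path is allowed (attention
    metrics are then skipped for that sample).
    """
    p = Path(path)
    try:
        df = pd.read_csv(p)
    except Exception as exc:  # noqa: BLE001 - rewrap with context
        raise ManifestError(f"cannot read manifest {p}: {exc}") from exc
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns and c != "split"]
    if missing:
        raise ManifestError(f"manifest {p} missing column(s): {', '.join(missing)}")
    stubs = []
    for i, row in df.iterrows():
        try:
            mask = row.get("mask_path")
            mask = None if (mask is None or (isinstance(mask, float) and np.isnan(mask))) else str(mask)
            stubs.append(
                SampleStub(
                    path=str(row["path"]),
                    class_index=int(row["class"]),
                    severity=float(row["severity"]),
                    mask_path=mask,
                    split=str(row["split"]) if "split" in df.columns else "train",
                )
            )
        except (TypeError, ValueError) as exc:
            raise ManifestError(f"manifest {p} row {i}: {exc}") from exc
    return stubs


def write_manifest(stubs: list[SampleStub], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "path": s.path,
                "class": s.class_index,
                "severity": s.severity,
                "mask_path": s.mask_path,
                "split": s.split,
            }
            for s in stubs
        ]
    ).to_csv(path, index=False)


def load_split(
    stubs: list[SampleStub], root: str | Path, split: str | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[SampleStub]]:
    """Load the images of one split as (images, classes, severities, stubs)."""
    root = Path(root)
    chosen = [s for s in stubs if split is None or s.split == split]
    if not chosen:
        raise ManifestError(f"no samples with split {split!r}")
    imgs = []
    for s in chosen:
        fp = root / s.path
        if not fp.exists():
            raise ManifestError(f"image path does not exist: {fp}")
        imgs.append(read_image(fp))
    return (
        np.stack(imgs),
        np.array([s.class_index for s in chosen]),
        np.array([s.severity for s in chosen]),
        chosen,
    )


# ---------------------------------------------------------------------------
# checkpoints


def save_checkpoint(
    params: dict[str, np.ndarray], config: ViTConfig, path: str | Path
) -> None:
    """Named-array archive (.npz) plus a JSON sidecar with the architecture;
    the round trip is bit-exact.  No pickled executable state is stored."""
    p = Path(path)
    np.savez(p, **{k: np.asarray(v) for k, v in params.items()})
    sidecar = {
        "image_size": list(config.image_size),
        "patch_size": config.patch_size,
        "embed_dim": config.embed_dim,
        "depth": config.depth,
        "heads": config.heads,
        "num_classes": config.num_classes,
        "mlp_ratio": config.mlp_ratio,
        "use_positional": config.use_positional,
        "positional": config.positional,
        "use_self_attention": config.use_self_attention,
        "use_cross_attention": config.use_cross_attention,
        "cross_source": config.cross_source,
        "use_severity_head": config.use_severity_head,
    }
    p.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_checkpoint(path: str | Path) -> tuple[dict[str, np.ndarray], ViTConfig]:
    p = Path(path)
    with np.load(p) as npz:
        params = {k: npz[k].copy() for k in npz.files}
    side = json.loads(p.with_suffix(".json").read_text())
    side["image_size"] = tuple(side["image_size"])
    return params, ViTConfig(**side)


def provenance_record(config_payload: dict, seed: int) -> dict:
    """Reproducibility stamp: canonical config hash, seed, library versions."""
    canonical = json.dumps(config_payload, sort_keys=True, default=str)
    from . import __version__

    return {
        "config_sha256": hashlib.sha256(canonical.encode()).hexdigest(),
        "seed": seed,
        "versions": {"fetalvit": __version__, "numpy": np.__version__},
    }
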