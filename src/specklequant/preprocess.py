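"""Image preprocessing chain: grayscale -> unit normalization -> block-mean
downsampling (1280x1024 -> 320x256 at the default factor 4)."""

from __future__ import annotations

import numpy as np

__all__ = ["to_grayscale", "normalize_unit", "downsample", "preprocess_image"]


def to_grayscale(img: np.ndarray) -> np.ndarray:
    """Reduce a raster image to a single channel.

    Three-channel inputs are reduced by the unweighted channel mean;
    single-channel inputs pass through unchanged.
    """
    img = np.asarray(img)
    if img.ndim == 2:
        return img
    if img.ndim == 3 and img.shape[2] in (1, 3):
        if img.shape[2] == 1:
            return img[:, :, 0]
        return img.mean(axis=2)
    raise ValueError(f"unsupported image shape {img.shape}")


def normalize_unit(
    img: np.ndarray, mode: str = "fixed", full_scale: float = 65535.0
) -> np.ndarray:
    """Map intensities to [0, 1].

    ``fixed`` (default) divides by the sensor full scale, preserving
    relative brightness between frames; ``minmax`` stretches each frame to
    its own range and raises on constant images.
    """
    img = np.asarray(img, dtype=float)
    if img.size == 0:
        raise ValueError("empty image")
    if mode == "fixed":
        if full_scale <= 0:
            raise ValueError("full_scale must be positive")
        return img / full_scale
    if mode == "minmax":
        lo, hi = float(img.min()), float(img.max())
        if hi == lo:
            raise ValueError("min-max normalization undefined for constant image")
        return (img - lo) / (hi - lo)
    raise ValueError(f"unknown normalization mode {mode!r}")


def downsample(img: np.ndarray, factor: int = 4) -> np.ndarray:
    """Non-overlapping ``factor x factor`` block means.

    Preserves the global mean exactly; dimensions must divide evenly (no
    implicit padding).
    """
    img = np.asarray(img, dtype=float)
    if factor < 1:
        raise ValueError("factor must be >= 1")
    if factor == 1:
        return img
    h, w = img.shape
    if h % factor or w % factor:
        raise ValueError(
            f"image shape {img.shape} not divisible by factor {factor}"
        )
    return img.reshape(h // factor, factor, w // factor, factor).mean(axis=(1, 3))


def preprocess_image(
    img: np.ndarray,
    factor: int = 4,
    norm: str = "fixed",
    full_scale: float = 65535.0,
) -> np.ndarray:
    """Full chain: grayscale -> normalize to [0,1] -> block-mean downsample."""
    return downsample(normalize_unit(to_grayscale(img), norm, full_scale), factor)
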