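"""Mask construction and per-slice background subtraction.

The analysis mask is built from the Z-projection of the spectral stack:
the projection is rescaled to the 8-bit range and thresholded, so the
subsequent per-pixel analysis is restricted to areas positive for
fluorescence. The complement of the mask is treated as the dark area
from which a scalar background is estimated for every spectral slice
and subtracted (with clipping at zero) inside the mask.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .spectral_io import SpectralStack

__all__ = [
    "Mask",
    "BackgroundEstimate",
    "z_project",
    "to_8bit_scale",
    "compute_mask",
    "estimate_background",
    "subtract_background",
]


@dataclass
class Mask:
    """Boolean per-pixel inclusion map plus the 8-bit threshold that made it."""

    include: np.ndarray
    threshold_8bit: int

    def __post_init__(self) -> None:
        self.include = np.asarray(self.include, dtype=bool)
        if self.include.ndim != 2:
            raise ValueError("mask must be 2-D")
        if not (0 <= self.threshold_8bit <= 255):
            raise ValueError(
                f"threshold must be within [0, 255], got {self.threshold_8bit}"
            )

    @property
    def n_included(self) -> int:
        return int(self.include.sum())


@dataclass
class BackgroundEstimate:
    """Scalar background intensity per spectral slice (detector units)."""

    per_slice: np.ndarray

    def __post_init__(self) -> None:
        self.per_slice = np.asarray(self.per_slice, dtype=float)
        if self.per_slice.ndim != 1:
            raise ValueError("per_slice must be 1-D")
        if not np.all(np.isfinite(self.per_slice)):
            raise ValueError("background estimates must be finite")
        if np.any(self.per_slice < 0):
            raise ValueError("background estimates must be >= 0")


def z_project(stack: SpectralStack) -> np.ndarray:
    """Pixelwise sum of the stack over the channel axis (rows x cols)."""
    return stack.data.sum(axis=2)


def to_8bit_scale(image: np.ndarray) -> np.ndarray:
    """Linear min->0, max->255 rescale, rounded to nearest integer.

    A constant image maps to all zeros by convention (degenerate range;
    with the strict ``>`` mask rule this is fail-safe: nothing passes a
    positive threshold).
    """
    image = np.asarray(image, dtype=float)
    if not np.all(np.isfinite(image)):
        raise ValueError("image must be finite")
    lo, hi = image.min(), image.max()
    if hi == lo:
        return np.zeros(image.shape, dtype=np.uint8)
    scaled = (image - lo) / (hi - lo) * 255.0
    return np.rint(scaled).astype(np.uint8)


def compute_mask(projection_8bit: np.ndarray, threshold: int) -> Mask:
    """Threshold an 8-bit projection: include pixels strictly above it."""
    if not (0 <= threshold <= 255):
        raise ValueError(f"threshold must be within [0, 255], got {threshold}")
    projection_8bit = np.asarray(projection_8bit)
    return Mask(include=projection_8bit > threshold, threshold_8bit=int(threshold))


def estimate_background(
    stack: SpectralStack, mask: Mask, statistic: str = "mean"
) -> BackgroundEstimate:
    """Per-slice background from the dark (mask-excluded) pixels.

    ``statistic`` is ``"mean"`` (default) or ``"median"`` for
    heavy-tailed backgrounds.
    """
    if mask.include.shape != stack.data.shape[:2]:
        raise ValueError(
            f"mask shape {mask.include.shape} does not match stack "
            f"spatial shape {stack.data.shape[:2]}"
        )
    dark = ~mask.include
    if not dark.any():
        raise ValueError(
            "no dark area available; disable background subtraction or "
            "lower threshold"
        )
    dark_spectra = stack.data[dark]  # (n_dark, n_channels)
    if statistic == "mean":
        per_slice = dark_spectra.mean(axis=0)
    elif statistic == "median":
        per_slice = np.median(dark_spectra, axis=0)
    else:
        raise ValueError(f"unknown background statistic {statistic!r}")
    return BackgroundEstimate(per_slice=per_slice)


def subtract_background(
    stack: SpectralStack, bg: BackgroundEstimate, mask: Mask
) -> SpectralStack:
    """Subtract the per-slice background inside the mask, clipping at zero.

    Mask-excluded pixels are returned bitwise unchanged; a new stack is
    returned, the input is not modified.
    """
    if bg.per_slice.size != stack.axis.n_channels:
        raise ValueError(
            f"background has {bg.per_slice.size} slices but stack has "
            f"{stack.axis.n_channels} channels"
        )
    if mask.include.shape != stack.data.shape[:2]:
        raise ValueError(
            f"mask shape {mask.include.shape} does not match stack "
            f"spatial shape {stack.data.shape[:2]}"
        )
    data = stack.data.copy()
    inside = mask.include
    data[inside] = np.clip(
        data[inside] - bg.per_slice[np.newaxis, :], 0.0, None
    )
    return SpectralStack(data=data, axis=stack.axis, source=stack.source)
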