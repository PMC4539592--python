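"""I/O for spectral (lambda) image stacks and for GP-analysis outputs.

A spectral stack is a 3-D array of detector intensities indexed
``(row, col, channel)`` whose channel axis maps to emission wavelength
through a uniform :class:`WavelengthAxis` (e.g. 32 channels of 8.9 nm
starting at 415 nm, covering 415-695 nm). Stacks travel as multi-page
grayscale TIFF, one page per channel in ascending wavelength order; the
axis comes from explicit configuration or from metadata embedded in the
file. Analysis products (GP map, mask, per-pixel R², histogram) are
written back as single-page TIFFs, a colormapped PNG rendering, and CSV
tables.
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd
import tifffile

if TYPE_CHECKING:  # pragma: no cover - import cycle guard, typing only
    from .gp import GPMap

__all__ = [
    "WavelengthAxis",
    "SpectralStack",
    "SensitivityCorrection",
    "read_spectral_stack",
    "write_spectral_stack",
    "apply_sensitivity_correction",
    "write_gp_outputs",
    "GP_COLORMAP",
]

#: Diverging colormap used for the 8-bit LUT rendering of GP maps over
#: [-1, 1] (blue = ordered / high GP ... red = disordered / low GP when
#: reversed; we map -1 -> blue end, +1 -> red end of matplotlib's RdYlBu_r).
GP_COLORMAP = "RdYlBu_r"

_DESCRIPTION_KEY = "spectralgp"


@dataclass(frozen=True)
class WavelengthAxis:
    """Uniform channel -> wavelength mapping for a spectral detector.

    Parameters
    ----------
    start_nm:
        Wavelength (nm) of the lower edge of the first detection channel.
    width_nm:
        Width (nm) of every channel.
    n_channels:
        Number of channels; at least 3 (a 3-4 parameter spectral model
        needs at least as many samples).

    The center of channel ``k`` is ``start_nm + width_nm * (k + 1/2)``.
    """

    start_nm: float
    width_nm: float
    n_channels: int

    def __post_init__(self) -> None:
        if not np.isfinite(self.start_nm):
            raise ValueError("start_nm must be finite")
        if not (self.width_nm > 0):
            raise ValueError(f"width_nm must be positive, got {self.width_nm}")
        if int(self.n_channels) != self.n_channels or self.n_channels < 3:
            raise ValueError(
                f"n_channels must be an integer >= 3, got {self.n_channels}"
            )

    @property
    def centers_nm(self) -> np.ndarray:
        """Channel-center wavelengths in nm, strictly increasing."""
        k = np.arange(self.n_channels, dtype=float)
        return self.start_nm + self.width_nm * (k + 0.5)

    @property
    def end_nm(self) -> float:
        """Upper edge of the last channel (nm)."""
        return self.start_nm + self.width_nm * self.n_channels

    def contains(self, wavelength_nm: float) -> bool:
        """Whether a wavelength lies within one channel width of the grid."""
        centers = self.centers_nm
        return (
            centers[0] - self.width_nm
            <= wavelength_nm
            <= centers[-1] + self.width_nm
        )

    def to_dict(self) -> dict:
        return {
            "start_nm": float(self.start_nm),
            "width_nm": float(self.width_nm),
            "n_channels": int(self.n_channels),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "WavelengthAxis":
        return cls(
            start_nm=float(d["start_nm"]),
            width_nm=float(d["width_nm"]),
            n_channels=int(d["n_channels"]),
        )

    @classmethod
    def from_string(cls, spec: str) -> "WavelengthAxis":
        """Parse a compact ``start:width:count`` axis spec, e.g. ``415:8.9:32``."""
        parts = spec.split(":")
        if len(parts) != 3:
            raise ValueError(
                f"axis spec must be 'start_nm:width_nm:n_channels', got {spec!r}"
            )
        return cls(float(parts[0]), float(parts[1]), int(parts[2]))


@dataclass
class SpectralStack:
    """Per-pixel emission spectra: intensities indexed (row, col, channel).

    Intensities are nonnegative detector units; the channel axis is bound
    to a :class:`WavelengthAxis`. ``source`` is free-text provenance (file
    path or ``"synthetic"``).
    """

    data: np.ndarray
    axis: WavelengthAxis
    source: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(
                f"stack data must be 3-D (row, col, channel), got ndim={self.data.ndim}"
            )
        if self.data.shape[2] != self.axis.n_channels:
            raise ValueError(
                f"stack has {self.data.shape[2]} channels but axis declares "
                f"{self.axis.n_channels}"
            )
        if np.any(self.data < 0):
            raise ValueError("stack intensities must be nonnegative")

    @property
    def shape(self) -> tuple:
        return self.data.shape

    @property
    def n_rows(self) -> int:
        return self.data.shape[0]

    @property
    def n_cols(self) -> int:
        return self.data.shape[1]


@dataclass(frozen=True)
class SensitivityCorrection:
    """Per-channel positive multipliers compensating detector sensitivity."""

    factors: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "factors", np.asarray(self.factors, dtype=float)
        )
        if self.factors.ndim != 1:
            raise ValueError("correction factors must be a 1-D sequence")
        if not np.all(self.factors > 0):
            raise ValueError("all sensitivity-correction factors must be > 0")

    @classmethod
    def identity(cls, n_channels: int) -> "SensitivityCorrection":
        return cls(np.ones(n_channels))


def _axis_from_metadata(tif: tifffile.TiffFile, path: Path) -> WavelengthAxis:
    """Recover a wavelength axis from a TIFF's own metadata.

    Two carriers are understood: a JSON payload under the ``spectralgp``
    key in the first page's ImageDescription (written by
    :func:`write_spectral_stack`), and OME-XML ``EmissionWavelength``
    channel attributes on a uniform grid.
    """
    desc = tif.pages[0].description or ""
    try:
        payload = json.loads(desc)
    except (json.JSONDecodeError, TypeError):
        payload = None
    if isinstance(payload, dict) and _DESCRIPTION_KEY in payload:
        return WavelengthAxis.from_dict(payload[_DESCRIPTION_KEY]["axis"])

    ome = tif.ome_metadata
    if ome:
        waves = [
            float(m)
            for m in re.findall(r'EmissionWavelength="([0-9.eE+-]+)"', ome)
        ]
        if len(waves) >= 3:
            centers = np.asarray(waves, float)
            spacing = np.diff(centers)
            if np.all(spacing > 0) and np.allclose(
                spacing, spacing[0], atol=1e-6
            ):
                width = float(spacing[0])
                return WavelengthAxis(
                    start_nm=float(centers[0] - width / 2),
                    width_nm=width,
                    n_channels=len(centers),
                )
    raise ValueError(
        f"{path}: no usable wavelength metadata found; pass an explicit "
        "WavelengthAxis (start_nm, width_nm, n_channels) instead of "
        "'from-metadata'"
    )


def read_spectral_stack(
    path, axis_spec: WavelengthAxis | str = "from-metadata"
) -> SpectralStack:
    """Read a multi-page TIFF / OME-TIFF as a spectral stack.

    Pages are interpreted as spectral channels in ascending wavelength
    order. Integer pixel types are promoted to float without rescaling.
    Small negative values (detector offsets) are clipped to zero with a
    warning. ``axis_spec`` is either an explicit :class:`WavelengthAxis`
    (which always wins and must match the page count) or the string
    ``"from-metadata"``.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        arr = tif.asarray()
        if axis_spec == "from-metadata":
            axis = _axis_from_metadata(tif, path)
        elif isinstance(axis_spec, WavelengthAxis):
            axis = axis_spec
        else:
            raise TypeError(
                "axis_spec must be a WavelengthAxis or the string 'from-metadata'"
            )

    if arr.ndim == 2:
        arr = arr[np.newaxis, ...]
    if arr.ndim != 3:
        raise ValueError(
            f"{path}: expected a stack of 2-D grayscale pages, got shape {arr.shape}"
        )
    n_pages = arr.shape[0]
    if n_pages != axis.n_channels:
        raise ValueError(
            f"{path}: file has {n_pages} pages but the wavelength axis "
            f"declares {axis.n_channels} channels"
        )
    data = np.moveaxis(arr, 0, -1).astype(float)
    if np.any(data < 0):
        warnings.warn(
            f"{path}: negative intensities clipped to 0 on load",
            stacklevel=2,
        )
        data = np.clip(data, 0.0, None)
    return SpectralStack(data=data, axis=axis, source=str(path))


def write_spectral_stack(stack: SpectralStack, path) -> Path:
    """Write a stack as multi-page TIFF with the axis embedded as JSON.

    The written file round-trips losslessly through
    :func:`read_spectral_stack` (float64 pages, one per channel).
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pages = np.moveaxis(stack.data, -1, 0)
    description = json.dumps(
        {_DESCRIPTION_KEY: {"axis": stack.axis.to_dict(), "source": stack.source}}
    )
    tifffile.imwrite(path, pages, description=description, metadata=None)
    return path


def apply_sensitivity_correction(
    stack: SpectralStack, corr: SensitivityCorrection
) -> SpectralStack:
    """Multiply each channel slice by its sensitivity factor.

    The identity correction (all ones) returns values equal to the input;
    any uniform correction leaves downstream GP values unchanged because
    GP is a normalized intensity ratio.
    """
    if corr.factors.size != stack.axis.n_channels:
        raise ValueError(
            f"correction has {corr.factors.size} factors but stack has "
            f"{stack.axis.n_channels} channels"
        )
    return SpectralStack(
        data=stack.data * corr.factors[np.newaxis, np.newaxis, :],
        axis=stack.axis,
        source=stack.source,
    )


def write_gp_outputs(gpmap: "GPMap", out_dir, bin_width: float = 0.02) -> dict:
    """Write the standard file set for a finalized GP map.

    Products (returned as a name -> path dict):

    - ``gp.tif`` — 32-bit float GP map; excluded pixels are NaN (0 is a
      legal GP value and is never used as a sentinel).
    - ``gp_lut.png`` — 8-bit rendering with the documented diverging
      colormap (:data:`GP_COLORMAP`) over [-1, 1]; excluded pixels black.
    - ``mask.tif`` — 8-bit mask, 255 inside / 0 outside.
    - ``r2.tif`` — 32-bit float per-pixel R² (fitting methods only).
    - ``histogram.csv`` — columns bin_left, bin_right, count.
    - ``summary.csv`` — mean, sd, median, median_positive,
      median_negative, n_pixels, n_fit_failures.
    """
    from .gp import gp_histogram  # deferred: gp imports this module's types

    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    gp32 = gpmap.gp.astype(np.float32)
    written["gp"] = out_dir / "gp.tif"
    tifffile.imwrite(written["gp"], gp32, metadata=None)

    cmap = matplotlib.colormaps[GP_COLORMAP].copy()
    cmap.set_bad("black")
    written["gp_lut"] = out_dir / "gp_lut.png"
    plt.imsave(written["gp_lut"], gpmap.gp, cmap=cmap, vmin=-1.0, vmax=1.0)

    mask8 = np.where(gpmap.mask.include, 255, 0).astype(np.uint8)
    written["mask"] = out_dir / "mask.tif"
    tifffile.imwrite(written["mask"], mask8, metadata=None)

    if gpmap.method != "direct":
        written["r2"] = out_dir / "r2.tif"
        tifffile.imwrite(
            written["r2"], gpmap.r2.astype(np.float32), metadata=None
        )

    hist = gp_histogram(gpmap, bin_width=bin_width)
    hist_df = pd.DataFrame(
        {
            "bin_left": hist.bin_edges[:-1],
            "bin_right": hist.bin_edges[1:],
            "count": hist.counts,
        }
    )
    if hist.n_pixels == 0:  # nothing to count: header-only CSV
        hist_df = hist_df.iloc[0:0]
    written["histogram"] = out_dir / "histogram.csv"
    hist_df.to_csv(written["histogram"], index=False)

    summary_df = pd.DataFrame(
        [
            {
                "mean": hist.mean,
                "sd": hist.sd,
                "median": hist.median,
                "median_positive": hist.median_positive,
                "median_negative": hist.median_negative,
                "n_pixels": hist.n_pixels,
                "n_fit_failures": gpmap.n_fit_failures,
            }
        ]
    )
    written["summary"] = out_dir / "summary.csv"
    summary_df.to_csv(written["summary"], index=False)
    return written
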