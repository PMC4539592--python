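"""Generalized polarization (GP) maps from spectral stacks.

GP quantifies the blue/red balance of a polarity-sensitive membrane
probe's emission:

    GP = (I_B - I_R) / (I_B + I_R)

where I_B and I_R are the intensities at the blue-shifted (lambda_Lo,
ordered-phase reference) and red-shifted (lambda_Ld, disordered-phase
reference) readout wavelengths. GP lies in [-1, 1]; higher values mean
tighter lipid packing. I_B and I_R are obtained either by direct
sampling of the spectral channel nearest each readout wavelength, or by
fitting the whole per-pixel emission spectrum (Gaussian or Gamma
Variate) and evaluating the fitted curve — which de-noises the map and
reads the curve at the exact wavelengths rather than channel centers.

Following the original plug-in convention, I_B and I_R are divided by
255 before the ratio; this is mathematically a no-op for GP and is kept
for parity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .config import METHODS, AnalysisConfig
from .fitting import evaluate_fit, fit_spectrum
from .preprocess import (
    Mask,
    compute_mask,
    estimate_background,
    subtract_background,
    to_8bit_scale,
    z_project,
)
from .spectral_io import (
    SpectralStack,
    WavelengthAxis,
    apply_sensitivity_correction,
)

__all__ = [
    "ProbePreset",
    "C_LAURDAN",
    "DI4_ANEPPDHQ",
    "PRESETS",
    "GPMap",
    "GPHistogram",
    "MethodComparison",
    "nearest_channel",
    "direct_sample_intensities",
    "gp_value",
    "compute_gp_map",
    "gp_histogram",
    "compare_methods",
]


@dataclass(frozen=True)
class ProbePreset:
    """Readout wavelengths of a polarity-sensitive probe.

    ``lambda_lo_nm`` is the blue-shifted emission maximum in a reference
    liquid-ordered membrane (I_B is read here); ``lambda_ld_nm`` the
    red-shifted maximum in a liquid-disordered reference (I_R).
    """

    name: str
    lambda_lo_nm: float
    lambda_ld_nm: float

    def __post_init__(self) -> None:
        if self.lambda_lo_nm == self.lambda_ld_nm:
            raise ValueError("lambda_lo_nm and lambda_ld_nm must differ")


#: C-Laurdan: blue readout 440 nm, red readout 490 nm.
C_LAURDAN = ProbePreset("c-laurdan", lambda_lo_nm=440.0, lambda_ld_nm=490.0)
#: Di-4-ANEPPDHQ: blue readout 565 nm, red readout 605 nm.
DI4_ANEPPDHQ = ProbePreset("di-4-aneppdhq", lambda_lo_nm=565.0, lambda_ld_nm=605.0)

PRESETS = {p.name: p for p in (C_LAURDAN, DI4_ANEPPDHQ)}


@dataclass
class GPMap:
    """Per-pixel GP values with provenance.

    ``gp`` is NaN wherever the mask excludes the pixel, the fit failed,
    or R^2 fell below the tolerance; finite values lie in [-1, 1].
    ``r2`` is all-NaN for the direct method.
    """

    gp: np.ndarray
    mask: Mask
    r2: np.ndarray
    method: str
    preset: ProbePreset
    n_fit_failures: int = 0

    @property
    def finite_values(self) -> np.ndarray:
        return self.gp[np.isfinite(self.gp)]


@dataclass
class GPHistogram:
    """Histogram plus summary statistics of a GP map's finite pixels.

    ``median_positive``/``median_negative`` are the medians of the
    strictly positive / strictly negative GP sub-populations (the
    ordered and disordered phases of a two-phase map), NaN when the
    subset is empty.
    """

    bin_edges: np.ndarray
    counts: np.ndarray
    mean: float
    sd: float
    median: float
    median_positive: float
    median_negative: float
    n_pixels: int

    def mode(self) -> float:
        """Center of the fullest bin (lowest bin on ties); NaN if empty."""
        if self.n_pixels == 0:
            return float("nan")
        i = int(np.argmax(self.counts))
        return float(0.5 * (self.bin_edges[i] + self.bin_edges[i + 1]))


def nearest_channel(axis: WavelengthAxis, wavelength_nm: float) -> int:
    """Index of the channel whose center is nearest a wavelength.

    Ties (wavelength exactly midway between two centers) break toward
    the lower-wavelength channel. Wavelengths more than one channel
    width outside the grid are rejected.
    """
    centers = axis.centers_nm
    if not axis.contains(wavelength_nm):
        raise ValueError(
            f"wavelength {wavelength_nm} nm outside detection range "
            f"[{centers[0] - axis.width_nm}, {centers[-1] + axis.width_nm}] nm"
        )
    dist = np.abs(centers - wavelength_nm)
    # first index within float tolerance of the minimum = lower wavelength
    return int(np.flatnonzero(dist <= dist.min() + 1e-9)[0])


def direct_sample_intensities(
    spectrum, axis: WavelengthAxis, preset: ProbePreset
) -> tuple[float, float]:
    """(I_B, I_R) read from the channels nearest lambda_Lo and lambda_Ld."""
    spectrum = np.asarray(spectrum, dtype=float)
    if spectrum.size != axis.n_channels:
        raise ValueError(
            f"spectrum has {spectrum.size} samples but axis declares "
            f"{axis.n_channels} channels"
        )
    i_b = spectrum[nearest_channel(axis, preset.lambda_lo_nm)]
    i_r = spectrum[nearest_channel(axis, preset.lambda_ld_nm)]
    return float(i_b), float(i_r)


def gp_value(i_b, i_r):
    """GP = (I_B - I_R)/(I_B + I_R), NaN where both intensities are zero.

    Inputs are normalized by 255 first (plug-in parity; value-neutral
    for the ratio). Negative intensities violate the preprocessing
    contract and are rejected. Works elementwise on arrays.
    """
    i_b = np.asarray(i_b, dtype=float)
    i_r = np.asarray(i_r, dtype=float)
    if np.any(i_b < 0) or np.any(i_r < 0):
        raise ValueError("intensities must be nonnegative")
    b = i_b / 255.0
    r = i_r / 255.0
    total = b + r
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(total > 0, (b - r) / np.where(total > 0, total, 1.0), np.nan)
    if out.ndim == 0:
        return float(out)
    return out


def _preprocess(
    stack: SpectralStack, config: AnalysisConfig
) -> tuple[SpectralStack, Mask]:
    """Shared head of the pipeline: correction, projection, mask, background."""
    work = stack
    corr = config.correction()
    if corr is not None:
        work = apply_sensitivity_correction(work, corr)
    projection = to_8bit_scale(z_project(work))
    mask = compute_mask(projection, config.mask_threshold)
    if config.background_subtraction and mask.include.any():
        bg = estimate_background(work, mask, statistic=config.background_statistic)
        work = subtract_background(work, bg, mask)
    return work, mask


def compute_gp_map(stack: SpectralStack, config: AnalysisConfig) -> GPMap:
    """Run the full per-pixel GP pipeline for one method.

    Pipeline: optional sensitivity correction -> Z-projection -> 8-bit
    rescale -> threshold mask -> optional per-slice background
    subtraction -> per-pixel I_B/I_R (direct sampling, or whole-spectrum
    fit evaluated at lambda_Lo/lambda_Ld with the R^2 tolerance filter)
    -> GP. Deterministic given (stack, config).
    """
    axis = stack.axis
    # validate the preset against the axis up front
    nearest_channel(axis, config.preset.lambda_lo_nm)
    nearest_channel(axis, config.preset.lambda_ld_nm)

    work, mask = _preprocess(stack, config)
    rows, cols = work.n_rows, work.n_cols
    gp = np.full((rows, cols), np.nan)
    r2 = np.full((rows, cols), np.nan)
    n_failures = 0

    if not mask.include.any():
        warnings.warn(
            "mask excludes every pixel; GP map is empty", stacklevel=2
        )
        return GPMap(gp=gp, mask=mask, r2=r2, method=config.method,
                     preset=config.preset, n_fit_failures=0)

    if config.method == "direct":
        k_b = nearest_channel(axis, config.preset.lambda_lo_nm)
        k_r = nearest_channel(axis, config.preset.lambda_ld_nm)
        inside = mask.include
        gp[inside] = gp_value(work.data[inside, k_b], work.data[inside, k_r])
    else:
        lam_lo = config.preset.lambda_lo_nm
        lam_ld = config.preset.lambda_ld_nm
        for rr, cc in zip(*np.nonzero(mask.include)):
            fit = fit_spectrum(
                work.data[rr, cc, :],
                axis,
                config.method,
                max_iterations=config.max_iterations,
            )
            if not fit.converged:
                n_failures += 1
                continue
            r2[rr, cc] = fit.r_squared
            if fit.r_squared < config.r2_tolerance:
                continue
            gp[rr, cc] = gp_value(
                evaluate_fit(fit, lam_lo), evaluate_fit(fit, lam_ld)
            )

    return GPMap(
        gp=gp,
        mask=mask,
        r2=r2,
        method=config.method,
        preset=config.preset,
        n_fit_failures=n_failures,
    )


def gp_histogram(gpmap, bin_width: float = 0.02) -> GPHistogram:
    """Histogram a GP map (or raw GP array) over [-1, 1] with uniform bins."""
    if not (bin_width > 0):
        raise ValueError("bin_width must be > 0")
    values = gpmap.gp if isinstance(gpmap, GPMap) else np.asarray(gpmap, float)
    finite = values[np.isfinite(values)]
    n_bins = max(int(round(2.0 / bin_width)), 1)
    edges = -1.0 + bin_width * np.arange(n_bins + 1)
    edges[-1] = max(edges[-1], 1.0)  # last edge covers +1 exactly
    counts, _ = np.histogram(finite, bins=edges)

    if finite.size == 0:
        nan = float("nan")
        return GPHistogram(edges, counts, nan, nan, nan, nan, nan, 0)

    pos = finite[finite > 0]
    neg = finite[finite < 0]
    return GPHistogram(
        bin_edges=edges,
        counts=counts,
        mean=float(finite.mean()),
        sd=float(finite.std()),
        median=float(np.median(finite)),
        median_positive=float(np.median(pos)) if pos.size else float("nan"),
        median_negative=float(np.median(neg)) if neg.size else float("nan"),
        n_pixels=int(finite.size),
    )


@dataclass
class MethodComparison:
    """Side-by-side GP analysis of one stack by several methods.

    ``maps`` and ``histograms`` are keyed by method name; ``summary`` is
    one row per method (mean/SD/median GP, mean R^2, failure counts,
    and per-phase mean/SD when ground-truth phase labels were given).
    """

    maps: dict
    histograms: dict
    summary: pd.DataFrame


def compare_methods(
    stack: SpectralStack,
    config: AnalysisConfig,
    methods: Iterable[str] = METHODS,
    phase_labels: Optional[np.ndarray] = None,
) -> MethodComparison:
    """Run the GP pipeline with each method on identical preprocessing.

    ``phase_labels`` (optional, from a synthetic ground truth) is an
    integer per-pixel map, -1 for background; when given, per-phase mean
    and SD of GP are reported for each method.
    """
    methods = list(methods)
    maps: dict = {}
    hists: dict = {}
    rows = []
    for method in methods:
        cfg = replace(config, method=method)
        gpmap = compute_gp_map(stack, cfg)
        hist = gp_histogram(gpmap, bin_width=config.hist_bin_width)
        maps[method] = gpmap
        hists[method] = hist
        finite_r2 = gpmap.r2[np.isfinite(gpmap.r2)]
        row = {
            "method": method,
            "n_pixels": hist.n_pixels,
            "mean_gp": hist.mean,
            "sd_gp": hist.sd,
            "median_gp": hist.median,
            "mean_r2": float(finite_r2.mean()) if finite_r2.size else float("nan"),
            "n_fit_failures": gpmap.n_fit_failures,
        }
        if phase_labels is not None:
            for label in np.unique(phase_labels[phase_labels >= 0]):
                sel = (phase_labels == label) & np.isfinite(gpmap.gp)
                vals = gpmap.gp[sel]
                row[f"phase{label}_mean_gp"] = (
                    float(vals.mean()) if vals.size else float("nan")
                )
                row[f"phase{label}_sd_gp"] = (
                    float(vals.std()) if vals.size else float("nan")
                )
        rows.append(row)
    return MethodComparison(maps=maps, histograms=hists, summary=pd.DataFrame(rows))
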