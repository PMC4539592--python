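"""Synthetic spectral scenes with known ground truth.

Renders vesicle-like equatorial-plane images: a bright ring (the
membrane) over a dim background, where each angular sector of the ring
carries its own single-peak emission spectrum — a blue-peaked ordered
(Lo-like) phase and a red-peaked disordered (Ld-like) phase in the
default two-phase scene. Every pixel of the rendered stack holds the
sector's model spectrum sampled at the channel centers plus a flat (or
per-channel) background, optionally corrupted by Poisson shot noise or
additive Gaussian noise from a seeded generator. The analytic GP of
each sector's continuous model is carried alongside as ground truth, so
the whole pipeline can be validated without microscope data.

Peak SNR is defined as the peak expected signal divided by its standard
deviation: ``sqrt(amplitude)`` under Poisson noise, ``amplitude/sd``
under additive Gaussian noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np

from .fitting import (
    GammaVariateParams,
    GaussianParams,
    gamma_variate_model,
    gaussian_model,
)
from .gp import C_LAURDAN, ProbePreset, gp_value, nearest_channel
from .spectral_io import SpectralStack, WavelengthAxis

__all__ = [
    "DEFAULT_AXIS",
    "PhaseSpec",
    "SyntheticScene",
    "GroundTruth",
    "make_two_phase_vesicle",
    "render_stack",
    "analytic_gp",
    "analytic_gp_sampled",
    "amplitude_for_peak_snr",
]

#: 32 channels of 8.9 nm starting at 415 nm (centers 419.45-695.35 nm).
DEFAULT_AXIS = WavelengthAxis(start_nm=415.0, width_nm=8.9, n_channels=32)

ModelParams = Union[GaussianParams, GammaVariateParams]


def _model_value(params: ModelParams, wavelength_nm):
    if isinstance(params, GaussianParams):
        return gaussian_model(wavelength_nm, params)
    return gamma_variate_model(wavelength_nm, params)


@dataclass(frozen=True)
class PhaseSpec:
    """One angular sector of the ring: [theta_start, theta_stop) radians
    plus the spectral model of its membrane phase (the model's amplitude
    is the sector's peak intensity)."""

    name: str
    params: ModelParams
    theta_start: float
    theta_stop: float


@dataclass
class SyntheticScene:
    """Parametric ground-truth description of a vesicle image.

    The ring is the set of pixels whose distance to ``ring_center`` is
    within ``ring_thickness/2`` of ``ring_radius``. ``background_level``
    is a flat scalar or a per-channel vector (detector units).
    ``amplitude_gradient`` optionally modulates ring amplitudes linearly
    along the column axis (fraction per half-width, for mask-robustness
    studies; 0 = constant amplitude within each sector).
    """

    image_size: tuple
    ring_center: tuple
    ring_radius: float
    ring_thickness: float
    phases: list
    background_level: Union[float, np.ndarray] = 2.0
    axis: WavelengthAxis = field(default_factory=lambda: DEFAULT_AXIS)
    amplitude_gradient: float = 0.0

    def __post_init__(self) -> None:
        rows, cols = self.image_size
        cy, cx = self.ring_center
        outer = self.ring_radius + self.ring_thickness / 2.0
        if not (
            outer <= cy <= rows - 1 - outer and outer <= cx <= cols - 1 - outer
        ):
            raise ValueError("ring does not fit inside the image")
        spans = sorted((p.theta_start, p.theta_stop) for p in self.phases)
        if not math.isclose(spans[0][0], 0.0, abs_tol=1e-9) or not math.isclose(
            spans[-1][1], 2 * math.pi, abs_tol=1e-9
        ):
            raise ValueError("phase sectors must partition [0, 2*pi)")
        for (_, stop), (start, _) in zip(spans[:-1], spans[1:]):
            if not math.isclose(stop, start, abs_tol=1e-9):
                raise ValueError("phase sectors must partition [0, 2*pi)")
        bg_max = float(np.max(self.background_level))
        for p in self.phases:
            if p.params.amplitude <= bg_max:
                raise ValueError(
                    f"phase {p.name!r} amplitude {p.params.amplitude} must "
                    f"exceed background {bg_max}"
                )

    def background_vector(self) -> np.ndarray:
        bg = np.asarray(self.background_level, dtype=float)
        if bg.ndim == 0:
            bg = np.full(self.axis.n_channels, float(bg))
        if bg.size != self.axis.n_channels:
            raise ValueError(
                f"background vector length {bg.size} does not match "
                f"{self.axis.n_channels} channels"
            )
        return bg


@dataclass
class GroundTruth:
    """Per-pixel truth for a rendered scene.

    ``phase_label`` is the sector index (-1 off the ring); ``gp_true``
    the analytic GP of the generating continuous spectrum at the given
    preset (NaN off the ring); ``spectra_params`` maps sector index to
    its model parameters.
    """

    phase_label: np.ndarray
    gp_true: np.ndarray
    spectra_params: dict
    preset: ProbePreset

    @property
    def ring(self) -> np.ndarray:
        return self.phase_label >= 0


def amplitude_for_peak_snr(
    peak_snr: float, noise: str, gaussian_sd: Optional[float] = None
) -> float:
    """Peak amplitude giving a requested peak SNR under a noise model."""
    if noise == "poisson":
        return float(peak_snr) ** 2
    if noise == "gaussian":
        if gaussian_sd is None:
            raise ValueError("gaussian noise needs gaussian_sd")
        return float(peak_snr) * float(gaussian_sd)
    raise ValueError(f"no SNR definition for noise model {noise!r}")


def make_two_phase_vesicle(
    n_phases: int = 2,
    image_size: tuple = (128, 128),
    ring_radius: float = 42.0,
    ring_thickness: float = 8.0,
    amplitude: float = 400.0,
    background_level: Union[float, np.ndarray] = 2.0,
    peak_lo_nm: float = 440.0,
    peak_ld_nm: float = 490.0,
    sigma_nm: float = 25.0,
    axis: Optional[WavelengthAxis] = None,
    skew_shape: Optional[float] = None,
) -> SyntheticScene:
    """Vesicle scene with ``n_phases`` equal angular sectors.

    Default: a two-phase ring whose ordered (Lo-like) half emits a
    Gaussian spectrum peaked at 440 nm and whose disordered (Ld-like)
    half peaks at 490 nm, both sigma = 25 nm, on the default 32-channel
    axis — the canonical phase-separated vesicle. ``n_phases=1`` gives a
    uniform (single-phase) vesicle at the ordered peak; larger counts
    interpolate peak positions between ``peak_lo_nm`` and ``peak_ld_nm``.

    ``skew_shape`` switches the sector spectra to right-skewed Gamma
    Variate curves with that shape parameter (same peak positions; the
    onset is kept blue of the detection window).
    """
    if n_phases < 1:
        raise ValueError("n_phases must be >= 1")
    axis = axis or DEFAULT_AXIS
    rows, cols = image_size
    center = ((rows - 1) / 2.0, (cols - 1) / 2.0)
    peaks = (
        [peak_lo_nm]
        if n_phases == 1
        else list(np.linspace(peak_lo_nm, peak_ld_nm, n_phases))
    )
    sector = 2 * math.pi / n_phases
    phases = []
    for i, peak in enumerate(peaks):
        if skew_shape is None:
            params: ModelParams = GaussianParams(
                amplitude=amplitude, center_nm=peak, sigma_nm=sigma_nm
            )
        else:
            # onset one channel blue of the window; scale sets the peak
            onset = axis.start_nm - axis.width_nm
            scale = (peak - onset) / skew_shape
            params = GammaVariateParams(
                amplitude=amplitude,
                onset_nm=onset,
                shape=skew_shape,
                scale_nm=scale,
            )
        phases.append(
            PhaseSpec(
                name=f"phase{i}",
                params=params,
                theta_start=i * sector,
                theta_stop=(i + 1) * sector if i < n_phases - 1 else 2 * math.pi,
            )
        )
    return SyntheticScene(
        image_size=image_size,
        ring_center=center,
        ring_radius=ring_radius,
        ring_thickness=ring_thickness,
        phases=phases,
        background_level=background_level,
        axis=axis,
    )


def analytic_gp(params: ModelParams, preset: ProbePreset) -> float:
    """GP of a continuous model spectrum read at the preset wavelengths."""
    i_b = _model_value(params, preset.lambda_lo_nm)
    i_r = _model_value(params, preset.lambda_ld_nm)
    if i_b == 0.0 and i_r == 0.0:
        return float("nan")
    return gp_value(i_b, i_r)


def analytic_gp_sampled(
    params: ModelParams, axis: WavelengthAxis, preset: ProbePreset
) -> float:
    """GP of a model spectrum read at the channel centers nearest the
    preset wavelengths — the quantity direct sampling estimates."""
    centers = axis.centers_nm
    i_b = _model_value(params, centers[nearest_channel(axis, preset.lambda_lo_nm)])
    i_r = _model_value(params, centers[nearest_channel(axis, preset.lambda_ld_nm)])
    if i_b == 0.0 and i_r == 0.0:
        return float("nan")
    return gp_value(i_b, i_r)


def render_stack(
    scene: SyntheticScene,
    noise: str = "none",
    seed: int = 0,
    gaussian_sd: Optional[float] = None,
    preset: ProbePreset = C_LAURDAN,
) -> tuple[SpectralStack, GroundTruth]:
    """Render a scene to a spectral stack plus its ground truth.

    ``noise``: ``"none"`` (exact model values), ``"poisson"`` (shot
    noise on the expected counts) or ``"gaussian"`` (additive, SD
    ``gaussian_sd``, clipped at zero). Rendering is deterministic given
    (scene, noise, seed).
    """
    if noise not in ("none", "poisson", "gaussian"):
        raise ValueError(f"unknown noise model {noise!r}")
    rows, cols = scene.image_size
    cy, cx = scene.ring_center
    yy, xx = np.mgrid[0:rows, 0:cols]
    dy = yy - cy
    dx = xx - cx
    radius = np.hypot(dy, dx)
    on_ring = np.abs(radius - scene.ring_radius) <= scene.ring_thickness / 2.0
    theta = np.mod(np.arctan2(dy, dx), 2 * math.pi)

    label = np.full((rows, cols), -1, dtype=int)
    for i, phase in enumerate(scene.phases):
        in_sector = (theta >= phase.theta_start) & (
            (theta < phase.theta_stop)
            | (math.isclose(phase.theta_stop, 2 * math.pi) & (theta < 2 * math.pi))
        )
        label[on_ring & in_sector] = i

    centers = scene.axis.centers_nm
    expected = np.tile(
        scene.background_vector(), (rows, cols, 1)
    ).astype(float)
    if scene.amplitude_gradient != 0.0:
        half = (cols - 1) / 2.0
        gain = 1.0 + scene.amplitude_gradient * (xx - cx) / half
        gain = np.clip(gain, 0.0, None)
    else:
        gain = None
    for i, phase in enumerate(scene.phases):
        spectrum = _model_value(phase.params, centers)
        sel = label == i
        if gain is None:
            expected[sel] += spectrum
        else:
            expected[sel] += gain[sel, np.newaxis] * spectrum[np.newaxis, :]

    rng = np.random.default_rng(seed)
    if noise == "none":
        data = expected
    elif noise == "poisson":
        data = rng.poisson(expected).astype(float)
    else:
        if gaussian_sd is None:
            raise ValueError("gaussian noise needs gaussian_sd")
        data = np.clip(
            expected + rng.normal(0.0, gaussian_sd, expected.shape), 0.0, None
        )

    gp_true = np.full((rows, cols), np.nan)
    spectra_params = {}
    for i, phase in enumerate(scene.phases):
        gp_true[label == i] = analytic_gp(phase.params, preset)
        spectra_params[i] = phase.params

    stack = SpectralStack(data=data, axis=scene.axis, source="synthetic")
    truth = GroundTruth(
        phase_label=label,
        gp_true=gp_true,
        spectra_params=spectra_params,
        preset=preset,
    )
    return stack, truth
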