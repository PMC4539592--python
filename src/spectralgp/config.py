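"""Analysis configuration shared by the library pipeline and the CLI."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

from .spectral_io import SensitivityCorrection, WavelengthAxis

__all__ = ["AnalysisConfig", "METHODS"]

METHODS = ("direct", "gaussian", "gamma_variate")


@dataclass
class AnalysisConfig:
    """All user-facing controls of the GP pipeline.

    Attributes
    ----------
    axis:
        Wavelength axis to impose on loaded stacks; ``None`` defers to
        file metadata.
    preset:
        Probe preset carrying the blue (lambda_Lo) and red (lambda_Ld)
        readout wavelengths; see :mod:`spectralgp.gp`.
    method:
        ``"direct"`` (nearest-channel sampling), ``"gaussian"`` or
        ``"gamma_variate"`` (whole-spectrum curve fitting).
    mask_threshold:
        8-bit threshold (0-255) on the Z-projection; strictly-greater
        pixels are analyzed. Default 15.
    background_subtraction / background_statistic:
        Per-slice scalar background from the dark (mask-excluded) area,
        subtracted inside the mask; ``mean`` (default) or ``median``.
    r2_tolerance:
        Minimum per-pixel R^2 for a fitted pixel to enter the GP map
        (fitting methods only). Default 0.8.
    hist_bin_width:
        GP histogram bin width over [-1, 1]. Default 0.02.
    sensitivity_correction:
        Optional per-channel positive multipliers.
    max_iterations:
        Optimizer iteration cap per pixel fit.
    """

    preset: "object" = None  # ProbePreset; default filled by gp module
    axis: Optional[WavelengthAxis] = None
    method: str = "direct"
    mask_threshold: int = 15
    background_subtraction: bool = True
    background_statistic: str = "mean"
    r2_tolerance: float = 0.8
    hist_bin_width: float = 0.02
    sensitivity_correction: Optional[Sequence[float]] = None
    max_iterations: int = 200

    def __post_init__(self) -> None:
        if self.preset is None:
            from .gp import C_LAURDAN

            self.preset = C_LAURDAN
        self.validate()

    def validate(self) -> None:
        if self.method not in METHODS:
            raise ValueError(
                f"method must be one of {METHODS}, got {self.method!r}"
            )
        if not (0 <= self.mask_threshold <= 255):
            raise ValueError(
                f"mask_threshold must be within [0, 255], got {self.mask_threshold}"
            )
        if self.background_statistic not in ("mean", "median"):
            raise ValueError(
                "background_statistic must be 'mean' or 'median', got "
                f"{self.background_statistic!r}"
            )
        if not (0.0 <= self.r2_tolerance <= 1.0):
            raise ValueError(
                f"r2_tolerance must be within [0, 1], got {self.r2_tolerance}"
            )
        if not (self.hist_bin_width > 0):
            raise ValueError("hist_bin_width must be > 0")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")

    def correction(self) -> Optional[SensitivityCorrection]:
        if self.sensitivity_correction is None:
            return None
        return SensitivityCorrection(self.sensitivity_correction)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["preset"] = {
            "name": self.preset.name,
            "lambda_lo_nm": self.preset.lambda_lo_nm,
            "lambda_ld_nm": self.preset.lambda_ld_nm,
        }
        d["axis"] = self.axis.to_dict() if self.axis is not None else None
        if self.sensitivity_correction is not None:
            d["sensitivity_correction"] = [
                float(f) for f in self.sensitivity_correction
            ]
        return d
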