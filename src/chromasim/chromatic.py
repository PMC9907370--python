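"""Ocular chromatic-aberration models and visual-angle geometry.

The eye's refractive power varies with wavelength (longitudinal chromatic
aberration, LCA) and the retinal image location varies with wavelength
(transverse chromatic aberration, TCA).  This module holds the standard
chromatic-difference-of-refraction polynomial, the achromatizing-lens /
optical-trombone correction scaling, TCA bookkeeping with its summary
statistics, the interocular-disparity prediction for chromostereopsis, and
the small geometric conversions (diopters, arcmin, pixels, vergence) used
throughout the package.

Sign conventions
----------------
TCA horizontal/vertical components are stored in the visual-field
convention: positive = rightward / upward in the visual field.  The
nasal/temporal view is derived (``field_to_temporal``), never stored.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import bisect

__all__ = [
    "ChromaticEyeModel",
    "SubjectLCAProfile",
    "TCAMeasurement",
    "TCASummary",
    "SystemTCA",
    "TromboneSetting",
    "GeometryContext",
    "NoRootError",
    "model_defocus",
    "zero_defocus_wavelength",
    "chromatic_span",
    "acl_dispersion",
    "trombone_lca_scaling",
    "predict_disparity",
    "tca_summary",
    "subtract_system_tca",
    "offset_to_phase",
    "vergence_distance",
    "diopters_to_distance",
    "pixels_to_arcmin",
    "field_to_temporal",
    "round_half_away",
]

ARCMIN_PER_DEG = 60.0

#: Wavelength (nm) at which the achromatizing lens is afocal.
ACL_AFOCAL_NM = 573.5


class NoRootError(ValueError):
    """The defocus polynomial does not change sign on the valid range."""


def round_half_away(x: float, ndigits: int = 2) -> float:
    """Round with ties going away from zero (matches 2-decimal reporting)."""
    scale = 10.0**ndigits
    return math.copysign(math.floor(abs(x) * scale + 0.5), x) / scale


@dataclass(frozen=True)
class ChromaticEyeModel:
    """Chromatic difference of refraction D(lambda) of the typical human eye.

    D(lambda) = c0 - c2/lambda^2 + c4/lambda^4 - c6/lambda^6, with lambda in
    nanometers and D in diopters.  With the default coefficients the model is
    in focus (D = 0) near 590 nm and strictly increasing from blue to red:
    short wavelengths are focused in front of the retina (negative power
    error), long wavelengths behind.
    """

    c0: float = 1.6091
    c2: float = 6.7094e5
    c4: float = 5.5533e10
    c6: float = 5.6000e15
    valid_range: tuple[float, float] = (400.0, 700.0)

    def defocus(self, wavelength_nm):
        """Evaluate D(lambda) in diopters; see :func:`model_defocus`."""
        return model_defocus(self, wavelength_nm)


def model_defocus(model: ChromaticEyeModel, wavelength_nm):
    """Chromatic defocus D(lambda) in diopters.

    Parameters
    ----------
    model : ChromaticEyeModel
    wavelength_nm : float or array_like
        Wavelength(s) in nm, inside ``model.valid_range``.

    Raises
    ------
    ValueError
        If any wavelength lies outside the model's valid range.
    """
    lam = np.asarray(wavelength_nm, dtype=float)
    lo, hi = model.valid_range
    if np.any(lam < lo) or np.any(lam > hi):
        raise ValueError(
            f"wavelength outside valid range [{lo}, {hi}] nm: {wavelength_nm!r}"
        )
    l2 = lam * lam
    out = model.c0 - model.c2 / l2 + model.c4 / l2**2 - model.c6 / l2**3
    return float(out) if np.isscalar(wavelength_nm) else out


def zero_defocus_wavelength(model: ChromaticEyeModel, tol_nm: float = 0.1) -> float:
    """Wavelength (nm) at which D(lambda) = 0, by bracketing + bisection.

    The valid range is scanned on a 1-nm grid for a sign change, then the
    root is refined by bisection to ``tol_nm``.

    Raises
    ------
    NoRootError
        If D does not change sign on the valid range.
    """
    lo, hi = model.valid_range
    grid = np.arange(lo, hi + 0.5, 1.0)
    grid[-1] = hi
    d = model_defocus(model, grid)
    sign = np.sign(d)
    idx = np.nonzero(np.diff(sign) != 0)[0]
    if len(idx) == 0:
        raise NoRootError("defocus polynomial has no zero crossing on the valid range")
    i = idx[0]
    if d[i] == 0.0:
        return float(grid[i])
    return float(
        bisect(lambda l: model_defocus(model, l), grid[i], grid[i + 1], xtol=tol_nm / 10)
    )


def chromatic_span(model: ChromaticEyeModel, lambda1_nm: float, lambda2_nm: float) -> float:
    """Chromatic difference of focus D(lambda2) - D(lambda1), diopters."""
    return model_defocus(model, lambda2_nm) - model_defocus(model, lambda1_nm)


def acl_dispersion(wavelength_nm, eye_model: ChromaticEyeModel | None = None):
    """Dispersion of the achromatizing lens (ACL), diopters.

    The ACL is designed equal and opposite to the typical eye and afocal at
    573.5 nm: LCA_ACL(lambda) = -(D(lambda) - D(573.5 nm)).
    """
    eye_model = eye_model if eye_model is not None else ChromaticEyeModel()
    return -(
        model_defocus(eye_model, wavelength_nm)
        - model_defocus(eye_model, ACL_AFOCAL_NM)
    )


@dataclass(frozen=True)
class TromboneSetting:
    """Optical-trombone state controlling the magnitude of LCA correction.

    ``magnification`` is M = f2/f1, the beam magnification at the ACL
    relative to the eye's pupil.  Because vergence between pupil conjugates
    scales with the inverse square of magnification, the LCA correction
    delivered at the eye is the ACL dispersion multiplied by M^2: a larger
    beam at the ACL gives a larger correction.
    """

    magnification: float = 1.0
    eye_model: ChromaticEyeModel = field(default_factory=ChromaticEyeModel)

    def __post_init__(self):
        if not self.magnification > 0:
            raise ValueError("trombone magnification M must be > 0")


def trombone_lca_scaling(setting: TromboneSetting, wavelength_nm) -> float:
    """LCA correction delivered at the eye for one trombone setting, diopters.

    correction(lambda) = LCA_ACL(lambda) * M^2.
    """
    if not setting.magnification > 0:
        raise ValueError("trombone magnification M must be > 0")
    return acl_dispersion(wavelength_nm, setting.eye_model) * setting.magnification**2


@dataclass(frozen=True)
class SubjectLCAProfile:
    """Per-eye LCA refraction offsets at the display primaries.

    Offsets are in diopters relative to the green (533 nm) primary, which is
    re-referenced to exactly zero; ``sd`` are setting standard deviations.
    """

    eye: str
    offsets_d: dict[int, float]
    sd_d: dict[int, float]
    n_settings: int = 1
    reference_nm: int = 533

    def __post_init__(self):
        if self.eye not in ("left", "right"):
            raise ValueError(f"eye must be 'left' or 'right', got {self.eye!r}")
        if self.n_settings < 1:
            raise ValueError("n_settings must be >= 1")
        ref = self.offsets_d.get(self.reference_nm, 0.0)
        if abs(ref) > 1e-12:
            raise ValueError("offset at the reference (green) primary must be 0")


@dataclass(frozen=True)
class TCAMeasurement:
    """Foveal TCA of one primary pair for one eye and LCA state.

    Horizontal/vertical components are in arcmin in the visual-field
    convention (positive = rightward / upward).
    """

    eye: str
    pair: str  # "blue-vs-red" | "green-vs-red"
    lca_state: str  # "corrected" | "uncorrected"
    horizontal: float
    vertical: float
    sd_h: float = 0.0
    sd_v: float = 0.0
    subject: str = ""

    def __post_init__(self):
        if self.eye not in ("left", "right"):
            raise ValueError(f"eye must be 'left' or 'right', got {self.eye!r}")
        if self.pair not in ("blue-vs-red", "green-vs-red"):
            raise ValueError(f"unknown primary pair {self.pair!r}")
        if self.lca_state not in ("corrected", "uncorrected"):
            raise ValueError(f"unknown lca_state {self.lca_state!r}")


@dataclass(frozen=True)
class SystemTCA:
    """Residual TCA of the instrument itself for one configuration (< 1 arcmin)."""

    horizontal: float = 0.0
    vertical: float = 0.0
    magnification: float = 1.0
    acl_present: bool = True

    def __post_init__(self):
        if math.hypot(self.horizontal, self.vertical) >= 1.0 + 1e-9:
            raise ValueError("system TCA magnitude must stay below 1 arcmin")


@dataclass(frozen=True)
class GeometryContext:
    """Display/viewing geometry: pixel pitch, field size, interpupillary distance."""

    ipd_mm: float = 60.0
    pixel_pitch_arcmin: float = 0.23
    field_deg: float = 3.0

    def __post_init__(self):
        if min(self.ipd_mm, self.pixel_pitch_arcmin, self.field_deg) <= 0:
            raise ValueError("geometry parameters must be positive")


def predict_disparity(tca_right_h: float, tca_left_h: float) -> float:
    """Predicted interocular disparity d = TCA_R - TCA_L (arcmin).

    Both inputs are horizontal TCA components in the visual-field
    convention.  The difference is the binocular disparity of the
    short-wavelength component that chromostereopsis should null.
    """
    return tca_right_h - tca_left_h


@dataclass(frozen=True)
class TCASummary:
    """Summary statistics of a set of TCA measurements (all arcmin).

    ``by_condition`` holds the median horizontal/vertical TCA per
    (eye, pair, lca_state) cell; the remaining fields are means of those
    condition medians: the mean absolute (horizontal) deviation from zero per
    primary pair and per LCA state, and the per-eye mean horizontal TCA.
    """

    by_condition: pd.DataFrame
    abs_dev_by_pair: dict[str, float]
    abs_dev_by_lca_state: dict[str, float]
    eye_mean_horizontal: dict[str, float]


def tca_summary(measurements: Sequence[TCAMeasurement]) -> TCASummary:
    """Condition medians and headline deviation statistics of TCA data."""
    if len(measurements) == 0:
        raise ValueError("tca_summary requires at least one measurement")
    df = pd.DataFrame(
        {
            "eye": [m.eye for m in measurements],
            "pair": [m.pair for m in measurements],
            "lca_state": [m.lca_state for m in measurements],
            "horizontal": [m.horizontal for m in measurements],
            "vertical": [m.vertical for m in measurements],
        }
    )
    med = (
        df.groupby(["eye", "pair", "lca_state"], sort=True)[["horizontal", "vertical"]]
        .median()
    )
    h = med["horizontal"]
    abs_by_pair = h.abs().groupby(level="pair").mean().to_dict()
    abs_by_state = h.abs().groupby(level="lca_state").mean().to_dict()
    eye_mean = h.groupby(level="eye").mean().to_dict()
    return TCASummary(
        by_condition=med,
        abs_dev_by_pair=abs_by_pair,
        abs_dev_by_lca_state=abs_by_state,
        eye_mean_horizontal=eye_mean,
    )


def subtract_system_tca(measured: TCAMeasurement, system: SystemTCA) -> TCAMeasurement:
    """Remove the instrument's own TCA from a measurement (componentwise)."""
    return replace(
        measured,
        horizontal=measured.horizontal - system.horizontal,
        vertical=measured.vertical - system.vertical,
    )


def offset_to_phase(offset_arcmin: float, spatial_frequency_cpd: float) -> float:
    """Phase (radians) of a lateral offset for a grating of given frequency.

    phi = 2*pi * offset * f / 60.  No wrapping is applied: a 3-arcmin offset
    of a 10-cpd grating is exactly pi (counterphase).
    """
    if not spatial_frequency_cpd > 0:
        raise ValueError("spatial frequency must be positive")
    return 2.0 * math.pi * offset_arcmin * spatial_frequency_cpd / ARCMIN_PER_DEG


def vergence_distance(ipd_mm: float, vergence_angle_deg: float) -> float:
    """Viewing distance (mm) consistent with an ocular vergence angle.

    distance = IPD / tan(angle).  A 60-mm IPD with the left eye's axis
    turned out by 5.15 degrees corresponds to 666 mm.
    """
    if not 0 < vergence_angle_deg < 90:
        raise ValueError("vergence angle must be in (0, 90) degrees")
    return ipd_mm / math.tan(math.radians(vergence_angle_deg))


def diopters_to_distance(vergence_d: float) -> float:
    """Viewing distance in meters for an optical vergence in diopters.

    0 D maps to infinity; negative vergence is rejected.
    """
    if vergence_d < 0:
        raise ValueError("vergence must be >= 0 diopters")
    if vergence_d == 0:
        return math.inf
    return 1.0 / vergence_d


def pixels_to_arcmin(ctx: GeometryContext, pixels: float) -> float:
    """Visual angle (arcmin) subtended by a number of display pixels."""
    return pixels * ctx.pixel_pitch_arcmin


def field_to_temporal(eye: str, horizontal_arcmin: float) -> float:
    """Convert a visual-field horizontal offset to temporalward-positive.

    Rightward in the visual field is temporal for the right eye and nasal
    for the left eye.
    """
    if eye == "right":
        return horizontal_arcmin
    if eye == "left":
        return -horizontal_arcmin
    raise ValueError(f"eye must be 'left' or 'right', got {eye!r}")
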