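"""Tri-primary stimulus rendering with sub-pixel chromatic offsets.

Stimuli are defined on a simulated display whose pixels subtend 0.23 arcmin
and whose visible field is a 3-degree circle.  Shapes are evaluated in a
10x up-sampled pixel space and box-averaged back to display resolution,
which provides 0.1-subpixel positioning (0.023 arcmin) and antialiasing.
Digital TCA offsets shift the green and blue planes relative to red in that
same up-sampled space.

Five stimulus classes are provided: Voronoi fields (focus adjustment),
duochrome disk-in-annulus targets (TCA alignment), tumbling-E optotypes
(acuity), red+blue composite Gabors (contrast sensitivity), and dichoptic
bar pairs (chromostereopsis).  All plane values are linear luminance in
[0, 1]; display gamma is out of scope.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass
from typing import Callable

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "CanvasSpec",
    "TriPrimaryImage",
    "TumblingESpec",
    "GaborCompositeSpec",
    "DuochromeSpec",
    "DichopticBarsSpec",
    "VoronoiSpec",
    "SubpixelQuantizationWarning",
    "render_subpixel",
    "make_tumbling_e",
    "make_gabor_composite",
    "make_duochrome",
    "make_dichoptic_bars",
    "make_voronoi",
    "BACKGROUND_PLANES",
]

ARCMIN_PER_DEG = 60.0

# Relative luminances of the display maxima (red, green, blue) used for the
# "white" background; the purple background mixes the three primaries at
# equal luminance instead.
_DISPLAY_LUMINANCE_RATIO = np.array([1.348, 3.933, 0.3604])
_DISPLAY_LUMINANCE_RATIO = _DISPLAY_LUMINANCE_RATIO / _DISPLAY_LUMINANCE_RATIO.sum()


class SubpixelQuantizationWarning(UserWarning):
    """An offset below the 0.1-subpixel quantum was rounded."""


@dataclass(frozen=True)
class CanvasSpec:
    """Display geometry and the up-sampling factor for sub-pixel rendering."""

    pixel_pitch_arcmin: float = 0.23
    size_px: int = 784
    upsample: int = 10
    field_deg: float = 3.0

    def __post_init__(self):
        if not self.pixel_pitch_arcmin > 0:
            raise ValueError("pixel pitch must be positive")
        if self.upsample < 1:
            raise ValueError("upsample factor must be >= 1")

    @property
    def quantum_arcmin(self) -> float:
        """Smallest representable offset: one up-sampled pixel."""
        return self.pixel_pitch_arcmin / self.upsample

    def axes_arcmin(self) -> tuple[np.ndarray, np.ndarray]:
        """Pixel-center coordinates (x, y) in arcmin, origin at canvas center."""
        n = self.size_px
        c = (np.arange(n) - (n - 1) / 2.0) * self.pixel_pitch_arcmin
        return c, c.copy()

    def field_mask(self) -> np.ndarray:
        x, y = self.axes_arcmin()
        xx, yy = np.meshgrid(x, y)
        r = self.field_deg * ARCMIN_PER_DEG / 2.0
        return (xx**2 + yy**2) <= r**2


@dataclass
class TriPrimaryImage:
    """Three luminance planes (red, green, blue), values in [0, 1]."""

    red: np.ndarray
    green: np.ndarray
    blue: np.ndarray

    def __post_init__(self):
        if not (self.red.shape == self.green.shape == self.blue.shape):
            raise ValueError("plane dimensions must match")
        for name in ("red", "green", "blue"):
            setattr(self, name, np.clip(np.asarray(getattr(self, name), float), 0.0, 1.0))

    @property
    def planes(self) -> dict[str, np.ndarray]:
        return {"red": self.red, "green": self.green, "blue": self.blue}

    def to_array(self) -> np.ndarray:
        return np.stack([self.red, self.green, self.blue], axis=-1)

    def total_luminance(self) -> np.ndarray:
        return self.red + self.green + self.blue

    def save_png(self, path) -> None:
        from PIL import Image

        arr = np.round(self.to_array() * 255).astype(np.uint8)
        Image.fromarray(arr, mode="RGB").save(path)

    def save_text(self, path_prefix) -> None:
        for name, plane in self.planes.items():
            np.savetxt(f"{path_prefix}_{name}.txt", plane, fmt="%.6f")


# ---------------------------------------------------------------------------
# sub-pixel shifting


def _shift_plane_1d(plane: np.ndarray, subpixels: int, upsample: int, axis: int) -> np.ndarray:
    """Shift by an integer number of up-sampled pixels along one axis.

    Equivalent to: up-sample by `upsample` (pixel replication), roll by
    `subpixels`, box-average back down.  For a shift of w whole pixels plus k
    subpixels that reduces to a two-tap linear blend of whole-pixel rolls,
    which is what is computed (exact, and without allocating the 10x grid).
    """
    w, k = divmod(subpixels, upsample)
    rolled = np.roll(plane, w, axis=axis)
    if k == 0:
        return rolled
    frac = k / upsample
    return (1.0 - frac) * rolled + frac * np.roll(plane, w + 1, axis=axis)


def render_subpixel(
    image: TriPrimaryImage,
    offsets: dict[str, tuple[float, float]],
    canvas: CanvasSpec,
) -> TriPrimaryImage:
    """Shift the green/blue planes relative to red by sub-pixel amounts.

    ``offsets`` maps plane name ("green", "blue") to an (dx, dy) offset in
    arcmin; positive dx shifts rightward (+x), positive dy upward.  Offsets
    are quantized to the 0.1-subpixel quantum (0.023 arcmin by default); a
    finer request raises :class:`SubpixelQuantizationWarning` and is rounded.
    The red plane is never shifted.
    """
    if "red" in offsets:
        raise ValueError("the red plane is the reference and cannot be shifted")
    q = canvas.quantum_arcmin
    out = {"red": image.red.copy(), "green": image.green, "blue": image.blue}
    for name in ("green", "blue"):
        dx, dy = offsets.get(name, (0.0, 0.0))
        sx, sy = round(dx / q), round(dy / q)
        if abs(sx * q - dx) > 1e-9 or abs(sy * q - dy) > 1e-9:
            warnings.warn(
                f"{name} offset ({dx}, {dy}) arcmin quantized to the "
                f"{q:.3f}-arcmin sub-pixel quantum",
                SubpixelQuantizationWarning,
            )
        plane = image.planes[name]
        # +y is up but row index grows downward
        plane = _shift_plane_1d(plane, sx, canvas.upsample, axis=1)
        plane = _shift_plane_1d(plane, -sy, canvas.upsample, axis=0)
        out[name] = plane
    return TriPrimaryImage(**out)


# ---------------------------------------------------------------------------
# up-sampled drawing (block-processed to bound memory)


def _draw(canvas: CanvasSpec, fn: Callable[[np.ndarray, np.ndarray], np.ndarray]) -> np.ndarray:
    """Evaluate fn(x_arcmin, y_arcmin) on the up-sampled grid, box-downsample."""
    n, u = canvas.size_px, canvas.upsample
    fine_pitch = canvas.pixel_pitch_arcmin / u
    nf = n * u
    xf = (np.arange(nf) - (nf - 1) / 2.0) * fine_pitch
    out = np.empty((n, n), dtype=float)
    rows_per_block = max(1, 256 // u)
    for r0 in range(0, n, rows_per_block):
        r1 = min(n, r0 + rows_per_block)
        yf = -xf[r0 * u : r1 * u]  # +y up, rows grow downward
        vals = fn(xf[None, :], yf[:, None])
        vals = vals.reshape(r1 - r0, u, n, u).mean(axis=(1, 3))
        out[r0:r1] = vals
    return out


def _apply_field(planes: dict[str, np.ndarray], canvas: CanvasSpec) -> TriPrimaryImage:
    mask = canvas.field_mask()
    return TriPrimaryImage(**{k: v * mask for k, v in planes.items()})


# ---------------------------------------------------------------------------
# stimulus specs


#: Background plane values (red, green, blue) at unit background luminance.
BACKGROUND_PLANES = {
    "green": np.array([0.0, 1.0, 0.0]),
    "purple": np.array([1.0, 1.0, 1.0]) / 3.0,  # equal-luminance mix of the three
    "white": _DISPLAY_LUMINANCE_RATIO,  # display-white luminance proportions
}


@dataclass(frozen=True)
class TumblingESpec:
    """Sloan-style tumbling E: 5x5 stroke grid, 20% Weber decrement letters."""

    orientation: str = "R"  # R, D, L, U (direction the limbs open toward)
    logmar: float = 0.0
    background: str = "white"
    letter_contrast: float = 0.20
    background_luminance: float = 0.9

    def __post_init__(self):
        if self.orientation not in ("R", "D", "L", "U"):
            raise ValueError("orientation must be one of R, D, L, U")
        if self.background not in BACKGROUND_PLANES:
            raise ValueError(f"unknown background {self.background!r}")

    @property
    def letter_height_arcmin(self) -> float:
        """Letter height = 5 x MAR, MAR = 10**logMAR arcmin."""
        return 5.0 * 10.0**self.logmar


@dataclass(frozen=True)
class GaborCompositeSpec:
    """Red + blue composite grating under a Gaussian window, tilted +-10 deg."""

    sf_cpd: float = 10.0
    contrast: float = 1.0
    blue_offset_arcmin: float = 0.0
    sigma_arcmin: float = 23.0
    tilt_deg: float = 10.0
    red_phase_rad: float = 0.0
    mean_luminance: float = 0.5

    def __post_init__(self):
        if self.tilt_deg not in (-10.0, 10.0):
            raise ValueError("tilt must be -10 or +10 degrees")
        if not (self.sf_cpd > 0 and self.sigma_arcmin > 0):
            raise ValueError("spatial frequency and sigma must be positive")


@dataclass(frozen=True)
class DuochromeSpec:
    """Colored disk inside a red annulus, separated by black gap/outline."""

    disk_diameter_px: float = 130.0
    line_px: float = 10.0
    annulus_width_px: float = 30.0
    disk_offset_px: tuple[float, float] = (0.0, 0.0)
    disk_primary: str = "blue"

    def __post_init__(self):
        if self.disk_primary not in ("blue", "green"):
            raise ValueError("disk primary must be 'blue' or 'green'")
        if min(self.disk_diameter_px, self.line_px, self.annulus_width_px) <= 0:
            raise ValueError("geometric parameters must be positive")


@dataclass(frozen=True)
class DichopticBarsSpec:
    """Red bar above a blue bar; the blue bar carries a binocular disparity."""

    bar_width_arcmin: float = 2.30
    bar_length_arcmin: float = 60.0
    gap_arcmin: float = 2.30
    disparity_arcmin: float = 0.0  # + = crossed (near) disparity of blue

    def __post_init__(self):
        if min(self.bar_width_arcmin, self.bar_length_arcmin, self.gap_arcmin) <= 0:
            raise ValueError("bar geometry must be positive")


@dataclass(frozen=True)
class VoronoiSpec:
    """Random Voronoi luminance field in a single primary on black."""

    seed_count: int = 200
    primary: str = "green"
    luminance_range: tuple[float, float] = (0.15, 1.0)

    def __post_init__(self):
        if self.seed_count < 2:
            raise ValueError("need at least 2 Voronoi seeds")
        if self.primary not in ("red", "green", "blue"):
            raise ValueError("primary must be red, green or blue")


def spec_to_json(spec) -> str:
    """Serialize any stimulus spec to JSON."""
    d = asdict(spec)
    d["__type__"] = type(spec).__name__
    return json.dumps(d, sort_keys=True)


# ---------------------------------------------------------------------------
# stimulus constructors


def _e_indicator(orientation: str):
    """Indicator of a tumbling E on the unit square, limbs opening to `orientation`.

    The canonical glyph (orientation 'R') has its spine on the left and three
    limbs (top, middle, bottom) extending rightward; all strokes are 1/5 of
    the letter height.
    """

    def base(u, v):  # u, v in [0, 1]; 'R' orientation
        inside = (u >= 0) & (u <= 1) & (v >= 0) & (v <= 1)
        spine = u <= 0.2
        limbs = (v <= 0.2) | ((v >= 0.4) & (v <= 0.6)) | (v >= 0.8)
        return inside & (spine | limbs)

    rotations = {"R": 0, "U": 1, "L": 2, "D": 3}
    k = rotations[orientation]

    def fn(u, v):
        for _ in range(k):  # rotate letter coords by -90 deg per step
            u, v = v, 1.0 - u
        return base(u, v)

    return fn


def make_tumbling_e(spec: TumblingESpec, canvas: CanvasSpec) -> TriPrimaryImage:
    """Dark tumbling E on a uniform bright background.

    Letter pixels are ``(1 - letter_contrast)`` times the background
    luminance (a 20% Weber decrement by default).  Backgrounds: ``green``
    (monochromatic), ``purple`` (equal-luminance red+green+blue) or ``white``
    (display-white luminance proportions).
    """
    h = spec.letter_height_arcmin
    if h > canvas.field_deg * ARCMIN_PER_DEG:
        raise ValueError("letter does not fit inside the visible field")
    glyph = _e_indicator(spec.orientation)

    def letter(x, y):
        return glyph((x + h / 2) / h, (y + h / 2) / h).astype(float)

    letter_map = _draw(canvas, letter)
    attenuation = 1.0 - spec.letter_contrast * letter_map
    bg = BACKGROUND_PLANES[spec.background] * spec.background_luminance
    planes = {
        name: bg[i] * attenuation for i, name in enumerate(("red", "green", "blue"))
    }
    return _apply_field(planes, canvas)


def make_gabor_composite(spec: GaborCompositeSpec, canvas: CanvasSpec) -> TriPrimaryImage:
    """Red and blue sinewave gratings of equal peak luminance, summed.

    Both gratings share frequency, tilt, and Gaussian window; the blue
    grating is displaced along the modulation axis by
    ``blue_offset_arcmin``.  A 3-arcmin offset of a 10-cpd grating puts the
    two in counterphase, leaving (at the display) a hue-only modulation; a
    0 offset gives a pure luminance grating.
    """
    period_arcmin = ARCMIN_PER_DEG / spec.sf_cpd
    theta = np.radians(spec.tilt_deg)
    m = spec.mean_luminance

    def plane(offset_arcmin, phase):
        def fn(x, y):
            u = x * np.cos(theta) - y * np.sin(theta)  # across-bars axis
            env = np.exp(-(x**2 + y**2) / (2.0 * spec.sigma_arcmin**2))
            carrier = np.sin(2 * np.pi * (u - offset_arcmin) / period_arcmin + phase)
            return m * (1.0 + spec.contrast * env * carrier)

        return _draw(canvas, fn)

    red = plane(0.0, spec.red_phase_rad)
    blue = plane(spec.blue_offset_arcmin, spec.red_phase_rad)
    green = np.zeros_like(red)
    return _apply_field({"red": red, "green": green, "blue": blue}, canvas)


def make_duochrome(spec: DuochromeSpec, canvas: CanvasSpec) -> TriPrimaryImage:
    """Blue (or green) disk within a red annulus, black gap and outlines.

    Defaults follow the TCA alignment target: 130-px (~0.5 deg) disk, 10-px
    gap and outline widths.  ``disk_offset_px`` displaces the disk (and only
    the disk) in pixels; +x right, +y up.
    """
    pitch = canvas.pixel_pitch_arcmin
    r_disk = spec.disk_diameter_px / 2.0 * pitch
    gap = spec.line_px * pitch
    r_in = r_disk + gap
    r_out = r_in + spec.annulus_width_px * pitch
    r_limit = canvas.field_deg * ARCMIN_PER_DEG / 2.0
    if r_out + spec.line_px * pitch > r_limit:
        raise ValueError("disk + annulus do not fit inside the visible field")
    dx, dy = (v * pitch for v in spec.disk_offset_px)

    def disk(x, y):
        return (((x - dx) ** 2 + (y - dy) ** 2) <= r_disk**2).astype(float)

    def annulus(x, y):
        r2 = x**2 + y**2
        return ((r2 >= r_in**2) & (r2 <= r_out**2)).astype(float)

    disk_map = _draw(canvas, disk)
    red = _draw(canvas, annulus)
    planes = {"red": red, "green": np.zeros_like(red), "blue": np.zeros_like(red)}
    planes[spec.disk_primary] = disk_map
    return _apply_field(planes, canvas)


def make_dichoptic_bars(
    spec: DichopticBarsSpec, canvas: CanvasSpec
) -> tuple[TriPrimaryImage, TriPrimaryImage]:
    """Left/right-eye images of a red bar over a blue bar with disparity.

    The red bar sits above the (vertical-gap-separated) blue bar; both are
    ``bar_width x bar_length`` arcmin vertical bars.  The blue bar's
    horizontal position differs between the eyes by ``disparity_arcmin``,
    split symmetrically: positive disparity is crossed (blue displaced
    rightward in the left eye and leftward in the right), i.e. blue nearer.
    """
    if abs(spec.disparity_arcmin) >= canvas.field_deg * ARCMIN_PER_DEG:
        raise ValueError("disparity exceeds the field")
    w, L, g = spec.bar_width_arcmin, spec.bar_length_arcmin, spec.gap_arcmin

    def bar(x, y, cx, cy):
        return (
            (np.abs(x - cx) <= w / 2.0) & (np.abs(y - cy) <= L / 2.0)
        ).astype(float)

    y_red = (L + g) / 2.0
    y_blue = -(L + g) / 2.0

    def eye_image(blue_dx):
        red = _draw(canvas, lambda x, y: bar(x, y, 0.0, y_red))
        blue = _draw(canvas, lambda x, y: bar(x, y, blue_dx, y_blue))
        return _apply_field(
            {"red": red, "green": np.zeros_like(red), "blue": blue}, canvas
        )

    half = spec.disparity_arcmin / 2.0
    return eye_image(+half), eye_image(-half)


def make_voronoi(spec: VoronoiSpec, rng_seed: int, canvas: CanvasSpec) -> TriPrimaryImage:
    """Nearest-seed Voronoi partition with random per-cell luminances.

    Deterministic for a fixed ``rng_seed``.  Cells are filled in a single
    primary on black; the pattern is evaluated at display resolution (cell
    structure is much coarser than a pixel).
    """
    rng = np.random.default_rng(rng_seed)
    r = canvas.field_deg * ARCMIN_PER_DEG / 2.0
    # rejection-sample seed points inside the circular field
    pts = []
    while len(pts) < spec.seed_count:
        cand = rng.uniform(-r, r, size=(spec.seed_count * 2, 2))
        cand = cand[np.hypot(cand[:, 0], cand[:, 1]) <= r]
        pts.extend(cand.tolist())
    pts = np.array(pts[: spec.seed_count])
    lum = rng.uniform(*spec.luminance_range, size=spec.seed_count)

    x, y = canvas.axes_arcmin()
    xx, yy = np.meshgrid(x, -x)  # rows grow downward
    _, labels = cKDTree(pts).query(np.column_stack([xx.ravel(), yy.ravel()]))
    plane = lum[labels].reshape(xx.shape)
    planes = {
        "red": np.zeros_like(plane),
        "green": np.zeros_like(plane),
        "blue": np.zeros_like(plane),
    }
    planes[spec.primary] = plane
    return _apply_field(planes, canvas)
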