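"""Colour spaces and the ΔE contrast metric.

All kinetic analysis in this package reduces a region of pixels to one
colour per frame and tracks how far that colour has moved from a reference
frame.  Distance is measured in CIE 1976 L*a*b*, a perceptually uniform
space: a change of 10 units along any axis is (approximately) equally
visible.  ΔE is the plain Euclidean distance between two L*a*b* points
(the CIE76 variant) — a colour-agnostic magnitude of colour change.

Conversions follow the published standards exactly: 8-bit sRGB is decoded
per IEC 61966-2-1, mapped to CIE XYZ under the D65 illuminant and the 2°
standard observer, and then to L*a*b* with the exact rational constants of
the CIE definition (delta = 6/29), not the truncated ``7.787`` shortcut
found in some implementations.  HSV uses the standard hexcone model.
"""

from __future__ import annotations

from typing import Iterable, NamedTuple

import numpy as np
from skimage.color import rgb2hsv


class RgbTriple(NamedTuple):
    """One colour as sRGB channels in [0, 255].

    Channels are conceptually 8-bit but stored as floats so that averaged
    colours keep fractional precision (no premature re-quantisation).
    """

    r: float
    g: float
    b: float


class LabTriple(NamedTuple):
    """One colour in CIE 1976 L*a*b* (D65, 2° observer).

    ``L`` is lightness in [0, 100]; ``a`` runs green (−) to red (+);
    ``b`` runs blue (−) to yellow (+).
    """

    L: float
    a: float
    b: float


class HsvTriple(NamedTuple):
    """One colour as hue (degrees, [0, 360)), saturation and value in [0, 1]."""

    h: float
    s: float
    v: float


# sRGB (linear) -> CIE XYZ, D65 / 2 degree observer, and the D65 white point.
_XYZ_FROM_LINEAR_RGB = np.array(
    [
        [0.412453, 0.357580, 0.180423],
        [0.212671, 0.715160, 0.072169],
        [0.019334, 0.119193, 0.950227],
    ]
)
_D65_WHITE = np.array([0.95047, 1.0, 1.08883])

_DELTA = 6.0 / 29.0  # CIE Lab linear-segment breakpoint


def _validate_rgb(arr: np.ndarray) -> np.ndarray:
    arr = np.asarray(arr, dtype=float)
    if arr.shape[-1] != 3:
        raise ValueError("RGB input must have 3 channels in the last axis")
    if not np.all(np.isfinite(arr)):
        raise ValueError("RGB channels must be finite")
    if arr.min(initial=0.0) < 0.0 or arr.max(initial=0.0) > 255.0:
        raise ValueError("RGB channels must lie in [0, 255]")
    return arr


def srgb_to_lab_array(rgb: np.ndarray) -> np.ndarray:
    """Vectorised sRGB (0–255) → CIE L*a*b*; last axis holds the channels."""
    v = _validate_rgb(rgb) / 255.0
    lin = np.where(v <= 0.04045, v / 12.92, ((v + 0.055) / 1.055) ** 2.4)
    xyz = lin @ _XYZ_FROM_LINEAR_RGB.T
    t = xyz / _D65_WHITE
    f = np.where(t > _DELTA**3, np.cbrt(t), t / (3.0 * _DELTA**2) + 4.0 / 29.0)
    fx, fy, fz = f[..., 0], f[..., 1], f[..., 2]
    return np.stack([116.0 * fy - 16.0, 500.0 * (fx - fy), 200.0 * (fy - fz)], axis=-1)


def srgb_to_hsv_array(rgb: np.ndarray) -> np.ndarray:
    """Vectorised sRGB (0–255) → HSV with hue in degrees."""
    v = _validate_rgb(rgb) / 255.0
    hsv = rgb2hsv(v.reshape(-1, 1, 3)).reshape(v.shape)
    hsv[..., 0] *= 360.0
    return hsv


def srgb_to_lab(c: RgbTriple) -> LabTriple:
    """Convert one sRGB colour to CIE L*a*b* (D65, 2°)."""
    return LabTriple(*srgb_to_lab_array(np.asarray(c, dtype=float)))


def srgb_to_hsv(c: RgbTriple) -> HsvTriple:
    """Convert one sRGB colour to HSV (hexcone model, hue in degrees)."""
    return HsvTriple(*srgb_to_hsv_array(np.asarray(c, dtype=float)))


def delta_e(x: LabTriple, y: LabTriple) -> float:
    """CIE76 colour difference: Euclidean distance between two Lab points."""
    return float(np.linalg.norm(np.subtract(x, y)))


def delta_e_array(lab: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """ΔE of each Lab row against a single reference Lab point."""
    lab = np.asarray(lab, dtype=float)
    return np.linalg.norm(lab - np.asarray(reference, dtype=float), axis=-1)


def mean_colour(pixels: Iterable[RgbTriple] | np.ndarray) -> RgbTriple:
    """Arithmetic per-channel mean of a pixel collection, in RGB.

    Averaging happens in RGB *before* any colour-space conversion; the mean
    keeps real-valued channels.  Raises on an empty collection.
    """
    arr = np.asarray(list(pixels) if not isinstance(pixels, np.ndarray) else pixels, dtype=float)
    if arr.size == 0:
        raise ValueError("cannot average an empty pixel collection")
    arr = _validate_rgb(arr.reshape(-1, 3))
    return RgbTriple(*arr.mean(axis=0))
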