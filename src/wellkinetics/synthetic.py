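"""Synthetic plate videos with programmed, analytically known kinetics.

The generator renders a plate of circular wells on a uniform background.
Each well's colour follows a programmed trajectory between two sRGB
endpoints, driven by a monotone mixing function m(t) with

    c(t) = colour_end + (colour_start − colour_end) · m(t)

The available models emulate the chemistries this kind of imaging is used
for: ``exponential_decay`` (dye decolourisation at rate k, optionally
lagged), ``logistic`` (sigmoidal colour change with a midpoint and
steepness, e.g. autocatalytic reddening), ``step``, ``constant``, and
``turbidity_clear`` (settling of suspended solid whose initial colour
offset scales with an amplitude, so the area under the resulting ΔE curve
grows with the amount of solid).

Per-pixel i.i.d. Gaussian noise and an optional saturated white glare disk
can be injected; a seed fixes all randomness.  The companion
``analytic_summary`` evaluates the same noiseless trajectory densely
through the colour pipeline and extracts endpoint / induction / AUC ground
truth from the continuous curve, so every downstream stage can be checked
against closed-form expectations.

Rendered channels are rounded to 8-bit by default; the ``quantise="none"``
policy keeps continuous channel values for noiseless recovery studies where
the ±1-count rounding floor would dominate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import imageio.v3 as iio
import numpy as np

from . import colour
from .kinetics import endpoint_from_gradient
from .roi import GridSpec, build_masks, masks_overlap
from .video_io import FrameRecord

MODELS = ("exponential_decay", "logistic", "step", "constant", "turbidity_clear")


@dataclass(frozen=True)
class WellKineticSpec:
    """Programmed colour trajectory for one well.

    ``rate`` is k (s⁻¹) for exponential/turbidity models and the logistic
    steepness s (s⁻¹); ``t_mid`` is the logistic midpoint; ``lag`` delays
    exponential models and is the switching time of the step model;
    ``amplitude`` in [0, 1] scales the initial turbidity offset.
    """

    model: str
    colour_start: tuple[float, float, float]
    colour_end: tuple[float, float, float]
    rate: float = 0.0
    t_mid: float = 0.0
    lag: float = 0.0
    amplitude: float = 1.0

    def __post_init__(self) -> None:
        if self.model not in MODELS:
            raise ValueError(f"unknown kinetic model {self.model!r}; expected one of {MODELS}")
        if self.model in ("exponential_decay", "logistic", "turbidity_clear") and self.rate <= 0:
            raise ValueError(f"model {self.model!r} requires a positive rate")
        if self.lag < 0:
            raise ValueError("lag must be non-negative")
        if not 0.0 <= self.amplitude <= 1.0:
            raise ValueError("amplitude must lie in [0, 1]")

    def mixing(self, t: np.ndarray) -> np.ndarray:
        """m(t): 1 at the start colour, decaying towards 0 (the end colour)."""
        t = np.asarray(t, dtype=float)
        if self.model == "constant":
            return np.ones_like(t)
        if self.model == "step":
            return np.where(t < self.lag, 1.0, 0.0)
        if self.model == "exponential_decay":
            return np.exp(-self.rate * np.maximum(0.0, t - self.lag))
        if self.model == "logistic":
            return 1.0 / (1.0 + np.exp(self.rate * (t - self.t_mid)))
        # turbidity_clear: amplitude-scaled settling
        return self.amplitude * np.exp(-self.rate * np.maximum(0.0, t - self.lag))

    def colour_at(self, t: np.ndarray) -> np.ndarray:
        """Continuous (unquantised) RGB trajectory, shape (..., 3)."""
        m = self.mixing(t)[..., None]
        start = np.asarray(self.colour_start, dtype=float)
        end = np.asarray(self.colour_end, dtype=float)
        return end + (start - end) * m


@dataclass(frozen=True)
class GlareSpec:
    """A saturated white disk burnt into every frame (specular highlight)."""

    centre: tuple[float, float]  # (x, y) pixels
    radius: float


@dataclass(frozen=True)
class PlateVideoSpec:
    """Full description of a synthetic plate video."""

    grid: GridSpec
    wells: dict[str, WellKineticSpec]
    height: int
    width: int
    fps: float = 25.0
    duration_s: float = 60.0
    background: tuple[float, float, float] = (210.0, 210.0, 205.0)
    noise_sd: float = 0.0
    glare: GlareSpec | None = None
    seed: int = 0
    quantise: str = "round"  # "round" (8-bit) or "none" (continuous)

    def __post_init__(self) -> None:
        missing = set(self.grid.labels()) - set(self.wells)
        if missing:
            raise ValueError(f"no kinetic spec for wells: {sorted(missing)}")
        if self.fps <= 0 or self.duration_s <= 0:
            raise ValueError("fps and duration must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.quantise not in ("round", "none"):
            raise ValueError("quantise must be 'round' or 'none'")

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_s * self.fps))

    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.fps


def iter_render(spec: PlateVideoSpec) -> Iterator[FrameRecord]:
    """Lazily render frames (memory-light for long videos)."""
    masks = build_masks(spec.grid, spec.height, spec.width)
    overlapping, pairs = masks_overlap(masks)
    if overlapping:
        raise ValueError(f"well disks overlap: {pairs}")
    rng = np.random.default_rng(spec.seed)
    base = np.empty((spec.height, spec.width, 3), dtype=float)
    base[:] = np.asarray(spec.background, dtype=float)
    if spec.glare is not None:
        gx, gy = spec.glare.centre
        rr, cc = np.mgrid[0 : spec.height, 0 : spec.width]
        glare_mask = (cc - gx) ** 2 + (rr - gy) ** 2 <= spec.glare.radius**2
    else:
        glare_mask = None
    specs = [spec.wells[m.label] for m in masks]
    for k, t in enumerate(spec.times()):
        img = base.copy()
        for m, wspec in zip(masks, specs):
            img[m.rows, m.cols] = wspec.colour_at(np.asarray(t))
        if glare_mask is not None:
            img[glare_mask] = 255.0
        if spec.noise_sd > 0:
            img += rng.normal(0.0, spec.noise_sd, img.shape)
        np.clip(img, 0.0, 255.0, out=img)
        if spec.quantise == "round":
            img = np.rint(img).astype(np.uint8)
        yield FrameRecord(index=k, timestamp=t, image=img)


def render(spec: PlateVideoSpec) -> list[FrameRecord]:
    """Render the whole video into memory; identical seeds give identical frames."""
    return list(iter_render(spec))


def write_image_sequence(spec: PlateVideoSpec, out_dir: str | Path) -> Path:
    """Render to a numbered 8-bit PNG sequence plus a ground-truth JSON.

    Continuous-valued frames are rounded at write time (PNG is integral).
    Returns the output directory.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for frame in iter_render(spec):
        img = frame.image
        if img.dtype != np.uint8:
            img = np.rint(img).astype(np.uint8)
        iio.imwrite(out_dir / f"frame_{frame.index:06d}.png", img)
    truth = analytic_summary(spec)
    meta = {
        "fps": spec.fps,
        "n_frames": spec.n_frames,
        "duration_s": spec.duration_s,
        "seed": spec.seed,
        "noise_sd": spec.noise_sd,
        "wells": truth,
    }
    (out_dir / "ground_truth.json").write_text(json.dumps(meta, indent=2))
    return out_dir


def analytic_delta_e(wspec: WellKineticSpec, t: np.ndarray) -> np.ndarray:
    """Noise-free continuous ΔE(t) of a well versus its own t = 0 colour."""
    rgb = wspec.colour_at(np.asarray(t, dtype=float))
    lab = colour.srgb_to_lab_array(np.clip(rgb, 0.0, 255.0))
    return colour.delta_e_array(lab, lab[0])


def analytic_summary(
    spec: PlateVideoSpec,
    gradient_threshold: float = 0.05,
    persistence_s: float = 10.0,
    dense_factor: int = 10,
) -> dict[str, dict]:
    """Ground truth per well from the continuous noiseless trajectory.

    ΔE(t) is evaluated through the colour pipeline on a grid ``dense_factor``
    times finer than the video sampling; endpoint (same activation +
    persistence rule as the detector, at the given threshold), induction
    (time of maximum |dΔE/dt|), max rate and trapezoidal AUC are read from
    that curve.  Resolution of the reported times is the dense-grid step.
    """
    if spec.n_frames < 2:  # a single frame has no kinetics
        return {
            label: {
                "model": spec.wells[label].model,
                "rate": spec.wells[label].rate,
                "amplitude": spec.wells[label].amplitude,
                "endpoint_s": None,
                "induction_s": None,
                "max_rate": 0.0,
                "auc": 0.0,
                "delta_e_final": 0.0,
            }
            for label in spec.grid.labels()
        }
    n = spec.n_frames * dense_factor
    t = np.linspace(0.0, spec.times()[-1], n)
    out: dict[str, dict] = {}
    for label in spec.grid.labels():
        wspec = spec.wells[label]
        de = analytic_delta_e(wspec, t)
        grad = np.gradient(de, t)
        endpoint = endpoint_from_gradient(t, grad, gradient_threshold, persistence_s)
        if np.allclose(de, de[0]):
            induction = None
        else:
            induction = float(t[int(np.argmax(np.abs(grad)))])
        out[label] = {
            "model": wspec.model,
            "rate": wspec.rate,
            "amplitude": wspec.amplitude,
            "endpoint_s": endpoint,
            "induction_s": induction,
            "max_rate": float(np.max(grad)),
            "auc": float(np.trapezoid(de, t)),
            "delta_e_final": float(de[-1]),
        }
    return out
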