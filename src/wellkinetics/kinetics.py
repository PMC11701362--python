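"""Per-well colour kinetics: ΔE profiles, endpoints, induction, AUC.

The pipeline reduces each circular ROI to its mean RGB colour per frame,
converts that mean to L*a*b* and HSV, and tracks ΔE (CIE76) against the
first frame of the same ROI — each well is compared to its own start, never
to another well.

Endpoint ("plateau") analysis declares a reaction finished when the rate of
colour change d(ΔE)/dt falls — and stays — below a threshold, by default
0.05 ΔE·s⁻¹.  Two guards make that operational on real profiles: the
reaction must first *activate* (the gradient must reach the threshold at
some point — otherwise a flat pre-reaction trace would "end" at t = 0), and
the gradient must remain below threshold for a persistence window so a
momentary dip does not count as a plateau.  Both are configurable.

The induction period of a channel (e.g. the a* reddening of a nitro
reduction) is read as the time of maximum rate of change of that channel;
an alternative first-threshold-crossing definition is available.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import colour
from .roi import ROIMask
from .video_io import FrameRecord

CHANNELS = ("R", "G", "B", "L", "a", "b", "H", "S", "V", "deltaE")


@dataclass
class ColourTrace:
    """Per-ROI time series of mean colour in RGB/Lab/HSV plus the ΔE profile."""

    label: str
    times: np.ndarray  # (n,) seconds
    rgb: np.ndarray  # (n, 3) mean colour, real-valued channels in [0, 255]
    lab: np.ndarray  # (n, 3)
    hsv: np.ndarray  # (n, 3), hue in degrees
    delta_e: np.ndarray  # (n,) CIE76 distance to the reference frame

    def __post_init__(self) -> None:
        n = len(self.times)
        if not (len(self.rgb) == len(self.lab) == len(self.hsv) == len(self.delta_e) == n):
            raise ValueError("all trace series must have equal length")

    def __len__(self) -> int:
        return len(self.times)

    def channel(self, name: str) -> np.ndarray:
        """Return one named channel series (R,G,B,L,a,b,H,S,V or deltaE)."""
        if name == "deltaE":
            return self.delta_e
        try:
            i = CHANNELS.index(name)
        except ValueError:
            raise KeyError(f"unknown channel {name!r}; expected one of {CHANNELS}") from None
        return (self.rgb, self.lab, self.hsv)[i // 3][:, i % 3]


@dataclass(frozen=True)
class EndpointConfig:
    """Plateau-detection parameters.

    gradient_threshold : ΔE·s⁻¹ below which the reaction counts as flat
        (default 0.05).
    smoothing_window : odd moving-average width in frames applied to ΔE
        before differentiation (default 25, i.e. 1 s at 25 fps).
    persistence_s : seconds the gradient must stay below threshold.
    """

    gradient_threshold: float = 0.05
    smoothing_window: int = 25
    persistence_s: float = 10.0

    def __post_init__(self) -> None:
        if self.gradient_threshold <= 0:
            raise ValueError("gradient_threshold must be positive")
        if self.smoothing_window < 1 or self.smoothing_window % 2 == 0:
            raise ValueError("smoothing_window must be an odd positive integer")
        if self.persistence_s < 0:
            raise ValueError("persistence_s must be non-negative")


@dataclass(frozen=True)
class KineticSummary:
    """Headline numbers for one well."""

    label: str
    endpoint_s: float | None
    induction_s: float | None
    max_rate: float  # ΔE·s⁻¹
    auc: float  # ΔE·s
    complete: bool


def extract_traces(
    frames: Iterable[FrameRecord],
    masks: Sequence[ROIMask],
    reference_index: int = 0,
    per_pixel_conversion: bool = False,
) -> list[ColourTrace]:
    """Mean colour per ROI per frame, in all three spaces, plus ΔE.

    By default each ROI is averaged in RGB and the *mean* is converted to
    Lab/HSV.  With ``per_pixel_conversion`` the conversion happens per pixel
    and Lab/HSV are averaged in their own spaces (the RGB mean is reported
    either way).  ΔE is computed against the reference frame (default: the
    first) of the same ROI.
    """
    if not masks:
        raise ValueError("need at least one ROI mask")
    times: list[float] = []
    means: list[list[np.ndarray]] = [[] for _ in masks]
    pp_lab: list[list[np.ndarray]] = [[] for _ in masks]
    pp_hsv: list[list[np.ndarray]] = [[] for _ in masks]
    shape_checked = False
    for frame in frames:
        img = np.asarray(frame.image, dtype=float)
        if not shape_checked:
            h, w = img.shape[:2]
            for m in masks:
                if len(m) and (m.rows.max() >= h or m.cols.max() >= w):
                    raise ValueError(f"mask {m.label} lies outside the {h}x{w} frame")
            shape_checked = True
        times.append(frame.timestamp)
        for i, m in enumerate(masks):
            px = img[m.rows, m.cols, :3]
            means[i].append(px.mean(axis=0))
            if per_pixel_conversion:
                pp_lab[i].append(colour.srgb_to_lab_array(px).mean(axis=0))
                pp_hsv[i].append(colour.srgb_to_hsv_array(px).mean(axis=0))
    if not times:
        raise ValueError("no frames supplied")
    if not 0 <= reference_index < len(times):
        raise ValueError("reference_index outside the frame range")
    t = np.asarray(times)
    traces = []
    for i, m in enumerate(masks):
        rgb = np.vstack(means[i])
        if per_pixel_conversion:
            lab = np.vstack(pp_lab[i])
            hsv = np.vstack(pp_hsv[i])
        else:
            lab = colour.srgb_to_lab_array(rgb)
            hsv = colour.srgb_to_hsv_array(rgb)
        de = colour.delta_e_array(lab, lab[reference_index])
        traces.append(ColourTrace(label=m.label, times=t, rgb=rgb, lab=lab, hsv=hsv, delta_e=de))
    return traces


def smooth(series: np.ndarray, window: int) -> np.ndarray:
    """Centred moving average; the window shrinks symmetrically at the edges.

    Length-preserving.  A window of 1 is the identity; an affine series is
    left unchanged everywhere (symmetric windows average out the slope).
    """
    series = np.asarray(series, dtype=float)
    n = len(series)
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be an odd positive integer")
    if window > n:
        raise ValueError(f"window {window} exceeds series length {n}")
    if window == 1:
        return series.copy()
    half = window // 2
    csum = np.concatenate([[0.0], np.cumsum(series)])
    idx = np.arange(n)
    h = np.minimum(half, np.minimum(idx, n - 1 - idx))
    lo, hi = idx - h, idx + h + 1
    return (csum[hi] - csum[lo]) / (hi - lo)


def gradient(series: np.ndarray, times: np.ndarray) -> np.ndarray:
    """d(series)/dt: central differences inside, one-sided at the ends."""
    series = np.asarray(series, dtype=float)
    times = np.asarray(times, dtype=float)
    if len(series) < 2:
        raise ValueError("need at least two samples to differentiate")
    if len(series) != len(times):
        raise ValueError("series and times must have equal length")
    return np.gradient(series, times)


def _smoothed_gradient(values: np.ndarray, times: np.ndarray, window: int) -> np.ndarray:
    return gradient(smooth(values, window), times)


def endpoint_from_gradient(
    times: np.ndarray, grad: np.ndarray, threshold: float, persistence_s: float
) -> float | None:
    """Shared plateau rule for measured and analytic profiles.

    The profile must first activate (gradient ≥ threshold); the endpoint is
    the earliest later time at which the gradient drops below threshold and
    stays below it for ``persistence_s`` seconds of recorded data.
    """
    above = np.flatnonzero(grad >= threshold)
    if len(above) == 0:
        return None  # never activated
    start = above[0] + 1
    below = grad < threshold
    i = start
    n = len(times)
    while i < n:
        if not below[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and below[j + 1]:
            j += 1
        # run [i, j] stays below threshold; it must cover the persistence window
        if times[j] - times[i] >= persistence_s:
            return float(times[i])
        i = j + 1
    return None


def detect_endpoint(trace: ColourTrace, cfg: EndpointConfig = EndpointConfig()) -> float | None:
    """Plateau endpoint of a ΔE profile, or None if the reaction never
    activates or never settles for the persistence window."""
    if len(trace) < cfg.smoothing_window:
        raise ValueError("trace shorter than the smoothing window")
    grad = _smoothed_gradient(trace.delta_e, trace.times, cfg.smoothing_window)
    return endpoint_from_gradient(trace.times, grad, cfg.gradient_threshold, cfg.persistence_s)


def induction_time(
    trace: ColourTrace,
    channel: str = "deltaE",
    smoothing_window: int = 25,
    method: str = "max_rate",
    threshold: float | None = None,
) -> float | None:
    """Induction period of one colour channel.

    ``max_rate`` (default): the time at which the smoothed rate of change of
    the channel is largest in magnitude.  ``threshold``: the earliest time
    at which that rate first reaches ``threshold``.  None for a constant
    series.
    """
    series = trace.channel(channel)
    if len(series) < max(2, smoothing_window):
        raise ValueError("trace too short for induction analysis")
    if np.allclose(series, series[0]):
        return None
    grad = np.abs(_smoothed_gradient(series, trace.times, smoothing_window))
    if method == "max_rate":
        return float(trace.times[int(np.argmax(grad))])
    if method == "threshold":
        if threshold is None or threshold <= 0:
            raise ValueError("threshold method needs a positive threshold")
        hit = np.flatnonzero(grad >= threshold)
        return float(trace.times[hit[0]]) if len(hit) else None
    raise ValueError(f"unknown induction method {method!r}")


def max_rate(trace: ColourTrace, smoothing_window: int = 25) -> float:
    """Largest smoothed d(ΔE)/dt over the trace, in ΔE·s⁻¹."""
    grad = _smoothed_gradient(trace.delta_e, trace.times, smoothing_window)
    return float(np.max(grad))


def auc(trace: ColourTrace) -> float:
    """Trapezoidal area under the ΔE–time curve over the whole recording."""
    if len(trace) < 2:
        raise ValueError("need at least two frames for an AUC")
    return float(np.trapezoid(trace.delta_e, trace.times))


def summarise(
    traces: Sequence[ColourTrace],
    cfg: EndpointConfig = EndpointConfig(),
    induction_channel: str = "deltaE",
) -> list[KineticSummary]:
    """Endpoint, induction, max rate and AUC for every trace."""
    out = []
    for t in traces:
        ep = detect_endpoint(t, cfg)
        out.append(
            KineticSummary(
                label=t.label,
                endpoint_s=ep,
                induction_s=induction_time(t, induction_channel, cfg.smoothing_window),
                max_rate=max_rate(t, cfg.smoothing_window),
                auc=auc(t),
                complete=ep is not None,
            )
        )
    return out


def summaries_to_frame(summaries: Sequence[KineticSummary]) -> pd.DataFrame:
    """Tabulate summaries; absent endpoints/inductions become empty cells."""
    return pd.DataFrame(
        {
            "label": [s.label for s in summaries],
            "endpoint_s": [s.endpoint_s for s in summaries],
            "induction_s": [s.induction_s for s in summaries],
            "max_rate": [s.max_rate for s in summaries],
            "auc": [s.auc for s in summaries],
            "complete": [s.complete for s in summaries],
        }
    )
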