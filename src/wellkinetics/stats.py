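"""Linking colour kinetics to offline measurements.

A camera samples colour at video rate (25 fps) while an offline assay such
as HPLC yields a handful of points.  To ask *which* colour parameter best
tracks the assay, each channel series is interpolated onto the assay's
sampling times and scored by mutual information (MI) — a dependence measure
that assumes no linearity, so a channel related to conversion through any
monotone response still scores highly.  Channels are then ranked, with
scores normalised to the best channel, and the conventional linear
ΔE–conversion fit is available alongside.

The MI estimator is the plug-in formula on an equal-frequency (quantile)
joint histogram with ⌈√n⌉ bins per variable.  Quantile bins depend only on
ranks, which is what buys invariance under strictly monotone transforms of
either variable; with the short series offline assays produce (n ≈ 5–15)
this rank-based estimator is far better behaved than k-NN alternatives.
MI is reported in nats and clamped at zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .kinetics import CHANNELS, ColourTrace


@dataclass(frozen=True)
class ExternalSeries:
    """A sparse offline measurement series, e.g. HPLC conversion vs time."""

    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if len(t) != len(v):
            raise ValueError("times and values must have equal length")
        if len(t) and not np.all(np.diff(t) > 0):
            raise ValueError("external sample times must be strictly increasing")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return len(self.times)


@dataclass(frozen=True)
class MIRanking:
    """Channels ordered by raw MI (nats); scores normalised to the maximum."""

    parameters: tuple[str, ...]
    raw_mi: tuple[float, ...]
    normalised_mi: tuple[float, ...]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "parameter": self.parameters,
                "raw_mi_nats": self.raw_mi,
                "normalised_mi": self.normalised_mi,
                "rank": np.arange(1, len(self.parameters) + 1),
            }
        )

    def top(self) -> str:
        return self.parameters[0]


def read_external_csv(path: str | Path) -> ExternalSeries:
    """Read a 2-column (time_s, value) CSV into an ExternalSeries."""
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError("external series CSV needs two columns: time_s, value")
    return ExternalSeries(times=df.iloc[:, 0].to_numpy(), values=df.iloc[:, 1].to_numpy())


def align(times: np.ndarray, values: np.ndarray, external_times: np.ndarray) -> np.ndarray:
    """Linearly interpolate a colour series onto the external sample times.

    The sparse series dictates the sample support; querying outside the
    recorded span is an error rather than an extrapolation.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    q = np.asarray(external_times, dtype=float)
    if len(q) == 0:
        raise ValueError("no external sample times")
    if q.min() < times[0] or q.max() > times[-1]:
        raise ValueError(
            f"external times [{q.min():g}, {q.max():g}] fall outside the recorded "
            f"span [{times[0]:g}, {times[-1]:g}]"
        )
    return np.interp(q, times, values)


def _quantile_bins(x: np.ndarray, n_bins: int) -> np.ndarray:
    # Equal-frequency binning via mid-ranks: depends only on the ordering,
    # hence invariant under strictly monotone transforms.
    r = rankdata(x, method="average")
    b = np.floor((r - 0.5) / len(x) * n_bins).astype(int)
    return np.clip(b, 0, n_bins - 1)


def mutual_information(x: Sequence[float], y: Sequence[float]) -> float:
    """Plug-in MI (nats) on an equal-frequency joint histogram.

    Bins per variable: ⌈√n⌉.  Requires n ≥ 4; clamped at zero.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    n = len(x)
    if n < 4:
        raise ValueError("mutual information needs at least 4 samples")
    n_bins = math.isqrt(n - 1) + 1  # ceil(sqrt(n))
    bx = _quantile_bins(x, n_bins)
    by = _quantile_bins(y, n_bins)
    joint = np.zeros((n_bins, n_bins))
    np.add.at(joint, (bx, by), 1.0)
    joint /= n
    px = joint.sum(axis=1, keepdims=True)
    py = joint.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = joint * np.log(joint / (px * py))
    return max(0.0, float(np.nansum(terms)))


def rank_parameters(
    trace: ColourTrace,
    external: ExternalSeries,
    channels: Sequence[str] = CHANNELS,
) -> MIRanking:
    """MI of every colour channel against the external values, ranked.

    Scores are normalised by the maximum raw MI; ties break alphabetically
    by parameter name.  If every channel scores zero (e.g. all constant) the
    ranking is returned with all-zero normalised scores.
    """
    if len(external) < 4:
        raise ValueError("external series too short for MI ranking (need >= 4 points)")
    scores = {}
    for ch in channels:
        aligned = align(trace.times, trace.channel(ch), external.times)
        scores[ch] = mutual_information(aligned, external.values)
    ordered = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
    raw = tuple(v for _, v in ordered)
    top = raw[0]
    norm = tuple(v / top for v in raw) if top > 0 else tuple(0.0 for _ in raw)
    return MIRanking(
        parameters=tuple(k for k, _ in ordered), raw_mi=raw, normalised_mi=norm
    )


def linear_fit(x: Sequence[float], y: Sequence[float]) -> tuple[float, float, float]:
    """Ordinary least squares y = slope·x + intercept, plus r².

    Constant x is an error; constant y returns slope 0 and r² = 0 by
    convention (there is no variance to explain).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 2:
        raise ValueError("linear fit needs two equal-length series of length >= 2")
    xc = x - x.mean()
    sxx = float(xc @ xc)
    if sxx == 0.0:
        raise ValueError("x is constant; slope is undefined")
    slope = float(xc @ (y - y.mean())) / sxx
    intercept = float(y.mean() - slope * x.mean())
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        return 0.0, float(y.mean()), 0.0
    ss_res = float(np.sum((y - slope * x - intercept) ** 2))
    return slope, intercept, 1.0 - ss_res / ss_tot
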