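"""Independent reference implementations used only to check the package.

These are deliberately written scalar-by-scalar, straight from the published
definitions, and share no code with the implementation under test.
"""

from __future__ import annotations

import math

import numpy as np


def cie_lab_oracle(r: int, g: int, b: int) -> tuple[float, float, float]:
    """sRGB (IEC 61966-2-1) → XYZ (D65, 2°) → CIE 1976 L*a*b*, one pixel."""

    def decode(u: float) -> float:
        u /= 255.0
        return u / 12.92 if u <= 0.04045 else ((u + 0.055) / 1.055) ** 2.4

    rl, gl, bl = decode(r), decode(g), decode(b)
    x = 0.412453 * rl + 0.357580 * gl + 0.180423 * bl
    y = 0.212671 * rl + 0.715160 * gl + 0.072169 * bl
    z = 0.019334 * rl + 0.119193 * gl + 0.950227 * bl

    def f(t: float) -> float:
        delta = 6.0 / 29.0
        return t ** (1.0 / 3.0) if t > delta**3 else t / (3 * delta**2) + 4.0 / 29.0

    fx, fy, fz = f(x / 0.95047), f(y / 1.0), f(z / 1.08883)
    return 116.0 * fy - 16.0, 500.0 * (fx - fy), 200.0 * (fy - fz)


def disk_membership_oracle(
    cx: float, cy: float, radius: float, height: int, width: int
) -> set[tuple[int, int]]:
    """Brute-force scan of every frame pixel against the ≤ radius rule."""
    out = set()
    for row in range(height):
        for col in range(width):
            if math.hypot(col - cx, row - cy) <= radius:
                out.add((row, col))
    return out


def plugin_mi_oracle(bx: np.ndarray, by: np.ndarray) -> float:
    """Plug-in MI (nats) from pre-binned labels, summed term by term."""
    n = len(bx)
    mi = 0.0
    for i in set(bx.tolist()):
        for j in set(by.tolist()):
            pij = np.sum((bx == i) & (by == j)) / n
            if pij > 0:
                pi = np.sum(bx == i) / n
                pj = np.sum(by == j) / n
                mi += pij * math.log(pij / (pi * pj))
    return mi


def ols_oracle(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Closed-form simple OLS: slope, intercept, r²."""
    n = len(x)
    sx, sy = x.sum(), y.sum()
    sxx, sxy = (x * x).sum(), (x * y).sum()
    slope = (n * sxy - sx * sy) / (n * sxx - sx * sx)
    intercept = (sy - slope * sx) / n
    yhat = slope * x + intercept
    ss_res = ((y - yhat) ** 2).sum()
    ss_tot = ((y - y.mean()) ** 2).sum()
    return slope, intercept, 1 - ss_res / ss_tot
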