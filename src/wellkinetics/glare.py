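"""Glare quality control via pixel dispersion in the L*–b* plane.

Specular glare shows up as a subpopulation of bright, washed-out pixels
inside an otherwise uniform well.  Converting every ROI pixel (not the
mean) to L*a*b* and scattering the points in the lightness / blue–yellow
plane makes this visible: a tight cluster means a uniform, glare-free
image, a smeared or bimodal cloud means glare.  To make "tight" testable
the cloud is summarised by a single scalar — the root-mean-square Euclidean
distance of the (L*, b*) points from their centroid.  The a* axis is
deliberately excluded so the scalar matches the two-dimensional plane being
plotted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .colour import srgb_to_lab_array
from .roi import ROIMask


@dataclass(frozen=True)
class GlareReport:
    """Per-pixel (L*, b*) cloud for one ROI and its dispersion scalar."""

    label: str
    points: np.ndarray  # (N, 2) columns L*, b*
    centroid: tuple[float, float]
    dispersion: float  # RMS distance from centroid, 0 iff all pixels identical


def glare_scatter(frame_image: np.ndarray, mask: ROIMask) -> GlareReport:
    """Per-pixel L*–b* scatter and RMS dispersion for one ROI in one frame."""
    if len(mask) == 0:
        raise ValueError(f"mask {mask.label} is empty")
    img = np.asarray(frame_image, dtype=float)
    h, w = img.shape[:2]
    if mask.rows.max() >= h or mask.cols.max() >= w:
        raise ValueError(f"mask {mask.label} lies outside the {h}x{w} frame")
    lab = srgb_to_lab_array(img[mask.rows, mask.cols, :3])
    points = lab[:, [0, 2]]  # (L*, b*)
    centroid = points.mean(axis=0)
    dispersion = float(np.sqrt(np.mean(np.sum((points - centroid) ** 2, axis=1))))
    return GlareReport(
        label=mask.label,
        points=points,
        centroid=(float(centroid[0]), float(centroid[1])),
        dispersion=dispersion,
    )
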