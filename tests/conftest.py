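"""Shared fixtures: small synthetic plates rendered once per session."""

from __future__ import annotations

import numpy as np
import pytest

import wellkinetics as wk


def make_plate_spec(
    n_rows=1,
    n_cols=2,
    radius=10,
    models=("exponential_decay", "constant"),
    fps=5.0,
    duration_s=40.0,
    noise_sd=0.0,
    quantise="round",
    seed=0,
    glare=None,
) -> wk.PlateVideoSpec:
    """A compact plate whose wells cycle through the given kinetic models."""
    pitch = 2 * radius + 6
    origin = radius + 4
    grid = wk.GridSpec(
        n_rows, n_cols, (origin, origin), pitch, pitch, 2 * radius
    )
    height = origin + (n_rows - 1) * pitch + radius + 4
    width = origin + (n_cols - 1) * pitch + radius + 4
    wells = {}
    for i, label in enumerate(grid.labels()):
        model = models[i % len(models)]
        kwargs = dict(colour_start=(110, 45, 150), colour_end=(215, 215, 210))
        if model == "exponential_decay":
            kwargs["rate"] = 0.15
        elif model == "logistic":
            kwargs.update(rate=1.0, t_mid=duration_s / 3)
        elif model == "step":
            kwargs["lag"] = duration_s / 4
        elif model == "turbidity_clear":
            kwargs.update(rate=0.15, amplitude=0.5)
        wells[label] = wk.WellKineticSpec(model=model, **kwargs)
    return wk.PlateVideoSpec(
        grid=grid,
        wells=wells,
        height=height,
        width=width,
        fps=fps,
        duration_s=duration_s,
        noise_sd=noise_sd,
        quantise=quantise,
        seed=seed,
        glare=glare,
    )


@pytest.fixture(scope="session")
def small_plate_spec() -> wk.PlateVideoSpec:
    return make_plate_spec()


@pytest.fixture(scope="session")
def small_plate_frames(small_plate_spec) -> list[wk.FrameRecord]:
    return wk.render(small_plate_spec)


@pytest.fixture(scope="session")
def small_plate_masks(small_plate_spec) -> list[wk.ROIMask]:
    s = small_plate_spec
    return wk.build_masks(s.grid, s.height, s.width)


@pytest.fixture(scope="session")
def small_plate_traces(small_plate_frames, small_plate_masks) -> list[wk.ColourTrace]:
    return wk.extract_traces(small_plate_frames, small_plate_masks)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
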