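"""Run configuration: a flat, typed YAML file validated before any frame is read.

Every under-specified analysis parameter (smoothing window, plateau
threshold, persistence, channels exported) has an explicit default that
``wellkinetics --print-config`` prints, so nothing is hidden.  Unknown keys
are rejected outright — a typo should fail loudly, not silently fall back
to a default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .kinetics import CHANNELS, EndpointConfig
from .roi import GridSpec

_GRID_KEYS = {"n_rows", "n_cols", "origin_x", "origin_y", "pitch_x", "pitch_y", "diameter"}
_ENDPOINT_KEYS = {"gradient_threshold", "smoothing_window", "persistence_s"}
_TOP_KEYS = {
    "input",
    "fps",
    "grid",
    "endpoint",
    "channels",
    "induction_channel",
    "external_csv",
    "output_dir",
    "seed",
}


@dataclass
class RunConfig:
    """Validated configuration for one analysis run."""

    input: Path
    grid: GridSpec
    endpoint: EndpointConfig = field(default_factory=EndpointConfig)
    fps: float | None = None
    channels: tuple[str, ...] = CHANNELS
    induction_channel: str = "deltaE"
    external_csv: Path | None = None
    output_dir: Path = Path("wellkinetics_out")
    seed: int = 0

    def __post_init__(self) -> None:
        unknown = set(self.channels) - set(CHANNELS)
        if unknown:
            raise ValueError(f"unknown channels: {sorted(unknown)}")
        if self.induction_channel not in CHANNELS:
            raise ValueError(f"unknown induction channel {self.induction_channel!r}")


def default_config_yaml() -> str:
    """The full default configuration, as commented YAML."""
    return (
        "# wellkinetics run configuration (all keys shown with their defaults)\n"
        "input: path/to/video.mp4        # video file or directory of numbered images\n"
        "fps: null                       # frames per second; REQUIRED for image dirs\n"
        "grid:\n"
        "  n_rows: 4\n"
        "  n_cols: 6\n"
        "  origin_x: 30.0                # centre of well A1, pixels\n"
        "  origin_y: 30.0\n"
        "  pitch_x: 40.0                 # centre-to-centre spacing, pixels\n"
        "  pitch_y: 40.0\n"
        "  diameter: 30.0\n"
        "endpoint:\n"
        "  gradient_threshold: 0.05      # dE per second\n"
        "  smoothing_window: 25          # frames, odd (1 s at 25 fps)\n"
        "  persistence_s: 10.0           # gradient must stay below threshold this long\n"
        "channels: [R, G, B, L, a, b, H, S, V, deltaE]\n"
        "induction_channel: deltaE\n"
        "external_csv: null              # 2-column (time_s, value) offline series\n"
        "output_dir: wellkinetics_out\n"
        "seed: 0\n"
    )


def _require_mapping(obj, name: str) -> dict:
    if not isinstance(obj, dict):
        raise ValueError(f"config section {name!r} must be a mapping")
    return obj


def load_config(path: str | Path) -> RunConfig:
    """Parse and validate a YAML run configuration."""
    raw = yaml.safe_load(Path(path).read_text())
    raw = _require_mapping(raw, "top level")
    unknown = set(raw) - _TOP_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "input" not in raw or "grid" not in raw:
        raise ValueError("config must provide 'input' and 'grid'")
    g = _require_mapping(raw["grid"], "grid")
    unknown = set(g) - _GRID_KEYS
    if unknown:
        raise ValueError(f"unknown grid keys: {sorted(unknown)}")
    missing = _GRID_KEYS - set(g)
    if missing:
        raise ValueError(f"grid section missing keys: {sorted(missing)}")
    grid = GridSpec(
        n_rows=int(g["n_rows"]),
        n_cols=int(g["n_cols"]),
        origin=(float(g["origin_x"]), float(g["origin_y"])),
        pitch_x=float(g["pitch_x"]),
        pitch_y=float(g["pitch_y"]),
        diameter=float(g["diameter"]),
    )
    e = _require_mapping(raw.get("endpoint", {}), "endpoint")
    unknown = set(e) - _ENDPOINT_KEYS
    if unknown:
        raise ValueError(f"unknown endpoint keys: {sorted(unknown)}")
    endpoint = EndpointConfig(
        gradient_threshold=float(e.get("gradient_threshold", 0.05)),
        smoothing_window=int(e.get("smoothing_window", 25)),
        persistence_s=float(e.get("persistence_s", 10.0)),
    )
    fps = raw.get("fps")
    external = raw.get("external_csv")
    return RunConfig(
        input=Path(raw["input"]),
        grid=grid,
        endpoint=endpoint,
        fps=float(fps) if fps is not None else None,
        channels=tuple(raw.get("channels", CHANNELS)),
        induction_channel=str(raw.get("induction_channel", "deltaE")),
        external_csv=Path(external) if external else None,
        output_dir=Path(raw.get("output_dir", "wellkinetics_out")),
        seed=int(raw.get("seed", 0)),
    )
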