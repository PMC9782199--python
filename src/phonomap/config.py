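"""Pipeline configuration with YAML round-trip.

Defaults are the standard operating point of the pipeline: 10 kHz PCG
sampling, 20-200 Hz order-4 Butterworth band-pass, coif5 wavelet at level 7
with the sqtwolog soft threshold, ECG conditioned at a 200 Hz intermediate
rate over 0.5-40 Hz and returned at 10 kHz, consistent-mode registration,
and the blue-to-red 240-0 degree hue map at saturation 1.0 / lightness 0.5.
"""
from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .mapping import ColorMapSpec
from .preprocess import BandpassSpec, WaveletSpec


@dataclass
class EcgConfig:
    intermediate_fs: float = 200.0
    output_fs: float = 10_000.0
    low_hz: float = 0.5
    high_hz: float = 40.0


@dataclass
class FixtureConfig:
    n_rows: int = 8
    n_cols: int = 9
    spacing: float = 40.0
    origin: tuple[float, float] = (120.0, 140.0)
    n_beats: int = 10
    rr_interval: float = 1.0
    noise_sd: float = 0.01
    ecg_noise_sd: float = 0.02
    duration: float | None = None


@dataclass
class PipelineConfig:
    fs: float = 10_000.0
    bandpass: BandpassSpec = field(default_factory=BandpassSpec)
    wavelet: WaveletSpec = field(default_factory=WaveletSpec)
    ecg: EcgConfig = field(default_factory=EcgConfig)
    colormap: ColorMapSpec = field(default_factory=ColorMapSpec)
    fixtures: FixtureConfig = field(default_factory=FixtureConfig)
    registration_mode: str = "consistent"
    grid_step: float = 1.0
    alpha: float = 0.6

    def validate(self) -> None:
        self.bandpass.validate(self.fs)
        if self.registration_mode not in ("consistent", "paper_literal"):
            raise ValueError(f"bad registration_mode {self.registration_mode!r}")
        if not 0 <= self.alpha <= 1:
            raise ValueError("alpha must lie in [0, 1]")

    def to_yaml(self, path: str | Path) -> None:
        # json round-trip turns tuples into lists, which YAML can represent
        payload = json.loads(json.dumps(asdict(self)))
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(
            fs=raw.get("fs", 10_000.0),
            bandpass=BandpassSpec(**raw.get("bandpass", {})),
            wavelet=WaveletSpec(**raw.get("wavelet", {})),
            ecg=EcgConfig(**raw.get("ecg", {})),
            colormap=ColorMapSpec(**raw.get("colormap", {})),
            fixtures=_fixture_config(raw.get("fixtures", {})),
            registration_mode=raw.get("registration_mode", "consistent"),
            grid_step=raw.get("grid_step", 1.0),
            alpha=raw.get("alpha", 0.6),
        )
        cfg.validate()
        return cfg


def _fixture_config(raw: dict) -> FixtureConfig:
    if "origin" in raw:
        raw = dict(raw, origin=tuple(raw["origin"]))
    return FixtureConfig(**raw)
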