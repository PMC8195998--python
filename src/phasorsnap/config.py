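"""Run configuration: a YAML-serialisable record of every parameter and seed.

Any run is reproducible from its config alone: the detection grid, camera
model (including offset and seed), filter calibration, intensity threshold,
display jitter, histogram binning, and display cutoff are all recorded, and
the config round-trips losslessly through YAML.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .phasor import DEFAULT_THRESHOLD, HISTOGRAM_BINS, FilterCalibration
from .simulate import CameraModel
from .spectral import WavelengthGrid

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    grid: WavelengthGrid = field(default_factory=WavelengthGrid)
    camera: CameraModel = field(default_factory=CameraModel)
    calibration: FilterCalibration = field(default_factory=FilterCalibration)
    threshold: float = DEFAULT_THRESHOLD
    jitter_halfwidth: float = 0.02
    jitter_seed: int = 0
    histogram_bins: int = HISTOGRAM_BINS
    display_cutoff_percent: float = 5.0

    def to_dict(self) -> dict:
        return {
            "grid": asdict(self.grid),
            "camera": asdict(self.camera),
            "calibration": asdict(self.calibration),
            "threshold": self.threshold,
            "jitter_halfwidth": self.jitter_halfwidth,
            "jitter_seed": self.jitter_seed,
            "histogram_bins": self.histogram_bins,
            "display_cutoff_percent": self.display_cutoff_percent,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(
            grid=WavelengthGrid(**d.get("grid", {})),
            camera=CameraModel(**d.get("camera", {})),
            calibration=FilterCalibration(**d.get("calibration", {})),
            threshold=float(d.get("threshold", DEFAULT_THRESHOLD)),
            jitter_halfwidth=float(d.get("jitter_halfwidth", 0.02)),
            jitter_seed=int(d.get("jitter_seed", 0)),
            histogram_bins=int(d.get("histogram_bins", HISTOGRAM_BINS)),
            display_cutoff_percent=float(d.get("display_cutoff_percent", 5.0)),
        )

    def save(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def load(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})
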