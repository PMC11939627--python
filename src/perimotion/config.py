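"""Analysis configuration shared by all pipeline stages."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import yaml


@dataclass
class AnalysisConfig:
    """Tunable parameters of the adhesion analysis.

    Attributes
    ----------
    hu_low, hu_high:
        Inclusive Hounsfield-unit window for adipose tissue. Fat attenuates
        between roughly -190 and -30 HU on contrast CT, which is the standard
        window for epicardial fat segmentation.
    n_bins:
        Number of equal-width histogram bins on the normalized disparity
        axis [0, 1].
    alpha_percent:
        Position (percent of the bin axis) of the reference bin used by the
        peak ratio; 25 places it at one quarter of the normalized range.
    pr_adhesion_threshold, dwi_adhesion_threshold:
        Adhesion is called when PR exceeds the former AND DWI falls below the
        latter.
    pr_nonadhesion_threshold, dwi_nonadhesion_threshold:
        Non-adhesion is called when PR falls below the former AND DWI exceeds
        the latter. Anything else is indeterminate.
    roi_radius_mm:
        Radius of the cylindrical assessment volume around the LAD centerline.
    roi_window:
        Either ``"mid-to-end"`` (arc lengths from the middle-segment start to
        the end of the centerline) or ``"mid-to-dist"`` (middle start to
        distal start).
    connectivity:
        Voxel connectivity for EAT component labelling (6, 18 or 26).
    min_component_voxels:
        Minimum connected-component size kept by the EAT segmentation;
        0 keeps everything.
    rng_seed:
        Seed for any stochastic step (plot jitter, subsampling); the core
        pipeline is deterministic.
    """

    hu_low: float = -190.0
    hu_high: float = -30.0
    n_bins: int = 100
    alpha_percent: float = 25.0
    pr_adhesion_threshold: float = 100.0
    pr_nonadhesion_threshold: float = 50.0
    dwi_adhesion_threshold: float = 0.3
    dwi_nonadhesion_threshold: float = 0.4
    roi_radius_mm: float = 6.0
    roi_window: str = "mid-to-end"
    connectivity: int = 26
    min_component_voxels: int = 0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not self.hu_low < self.hu_high:
            raise ValueError(f"hu_low must be < hu_high, got [{self.hu_low}, {self.hu_high}]")
        if self.n_bins < 10:
            raise ValueError(f"n_bins must be >= 10, got {self.n_bins}")
        if not 0.0 < self.alpha_percent < 100.0:
            raise ValueError(f"alpha_percent must be in (0, 100), got {self.alpha_percent}")
        if self.roi_window not in ("mid-to-end", "mid-to-dist"):
            raise ValueError(f"unknown roi_window {self.roi_window!r}")
        if self.connectivity not in (6, 18, 26):
            raise ValueError(f"connectivity must be 6, 18 or 26, got {self.connectivity}")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_file(cls, path: str | Path) -> "AnalysisConfig":
        """Load a config from YAML or JSON (keys mirror the attributes)."""
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls(**data)

    def to_file(self, path: str | Path) -> None:
        path = Path(path)
        if path.suffix == ".json":
            path.write_text(json.dumps(self.to_dict(), indent=2))
        else:
            path.write_text(yaml.safe_dump(self.to_dict()))
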