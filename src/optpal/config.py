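"""Run configuration with documented defaults, YAML round-tripping."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml


@dataclass
class RunConfig:
    """All pipeline tunables plus paths; lengths in um, stresses in kPa."""

    series_dir: str = ""
    calibration_csvs: list[str] = field(default_factory=list)
    output_dir: str = "optpal_out"
    prominence_tol: float = 0.05
    min_drop_um: float = 20.0
    linearity_r2: float = 0.95
    linear_region_max_strain: float = 0.25
    blur_sigma_px: float = 3.0
    bandstop_rel_width: float = 0.10
    bandstop_peak_factor: float = 50.0
    edge_margin_um: float = 1000.0
    max_height_variation: float = 0.14
    rng_seed: int = 0
    log_level: str = "INFO"

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def hash(self) -> str:
        """Stable hash of the configuration for run manifests."""
        canon = json.dumps(asdict(self), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]
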