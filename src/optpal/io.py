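"""Reading and writing the pipeline's file formats.

Volumes travel as one multi-page 16-bit grayscale TIFF per stage increment
(pages are depth slices) plus a JSON sidecar holding pixel sizes, per-file
stage positions and the generator seed.  Calibration tables and summaries
are plain CSV; curves and manifests are JSON.  Proprietary OCT vendor
formats are out of scope — adapt them by converting to this layout.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .layers import OctVolume
from .phantom import GroundTruth

SIDECAR_NAME = "series.json"
_TIFF_SCALE = 60000  # 16-bit head-room for intensities normalized to volume max


def save_series(
    directory: str | Path,
    volumes: list[OctVolume],
    rng_seed: int | None = None,
) -> Path:
    """Write a compression series as TIFF stacks plus a JSON sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    names, positions = [], []
    peak = max(v.intensity.max() for v in volumes) or 1.0
    for i, vol in enumerate(volumes):
        name = f"volume_{i:02d}.tif"
        scaled = np.clip(vol.intensity / peak * _TIFF_SCALE, 0, 65535).astype(np.uint16)
        # pages = depth slices: (nz, nx, ny)
        tifffile.imwrite(directory / name, np.moveaxis(scaled, 2, 0))
        names.append(name)
        positions.append(vol.stage_position)
    v0 = volumes[0]
    sidecar = {
        "dx_um": v0.dx,
        "dy_um": v0.dy,
        "dz_um": v0.dz,
        "files": names,
        "stage_position_um": positions,
        "rng_seed": rng_seed,
        "intensity_scale": peak / _TIFF_SCALE,
    }
    (directory / SIDECAR_NAME).write_text(json.dumps(sidecar, indent=2))
    return directory


def load_series(directory: str | Path) -> list[OctVolume]:
    """Load a TIFF+sidecar compression series back into volumes."""
    directory = Path(directory)
    sidecar = json.loads((directory / SIDECAR_NAME).read_text())
    scale = sidecar.get("intensity_scale", 1.0)
    volumes = []
    for name, pos in zip(sidecar["files"], sidecar["stage_position_um"]):
        pages = tifffile.imread(directory / name)
        volumes.append(
            OctVolume(
                intensity=np.moveaxis(pages, 0, 2).astype(float) * scale,
                dx=sidecar["dx_um"],
                dy=sidecar["dy_um"],
                dz=sidecar["dz_um"],
                stage_position=pos,
                source_id=str(directory / name),
            )
        )
    return volumes


def save_ground_truth(directory: str | Path, truth: GroundTruth) -> None:
    """Ground truth as a compressed array container plus a CSV summary."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    np.savez_compressed(
        directory / "ground_truth.npz",
        thickness=truth.thickness,
        eps1=truth.eps1,
        eps2=truth.eps2,
        sigma=truth.sigma,
        preload_index_true=truth.preload_index_true,
        stage_positions=truth.stage_positions,
    )
    pd.DataFrame(
        {
            "increment": np.arange(truth.thickness.shape[0]),
            "stage_um": truth.stage_positions,
            "mean_eps1": truth.eps1.mean(axis=(1, 2)),
            "mean_sigma_kpa": truth.sigma.mean(axis=(1, 2)),
        }
    ).to_csv(directory / "ground_truth_summary.csv", index=False)


def load_ground_truth(directory: str | Path) -> GroundTruth:
    with np.load(Path(directory) / "ground_truth.npz") as z:
        return GroundTruth(
            thickness=z["thickness"],
            eps1=z["eps1"],
            eps2=z["eps2"],
            sigma=z["sigma"],
            preload_index_true=int(z["preload_index_true"]),
            stage_positions=z["stage_positions"],
        )


def read_calibration_csv(path: str | Path) -> pd.DataFrame:
    """Read one calibration replicate, validating rows eagerly."""
    df = pd.read_csv(path)
    from .calibration import REQUIRED_COLUMNS

    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    for col in ("force_N", "diameter_mm", "thickness_um"):
        bad = df.index[~np.isfinite(df[col].to_numpy(float))]
        if len(bad):
            raise ValueError(f"{path}: non-numeric {col} at row {bad[0] + 2}")
    if (df["force_N"] < 0).any() or (df["force_N"] > 4.5).any():
        raise ValueError(f"{path}: force outside the 0-4.5 N sensor range")
    return df
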