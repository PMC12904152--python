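"""End-to-end analysis: volumes -> thickness -> strain -> stress map."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import compression, layers, stressmap
from .calibration import CalibrationCurve, stress_from_strain
from .config import RunConfig
from .layers import OctVolume, QCReport, ThicknessMap
from .stressmap import BandstopParams, StressMap


@dataclass
class AnalysisResult:
    thickness_maps: list[ThicknessMap]
    series: compression.CompressionSeries
    preload_index: int
    compressed_index: int
    strain: compression.StrainMap
    stress_map: StressMap
    qc: QCReport
    qc_all: list[QCReport] = field(default_factory=list)

    @property
    def mean_stress_kpa(self) -> float:
        return self.stress_map.mean_stress

    @property
    def valid_fraction(self) -> float:
        return float(self.stress_map.valid.mean())


def analyze_volumes(
    volumes: list[OctVolume],
    curve: CalibrationCurve,
    config: RunConfig | None = None,
    enforce_qc: bool = True,
) -> AnalysisResult:
    """Run the full optical-palpation analysis on a compression series.

    Thickness maps are measured at every A-scan, lateral borders are
    cropped by the configured edge margin, the preload/compressed states
    are located on the mean-thickness curve, and the per-pixel strain is
    converted to stress through the calibration curve, smoothed, and
    summarized.  With ``enforce_qc`` a failing surface-flatness or
    artifact check raises ``QCError``.
    """
    cfg = config or RunConfig()
    maps, reports = [], []
    for vol in volumes:
        tmap = layers.thickness_map(vol, cfg.prominence_tol)
        report, cropped = layers.qc_roi(
            vol, tmap, cfg.edge_margin_um, cfg.max_height_variation
        )
        maps.append(cropped)
        reports.append(report)
    series = compression.CompressionSeries(
        thickness_maps=maps,
        stage_positions=np.array([v.stage_position for v in volumes]),
        provenance=[v.source_id for v in volumes],
    )
    preload = compression.detect_preload(series, cfg.min_drop_um, cfg.linearity_r2)
    comp = compression.compressed_index(preload, len(series))
    qc = reports[preload]
    if enforce_qc and not qc.passed:
        raise QCError(
            f"QC failed at preload volume: height variation "
            f"{qc.height_variation:.3f} (limit {cfg.max_height_variation}), "
            f"artifact={qc.artifact_present}"
        )
    smap = compression.strain_map(series, preload, comp)
    raw_stress, valid = stress_from_strain(curve, smap)
    smoothed = stressmap.smooth_stress(
        raw_stress,
        valid,
        blur_sigma_px=cfg.blur_sigma_px,
        bandstop=BandstopParams(
            rel_width=cfg.bandstop_rel_width, peak_factor=cfg.bandstop_peak_factor
        ),
    )
    stress = StressMap(
        stress=smoothed,
        valid=valid,
        dx=volumes[0].dx,
        dy=volumes[0].dy,
        provenance={
            "sources": [v.source_id for v in volumes],
            "preload_index": preload,
            "compressed_index": comp,
            "E1_kpa": curve.E1,
            "config_hash": cfg.hash(),
        },
    )
    return AnalysisResult(
        thickness_maps=maps,
        series=series,
        preload_index=preload,
        compressed_index=comp,
        strain=smap,
        stress_map=stress,
        qc=qc,
        qc_all=reports,
    )


class QCError(RuntimeError):
    """Region-of-interest quality control failed."""
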