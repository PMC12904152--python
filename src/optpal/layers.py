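"""Reference-layer interface detection and per-volume thickness maps.

In optical palpation the transparent silicone reference layer is bounded by
two bright Fresnel-reflection peaks in every A-scan: the glass/layer
interface above and the layer/tissue interface below.  The layer thickness
at each lateral position is the pixel distance between the two highest
sufficiently prominent maxima of the A-scan, converted to micrometres via
the depth pixel size.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks


@dataclass
class OctVolume:
    """A 3D OCT intensity volume with physical pixel sizes.

    Attributes
    ----------
    intensity : ndarray, shape (nx, ny, nz)
        Non-negative intensity in arbitrary units; depth index 0 is the
        shallowest sample (nearest the glass slide).
    dx, dy, dz : float
        Pixel sizes in micrometres.
    stage_position : float
        Cumulative stage displacement (um) at which the volume was taken.
    source_id : str
        Provenance tag (file name or phantom descriptor).
    """

    intensity: np.ndarray
    dx: float
    dy: float
    dz: float
    stage_position: float = 0.0
    source_id: str = ""

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.ndim != 3:
            raise ValueError("intensity must be a 3D (x, y, z) array")
        if not np.all(np.isfinite(self.intensity)) or np.any(self.intensity < 0):
            raise ValueError("intensities must be finite and non-negative")
        if self.dz <= 0 or self.dx <= 0 or self.dy <= 0:
            raise ValueError("pixel sizes must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensity.shape

    def enface(self, reducer=np.mean) -> np.ndarray:
        """Top-down (x, y) projection of the volume."""
        return reducer(self.intensity, axis=2)


@dataclass
class ThicknessMap:
    """Per-lateral-pixel reference-layer thickness with a validity mask.

    ``thickness`` is in micrometres and is NaN wherever ``valid`` is False;
    invalid pixels are never zero-filled.  ``top_interface`` and
    ``bottom_interface`` hold depth indices (pixels), -1 where invalid.
    """

    thickness: np.ndarray
    valid: np.ndarray
    top_interface: np.ndarray
    bottom_interface: np.ndarray
    stage_position: float
    dz: float
    source_id: str = ""

    def __post_init__(self) -> None:
        v = self.valid
        if np.any(self.thickness[v] <= 0):
            raise ValueError("valid thicknesses must be positive")
        expected = (self.bottom_interface[v] - self.top_interface[v]) * self.dz
        if not np.allclose(self.thickness[v], expected):
            raise ValueError("thickness inconsistent with interface indices")

    @property
    def n_valid(self) -> int:
        return int(self.valid.sum())


def detect_interfaces(
    ascan: np.ndarray, prominence_tol: float = 0.05
) -> tuple[int, int] | None:
    """Locate the two reference-layer interfaces in one A-scan.

    Returns the depth indices of the two highest local maxima whose
    prominence is at least ``prominence_tol`` times the profile's intensity
    range, ordered shallow-to-deep, or None when fewer than two maxima
    qualify (flat, monotone, or low-contrast profiles).

    Equal-height candidates are disambiguated by preferring higher
    prominence, then smaller depth, so degenerate profiles resolve
    deterministically.
    """
    profile = np.asarray(ascan, dtype=float)
    if profile.ndim != 1 or profile.size < 3:
        raise ValueError("A-scan must be a 1D profile of length >= 3")
    rng = profile.max() - profile.min()
    if rng <= 0:
        return None
    peaks, props = find_peaks(profile, prominence=prominence_tol * rng)
    if peaks.size < 2:
        return None
    # sort by height desc, prominence desc, depth asc; take the top two
    order = np.lexsort((peaks, -props["prominences"], -profile[peaks]))
    chosen = np.sort(peaks[order[:2]])
    return int(chosen[0]), int(chosen[1])


def thickness_map(volume: OctVolume, prominence_tol: float = 0.05) -> ThicknessMap:
    """Measure reference-layer thickness at every A-scan of a volume.

    Per-pixel failures (no qualifying interface pair) are recorded in the
    validity mask rather than raised.
    """
    nx, ny, _ = volume.shape
    top = np.full((nx, ny), -1, dtype=int)
    bottom = np.full((nx, ny), -1, dtype=int)
    valid = np.zeros((nx, ny), dtype=bool)
    for ix in range(nx):
        for iy in range(ny):
            res = detect_interfaces(volume.intensity[ix, iy], prominence_tol)
            if res is not None:
                top[ix, iy], bottom[ix, iy] = res
                valid[ix, iy] = True
    thickness = np.where(valid, (bottom - top) * volume.dz, np.nan)
    return ThicknessMap(
        thickness=thickness,
        valid=valid,
        top_interface=top,
        bottom_interface=bottom,
        stage_position=volume.stage_position,
        dz=volume.dz,
        source_id=volume.source_id,
    )


def mean_thickness(tmap: ThicknessMap) -> float:
    """Arithmetic mean thickness (um) over valid pixels only."""
    if tmap.n_valid == 0:
        raise ValueError("no valid pixels: volume unusable for thickness averaging")
    return float(np.mean(tmap.thickness[tmap.valid]))


@dataclass
class QCReport:
    """Outcome of region-of-interest quality control."""

    height_variation: float
    height_variation_pass: bool
    artifact_present: bool
    edge_margin_px: tuple[int, int]
    roi_shape: tuple[int, int]
    passed: bool = field(init=False)

    def __post_init__(self) -> None:
        self.passed = self.height_variation_pass and not self.artifact_present


def qc_roi(
    volume: OctVolume,
    tmap: ThicknessMap,
    edge_margin_um: float = 1000.0,
    max_height_variation: float = 0.14,
) -> tuple[QCReport, ThicknessMap]:
    """Crop lateral borders and check surface flatness and artifacts.

    The region of interest excludes ``edge_margin_um`` from every lateral
    border (samples near the edge are unreliable).  The surface-height
    variation of the layer/tissue interface over the ROI is
    (max - min) / mean of its depth; it must not exceed
    ``max_height_variation``.  An artifact flag is raised when any sample
    in a valid A-scan is brighter than both of its detected interface
    peaks (saturating reflections).
    """
    mx = int(np.ceil(edge_margin_um / volume.dx))
    my = int(np.ceil(edge_margin_um / volume.dy))
    nx, ny, _ = volume.shape
    if nx - 2 * mx < 1 or ny - 2 * my < 1:
        raise ValueError("ROI empty after edge crop")
    sl = (slice(mx, nx - mx) if mx else slice(None), slice(my, ny - my) if my else slice(None))
    valid = tmap.valid[sl]
    if not valid.any():
        raise ValueError("ROI contains no valid pixels")
    bottom = tmap.bottom_interface[sl]
    depth_um = bottom[valid] * volume.dz
    variation = float((depth_um.max() - depth_um.min()) / depth_um.mean())

    roi_int = volume.intensity[sl]
    top = tmap.top_interface[sl]
    xs, ys = np.nonzero(valid)
    peak_int = np.maximum(
        roi_int[xs, ys, top[valid]], roi_int[xs, ys, bottom[valid]]
    )
    artifact = bool(np.any(roi_int[xs, ys].max(axis=1) > peak_int))

    report = QCReport(
        height_variation=variation,
        height_variation_pass=variation <= max_height_variation,
        artifact_present=artifact,
        edge_margin_px=(mx, my),
        roi_shape=valid.shape,
    )
    cropped = ThicknessMap(
        thickness=tmap.thickness[sl].copy(),
        valid=valid.copy(),
        top_interface=top.copy(),
        bottom_interface=bottom.copy(),
        stage_position=tmap.stage_position,
        dz=tmap.dz,
        source_id=tmap.source_id,
    )
    return report, cropped
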