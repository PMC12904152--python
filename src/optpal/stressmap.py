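"""Spatially resolved surface-stress maps and group summaries.

Raw per-pixel stress from the calibration lookup is smoothed in two steps:
a masked Gaussian blur (sd 3 pixels, normalized convolution so invalid
pixels carry no weight) to suppress occasional erroneous peak detections,
then a Fourier band-stop notch that removes the periodic stripe artifact
produced by finite depth-pixel quantization of the thickness maps.  The
band-stop is adaptive: the dominant non-DC spectral peak is notched only
when it stands well above the rest of the spectrum, so smooth maps pass
through unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from matplotlib import colormaps
from scipy import ndimage

LIGHT_GRAY = (211, 211, 211)


@dataclass
class BandstopParams:
    """Adaptive notch configuration.

    rel_width : half-width of the notched radial-frequency annulus,
        relative to the detected artifact frequency.
    peak_factor : the dominant non-DC power-spectrum bin must exceed this
        multiple of the median power within its own radial annulus for the
        notch to engage.  Comparing against the annulus (rather than the
        whole spectrum) distinguishes an isolated stripe peak from the
        smooth, radially decaying spectrum of genuine structure, which
        must never be notched.
    min_annulus_bins : annuli with fewer bins than this are never notched
        (they hold the map's coarse structure, not a stripe artifact).
    """

    rel_width: float = 0.10
    peak_factor: float = 50.0
    min_annulus_bins: int = 8
    enabled: bool = True


@dataclass
class StressMap:
    """Smoothed per-pixel surface stress (kPa) with validity mask."""

    stress: np.ndarray
    valid: np.ndarray
    dx: float
    dy: float
    provenance: dict = field(default_factory=dict)

    @property
    def mean_stress(self) -> float:
        return mean_stress(self)


def _masked_gaussian(values: np.ndarray, valid: np.ndarray, sigma: float) -> np.ndarray:
    filled = np.where(valid, values, 0.0)
    num = ndimage.gaussian_filter(filled, sigma)
    den = ndimage.gaussian_filter(valid.astype(float), sigma)
    out = np.full(values.shape, np.nan)
    ok = den > 1e-12
    out[ok] = num[ok] / den[ok]
    return out


def estimate_artifact_frequency(
    values: np.ndarray, params: BandstopParams
) -> float | None:
    """Radial frequency (cycles/pixel) of the dominant stripe peak, if any.

    The strongest non-DC bin of the 2D power spectrum qualifies as a
    stripe artifact only when it exceeds ``peak_factor`` times the median
    power of its own radial annulus: a quantization stripe concentrates
    power in one or two bins of an otherwise quiet annulus, whereas
    genuine image structure fills its annulus roughly evenly.  Returns
    None when no bin qualifies.
    """
    spec = np.abs(np.fft.fft2(values - values.mean())) ** 2
    fx = np.fft.fftfreq(values.shape[0])
    fy = np.fft.fftfreq(values.shape[1])
    fr = np.hypot(fx[:, None], fy[None, :])
    nondc = fr > 0
    power = spec[nondc]
    radius = fr[nondc]
    if power.size == 0 or power.max() <= 0:
        return None
    peak = float(power.max())
    f0 = float(radius[np.argmax(power)])
    annulus = (radius >= f0 * (1 - params.rel_width)) & (
        radius <= f0 * (1 + params.rel_width)
    )
    if annulus.sum() < params.min_annulus_bins:
        return None
    floor = max(float(np.median(power[annulus])), peak * 1e-12)
    if peak <= params.peak_factor * floor:
        return None
    return f0


def smooth_stress(
    raw_stress: np.ndarray,
    valid: np.ndarray,
    blur_sigma_px: float = 3.0,
    bandstop: BandstopParams | None = None,
) -> np.ndarray:
    """Masked Gaussian blur followed by an adaptive Fourier band-stop.

    Invalid pixels contribute no weight to the blur and remain NaN in the
    output (they are in-painted internally only so the FFT step has a
    complete field).  Constant maps are preserved to numerical precision.
    """
    valid = np.asarray(valid, dtype=bool)
    if not valid.any():
        raise ValueError("empty validity mask: nothing to smooth")
    if bandstop is None:
        bandstop = BandstopParams()
    out = _masked_gaussian(np.asarray(raw_stress, dtype=float), valid, blur_sigma_px)
    if bandstop.enabled:
        filled = np.where(np.isfinite(out), out, np.nanmean(out))
        f0 = estimate_artifact_frequency(filled, bandstop)
        if f0 is not None:
            F = np.fft.fft2(filled)
            fx = np.fft.fftfreq(filled.shape[0])
            fy = np.fft.fftfreq(filled.shape[1])
            fr = np.hypot(fx[:, None], fy[None, :])
            notch = (fr >= f0 * (1 - bandstop.rel_width)) & (
                fr <= f0 * (1 + bandstop.rel_width)
            )
            F[notch] = 0.0
            filtered = np.real(np.fft.ifft2(F))
            out = np.where(valid, filtered, np.nan)
    out[~valid] = np.nan
    return out


def mean_stress(smap: StressMap) -> float:
    """Mean stress (kPa) over valid pixels of the smoothed map."""
    if not smap.valid.any():
        raise ValueError("empty validity mask: no stress statistic available")
    return float(np.mean(smap.stress[smap.valid]))


def overlay(
    smap: StressMap,
    enface: np.ndarray,
    colormap: str = "viridis",
    alpha: float = 0.6,
    vmin: float | None = None,
    vmax: float | None = None,
    scale_bar_um: float | None = 500.0,
) -> np.ndarray:
    """Render the stress map over a grayscale en face OCT image.

    Returns an RGBA uint8 array with the en face image's lateral shape.
    The stress map is nearest-neighbor resampled if the grids differ;
    invalid pixels render light gray.  A white scale bar of
    ``scale_bar_um`` physical length (from ``dx``) is drawn in the bottom
    left unless disabled with None.
    """
    enface = np.asarray(enface, dtype=float)
    if enface.ndim != 2 or enface.size == 0:
        raise ValueError("en face image must be a non-empty 2D array")
    stress, valid = smap.stress, smap.valid
    if stress.shape != enface.shape:
        xi = np.clip(
            np.round(np.linspace(0, stress.shape[0] - 1, enface.shape[0])).astype(int),
            0, stress.shape[0] - 1,
        )
        yi = np.clip(
            np.round(np.linspace(0, stress.shape[1] - 1, enface.shape[1])).astype(int),
            0, stress.shape[1] - 1,
        )
        stress = stress[np.ix_(xi, yi)]
        valid = valid[np.ix_(xi, yi)]
        if stress.shape != enface.shape:
            raise ValueError("stress map and en face geometry mismatch after resampling")

    lo, hi_ = np.nanmin(enface), np.nanmax(enface)
    gray = (enface - lo) / (hi_ - lo) if hi_ > lo else np.zeros_like(enface)
    rgba = np.empty(enface.shape + (4,), dtype=np.uint8)
    rgba[..., :3] = (gray[..., None] * 255).astype(np.uint8)
    rgba[..., 3] = 255

    if valid.any():
        if vmin is None:
            vmin = float(np.nanmin(stress[valid]))
        if vmax is None:
            vmax = float(np.nanmax(stress[valid]))
        span = vmax - vmin if vmax > vmin else 1.0
        norm = np.clip((stress - vmin) / span, 0.0, 1.0)
        cmap = colormaps[colormap]
        colored = (cmap(np.nan_to_num(norm))[..., :3] * 255).astype(np.uint8)
        blend = (alpha * colored + (1 - alpha) * rgba[..., :3]).astype(np.uint8)
        rgba[..., :3] = np.where(valid[..., None], blend, rgba[..., :3])
    rgba[~valid, :3] = LIGHT_GRAY

    if scale_bar_um is not None:
        bar_px = max(1, int(round(scale_bar_um / smap.dx)))
        h, w = enface.shape
        bar_px = min(bar_px, w - 2)
        rgba[h - max(2, h // 50) - 1 : h - 1, 1 : 1 + bar_px, :3] = 255
    return rgba


def group_summary(fov_results: list[tuple[str, float]]) -> pd.DataFrame:
    """Per-class mean and SD of per-FOV mean stresses.

    One row per label with columns ``label, n, mean_kpa, sd_kpa``; the SD
    is the population SD of the per-FOV means (0 for single-member
    classes).  Assigning each FOV its sample's most severe diagnosis is
    the caller's responsibility.
    """
    if not fov_results:
        raise ValueError("at least one FOV result required")
    df = pd.DataFrame(fov_results, columns=["label", "mean_kpa"])
    out = (
        df.groupby("label", sort=False)["mean_kpa"]
        .agg(n="size", mean_kpa="mean", sd_kpa=lambda s: float(np.std(s, ddof=0)))
        .reset_index()
    )
    out["n"] = out["n"].astype(int)
    return out
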