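"""Stress-strain calibration of the silicone reference layer.

Force-sensor measurements of the bare layer under stepwise compression
give paired (strain, stress) points; the Young's modulus E1 is the slope
of an ordinary least-squares line fitted over the low-strain region.  The
fitted curve then converts measured layer strains into surface stresses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .compression import StrainMap

REQUIRED_COLUMNS = ("increment", "stage_um", "force_N", "diameter_mm", "thickness_um")


@dataclass
class CalibrationCurve:
    """Averaged stress-strain curve of the reference material.

    ``strain_points``/``stress_points`` are replicate means per increment
    (strain unitless, stress in kPa) with per-point stress SD; ``E1`` is
    the slope of the low-strain OLS fit (free intercept — contact offsets
    may shift the curve, so only the slope is mechanical).
    """

    strain_points: np.ndarray
    stress_points: np.ndarray
    stress_sd: np.ndarray
    linear_region_max_strain: float = 0.25
    n_replicates: int = 1
    E1: float | None = None
    fit_r2: float | None = None
    fit_intercept: float | None = None

    def __post_init__(self) -> None:
        self.strain_points = np.asarray(self.strain_points, dtype=float)
        self.stress_points = np.asarray(self.stress_points, dtype=float)
        self.stress_sd = np.asarray(self.stress_sd, dtype=float)
        if self.strain_points[0] != 0.0 or np.any(np.diff(self.strain_points) <= 0):
            raise ValueError("strain points must increase strictly from 0")

    @property
    def max_strain(self) -> float:
        return float(self.strain_points[-1])

    def to_dict(self) -> dict:
        return {
            "strain_points": self.strain_points.tolist(),
            "stress_points_kpa": self.stress_points.tolist(),
            "stress_sd_kpa": self.stress_sd.tolist(),
            "linear_region_max_strain": self.linear_region_max_strain,
            "n_replicates": self.n_replicates,
            "E1_kpa": self.E1,
            "fit_r2": self.fit_r2,
            "fit_intercept_kpa": self.fit_intercept,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CalibrationCurve":
        return cls(
            strain_points=np.asarray(d["strain_points"]),
            stress_points=np.asarray(d["stress_points_kpa"]),
            stress_sd=np.asarray(d["stress_sd_kpa"]),
            linear_region_max_strain=d["linear_region_max_strain"],
            n_replicates=d["n_replicates"],
            E1=d["E1_kpa"],
            fit_r2=d["fit_r2"],
            fit_intercept=d["fit_intercept_kpa"],
        )


def stress_kpa_from_force(force_n: np.ndarray, diameter_mm: np.ndarray) -> np.ndarray:
    """Engineering stress (kPa) from force (N) over a disk of given diameter (mm)."""
    area_m2 = np.pi * (np.asarray(diameter_mm) / 2.0 * 1e-3) ** 2
    return np.asarray(force_n) / area_m2 * 1e-3


def build_curve(
    replicates: list[pd.DataFrame],
    linear_region_max_strain: float = 0.25,
    use_initial_area: bool = False,
) -> CalibrationCurve:
    """Build the averaged stress-strain curve from replicate measurements.

    Per replicate and increment, stress is force divided by the disk area
    from the measured compressed diameter (or the initial diameter when
    ``use_initial_area`` is set, for sensitivity analysis), and strain is
    the thickness change relative to the first increment.  Replicates are
    aligned by increment index and averaged pointwise; unequal lengths are
    truncated to the shortest with a warning.
    """
    if not replicates:
        raise ValueError("at least one replicate required")
    strains, stresses = [], []
    for rep_i, rep in enumerate(replicates):
        missing = [c for c in REQUIRED_COLUMNS if c not in rep.columns]
        if missing:
            raise ValueError(f"replicate {rep_i} missing columns {missing}")
        if len(rep) < 4:
            raise ValueError(f"replicate {rep_i} has fewer than 4 increments")
        rep = rep.sort_values("increment")
        L0 = float(rep["thickness_um"].iloc[0])
        eps = (L0 - rep["thickness_um"].to_numpy(float)) / L0
        if np.any(np.diff(eps) <= 0):
            raise ValueError(f"replicate {rep_i}: strain not strictly increasing")
        diameter = rep["diameter_mm"].to_numpy(float)
        if use_initial_area:
            diameter = np.full_like(diameter, diameter[0])
        strains.append(eps)
        stresses.append(stress_kpa_from_force(rep["force_N"].to_numpy(float), diameter))
    n_min = min(len(s) for s in strains)
    if any(len(s) != n_min for s in strains):
        warnings.warn(
            f"replicates have unequal increment counts; truncating to {n_min}",
            stacklevel=2,
        )
    strains = np.array([s[:n_min] for s in strains])
    stresses = np.array([s[:n_min] for s in stresses])
    return CalibrationCurve(
        strain_points=strains.mean(axis=0),
        stress_points=stresses.mean(axis=0),
        stress_sd=stresses.std(axis=0, ddof=0),
        linear_region_max_strain=linear_region_max_strain,
        n_replicates=len(replicates),
    )


def fit_modulus(curve: CalibrationCurve) -> tuple[float, float]:
    """OLS fit of stress on strain over the low-strain region.

    Returns ``(E1, r2)`` and stores them (plus the free intercept) on the
    curve.  Requires at least three points with strain not exceeding
    ``linear_region_max_strain``.
    """
    sel = curve.strain_points <= curve.linear_region_max_strain
    if sel.sum() < 3:
        raise ValueError(
            f"only {int(sel.sum())} points in the linear region "
            f"(strain <= {curve.linear_region_max_strain}); need >= 3"
        )
    x = curve.strain_points[sel]
    if np.ptp(x) == 0:
        raise ValueError("degenerate design: all linear-region strains equal")
    fit = stats.linregress(x, curve.stress_points[sel])
    curve.E1 = float(fit.slope)
    curve.fit_r2 = float(fit.rvalue**2)
    curve.fit_intercept = float(fit.intercept)
    if curve.E1 <= 0:
        raise ValueError(f"fitted modulus {curve.E1:.3g} kPa is not positive")
    return curve.E1, curve.fit_r2


def stress_from_strain(curve: CalibrationCurve, smap: StrainMap) -> tuple[np.ndarray, np.ndarray]:
    """Convert a strain map to surface stress (kPa) via the calibration curve.

    Strains within the linear region map through sigma = E1 * eps; larger
    strains interpolate the measured curve piecewise-linearly.  Negative
    strains have no defined stress and invalidate the pixel.  Strains
    beyond the calibrated range raise (no extrapolation).

    Returns ``(stress, valid)``; stress is NaN where invalid.
    """
    if curve.E1 is None:
        raise ValueError("curve has no fitted modulus; call fit_modulus first")
    valid = smap.valid & ~smap.negative
    eps = smap.strain
    over = valid & (eps > curve.max_strain)
    if over.any():
        raise ValueError(
            f"{int(over.sum())} pixel(s) exceed the calibrated strain range "
            f"(max {curve.max_strain:.3f}); cannot extrapolate"
        )
    stress = np.full(eps.shape, np.nan)
    lin = valid & (eps <= curve.linear_region_max_strain)
    stress[lin] = curve.E1 * eps[lin]
    hi = valid & ~lin
    if hi.any():
        stress[hi] = np.interp(eps[hi], curve.strain_points, curve.stress_points)
    return stress, valid
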