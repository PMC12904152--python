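"""Synthetic compression-phantom generator with known ground truth.

Emulates the data an optical-palpation experiment produces: a stack of OCT
volumes acquired while a z-stage compresses a tissue sample against a glass
slide through a transparent silicone reference layer, plus force-sensor
calibration tables for the reference material.

Mechanics
---------
The layer (modulus ``E1``, rest thickness ``L0``) and the tissue beneath it
(per-pixel modulus ``E2(x, y)``, rest thickness ``H(x, y)``) are modelled as
two linear springs in series carrying the same uniaxial stress, uniform in
depth.  A stage displacement ``d`` beyond the contact dead zone partitions
between the two according to their compliances ``L0/E1`` and ``H/E2``:

    delta1 = d * (L0/E1) / (L0/E1 + H/E2),   eps1 = delta1 / L0,
    sigma  = E1 * eps1 = E2 * eps2.

The first ``dead_zone_increments`` stage steps transmit no stress
(insufficient contact / interfacial fluid), so the layer stays at ``L0``.

Rendering
---------
Each A-scan shows a bright peak at the glass/layer interface, a dark layer
interior, a second bright peak at the layer/tissue interface, and below it
speckle-textured tissue with exponential depth attenuation.  Speckle is
multiplicative with exponentially distributed intensity (fully developed
coherent speckle at ``speckle_contrast = 1``), plus additive Gaussian
detector noise.  No physical-optics simulation is attempted; intensity
units are arbitrary.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .layers import OctVolume

__all__ = [
    "PhantomSpec",
    "CompressionState",
    "GroundTruth",
    "compute_compression_state",
    "render_volume",
    "generate_series",
    "generate_calibration_data",
    "solve_stress_bisection",
    "FORCE_SENSOR_MAX_N",
]

FORCE_SENSOR_MAX_N = 4.5  # range of the miniature force sensor


def _as_map(value, nx: int, ny: int) -> np.ndarray:
    arr = np.asarray(value, dtype=float)
    if arr.ndim == 0:
        return np.full((nx, ny), float(arr))
    if arr.shape != (nx, ny):
        raise ValueError(f"map shape {arr.shape} does not match grid ({nx}, {ny})")
    return arr.copy()


@dataclass
class PhantomSpec:
    """Full description of a synthetic compression experiment.

    Parameters
    ----------
    nx, ny : int
        Lateral grid size in pixels.
    nz : int
        Depth samples per A-scan.
    dx, dy : float
        Lateral pixel size (um); 13.67 um matches the elastography FOV
        sampling of the benchtop system being emulated.
    dz : float
        Depth pixel size (um), default 3.50.
    L0 : float
        Uncompressed reference-layer thickness (um), default 600.
    E1 : float
        Reference-layer Young's modulus (kPa), default 49 (the calibrated
        value of the 1:10:40 PDMS formulation).
    tissue_modulus_map : float or (nx, ny) array
        Tissue Young's modulus E2 (kPa) per lateral pixel.
    tissue_thickness_map : float or (nx, ny) array
        Tissue rest thickness H (um) per lateral pixel (mechanical only;
        tissue is rendered to the bottom of the volume).
    glass_depth : float
        Depth (um) of the glass/layer interface in the volume.
    dead_zone_increments : int
        Count k of initial stage steps transmitting no stress.
    stage_step : float
        Stage increment (um), default 100.
    n_increments : int
        Number of volumes collected (at most 16).
    interface_reflectivity : (float, float)
        Peak amplitudes of the glass/layer and layer/tissue interfaces
        (arbitrary intensity units).
    tissue_level : float
        Mean tissue backscatter amplitude just below the layer.
    speckle_contrast : float
        0 = noiseless tissue, 1 = fully developed speckle.
    attenuation_coeff : float
        Tissue attenuation (1/um) of the mean intensity profile.
    noise_sd : float
        Additive Gaussian noise standard deviation (intensity units).
    dead_zone_jitter_um : float
        Small random thickness jitter (um, at most one depth pixel)
        applied in the dead zone to mimic interfacial fluid.
    nonlinear_strain_onset : float
        Strain above which the reference material stiffens; used only by
        the calibration generator.
    rng_seed : int
        Seed making every generated artifact reproducible.
    """

    nx: int = 64
    ny: int = 64
    nz: int = 256
    dx: float = 13.67
    dy: float = 13.67
    dz: float = 3.50
    L0: float = 600.0
    E1: float = 49.0
    tissue_modulus_map: np.ndarray | float = 25.0
    tissue_thickness_map: np.ndarray | float = 800.0
    glass_depth: float = 50.0
    dead_zone_increments: int = 1
    stage_step: float = 100.0
    n_increments: int = 8
    interface_reflectivity: tuple[float, float] = (6.0, 5.0)
    tissue_level: float = 0.35
    speckle_contrast: float = 1.0
    attenuation_coeff: float = 0.002
    noise_sd: float = 0.02
    dead_zone_jitter_um: float = 0.0
    nonlinear_strain_onset: float = 0.25
    rng_seed: int = 0

    E2: np.ndarray = field(init=False, repr=False)
    H: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.E2 = _as_map(self.tissue_modulus_map, self.nx, self.ny)
        self.H = _as_map(self.tissue_thickness_map, self.nx, self.ny)
        self.validate()

    def validate(self) -> None:
        if min(self.nx, self.ny) < 1 or self.nz < 3:
            raise ValueError("grid sizes must be positive (nz >= 3)")
        if self.dz <= 0 or self.dx <= 0 or self.dy <= 0:
            raise ValueError("pixel sizes must be positive")
        if self.L0 <= 0 or self.E1 <= 0:
            raise ValueError("L0 and E1 must be positive")
        if np.any(self.E2 <= 0) or np.any(self.H <= 0):
            raise ValueError("tissue modulus and thickness maps must be positive")
        if self.L0 / self.dz < 10:
            raise ValueError("layer must span at least 10 depth pixels (L0/dz >= 10)")
        if self.n_increments > 16:
            raise ValueError("at most 16 stage increments are supported")
        if not (0 <= self.dead_zone_increments < self.n_increments - 3):
            raise ValueError("need dead_zone_increments in [0, n_increments - 4]")
        if self.stage_step <= 0:
            raise ValueError("stage_step must be positive")
        if self.dead_zone_jitter_um > self.dz:
            raise ValueError("dead-zone jitter must not exceed one depth pixel")

    def with_(self, **kwargs) -> "PhantomSpec":
        """Copy of this spec with some fields replaced."""
        return replace(self, **kwargs)

    @property
    def stage_positions(self) -> np.ndarray:
        return np.arange(self.n_increments) * self.stage_step


@dataclass
class CompressionState:
    """Ground-truth mechanical state at one stage increment (all per-pixel)."""

    increment: int
    displacement: float
    thickness: np.ndarray  # layer thickness, um
    eps1: np.ndarray  # layer strain
    eps2: np.ndarray  # tissue strain
    sigma: np.ndarray  # transmitted stress, kPa


@dataclass
class GroundTruth:
    """Stacked per-increment ground truth for a whole compression series."""

    thickness: np.ndarray  # (n, nx, ny) um
    eps1: np.ndarray
    eps2: np.ndarray
    sigma: np.ndarray  # kPa
    preload_index_true: int
    stage_positions: np.ndarray

    def state(self, i: int) -> CompressionState:
        return CompressionState(
            increment=i,
            displacement=float(self.stage_positions[i]),
            thickness=self.thickness[i],
            eps1=self.eps1[i],
            eps2=self.eps2[i],
            sigma=self.sigma[i],
        )

    def self_check(self, E1: float, E2: np.ndarray, atol_kpa: float = 1e-9) -> None:
        """Verify the equal-stress spring relations at machine precision."""
        if np.any(self.eps1 < 0) or np.any(self.eps1 >= 1):
            raise AssertionError("eps1 out of [0, 1)")
        if np.any(self.eps2 < 0) or np.any(self.eps2 >= 1):
            raise AssertionError("eps2 out of [0, 1)")
        if np.any(np.abs(self.sigma - E1 * self.eps1) > atol_kpa):
            raise AssertionError("sigma != E1*eps1 beyond tolerance")
        if np.any(np.abs(self.sigma - E2[None] * self.eps2) > atol_kpa):
            raise AssertionError("sigma != E2*eps2 beyond tolerance")


def compute_compression_state(spec: PhantomSpec, increment_index: int) -> CompressionState:
    """Mechanical equilibrium of the layer/tissue stack at one increment.

    The effective displacement ``d = max(0, (i - k) * stage_step)`` is split
    between the two springs in series; both carry the same stress.

    Raises
    ------
    ValueError
        If the index is out of range or the state would require the layer
        (or tissue) to be compressed past its full thickness.
    """
    if not 0 <= increment_index < spec.n_increments:
        raise ValueError(
            f"increment_index {increment_index} outside [0, {spec.n_increments})"
        )
    d = max(0.0, (increment_index - spec.dead_zone_increments) * spec.stage_step)
    c1 = spec.L0 / spec.E1  # layer compliance, um/kPa
    c2 = spec.H / spec.E2  # tissue compliance map
    delta1 = d * c1 / (c1 + c2)
    delta2 = d - delta1
    if np.any(delta1 >= spec.L0):
        raise ValueError(
            f"negative-thickness state at increment {increment_index}: "
            f"max layer compression {delta1.max():.1f} um >= L0 = {spec.L0} um"
        )
    if np.any(delta2 >= spec.H):
        raise ValueError(
            f"tissue fully compressed at increment {increment_index}"
        )
    eps1 = delta1 / spec.L0
    return CompressionState(
        increment=increment_index,
        displacement=d,
        thickness=spec.L0 - delta1,
        eps1=eps1,
        eps2=delta2 / spec.H,
        sigma=spec.E1 * eps1,
    )


def solve_stress_bisection(
    d: float, L0: float, E1: float, H: float, E2: float, tol: float = 1e-12
) -> float:
    """Independent scalar solver for the series-spring equilibrium stress.

    Finds sigma such that ``sigma*L0/E1 + sigma*H/E2 = d`` by root
    bracketing; used as a cross-check oracle for
    :func:`compute_compression_state`, not by the pipeline itself.
    """
    if d <= 0:
        return 0.0
    hi = max(E1, E2) * 10.0
    while hi * L0 / E1 + hi * H / E2 < d:
        hi *= 2.0
    return brentq(lambda s: s * L0 / E1 + s * H / E2 - d, 0.0, hi, xtol=tol)


def render_volume(
    spec: PhantomSpec,
    state: CompressionState,
    rng: np.random.Generator | None = None,
) -> OctVolume:
    """Render one OCT-like volume from a mechanical state.

    The noiseless A-scan has exactly two local maxima, at the rounded
    depth pixels of the two layer interfaces; tissue below the layer
    decays monotonically, so detection oracles are exact when speckle and
    noise are disabled.
    """
    if rng is None:
        rng = np.random.default_rng(spec.rng_seed)
    nx, ny, nz = spec.nx, spec.ny, spec.nz
    a_top, a_bottom = spec.interface_reflectivity
    baseline = 0.02 * a_top

    bottom_depth = spec.glass_depth + state.thickness
    if np.any(bottom_depth >= (nz - 1) * spec.dz):
        raise ValueError(
            f"layer bottom at {bottom_depth.max():.0f} um exceeds imaging depth "
            f"{(nz - 1) * spec.dz:.0f} um"
        )
    top_idx = int(round(spec.glass_depth / spec.dz))
    bottom_idx = np.rint(bottom_depth / spec.dz).astype(int)  # (nx, ny)

    z = np.arange(nz)
    vol = np.full((nx, ny, nz), baseline)
    # tissue mean profile: exponential attenuation below the layer
    depth_below = (z[None, None, :] - bottom_idx[:, :, None]) * spec.dz
    tissue_region = depth_below > 0
    mean_tissue = spec.tissue_level * np.exp(-spec.attenuation_coeff * depth_below,
                                             where=tissue_region, out=np.zeros_like(depth_below))
    if spec.speckle_contrast > 0:
        speckle = (1.0 - spec.speckle_contrast) + spec.speckle_contrast * rng.exponential(
            1.0, size=vol.shape
        )
    else:
        speckle = 1.0
    vol = np.where(tissue_region, np.maximum(mean_tissue * speckle, 0.0), vol)
    vol[:, :, top_idx] = a_top
    np.put_along_axis(vol, bottom_idx[:, :, None], a_bottom, axis=2)
    if spec.noise_sd > 0:
        vol = vol + rng.normal(0.0, spec.noise_sd, size=vol.shape)
    vol = np.clip(vol, 0.0, None)
    return OctVolume(
        intensity=vol,
        dx=spec.dx,
        dy=spec.dy,
        dz=spec.dz,
        stage_position=float(state.increment * spec.stage_step),
        source_id=f"phantom-seed{spec.rng_seed}-inc{state.increment:02d}",
    )


def generate_series(spec: PhantomSpec) -> tuple[list[OctVolume], GroundTruth]:
    """Generate the full compression series and its ground truth.

    Stage positions increase monotonically by ``stage_step``; dead-zone
    volumes keep the layer at ``L0`` (with optional sub-pixel jitter).
    Deterministic for a given ``rng_seed``.
    """
    rng = np.random.default_rng(spec.rng_seed)
    volumes: list[OctVolume] = []
    n = spec.n_increments
    thickness = np.empty((n, spec.nx, spec.ny))
    eps1 = np.empty_like(thickness)
    eps2 = np.empty_like(thickness)
    sigma = np.empty_like(thickness)
    for i in range(n):
        state = compute_compression_state(spec, i)
        render_state = state
        if (
            spec.dead_zone_jitter_um > 0
            and i <= spec.dead_zone_increments
            and state.displacement == 0.0
        ):
            jitter = rng.uniform(-spec.dead_zone_jitter_um, spec.dead_zone_jitter_um)
            render_state = CompressionState(
                increment=state.increment,
                displacement=0.0,
                thickness=state.thickness + jitter,
                eps1=state.eps1,
                eps2=state.eps2,
                sigma=state.sigma,
            )
        volumes.append(render_volume(spec, render_state, rng))
        thickness[i] = state.thickness
        eps1[i] = state.eps1
        eps2[i] = state.eps2
        sigma[i] = state.sigma
    truth = GroundTruth(
        thickness=thickness,
        eps1=eps1,
        eps2=eps2,
        sigma=sigma,
        preload_index_true=spec.dead_zone_increments,
        stage_positions=spec.stage_positions.astype(float),
    )
    return volumes, truth


def _calibration_stress(eps: np.ndarray, E1: float, onset: float,
                        stiffening_kpa: float) -> np.ndarray:
    """Reference-material constitutive law: linear then quadratic stiffening."""
    eps = np.asarray(eps, dtype=float)
    extra = np.where(eps > onset, stiffening_kpa * (eps - onset) ** 2, 0.0)
    return E1 * eps + extra


def generate_calibration_data(
    spec: PhantomSpec,
    layer_diameter_mm: float = 10.0,
    layer_thickness_um: float = 1500.0,
    force_noise_frac: float = 0.0,
    stiffening_kpa: float = 300.0,
    conserve_volume: bool = True,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Synthesize one force-sensor calibration run of the bare layer.

    A silicone disk (no tissue; the ``H -> 0`` limit of the stack) rests on
    a force sensor and is compressed in ``stage_step`` increments, its mean
    thickness decreasing by one step per increment.  Per increment the
    emitted force is ``sigma * area`` with ``sigma = E1 * eps1`` in the
    linear regime and quadratic stiffening above ``nonlinear_strain_onset``.
    The compressed diameter grows to conserve disk volume (incompressible
    approximation) unless ``conserve_volume`` is False.  The series stops
    before the first force exceeding the 4.5 N sensor range.

    The default slab is thicker than the imaging reference layer so that
    fixed 100 um stage steps sample the low-strain region finely enough
    for a linear fit.

    Returns a table with columns
    ``increment, stage_um, force_N, diameter_mm, thickness_um``.
    """
    if rng is None:
        rng = np.random.default_rng(spec.rng_seed)
    if layer_diameter_mm <= 0 or layer_thickness_um <= 0:
        raise ValueError("diameter and thickness must be positive")
    area0_m2 = np.pi * (layer_diameter_mm / 2 * 1e-3) ** 2
    rows = []
    i = 0
    while True:
        stage = i * spec.stage_step
        L = layer_thickness_um - stage
        if L <= 0:
            break
        eps = stage / layer_thickness_um
        sigma_kpa = float(_calibration_stress(eps, spec.E1, spec.nonlinear_strain_onset,
                                              stiffening_kpa))
        if conserve_volume:
            diameter = layer_diameter_mm / np.sqrt(1.0 - eps)
            area = area0_m2 / (1.0 - eps)
        else:
            diameter = layer_diameter_mm
            area = area0_m2
        force = sigma_kpa * 1e3 * area
        if force_noise_frac > 0:
            force *= 1.0 + force_noise_frac * rng.standard_normal()
        if force > FORCE_SENSOR_MAX_N:
            break
        rows.append(
            {
                "increment": i,
                "stage_um": stage,
                "force_N": max(force, 0.0),
                "diameter_mm": float(diameter),
                "thickness_um": float(L),
            }
        )
        i += 1
    return pd.DataFrame(rows)
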