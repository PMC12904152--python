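"""Preload/compressed-state identification and reference-layer strain maps.

The stage is raised in equal increments; early increments produce little
thickness change (poor contact, interfacial fluid), after which thickness
decreases linearly.  The preload state is the onset of that distinct linear
decrease, and the compressed state is three increments (300 um of stage
travel at the default 100 um step) later.  Layer strain per lateral pixel
is eps1 = (L_preload - L_compressed) / L_preload.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .layers import ThicknessMap, mean_thickness

PRELOAD_TO_COMPRESSED_INCREMENTS = 3


class PreloadNotFoundError(RuntimeError):
    """No stage increment satisfied the preload criteria."""


@dataclass
class CompressionSeries:
    """Ordered thickness maps across stage increments.

    Stage positions must be strictly increasing with uniform steps (the
    stage moves in precise, equal increments); at least five increments
    are required so a preload with three subsequent compression steps and
    at least one earlier point can exist.
    """

    thickness_maps: list[ThicknessMap]
    stage_positions: np.ndarray
    provenance: list[str] | None = None

    def __post_init__(self) -> None:
        self.stage_positions = np.asarray(self.stage_positions, dtype=float)
        if len(self.thickness_maps) != len(self.stage_positions):
            raise ValueError("one stage position per thickness map required")
        if len(self.thickness_maps) < 5:
            raise ValueError("need at least 5 increments")
        steps = np.diff(self.stage_positions)
        if np.any(steps <= 0):
            raise ValueError("stage positions must be strictly increasing")
        if np.any(np.abs(steps - steps.mean()) > 0.01 * steps.mean()):
            raise ValueError("stage steps must be uniform within 1%")

    def __len__(self) -> int:
        return len(self.thickness_maps)

    @property
    def step_um(self) -> float:
        return float(np.diff(self.stage_positions).mean())

    def mean_thickness_curve(self) -> np.ndarray:
        """Volume-mean thickness (um) at each increment."""
        return np.array([mean_thickness(m) for m in self.thickness_maps])


@dataclass
class StrainMap:
    """Per-pixel layer strain between the preload and compressed states.

    ``negative`` flags pixels where noise made the layer appear thicker
    under compression; their (negative) strain values are retained rather
    than clamped, and downstream stress lookup excludes them.
    """

    strain: np.ndarray
    valid: np.ndarray
    negative: np.ndarray
    preload_index: int
    compressed_index: int
    preload_thickness: np.ndarray

    def __post_init__(self) -> None:
        if self.compressed_index != self.preload_index + PRELOAD_TO_COMPRESSED_INCREMENTS:
            raise ValueError("compressed state must be 3 increments after preload")
        s = self.strain[self.valid]
        if s.size and (np.nanmax(s) >= 1.0):
            raise ValueError("valid strains must be < 1")


def detect_preload(
    series: CompressionSeries,
    min_drop_um: float = 20.0,
    linearity_r2: float = 0.95,
) -> int:
    """Find the preload increment on the mean-thickness curve.

    Returns the smallest index ``i`` whose mean thickness drops by at
    least ``min_drop_um`` to the next increment and where a linear fit
    over increments ``[i, i+3]`` has negative slope and R^2 at least
    ``linearity_r2`` — a distinct, linear decrease.
    """
    means = series.mean_thickness_curve()
    n = len(series)
    candidates = [
        i for i in range(n - 1) if means[i] - means[i + 1] >= min_drop_um
    ]
    if not candidates:
        raise PreloadNotFoundError(
            f"preload not found: no drop of >= {min_drop_um} um between "
            "consecutive increments"
        )
    for i in candidates:
        if i + PRELOAD_TO_COMPRESSED_INCREMENTS >= n:
            raise PreloadNotFoundError(
                f"insufficient compression range: candidate preload {i} leaves "
                "fewer than 3 increments"
            )
        x = series.stage_positions[i : i + 4]
        y = means[i : i + 4]
        fit = stats.linregress(x, y)
        if fit.slope < 0 and fit.rvalue**2 >= linearity_r2:
            return i
    raise PreloadNotFoundError(
        "preload not found: no candidate passed the linearity criterion"
    )


def compressed_index(preload_index: int, n_increments: int) -> int:
    """Index of the compressed state: three increments after the preload."""
    idx = preload_index + PRELOAD_TO_COMPRESSED_INCREMENTS
    if idx >= n_increments:
        raise ValueError(
            f"compressed index {idx} out of range for {n_increments} increments"
        )
    return idx


def strain_map(
    series: CompressionSeries, preload_index: int, compressed_index: int
) -> StrainMap:
    """Per-pixel strain eps1 = (L_pre - L_comp) / L_pre.

    Valid only where both thickness maps are valid; raises if the overlap
    is empty.
    """
    if not 0 <= preload_index < compressed_index < len(series):
        raise ValueError("preload/compressed indices out of range or misordered")
    pre = series.thickness_maps[preload_index]
    comp = series.thickness_maps[compressed_index]
    valid = pre.valid & comp.valid
    if not valid.any():
        raise ValueError("no pixel valid in both preload and compressed maps")
    strain = np.full(pre.thickness.shape, np.nan)
    strain[valid] = (pre.thickness[valid] - comp.thickness[valid]) / pre.thickness[valid]
    negative = np.zeros_like(valid)
    negative[valid] = strain[valid] < 0
    return StrainMap(
        strain=strain,
        valid=valid,
        negative=negative,
        preload_index=preload_index,
        compressed_index=compressed_index,
        preload_thickness=np.where(valid, pre.thickness, np.nan),
    )
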