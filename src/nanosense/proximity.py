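"""Distance-dependent ion-current model and surface detection.

Near a surface the pipette orifice is progressively occluded, so the
ion current falls from its steady-state value as

    I(d) = I_inf / (1 + c / d),   c = (3/2) * ln(r_o / r_i) * r_i * r_e / h_p

with d the tip-surface distance. The relative-drop criterion inverts in
closed form: the current has fallen by fraction p at d* = c * (1 - p) / p.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import median_filter

__all__ = [
    "PipetteGeometry",
    "ApproachModel",
    "ApproachTrace",
    "SurfaceDetection",
    "ion_current",
    "stop_distance",
    "simulate_approach",
    "detect_surface",
]


@dataclass(frozen=True)
class PipetteGeometry:
    """Tip/base radii and cone height, all in meters."""

    r_i: float = 50e-9
    r_o: float = 110e-9
    r_e: float = 0.5e-3
    h_p: float = 5e-3

    def __post_init__(self) -> None:
        if not (0 < self.r_i < self.r_o):
            raise ValueError("need 0 < r_i < r_o")
        if self.r_e < self.r_i:
            raise ValueError("need r_e >= r_i")
        if self.h_p <= 0:
            raise ValueError("need h_p > 0")


@dataclass(frozen=True)
class ApproachModel:
    """Current-vs-distance model; U is informational (I_inf = U / R_p)."""

    geometry: PipetteGeometry = PipetteGeometry()
    i_inf: float = 1e-9
    u: float | None = None

    def __post_init__(self) -> None:
        if self.i_inf <= 0:
            raise ValueError("i_inf must be positive")

    @property
    def occlusion_length(self) -> float:
        """The length scale c (meters) at which the current is halved."""
        g = self.geometry
        return 1.5 * np.log(g.r_o / g.r_i) * g.r_i * g.r_e / g.h_p


@dataclass
class ApproachTrace:
    distances: np.ndarray  # meters, strictly decreasing over the approach
    current: np.ndarray  # amperes
    noise_sigma: float = 0.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        d = np.asarray(self.distances, dtype=float)
        i = np.asarray(self.current, dtype=float)
        if d.size != i.size or d.size == 0:
            raise ValueError("distances and current must be nonempty, equal length")
        if d.size > 1 and not np.all(np.diff(d) < 0):
            raise ValueError("distances must be strictly decreasing")
        self.distances = d
        self.current = i


@dataclass
class SurfaceDetection:
    detected: bool
    index: int | None = None
    distance: float | None = None  # meters, stage position at detection
    baseline: float = float("nan")


def ion_current(d, model: ApproachModel):
    """Evaluate I(d) for scalar or array distances (meters)."""
    d = np.asarray(d, dtype=float)
    if np.any(d <= 0):
        raise ValueError("distance must be positive")
    out = model.i_inf / (1.0 + model.occlusion_length / d)
    return float(out) if out.ndim == 0 else out


def stop_distance(model: ApproachModel, drop_fraction: float) -> float:
    """Distance at which the current has dropped by ``drop_fraction``.

    Closed-form inversion: I(d*) = (1 - p) * I_inf at d* = c (1 - p) / p.
    """
    p = drop_fraction
    if not (0 < p < 1):
        raise ValueError("drop_fraction must lie in (0, 1)")
    return model.occlusion_length * (1.0 - p) / p


def simulate_approach(
    model: ApproachModel,
    distances,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> ApproachTrace:
    """Noisy current trace over a strictly decreasing distance schedule."""
    d = np.asarray(distances, dtype=float)
    current = ion_current(d, model)
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        current = current + rng.normal(0.0, noise_sigma, size=current.shape)
    return ApproachTrace(
        distances=d, current=current, noise_sigma=noise_sigma, rng_seed=seed
    )


def detect_surface(
    trace: ApproachTrace,
    drop_fraction: float = 0.02,
    baseline_n: int = 20,
    smooth_w: int = 5,
    confirm_m: int = 3,
) -> SurfaceDetection:
    """First position where the smoothed current has durably dropped.

    The steady-state current is estimated as the median of the first
    ``baseline_n`` samples; the trace is smoothed by a centered moving
    median of width ``smooth_w``; detection fires at the first index
    opening a run of ``confirm_m`` consecutive smoothed samples at or
    below ``(1 - drop_fraction) * baseline``.
    """
    if not (0 < drop_fraction < 1):
        raise ValueError("drop_fraction must lie in (0, 1)")
    n = trace.current.size
    if n <= baseline_n + confirm_m:
        raise ValueError("trace too short for the requested windows")
    baseline = float(np.median(trace.current[:baseline_n]))
    smoothed = median_filter(trace.current, size=smooth_w, mode="nearest")
    below = smoothed <= (1.0 - drop_fraction) * baseline
    run = 0
    for i, flag in enumerate(below):
        run = run + 1 if flag else 0
        if run == confirm_m:
            start = i - confirm_m + 1
            return SurfaceDetection(
                detected=True,
                index=start,
                distance=float(trace.distances[start]),
                baseline=baseline,
            )
    return SurfaceDetection(detected=False, baseline=baseline)
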