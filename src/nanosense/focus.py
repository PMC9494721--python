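"""Focus measures and focus-curve analysis.

The contour-count measure (``nocc``) is provided by :mod:`.cell_detect`;
this module adds the four classical gradient/statistics measures used for
comparison, curve construction and normalization, argmax search over a
z-stack, and the curve-quality metrics (range, false maxima, noise level).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, NamedTuple, Sequence

import numpy as np

from . import cell_detect
from .cell_detect import DetectionParams, DetectionResult

__all__ = [
    "FocusCurve",
    "CurveQuality",
    "CurveRange",
    "NoFocusFoundError",
    "tenengrad",
    "energy",
    "brenner",
    "variance",
    "METRICS",
    "focus_curve",
    "find_best_defocus",
    "count_false_maxima",
    "curve_range",
    "noise_level",
    "curve_quality",
]


class NoFocusFoundError(RuntimeError):
    """The focus measure was zero on every plane of the stack."""


@dataclass(frozen=True)
class FocusCurve:
    z: np.ndarray  # micrometers, strictly monotone
    values: np.ndarray
    metric_name: str = ""
    normalized: bool = False

    def __post_init__(self) -> None:
        z = np.asarray(self.z, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if z.size != v.size or z.size == 0:
            raise ValueError("z and values must be nonempty and the same length")
        if z.size > 1:
            dz = np.diff(z)
            if not (np.all(dz > 0) or np.all(dz < 0)):
                raise ValueError("z must be strictly monotone")
        object.__setattr__(self, "z", z)
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return int(self.z.size)

    def normalize(self) -> "FocusCurve":
        """Min-max rescale to [0, 1]; an all-equal curve maps to zeros."""
        v = self.values
        span = v.max() - v.min()
        scaled = np.zeros_like(v) if span == 0 else (v - v.min()) / span
        return replace(self, values=scaled, normalized=True)


class CurveRange(NamedTuple):
    range_um: float
    bracketed: bool  # False when the required flanking extrema were absent


@dataclass(frozen=True)
class CurveQuality:
    range_um: float
    false_maxima: int
    noise_level: float
    best_z: float


def _check_image(img: np.ndarray) -> np.ndarray:
    arr = np.asarray(img, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 3 or arr.shape[1] < 3:
        raise ValueError("focus measures need a 2-D image of at least 3x3")
    return arr


def tenengrad(img: np.ndarray) -> float:
    """Sum of squared Sobel gradient magnitudes."""
    arr = _check_image(img)
    kx = np.array([[-1, 0, 1], [-2, 0, 2], [-1, 0, 1]], dtype=float)
    gx = _valid_convolve(arr, kx)
    gy = _valid_convolve(arr, kx.T)
    return float((gx**2 + gy**2).sum())


def _valid_convolve(arr: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    from scipy.signal import convolve2d

    return convolve2d(arr, kernel[::-1, ::-1], mode="valid")


def energy(img: np.ndarray) -> float:
    """Sum of squared first differences along both axes."""
    arr = _check_image(img)
    dx = np.diff(arr, axis=1)
    dy = np.diff(arr, axis=0)
    return float((dx**2).sum() + (dy**2).sum())


def brenner(img: np.ndarray) -> float:
    """Sum of squared two-pixel horizontal differences."""
    arr = _check_image(img)
    d = arr[:, 2:] - arr[:, :-2]
    return float((d**2).sum())


def variance(img: np.ndarray) -> float:
    """Sum of squared deviations from the image mean."""
    arr = _check_image(img)
    return float(((arr - arr.mean()) ** 2).sum())


METRICS: dict[str, Callable[[np.ndarray], float]] = {
    "tenengrad": tenengrad,
    "energy": energy,
    "brenner": brenner,
    "variance": variance,
    "nocc": cell_detect.nocc,
}


def focus_curve(
    zstack: Sequence[np.ndarray],
    z_list: Sequence[float],
    metric: str,
    params: DetectionParams | None = None,
    normalize: bool = False,
) -> FocusCurve:
    """Evaluate a named focus measure on every plane of a stack."""
    if len(zstack) == 0:
        raise ValueError("empty stack")
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}; choose from {sorted(METRICS)}")
    fn = METRICS[metric]
    if metric == "nocc":
        values = [float(fn(plane, params)) for plane in zstack]
    else:
        values = [fn(plane) for plane in zstack]
    curve = FocusCurve(z=np.asarray(z_list, float), values=np.asarray(values), metric_name=metric)
    return curve.normalize() if normalize else curve


def find_best_defocus(
    zstack: Sequence[np.ndarray],
    z_list: Sequence[float],
    params: DetectionParams | None = None,
) -> tuple[float, DetectionResult]:
    """Exhaustive argmax of the contour count over the stack.

    Ties are broken by the smallest |z| (then the smaller z). Raises
    :class:`NoFocusFoundError` when no plane yields any contour.
    """
    if len(zstack) == 0:
        raise ValueError("empty stack")
    z = np.asarray(z_list, dtype=float)
    results = [cell_detect.detect_cells(plane, params) for plane in zstack]
    counts = np.array([r.nocc for r in results])
    if counts.max() == 0:
        raise NoFocusFoundError("contour count was zero on every plane")
    best = np.flatnonzero(counts == counts.max())
    winner = min(best, key=lambda i: (abs(z[i]), z[i]))
    return float(z[winner]), results[winner]


def _collapse_plateaus(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Compress runs of equal values to one sample at the run's center index."""
    values = np.asarray(values, dtype=float)
    starts = np.flatnonzero(np.r_[True, np.diff(values) != 0])
    ends = np.r_[starts[1:], values.size]  # exclusive
    centers = (starts + ends - 1) // 2
    return values[starts], centers


def count_false_maxima(curve: FocusCurve) -> int:
    """Strict interior local maxima other than the global maximum.

    Plateaus are collapsed to a single candidate before counting.
    """
    if len(curve) < 3:
        raise ValueError("curve must have at least 3 samples")
    v, _ = _collapse_plateaus(curve.values)
    if v.size < 3:
        return 0
    interior = np.flatnonzero((v[1:-1] > v[:-2]) & (v[1:-1] > v[2:])) + 1
    if interior.size == 0:
        return 0
    global_val = curve.values.max()
    count = int(interior.size)
    if np.any(v[interior] == global_val):
        count -= 1  # one of the local maxima is the true peak
    return count


def curve_range(curve: FocusCurve, mode: str = "minima_bracket") -> CurveRange:
    """Z-extent of the usable monotone region around the focus feature.

    ``minima_bracket``: distance between the local minima flanking the
    global maximum (curve ends count as minima). ``maxima_bracket``: for
    measures that dip at the focus plane -- distance between the local
    maxima flanking that interior dip. When a required extremum is
    missing, the full z-span is returned with ``bracketed=False``.
    """
    if len(curve) < 3:
        raise ValueError("curve must have at least 3 samples")
    if mode not in ("minima_bracket", "maxima_bracket"):
        raise ValueError(f"unknown mode {mode!r}")
    v, centers = _collapse_plateaus(curve.values)
    z = curve.z
    full_span = float(abs(z[-1] - z[0]))

    if mode == "minima_bracket":
        pivot = int(np.argmax(v))
        if pivot == 0 or pivot == v.size - 1:
            return CurveRange(full_span, False)

        def is_flank(i: int) -> bool:  # local minimum; curve ends count
            return i == 0 or i == v.size - 1 or (v[i] < v[i - 1] and v[i] < v[i + 1])

        left = pivot - 1
        while not is_flank(left):
            left -= 1
        right = pivot + 1
        while not is_flank(right):
            right += 1
        return CurveRange(float(abs(z[centers[right]] - z[centers[left]])), True)

    # maxima_bracket: the focus plane is an interior local minimum; among
    # the dips, take the one whose flanking local maxima are highest
    n = v.size
    local_min = [i for i in range(1, n - 1) if v[i] < v[i - 1] and v[i] < v[i + 1]]
    local_max = [i for i in range(1, n - 1) if v[i] > v[i - 1] and v[i] > v[i + 1]]
    best: tuple[float, int, int] | None = None
    for i in local_min:
        lefts = [j for j in local_max if j < i]
        rights = [j for j in local_max if j > i]
        if not lefts or not rights:
            continue
        lj, rj = max(lefts), min(rights)
        score = min(v[lj], v[rj])
        if best is None or score > best[0]:
            best = (float(score), lj, rj)
    if best is None:
        return CurveRange(full_span, False)
    _, lj, rj = best
    return CurveRange(float(abs(z[centers[rj]] - z[centers[lj]])), True)


def noise_level(curve: FocusCurve, normalize: bool = False) -> float:
    """Sum of squared discrete second differences of the curve values."""
    if len(curve) < 3:
        raise ValueError("curve must have at least 3 samples")
    v = curve.normalize().values if normalize else curve.values
    second = v[:-2] - 2 * v[1:-1] + v[2:]
    return float((second**2).sum())


def curve_quality(curve: FocusCurve, mode: str = "minima_bracket") -> CurveQuality:
    """Bundle the curve metrics; noise level is taken on the normalized curve."""
    norm = curve if curve.normalized else curve.normalize()
    rng = curve_range(curve, mode=mode)
    best_idx = int(np.argmax(curve.values))
    return CurveQuality(
        range_um=rng.range_um,
        false_maxima=count_false_maxima(curve),
        noise_level=noise_level(norm),
        best_z=float(curve.z[best_idx]),
    )
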