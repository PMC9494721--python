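"""Zero-mean normalized cross-correlation and the nonovershoot descent.

The similarity map is the normalized correlation coefficient between a
mean-subtracted template and every same-size image window; the descent
controller lowers a virtual tip stage until the best match crosses a
similarity threshold, which (for a sub-critical threshold) halts it on
the near side of the focal plane.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import fftconvolve

from .scene_sim import TipStage

__all__ = [
    "SimilarityMap",
    "ApproachLog",
    "ncc_similarity",
    "best_match",
    "extract_template",
    "approach_until_similar",
]

_EPS = 1e-12


@dataclass(frozen=True)
class SimilarityMap:
    values: np.ndarray  # (H-h+1, W-w+1) raster of correlation coefficients

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class ApproachLog:
    z_sequence: list[float] = field(default_factory=list)
    similarity_sequence: list[float] = field(default_factory=list)
    stop_z: float = float("nan")
    crossed: bool = False  # similarity threshold reached before z_limit
    stopped_before_focus: bool = False


def _window_sums(img: np.ndarray, h: int, w: int) -> tuple[np.ndarray, np.ndarray]:
    """Sliding-window sums of I and I^2 via padded cumulative sums."""
    s1 = np.cumsum(np.cumsum(img, axis=0), axis=1)
    s2 = np.cumsum(np.cumsum(img * img, axis=0), axis=1)

    def box(s: np.ndarray) -> np.ndarray:
        s = np.pad(s, ((1, 0), (1, 0)))
        return s[h:, w:] - s[:-h, w:] - s[h:, :-w] + s[:-h, :-w]

    return box(s1), box(s2)


def ncc_similarity(img: np.ndarray, template: np.ndarray) -> SimilarityMap:
    """Correlation-coefficient map of the template over every image window.

    For each offset (x, y):

        S = sum(T' * I') / sqrt(sum(T'^2) * sum(I'^2))

    with T' and I' the mean-subtracted template and window. Windows with
    zero variance get S = 0 (a flat patch cannot match a structured
    template). A constant template is an error.
    """
    img = np.asarray(img, dtype=float)
    tmpl = np.asarray(template, dtype=float)
    if img.ndim != 2 or tmpl.ndim != 2:
        raise ValueError("image and template must be 2-D")
    h, w = tmpl.shape
    if h < 2 or w < 2:
        raise ValueError("template must be at least 2x2")
    if h > img.shape[0] or w > img.shape[1]:
        raise ValueError("template must fit inside the image")
    t_zero = tmpl - tmpl.mean()
    t_ss = float((t_zero**2).sum())
    if t_ss <= _EPS:
        raise ValueError("constant template has no correlation structure")
    # numerator: since sum(T') = 0, sum(T'*(I - mean_w)) = sum(T'*I)
    num = fftconvolve(img, t_zero[::-1, ::-1], mode="valid")
    s1, s2 = _window_sums(img, h, w)
    win_var = s2 - s1 * s1 / (h * w)  # sum of squared deviations per window
    win_var = np.maximum(win_var, 0.0)
    denom = np.sqrt(t_ss * win_var)
    flat = denom <= np.sqrt(t_ss) * 1e-7
    with np.errstate(divide="ignore", invalid="ignore"):
        values = np.where(flat, 0.0, num / np.where(flat, 1.0, denom))
    return SimilarityMap(values=values)


def best_match(smap: SimilarityMap) -> tuple[float, tuple[int, int]]:
    """Maximal similarity and its offset; ties -> smallest row, then column."""
    values = smap.values
    if values.size == 0:
        raise ValueError("empty similarity map")
    idx = int(np.argmax(values))  # row-major argmax implements the tie rule
    offset = np.unravel_index(idx, values.shape)
    return float(values[offset]), (int(offset[0]), int(offset[1]))


def extract_template(
    img: np.ndarray, center: tuple[float, float], half: int = 24
) -> np.ndarray:
    """Crop a square template around a point, clamped to the image."""
    r0 = int(np.clip(round(center[0]) - half, 0, img.shape[0] - 1))
    c0 = int(np.clip(round(center[1]) - half, 0, img.shape[1] - 1))
    r1 = min(r0 + 2 * half, img.shape[0])
    c1 = min(c0 + 2 * half, img.shape[1])
    return np.asarray(img)[r0:r1, c0:c1].copy()


def approach_until_similar(
    stage: TipStage,
    template: np.ndarray,
    threshold: float = 0.92,
    step: float = 5.0,
    z_start: float = 150.0,
    z_limit: float = -50.0,
) -> ApproachLog:
    """Lower the stage until the best template match reaches the threshold.

    Descends from ``z_start`` in ``step``-micrometer decrements, recording
    the max correlation at every visited position; stops at the first
    position with S >= threshold, or at ``z_limit`` with ``crossed=False``.
    ``stopped_before_focus`` reports whether the halt position is still
    above the stage's focal plane.
    """
    if not (0 < threshold < 1):
        raise ValueError("threshold must lie in (0, 1)")
    if step <= 0:
        raise ValueError("step must be positive")
    log = ApproachLog()
    z = float(z_start)
    while True:
        frame = stage.observe(z)
        s_max, _ = best_match(ncc_similarity(frame, template))
        log.z_sequence.append(z)
        log.similarity_sequence.append(s_max)
        if s_max >= threshold:
            log.crossed = True
            break
        if z - step < z_limit:
            break
        z -= step
    log.stop_z = log.z_sequence[-1]
    log.stopped_before_focus = log.stop_z > stage.tip.z_focus
    return log
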