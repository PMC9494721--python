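"""Pipette-tip localization in a single frame.

Chain: gamma enhancement -> Otsu binarization -> morphological close ->
inversion -> longest contour -> closed-curve polygon simplification ->
triangle test -> apex (sharpest vertex). A non-triangular fit means "tip
not detected", which is a result, not an error.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cell_detect import (
    Contour,
    DegenerateHistogramError,
    extract_contours,
    morph_close,
    otsu_threshold,
    to_gray,
)

__all__ = [
    "TipDetection",
    "TipParams",
    "gamma_transform",
    "longest_contour",
    "fit_polygon",
    "locate_tip",
]


@dataclass(frozen=True)
class TipParams:
    gamma: float = 0.6
    close_radius: int = 1  # radius 2 erodes the sharp apex by several pixels
    min_area: int = 30
    epsilon_frac: float = 0.02
    min_area_ratio: float = 0.8  # polygon area / contour area, rejects slivers


@dataclass
class TipDetection:
    detected: bool
    apex: tuple[float, float] | None = None
    polygon: np.ndarray | None = None
    contour_length: float = 0.0
    extras: dict = field(default_factory=dict)


def gamma_transform(img: np.ndarray, gamma: float) -> np.ndarray:
    """Pointwise power-law enhancement: round(255 * (I/255)**gamma)."""
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    img = to_gray(img)
    lut = np.rint(255.0 * (np.arange(256) / 255.0) ** gamma).astype(np.uint8)
    return lut[img]


def longest_contour(contours: list[Contour]) -> Contour:
    """Contour of maximal perimeter; ties broken by larger area."""
    if not contours:
        raise ValueError("no contours to choose from")
    return max(contours, key=lambda c: (c.perimeter, c.area))


def _rdp_open(points: np.ndarray, eps: float) -> np.ndarray:
    """Ramer-Douglas-Peucker on an open chain, keeping both endpoints."""
    if len(points) < 3:
        return points
    start, end = points[0], points[-1]
    seg = end - start
    norm = np.hypot(*seg)
    d = points - start
    if norm == 0:
        dist = np.hypot(d[:, 0], d[:, 1])
    else:
        dist = np.abs(seg[0] * d[:, 1] - seg[1] * d[:, 0]) / norm
    idx = int(np.argmax(dist))
    if dist[idx] <= eps:
        return np.vstack([start, end])
    left = _rdp_open(points[: idx + 1], eps)
    right = _rdp_open(points[idx:], eps)
    return np.vstack([left[:-1], right])


def fit_polygon(contour: Contour, epsilon_frac: float = 0.02) -> np.ndarray:
    """Closed-curve RDP simplification with tolerance epsilon_frac * perimeter.

    The ring is split at its two mutually farthest anchor vertices and each
    half is simplified independently, so the result does not depend on
    where the ring happens to start. Output vertices are a subset of the
    input vertices.
    """
    if epsilon_frac <= 0:
        raise ValueError("epsilon_frac must be positive")
    pts = np.asarray(contour.vertices, dtype=float)
    if len(pts) <= 3:
        return pts
    eps = epsilon_frac * contour.perimeter
    # anchor 0: farthest from the centroid; anchor 1: farthest from anchor 0
    ref = pts.mean(axis=0)
    a0 = int(np.argmax(((pts - ref) ** 2).sum(axis=1)))
    a1 = int(np.argmax(((pts - pts[a0]) ** 2).sum(axis=1)))
    i, j = sorted((a0, a1))
    half1 = pts[i : j + 1]
    half2 = np.vstack([pts[j:], pts[: i + 1]])
    simp1 = _rdp_open(half1, eps)
    simp2 = _rdp_open(half2, eps)
    return np.vstack([simp1[:-1], simp2[:-1]])


def _interior_angles(poly: np.ndarray) -> np.ndarray:
    prev = np.roll(poly, 1, axis=0)
    nxt = np.roll(poly, -1, axis=0)
    v1 = prev - poly
    v2 = nxt - poly
    dot = (v1 * v2).sum(axis=1)
    n1 = np.hypot(*v1.T)
    n2 = np.hypot(*v2.T)
    with np.errstate(invalid="ignore", divide="ignore"):
        cosang = np.clip(dot / (n1 * n2), -1.0, 1.0)
    return np.arccos(cosang)


def _poly_area(poly: np.ndarray) -> float:
    r, c = poly[:, 0], poly[:, 1]
    return 0.5 * abs(np.dot(c, np.roll(r, -1)) - np.dot(r, np.roll(c, -1)))


def locate_tip(
    img: np.ndarray,
    params: TipParams | None = None,
    roi_center: tuple[float, float] | None = None,
    roi_half: int = 80,
) -> TipDetection:
    """Find the pipette apex; ``detected`` is False for non-triangular scenes.

    When ``roi_center`` is given, detection runs inside a window of
    half-size ``roi_half`` around the prior estimate (clamped to the
    image) and coordinates are reported in full-image frame.
    """
    params = params or TipParams()
    gray = to_gray(img)
    offset = np.zeros(2)
    if roi_center is not None:
        r0 = int(np.clip(roi_center[0] - roi_half, 0, gray.shape[0]))
        r1 = int(np.clip(roi_center[0] + roi_half, 0, gray.shape[0]))
        c0 = int(np.clip(roi_center[1] - roi_half, 0, gray.shape[1]))
        c1 = int(np.clip(roi_center[1] + roi_half, 0, gray.shape[1]))
        gray = gray[r0:r1, c0:c1]
        offset = np.array([r0, c0], dtype=float)
        if gray.size == 0:
            return TipDetection(detected=False, extras={"reason": "empty_roi"})
    enhanced = gamma_transform(gray, params.gamma)
    try:
        thr = otsu_threshold(enhanced)
    except DegenerateHistogramError:
        return TipDetection(detected=False, extras={"reason": "flat_image"})
    binary = enhanced > thr
    closed = morph_close(binary, params.close_radius)
    inverted = ~closed  # tip is darker than the background
    contours = extract_contours(inverted, min_area=params.min_area)
    if not contours:
        return TipDetection(detected=False, extras={"reason": "no_contours"})
    contour = longest_contour(contours)
    poly = fit_polygon(contour, params.epsilon_frac)
    detection = TipDetection(
        detected=False,
        polygon=poly + offset,
        contour_length=contour.perimeter,
    )
    if len(poly) != 3:
        detection.extras["reason"] = f"{len(poly)}_vertices"
        return detection
    ratio = _poly_area(poly) / max(contour.area, 1e-9)
    if ratio < params.min_area_ratio:
        detection.extras["reason"] = f"area_ratio_{ratio:.2f}"
        return detection
    apex_idx = int(np.argmin(_interior_angles(poly)))
    # refine against the full-resolution contour: the apex is the centroid
    # of the contour points (nearly) farthest from the base edge -- tie-free,
    # so it is stable under image rotation
    base = np.delete(poly, apex_idx, axis=0)
    seg = base[1] - base[0]
    norm = np.hypot(seg[0], seg[1])
    pts = contour.vertices
    if norm > 0:
        d = pts - base[0]
        dist = np.abs(seg[0] * d[:, 1] - seg[1] * d[:, 0]) / norm
        apex = pts[dist >= dist.max() - 0.75].mean(axis=0) + offset
    else:
        apex = poly[apex_idx] + offset
    poly[apex_idx] = apex - offset
    detection.polygon = poly + offset
    detection.detected = True
    detection.apex = (float(apex[0]), float(apex[1]))
    return detection
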