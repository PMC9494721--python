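"""Defocused-cell segmentation and penetration-site extraction.

The chain is: Gaussian blur -> grayscale -> hybrid triangle/Otsu
binarization -> morphological close -> inversion -> outer-contour
extraction -> contour count (NOCC) and per-contour centroids.

The hybrid binarization step is what keeps the contour count at zero on
the negative-defocus side: when the Otsu threshold exceeds the histogram
peak the image is thresholded by the triangle rule toward the brighter
end, which leaves the background as one connected region.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import measure, morphology

__all__ = [
    "Contour",
    "DetectionResult",
    "DetectionParams",
    "DegenerateHistogramError",
    "to_gray",
    "gaussian_blur",
    "otsu_threshold",
    "histogram_peak",
    "triangle_threshold",
    "hybrid_binarize",
    "morph_close",
    "extract_contours",
    "nocc",
    "detect_cells",
    "penetration_sites",
]

# (row, col), 0-based, origin top-left; contour vertices are pixel centers.

_LUMA = np.array([0.2125, 0.7154, 0.0721])  # Rec. 709 weights


class DegenerateHistogramError(ValueError):
    """Histogram has no structure to threshold (e.g. constant image)."""


@dataclass(frozen=True)
class Contour:
    """Closed outer boundary of one segmented component."""

    vertices: np.ndarray  # (n, 2) float array of (row, col) points, closed ring
    pixel_area: int  # component size in pixels

    @property
    def area(self) -> float:
        """Shoelace area of the boundary polygon."""
        r = self.vertices[:, 0]
        c = self.vertices[:, 1]
        return 0.5 * abs(np.dot(c, np.roll(r, -1)) - np.dot(r, np.roll(c, -1)))

    @property
    def perimeter(self) -> float:
        d = np.diff(self.vertices, axis=0, append=self.vertices[:1])
        return float(np.hypot(d[:, 0], d[:, 1]).sum())

    def centroid(self) -> tuple[float, float]:
        """Area-moment centroid of the filled boundary polygon."""
        r = self.vertices[:, 0]
        c = self.vertices[:, 1]
        rn = np.roll(r, -1)
        cn = np.roll(c, -1)
        cross = c * rn - cn * r
        a6 = 3.0 * cross.sum()  # 6 * signed area
        if abs(a6) < 1e-12:
            # degenerate ring: fall back to the vertex mean
            return float(r.mean()), float(c.mean())
        cy = ((r + rn) * cross).sum() / a6
        cx = ((c + cn) * cross).sum() / a6
        return float(cy), float(cx)


@dataclass(frozen=True)
class DetectionParams:
    """Tuning knobs of the segmentation chain (defaults at 1024-width scale)."""

    blur_sigma: float = 2.0
    close_radius: int = 2
    min_area: int = 30
    max_area_frac: float = 0.3  # components above this fraction are background


@dataclass
class DetectionResult:
    contours: list[Contour] = field(default_factory=list)
    sites: list[tuple[float, float]] = field(default_factory=list)
    t_otsu: int = 0
    t_peak: int = 0
    branch: str = ""  # "otsu" | "triangle"
    threshold: int = 0

    @property
    def nocc(self) -> int:
        return len(self.contours)


def to_gray(img: np.ndarray) -> np.ndarray:
    """Coerce an image to a 2-D uint8 raster (RGB via Rec. 709 luminance)."""
    arr = np.asarray(img)
    if arr.ndim == 3:
        arr = arr[..., :3] @ _LUMA
    if arr.ndim != 2 or arr.size == 0:
        raise ValueError("expected a nonempty 2-D (or RGB) image")
    return np.clip(np.rint(arr.astype(float)), 0, 255).astype(np.uint8)


def gaussian_blur(img: np.ndarray, sigma: float) -> np.ndarray:
    """Separable Gaussian blur with reflective borders; sigma=0 is identity."""
    if sigma < 0:
        raise ValueError("sigma must be nonnegative")
    img = np.asarray(img)
    if sigma == 0:
        return img.copy()
    out = ndimage.gaussian_filter(img.astype(float), sigma, mode="reflect")
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def _histogram(img: np.ndarray) -> np.ndarray:
    return np.bincount(np.asarray(img, dtype=np.uint8).ravel(), minlength=256)


def otsu_threshold(img: np.ndarray) -> int:
    """Gray level maximizing between-class variance; ties -> smallest level.

    The returned level t partitions the histogram into [0, t] and
    [t+1, 255].
    """
    hist = _histogram(img).astype(float)
    if np.count_nonzero(hist) < 2:
        raise DegenerateHistogramError("constant image has no Otsu threshold")
    total = hist.sum()
    levels = np.arange(256)
    w0 = np.cumsum(hist)
    mu = np.cumsum(hist * levels)
    mu_t = mu[-1]
    w1 = total - w0
    with np.errstate(divide="ignore", invalid="ignore"):
        var_between = np.where(
            (w0 > 0) & (w1 > 0), (mu_t * w0 - mu * total) ** 2 / (w0 * w1), -np.inf
        )
    return int(np.argmax(var_between))


def histogram_peak(img: np.ndarray) -> int:
    """Mode of the 256-bin histogram; ties -> smallest level."""
    hist = _histogram(img)
    if hist.sum() == 0:
        raise ValueError("empty image")
    return int(np.argmax(hist))


def triangle_threshold(img: np.ndarray, toward: str = "brighter_end") -> int:
    """Triangle-rule threshold toward the requested end of the histogram.

    A line joins (peak bin, peak count) and (end bin, end count), where the
    end bin is the farthest nonzero bin on the requested side of the peak;
    the returned bin maximizes the perpendicular distance from the
    histogram curve to that line.
    """
    if toward not in ("brighter_end", "darker_end"):
        raise ValueError(f"unknown side {toward!r}")
    hist = _histogram(img).astype(float)
    if np.count_nonzero(hist) < 2:
        raise DegenerateHistogramError("constant image has no triangle threshold")
    peak = int(np.argmax(hist))
    nonzero = np.flatnonzero(hist)
    end = int(nonzero[-1]) if toward == "brighter_end" else int(nonzero[0])
    if end == peak:
        raise DegenerateHistogramError(f"histogram peak is already at the {toward}")
    lo, hi = sorted((peak, end))
    if hi - lo < 2:
        raise DegenerateHistogramError("no bins strictly between peak and end")
    bins = np.arange(lo, hi + 1, dtype=float)
    counts = hist[lo : hi + 1]
    # perpendicular distance from (bin, count) to the peak-end chord
    dx = float(end - peak)
    dy = float(hist[end] - hist[peak])
    norm = np.hypot(dx, dy)
    dist = np.abs(dy * (bins - peak) - dx * (counts - hist[peak])) / norm
    interior = (bins != peak) & (bins != end)
    dist[~interior] = -np.inf
    return int(bins[np.argmax(dist)])


def hybrid_binarize(img: np.ndarray) -> tuple[np.ndarray, dict]:
    """Binarize with the defocus-sign-aware threshold choice.

    Returns ``(binary, record)`` where ``binary`` is True for pixels above
    the chosen threshold (bright background) and ``record`` holds
    ``t_otsu``, ``t_peak``, the branch taken and the threshold applied.

    Branch rule: Otsu threshold above (or equal to) the histogram peak is
    the negative-defocus signature -> triangle threshold toward the
    brighter end (background stays one connected region); Otsu below the
    peak -> threshold at the Otsu level (cell bodies separate out).
    """
    img = to_gray(img)
    t_otsu = otsu_threshold(img)
    t_peak = histogram_peak(img)
    if t_otsu >= t_peak:  # ties treated as negative defocus
        branch = "triangle"
        thr = triangle_threshold(img, toward="brighter_end")
    else:
        branch = "otsu"
        thr = t_otsu
    binary = img > thr
    record = {"t_otsu": t_otsu, "t_peak": t_peak, "branch": branch, "threshold": thr}
    return binary, record


def morph_close(binary: np.ndarray, se_radius: int = 2) -> np.ndarray:
    """Dilation then erosion with a disk structuring element."""
    if se_radius < 1:
        raise ValueError("se_radius must be >= 1")
    yy, xx = np.mgrid[-se_radius : se_radius + 1, -se_radius : se_radius + 1]
    se = (yy**2 + xx**2) <= se_radius**2
    # skimage pads each half-operation with its neutral value, so the result
    # is a true (idempotent) closing with no border-frame artifact
    return morphology.closing(np.asarray(binary, bool), footprint=se)


def extract_contours(
    binary: np.ndarray, min_area: int = 0, max_area: int | None = None
) -> list[Contour]:
    """Outer boundaries of 8-connected foreground components.

    Components smaller than ``min_area`` pixels (or larger than
    ``max_area``, when given -- used to reject the connected background)
    are discarded. Contours are returned by descending component area.
    """
    binary = np.asarray(binary, bool)
    labels, n = ndimage.label(binary, structure=np.ones((3, 3), int))
    out: list[Contour] = []
    if n == 0:
        return out
    areas = ndimage.sum_labels(binary, labels, index=np.arange(1, n + 1)).astype(int)
    slices = ndimage.find_objects(labels)
    for lab, (area, slc) in enumerate(zip(areas, slices), start=1):
        if area < min_area or (max_area is not None and area > max_area):
            continue
        # pad so components touching the border still close their ring
        mask = np.pad(labels[slc] == lab, 1).astype(float)
        rings = measure.find_contours(mask, 0.5)
        ring = max(rings, key=len)
        offset = np.array([slc[0].start - 1, slc[1].start - 1], dtype=float)
        out.append(Contour(vertices=ring[:-1] + offset, pixel_area=int(area)))
    out.sort(key=lambda c: c.pixel_area, reverse=True)
    return out


def detect_cells(img: np.ndarray, params: DetectionParams | None = None) -> DetectionResult:
    """Run the full segmentation chain and collect contours + centroids."""
    params = params or DetectionParams()
    gray = to_gray(gaussian_blur(to_gray(img), params.blur_sigma))
    try:
        binary, record = hybrid_binarize(gray)
    except DegenerateHistogramError:
        # featureless frame: nothing to segment
        return DetectionResult(branch="degenerate")
    closed = morph_close(binary, params.close_radius)
    inverted = ~closed
    max_area = int(params.max_area_frac * inverted.size)
    contours = extract_contours(inverted, min_area=params.min_area, max_area=max_area)
    result = DetectionResult(
        contours=contours,
        t_otsu=record["t_otsu"],
        t_peak=record["t_peak"],
        branch=record["branch"],
        threshold=record["threshold"],
    )
    result.sites = penetration_sites(contours)
    return result


def nocc(img: np.ndarray, params: DetectionParams | None = None) -> int:
    """Number of cell contours: the focus measure driving z-positioning."""
    return detect_cells(img, params).nocc


def penetration_sites(contours: list[Contour]) -> list[tuple[float, float]]:
    """Per-contour area-moment centroids; zero-area contours are skipped."""
    sites = []
    for c in contours:
        if c.area <= 0 and c.pixel_area <= 0:
            continue
        sites.append(c.centroid())
    return sites
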