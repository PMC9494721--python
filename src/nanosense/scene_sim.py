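"""Synthetic scene generation for the virtual sensing bench.

Renders three families of inputs entirely in software:

* defocused images (and z-stacks) of transparent adherent cells, whose
  contrast is ``defocus * delta_n * laplacian(thickness)`` relative to the
  background intensity,
* images of an opaque triangular pipette tip whose blur and contrast
  degrade with distance from its focal plane,
* per-cell ground-truth masks and centroids for evaluation.

All randomness is drawn from generators seeded explicitly, so identical
configuration + seed yields bit-identical rasters.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import ndimage
from skimage.draw import polygon as draw_polygon

__all__ = [
    "CellPhantom",
    "Scene",
    "TipPhantom",
    "GroundTruth",
    "InvalidPhantomError",
    "thickness_field",
    "render_cell_image",
    "render_zstack",
    "render_tip_image",
    "make_ground_truth",
    "TipStage",
]


class InvalidPhantomError(ValueError):
    """Raised for phantoms with non-physical geometry."""


@dataclass(frozen=True)
class CellPhantom:
    """A single adherent-cell phantom described by its thickness profile.

    Parameters
    ----------
    center : (row, col) position of the cell apex, pixels.
    semi_axes : (a, b) support semi-axes in pixels (a along columns,
        b along rows).
    h_max : peak thickness in micrometers.
    delta_n : refractive-index difference between cell and medium.
    profile_kind : ``"ellipsoid"`` (spherical-cap-like, continuous slope
        truncation at the rim) or ``"paraboloid"`` (constant Laplacian
        inside the support -- handy as an analytic oracle).
    """

    center: tuple[float, float]
    semi_axes: tuple[float, float]
    h_max: float
    delta_n: float = 0.02
    profile_kind: Literal["ellipsoid", "paraboloid"] = "ellipsoid"

    def __post_init__(self) -> None:
        a, b = self.semi_axes
        if a <= 0 or b <= 0:
            raise InvalidPhantomError(f"semi-axes must be positive, got {self.semi_axes}")
        if self.h_max <= 0:
            raise InvalidPhantomError(f"h_max must be positive, got {self.h_max}")
        if self.profile_kind not in ("ellipsoid", "paraboloid"):
            raise InvalidPhantomError(f"unknown profile_kind {self.profile_kind!r}")


@dataclass(frozen=True)
class Scene:
    """A renderable collection of cell phantoms on a uniform background."""

    phantoms: tuple[CellPhantom, ...]
    background_intensity: float = 128.0
    image_shape: tuple[int, int] = (256, 256)
    pixel_size: float = 1.0
    noise_sigma: float = 0.0
    rng_seed: int = 0
    allow_overlap: bool = False

    def __post_init__(self) -> None:
        if not (0 < self.background_intensity < 255):
            raise ValueError("background_intensity must lie strictly inside (0, 255)")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be nonnegative")
        object.__setattr__(self, "phantoms", tuple(self.phantoms))
        if not self.allow_overlap:
            self._check_overlap()

    def _check_overlap(self) -> None:
        ph = self.phantoms
        for i in range(len(ph)):
            for j in range(i + 1, len(ph)):
                ri, ci = ph[i].center
                rj, cj = ph[j].center
                dist = np.hypot(ri - rj, ci - cj)
                reach_i = max(ph[i].semi_axes)
                reach_j = max(ph[j].semi_axes)
                if dist < reach_i + reach_j:
                    raise ValueError(
                        f"phantoms {i} and {j} may overlap; pass allow_overlap=True "
                        "to permit this"
                    )

    def replace(self, **kwargs) -> "Scene":
        return dataclasses.replace(self, **kwargs)


@dataclass(frozen=True)
class TipPhantom:
    """Opaque triangular pipette-tip phantom.

    The triangle has its sharp vertex at ``apex``; the two edges leave the
    apex at ``orientation +/- half_angle`` (degrees, measured from the +col
    axis, row axis pointing down) and extend ``length`` pixels.
    """

    apex: tuple[float, float]
    half_angle: float = 20.0
    orientation: float = 225.0
    length: float = 110.0
    opacity: float = 90.0
    z_focus: float = 0.0
    sigma0: float = 1.0
    blur_gain: float = 0.03  # with fade_um=140: detection fails near 110 um defocus
    fade_um: float = 140.0

    def __post_init__(self) -> None:
        if not (0 < self.half_angle < 90):
            raise InvalidPhantomError("half_angle must be in (0, 90) degrees")
        if self.length <= 0:
            raise InvalidPhantomError("length must be positive")
        if self.opacity <= 0:
            raise InvalidPhantomError("opacity must be positive")

    def vertices(self) -> np.ndarray:
        """Triangle vertices as an (3, 2) array of (row, col) floats."""
        r0, c0 = self.apex
        verts = [(r0, c0)]
        for sign in (+1, -1):
            ang = np.deg2rad(self.orientation + sign * self.half_angle)
            verts.append((r0 + self.length * np.sin(ang), c0 + self.length * np.cos(ang)))
        return np.asarray(verts, dtype=float)


@dataclass
class GroundTruth:
    """Per-cell truth rasters for scoring detections."""

    nucleus_masks: list[np.ndarray] = field(default_factory=list)
    centroids: list[tuple[float, float]] = field(default_factory=list)

    @property
    def cell_count(self) -> int:
        return len(self.nucleus_masks)


def thickness_field(phantom: CellPhantom, shape: tuple[int, int]) -> np.ndarray:
    """Evaluate the phantom's thickness profile (micrometers) on a pixel grid.

    ellipsoid:  h = h_max * sqrt(max(0, 1 - (x/a)^2 - (y/b)^2))
    paraboloid: h = h_max * max(0, 1 - (x/a)^2 - (y/b)^2)

    with (x, y) the col/row offsets from the phantom center.
    """
    rows, cols = shape
    if rows <= 0 or cols <= 0:
        raise ValueError(f"shape must be positive, got {shape}")
    r0, c0 = phantom.center
    a, b = phantom.semi_axes
    rr, cc = np.mgrid[0:rows, 0:cols]
    q = 1.0 - ((cc - c0) / a) ** 2 - ((rr - r0) / b) ** 2
    q = np.maximum(q, 0.0)
    if phantom.profile_kind == "ellipsoid":
        return phantom.h_max * np.sqrt(q)
    return phantom.h_max * q


def _laplacian(field_2d: np.ndarray, pixel_size: float) -> np.ndarray:
    """5-point-stencil Laplacian scaled to physical units (per micrometer)."""
    kernel = np.array([[0.0, 1.0, 0.0], [1.0, -4.0, 1.0], [0.0, 1.0, 0.0]])
    return ndimage.convolve(field_2d, kernel, mode="nearest") / pixel_size**2


def contrast_field(scene: Scene, delta_f: float) -> np.ndarray:
    """Dimensionless contrast ``delta_f * delta_n * laplacian(h)``, pre-clip.

    Phantom thickness fields are summed; each phantom carries its own
    refractive-index difference, so the contrast is the sum of per-phantom
    terms.
    """
    total = np.zeros(scene.image_shape, dtype=float)
    for ph in scene.phantoms:
        h = thickness_field(ph, scene.image_shape)
        total += ph.delta_n * _laplacian(h, scene.pixel_size)
    return delta_f * total


def render_cell_image(
    scene: Scene, delta_f: float, *, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Render the scene at signed defocus ``delta_f`` (micrometers) as uint8.

    I = clip(I0 * (1 + contrast) + noise, 0, 255); positive defocus darkens
    cell interiors relative to the background.
    """
    i0 = scene.background_intensity
    img = i0 * (1.0 + contrast_field(scene, delta_f))
    if scene.noise_sigma > 0:
        if rng is None:
            rng = np.random.default_rng(scene.rng_seed)
        img = img + rng.normal(0.0, scene.noise_sigma, size=img.shape)
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


def render_zstack(scene: Scene, z_list: Sequence[float]) -> list[np.ndarray]:
    """Render one image per defocus value; per-plane noise seeds are derived
    from the scene seed and plane index, so stacks are reproducible."""
    z = np.asarray(list(z_list), dtype=float)
    if z.size == 0:
        raise ValueError("z_list must be nonempty")
    dz = np.diff(z)
    if z.size > 1 and not (np.all(dz > 0) or np.all(dz < 0)):
        raise ValueError("z_list must be strictly monotone")
    stack = []
    for idx, zi in enumerate(z):
        rng = np.random.default_rng(np.random.SeedSequence([scene.rng_seed, idx]))
        stack.append(render_cell_image(scene, zi, rng=rng))
    return stack


def render_tip_image(
    tip: TipPhantom,
    z: float,
    shape: tuple[int, int],
    background: float = 180.0,
    noise_sigma: float = 0.0,
    rng_seed: int = 0,
) -> np.ndarray:
    """Render the tip phantom at stage position ``z`` (micrometers) as uint8.

    The filled triangle is drawn at depth ``background - opacity``, then
    blurred with sigma = sigma0 + blur_gain * |z - z_focus| and its contrast
    attenuated linearly to zero at ``fade_um`` of defocus, so detectability
    degrades monotonically away from focus.
    """
    rows, cols = shape
    if rows <= 0 or cols <= 0:
        raise ValueError(f"shape must be positive, got {shape}")
    dz = abs(z - tip.z_focus)
    atten = max(0.0, 1.0 - dz / tip.fade_um)
    img = np.full(shape, float(background))
    if atten > 0:
        verts = tip.vertices()
        rr, cc = draw_polygon(verts[:, 0], verts[:, 1], shape=shape)
        depth = np.zeros(shape)
        depth[rr, cc] = tip.opacity * atten
        sigma = tip.sigma0 * (dz > 0) + tip.blur_gain * dz
        if sigma > 0:
            depth = ndimage.gaussian_filter(depth, sigma, mode="constant")
        img -= depth
    if noise_sigma > 0:
        rng = np.random.default_rng(rng_seed)
        img = img + rng.normal(0.0, noise_sigma, size=img.shape)
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


def make_ground_truth(scene: Scene) -> GroundTruth:
    """Boolean support mask and centroid per phantom (centroid = center)."""
    truth = GroundTruth()
    for ph in scene.phantoms:
        mask = thickness_field(ph, scene.image_shape) > 0
        truth.nucleus_masks.append(mask)
        truth.centroids.append(tuple(ph.center))
    return truth


def grid_scene(
    n_cells: int,
    image_shape: tuple[int, int] = (256, 320),
    seed: int = 0,
    margin: int = 24,
    semi_axis_range: tuple[float, float] = (7.0, 11.0),
    h_max_range: tuple[float, float] = (4.0, 6.0),
    delta_n: float = 0.02,
    background_intensity: float = 150.0,
    noise_sigma: float = 0.0,
    profile_kind: str = "ellipsoid",
    jitter_frac: float = 0.25,
) -> Scene:
    """Scene with ``n_cells`` well-separated phantoms on a jittered grid.

    Cell positions, sizes and heights are drawn from a generator seeded by
    ``seed``; grid pitch is chosen so neighboring supports cannot touch.
    """
    rng = np.random.default_rng(seed)
    rows, cols = image_shape
    if n_cells == 0:
        return Scene(
            phantoms=(),
            background_intensity=background_intensity,
            image_shape=image_shape,
            noise_sigma=noise_sigma,
            rng_seed=seed,
        )
    aspect = (cols - 2 * margin) / (rows - 2 * margin)
    n_cols = max(1, int(np.ceil(np.sqrt(n_cells * aspect))))
    n_rows = int(np.ceil(n_cells / n_cols))
    r_centers = np.linspace(margin, rows - margin, n_rows)
    c_centers = np.linspace(margin, cols - margin, n_cols)
    pitch_r = r_centers[1] - r_centers[0] if n_rows > 1 else rows
    pitch_c = c_centers[1] - c_centers[0] if n_cols > 1 else cols
    a_hi = semi_axis_range[1]
    jitter = jitter_frac * max(min(pitch_r, pitch_c) / 2 - a_hi, 0.0)
    phantoms = []
    cells_left = n_cells
    for rc in r_centers:
        for cc in c_centers:
            if cells_left == 0:
                break
            a = rng.uniform(*semi_axis_range)
            b = rng.uniform(*semi_axis_range)
            h = rng.uniform(*h_max_range)
            dr, dc = rng.uniform(-jitter, jitter, size=2)
            phantoms.append(
                CellPhantom(
                    center=(float(rc + dr), float(cc + dc)),
                    semi_axes=(float(a), float(b)),
                    h_max=float(h),
                    delta_n=delta_n,
                    profile_kind=profile_kind,  # type: ignore[arg-type]
                )
            )
            cells_left -= 1
    return Scene(
        phantoms=tuple(phantoms),
        background_intensity=background_intensity,
        image_shape=image_shape,
        noise_sigma=noise_sigma,
        rng_seed=seed,
        allow_overlap=True,  # pitch already guarantees separation
    )


class TipStage:
    """A virtual z-stage carrying a tip phantom over a fixed background.

    ``observe(z)`` renders the camera view with the tip at stage position
    ``z``. Noise per observation is seeded from (seed, quantized z) so a
    revisit of the same position reproduces the same frame.
    """

    def __init__(
        self,
        tip: TipPhantom,
        shape: tuple[int, int] = (256, 256),
        background: float = 180.0,
        noise_sigma: float = 0.0,
        seed: int = 0,
    ) -> None:
        self.tip = tip
        self.shape = shape
        self.background = background
        self.noise_sigma = noise_sigma
        self.seed = seed

    def observe(self, z: float) -> np.ndarray:
        key = int(np.round(z * 1e3))
        rng_seed = int(np.random.SeedSequence([self.seed, key & 0xFFFFFFFF]).generate_state(1)[0])
        return render_tip_image(
            self.tip,
            z,
            self.shape,
            background=self.background,
            noise_sigma=self.noise_sigma,
            rng_seed=rng_seed,
        )
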