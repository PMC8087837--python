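"""Segmentation and the ten particle properties.

One brightfield frame holds one particle (a cell or a colony).  The frame
is segmented by a global dark-object threshold on the grey image; the ten
properties below are then measured on the segmented mask, mirroring the
property catalogue of imaging-flow-cytometry software:

``Average Blue``
    mean blue-channel value over the particle pixels,
``Diameter (ABD)``
    area-based diameter: diameter of the circle whose area equals the
    particle pixel area, in micrometres,
``Edge gradient``
    mean 3x3 Sobel gradient magnitude over the one-pixel ring just
    outside the particle,
``Intensity`` / ``Sigma intensity``
    mean and population standard deviation of the particle's grey values,
``Length``
    the largest of 36 Feret (caliper) measurements, 0..175 deg in 5 deg
    steps, in micrometres,
``Perimeter``
    total crack-boundary length including the edges of interior holes,
``Ratio red/blue`` / ``Ratio red/green``
    ratios of channel means over the particle,
``Roughness``
    perimeter divided by the convex-hull perimeter (hull taken over pixel
    corners), exactly 1 for a filled axis-aligned rectangle.

Conventions that the instrument software leaves undocumented are fixed
here and stated in the docstrings: grey = unweighted mean of R, G, B; the
crack-boundary perimeter counts exposed unit pixel edges; the Sobel
kernels are the unnormalised [1, 2, 1] x [-1, 0, 1] pair, with per-pixel
magnitudes clamped to the 8-bit range before averaging; Sigma intensity
uses the population (n) denominator.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull

from .errors import NoParticleError, UndefinedRatioError

#: Default micrometres per pixel of the 10x objective.
DEFAULT_PIXEL_SIZE_UM = 0.554

#: Default grey threshold: pixels strictly darker than this are foreground.
DEFAULT_THRESHOLD = 200.0

AVERAGE_BLUE = "Average Blue"
DIAMETER_ABD = "Diameter (ABD)"
EDGE_GRADIENT = "Edge gradient"
INTENSITY = "Intensity"
LENGTH = "Length"
PERIMETER = "Perimeter"
RATIO_RED_BLUE = "Ratio red/blue"
RATIO_RED_GREEN = "Ratio red/green"
ROUGHNESS = "Roughness"
SIGMA_INTENSITY = "Sigma intensity"

#: Canonical particle-property order (also the tie-break order used by
#: gate reduction).
FEATURE_NAMES = (
    AVERAGE_BLUE,
    DIAMETER_ABD,
    EDGE_GRADIENT,
    INTENSITY,
    LENGTH,
    PERIMETER,
    RATIO_RED_BLUE,
    RATIO_RED_GREEN,
    ROUGHNESS,
    SIGMA_INTENSITY,
)

#: Feature names measured in micrometres (scale linearly with pixel size).
MICRON_FEATURES = (DIAMETER_ABD, LENGTH, PERIMETER)

_EIGHT = np.ones((3, 3), bool)
_FERET_ANGLES_DEG = np.arange(0, 180, 5)  # 36 caliper orientations


@dataclass
class ParticleImage:
    """One RGB brightfield frame plus its pixel calibration."""

    pixels: np.ndarray  # (H, W, 3) uint8
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError("pixels must be an (H, W, 3) RGB array")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")

    @property
    def gray(self) -> np.ndarray:
        """Grey image as the unweighted channel mean, float64."""
        return self.pixels.astype(np.float64).mean(axis=2)


@dataclass
class ParticleMask:
    """Binary support of the single segmented particle (holes allowed)."""

    mask: np.ndarray  # (H, W) bool
    area_px: int = 0
    hole_count: int = 0

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        self.area_px = int(self.mask.sum())
        filled = ndimage.binary_fill_holes(self.mask)
        holes = filled & ~self.mask
        self.hole_count = int(ndimage.label(holes, structure=_EIGHT)[1])


@dataclass
class FeatureVector:
    """The ten particle properties of one particle."""

    average_blue: float
    diameter_abd_um: float
    edge_gradient: float
    intensity: float
    length_um: float
    perimeter_um: float
    ratio_red_blue: float
    ratio_red_green: float
    roughness: float
    sigma_intensity: float

    _ATTRS = (
        "average_blue",
        "diameter_abd_um",
        "edge_gradient",
        "intensity",
        "length_um",
        "perimeter_um",
        "ratio_red_blue",
        "ratio_red_green",
        "roughness",
        "sigma_intensity",
    )

    def as_dict(self) -> dict[str, float]:
        """Map canonical feature names to values."""
        return dict(zip(FEATURE_NAMES, (getattr(self, a) for a in self._ATTRS)))


def segment_particle(
    image: ParticleImage, threshold: float = DEFAULT_THRESHOLD
) -> ParticleMask:
    """Threshold the grey image and keep the largest dark component.

    Foreground is every pixel with grey value strictly below ``threshold``;
    connectivity is 8; interior holes are preserved so that the perimeter
    and roughness can account for them.

    Raises
    ------
    NoParticleError
        if no pixel is below the threshold.
    """
    fg = image.gray < threshold
    if not fg.any():
        raise NoParticleError(f"no pixel below grey threshold {threshold}")
    labels, n = ndimage.label(fg, structure=_EIGHT)
    if n > 1:
        counts = np.bincount(labels.ravel())
        counts[0] = 0
        fg = labels == int(np.argmax(counts))
    return ParticleMask(fg)


def intensity_stats(
    image: ParticleImage, mask: ParticleMask
) -> tuple[float, float, float, float, float]:
    """Grey and colour statistics over the particle pixels.

    Returns ``(intensity, sigma_intensity, average_blue, ratio_red_blue,
    ratio_red_green)``.  Sigma intensity is the population (n) standard
    deviation.  A zero blue or green channel mean raises
    :class:`UndefinedRatioError` rather than returning infinity.
    """
    m = mask.mask
    if not m.any():
        raise NoParticleError("empty mask")
    rgb = image.pixels.astype(np.float64)
    gray = rgb.mean(axis=2)[m]
    mean_r = float(rgb[..., 0][m].mean())
    mean_g = float(rgb[..., 1][m].mean())
    mean_b = float(rgb[..., 2][m].mean())
    if mean_b == 0.0 or mean_g == 0.0:
        raise UndefinedRatioError("zero blue or green channel mean")
    return (
        float(gray.mean()),
        float(gray.std()),  # population denominator
        mean_b,
        mean_r / mean_b,
        mean_r / mean_g,
    )


def abd_diameter(mask: ParticleMask, pixel_size_um: float) -> float:
    """Diameter of the circle whose area equals the particle pixel area."""
    if mask.area_px < 1:
        raise NoParticleError("empty mask")
    return float(2.0 * np.sqrt(mask.area_px / np.pi) * pixel_size_um)


def _boundary_corner_points(mask: np.ndarray) -> np.ndarray:
    """Pixel-corner points of the mask's boundary pixels, as (x, y).

    The corner set of the boundary pixels contains every vertex of the
    convex hull of the full corner set, which is all the caliper and hull
    computations need.
    """
    boundary = mask & ~ndimage.binary_erosion(mask, structure=_EIGHT)
    ys, xs = np.nonzero(boundary)
    if ys.size == 0:  # single-pixel-thin masks erode to nothing
        ys, xs = np.nonzero(mask)
    corners = np.concatenate(
        [
            np.column_stack((xs, ys)),
            np.column_stack((xs + 1, ys)),
            np.column_stack((xs, ys + 1)),
            np.column_stack((xs + 1, ys + 1)),
        ]
    )
    return np.unique(corners, axis=0).astype(np.float64)


def _hull_points(mask: np.ndarray) -> np.ndarray:
    """Convex hull vertices (x, y) of the mask's pixel-corner points."""
    pts = _boundary_corner_points(mask)
    if len(pts) <= 3:
        return pts
    hull = ConvexHull(pts)
    return pts[hull.vertices]


def feret_length(mask: ParticleMask, pixel_size_um: float) -> float:
    """Largest of 36 caliper (Feret) measurements, in micrometres.

    The caliper extent of the mask's pixel-corner point set is measured at
    36 orientations evenly spaced over a half turn (0, 5, ..., 175 deg);
    the maximum is returned.  A single pixel therefore measures sqrt(2)
    pixel widths (the unit square's diagonal, attained at 45 deg).
    """
    if not mask.mask.any():
        raise NoParticleError("empty mask")
    pts = _hull_points(mask.mask)
    theta = np.deg2rad(_FERET_ANGLES_DEG)
    proj = pts @ np.vstack((np.cos(theta), np.sin(theta)))
    extents = proj.max(axis=0) - proj.min(axis=0)
    return float(extents.max() * pixel_size_um)


def _crack_perimeter_px(mask: np.ndarray) -> int:
    """Number of exposed unit pixel edges (outer contour plus hole edges)."""
    padded = np.pad(mask, 1)
    horiz = padded[:, 1:] != padded[:, :-1]
    vert = padded[1:, :] != padded[:-1, :]
    return int(horiz.sum() + vert.sum())


def perimeter_and_roughness(
    mask: ParticleMask, pixel_size_um: float
) -> tuple[float, float]:
    """Crack-boundary perimeter (micrometres) and roughness.

    The perimeter sums every exposed unit pixel edge, on the outer contour
    and around every interior hole.  The convex perimeter is the perimeter
    of the convex hull of the mask's pixel corners; roughness is their
    ratio and is >= 1 by construction (the hull is the shortest convex
    curve enclosing the corner set, and the crack boundary encloses it
    too).  For a filled axis-aligned rectangle both lengths coincide and
    roughness is exactly 1.  Note the digitisation bias for smooth convex
    shapes: a rasterised disk has crack perimeter ~ 8r against a hull
    perimeter ~ 2*pi*r, giving roughness ~ 4/pi ~ 1.27.
    """
    if not mask.mask.any():
        raise NoParticleError("empty mask")
    perim_px = _crack_perimeter_px(mask.mask)
    hull = _hull_points(mask.mask)
    if len(hull) < 2:
        hull_perim = 4.0  # a single pixel: its own square boundary
    else:
        edges = np.diff(np.vstack((hull, hull[:1])), axis=0)
        hull_perim = float(np.hypot(edges[:, 0], edges[:, 1]).sum())
    perimeter_um = perim_px * pixel_size_um
    return perimeter_um, float(perim_px / hull_perim)


def edge_gradient(image: ParticleImage, mask: ParticleMask) -> float:
    """Mean Sobel gradient magnitude over the particle's outside border.

    The 3x3 Sobel pair ([1, 2, 1] smoothing x [-1, 0, 1] derivative,
    unnormalised) is applied to the grey image; per-pixel magnitudes are
    clamped to [0, 255] (the 8-bit edge-image convention) and averaged
    over the one-pixel ring just outside the particle (8-connected
    dilation of the mask minus the mask).  An ideal step of height h
    yields a per-pixel response of 4h at the pixels flanking the step.

    If the particle touches the frame edge the ring is truncated; a
    warning is emitted and the mean uses the available ring pixels.
    """
    m = mask.mask
    if not m.any():
        raise NoParticleError("empty mask")
    if m[0, :].any() or m[-1, :].any() or m[:, 0].any() or m[:, -1].any():
        warnings.warn(
            "particle touches the frame edge; border ring truncated",
            stacklevel=2,
        )
    gray = image.gray
    gx = ndimage.sobel(gray, axis=1, mode="nearest")
    gy = ndimage.sobel(gray, axis=0, mode="nearest")
    mag = np.clip(np.hypot(gx, gy), 0.0, 255.0)
    ring = ndimage.binary_dilation(m, structure=_EIGHT) & ~m
    if not ring.any():  # mask fills the whole frame
        return 0.0
    return float(mag[ring].mean())


def extract_features(
    image: ParticleImage, threshold: float = DEFAULT_THRESHOLD
) -> FeatureVector:
    """Segment the frame and compute all ten properties on one mask."""
    mask = segment_particle(image, threshold)
    intensity, sigma, avg_blue, rrb, rrg = intensity_stats(image, mask)
    perimeter_um, roughness = perimeter_and_roughness(mask, image.pixel_size_um)
    return FeatureVector(
        average_blue=avg_blue,
        diameter_abd_um=abd_diameter(mask, image.pixel_size_um),
        edge_gradient=edge_gradient(image, mask),
        intensity=intensity,
        length_um=feret_length(mask, image.pixel_size_um),
        perimeter_um=perimeter_um,
        ratio_red_blue=rrb,
        ratio_red_green=rrg,
        roughness=roughness,
        sigma_intensity=sigma,
    )
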