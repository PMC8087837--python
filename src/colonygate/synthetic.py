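"""Synthetic brightfield colony images and feature tables.

The generator emulates the particle classes of a mesocosm *Microcystis*
bloom as seen by a brightfield imaging flow cytometer: five colonial
*Microcystis* morphospecies, the colonial green alga *Micractinium*
(spiny), and the unicellular flagellate *Cryptomonas*.  Colonies are
rendered as unions of jittered filled disks with optional interior holes
(raising roughness), an optional semi-transparent halo rendered as a
linear intensity ramp (controlling the edge gradient), a per-class base
colour (controlling intensity, average blue and the channel ratios) and
per-pixel luminance noise (controlling sigma intensity).  Each profile is
calibrated so that, at ``overlap_scale = 0``, the features extracted from
its renderings fall inside the published reference gate ranges for its
class (:mod:`colonygate.reference`).

Two generation modes exist.  *Image mode* renders every particle and runs
the real feature extractor on it.  *Table mode* skips rendering and draws
each feature independently from a truncated normal centred mid-envelope
with sd = width/5, truncated at the envelope; it is the fast path used
for classifier-level experiments.  ``overlap_scale`` inflates the
within-class spread (sd and truncation half-width scale with
``1 + overlap_scale``) to emulate the phenotypic heterogeneity of a
seasonal bloom; 0 gives the well-separated baseline.

Determinism: a configuration plus seed fully determines every image and
table byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.stats import truncnorm
from skimage.draw import disk as draw_disk
from skimage.draw import line as draw_line

from .dataset import (
    CLASS_COLUMN,
    DATE_COLUMN,
    ID_COLUMN,
    LabeledDataset,
    TANK_COLUMN,
)
from .errors import DuplicateClassError, FrameOverflowError
from .particles import (
    AVERAGE_BLUE,
    DEFAULT_PIXEL_SIZE_UM,
    DEFAULT_THRESHOLD,
    DIAMETER_ABD,
    EDGE_GRADIENT,
    FEATURE_NAMES,
    INTENSITY,
    LENGTH,
    PERIMETER,
    ParticleImage,
    ParticleMask,
    RATIO_RED_BLUE,
    RATIO_RED_GREEN,
    ROUGHNESS,
    SIGMA_INTENSITY,
    abd_diameter,
    extract_features,
    feret_length,
    perimeter_and_roughness,
)
from . import reference

_EIGHT = np.ones((3, 3), bool)

#: Mesocosm-style sample metadata: 12 high-nutrient tanks, 13 sampling
#: dates across one growth season, assigned round-robin.
TANKS = (
    "A1", "A2", "A3", "D1", "D2", "D3",
    "F1", "F2", "F3", "G1", "G2", "G3",
)
DATES = tuple(
    d.date().isoformat()
    for d in pd.date_range("2019-05-23", "2019-09-17", periods=13)
)

BACKGROUND_RGB = (230.0, 230.0, 230.0)
BACKGROUND_NOISE_SD = 3.0


@dataclass
class MorphospeciesProfile:
    """Rendering recipe for one particle class.

    Geometry is parameterised in micrometres; ``colony_spread_um`` is the
    radius of the disk in which cell centres are scattered.  Where
    ``size_feature``/``size_target_um`` are set, the rendered colony is
    rescaled so that the named size feature lands near a target drawn
    uniformly from the given interval (uniform because the published
    reference ranges are min/max envelopes, not distributions).
    ``feature_envelopes`` documents, per gated feature, the published
    range the renderings are calibrated to stay inside.
    """

    class_name: str
    n_cells: tuple[int, int]
    cell_radius_um: tuple[float, float]
    colony_spread_um: tuple[float, float]
    hole_fraction: float = 0.0
    halo_strength: float = 0.0  # halo ramp width, px; 0 = crisp edge
    base_color: tuple[float, float, float] = (100.0, 100.0, 100.0)
    intensity_sd: float = 10.0
    color_jitter: float = 2.0  # per-particle sd of the base colour, per channel
    n_spines: int = 0
    size_feature: str | None = None
    size_target_um: tuple[float, float] | None = None
    feature_envelopes: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("n_cells", "cell_radius_um", "colony_spread_um"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name}: min {lo} > max {hi}")
        if self.colony_spread_um[1] < self.cell_radius_um[0]:
            raise ValueError("colony_spread_um must be >= cell_radius_um")
        if not 0.0 <= self.hole_fraction <= 1.0:
            raise ValueError("hole_fraction must lie in [0, 1]")
        if self.halo_strength < 0 or self.intensity_sd < 0:
            raise ValueError("halo_strength and intensity_sd must be >= 0")
        if not all(0 <= c <= 255 for c in self.base_color):
            raise ValueError("base_color channels must lie in [0, 255]")
        if not self.feature_envelopes:
            self.feature_envelopes = reference.class_envelopes(self.class_name)


@dataclass
class GenerationConfig:
    """Full specification of one synthetic dataset."""

    profiles: list[MorphospeciesProfile]
    n_per_class: int
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    image_side_px: int = 512
    seed: int = 0
    overlap_scale: float = 0.0
    mode: str = "table"  # "table" (feature draws) or "image" (render+extract)
    threshold: float = DEFAULT_THRESHOLD

    def __post_init__(self) -> None:
        if self.n_per_class < 1:
            raise ValueError("n_per_class must be >= 1")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if self.overlap_scale < 0:
            raise ValueError("overlap_scale must be >= 0")
        if self.mode not in ("table", "image"):
            raise ValueError("mode must be 'table' or 'image'")
        names = [p.class_name for p in self.profiles]
        if len(set(names)) != len(names):
            raise DuplicateClassError("duplicate class names in profiles")


def default_profiles() -> list[MorphospeciesProfile]:
    """The seven default class profiles, calibrated to the reference gates.

    Base colours follow the classes' brightfield appearance (brown-green
    *Cryptomonas*, green *Micractinium*, brown-to-olive *Microcystis*
    colonies); the numeric values are chosen so channel means, grey
    statistics and geometry land inside each class's published envelope
    (see ``feature_envelopes`` on each profile).
    """
    return [
        MorphospeciesProfile(
            class_name=reference.CRYPTOMONAS,
            n_cells=(1, 1),
            cell_radius_um=(4.3, 5.6),
            colony_spread_um=(4.3, 5.6),
            base_color=(110.0, 100.0, 70.0),
            intensity_sd=10.0,
            color_jitter=3.0,
            size_feature=DIAMETER_ABD,
            size_target_um=(8.6, 11.2),
        ),
        MorphospeciesProfile(
            class_name=reference.MICRACTINIUM,
            n_cells=(6, 14),
            cell_radius_um=(2.8, 4.2),
            colony_spread_um=(9.0, 16.0),
            base_color=(95.0, 103.0, 80.0),
            intensity_sd=10.0,
            color_jitter=3.0,
            n_spines=8,
            size_feature=DIAMETER_ABD,
            size_target_um=(18.5, 38.0),
        ),
        MorphospeciesProfile(
            class_name=reference.M_AERUGINOSA,
            n_cells=(80, 130),
            cell_radius_um=(4.5, 6.0),
            colony_spread_um=(25.0, 40.0),
            halo_strength=9.3,
            base_color=(97.0, 90.0, 77.0),
            intensity_sd=20.0,
            color_jitter=1.2,
            size_feature=PERIMETER,
            size_target_um=(560.0, 860.0),
        ),
        MorphospeciesProfile(
            class_name=reference.M_ICHTHYOBLABE,
            n_cells=(14, 30),
            cell_radius_um=(4.0, 6.0),
            colony_spread_um=(16.0, 30.0),
            hole_fraction=0.15,
            base_color=(108.0, 96.0, 87.0),
            intensity_sd=25.3,
            color_jitter=1.4,
            size_feature=LENGTH,
            size_target_um=(68.0, 120.0),
        ),
        MorphospeciesProfile(
            class_name=reference.M_NOVACEKII,
            n_cells=(25, 60),
            cell_radius_um=(4.5, 6.5),
            colony_spread_um=(20.0, 36.0),
            hole_fraction=0.04,
            base_color=(70.0, 62.0, 54.0),
            intensity_sd=9.0,
            color_jitter=3.0,
            size_feature=DIAMETER_ABD,
            size_target_um=(49.5, 79.5),
        ),
        MorphospeciesProfile(
            class_name=reference.M_SMITHII,
            n_cells=(40, 65),
            cell_radius_um=(4.5, 6.5),
            colony_spread_um=(20.0, 32.0),
            hole_fraction=0.40,
            base_color=(126.0, 100.0, 92.0),
            intensity_sd=20.0,
            color_jitter=1.8,
        ),
        MorphospeciesProfile(
            class_name=reference.M_WESENBERGII,
            n_cells=(20, 50),
            cell_radius_um=(4.0, 6.0),
            colony_spread_um=(15.0, 28.0),
            hole_fraction=0.08,
            base_color=(96.0, 80.0, 75.0),
            intensity_sd=35.0,
            color_jitter=0.8,
        ),
    ]


# ---------------------------------------------------------------------------
# image mode


def _sample_layout(
    profile: MorphospeciesProfile,
    rng: np.random.Generator,
    px: float,
    overlap_scale: float,
):
    """Draw one colony layout (centres, radii, holes, spines) in pixels."""
    widen = 1.0 + overlap_scale

    def _uniform(lo: float, hi: float) -> float:
        mid, half = 0.5 * (lo + hi), 0.5 * (hi - lo) * widen
        return float(rng.uniform(mid - half, mid + half))

    k = int(rng.integers(profile.n_cells[0], profile.n_cells[1] + 1))
    r_px = max(_uniform(*profile.cell_radius_um) / px, 1.5)
    s_px = max(_uniform(*profile.colony_spread_um) / px, r_px)
    centers = [(0.0, 0.0)]
    core = max(s_px - r_px, 0.5)
    for _ in range(k - 1):
        rad = core * np.sqrt(rng.uniform())
        ang = rng.uniform(0.0, 2.0 * np.pi)
        centers.append((rad * np.sin(ang), rad * np.cos(ang)))
    # Holes are kept mutually separated so they perforate the colony
    # instead of merging into cuts that would shred it.
    holes = []
    for _ in range(int(round(profile.hole_fraction * k))):
        hr = rng.uniform(0.45, 0.75) * r_px
        for _attempt in range(40):
            rad = 0.75 * s_px * np.sqrt(rng.uniform())
            ang = rng.uniform(0.0, 2.0 * np.pi)
            hy, hx = rad * np.sin(ang), rad * np.cos(ang)
            if all(
                np.hypot(hy - oy, hx - ox) >= 1.2 * (hr + orr)
                for oy, ox, orr in holes
            ):
                holes.append((hy, hx, hr))
                break
    spines = []
    for _ in range(profile.n_spines):
        ang = rng.uniform(0.0, 2.0 * np.pi)
        spines.append((ang, rng.uniform(1.1, 1.5) * s_px))
    return np.array(centers), r_px, s_px, holes, spines


def _draw_support(
    centers: np.ndarray,
    r_px: float,
    holes: list,
    spines: list,
    scale: float,
    side: int,
) -> np.ndarray:
    """Rasterise one layout at the given scale onto a ``side`` canvas."""
    support = np.zeros((side, side), bool)
    c0 = side / 2.0
    for cy, cx in centers * scale:
        rr, cc = draw_disk((c0 + cy, c0 + cx), r_px * scale, shape=support.shape)
        support[rr, cc] = True
    for ang, length in spines:
        y0 = int(round(c0))
        x0 = int(round(c0))
        y1 = int(np.clip(round(c0 + np.sin(ang) * length * scale), 0, side - 1))
        x1 = int(np.clip(round(c0 + np.cos(ang) * length * scale), 0, side - 1))
        rr, cc = draw_line(y0, x0, y1, x1)
        support[rr, cc] = True
    for hy, hx, hr in holes:
        rr, cc = draw_disk(
            (c0 + hy * scale, c0 + hx * scale), hr * scale, shape=support.shape
        )
        support[rr, cc] = False
    labels, n = ndimage.label(support, structure=_EIGHT)
    if n > 1:
        counts = np.bincount(labels.ravel())
        counts[0] = 0
        support = labels == int(np.argmax(counts))
    return support


def _measure_size(support: np.ndarray, feature: str, px: float) -> float:
    mask = ParticleMask(support)
    if feature == DIAMETER_ABD:
        return abd_diameter(mask, px)
    if feature == LENGTH:
        return feret_length(mask, px)
    if feature == PERIMETER:
        return perimeter_and_roughness(mask, px)[0]
    raise ValueError(f"unsupported size feature {feature!r}")


def render_particle(
    profile: MorphospeciesProfile,
    rng: np.random.Generator,
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM,
    image_side_px: int = 512,
    overlap_scale: float = 0.0,
    threshold: float = DEFAULT_THRESHOLD,
) -> tuple[ParticleImage, str]:
    """Render one particle; returns the frame and its true class label.

    The background is strictly brighter than the particle; segmentation
    at the default threshold recovers exactly one connected particle.  If
    the colony (plus the sub-threshold part of its halo) would come
    within two pixels of the frame edge, :class:`FrameOverflowError` is
    raised rather than cropping silently.
    """
    px = pixel_size_um
    side = image_side_px
    centers, r_px, s_px, holes, spines = _sample_layout(
        profile, rng, px, overlap_scale
    )

    # Work canvas is oversized so the pre-calibration pass never clips.
    work_side = 2 * side
    support = _draw_support(centers, r_px, holes, spines, 1.0, work_side)
    scale = 1.0
    if profile.size_feature is not None and profile.size_target_um is not None:
        lo, hi = profile.size_target_um
        mid, half = 0.5 * (lo + hi), 0.5 * (hi - lo) * (1.0 + overlap_scale)
        target = float(rng.uniform(max(mid - half, 0.05 * mid), mid + half))
        measured = _measure_size(support, profile.size_feature, px)
        scale = target / measured
        support = _draw_support(centers, r_px, holes, spines, scale, work_side)

    # Halo ramp width, with a little per-particle variation.
    w = profile.halo_strength
    if w > 0:
        w = float(w * rng.uniform(0.87, 1.13))

    # Overflow check before painting: the mask can extend into the halo
    # up to the grey level crossing the segmentation threshold.
    base = np.array(profile.base_color, float)
    bg = np.array(BACKGROUND_RGB, float)
    gray_base, gray_bg = base.mean(), bg.mean()
    tau = max((threshold - gray_base) / max(gray_bg - gray_base, 1e-9), 0.0)
    margin = int(np.ceil(w * tau)) + 3
    ys, xs = np.nonzero(support)
    half_extent = max(
        np.abs(ys - work_side / 2.0).max(), np.abs(xs - work_side / 2.0).max()
    )
    if half_extent + margin >= side / 2.0:
        raise FrameOverflowError(
            f"{profile.class_name}: particle needs a frame of at least "
            f"{int(2 * (half_extent + margin)) + 1} px; enlarge image_side_px"
        )
    lo_off = work_side // 2 - side // 2
    support = support[lo_off : lo_off + side, lo_off : lo_off + side]

    jitter = rng.normal(0.0, profile.color_jitter * (1.0 + overlap_scale), 3)
    color = np.clip(base + jitter, 0.0, 255.0)

    filled = ndimage.binary_fill_holes(support)
    outside = ~filled
    img = np.empty((side, side, 3), float)
    # Background / halo: a linear ramp from the particle colour to the
    # background over w pixels of Euclidean distance from the support.
    if w > 0:
        dist = ndimage.distance_transform_edt(~support)
        t = np.clip(dist / w, 0.0, 1.0)
    else:
        t = np.ones((side, side))
    for c in range(3):
        img[..., c] = color[c] + t * (bg[c] - color[c])
    # Interior holes show the background, not the halo.
    img[filled & ~support] = bg
    # Particle body: base colour plus luminance noise.
    body_noise = rng.normal(0.0, profile.intensity_sd, (side, side))
    for c in range(3):
        ch = img[..., c]
        ch[support] = color[c] + body_noise[support]
    # Sensor noise over the non-particle area.
    bg_noise = rng.normal(0.0, BACKGROUND_NOISE_SD, (side, side))
    for c in range(3):
        ch = img[..., c]
        ch[~support] += bg_noise[~support]
    pixels = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return ParticleImage(pixels, px), profile.class_name


# ---------------------------------------------------------------------------
# table mode

#: Nominal (centre, sd) for features *not* gated for a class, matching the
#: typical output of the image renderer for that class.  Gated features
#: are drawn from their published envelope instead (centre mid-range,
#: sd = width / 5).
_NOMINAL_TABLE: dict[str, dict[str, tuple[float, float]]] = {
    reference.CRYPTOMONAS: {
        AVERAGE_BLUE: (70.5, 3.0),
        EDGE_GRADIENT: (237.0, 3.0),
        INTENSITY: (93.3, 2.5),
        LENGTH: (10.4, 0.9),
        PERIMETER: (39.0, 4.0),
        RATIO_RED_BLUE: (1.55, 0.07),
        RATIO_RED_GREEN: (1.09, 0.035),
        ROUGHNESS: (1.21, 0.04),
        SIGMA_INTENSITY: (9.9, 0.5),
    },
    reference.MICRACTINIUM: {
        AVERAGE_BLUE: (80.0, 3.3),
        EDGE_GRADIENT: (236.0, 2.5),
        LENGTH: (53.0, 12.0),
        PERIMETER: (406.0, 125.0),
        RATIO_RED_BLUE: (1.18, 0.06),
        RATIO_RED_GREEN: (0.91, 0.04),
        ROUGHNESS: (2.75, 0.40),
        SIGMA_INTENSITY: (10.0, 0.3),
    },
    reference.M_AERUGINOSA: {
        DIAMETER_ABD: (128.0, 32.0),
        INTENSITY: (97.0, 3.0),
        LENGTH: (139.0, 34.0),
        RATIO_RED_GREEN: (1.07, 0.02),
        ROUGHNESS: (1.70, 0.30),
    },
    reference.M_ICHTHYOBLABE: {
        DIAMETER_ABD: (67.0, 13.0),
        EDGE_GRADIENT: (235.0, 1.5),
        PERIMETER: (576.0, 146.0),
        RATIO_RED_GREEN: (1.12, 0.02),
    },
    reference.M_NOVACEKII: {
        AVERAGE_BLUE: (54.0, 3.0),
        EDGE_GRADIENT: (249.0, 1.5),
        LENGTH: (78.0, 10.0),
        PERIMETER: (505.0, 121.0),
        RATIO_RED_BLUE: (1.30, 0.09),
        RATIO_RED_GREEN: (1.12, 0.07),
        ROUGHNESS: (2.17, 0.43),
        SIGMA_INTENSITY: (9.0, 0.3),
    },
    reference.M_SMITHII: {
        AVERAGE_BLUE: (92.0, 1.5),
        DIAMETER_ABD: (37.0, 5.0),
        EDGE_GRADIENT: (232.5, 1.5),
        LENGTH: (50.0, 6.5),
        PERIMETER: (564.0, 119.0),
        RATIO_RED_BLUE: (1.37, 0.04),
        SIGMA_INTENSITY: (19.9, 0.5),
    },
    reference.M_WESENBERGII: {
        DIAMETER_ABD: (34.0, 5.4),
        EDGE_GRADIENT: (240.0, 1.5),
        LENGTH: (42.0, 6.6),
        PERIMETER: (271.0, 71.0),
        ROUGHNESS: (2.15, 0.30),
    },
}

#: Hard validity bounds per feature (the particle-property value ranges).
_VALIDITY: dict[str, tuple[float, float]] = {
    AVERAGE_BLUE: (0.0, 255.0),
    DIAMETER_ABD: (0.1, np.inf),
    EDGE_GRADIENT: (0.0, 255.0),
    INTENSITY: (0.0, 255.0),
    LENGTH: (0.1, np.inf),
    PERIMETER: (0.1, np.inf),
    RATIO_RED_BLUE: (0.0, np.inf),
    RATIO_RED_GREEN: (0.0, np.inf),
    ROUGHNESS: (1.0, np.inf),
    SIGMA_INTENSITY: (0.0, np.inf),
}


def table_mode_stats(
    profile: MorphospeciesProfile, overlap_scale: float = 0.0
) -> dict[str, tuple[float, float, float, float]]:
    """Per-feature ``(centre, sd, lo, hi)`` for table-mode draws.

    Gated features are centred mid-envelope with sd = width/5 and
    truncated at the envelope; ungated features use the nominal values
    above with a +/- 2.5 sd truncation.  ``overlap_scale`` multiplies the
    sd and the truncation half-width by ``1 + overlap_scale``; hard
    validity bounds are always enforced.
    """
    widen = 1.0 + overlap_scale
    nominal = _NOMINAL_TABLE.get(profile.class_name, {})
    out = {}
    for feat in FEATURE_NAMES:
        if feat in profile.feature_envelopes:
            lo, hi = profile.feature_envelopes[feat]
            ctr, sd = 0.5 * (lo + hi), (hi - lo) / 5.0
            half = 0.5 * (hi - lo)
        elif feat in nominal:
            ctr, sd = nominal[feat]
            half = 2.5 * sd
        else:
            raise ValueError(
                f"no table-mode statistics for {profile.class_name!r} / {feat!r}"
            )
        sd *= widen
        half *= widen
        vlo, vhi = _VALIDITY[feat]
        lo = float(np.clip(ctr - half, vlo, vhi))
        hi = float(np.clip(ctr + half, vlo, vhi))
        out[feat] = (float(ctr), float(sd), lo, hi)
    return out


def _draw_table_rows(
    profile: MorphospeciesProfile,
    n: int,
    rng: np.random.Generator,
    overlap_scale: float,
) -> pd.DataFrame:
    stats = table_mode_stats(profile, overlap_scale)
    cols = {}
    for feat, (ctr, sd, lo, hi) in stats.items():
        a, b = (lo - ctr) / sd, (hi - ctr) / sd
        cols[feat] = truncnorm.rvs(a, b, loc=ctr, scale=sd, size=n, random_state=rng)
    return pd.DataFrame(cols)[list(FEATURE_NAMES)]


# ---------------------------------------------------------------------------
# dataset assembly


def _metadata(n_total: int) -> tuple[list[str], list[str]]:
    combos = [(t, d) for d in DATES for t in TANKS]
    tanks, dates = [], []
    for i in range(n_total):
        t, d = combos[i % len(combos)]
        tanks.append(t)
        dates.append(d)
    return tanks, dates


def generate_dataset(
    config: GenerationConfig, out_dir=None
) -> LabeledDataset:
    """Generate a balanced labelled dataset per the configuration.

    Emits exactly ``n_per_class`` rows per profile.  In image mode every
    particle is rendered and measured with the real feature extractor; if
    ``out_dir`` is given the frames are saved as 8-bit RGB PNGs together
    with a ``manifest.csv`` (image_path, class, tank, date, seed).  In
    table mode features are drawn directly from the class-conditional
    distributions and the manifest records ``mode=table``.
    """
    rng = np.random.default_rng(config.seed)
    frames: list[pd.DataFrame] = []
    images: list[tuple[str, ParticleImage]] = []
    counter = 0
    for profile in config.profiles:
        if config.mode == "image":
            rows = []
            for _ in range(config.n_per_class):
                image, label = render_particle(
                    profile,
                    rng,
                    pixel_size_um=config.pixel_size_um,
                    image_side_px=config.image_side_px,
                    overlap_scale=config.overlap_scale,
                    threshold=config.threshold,
                )
                fv = extract_features(image, config.threshold)
                rows.append(fv.as_dict())
                images.append((f"p{counter:06d}", image))
                counter += 1
            block = pd.DataFrame(rows)[list(FEATURE_NAMES)]
        else:
            block = _draw_table_rows(
                profile, config.n_per_class, rng, config.overlap_scale
            )
            counter += config.n_per_class
        block.insert(0, CLASS_COLUMN, profile.class_name)
        frames.append(block)
    table = pd.concat(frames, ignore_index=True)
    table.insert(0, ID_COLUMN, [f"p{i:06d}" for i in range(len(table))])
    tanks, dates = _metadata(len(table))
    table[TANK_COLUMN] = tanks
    table[DATE_COLUMN] = dates

    if out_dir is not None:
        _write_outputs(config, table, images, out_dir)
    return LabeledDataset(table)


def _write_outputs(config, table, images, out_dir) -> None:
    from pathlib import Path
    from PIL import Image

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    if config.mode == "image":
        img_dir = out / "images"
        img_dir.mkdir(exist_ok=True)
        for pid, image in images:
            path = img_dir / f"{pid}.png"
            Image.fromarray(image.pixels, mode="RGB").save(path)
            paths.append(str(Path("images") / f"{pid}.png"))
    else:
        paths = ["" for _ in range(len(table))]
    manifest = pd.DataFrame(
        {
            "image_path": paths,
            "class": table[CLASS_COLUMN],
            "tank": table[TANK_COLUMN],
            "date": table[DATE_COLUMN],
            "seed": config.seed,
            "mode": config.mode,
        }
    )
    manifest.to_csv(out / "manifest.csv", index=False)


def generate_season(
    config: GenerationConfig,
    class_weights: pd.DataFrame,
    n_per_sample: int = 40,
) -> LabeledDataset:
    """Generate an unbalanced seasonal series with date-varying mixtures.

    ``class_weights`` is indexed by date (ISO strings) with one column per
    class; each (tank, date) sample draws ``n_per_sample`` particles from
    a multinomial over the date's (renormalised) weights, so zeroing a
    class's weight over a date window makes it disappear from the series
    and re-appear afterwards.  Table mode only.
    """
    if config.mode != "table":
        raise ValueError("seasonal generation runs in table mode")
    profiles = {p.class_name: p for p in config.profiles}
    unknown = set(class_weights.columns) - set(profiles)
    if unknown:
        raise ValueError(f"weights for unknown classes: {sorted(unknown)}")
    rng = np.random.default_rng(config.seed)
    blocks = []
    for date in class_weights.index:
        w = class_weights.loc[date].to_numpy(float)
        if w.sum() <= 0:
            raise ValueError(f"all-zero class weights on {date}")
        p = w / w.sum()
        for tank in TANKS:
            counts = rng.multinomial(n_per_sample, p)
            for cls, cnt in zip(class_weights.columns, counts):
                if cnt == 0:
                    continue
                block = _draw_table_rows(
                    profiles[cls], int(cnt), rng, config.overlap_scale
                )
                block[CLASS_COLUMN] = cls
                block[TANK_COLUMN] = tank
                block[DATE_COLUMN] = date
                blocks.append(block)
    table = pd.concat(blocks, ignore_index=True)
    table.insert(0, ID_COLUMN, [f"s{i:06d}" for i in range(len(table))])
    return LabeledDataset(table)
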