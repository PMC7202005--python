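"""Karyosome measurement protocol for Prometaphase I confocal stacks.

Implements the cytological pipeline used to quantify dot-chromosome
behavior on the meiotic spindle:

1. maximum-intensity projection of the stack;
2. segmentation of chromosome blobs in the projection, separating the
   large exchange-chromosome mass from small dot-chromosome candidates;
3. "out on the spindle" classification of each dot by the 50%-dip rule on
   a background-subtracted intensity line profile between the dot and the
   adjacent chromosome mass;
4. XY separation between the two dots' outer edges, Z separation from the
   offset (in whole sections) between the dot light-cone centers, and the
   3D separation via the Pythagorean theorem distance = sqrt(d² + z²);
5. cross-sectional dot areas (pixel count × pixel size²);
6. per-oocyte configuration triage: oocytes with both dots on the same
   side of the spindle, extra nonexchange chromosomes, or otherwise
   abnormal figures are excluded from distance measurement but still count
   toward the proportion of oocytes with chromosomes out.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from scipy import ndimage
from skimage import filters
from skimage import measure as skmeasure

from .stack import ConfocalStack

__all__ = [
    "Configuration",
    "LineProfile",
    "ChromosomeBlob",
    "OocyteMeasurement",
    "UnclassifiableProfileError",
    "max_intensity_projection",
    "estimate_background",
    "segment_blobs",
    "extract_line_profile",
    "classify_dot_out",
    "xy_distance",
    "z_offset_sections",
    "compute_3d_distance",
    "measure_area",
    "classify_configuration",
    "proportion_out",
    "measure_oocyte",
]

#: Default dip threshold: "out" requires at least a 50% dip in
#: background-subtracted intensity between the dot and the adjacent mass.
DIP_THRESHOLD = 0.50
#: Blobs smaller than this fraction of the largest blob are dot candidates.
DOT_AREA_FRACTION = 0.25
#: A flanking peak is "detectable" only if its background-subtracted height
#: is at least this fraction of the profile's global background-subtracted
#: maximum; profiles without two such peaks are unclassifiable.
MIN_PEAK_FRACTION = 0.10


class Configuration(str, Enum):
    """Per-oocyte triage labels.

    Distance-eligible: at least one dot out with the other locatable, or
    both out on opposite sides. Everything else is excluded from distance
    measurement; anything with a chromosome out still counts toward the
    proportion out.
    """

    ONE_OUT_OTHER_LOCATABLE = "one_out_other_locatable"
    BOTH_OUT = "both_out"
    BOTH_SAME_SIDE = "both_same_side"
    EXTRA_NONEXCHANGE = "extra_nonexchange"
    ABNORMAL = "abnormal"
    NONE_OUT = "none_out"

    @property
    def distance_eligible(self) -> bool:
        return self in (Configuration.ONE_OUT_OTHER_LOCATABLE, Configuration.BOTH_OUT)

    @property
    def counts_as_out(self) -> bool:
        return self not in (Configuration.NONE_OUT, Configuration.ABNORMAL)


class UnclassifiableProfileError(ValueError):
    """Line profile lacks two detectable peaks; the figure is abnormal."""


@dataclass
class LineProfile:
    """Ordered intensity samples along a path in the projected image."""

    samples: np.ndarray
    start: tuple[float, float]
    end: tuple[float, float]
    background: float

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.size < 3:
            raise ValueError("a line profile needs at least 3 samples")
        if not 0 <= self.background <= float(self.samples.max()):
            raise ValueError("background must lie in [0, max sample]")


@dataclass
class ChromosomeBlob:
    """One connected chromosome region in the projected image."""

    pixels: np.ndarray  # (n, 2) array of (row, col) member pixels
    centroid: tuple[float, float]
    area_px: int
    area_um2: float
    peak_intensity: float
    is_dot: bool
    light_cone_section: int | None = None

    @classmethod
    def from_pixels(
        cls, pixels: np.ndarray, image: np.ndarray, pixel_size_xy: float, is_dot: bool = False
    ) -> "ChromosomeBlob":
        pixels = np.asarray(pixels, dtype=int)
        if pixels.size == 0:
            raise ValueError("a blob needs at least one member pixel")
        vals = image[pixels[:, 0], pixels[:, 1]]
        return cls(
            pixels=pixels,
            centroid=(float(pixels[:, 0].mean()), float(pixels[:, 1].mean())),
            area_px=len(pixels),
            area_um2=len(pixels) * pixel_size_xy**2,
            peak_intensity=float(vals.max()),
            is_dot=is_dot,
        )


@dataclass
class OocyteMeasurement:
    """Everything the protocol records for one oocyte."""

    oocyte_id: str
    configuration: Configuration
    n_out: int
    d_xy_um: float | None = None
    z_sections: int | None = None
    z_um: float | None = None
    distance_um: float | None = None
    dot_areas_um2: list[float] = field(default_factory=list)
    notes: str = ""


# ---------------------------------------------------------------------------
# Projection, background, segmentation


def max_intensity_projection(stack: ConfocalStack) -> np.ndarray:
    """Collapse the Z axis by per-pixel maximum."""
    if stack.data.size == 0:
        raise ValueError("cannot project an empty stack")
    return stack.data.max(axis=0)


def estimate_background(values: np.ndarray) -> float:
    """Background = median of the lowest-decile intensities.

    On a projected oocyte field the chromosomes occupy a small fraction of
    pixels, so the bottom decile is essentially pure off-chromosome signal;
    the median of it is robust to stray dark pixels. For a constant input
    this returns that constant.
    """
    values = np.asarray(values, dtype=float).ravel()
    if values.size == 0:
        raise ValueError("cannot estimate background of an empty input")
    cutoff = np.quantile(values, 0.10)
    low = values[values <= cutoff]
    return float(np.median(low))


#: Component-finding threshold: background + this fraction of the image's
#: background-subtracted maximum. Low enough to separate dim dots from the
#: background, high enough that an out dot's valley (< 50% of its peak by
#: definition) splits it from the main mass.
SEGMENT_FRACTION = 0.25


def _threshold_value(image: np.ndarray, policy: str | float, background: float) -> float:
    if isinstance(policy, (int, float)):
        return float(policy)
    if policy == "relative":
        return background + SEGMENT_FRACTION * (float(image.max()) - background)
    if policy == "half_max":
        return background + 0.5 * (float(image.max()) - background)
    if policy == "otsu":
        return float(filters.threshold_otsu(image))
    raise ValueError(f"unknown threshold policy {policy!r}")


def segment_blobs(
    image: np.ndarray,
    threshold: str | float = "relative",
    dot_area_fraction: float = DOT_AREA_FRACTION,
    pixel_size_xy: float = 0.054,
    refine_half_max: bool = True,
    background: float | None = None,
) -> list[ChromosomeBlob]:
    """Find chromosome blobs in a projected image.

    Connected components above the threshold, largest first. ``threshold``
    is ``"relative"`` (background + :data:`SEGMENT_FRACTION` of the
    background-subtracted global peak), ``"half_max"``, ``"otsu"``, or an
    absolute intensity. With ``refine_half_max`` each blob's member pixel
    set is re-cut at the blob-local half-max: the half-maximum contour of
    a symmetrically blurred object sits at the object's true edge, so
    per-blob half-max makes areas comparable between dim and bright
    structures. Returns ``[]`` when nothing exceeds the threshold.
    """
    image = np.asarray(image, dtype=float)
    if image.size == 0:
        raise ValueError("cannot segment an empty image")
    if background is None:
        background = estimate_background(image)
    thr = _threshold_value(image, threshold, background)
    mask = image > thr
    if not mask.any():
        return []
    labels = skmeasure.label(mask, connectivity=2)
    blobs: list[ChromosomeBlob] = []
    for region in skmeasure.regionprops(labels):
        pixels = region.coords
        if refine_half_max:
            vals = image[pixels[:, 0], pixels[:, 1]]
            local_thr = background + 0.5 * (vals.max() - background)
            keep = vals >= local_thr
            if keep.any():
                pixels = pixels[keep]
        blobs.append(ChromosomeBlob.from_pixels(pixels, image, pixel_size_xy))
    blobs.sort(key=lambda b: b.area_px, reverse=True)
    largest = blobs[0].area_px
    for b in blobs[1:]:
        b.is_dot = b.area_px < dot_area_fraction * largest
    return blobs


# ---------------------------------------------------------------------------
# The 50%-dip out-classifier


def extract_line_profile(
    image: np.ndarray,
    start: tuple[float, float],
    end: tuple[float, float],
    background: float | None = None,
) -> LineProfile:
    """Sample intensities along the segment start → end ((row, col), px)."""
    image = np.asarray(image, dtype=float)
    if background is None:
        background = estimate_background(image)
    samples = skmeasure.profile_line(
        image, start, end, linewidth=1, mode="nearest", order=1
    )
    background = min(background, float(samples.max()))
    return LineProfile(samples=samples, start=tuple(start), end=tuple(end), background=background)


def classify_dot_out(profile: LineProfile, dip_threshold: float = DIP_THRESHOLD) -> bool:
    """Apply the 50%-dip rule to a dot ↔ adjacent-chromosome profile.

    The chromosome is "out" if somewhere between the two flanking peaks the
    background-subtracted intensity falls to at most ``1 - dip_threshold``
    of the background-subtracted reference peak, the reference being the
    lower of the two flanking peaks (a dip relative to the dimmer structure
    guarantees a dip relative to both). A dip of exactly the threshold
    counts as out ("at least a 50% dip").

    Concretely: out iff there is an interior sample v with
    ``bgsub[v] <= (1 - dip_threshold) * min(max(bgsub[:v]), max(bgsub[v+1:]))``
    where both flanking maxima are detectable peaks (at least
    :data:`MIN_PEAK_FRACTION` of the global background-subtracted maximum).

    Raises
    ------
    UnclassifiableProfileError
        If the profile does not show two detectable flanking peaks (e.g. a
        single peak decaying into flat background); such figures are
        triaged as abnormal.
    """
    bgsub = profile.samples - profile.background
    floor = MIN_PEAK_FRACTION * float(bgsub.max())
    prefix = np.maximum.accumulate(bgsub)[:-1]  # max over [0..v-1] at index v-1
    suffix = np.maximum.accumulate(bgsub[::-1])[::-1][1:]  # max over [v+1..] at v
    interior = bgsub[1:-1]
    left = prefix[:-1]
    right = suffix[1:]
    valid = (left > 0) & (right > 0) & (left >= floor) & (right >= floor)
    if not valid.any():
        raise UnclassifiableProfileError(
            "profile has fewer than two detectable peaks; cannot apply the dip rule"
        )
    ref = np.minimum(left, right)
    keep_fraction = 1.0 - dip_threshold
    return bool(np.any(valid & (interior <= keep_fraction * ref)))


# ---------------------------------------------------------------------------
# Geometry


def _projected_extent(
    blob: ChromosomeBlob, origin: np.ndarray, direction: np.ndarray
) -> tuple[float, float]:
    proj = (blob.pixels - origin) @ direction
    return float(proj.min()), float(proj.max())


def xy_distance(blob_a: ChromosomeBlob, blob_b: ChromosomeBlob, pixel_size_xy: float) -> float:
    """XY separation between the two blobs' outer edges, in µm.

    The farthest-apart pair of member pixels of the two blobs, projected on
    the line through their centroids, plus one pixel per side for the pixel
    extent beyond its center — the automated equivalent of drawing a line
    across both chromosomes' outer edges. Overlapping blobs return 0 with a
    warning.
    """
    a_set = {tuple(p) for p in blob_a.pixels}
    if any(tuple(p) in a_set for p in blob_b.pixels):
        warnings.warn("blobs overlap; outer-edge XY distance set to 0", stacklevel=2)
        return 0.0
    ca = np.asarray(blob_a.centroid)
    cb = np.asarray(blob_b.centroid)
    sep = cb - ca
    norm = np.linalg.norm(sep)
    if norm == 0:
        warnings.warn("blobs share a centroid; outer-edge XY distance set to 0", stacklevel=2)
        return 0.0
    u = sep / norm
    lo_a, _ = _projected_extent(blob_a, ca, u)
    _, hi_b = _projected_extent(blob_b, ca, u)
    length_px = (hi_b - lo_a) + 2.0  # one pixel per side
    return length_px * pixel_size_xy


def z_offset_sections(
    stack: ConfocalStack, blob_a: ChromosomeBlob, blob_b: ChromosomeBlob
) -> int:
    """Sections between the two blobs' light-cone centers.

    Each blob's light-cone center is the section maximizing the summed
    intensity over the blob's projected pixel footprint (the orthogonal-
    projection reading of where the structure is in focus).
    """

    def center_section(blob: ChromosomeBlob) -> int:
        rows, cols = blob.pixels[:, 0], blob.pixels[:, 1]
        if rows.max() >= stack.shape[1] or cols.max() >= stack.shape[2]:
            raise ValueError("blob lies outside the stack's XY extent")
        per_section = stack.data[:, rows, cols].sum(axis=1)
        return int(np.argmax(per_section))

    sa, sb = center_section(blob_a), center_section(blob_b)
    blob_a.light_cone_section = sa
    blob_b.light_cone_section = sb
    return abs(sa - sb)


def compute_3d_distance(d_xy: float, z_sections: int, section_thickness: float) -> float:
    """3D separation: sqrt(d_xy² + (z_sections × section_thickness)²), µm."""
    if d_xy < 0:
        raise ValueError("d_xy must be >= 0")
    if z_sections < 0:
        raise ValueError("z_sections must be >= 0")
    if section_thickness <= 0:
        raise ValueError("section_thickness must be > 0")
    return math.hypot(d_xy, z_sections * section_thickness)


def measure_area(blob: ChromosomeBlob, pixel_size_xy: float) -> float:
    """Cross-sectional blob area: pixel count × pixel size², µm²."""
    if blob.area_px == 0:
        raise ValueError("cannot measure an empty blob")
    return blob.area_px * pixel_size_xy**2


# ---------------------------------------------------------------------------
# Per-oocyte triage


def classify_configuration(
    dot_blobs: list[ChromosomeBlob],
    out_flags: list[bool],
    mass_centroid: tuple[float, float] | None = None,
) -> Configuration:
    """Triage one oocyte from its dot candidates and their out flags.

    Sides of the spindle are signed displacements from the main-mass
    centroid along the axis through the farthest out dot. More than two
    dot candidates with any out is an extra-nonexchange figure; inputs the
    rules cannot resolve map to ``ABNORMAL``, never an exception.
    """
    if len(dot_blobs) != len(out_flags):
        raise ValueError("need one out flag per dot blob")
    n_out = int(sum(out_flags))
    if n_out == 0:
        return Configuration.NONE_OUT
    if len(dot_blobs) > 2:
        return Configuration.EXTRA_NONEXCHANGE
    if len(dot_blobs) == 1:
        # One dot out, the other not even locatable.
        return Configuration.ABNORMAL
    if mass_centroid is None:
        centroids = np.array([b.centroid for b in dot_blobs])
        mass_centroid = tuple(centroids.mean(axis=0))
    disp = np.array([np.asarray(b.centroid) - np.asarray(mass_centroid) for b in dot_blobs])
    out_idx = [i for i, f in enumerate(out_flags) if f]
    axis_vec = disp[max(out_idx, key=lambda i: np.linalg.norm(disp[i]))]
    norm = np.linalg.norm(axis_vec)
    if norm == 0:
        return Configuration.ABNORMAL
    sides = np.sign(disp @ (axis_vec / norm))
    if n_out == 2:
        return (
            Configuration.BOTH_SAME_SIDE
            if sides[0] == sides[1]
            else Configuration.BOTH_OUT
        )
    return Configuration.ONE_OUT_OTHER_LOCATABLE


def proportion_out(n_with_any_out: int, n_total_past_prophase: int) -> float:
    """Fraction of post-Prophase oocytes with one or more chromosomes out."""
    if n_total_past_prophase <= 0:
        raise ValueError("total oocyte count must be > 0")
    if not 0 <= n_with_any_out <= n_total_past_prophase:
        raise ValueError("out count must be between 0 and the total count")
    return n_with_any_out / n_total_past_prophase


# ---------------------------------------------------------------------------
# Whole-stack pipeline


def _locate_embedded_dot(
    image: np.ndarray,
    mass: ChromosomeBlob,
    dot_radius_px: float,
    background: float,
) -> tuple[float, float] | None:
    """Look for a not-out dot merged with the main mass.

    A dot hugging the mass edge leaves a local intensity maximum displaced
    from the mass body. We scan the mass component (slightly dilated) for
    maxima at least one dot radius from the mass centroid along the image
    rows/cols and return the strongest such peak, or None.
    """
    from skimage.feature import peak_local_max

    mask = np.zeros(image.shape, dtype=bool)
    mask[mass.pixels[:, 0], mass.pixels[:, 1]] = True
    mask = ndimage.binary_dilation(mask, iterations=2)
    min_dist = max(2, int(round(dot_radius_px)))
    peaks = peak_local_max(
        image, labels=mask.astype(int), min_distance=min_dist,
        threshold_abs=background, num_peaks=5,
    )
    c = np.asarray(mass.centroid)
    best: tuple[float, float] | None = None
    best_val = -np.inf
    for p in peaks:
        if np.linalg.norm(p - c) >= 1.5 * dot_radius_px and image[p[0], p[1]] > best_val:
            best_val = image[p[0], p[1]]
            best = (float(p[0]), float(p[1]))
    return best


def measure_oocyte(
    stack: ConfocalStack,
    oocyte_id: str = "oocyte",
    threshold: str | float = "relative",
    dip_threshold: float = DIP_THRESHOLD,
    dot_area_fraction: float = DOT_AREA_FRACTION,
    smooth_sigma_px: float = 1.0,
) -> OocyteMeasurement:
    """Run the full measurement protocol on one stack.

    Projection → segmentation → per-dot 50%-dip classification →
    configuration triage → (when eligible) outer-edge XY distance, light-
    cone Z offset, 3D distance, and dot areas.

    ``smooth_sigma_px`` lightly Gaussian-smooths the stack in 3D before
    projection (the Z sigma is scaled to roughly one section). A symmetric
    smooth leaves the half-maximum edge contour in place while suppressing
    noise; denoising *before* the maximum projection matters because the
    per-pixel maximum over many noisy sections raises the background floor
    without raising in-focus structure pixels, which would otherwise pull
    the half-max contour inward.
    """
    if smooth_sigma_px > 0:
        sigma_z = 0.6  # sections; just enough to pool adjacent sections
        data = ndimage.gaussian_filter(
            stack.data.astype(float), (sigma_z, smooth_sigma_px, smooth_sigma_px)
        )
        stack = ConfocalStack(data, stack.pixel_size_xy, stack.section_thickness_z)
    image = max_intensity_projection(stack).astype(float)
    # Background from the stack voxels, not the projection: the per-pixel
    # maximum over many sections raises the floor of background pixels but
    # not of in-focus structure pixels, so a projection-based estimate
    # would overstate the background under the chromosomes.
    background = estimate_background(stack.data)
    blobs = segment_blobs(
        image,
        threshold=threshold,
        dot_area_fraction=dot_area_fraction,
        pixel_size_xy=stack.pixel_size_xy,
        background=background,
    )
    if not blobs:
        return OocyteMeasurement(
            oocyte_id, Configuration.NONE_OUT, 0, notes="no chromosomes detected"
        )
    mass = blobs[0]
    dots = [b for b in blobs[1:] if b.is_dot]

    out_flags: list[bool] = []
    kept_dots: list[ChromosomeBlob] = []
    for dot in dots:
        profile = extract_line_profile(image, dot.centroid, mass.centroid, background)
        try:
            out_flags.append(classify_dot_out(profile, dip_threshold))
            kept_dots.append(dot)
        except UnclassifiableProfileError:
            return OocyteMeasurement(
                oocyte_id,
                Configuration.ABNORMAL,
                0,
                notes="unclassifiable line profile",
            )

    notes = ""
    if len(kept_dots) == 1 and out_flags[0]:
        # One dot clearly out; try to locate its partner merged with the mass.
        r_px = math.sqrt(kept_dots[0].area_px / math.pi)
        peak = _locate_embedded_dot(image, mass, r_px, background)
        if peak is not None:
            pseudo = ChromosomeBlob(
                pixels=np.array([[int(round(peak[0])), int(round(peak[1]))]]),
                centroid=peak,
                area_px=1,
                area_um2=stack.pixel_size_xy**2,
                peak_intensity=float(image[int(round(peak[0])), int(round(peak[1]))]),
                is_dot=True,
            )
            kept_dots.append(pseudo)
            out_flags.append(False)
            notes = "partner dot located within main mass (approximate edge)"

    config = classify_configuration(kept_dots, out_flags, mass.centroid)
    n_out = int(sum(out_flags))
    meas = OocyteMeasurement(oocyte_id, config, n_out, notes=notes)

    if config.distance_eligible and len(kept_dots) >= 2:
        # The two dots: prefer the out ones; in the one-out case the
        # pseudo-blob stands in for the embedded partner.
        order = np.argsort([not f for f in out_flags])
        a, b = kept_dots[order[0]], kept_dots[order[1]]
        d_xy = xy_distance(a, b, stack.pixel_size_xy)
        zs = z_offset_sections(stack, a, b)
        meas.d_xy_um = d_xy
        meas.z_sections = zs
        meas.z_um = zs * stack.section_thickness_z
        meas.distance_um = compute_3d_distance(d_xy, zs, stack.section_thickness_z)
        meas.dot_areas_um2 = [
            measure_area(d, stack.pixel_size_xy) for d in kept_dots if d.area_px > 1
        ]
    return meas
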