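"""Synthetic Prometaphase I karyosome stacks and per-oocyte tables.

The generator emulates what a fixed, DAPI-stained oocyte looks like in a
single-channel confocal stack: a bright mass of exchange chromosomes at the
spindle midzone, and zero, one or two small dot-chromosome foci displaced
toward the spindle poles. Structures are rendered as solid ellipsoids,
convolved with an anisotropic Gaussian (broader in Z, mimicking the optical
"light cone"), scaled to a peak intensity over a constant background, and
optionally degraded with additive Gaussian noise. Every stack ships with a
ground-truth record so measurement code can be tested for parameter
recovery without any real micrographs.

Distance convention: the study reports dot-dot separation as the XY
distance between the *outer* chromosome edges combined with a Z offset in
whole sections. Ground truth here is defined on the same convention — dot
centers are placed so that the outer-edge XY distance equals the requested
value — because that is the quantity the measurement protocol returns.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .stack import ConfocalStack

__all__ = [
    "SimulationParams",
    "GroundTruth",
    "SpeciesSimSpec",
    "generate_oocyte_stack",
    "generate_species_dataset",
    "SPECIES_TABLE_COLUMNS",
]

CONFIGURATIONS = ("normal", "both_same_side", "extra_nonexchange")


@dataclass
class SimulationParams:
    """Knobs for one synthetic oocyte stack.

    All physical lengths are in µm; areas in µm²; intensities in arbitrary
    units. ``true_separation_3d`` is the outer-edge 3D dot-dot separation
    (only meaningful when two dots are rendered). ``z_offset_sections`` is
    how many whole optical sections separate the two dot light-cone
    centers; the XY component is derived so the 3D separation matches.
    """

    shape: tuple[int, int, int] = (24, 192, 192)  # sections, rows, cols
    pixel_size_xy: float = 0.054
    section_thickness_z: float = 0.5
    true_separation_3d: float = 6.0
    dot_area: float = 0.85
    main_mass_area: float = 8.0
    peak_intensity: float = 200.0
    background_level: float = 20.0
    noise_sd: float = 0.0
    blur_sigma_xy: float = 0.08
    blur_sigma_z: float = 0.3
    n_dots_out: int = 2
    z_offset_sections: int = 2
    configuration: str = "normal"
    seed: int = 0

    def validate(self) -> None:
        s, r, c = self.shape
        if min(s, r, c) < 1:
            raise ValueError(f"non-positive stack dimension in shape {self.shape}")
        if self.pixel_size_xy <= 0:
            raise ValueError("pixel_size_xy must be > 0")
        if self.section_thickness_z <= 0:
            raise ValueError("section_thickness_z must be > 0")
        if self.true_separation_3d < 0:
            raise ValueError("true_separation_3d must be >= 0")
        if self.dot_area <= 0:
            raise ValueError("dot_area must be > 0")
        if self.main_mass_area <= 0:
            raise ValueError("main_mass_area must be > 0")
        if self.n_dots_out not in (0, 1, 2):
            raise ValueError("n_dots_out must be 0, 1, or 2")
        if self.z_offset_sections < 0:
            raise ValueError("z_offset_sections must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.configuration not in CONFIGURATIONS:
            raise ValueError(
                f"configuration must be one of {CONFIGURATIONS}, got {self.configuration!r}"
            )


@dataclass
class GroundTruth:
    """What was actually placed in a generated stack.

    ``d_xy_um``/``z_um``/``separation_um`` follow the measurement
    convention (outer-edge XY, section-center Z) and satisfy
    separation = sqrt(d_xy² + z²) by construction.
    """

    dot_centers_um: list[tuple[float, float, float]]  # (z, y, x) per dot
    dot_areas_um2: list[float]
    d_xy_um: float
    z_um: float
    separation_um: float
    configuration: str
    n_dots_out: int
    seed: int

    def check(self, atol: float = 1e-9) -> None:
        if self.separation_um or self.d_xy_um or self.z_um:
            assert math.isclose(
                self.separation_um,
                math.hypot(self.d_xy_um, self.z_um),
                abs_tol=atol,
            ), "ground truth violates separation = sqrt(d_xy² + z²)"


def _ellipsoid_mask(
    shape: tuple[int, int, int],
    center: tuple[float, float, float],
    semi_axes_um: tuple[float, float, float],
    pixel_size_xy: float,
    section_thickness_z: float,
    z_exponent: float = 2.0,
) -> np.ndarray:
    """Boolean solid ellipsoid on the anisotropic voxel grid (center in voxels).

    ``z_exponent`` > 2 flattens the solid along Z (a superellipsoid): the
    body keeps nearly full thickness out to its XY rim, so the projected
    cross-section has a sharp, well-defined edge at the nominal radius.
    """
    zz, yy, xx = np.ogrid[: shape[0], : shape[1], : shape[2]]
    az, ay, ax = semi_axes_um
    dz = (zz - center[0]) * section_thickness_z / az
    dy = (yy - center[1]) * pixel_size_xy / ay
    dx = (xx - center[2]) * pixel_size_xy / ax
    return np.abs(dz) ** z_exponent + dy**2 + dx**2 <= 1.0


def _check_bounds(
    name: str,
    center: tuple[float, float, float],
    extent_vox: tuple[float, float, float],
    shape: tuple[int, int, int],
) -> None:
    axes = ("sections (Z)", "rows (Y)", "cols (X)")
    for ax in range(3):
        lo = center[ax] - extent_vox[ax]
        hi = center[ax] + extent_vox[ax]
        if lo < 0 or hi > shape[ax] - 1:
            raise ValueError(
                f"{name} does not fit along {axes[ax]}: needs voxel range "
                f"[{lo:.1f}, {hi:.1f}] in a dimension of size {shape[ax]}; "
                "reduce the separation or enlarge the stack"
            )


def generate_oocyte_stack(
    params: SimulationParams,
) -> tuple[ConfocalStack, GroundTruth]:
    """Render one synthetic oocyte stack and its ground truth.

    Identical ``params`` (including seed) give a bit-identical stack.
    """
    params.validate()
    S, R, C = params.shape
    px = params.pixel_size_xy
    dz = params.section_thickness_z
    rng = np.random.default_rng(params.seed)

    r_dot = math.sqrt(params.dot_area / math.pi)  # µm, in-plane radius
    r_mass = math.sqrt(params.main_mass_area / math.pi)
    # Z semi-axes: dots are compact; the mass spans a couple of sections.
    dot_semi = (max(1.0 * dz, 0.5 * r_dot), r_dot, r_dot)
    # Metaphase-plate-like mass: elongated across the spindle (X), thinner
    # along it (Y); projected area equals main_mass_area.
    mass_semi = (1.2 * dz, r_mass / 1.3, 1.3 * r_mass)

    z_mid = S // 2
    y_mid = (R - 1) / 2
    x_mid = (C - 1) / 2
    mass_center = (float(z_mid), y_mid, x_mid)

    z_um = params.z_offset_sections * dz
    if params.true_separation_3d < z_um:
        raise ValueError(
            f"true_separation_3d ({params.true_separation_3d} µm) is smaller than the "
            f"Z offset {z_um} µm ({params.z_offset_sections} sections × {dz} µm); "
            "reduce z_offset_sections"
        )
    d_xy = math.sqrt(params.true_separation_3d**2 - z_um**2)
    # Outer-edge convention: measured XY distance spans both dots' far edges
    # (center distance + 2 r_dot) plus one pixel of edge extent per side.
    c2c_um = d_xy - 2 * r_dot - px
    clearance = mass_semi[1] + r_dot + 3 * params.blur_sigma_xy
    if params.n_dots_out >= 1 and c2c_um / 2 < clearance:
        raise ValueError(
            f"true_separation_3d ({params.true_separation_3d} µm) too small: out dots "
            f"at ±{c2c_um / 2:.2f} µm would touch the main mass (needs ≥ {clearance:.2f} µm "
            "along rows (Y)); increase the separation or shrink main_mass_area"
        )

    k = params.z_offset_sections
    z_a = z_mid - (k - k // 2)
    z_b = z_mid + k // 2

    half_px = (c2c_um / 2) / px  # displacement of each out dot from midzone, px
    # A not-out dot sits just off the mass edge: the tiny gap blurs into a
    # shallow (<50%) dip, so the dot is locatable but not "out".
    touch_px = (mass_semi[1] + r_dot + 0.12) / px

    def out_center(sign: float, zc: int) -> tuple[float, float, float]:
        return (float(zc), y_mid + sign * half_px, x_mid)

    def in_center(sign: float) -> tuple[float, float, float]:
        return (float(z_mid), y_mid + sign * touch_px, x_mid)

    config = params.configuration
    if config == "both_same_side":
        # Both dots displaced toward the same pole, laterally separated.
        centers = [
            (float(z_a), y_mid + half_px, x_mid - 1.5 * r_dot / px),
            (float(z_b), y_mid + half_px, x_mid + 1.5 * r_dot / px),
        ]
        n_out = 2
    else:
        n_out = params.n_dots_out
        if n_out == 2:
            centers = [out_center(-1.0, z_a), out_center(+1.0, z_b)]
        elif n_out == 1:
            centers = [out_center(-1.0, z_a), in_center(+1.0)]
        else:
            centers = [in_center(-1.0), in_center(+1.0)]

    extra_centers: list[tuple[float, float, float]] = []
    if config == "extra_nonexchange":
        # A third small chromosome out on the spindle, off the dot axis.
        extra_centers.append(
            (float(z_mid), y_mid + 0.7 * half_px, x_mid + (r_mass + 4 * r_dot) / px)
        )

    geometry = np.zeros((S, R, C), dtype=np.float64)
    _check_bounds(
        "main chromosome mass",
        mass_center,
        (mass_semi[0] / dz + 1, mass_semi[1] / px + 2, mass_semi[2] / px + 2),
        (S, R, C),
    )
    geometry = np.maximum(
        geometry,
        _ellipsoid_mask((S, R, C), mass_center, mass_semi, px, dz).astype(float),
    )
    for i, ctr in enumerate(centers + extra_centers):
        _check_bounds(
            f"dot focus {i}",
            ctr,
            (dot_semi[0] / dz + 1, dot_semi[1] / px + 2, dot_semi[2] / px + 2),
            (S, R, C),
        )
        geometry = np.maximum(
            geometry,
            _ellipsoid_mask((S, R, C), ctr, dot_semi, px, dz, z_exponent=4.0).astype(
                float
            ),
        )

    sigma_vox = (params.blur_sigma_z / dz, params.blur_sigma_xy / px, params.blur_sigma_xy / px)
    blurred = ndimage.gaussian_filter(geometry, sigma=sigma_vox)
    volume = blurred * params.peak_intensity + params.background_level
    if params.noise_sd > 0:
        volume = volume + rng.normal(0.0, params.noise_sd, size=volume.shape)
    volume = np.clip(volume, 0.0, None).astype(np.float32)

    centers_um = [(c[0] * dz, c[1] * px, c[2] * px) for c in centers]
    if params.n_dots_out == 2 and config != "both_same_side":
        truth = GroundTruth(
            dot_centers_um=centers_um,
            dot_areas_um2=[params.dot_area, params.dot_area],
            d_xy_um=d_xy,
            z_um=z_um,
            separation_um=params.true_separation_3d,
            configuration=config,
            n_dots_out=n_out,
            seed=params.seed,
        )
    else:
        # Separation is only defined for the measurable two-dots-out geometry.
        truth = GroundTruth(
            dot_centers_um=centers_um,
            dot_areas_um2=[params.dot_area] * len(centers),
            d_xy_um=0.0,
            z_um=0.0,
            separation_um=0.0,
            configuration=config,
            n_dots_out=n_out,
            seed=params.seed,
        )
    truth.check()
    stack = ConfocalStack(volume, pixel_size_xy=px, section_thickness_z=dz)
    return stack, truth


# ---------------------------------------------------------------------------
# Tabular per-oocyte datasets (slide-survey stand-in)

SPECIES_TABLE_COLUMNS = [
    "oocyte_id",
    "out_flag",
    "configuration",
    "d_xy_um",
    "z_sections",
    "distance_um",
    "area1_um2",
    "area2_um2",
]


@dataclass
class SpeciesSimSpec:
    """Sampling spec for one species' per-oocyte table.

    Emulates a slide survey: each post-Prophase oocyte shows a chromosome
    out on the spindle with probability ``probability_out``; oocytes that
    are out carry a 3D separation draw (normal, truncated at 0) and two
    dot cross-sectional area draws (normal, truncated at 0).
    """

    species: str
    n_oocytes: int = 100
    probability_out: float = 0.25
    distance_mean_um: float = 7.0
    distance_sd_um: float = 2.0
    area_mean_um2: float = 0.5
    area_sd_um2: float = 0.15
    section_thickness_z: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 <= self.probability_out <= 1.0:
            raise ValueError("probability_out must be in [0, 1]")
        if self.n_oocytes < 0:
            raise ValueError("n_oocytes must be >= 0")
        if self.distance_sd_um < 0 or self.area_sd_um2 < 0:
            raise ValueError("standard deviations must be >= 0")


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, size: int
) -> np.ndarray:
    if sd == 0:
        return np.full(size, mean)
    a = (0.0 - mean) / sd  # truncate at zero
    return stats.truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=size, random_state=rng)


def generate_species_dataset(spec: SpeciesSimSpec) -> pd.DataFrame:
    """Draw one species' per-oocyte measurement table.

    Returns a DataFrame with :data:`SPECIES_TABLE_COLUMNS`; rows not out
    carry NaN for the geometric columns. Reproducible under ``spec.seed``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_oocytes
    out = rng.random(n) < spec.probability_out
    n_out = int(out.sum())

    distance = np.full(n, np.nan)
    d_xy = np.full(n, np.nan)
    z_sections = np.full(n, np.nan)
    area1 = np.full(n, np.nan)
    area2 = np.full(n, np.nan)

    if n_out:
        dist = _truncated_normal(rng, spec.distance_mean_um, spec.distance_sd_um, n_out)
        # Decompose into XY + whole-section Z the way the protocol records them.
        k = rng.integers(0, 5, size=n_out)
        z = k * spec.section_thickness_z
        too_steep = z >= dist
        k[too_steep] = 0
        z[too_steep] = 0.0
        distance[out] = dist
        z_sections[out] = k
        d_xy[out] = np.sqrt(dist**2 - z**2)
        area1[out] = _truncated_normal(rng, spec.area_mean_um2, spec.area_sd_um2, n_out)
        area2[out] = _truncated_normal(rng, spec.area_mean_um2, spec.area_sd_um2, n_out)

    configuration = np.where(out, "both_out", "none_out")
    return pd.DataFrame(
        {
            "oocyte_id": [f"{spec.species}_{i:04d}" for i in range(n)],
            "out_flag": out,
            "configuration": configuration,
            "d_xy_um": d_xy,
            "z_sections": z_sections,
            "distance_um": distance,
            "area1_um2": area1,
            "area2_um2": area2,
        }
    )
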