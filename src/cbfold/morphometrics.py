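"""Contour morphometrics of midsagittal cerebellar sections.

Implements the measurements used to characterise folding initiation:

* arc length, enclosed area and signed curvature of boundary contours;
* the folding index ``100 * (1 - convex length / total length)``, which is 0
  for a convex (unfolded) section and grows as concave arcs appear;
* EGL thickness profiles: shortest distances from points every 12.5 um along
  the inner EGL boundary to the outer boundary, and AC/flank thickness ratios;
* the dimensionless shape factor (half perimeter / sqrt(half area), equal to
  sqrt(2*pi) for a perfect semicircle);
* reference expansion curves (semicircular and columnar) that relate EGL
  length to core area under proportional growth;
* 3D sphericity of voxelised cell masks;
* the acoustic bulk modulus K = Z * c.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import label as _cc_label
from shapely.geometry import Point

from cbfold.contour import Contour, ContourError

log = logging.getLogger(__name__)

SEMICIRCLE_SHAPE_FACTOR = math.sqrt(2.0 * math.pi)


@dataclass(frozen=True)
class ContourMetrics:
    """Length (um), enclosed area (um^2, closed contours only) and per-point
    signed curvature (1/um) of a contour."""

    length: float
    area: float | None
    curvature: np.ndarray


@dataclass(frozen=True)
class ThicknessProfile:
    """EGL thickness sampled along the inner boundary.

    ``positions`` are arc-length coordinates (um) along the inner contour,
    strictly increasing; ``normalized`` is thickness divided by its mean.
    """

    positions: np.ndarray
    thickness: np.ndarray
    spacing: float

    def __post_init__(self):
        pos = np.asarray(self.positions, dtype=float)
        thick = np.asarray(self.thickness, dtype=float)
        if pos.shape != thick.shape or pos.ndim != 1 or len(pos) == 0:
            raise ValueError("positions and thickness must be matching 1D arrays")
        if np.any(np.diff(pos) <= 0):
            raise ValueError("positions must be strictly increasing")
        if np.any(thick <= 0):
            raise ValueError("thickness values must be positive")
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "thickness", thick)

    @property
    def mean_thickness(self) -> float:
        return float(self.thickness.mean())

    @property
    def normalized(self) -> np.ndarray:
        return self.thickness / self.mean_thickness


@dataclass(frozen=True)
class ExpansionSeries:
    """EGL length and core area across developmental stages for one region."""

    stages: np.ndarray
    egl_length: np.ndarray
    core_area: np.ndarray
    region: str = "whole"

    def __post_init__(self):
        stages = np.asarray(self.stages, dtype=float)
        length = np.asarray(self.egl_length, dtype=float)
        area = np.asarray(self.core_area, dtype=float)
        if not (stages.shape == length.shape == area.shape):
            raise ValueError("stages, egl_length and core_area must align")
        if np.any(np.diff(stages) <= 0):
            raise ValueError("stages must be strictly increasing")
        if np.any(length <= 0) or np.any(area <= 0):
            raise ValueError("lengths and areas must be strictly positive")
        object.__setattr__(self, "stages", stages)
        object.__setattr__(self, "egl_length", length)
        object.__setattr__(self, "core_area", area)


# ---------------------------------------------------------------------------
# Basic contour metrics


def enclosed_area(contour: Contour) -> float:
    """Shoelace area (um^2) of a closed contour; error on open contours."""
    if not contour.closed:
        raise ContourError("area is only defined for closed contours")
    x, y = contour.points[:, 0], contour.points[:, 1]
    return float(0.5 * np.abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))))


def contour_metrics(contour: Contour, smoothing_scale: float = 0.0) -> ContourMetrics:
    """Arc length, enclosed area (closed only) and signed curvature.

    ``smoothing_scale`` (um) is the std of an arc-length Gaussian applied
    before measuring; 0 measures the raw polyline.
    """
    if smoothing_scale < 0:
        raise ValueError("smoothing_scale must be >= 0")
    work = contour.smoothed(smoothing_scale) if smoothing_scale > 0 else contour
    area = enclosed_area(work) if contour.closed else None
    return ContourMetrics(
        length=work.arc_length, area=area, curvature=work.signed_curvature()
    )


def folding_index(
    outer: Contour,
    smoothing_scale: float = 10.0,
    curvature_tolerance: float = 1e-4,
) -> float:
    """Folding index in percent: ``100 * (1 - convex length / total length)``.

    Convex length is the arc length of segments whose signed curvature is
    >= -curvature_tolerance after Gaussian smoothing over arc length
    (default scale 10 um, tolerance 1e-4 1/um).  0 for any convex contour.
    """
    work = outer.smoothed(smoothing_scale) if smoothing_scale > 0 else outer
    total = work.arc_length
    if total <= 0:
        raise ContourError("contour has zero length")
    kappa = work.signed_curvature()
    seg = work.segment_lengths
    if work.closed:
        # segment i joins vertex i to i+1; use mean of endpoint curvatures
        kseg = 0.5 * (kappa + np.roll(kappa, -1))
    else:
        kseg = 0.5 * (kappa[:-1] + kappa[1:])
    convex = float(seg[kseg >= -curvature_tolerance].sum())
    return float(np.clip(100.0 * (1.0 - convex / total), 0.0, 100.0))


# ---------------------------------------------------------------------------
# Thickness


def thickness_profile(
    inner: Contour,
    outer: Contour,
    spacing: float = 12.5,
) -> ThicknessProfile:
    """EGL thickness every ``spacing`` um of arc length along the inner boundary.

    Thickness is the shortest Euclidean distance from each inner sample point
    to the outer boundary polyline.  For an open outer boundary, samples whose
    nearest point falls on an endpoint of the outer arc are dropped and logged
    (the shortest-distance foot leaves the measured arc).
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    inner_len = inner.arc_length
    if spacing > inner_len:
        raise ContourError("spacing exceeds inner contour length")
    outer_ls = outer.as_linestring()
    if inner.as_linestring().intersects(outer_ls):
        raise ContourError("inner and outer contours intersect")

    positions = np.arange(0.0, inner_len, spacing)
    samples = inner.point_at(positions)
    keep_pos, thick = [], []
    n_dropped = 0
    end_tol = 1e-6 * max(outer_ls.length, 1.0)
    for s, p in zip(positions, samples):
        pt = Point(p)
        d = outer_ls.distance(pt)
        if not outer.closed:
            foot = outer_ls.project(pt)
            if foot <= end_tol or foot >= outer_ls.length - end_tol:
                n_dropped += 1
                continue
        keep_pos.append(s)
        thick.append(d)
    if n_dropped:
        log.info("thickness_profile: dropped %d boundary samples", n_dropped)
    if not keep_pos:
        raise ContourError("no valid thickness samples (all feet off the outer arc)")
    return ThicknessProfile(np.asarray(keep_pos), np.asarray(thick), spacing)


def ac_thickness_ratio(
    profile: ThicknessProfile,
    ac_position: float,
    ac_halfwidth: float = 25.0,
    flank_extent: float = 250.0,
) -> float:
    """Mean thickness in the AC window over mean thickness of the flanks.

    The AC window is ``ac_position +/- ac_halfwidth``; the flanks extend to
    ``+/- flank_extent`` excluding the AC window.  Values above 1 mean the
    EGL is thicker at the anchoring center than in the surrounding EGL.
    """
    pos = profile.positions
    if not (pos[0] <= ac_position <= pos[-1]):
        raise ValueError("ac_position outside profile range")
    dist = np.abs(pos - ac_position)
    in_ac = dist <= ac_halfwidth
    in_flank = (dist > ac_halfwidth) & (dist <= flank_extent)
    if not np.any(in_ac):
        raise ValueError("AC window contains no samples")
    if not np.any(in_flank):
        raise ValueError("flank region contains no samples")
    return float(profile.thickness[in_ac].mean() / profile.thickness[in_flank].mean())


# ---------------------------------------------------------------------------
# Shape factor and expansion references


def shape_factor(outer_half: Contour, core_half_area: float) -> float:
    """Half perimeter divided by sqrt(half area); sqrt(2*pi) for a semicircle.

    ``outer_half`` is the outer surface arc over the half domain; its arc
    length is the half perimeter.  ``core_half_area`` is the area enclosed by
    that arc and the closing base segment.
    """
    if core_half_area <= 0:
        raise ValueError("core_half_area must be positive")
    return float(outer_half.arc_length / math.sqrt(core_half_area))


def reference_expansion(
    area: float,
    mode: str = "semicircle",
    column_width: float | None = None,
    column_convention: str = "three_sides",
) -> float:
    """Predicted EGL length for a core of the given area under a reference shape.

    ``semicircle``: a semicircle of area A has exposed (curved) perimeter
    L = sqrt(2*pi*A); proportional expansion keeps (L, A) on this curve.

    ``column``: a fixed-width rectangle of area A.  Under the default
    ``three_sides`` convention the exposed perimeter is the two sides plus the
    distal end, L = 2*A/w + w; ``distal_only`` returns the constant w.
    """
    if area <= 0:
        raise ValueError("area must be positive")
    if mode == "semicircle":
        return math.sqrt(2.0 * math.pi * area)
    if mode == "column":
        if column_width is None or column_width <= 0:
            raise ValueError("column mode requires a positive column_width")
        if column_convention == "three_sides":
            return 2.0 * area / column_width + column_width
        if column_convention == "distal_only":
            return float(column_width)
        raise ValueError(f"unknown column convention {column_convention!r}")
    raise ValueError(f"unknown reference mode {mode!r}")


def expansion_deviation(
    series: ExpansionSeries,
    mode: str = "semicircle",
    column_width: float | None = None,
) -> np.ndarray:
    """Relative deviation of measured EGL length from the reference curve.

    Positive values mean the EGL has grown longer than proportional expansion
    of the core allows, i.e. differential expansion.
    """
    ref = np.array(
        [reference_expansion(a, mode=mode, column_width=column_width) for a in series.core_area]
    )
    return (series.egl_length - ref) / ref


# ---------------------------------------------------------------------------
# 3D sphericity and acoustics


def sphericity(mask: np.ndarray, voxel_size: float = 1.0) -> float:
    """Sphericity of a voxelised body: surface area of the equal-volume sphere
    divided by the body's surface area (1 for a sphere, < 1 otherwise).

    The volume is the voxel count times voxel volume; the surface area comes
    from a marching-cubes triangulation of the isosurface of the lightly
    smoothed mask (smoothing removes the voxel staircase, which would
    otherwise inflate the area by ~8% regardless of resolution).
    """
    from scipy.ndimage import gaussian_filter
    from skimage.measure import marching_cubes, mesh_surface_area

    mask = np.asarray(mask).astype(bool)
    if mask.ndim != 3:
        raise ValueError("mask must be a 3D array")
    if not mask.any():
        raise ValueError("mask is empty")
    _, n_comp = _cc_label(mask)
    if n_comp != 1:
        raise ValueError(f"mask must be a single connected component, found {n_comp}")
    volume = mask.sum() * voxel_size**3
    padded = np.pad(mask, 3).astype(float)
    smoothed = gaussian_filter(padded, sigma=1.5)
    verts, faces, _, _ = marching_cubes(smoothed, level=0.5, spacing=(voxel_size,) * 3)
    area = mesh_surface_area(verts, faces)
    return float(math.pi ** (1.0 / 3.0) * (6.0 * volume) ** (2.0 / 3.0) / area)


def bulk_modulus_from_acoustics(impedance_mrayl: float, speed_of_sound_mps: float) -> float:
    """Bulk modulus (GPa) as the product of acoustic impedance and sound speed.

    K = Z * c with Z in MRayl (1e6 Pa s/m) and c in m/s gives K in units of
    1e6 * Z * c Pa; returned in GPa.
    """
    if impedance_mrayl <= 0 or speed_of_sound_mps <= 0:
        raise ValueError("impedance and speed of sound must be positive")
    return impedance_mrayl * speed_of_sound_mps * 1e-3
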