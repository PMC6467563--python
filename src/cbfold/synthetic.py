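"""Ground-truth-carrying generators of synthetic data.

Every generator is a pure function of its parameters and a seed, returns a
:class:`GroundTruth` record alongside the data, and writes/reads the same
file dialects the measurement modules consume.  The generators emulate the
statistical structure the analysis assumes -- model-shaped section
boundaries, Bernoulli-labelled cells in the EGL band, fiber images with
known crossing counts, voxelised cells of known sphericity, expansion
series on known reference curves -- not photorealistic histology.

Default study conditions (chosen once; see docs/methods.md): r0 = 480 um at
E16.5 (so t0 = 30 um via r0/t0 = 16), EGL cell density 12 cells / 1000 um^2,
EdU rate 0.35, P27 rate 0.2, fiber width 1.5 um, SNR 5, pixel size 0.4 um.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.special import ellipeinc, ellipkinc
from shapely.geometry import Point

from cbfold.cellquant import CellRecord, FiberImage
from cbfold.contour import Contour, ContourError, SectionGeometry
from cbfold.model import (
    annulus_params,
    model_shape,
    params_from_epsilon,
    shape_to_section,
    EPSILON_ONSET_DAY,
    EPSILON_RATE_PER_DAY,
)
from cbfold.morphometrics import ExpansionSeries, reference_expansion

DEFAULT_R0_UM = 480.0


@dataclass(frozen=True)
class GroundTruth:
    """Machine-readable provenance of a generated dataset: the generator
    name, seed and parameters, and the derived true values the measurement
    pipeline is expected to recover."""

    generator: str
    seed: int
    params: dict
    derived: dict = field(default_factory=dict)

    def to_json(self) -> str:
        def default(o):
            if isinstance(o, np.ndarray):
                return o.tolist()
            if isinstance(o, (np.floating, np.integer)):
                return o.item()
            raise TypeError(type(o))

        return json.dumps(dataclasses.asdict(self), indent=1, default=default)

    def save(self, path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def load(cls, path) -> "GroundTruth":
        return cls(**json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# Sections


def gen_section(
    epsilon: float,
    r0: float = DEFAULT_R0_UM,
    n_points: int = 1441,
    boundary_noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[SectionGeometry, GroundTruth]:
    """Half-domain section with boundaries from the multi-phase model.

    eps = 0 gives a clean semicircular annulus (t0/r0 = 1/16); eps > 0 uses
    the calibrated parameter mapping with phi = -pi/2 so an AC sits at the
    top of the section.  ``boundary_noise_sd`` adds independent radial
    Gaussian jitter (um) to both boundaries; noisy draws that make the
    boundaries cross are regenerated (up to 3 attempts).
    """
    if not 0.0 <= epsilon < 1.0:
        raise ValueError("epsilon must be in [0, 1)")
    params = (
        annulus_params(r0=r0)
        if epsilon == 0.0
        else params_from_epsilon(epsilon, r0=r0, phi=-math.pi / 2.0)
    )
    shape = model_shape(params, n_theta=n_points, domain="half")
    rng = np.random.default_rng(seed)
    last_err = None
    for _ in range(3):
        theta = shape.theta
        r = shape.r + (rng.normal(0.0, boundary_noise_sd, len(theta)) if boundary_noise_sd else 0.0)
        rho = shape.inner + (
            rng.normal(0.0, boundary_noise_sd, len(theta)) if boundary_noise_sd else 0.0
        )
        try:
            if np.any(rho >= r):
                raise ContourError("boundary noise made the EGL boundaries cross")
            outer = Contour(np.column_stack([r * np.cos(theta), r * np.sin(theta)]))
            inner = Contour(np.column_stack([rho * np.cos(theta), rho * np.sin(theta)]))
            if outer.as_linestring().intersects(inner.as_linestring()):
                raise ContourError("boundary noise made the EGL boundaries intersect")
        except ContourError as err:
            last_err = err
            continue
        clean = shape_to_section(shape)
        section = SectionGeometry(
            outer_egl=outer,
            inner_egl=inner,
            base=np.array([inner.points[-1], inner.points[0]]),
            ac_positions=clean.ac_positions,
            stage=EPSILON_ONSET_DAY + epsilon / EPSILON_RATE_PER_DAY,
        )
        gt = GroundTruth(
            generator="gen_section",
            seed=seed,
            params={
                "epsilon": epsilon,
                "r0": r0,
                "n_points": n_points,
                "boundary_noise_sd": boundary_noise_sd,
            },
            derived={
                "t0": params.t0,
                "at": params.at,
                "at_over_t0": (params.at / params.t0) if params.t0 else 0.0,
                "c3": shape.c3,
                "fold_count": int(params.q // 2) if params.at > 0 else 0,
                "ac_positions_inner": clean.ac_positions,
                "ac_theta": (
                    np.pi * (2 * np.arange(int(params.q // 2)) + 1) / params.q
                    if params.at > 0
                    else np.empty(0)
                ),
                "stage": EPSILON_ONSET_DAY + epsilon / EPSILON_RATE_PER_DAY,
            },
        )
        return section, gt
    raise ContourError(f"could not generate non-crossing boundaries after 3 attempts: {last_err}")


def ac_positions_outer(section: SectionGeometry, gt: GroundTruth) -> np.ndarray:
    """Arc-length positions of the ACs along the *outer* EGL contour (the
    frame AC measuring windows are defined in)."""
    theta = np.asarray(gt.derived.get("ac_theta", []), dtype=float)
    if len(theta) == 0:
        return np.empty(0)
    outer = section.outer_egl
    pts = outer.points
    ang = np.arctan2(pts[:, 1], pts[:, 0])
    s = outer.arclength_coords
    return np.interp(theta, ang, s)


# ---------------------------------------------------------------------------
# Cells


def gen_cells(
    geometry: SectionGeometry,
    density: float = 12.0,
    edu_rate=0.35,
    p27_rate: float = 0.2,
    seed: int = 0,
) -> tuple[list[CellRecord], GroundTruth]:
    """Poisson-uniform cells in the EGL band with Bernoulli marker labels.

    ``density`` is cells per 1000 um^2.  All cells are DAPI+; P27 is drawn
    Bernoulli(p27_rate); EdU is drawn Bernoulli(edu_rate) among P27- cells
    only (S-phase cells have degraded P27).  ``edu_rate`` may be a scalar or
    a dict mapping region labels to rates.  Region labels are the AC-
    delimited compartments R0..Rk along the inner boundary.
    """
    band = geometry.egl_band_polygon()
    area = band.area
    if area <= 0:
        raise ValueError("EGL band has zero area")
    rng = np.random.default_rng(seed)
    n = int(rng.poisson(density * area / 1000.0))
    minx, miny, maxx, maxy = band.bounds
    xs, ys = [], []
    while len(xs) < n:
        cand = rng.uniform((minx, miny), (maxx, maxy), size=(max(64, 2 * (n - len(xs))), 2))
        for x, y in cand:
            if band.covers(Point(x, y)):
                xs.append(x)
                ys.append(y)
                if len(xs) == n:
                    break

    # region = AC-delimited compartment of the projection onto the inner contour
    inner = geometry.inner_egl
    bounds = np.asarray(geometry.ac_positions, dtype=float)
    inner_pts = inner.points
    inner_s = inner.arclength_coords

    def region_of(x, y):
        d2 = (inner_pts[:, 0] - x) ** 2 + (inner_pts[:, 1] - y) ** 2
        s = inner_s[int(np.argmin(d2))]
        return f"R{int(np.searchsorted(bounds, s))}"

    cells = []
    rates = edu_rate if isinstance(edu_rate, dict) else None
    for x, y in zip(xs, ys):
        region = region_of(x, y)
        p27 = bool(rng.random() < p27_rate)
        rate = rates.get(region, 0.0) if rates is not None else edu_rate
        edu = bool((not p27) and rng.random() < rate)
        cells.append(CellRecord(x=x, y=y, dapi=True, edu=edu, p27=p27, region=region))
    gt = GroundTruth(
        generator="gen_cells",
        seed=seed,
        params={
            "density": density,
            "edu_rate": edu_rate,
            "p27_rate": p27_rate,
            "band_area": area,
        },
        derived={
            "n_cells": len(cells),
            "n_p27": sum(c.p27 for c in cells),
            "n_edu": sum(c.edu for c in cells),
            "regions": sorted({c.region for c in cells}),
        },
    )
    return cells, gt


# ---------------------------------------------------------------------------
# Fiber images


def gen_fiber_image(
    geometry: SectionGeometry,
    fibers_per_bin,
    fiber_width: float = 1.5,
    snr: float = 5.0,
    pixel_size: float = 0.4,
    seed: int = 0,
    bin_width: float = 50.0,
    ac_index: int = 0,
    depth: float = 80.0,
    background: float = 0.2,
) -> tuple[FiberImage, GroundTruth]:
    """Render a patch of the outer EGL around an AC with known fiber crossings.

    The section is rotated so the chosen AC's outward normal points up, and a
    patch spanning ``len(fibers_per_bin)`` bins of ``bin_width`` um along the
    outer surface is rasterised with the outer edge near the top of the image
    and the tissue below.  Each bin receives the requested number of roughly
    radial fibers (Gaussian cross-profile of the stated width, reaching
    ``depth`` um beneath the surface) over Gaussian background noise with
    SNR = peak fiber amplitude / noise standard deviation.
    """
    fibers_per_bin = np.asarray(fibers_per_bin, dtype=int)
    if fibers_per_bin.ndim != 1 or len(fibers_per_bin) == 0 or np.any(fibers_per_bin < 0):
        raise ValueError("fibers_per_bin must be a 1D array of non-negative counts")
    if snr <= 0:
        raise ValueError("snr must be positive")
    rng = np.random.default_rng(seed)
    outer = geometry.outer_egl

    # AC arc position along the outer contour, via the AC's angular position
    pts = outer.points
    ang = np.arctan2(pts[:, 1], pts[:, 0])
    s_coords = outer.arclength_coords
    if len(geometry.ac_positions) > 0:
        # project the inner-contour AC onto the outer contour by angle
        inner = geometry.inner_egl
        p_ac = inner.point_at(geometry.ac_positions[min(ac_index, len(geometry.ac_positions) - 1)])[0]
        theta_ac = math.atan2(p_ac[1], p_ac[0])
    else:
        theta_ac = math.pi / 2.0
    s_ac = float(np.interp(theta_ac, ang, s_coords))

    n_bins = len(fibers_per_bin)
    span = n_bins * bin_width
    s_lo = s_ac - span / 2.0
    if s_lo < 0 or s_ac + span / 2.0 > outer.arc_length:
        raise ValueError("requested bins extend beyond the outer contour")

    # local frame: u along the arc, v depth beneath the surface
    margin = 8.0
    s_grid = np.arange(s_lo - margin, s_lo + span + margin, pixel_size / 2.0)
    arc_pts = outer.point_at(s_grid)
    normals_all = outer.normals_inward()
    nx = np.interp(s_grid, s_coords, normals_all[:, 0])
    ny = np.interp(s_grid, s_coords, normals_all[:, 1])
    nrm = np.hypot(nx, ny)
    normals = np.column_stack([nx / nrm, ny / nrm])

    # rotate so the AC outward normal points to -y (surface up, tissue down),
    # then shift into a positive image frame
    i_ac = int(np.argmin(np.abs(s_grid - s_ac)))
    n_ac = normals[i_ac]
    rot_angle = math.atan2(n_ac[0], n_ac[1])  # send inward normal to +y
    c, sn = math.cos(rot_angle), math.sin(rot_angle)
    R = np.array([[c, -sn], [sn, c]])

    def to_frame(p):
        return p @ R.T

    arc_f = to_frame(arc_pts)
    normals_f = to_frame(normals)

    # fibers: per bin, uniform arc positions, along the local inward normal
    fiber_segments = []
    true_positions = []
    for j, count in enumerate(fibers_per_bin):
        lo = s_lo + j * bin_width
        if count == 0:
            continue
        # stratified placement with jitter: fibers are roughly evenly spaced
        # in tissue, and bin-edge margins keep crossings unambiguous
        pitch = (bin_width - 8.0) / count
        pos = lo + 4.0 + pitch * (np.arange(count) + 0.5 + rng.uniform(-0.2, 0.2, count))
        for s_f in np.sort(pos):
            i = int(np.argmin(np.abs(s_grid - s_f)))
            p0 = arc_f[i] - 3.0 * normals_f[i]
            tilt = math.radians(rng.uniform(-3.0, 3.0))
            ct, st = math.cos(tilt), math.sin(tilt)
            d = normals_f[i]
            d = np.array([d[0] * ct - d[1] * st, d[0] * st + d[1] * ct])
            p1 = arc_f[i] + (depth + 3.0) * d
            fiber_segments.append((p0, p1))
            true_positions.append(s_f - s_lo)

    all_pts = np.vstack([arc_f, arc_f + depth * normals_f])
    pad = 6.0
    origin = all_pts.min(axis=0) - pad
    extent = all_pts.max(axis=0) - origin + pad
    width_px = int(math.ceil(extent[0] / pixel_size))
    height_px = int(math.ceil(extent[1] / pixel_size))

    img = np.zeros((height_px, width_px))
    yy, xx = np.mgrid[0:height_px, 0:width_px]
    px = xx * pixel_size + origin[0]
    py = yy * pixel_size + origin[1]
    for p0, p1 in fiber_segments:
        d = p1 - p0
        L2 = float(d @ d)
        tproj = ((px - p0[0]) * d[0] + (py - p0[1]) * d[1]) / L2
        tproj = np.clip(tproj, 0.0, 1.0)
        cx = p0[0] + tproj * d[0]
        cy = p0[1] + tproj * d[1]
        dist2 = (px - cx) ** 2 + (py - cy) ** 2
        img += np.exp(-dist2 / (2.0 * fiber_width**2))

    peak = 1.0  # Gaussian profile peak amplitude per fiber
    noise_sd = peak / snr
    img = background + img + rng.normal(0.0, noise_sd, img.shape)

    edge_um = arc_f - origin
    edge = Contour(edge_um[:: max(1, len(edge_um) // 400)])
    image = FiberImage(
        intensity=img,
        pixel_size=pixel_size,
        egl_outer_edge=edge,
        meta={"origin_um": origin.tolist(), "s_lo": s_lo},
    )
    # AC arc position within the patch, measured along the edge from its start
    ac_in_patch = s_ac - (s_lo - margin)
    gt = GroundTruth(
        generator="gen_fiber_image",
        seed=seed,
        params={
            "fibers_per_bin": fibers_per_bin,
            "fiber_width": fiber_width,
            "snr": snr,
            "pixel_size": pixel_size,
            "bin_width": bin_width,
            "depth": depth,
        },
        derived={
            "ac_position": ac_in_patch,
            "bin_start": margin,
            "crossing_positions": np.asarray(true_positions) + margin,
            "n_fibers": int(fibers_per_bin.sum()),
        },
    )
    return image, gt


# ---------------------------------------------------------------------------
# Voxel masks


def ellipsoid_surface_area(a: float, b: float, c: float) -> float:
    """Exact surface area of an ellipsoid with semi-axes a >= b >= c (any
    input order accepted), via Legendre elliptic integrals; closed forms for
    the sphere and spheroid limits."""
    a, b, c = sorted((float(a), float(b), float(c)), reverse=True)
    if a <= 0:
        raise ValueError("semi-axes must be positive")
    if math.isclose(a, c, rel_tol=1e-12):
        return 4.0 * math.pi * a * a
    if math.isclose(b, c, rel_tol=1e-12):  # prolate
        e = math.sqrt(1.0 - (c / a) ** 2)
        return 2.0 * math.pi * c * c * (1.0 + (a / (c * e)) * math.asin(e))
    if math.isclose(a, b, rel_tol=1e-12):  # oblate
        e = math.sqrt(1.0 - (c / a) ** 2)
        return 2.0 * math.pi * a * a * (1.0 + ((1.0 - e * e) / e) * math.atanh(e))
    phi = math.acos(c / a)
    k2 = (a * a * (b * b - c * c)) / (b * b * (a * a - c * c))
    F = ellipkinc(phi, k2)
    E = ellipeinc(phi, k2)
    sin_phi = math.sin(phi)
    return 2.0 * math.pi * c * c + (2.0 * math.pi * a * b / sin_phi) * (
        E * sin_phi**2 + F * math.cos(phi) ** 2
    )


def analytic_sphericity(a: float, b: float, c: float) -> float:
    volume = 4.0 / 3.0 * math.pi * a * b * c
    area = ellipsoid_surface_area(a, b, c)
    return math.pi ** (1.0 / 3.0) * (6.0 * volume) ** (2.0 / 3.0) / area


def gen_ellipsoid_mask(
    semi_axes, voxel_size: float = 1.0, seed: int = 0
) -> tuple[np.ndarray, GroundTruth]:
    """Boolean voxel mask of an ellipsoid with its analytic sphericity as
    ground truth.  Semi-axes are in um; each must exceed 2 voxels."""
    axes = np.asarray(semi_axes, dtype=float)
    if axes.shape != (3,) or np.any(axes <= 0):
        raise ValueError("semi_axes must be three positive lengths")
    if np.any(axes < 2.0 * voxel_size):
        raise ValueError("semi-axes must exceed 2 voxels for a resolvable mask")
    half = np.ceil(axes / voxel_size).astype(int) + 2
    grids = np.meshgrid(
        *[(np.arange(-h, h + 1)) * voxel_size for h in half], indexing="ij"
    )
    mask = sum((g / ax) ** 2 for g, ax in zip(grids, axes)) <= 1.0
    gt = GroundTruth(
        generator="gen_ellipsoid_mask",
        seed=seed,
        params={"semi_axes": axes, "voxel_size": voxel_size},
        derived={
            "sphericity": analytic_sphericity(*axes),
            "volume": 4.0 / 3.0 * math.pi * float(np.prod(axes)),
            "surface_area": ellipsoid_surface_area(*axes),
        },
    )
    return mask, gt


# ---------------------------------------------------------------------------
# Expansion series


def gen_expansion_series(
    mode: str = "semicircle",
    stages=(16.5, 17.5, 18.5, 19.5),
    seed: int = 0,
    area0: float = 2.2e5,
    growth_per_day: float = 1.6,
    switch_stage: float | None = None,
    inflation_per_day: float = 0.15,
    column_width: float | None = 300.0,
    region: str = "whole",
) -> tuple[ExpansionSeries, GroundTruth]:
    """EGL-length / core-area series on a known reference curve.

    ``semicircle``: (L, A) exactly on L = sqrt(2 pi A); ``column``: on the
    fixed-width columnar reference; ``differential``: on the semicircle curve
    until ``switch_stage``, after which L inflates by ``inflation_per_day``
    per day beyond the curve (differential expansion).  Areas grow
    geometrically by ``growth_per_day`` per embryonic day from ``area0``.
    """
    stages = np.asarray(stages, dtype=float)
    if len(stages) < 2:
        raise ValueError("need at least 2 stages")
    if mode not in ("semicircle", "column", "differential"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "differential" and switch_stage is None:
        switch_stage = float(stages[len(stages) // 2])
    areas = area0 * growth_per_day ** (stages - stages[0])
    ref_mode = "column" if mode == "column" else "semicircle"
    lengths = np.array(
        [reference_expansion(a, mode=ref_mode, column_width=column_width) for a in areas]
    )
    if mode == "differential":
        excess = np.clip(stages - switch_stage, 0.0, None) * inflation_per_day
        lengths = lengths * (1.0 + excess)
    series = ExpansionSeries(stages=stages, egl_length=lengths, core_area=areas, region=region)
    gt = GroundTruth(
        generator="gen_expansion_series",
        seed=seed,
        params={
            "mode": mode,
            "stages": stages,
            "area0": area0,
            "growth_per_day": growth_per_day,
            "switch_stage": switch_stage,
            "inflation_per_day": inflation_per_day,
            "column_width": column_width,
        },
        derived={
            "deviation": (
                np.clip(stages - switch_stage, 0.0, None) * inflation_per_day
                if mode == "differential"
                else np.zeros_like(stages)
            )
        },
    )
    return series, gt
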