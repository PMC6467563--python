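"""Cell- and fiber-level quantification in the EGL.

Three measurement families defined over a section's outer EGL boundary:

* AC-centered measuring windows: 50 um wide regions along the outer surface,
  extending a fixed depth inward, placed every 25 um up to +/-250 um around
  an anchoring center.
* S-phase proliferation index: EdU+ / (DAPI+; P27-) among the cells falling
  inside a window polygon.
* Fiber density: a 4th/5th order polynomial is fitted to the outer edge of a
  fluorescence image, five scan lines are offset at 12.2 um intervals beneath
  and parallel to it, intensity peaks are counted with minimum/maximum
  filters under fixed parameters, and counts are binned per 50 um of arc
  measured along the fitted contour.
"""

from __future__ import annotations

import json
import logging
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter, map_coordinates, maximum_filter1d, minimum_filter1d
from shapely.geometry import Point, Polygon

from cbfold.contour import Contour, ContourError

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class CellRecord:
    """One counted cell: position (um) and marker status."""

    x: float
    y: float
    dapi: bool = True
    edu: bool = False
    p27: bool = False
    region: str = ""

    def __post_init__(self):
        if self.edu and not self.dapi:
            raise ValueError("EdU+ implies DAPI+")
        if self.p27 and not self.dapi:
            raise ValueError("P27+ implies DAPI+")


def cells_to_dataframe(cells) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "x_um": [c.x for c in cells],
            "y_um": [c.y for c in cells],
            "dapi": [c.dapi for c in cells],
            "edu": [c.edu for c in cells],
            "p27": [c.p27 for c in cells],
            "region": [c.region for c in cells],
        }
    )


def cells_from_dataframe(df: pd.DataFrame) -> list[CellRecord]:
    return [
        CellRecord(
            x=row.x_um, y=row.y_um, dapi=bool(row.dapi), edu=bool(row.edu),
            p27=bool(row.p27), region=getattr(row, "region", "") or "",
        )
        for row in df.itertuples()
    ]


def write_cells_csv(path, cells) -> None:
    cells_to_dataframe(cells).to_csv(path, index=False)


def read_cells_csv(path) -> list[CellRecord]:
    return cells_from_dataframe(pd.read_csv(path, keep_default_na=False))


@dataclass(frozen=True)
class RegionWindow:
    """A measuring window along the outer EGL surface.

    ``center`` is the arc-length coordinate (um) of the window midpoint along
    the contour it was built on; the polygon extends from the outer surface
    a fixed depth inward.
    """

    center: float
    width: float
    polygon: Polygon
    truncated: bool = False

    def __post_init__(self):
        if self.width <= 0:
            raise ValueError("window width must be positive")
        if self.polygon.is_empty or self.polygon.area <= 0:
            raise ValueError("window polygon is degenerate")


def _band_polygon(contour: Contour, lo: float, hi: float, depth: float, step: float = 1.0) -> Polygon:
    """Polygon between arc lengths [lo, hi] on the contour and its inward
    offset at the given depth."""
    s = np.linspace(lo, hi, max(int(round((hi - lo) / step)) + 1, 4))
    pts = contour.point_at(s)
    # normals interpolated from the contour's vertex normals
    coords = contour.arclength_coords
    normals = contour.normals_inward()
    nx = np.interp(s, coords, normals[:, 0])
    ny = np.interp(s, coords, normals[:, 1])
    nrm = np.hypot(nx, ny)
    inner = pts + depth * np.column_stack([nx / nrm, ny / nrm])
    poly = Polygon(np.vstack([pts, inner[::-1]]))
    if not poly.is_valid:
        poly = poly.buffer(0)
    return poly


def ac_windows(
    contour: Contour,
    ac_position: float,
    window: float = 50.0,
    step: float = 25.0,
    extent: float = 250.0,
    depth: float = 50.0,
) -> list[RegionWindow]:
    """Measuring windows centered at the AC and every ``step`` um out to
    ``+/- extent``, each ``window`` um wide along the arc and ``depth`` um
    deep from the outer surface inward (21 windows at the defaults).

    Windows extending past the ends of an open contour are truncated and
    flagged.  The contour must be oriented with the tissue to the left of
    the direction of travel (counterclockwise parent section).
    """
    if window <= 0 or step <= 0 or extent < 0 or depth <= 0:
        raise ValueError("window, step and depth must be positive; extent >= 0")
    if extent > 0 and not math.isclose(extent / step, round(extent / step), abs_tol=1e-9):
        raise ValueError("extent must be a whole multiple of step")
    total = contour.arc_length
    if not 0 <= ac_position <= total:
        raise ValueError("ac_position must lie on the contour")
    n_side = int(round(extent / step)) if extent > 0 else 0
    out = []
    for k in range(-n_side, n_side + 1):
        center = ac_position + k * step
        lo, hi = center - window / 2.0, center + window / 2.0
        truncated = False
        if not contour.closed:
            lo_c, hi_c = max(lo, 0.0), min(hi, total)
            if lo_c >= hi_c:
                log.warning("window at %+d*step lies entirely off the contour; skipped", k)
                continue
            truncated = (lo_c != lo) or (hi_c != hi)
            lo, hi = lo_c, hi_c
        poly = _band_polygon(contour, lo, hi, depth)
        out.append(RegionWindow(center=center, width=hi - lo, polygon=poly, truncated=truncated))
    return out


def ac_sector_window(section, ac_position: float, halfangle_deg: float = 15.0) -> Polygon:
    """E18.5-style AC region: the angular sector of the section proximal to
    the centroid under the AC midpoint.  Experimental: the sector construction
    is one reading of a 2D definition that is not fully constrained.
    """
    centroid = np.asarray(section.cerebellar_polygon().centroid.coords[0])
    apex = section.inner_egl.point_at(ac_position)[0]
    direction = apex - centroid
    angle = math.atan2(direction[1], direction[0])
    radius = 2.0 * max(section.outer_egl.points.max(), 1.0)
    half = math.radians(halfangle_deg)
    arc = np.linspace(angle - half, angle + half, 32)
    wedge = np.vstack(
        [centroid, centroid + radius * np.column_stack([np.cos(arc), np.sin(arc)])]
    )
    return Polygon(wedge).intersection(section.cerebellar_polygon())


def cells_in_window(cells, window: RegionWindow) -> list[CellRecord]:
    poly = window.polygon
    return [c for c in cells if poly.covers(Point(c.x, c.y))]


def proliferation_rate(cells, window: RegionWindow) -> float:
    """EdU+ / (DAPI+; P27-) among cells inside the window polygon.

    Returns NaN (missing, not zero) when the denominator is empty.
    """
    inside = cells_in_window(cells, window)
    denom = [c for c in inside if c.dapi and not c.p27]
    if not denom:
        return float("nan")
    num = sum(1 for c in denom if c.edu)
    return num / len(denom)


def proliferation_by_windows(cells, windows) -> pd.DataFrame:
    """Per-window proliferation table.  Cells exactly on a shared boundary
    are credited to the window whose center is nearest (ties broken toward
    the anterior, i.e. smaller arc-length center)."""
    boundary_tol = 1e-9
    rows = []
    for w in sorted(windows, key=lambda w: w.center):
        inside = []
        for c in cells:
            pt = Point(c.x, c.y)
            if not w.polygon.covers(pt):
                continue
            if w.polygon.boundary.distance(pt) < boundary_tol:
                # boundary cell: nearest-center rule, anterior tie-break
                if _nearest_center_window(windows, pt) is not w:
                    continue
            inside.append(c)
        denom = [c for c in inside if c.dapi and not c.p27]
        num = sum(1 for c in denom if c.edu)
        rows.append(
            {
                "center_um": w.center,
                "n_cells": len(inside),
                "n_denominator": len(denom),
                "n_edu": num,
                "rate": (num / len(denom)) if denom else float("nan"),
                "truncated": w.truncated,
            }
        )
    return pd.DataFrame(rows)


def _nearest_center_window(windows, pt: Point) -> RegionWindow:
    covering = [w for w in windows if w.polygon.covers(pt)]
    return min(covering, key=lambda w: (pt.distance(w.polygon.centroid), w.center))


# ---------------------------------------------------------------------------
# Fiber-density scan-line pipeline


@dataclass(frozen=True)
class FiberImage:
    """A fiber-stain image with physical scale and the EGL outer edge.

    ``intensity`` is 2D (y, x) or 3D (z, y, x); coordinates are in um with
    x = column * pixel_size, y = row * pixel_size, and the tissue lying at
    larger y (beneath the outer edge).  ``egl_outer_edge`` is a contour in
    the same um frame.
    """

    intensity: np.ndarray
    pixel_size: float
    egl_outer_edge: Contour
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        arr = np.asarray(self.intensity, dtype=float)
        if arr.ndim not in (2, 3):
            raise ValueError("intensity must be 2D or 3D")
        if self.pixel_size <= 0:
            raise ValueError("pixel size must be positive")
        h = arr.shape[-2] * self.pixel_size
        w = arr.shape[-1] * self.pixel_size
        pts = self.egl_outer_edge.points
        if pts[:, 0].min() < -self.pixel_size or pts[:, 0].max() > w + self.pixel_size:
            raise ValueError("EGL edge leaves the image in x")
        if pts[:, 1].min() < -self.pixel_size or pts[:, 1].max() > h + self.pixel_size:
            raise ValueError("EGL edge leaves the image in y")
        object.__setattr__(self, "intensity", arr)

    @property
    def planes(self) -> np.ndarray:
        arr = self.intensity
        return arr[None] if arr.ndim == 2 else arr


def write_fiber_image(path, image: FiberImage) -> None:
    """Write the image as TIFF with a JSON sidecar carrying scale and edge."""
    import tifffile

    path = Path(path)
    tifffile.imwrite(path, image.intensity.astype(np.float32))
    sidecar = {
        "pixel_size_um": image.pixel_size,
        "egl_outer_edge": image.egl_outer_edge.points.tolist(),
        "meta": image.meta,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar))


def read_fiber_image(path) -> FiberImage:
    import tifffile

    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    return FiberImage(
        intensity=tifffile.imread(path),
        pixel_size=float(sidecar["pixel_size_um"]),
        egl_outer_edge=Contour(np.asarray(sidecar["egl_outer_edge"])),
        meta=sidecar.get("meta", {}),
    )


def _count_peaks_1d(
    values: np.ndarray,
    neighborhood: int,
    threshold: float,
    noise_floor: float = -np.inf,
) -> np.ndarray:
    """Indices of peaks found with minimum/maximum filters.

    A sample is a peak if it equals the maximum over ``neighborhood`` samples,
    exceeds the local background (minimum filter over a 4x wider support, so
    a smooth peak does not shadow its own prominence) by ``threshold`` times
    the line's dynamic range, and clears ``noise_floor`` (an absolute bound
    on noise-only intensity excursions, so a fiber-free noisy line yields no
    peaks).  Adjacent detections within one neighborhood are merged.
    """
    vmax = maximum_filter1d(values, size=neighborhood, mode="nearest")
    vmin = minimum_filter1d(values, size=4 * neighborhood + 1, mode="nearest")
    rng = values.max() - values.min()
    if rng <= 1e-9 * max(np.abs(values).max(), 1.0):  # flat line
        return np.empty(0, dtype=int)
    is_peak = (values >= vmax) & (values > vmin + threshold * rng) & (values > noise_floor)
    idx = np.where(is_peak)[0]
    if len(idx) < 2:
        return idx
    keep = [idx[0]]
    for i in idx[1:]:
        if i - keep[-1] >= neighborhood:
            keep.append(i)
    return np.asarray(keep)


def fiber_density_profile(
    image: FiberImage,
    ac_position: float,
    poly_order: int = 4,
    n_scanlines: int = 5,
    scan_spacing: float = 12.2,
    bin_width: float = 50.0,
    smooth_sigma: float = 2.0,
    peak_neighborhood: int = 7,
    peak_threshold: float = 0.2,
    max_fit_residual: float = 5.0,
) -> pd.DataFrame:
    """Mean fiber-crossing counts per 50 um bin around the AC.

    A polynomial of order 4 or 5 is fitted to the outer EGL edge; scan lines
    are offset 1..n_scanlines spacings beneath the fitted surface, parallel
    to it.  Each plane is normalised to its mean intensity and Gaussian
    smoothed; peaks are counted with minimum/maximum filters under constant
    neighborhood/threshold parameters and binned by arc length measured
    along the fitted contour, bins centered at ``ac_position``.  Scan lines
    that exit the image are dropped with a warning.  Returns a DataFrame
    with bin centers (um) and the count mean over scan lines and planes.
    """
    if poly_order not in (4, 5):
        raise ValueError("poly_order must be 4 or 5")
    edge = image.egl_outer_edge.points
    coeffs = np.polyfit(edge[:, 0], edge[:, 1], poly_order)
    fit = np.poly1d(coeffs)
    resid = np.sqrt(np.mean((fit(edge[:, 0]) - edge[:, 1]) ** 2))
    if resid > max_fit_residual:
        raise ContourError(
            f"outer-edge polynomial fit residual {resid:.2f} um exceeds {max_fit_residual} um"
        )

    # parameterise the fitted curve by arc length at ~half-pixel resolution
    x0, x1 = edge[:, 0].min(), edge[:, 0].max()
    xs = np.arange(x0, x1, image.pixel_size / 2.0)
    ys = fit(xs)
    ds = np.hypot(np.diff(xs), np.diff(ys))
    s = np.concatenate([[0.0], np.cumsum(ds)])
    slope = fit.deriv()(xs)
    norm = np.sqrt(1.0 + slope**2)
    # unit normal pointing into the tissue (+y side)
    nx, ny = -slope / norm, 1.0 / norm

    if not (0 <= ac_position <= s[-1]):
        raise ValueError("ac_position outside the fitted contour's arc length")

    n_side = int(math.floor(min(ac_position, s[-1] - ac_position) / bin_width - 0.5)) + 1
    n_side = max(n_side, 0)
    centers = ac_position + bin_width * np.arange(-n_side, n_side + 1)
    edges = np.concatenate([centers - bin_width / 2.0, [centers[-1] + bin_width / 2.0]])

    h, w = image.intensity.shape[-2], image.intensity.shape[-1]
    per_line_counts = []
    for plane in image.planes:
        normed = plane / plane.mean() if plane.mean() > 0 else plane
        smoothed = gaussian_filter(normed, smooth_sigma)
        # absolute noise floor: the smoothed plane's low percentile is the
        # fiber-free background level; the background noise scale comes from
        # the lower side of the raw normalised plane, attenuated by the known
        # smoothing (white-noise variance shrinks by 4 pi sigma^2 under a 2D
        # Gaussian filter).  Peaks must clear background + 6 sigma.
        med_plane = np.median(normed)
        below = med_plane - normed[normed < med_plane]
        sigma_bg = 1.4826 * float(np.median(below)) if below.size else 0.0
        attenuation = 1.0 / math.sqrt(4.0 * math.pi * max(smooth_sigma, 0.5) ** 2)
        noise_floor = float(np.percentile(smoothed, 10.0)) + 6.0 * sigma_bg * attenuation
        for k in range(1, n_scanlines + 1):
            off = k * scan_spacing
            px = xs + off * nx
            py = ys + off * ny
            rows = py / image.pixel_size
            cols = px / image.pixel_size
            tol = 1e-6
            if (
                rows.min() < -tol
                or rows.max() > h - 1 + tol
                or cols.min() < -tol
                or cols.max() > w - 1 + tol
            ):
                warnings.warn(f"scan line at {off:.1f} um depth exits the image; dropped")
                continue
            rows = np.clip(rows, 0, h - 1)
            cols = np.clip(cols, 0, w - 1)
            values = map_coordinates(smoothed, [rows, cols], order=1)
            # neighborhood is specified in pixels; scan samples sit half a
            # pixel apart along the arc
            size = max(3, int(round(peak_neighborhood * 2)))
            peak_idx = _count_peaks_1d(values, size, peak_threshold, noise_floor)
            peak_s = s[peak_idx]
            counts, _ = np.histogram(peak_s, bins=edges)
            per_line_counts.append(counts)
    if not per_line_counts:
        raise ValueError("all scan lines exited the image")
    counts = np.mean(per_line_counts, axis=0)
    return pd.DataFrame(
        {
            "bin_center_um": centers,
            "count_mean": counts,
            "n_lines": len(per_line_counts),
        }
    )
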