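"""Contours and section geometry.

A :class:`Contour` is an ordered polyline of (x, y) points in micrometres,
open (an EGL arc) or closed (a full tissue outline).  Closed contours are
stored without a repeated endpoint and must be simple and counterclockwise,
so that the tissue interior lies to the left of the direction of travel and
convex (outward-bulging) arcs carry positive signed curvature.

A :class:`SectionGeometry` assembles a midsagittal section: the outer and
inner EGL boundaries, the straight base segment that closes the core region
against the ventricular zone, anchoring-center (AC) positions as arc-length
coordinates along the inner boundary, and the embryonic-day stage label.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d
from shapely.geometry import LineString, Polygon


class ContourError(ValueError):
    """Raised for degenerate or inconsistent contour input."""


def _as_points(points) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ContourError(f"expected an (N, 2) point array, got shape {pts.shape}")
    return pts


@dataclass(frozen=True)
class Contour:
    """Ordered 2D polyline in micrometres.

    Parameters
    ----------
    points:
        (N, 2) array of (x, y) coordinates in um.  For closed contours the
        first point is not repeated at the end.
    closed:
        Whether the polyline is a closed loop.
    """

    points: np.ndarray
    closed: bool = False

    def __post_init__(self):
        pts = _as_points(self.points)
        if len(pts) >= 2 and self.closed and np.allclose(pts[0], pts[-1]):
            pts = pts[:-1]
        if len(pts) < 3:
            raise ContourError("a contour needs at least 3 points")
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        if np.any(seg < 1e-12):
            raise ContourError("consecutive duplicate points in contour")
        if self.closed:
            ring = Polygon(pts)
            if not ring.is_valid:
                raise ContourError("closed contour is self-intersecting")
            if ring.area < 1e-12:
                raise ContourError("closed contour is degenerate (zero area)")
            if not ring.exterior.is_ccw:
                raise ContourError(
                    "closed contour must be counterclockwise; use Contour.ccw()"
                )
        object.__setattr__(self, "points", pts)

    @classmethod
    def ccw(cls, points, closed: bool = True) -> "Contour":
        """Build a closed contour, reorienting to counterclockwise if needed."""
        pts = _as_points(points)
        if closed and np.allclose(pts[0], pts[-1]):
            pts = pts[:-1]
        if closed and not Polygon(pts).exterior.is_ccw:
            pts = pts[::-1]
        return cls(pts, closed=closed)

    @property
    def segment_lengths(self) -> np.ndarray:
        pts = self.points
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        if self.closed:
            seg = np.append(seg, np.linalg.norm(pts[0] - pts[-1]))
        return seg

    @property
    def arc_length(self) -> float:
        """Total polyline length in um."""
        return float(self.segment_lengths.sum())

    @property
    def arclength_coords(self) -> np.ndarray:
        """Cumulative arc length at each vertex, starting at 0."""
        return np.concatenate([[0.0], np.cumsum(self.segment_lengths)])[: len(self.points)]

    def point_at(self, s) -> np.ndarray:
        """Linear interpolation of position at arc-length coordinate(s) ``s``."""
        s = np.atleast_1d(np.asarray(s, dtype=float))
        total = self.arc_length
        if self.closed:
            s = np.mod(s, total)
        elif np.any((s < -1e-9) | (s > total + 1e-9)):
            raise ContourError("arc-length coordinate outside contour range")
        coords = self.arclength_coords
        pts = self.points
        if self.closed:
            coords = np.append(coords, total)
            pts = np.vstack([pts, pts[:1]])
        x = np.interp(s, coords, pts[:, 0])
        y = np.interp(s, coords, pts[:, 1])
        return np.column_stack([x, y])

    def resample(self, spacing: float | None = None, n: int | None = None) -> "Contour":
        """Resample to uniform arc-length spacing.

        Exactly one of ``spacing`` (um) or ``n`` (point count) is given.
        Closed contours get ``n`` points over the full loop (endpoint
        excluded); open contours include both endpoints.
        """
        total = self.arc_length
        if (spacing is None) == (n is None):
            raise ValueError("give exactly one of spacing or n")
        if spacing is not None:
            if spacing <= 0 or spacing > total:
                raise ContourError("resample spacing must be in (0, arc length]")
            n = max(int(round(total / spacing)), 3)
        if self.closed:
            s = np.linspace(0.0, total, n, endpoint=False)
        else:
            s = np.linspace(0.0, total, n)
        return Contour(self.point_at(s), closed=self.closed)

    def smoothed(self, scale: float) -> "Contour":
        """Gaussian-smooth coordinates over arc length with std ``scale`` um.

        The contour is first resampled to uniform spacing (keeping the point
        count), then each coordinate is filtered; closed contours wrap.
        """
        if scale < 0:
            raise ValueError("smoothing scale must be >= 0")
        if scale == 0:
            return self
        rs = self.resample(n=len(self.points))
        spacing = rs.arc_length / (len(rs.points) if rs.closed else len(rs.points) - 1)
        sigma = scale / spacing
        mode = "wrap" if self.closed else "nearest"
        pts = np.column_stack(
            [gaussian_filter1d(rs.points[:, i], sigma, mode=mode) for i in (0, 1)]
        )
        try:
            return Contour(pts, closed=self.closed)
        except ContourError as exc:  # heavy smoothing can collapse points
            raise ContourError(f"smoothing at scale {scale} um degenerated contour: {exc}")

    def signed_curvature(self) -> np.ndarray:
        """Signed curvature (1/um) at each vertex.

        Positive for convex (outward-bulging) arcs of a counterclockwise
        contour.  Uses centered finite differences on the polyline; for an
        open contour one-sided differences apply at the endpoints.
        """
        pts = self.points
        if self.closed:
            ext = np.vstack([pts[-2:], pts, pts[:2]])
            s = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(ext, axis=0), axis=1))])
            d1 = np.gradient(ext, s, axis=0)
            d2 = np.gradient(d1, s, axis=0)
            d1, d2 = d1[2:-2], d2[2:-2]
        else:
            s = self.arclength_coords
            d1 = np.gradient(pts, s, axis=0)
            d2 = np.gradient(d1, s, axis=0)
        num = d1[:, 0] * d2[:, 1] - d1[:, 1] * d2[:, 0]
        den = (d1[:, 0] ** 2 + d1[:, 1] ** 2) ** 1.5
        return num / np.where(den == 0, np.inf, den)

    def normals_inward(self) -> np.ndarray:
        """Unit normals pointing to the left of travel (tissue interior)."""
        pts = self.points
        if self.closed:
            ext = np.vstack([pts[-1:], pts, pts[:1]])
            tang = ext[2:] - ext[:-2]
        else:
            tang = np.gradient(pts, self.arclength_coords, axis=0)
        tang = tang / np.linalg.norm(tang, axis=1, keepdims=True)
        return np.column_stack([-tang[:, 1], tang[:, 0]])

    def as_linestring(self) -> LineString:
        pts = self.points
        if self.closed:
            pts = np.vstack([pts, pts[:1]])
        return LineString(pts)


@dataclass(frozen=True)
class SectionGeometry:
    """A midsagittal section: EGL boundaries, base segment, ACs, stage."""

    outer_egl: Contour
    inner_egl: Contour
    base: np.ndarray  # (2, 2) endpoints of the straight closing segment, um
    ac_positions: np.ndarray = field(default_factory=lambda: np.empty(0))
    stage: float = float("nan")

    def __post_init__(self):
        base = np.asarray(self.base, dtype=float).reshape(2, 2)
        ac = np.sort(np.asarray(self.ac_positions, dtype=float).ravel())
        inner_len = self.inner_egl.arc_length
        if np.any((ac < 0) | (ac > inner_len)):
            raise ContourError("AC positions must lie within the inner EGL arc length")
        object.__setattr__(self, "base", base)
        object.__setattr__(self, "ac_positions", ac)

    def core_polygon(self) -> Polygon:
        """Core region: inner EGL boundary closed by the base segment."""
        pts = self.inner_egl.points
        poly = Polygon(np.vstack([pts, self.base[::-1]]))
        if not poly.is_valid:
            poly = poly.buffer(0)
        return poly

    def cerebellar_polygon(self) -> Polygon:
        """Whole-section region: outer EGL boundary closed by the base line."""
        pts = self.outer_egl.points
        poly = Polygon(pts)
        if not poly.is_valid:
            poly = poly.buffer(0)
        return poly

    def egl_band_polygon(self) -> Polygon:
        """EGL band between outer and inner boundaries, closed at the ends."""
        poly = Polygon(np.vstack([self.outer_egl.points, self.inner_egl.points[::-1]]))
        if not poly.is_valid:
            poly = poly.buffer(0)
        return poly


# ---------------------------------------------------------------------------
# File formats: contour CSV (header x_um,y_um) and section manifest JSON.

def write_contour_csv(path, contour: Contour) -> None:
    df = pd.DataFrame(contour.points, columns=["x_um", "y_um"])
    df.to_csv(path, index=False)


def read_contour_csv(path, closed: bool = False) -> Contour:
    df = pd.read_csv(path)
    if not {"x_um", "y_um"} <= set(df.columns):
        raise ContourError(f"{path}: expected columns x_um,y_um")
    return Contour(df[["x_um", "y_um"]].to_numpy(), closed=closed)


def write_section(directory, section: SectionGeometry, prefix: str = "section") -> Path:
    """Write a section as two contour CSVs plus a JSON manifest; return manifest path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    outer = f"{prefix}_outer.csv"
    inner = f"{prefix}_inner.csv"
    write_contour_csv(directory / outer, section.outer_egl)
    write_contour_csv(directory / inner, section.inner_egl)
    manifest = {
        "outer_egl": outer,
        "inner_egl": inner,
        "base": section.base.tolist(),
        "ac_positions": section.ac_positions.tolist(),
        "stage": None if np.isnan(section.stage) else section.stage,
    }
    mpath = directory / f"{prefix}_manifest.json"
    mpath.write_text(json.dumps(manifest, indent=1))
    return mpath


def read_section(manifest_path) -> SectionGeometry:
    manifest_path = Path(manifest_path)
    manifest = json.loads(manifest_path.read_text())
    root = manifest_path.parent
    stage = manifest.get("stage")
    return SectionGeometry(
        outer_egl=read_contour_csv(root / manifest["outer_egl"]),
        inner_egl=read_contour_csv(root / manifest["inner_egl"]),
        base=np.asarray(manifest["base"], dtype=float),
        ac_positions=np.asarray(manifest["ac_positions"], dtype=float),
        stage=float("nan") if stage is None else float(stage),
    )
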