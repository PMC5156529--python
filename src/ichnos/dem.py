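"""Elevation-raster substrate: gridding, contouring, footprint extraction.

Scattered (x, y, z) points are gridded by Delaunay triangulation with
linear (barycentric) interpolation — exact on planes, never extrapolating
beyond the data z-range, and blanking every node outside the data's
convex hull.  Contours are marching-squares level sets at multiples of a
fixed interval (2 mm by default, the interval used on the site contour
maps).  Footprint extraction references depths against a robust local
plane fitted to the undisturbed surface and segments the depression
deeper than a threshold below it.

Grid rasters read and write the plain-text ESRI ASCII grid format
(ncols/nrows/xllcorner/yllcorner/cellsize/nodata_value header then
row-major heights, northernmost row first).
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.interpolate import LinearNDInterpolator
from scipy.ndimage import label as cc_label
from scipy.spatial import Delaunay, QhullError
from skimage import measure as _skmeasure

from ._util import InvalidArgumentError
from .morphometry import Footprint, FootprintMetrics

NODATA = -9999.0


@dataclass
class ElevationGrid:
    """Regular-spacing height raster; blank cells are NaN."""

    origin: tuple          # (x, y) of the lower-left cell centre, mm
    spacing: float         # mm
    heights: np.ndarray    # (nrows, ncols), row 0 = southernmost

    def __post_init__(self):
        if self.spacing <= 0:
            raise InvalidArgumentError("grid spacing must be positive")
        self.heights = np.asarray(self.heights, dtype=float)

    @property
    def shape(self) -> tuple:
        return self.heights.shape

    def xy(self):
        """Cell-centre coordinate vectors (x along columns, y along rows)."""
        ny, nx = self.heights.shape
        return (self.origin[0] + self.spacing * np.arange(nx),
                self.origin[1] + self.spacing * np.arange(ny))

    def to_ascii(self) -> str:
        ny, nx = self.heights.shape
        half = self.spacing / 2.0
        buf = io.StringIO()
        buf.write(f"ncols {nx}\nnrows {ny}\n")
        buf.write(f"xllcorner {self.origin[0] - half:.6g}\n")
        buf.write(f"yllcorner {self.origin[1] - half:.6g}\n")
        buf.write(f"cellsize {self.spacing:.6g}\nnodata_value {NODATA:.6g}\n")
        data = np.where(np.isnan(self.heights), NODATA, self.heights)
        for row in data[::-1]:  # northernmost row first
            buf.write(" ".join(f"{v:.6g}" for v in row) + "\n")
        return buf.getvalue()

    @classmethod
    def from_ascii(cls, text: str) -> "ElevationGrid":
        lines = [ln for ln in text.splitlines() if ln.strip()]
        hdr = {}
        for ln in lines[:6]:
            key, val = ln.split()
            hdr[key.lower()] = float(val)
        nx, ny = int(hdr["ncols"]), int(hdr["nrows"])
        spacing = hdr["cellsize"]
        rows = [np.array(ln.split(), dtype=float) for ln in lines[6:6 + ny]]
        data = np.vstack(rows)[::-1]
        if data.shape != (ny, nx):
            raise InvalidArgumentError(
                f"raster body shape {data.shape} does not match header ({ny}, {nx})")
        nodata = hdr.get("nodata_value", NODATA)
        data = np.where(data == nodata, np.nan, data)
        origin = (hdr["xllcorner"] + spacing / 2.0, hdr["yllcorner"] + spacing / 2.0)
        return cls(origin=origin, spacing=spacing, heights=data)


@dataclass
class ContourSet:
    interval: float
    polylines: list  # (level, (n, 2) array of (x, y) vertices)

    def levels(self):
        return sorted({lv for lv, _ in self.polylines})


def grid_points(points, spacing: float = 1.0) -> ElevationGrid:
    """Grid scattered (x, y, z) points by triangulation with linear
    interpolation; nodes outside the convex hull are blanked."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 3:
        raise InvalidArgumentError("cannot triangulate: need >= 3 (x, y, z) points")
    if spacing <= 0:
        raise InvalidArgumentError("spacing must be positive")
    try:
        tri = Delaunay(pts[:, :2])
    except QhullError as exc:
        raise InvalidArgumentError(f"cannot triangulate: {exc}") from exc
    if tri.simplices.size == 0:
        raise InvalidArgumentError("cannot triangulate: points are collinear")

    x0, y0 = pts[:, 0].min(), pts[:, 1].min()
    nx = int(np.floor((pts[:, 0].max() - x0) / spacing)) + 1
    ny = int(np.floor((pts[:, 1].max() - y0) / spacing)) + 1
    xs = x0 + spacing * np.arange(nx)
    ys = y0 + spacing * np.arange(ny)
    gx, gy = np.meshgrid(xs, ys)

    interp = LinearNDInterpolator(tri, pts[:, 2])
    z = interp(gx, gy)
    return ElevationGrid(origin=(x0, y0), spacing=spacing, heights=z)


def contour_grid(grid: ElevationGrid, interval: float = 2.0) -> ContourSet:
    """Marching-squares contours at integer multiples of *interval*,
    clipped at blank regions (a flat grid yields an empty set)."""
    if interval <= 0:
        raise InvalidArgumentError("contour interval must be positive")
    z = grid.heights
    finite = np.isfinite(z)
    if not finite.any():
        raise InvalidArgumentError("grid has no non-blank cells")
    zmin, zmax = np.nanmin(z), np.nanmax(z)
    lo = int(np.ceil(zmin / interval))
    hi = int(np.floor(zmax / interval))
    polylines = []
    for k in range(lo, hi + 1):
        level = k * interval
        if level <= zmin or level >= zmax:
            continue  # find_contours needs the level strictly inside the range
        for rc in _skmeasure.find_contours(z, level):
            xy = np.column_stack([
                grid.origin[0] + rc[:, 1] * grid.spacing,
                grid.origin[1] + rc[:, 0] * grid.spacing,
            ])
            polylines.append((level, xy))
    return ContourSet(interval=interval, polylines=polylines)


def fit_reference_plane(grid: ElevationGrid, trim: float = 0.2,
                        n_iter: int = 3) -> np.ndarray:
    """Trimmed least-squares plane z = a x + b y + c over non-blank cells.

    Iteratively refits after dropping the *trim* fraction of cells with
    the largest absolute residuals, so a localized depression does not
    drag the reference surface down.
    """
    xs, ys = grid.xy()
    gx, gy = np.meshgrid(xs, ys)
    mask = np.isfinite(grid.heights)
    A = np.column_stack([gx[mask], gy[mask], np.ones(mask.sum())])
    z = grid.heights[mask]
    keep = np.ones(len(z), dtype=bool)
    coef = None
    for _ in range(n_iter):
        coef, *_ = np.linalg.lstsq(A[keep], z[keep], rcond=None)
        resid = np.abs(A @ coef - z)
        cutoff = np.quantile(resid, 1.0 - trim)
        keep = resid <= cutoff
    return coef


def measure_from_dem(grid: ElevationGrid, depth_threshold: float = 2.0,
                     footprint_id: str = "dem", side: str = "right"):
    """Extract landmarks and metrics for a single footprint depression.

    The reference surface is a trimmed least-squares plane through the
    undisturbed cells; the depression mask collects cells deeper than
    *depth_threshold* below it.  The foot axis is the principal axis of
    the mask; landmarks are the extreme mask cells along and across it.
    """
    coef = fit_reference_plane(grid)
    xs, ys = grid.xy()
    gx, gy = np.meshgrid(xs, ys)
    depth = (coef[0] * gx + coef[1] * gy + coef[2]) - grid.heights
    mask = np.isfinite(grid.heights) & (depth > depth_threshold)

    labels, n_comp = cc_label(mask)
    if n_comp == 0:
        raise InvalidArgumentError("no depression found below the reference surface")
    if n_comp > 1:
        sizes = np.bincount(labels.ravel())[1:]
        # tolerate crumbs of a few cells (noise speckle); real multiples fail
        major = np.flatnonzero(sizes >= max(9, 0.05 * sizes.max())) + 1
        if len(major) > 1:
            raise InvalidArgumentError(
                f"expected one depression, found {len(major)} components "
                f"with sizes {sorted(sizes[major - 1].tolist(), reverse=True)}")
        mask = labels == major[0]

    pts = np.column_stack([gx[mask], gy[mask]])
    centroid = pts.mean(axis=0)
    _, _, vt = np.linalg.svd(pts - centroid, full_matrices=False)
    axis = vt[0]
    perp = np.array([-axis[1], axis[0]])

    t = (pts - centroid) @ axis
    heel_pt = pts[np.argmin(t)]
    toe_pt = pts[np.argmax(t)]
    # orient the axis heel -> toe by convention: deepest cell near the heel
    heel_depth = depth[mask][np.argmin(t)]
    toe_depth = depth[mask][np.argmax(t)]
    if heel_depth < toe_depth:
        axis, perp, t = -axis, -perp, -t
        heel_pt, toe_pt = toe_pt, heel_pt
    length = float(t.max() - t.min())

    # max width: caliper across the axis in the anterior 60 % of the length
    rel = (t - t.min()) / length if length > 0 else t * 0.0
    w = (pts - centroid) @ perp
    ant = rel >= 0.4
    max_width = float(w[ant].max() - w[ant].min()) if ant.any() else float(np.ptp(w))
    post = rel <= 0.3
    heel_width = float(w[post].max() - w[post].min()) if post.any() else None

    ball_c = centroid + axis * (t.min() + 0.69 * length)
    landmarks = {
        "heel_posterior_tip": heel_pt,
        "hallux_anterior_tip": toe_pt,
        "ball_medial": ball_c - perp * max_width / 2.0,
        "ball_lateral": ball_c + perp * max_width / 2.0,
    }
    fp = Footprint(id=footprint_id, side=side, landmarks=landmarks)
    metrics = FootprintMetrics(length=length, max_width=max_width,
                               heel_width=heel_width)
    return fp, metrics
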