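"""Nuclear geometry: masks, boundary polylines and distance-to-lamina maps.

A :class:`NucleusGeometry` couples a raster view (boolean mask on a square
lattice, Euclidean distance transform) used by the field simulator with a
vector view (closed boundary polyline) used by localization-based
quantification.  Either view can be primary: simulated nuclei start from an
analytic circle/ellipse, imaged nuclei from an alpha-shape of the
localization cloud (see :mod:`ladkit.storm`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree


__all__ = ["NucleusGeometry", "make_geometry", "geometry_from_mask",
           "geometry_from_polygon"]


@dataclass
class NucleusGeometry:
    """Raster + vector description of one nucleus.

    Attributes
    ----------
    h : float
        Lattice spacing (nm).
    mask : ndarray of bool
        True inside the nucleus.
    boundary : ndarray, shape (m, 2)
        Ordered closed boundary polyline in nm (last point connects to the
        first).
    distance : ndarray
        Distance to the nuclear envelope (nm), >= 0 inside the mask and ~0
        on boundary cells.
    """

    h: float
    mask: np.ndarray
    boundary: np.ndarray
    distance: np.ndarray
    origin: tuple[float, float] = (0.0, 0.0)
    _arc_tree: cKDTree | None = field(default=None, repr=False)
    _arc_s: np.ndarray | None = field(default=None, repr=False)

    @property
    def area(self) -> float:
        """Nuclear area from the raster mask (nm^2)."""
        return float(np.count_nonzero(self.mask) * self.h ** 2)

    @property
    def R_nuc(self) -> float:
        """Effective nuclear radius sqrt(A/pi) (nm)."""
        return float(np.sqrt(self.area / np.pi))

    @property
    def perimeter(self) -> float:
        """Arc length of the closed boundary polyline (nm)."""
        seg = np.diff(np.vstack([self.boundary, self.boundary[:1]]), axis=0)
        return float(np.sum(np.hypot(seg[:, 0], seg[:, 1])))

    def cell_centers(self):
        """(x, y) coordinate arrays of the lattice cell centers, in nm."""
        ny, nx = self.mask.shape
        x = self.origin[0] + (np.arange(nx) + 0.5) * self.h
        y = self.origin[1] + (np.arange(ny) + 0.5) * self.h
        return np.meshgrid(x, y)

    # -- arc-length parameterization ------------------------------------
    def _ensure_arc_index(self, resolution: float | None = None):
        if self._arc_tree is not None:
            return
        res = resolution if resolution is not None else max(self.h / 2.0, 1.0)
        pts = np.vstack([self.boundary, self.boundary[:1]])
        seg = np.diff(pts, axis=0)
        seglen = np.hypot(seg[:, 0], seg[:, 1])
        s_knots = np.concatenate([[0.0], np.cumsum(seglen)])
        total = s_knots[-1]
        n = max(int(np.ceil(total / res)), 16)
        s_dense = np.linspace(0.0, total, n, endpoint=False)
        ix = np.searchsorted(s_knots, s_dense, side="right") - 1
        frac = (s_dense - s_knots[ix]) / np.maximum(seglen[ix], 1e-300)
        dense = pts[ix] + seg[ix] * frac[:, None]
        self._arc_tree = cKDTree(dense)
        self._arc_s = s_dense

    def arc_position(self, points: np.ndarray) -> np.ndarray:
        """Arc-length position (nm) of the boundary point nearest each query."""
        self._ensure_arc_index()
        _, idx = self._arc_tree.query(np.atleast_2d(points))
        return self._arc_s[idx]

    def distance_to_boundary(self, points: np.ndarray) -> np.ndarray:
        """Unsigned Euclidean distance (nm) from points to the boundary polyline."""
        self._ensure_arc_index()
        d, _ = self._arc_tree.query(np.atleast_2d(points))
        return d


def _distance_map(mask: np.ndarray, h: float) -> np.ndarray:
    """EDT-based distance to the envelope; ~0 on the outermost mask ring."""
    if mask.all():
        # full-rectangle nucleus: distance to the array edge
        ny, nx = mask.shape
        iy = (np.arange(ny) + 0.5) * h
        ix = (np.arange(nx) + 0.5) * h
        dy = np.minimum(iy, iy[::-1])
        dx = np.minimum(ix, ix[::-1])
        return np.maximum(np.minimum(dy[:, None], dx[None, :]) - 0.5 * h, 0.0)
    d = ndimage.distance_transform_edt(mask) * h
    return np.maximum(d - 0.5 * h, 0.0)


def make_geometry(shape: str, radii, h: float, margin: int = 2) -> NucleusGeometry:
    """Build a circular or elliptical nucleus on a square lattice.

    Parameters
    ----------
    shape : {"circle", "ellipse"}
    radii : float or (float, float)
        Radius, or semi-axes (a, b), in nm.
    h : float
        Lattice spacing (nm); should resolve the interface width of the
        model it will be used with (h <= l_int/2 recommended).
    """
    if shape == "circle":
        r = float(np.atleast_1d(radii)[0])
        a = b = r
    elif shape == "ellipse":
        a, b = (float(v) for v in radii)
    elif shape == "square":
        # full-rectangle nucleus with half-side `radii`; its all-True mask
        # lets the integrator use the fast DCT spectral path
        r = float(np.atleast_1d(radii)[0])
        if r <= 0:
            raise ValueError("radii must be positive")
        n = int(np.ceil(2 * r / h))
        mask = np.ones((n, n), dtype=bool)
        side = n * h
        boundary = np.array([[0.0, 0.0], [side, 0.0], [side, side],
                             [0.0, side]])
        return NucleusGeometry(h=h, mask=mask, boundary=boundary,
                               distance=_distance_map(mask, h))
    else:
        raise ValueError(f"unknown shape {shape!r}")
    if a <= 0 or b <= 0:
        raise ValueError("radii must be positive")
    if min(a, b) < 10 * h:
        warnings.warn("nucleus radii are not much larger than the lattice "
                      "spacing; geometry will be poorly resolved")

    nx = int(np.ceil(2 * a / h)) + 2 * margin
    ny = int(np.ceil(2 * b / h)) + 2 * margin
    cx, cy = nx * h / 2.0, ny * h / 2.0
    x = (np.arange(nx) + 0.5) * h
    y = (np.arange(ny) + 0.5) * h
    X, Y = np.meshgrid(x, y)
    mask = ((X - cx) / a) ** 2 + ((Y - cy) / b) ** 2 <= 1.0
    if not mask.any():
        raise ValueError("degenerate radii: empty mask")

    # analytic boundary polyline, resolved to ~h/2
    per_est = np.pi * (3 * (a + b) - np.sqrt((3 * a + b) * (a + 3 * b)))
    m = max(int(np.ceil(per_est / (h / 2.0))), 64)
    t = np.linspace(0, 2 * np.pi, m, endpoint=False)
    boundary = np.column_stack([cx + a * np.cos(t), cy + b * np.sin(t)])

    return NucleusGeometry(h=h, mask=mask, boundary=boundary,
                           distance=_distance_map(mask, h))


def geometry_from_mask(mask: np.ndarray, h: float,
                       boundary: np.ndarray | None = None) -> NucleusGeometry:
    """Wrap an arbitrary boolean mask (single connected component expected).

    If no polyline is given, the boundary is traced with marching squares.
    """
    if boundary is None:
        from skimage import measure

        contours = measure.find_contours(mask.astype(float), 0.5)
        if not contours:
            raise ValueError("mask has no boundary contour")
        contour = max(contours, key=len)  # outer boundary
        # find_contours returns (row, col); convert to (x, y) in nm
        boundary = np.column_stack([(contour[:, 1] + 0.5) * h,
                                    (contour[:, 0] + 0.5) * h])
    return NucleusGeometry(h=h, mask=mask, boundary=np.asarray(boundary),
                           distance=_distance_map(mask, h))


def geometry_from_polygon(polygon, h: float) -> NucleusGeometry:
    """Rasterize a shapely polygon (coordinates in nm) onto a lattice."""
    import shapely

    minx, miny, maxx, maxy = polygon.bounds
    pad = 2 * h
    ox, oy = minx - pad, miny - pad
    nx = int(np.ceil((maxx - minx + 2 * pad) / h))
    ny = int(np.ceil((maxy - miny + 2 * pad) / h))
    x = ox + (np.arange(nx) + 0.5) * h
    y = oy + (np.arange(ny) + 0.5) * h
    X, Y = np.meshgrid(x, y)
    mask = shapely.contains_xy(polygon, X.ravel(), Y.ravel()).reshape(ny, nx)
    boundary = np.asarray(polygon.exterior.coords)[:-1]
    return NucleusGeometry(h=h, mask=mask, boundary=boundary,
                           distance=_distance_map(mask, h), origin=(ox, oy))
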