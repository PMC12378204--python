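"""Quantification of single-molecule localization (STORM) data.

Pipeline, per nucleus:

1. Voronoi tessellation of the 2D localizations; each localization's local
   density is the inverse of its polygon area.  Unbounded (convex-hull)
   polygons are flagged as ``edge`` and excluded from area sums; the
   nuclear area estimate is the sum of non-edge polygon areas.  Densities
   are normalized per nucleus by the mean non-edge polygon area, giving the
   dimensionless *reduced Voronoi density*.
2. Density classes from percentiles of the reduced densities pooled over
   all nuclei passed in one call: sparse chromatin up to the 30th
   percentile, dense chromatin in the 31-70 band, ultradense above.
3. DBSCAN clustering of the dense-and-above localizations into
   heterochromatin domains (>= 3 localizations per cluster).
4. Nuclear boundary estimation as an alpha-shape of all localizations.
5. LAD classification: a cluster is a LAD iff any member localization lies
   within 2.5% of the effective nuclear radius from the envelope; LAD
   thickness profiles by the same equal-arc segment rule as for simulated
   fields.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
from scipy.spatial import Delaunay, Voronoi, cKDTree
from shapely.geometry import Polygon
from sklearn.cluster import DBSCAN

from .domains import LADProfile, profile_from_assignments
from .geometry import NucleusGeometry, geometry_from_polygon

__all__ = ["LocalizationTable", "VoronoiSummary", "read_localizations",
           "voronoi_density", "classify_density", "cluster_domains",
           "estimate_boundary", "classify_lads", "lad_thickness_profile",
           "quantify_nucleus"]

log = logging.getLogger(__name__)

LOC_COLUMNS = ["nucleus_id", "x_nm", "y_nm"]
NOISE = -1  # DBSCAN noise label


@dataclass
class VoronoiSummary:
    """Per-nucleus tessellation bookkeeping."""

    nucleus_id: object
    n_localizations: int
    n_edge: int
    mean_polygon_area: float  # non-edge mean, nm^2
    nuclear_area: float       # sum of non-edge polygon areas, nm^2

    def to_dict(self):
        return dict(nucleus_id=self.nucleus_id,
                    n_localizations=self.n_localizations, n_edge=self.n_edge,
                    mean_polygon_area=self.mean_polygon_area,
                    nuclear_area=self.nuclear_area)


class LocalizationTable:
    """Per-nucleus 2D localizations with pipeline annotations.

    Thin wrapper over a pandas DataFrame with columns ``nucleus_id``,
    ``x_nm``, ``y_nm`` plus annotations added as the pipeline runs:
    ``voronoi_area_nm2``, ``edge`` (bool), ``reduced_density``,
    ``density_class`` and ``cluster_id``.
    """

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in LOC_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"missing localization columns: {missing}")
        self.df = df.reset_index(drop=True)
        for nid, sub in self.df.groupby("nucleus_id"):
            if len(sub) < 4:
                raise ValueError(
                    f"nucleus {nid!r} has {len(sub)} localizations; "
                    "at least 4 are required for tessellation")

    def __len__(self):
        return len(self.df)

    @property
    def nucleus_ids(self):
        return list(dict.fromkeys(self.df["nucleus_id"]))

    def nucleus(self, nucleus_id) -> pd.DataFrame:
        return self.df[self.df["nucleus_id"] == nucleus_id]

    def points(self, nucleus_id) -> np.ndarray:
        sub = self.nucleus(nucleus_id)
        return sub[["x_nm", "y_nm"]].to_numpy(float)


def read_localizations(path, jitter_seed: int = 0) -> LocalizationTable:
    """Read a localization CSV (columns x_nm, y_nm[, nucleus_id, frame]).

    Exact duplicate coordinates within a nucleus are jittered by < 0.01 nm
    (logged, seeded) to guard the tessellation against degeneracy.
    """
    df = pd.read_csv(path)
    for col in ("x_nm", "y_nm"):
        if col not in df.columns:
            raise ValueError(f"localization file is missing column {col!r}")
    if "nucleus_id" not in df.columns:
        df["nucleus_id"] = 0
    for col in ("x_nm", "y_nm"):
        df[col] = pd.to_numeric(df[col], errors="raise").astype(float)
    rng = np.random.default_rng(jitter_seed)
    dup = df.duplicated(subset=["nucleus_id", "x_nm", "y_nm"], keep="first")
    ndup = int(dup.sum())
    if ndup:
        log.info("jittering %d duplicate localizations (< 0.01 nm, seed=%d)",
                 ndup, jitter_seed)
        df.loc[dup, "x_nm"] += rng.uniform(-5e-3, 5e-3, ndup)
        df.loc[dup, "y_nm"] += rng.uniform(-5e-3, 5e-3, ndup)
    cols = ["nucleus_id", "x_nm", "y_nm"] + (
        ["frame"] if "frame" in df.columns else [])
    return LocalizationTable(df[cols].copy())


def _voronoi_polygon_areas(points: np.ndarray):
    """(areas, edge_flags): polygon area per input point; unbounded -> edge."""
    vor = Voronoi(points)
    areas = np.full(len(points), np.nan)
    edge = np.zeros(len(points), dtype=bool)
    for i, reg_idx in enumerate(vor.point_region):
        region = vor.regions[reg_idx]
        if -1 in region or len(region) < 3:
            edge[i] = True
            continue
        poly = vor.vertices[region]
        x, y = poly[:, 0], poly[:, 1]
        areas[i] = 0.5 * abs(np.dot(x, np.roll(y, 1)) - np.dot(y, np.roll(x, 1)))
    return areas, edge


def voronoi_density(tab: LocalizationTable):
    """Annotate Voronoi areas and reduced densities; summarize per nucleus.

    The reduced density of localization *i* is ``A_bar / A_i`` where
    ``A_bar`` is that nucleus's mean non-edge polygon area, so a uniform
    cloud has reduced density ~1 everywhere.
    """
    df = tab.df
    df["voronoi_area_nm2"] = np.nan
    df["edge"] = False
    df["reduced_density"] = np.nan
    summaries = []
    for nid in tab.nucleus_ids:
        sel = df["nucleus_id"] == nid
        pts = df.loc[sel, ["x_nm", "y_nm"]].to_numpy(float)
        areas, edge = _voronoi_polygon_areas(pts)
        ok = ~edge
        if not ok.any():
            raise ValueError(f"nucleus {nid!r}: all Voronoi polygons are "
                             "edge polygons (degenerate input)")
        mean_area = float(areas[ok].mean())
        df.loc[sel, "voronoi_area_nm2"] = areas
        df.loc[sel, "edge"] = edge
        red = np.full(len(pts), np.nan)
        red[ok] = mean_area / areas[ok]
        df.loc[sel, "reduced_density"] = red
        summaries.append(VoronoiSummary(
            nucleus_id=nid, n_localizations=len(pts), n_edge=int(edge.sum()),
            mean_polygon_area=mean_area,
            nuclear_area=float(areas[ok].sum())))
    return tab, summaries


def classify_density(tabs, dense_band: tuple[float, float] = (30.0, 70.0),
                     include_ultradense: bool = True):
    """Percentile density classes pooled over all given tables.

    Thresholds sit at the ``dense_band`` percentiles (default 30 and 70) of
    the pooled non-edge reduced densities: sparse <= P30 < dense <= P70 <
    ultradense.  The clustering mask is dense plus (by default) ultradense;
    pass ``include_ultradense=False`` for the literal dense-only band.
    Returns the tables with ``density_class`` and ``in_cluster_mask``
    columns, plus the thresholds used.
    """
    if not isinstance(tabs, (list, tuple)):
        tabs = [tabs]
    pool = np.concatenate([
        t.df.loc[~t.df["edge"], "reduced_density"].to_numpy(float)
        for t in tabs])
    if pool.size == 0:
        raise ValueError("empty density pool")
    lo, hi = np.percentile(pool, dense_band)
    if lo == hi:
        warnings.warn("degenerate density distribution: all localizations "
                      "labeled dense")
    for t in tabs:
        df = t.df
        rd = df["reduced_density"]
        cls = np.where(df["edge"], "edge",
                       np.where(rd <= lo, "sparse",
                                np.where(rd <= hi, "dense", "ultradense")))
        if lo == hi:
            cls = np.where(df["edge"], "edge", "dense")
        df["density_class"] = cls
        allowed = ("dense", "ultradense") if include_ultradense else ("dense",)
        df["in_cluster_mask"] = np.isin(cls, allowed)
    log.info("density thresholds: P%g=%.4g P%g=%.4g (ultradense %s in "
             "clustering mask)", dense_band[0], lo, dense_band[1], hi,
             "included" if include_ultradense else "excluded")
    return tabs, (float(lo), float(hi))


def _default_eps(points: np.ndarray) -> float:
    """3 x median nearest-neighbor distance; scale-free across densities.

    For a Poisson field of intensity lambda the median spacing is about
    0.5/sqrt(lambda), so eps = 3x spacing gives a filling factor
    lambda*pi*eps^2 ~ 7, safely above the 2D continuum-percolation
    threshold (~4.5): a domain of uniform density connects into one
    cluster instead of shattering, while sparse background stays far
    below its own percolation point.
    """
    tree = cKDTree(points)
    d, _ = tree.query(points, k=2)
    return 3.0 * float(np.median(d[:, 1]))


def _merge_adjacent_clusters(pts: np.ndarray, labels: np.ndarray,
                             radius: float) -> np.ndarray:
    """Single-linkage merge of clusters whose point sets come within
    ``radius`` of each other (union-find over close point pairs).

    Density fringes (e.g. the blurred inner edge of a LAD band) can break
    off as small satellite clusters just beyond DBSCAN reachability; true
    neighboring domains are separated by much more than the merge radius.
    """
    clustered = labels >= 0
    if not clustered.any():
        return labels
    tree = cKDTree(pts[clustered])
    lab = labels[clustered]
    parent = {int(c): int(c) for c in np.unique(lab)}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, j in tree.query_pairs(radius):
        a, b = find(int(lab[i])), find(int(lab[j]))
        if a != b:
            parent[max(a, b)] = min(a, b)
    out = labels.copy()
    out[clustered] = [find(int(c)) for c in lab]
    return out


def cluster_domains(tab: LocalizationTable, eps: float | None = None,
                    min_pts: int = 3,
                    merge_factor: float = 2.0) -> LocalizationTable:
    """DBSCAN the clustering-mask localizations into heterochromatin domains.

    ``eps`` defaults per nucleus to three times the median nearest-neighbor
    distance among its masked localizations (see :func:`_default_eps`).
    Clusters whose point sets approach within ``merge_factor * eps`` are
    merged (fringe satellites); set ``merge_factor=0`` to disable.  Labels
    are written to ``cluster_id`` (noise = -1).
    """
    if eps is not None and eps <= 0:
        raise ValueError("eps must be positive")
    df = tab.df
    if "in_cluster_mask" not in df.columns:
        raise ValueError("run classify_density before cluster_domains")
    df["cluster_id"] = NOISE
    offset = 0
    for nid in tab.nucleus_ids:
        sel = (df["nucleus_id"] == nid) & df["in_cluster_mask"]
        pts = df.loc[sel, ["x_nm", "y_nm"]].to_numpy(float)
        if len(pts) < min_pts:
            continue
        e = eps if eps is not None else _default_eps(pts)
        labels = DBSCAN(eps=e, min_samples=min_pts).fit_predict(pts)
        if merge_factor > 0:
            labels = _merge_adjacent_clusters(pts, labels, merge_factor * e)
        labels = np.where(labels >= 0, labels + offset, NOISE)
        df.loc[sel, "cluster_id"] = labels
        if labels.max(initial=NOISE) >= 0:
            offset = labels.max() + 1
    return tab


def alpha_shape(points: np.ndarray, alpha: float) -> Polygon:
    """Alpha-shape (concave hull): union of Delaunay triangles with
    circumradius below ``alpha``."""
    tri = Delaunay(points)
    simplices = tri.simplices
    p = points[simplices]
    a = np.linalg.norm(p[:, 0] - p[:, 1], axis=1)
    b = np.linalg.norm(p[:, 1] - p[:, 2], axis=1)
    c = np.linalg.norm(p[:, 2] - p[:, 0], axis=1)
    s = (a + b + c) / 2.0
    area = np.sqrt(np.maximum(s * (s - a) * (s - b) * (s - c), 1e-300))
    circum_r = a * b * c / (4.0 * area)
    keep = circum_r < alpha
    if not keep.any():
        raise ValueError("alpha too small: no triangles kept; increase alpha")
    polys = [Polygon(points[sx]) for sx in simplices[keep]]
    merged = shapely.union_all(polys)
    merged = shapely.make_valid(merged)
    if merged.geom_type == "MultiPolygon":
        biggest = max(merged.geoms, key=lambda g: g.area)
        if biggest.area < 0.9 * merged.area:
            raise ValueError(
                "alpha too small: hull is disconnected; increase alpha "
                "(e.g. several times the median nearest-neighbor distance)")
        merged = biggest
    return Polygon(merged.exterior)


def estimate_boundary(tab_or_points, alpha: float | None = None,
                      nucleus_id=None, h: float = 20.0) -> NucleusGeometry:
    """Estimate the nuclear envelope as an alpha-shape of all localizations.

    ``alpha`` defaults to 5 x the median nearest-neighbor distance.  The
    polygon is rasterized (spacing ``h`` nm) so the geometry carries both
    the vector boundary and a distance map.
    """
    if isinstance(tab_or_points, LocalizationTable):
        if nucleus_id is None:
            nucleus_id = tab_or_points.nucleus_ids[0]
        points = tab_or_points.points(nucleus_id)
    else:
        points = np.asarray(tab_or_points, float)
    if len(points) < 10:
        raise ValueError("need at least 10 localizations to estimate a boundary")
    auto = alpha is None
    if auto:
        # scale from the sparse (background) end of the spacing
        # distribution so dense clusters do not shrink the alpha radius
        tree = cKDTree(points)
        d, _ = tree.query(points, k=2)
        alpha = 5.0 * float(np.percentile(d[:, 1], 90))
    last_err = None
    for _ in range(3 if auto else 1):
        try:
            poly = alpha_shape(points, alpha)
            return geometry_from_polygon(poly, h=h)
        except ValueError as err:
            last_err = err
            alpha *= 2.0
    raise last_err


def classify_lads(tab: LocalizationTable, geom: NucleusGeometry,
                  frac: float = 0.025, nucleus_id=None,
                  require_ultradense_core: bool = True,
                  max_area_fraction: float = 0.5) -> pd.DataFrame:
    """Per-cluster DomainTable with interior/LAD classification.

    A cluster is a LAD iff any member localization is within
    ``frac * R_nuc`` (inclusive) of the envelope.  The domain area is the
    sum of member non-edge Voronoi polygon areas and the interior radius is
    the area-equivalent ``R_d = sqrt(area/pi)``.

    Two domain-calling guards (both documented defaults, switchable):
    a cluster without a single ultradense localization lacks a
    heterochromatin core and is dropped as a background density
    fluctuation; a cluster covering more than ``max_area_fraction`` of the
    nuclear area is an unsegmented background percolation, not a domain.
    """
    if geom is None:
        raise ValueError("missing nucleus geometry")
    if nucleus_id is None:
        nucleus_id = tab.nucleus_ids[0]
    sub = tab.nucleus(nucleus_id)
    if "cluster_id" not in sub.columns:
        raise ValueError("run cluster_domains before classify_lads")
    has_ultra_class = ("density_class" in sub.columns
                      and (sub["density_class"] == "ultradense").any())
    pts = sub[["x_nm", "y_nm"]].to_numpy(float)
    dist = geom.distance_to_boundary(pts)
    band = frac * geom.R_nuc
    rows = []
    clustered = sub[sub["cluster_id"] >= 0]
    for cid, grp in clustered.groupby("cluster_id"):
        idx = grp.index
        d = dist[sub.index.get_indexer(idx)]
        area = float(grp.loc[~grp["edge"], "voronoi_area_nm2"].sum())
        if require_ultradense_core and has_ultra_class and \
                not (grp["density_class"] == "ultradense").any():
            continue
        if area > max_area_fraction * geom.area:
            log.info("dropping cluster %s: area %.3g nm^2 exceeds %.0f%% of "
                     "the nucleus (unsegmented background)", cid, area,
                     100 * max_area_fraction)
            continue
        is_lad = bool((d <= band).any())
        rows.append(dict(
            domain_id=int(cid), type="LAD" if is_lad else "interior",
            n_px_or_locs=len(grp), area_nm2=area,
            R_d_nm=float(np.sqrt(area / np.pi)),
            centroid_x_nm=float(grp["x_nm"].mean()),
            centroid_y_nm=float(grp["y_nm"].mean()),
            min_dist_to_boundary_nm=float(d.min()),
            theta_deg=np.nan))
    from .domains import empty_domain_table
    table = pd.DataFrame(rows) if rows else empty_domain_table()
    table.attrs["nucleus_id"] = nucleus_id
    table.attrs["band_nm"] = band
    return table


def lad_thickness_profile(tab: LocalizationTable, domains: pd.DataFrame,
                          geom: NucleusGeometry, n_segments: int = 50,
                          nucleus_id=None) -> LADProfile:
    """Equal-arc-segment LAD thickness profile from localization polygons.

    Each LAD localization contributes its (non-edge) Voronoi polygon area
    to the boundary segment nearest to it; segment thickness is the
    accumulated area over the segment arc length.
    """
    if nucleus_id is None:
        nucleus_id = domains.attrs.get("nucleus_id", tab.nucleus_ids[0])
    sub = tab.nucleus(nucleus_id)
    lad_ids = set(domains.loc[domains["type"] == "LAD", "domain_id"])
    total_hc = float(domains["area_nm2"].sum())
    members = sub[sub["cluster_id"].isin(lad_ids) & ~sub["edge"]]
    if len(members) == 0:
        return profile_from_assignments(np.empty(0), np.empty(0),
                                        geom.perimeter, n_segments, total_hc)
    pts = members[["x_nm", "y_nm"]].to_numpy(float)
    s = geom.arc_position(pts)
    areas = members["voronoi_area_nm2"].to_numpy(float)
    return profile_from_assignments(s, areas, geom.perimeter, n_segments,
                                    total_hc)


def quantify_nucleus(tab: LocalizationTable, nucleus_id=None, *,
                     eps: float | None = None, min_pts: int = 3,
                     frac: float = 0.025, n_segments: int = 50,
                     alpha: float | None = None,
                     dense_band: tuple[float, float] = (30.0, 70.0),
                     include_ultradense: bool = True):
    """Run the full per-nucleus pipeline; returns (domains, profile, geom).

    Convenience wrapper: tessellation, pooled density classes (this nucleus
    only), DBSCAN, boundary estimation, LAD classification and thickness.
    For multi-nucleus/multi-condition pooling call the stages explicitly.
    """
    voronoi_density(tab)
    classify_density([tab], dense_band=dense_band,
                     include_ultradense=include_ultradense)
    cluster_domains(tab, eps=eps, min_pts=min_pts)
    geom = estimate_boundary(tab, alpha=alpha, nucleus_id=nucleus_id)
    domains = classify_lads(tab, geom, frac=frac, nucleus_id=nucleus_id)
    profile = lad_thickness_profile(tab, domains, geom, n_segments=n_segments,
                                    nucleus_id=nucleus_id)
    return domains, profile, geom
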