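"""Morphometrics shared by simulated fields and localization data.

Simulated composition fields are binarized into a heterochromatin mask and
decomposed into connected domains; localization-based domains arrive from
:mod:`ladkit.storm` already clustered.  Both modalities land in one
DomainTable schema (pandas DataFrame) so downstream extraction and
condition comparisons are modality-agnostic:

    domain_id, type {interior|LAD}, n_px_or_locs, area_nm2, R_d_nm,
    centroid_x_nm, centroid_y_nm, min_dist_to_boundary_nm, theta_deg

Interior domain size is reported as the area-equivalent radius
``R_d = sqrt(area/pi)``; peripheral (LAD) extent is quantified by a
thickness profile: the boundary is split into ``n`` equal-arc segments and
each segment's accumulated LAD area is divided by the segment length.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .geometry import NucleusGeometry
from .model import CompositionField, ModelParams

__all__ = ["DOMAIN_COLUMNS", "LADProfile", "binarize_heterochromatin",
           "label_domains", "lad_thickness_from_mask", "contact_angle",
           "size_distributions"]

DOMAIN_COLUMNS = ["domain_id", "type", "n_px_or_locs", "area_nm2", "R_d_nm",
                  "centroid_x_nm", "centroid_y_nm", "min_dist_to_boundary_nm",
                  "theta_deg"]

_EIGHT = np.ones((3, 3), dtype=int)  # 8-connectivity for components


def empty_domain_table() -> pd.DataFrame:
    return pd.DataFrame({c: pd.Series(dtype=t) for c, t in zip(
        DOMAIN_COLUMNS,
        [int, object, int, float, float, float, float, float, float])})


@dataclass
class LADProfile:
    """Per-segment LAD thickness along the nuclear boundary.

    ``segments`` has columns segment_idx, arc_start_nm, arc_length_nm,
    lad_area_nm2, thickness_nm.  ``peripheral_fraction`` is LAD area over
    total heterochromatin area (interior + LAD).
    """

    segments: pd.DataFrame
    mean_thickness: float
    median_thickness: float
    peripheral_fraction: float
    total_lad_area: float


def binarize_heterochromatin(fieldc: CompositionField, threshold: float | None = None,
                             params: ModelParams | None = None) -> np.ndarray:
    """Heterochromatin mask ``phi_h >= threshold``.

    Default threshold is the midpoint of the two bulk wells, ``phi_h0 / 2``.
    """
    phi_h0 = params.phi_h0 if params is not None else 0.8
    thr = phi_h0 / 2.0 if threshold is None else threshold
    if not (0 < thr < phi_h0 + 1e-12):
        raise ValueError("threshold must lie in (0, phi_h0)")
    return (fieldc.phi_h >= thr) & fieldc.mask


def label_domains(hc_mask: np.ndarray, geom: NucleusGeometry,
                  band: float | None = None,
                  compute_theta: bool = False) -> pd.DataFrame:
    """Connected heterochromatin components with per-domain metrics.

    A component is a LAD iff the minimum distance-to-boundary over its
    cells is <= ``band`` (default 2.5% of the effective nuclear radius,
    mirroring the imaging rule); otherwise it is an interior domain.
    """
    if hc_mask.shape != geom.mask.shape:
        raise ValueError("mask and geometry lattices do not match")
    band = 0.025 * geom.R_nuc if band is None else band
    labels, n = ndimage.label(hc_mask, structure=_EIGHT)
    if n == 0:
        return empty_domain_table()
    h = geom.h
    areas = ndimage.sum_labels(np.ones_like(labels), labels, range(1, n + 1)) * h * h
    mind = ndimage.minimum(geom.distance, labels, range(1, n + 1))
    cy, cx = zip(*ndimage.center_of_mass(hc_mask, labels, range(1, n + 1)))
    counts = (areas / (h * h)).round().astype(int)
    types = np.where(mind <= band, "LAD", "interior")
    thetas = np.full(n, np.nan)
    if compute_theta:
        for i in range(1, n + 1):
            if types[i - 1] == "LAD":
                thetas[i - 1] = contact_angle(labels == i, geom)
    df = pd.DataFrame({
        "domain_id": np.arange(1, n + 1),
        "type": types,
        "n_px_or_locs": counts,
        "area_nm2": areas,
        "R_d_nm": np.sqrt(areas / np.pi),
        "centroid_x_nm": (np.array(cx) + 0.5) * h + geom.origin[0],
        "centroid_y_nm": (np.array(cy) + 0.5) * h + geom.origin[1],
        "min_dist_to_boundary_nm": mind,
        "theta_deg": thetas,
    })
    df.attrs["labels"] = labels
    df.attrs["band_nm"] = band
    return df


def _segment_edges(perimeter: float, n_segments: int):
    edges = np.linspace(0.0, perimeter, n_segments + 1)
    return edges


def profile_from_assignments(arc_pos: np.ndarray, areas: np.ndarray,
                             perimeter: float, n_segments: int,
                             total_hc_area: float,
                             curvature: float | None = None) -> LADProfile:
    """Accumulate LAD element areas into equal-arc boundary segments.

    Thickness inverts the inner-band area of a convex boundary,
    ``area = len * t - (pi/n) * t**2`` (total turning 2*pi spread uniformly
    over the segments), so a uniform annulus of thickness t reads back as
    exactly t; in the thin-band limit this reduces to area / length.
    """
    if n_segments < 4:
        raise ValueError("need at least 4 boundary segments")
    edges = _segment_edges(perimeter, n_segments)
    seg_len = perimeter / n_segments
    idx = np.clip(np.searchsorted(edges, arc_pos, side="right") - 1,
                  0, n_segments - 1)
    seg_area = np.bincount(idx, weights=areas, minlength=n_segments)
    kappa_b = (2.0 * np.pi / perimeter) if curvature is None else curvature
    if kappa_b > 0:
        disc = np.maximum(1.0 - 2.0 * kappa_b * seg_area / seg_len, 0.0)
        thickness = (1.0 - np.sqrt(disc)) / kappa_b
        # beyond the invertible range (band deeper than the inradius)
        # fall back to the flat estimate
        deep = disc == 0.0
        thickness[deep] = np.maximum(seg_area[deep] / seg_len, 1.0 / kappa_b)
    else:
        thickness = seg_area / seg_len
    df = pd.DataFrame({
        "segment_idx": np.arange(n_segments),
        "arc_start_nm": edges[:-1],
        "arc_length_nm": np.full(n_segments, seg_len),
        "lad_area_nm2": seg_area,
        "thickness_nm": thickness,
    })
    total_lad = float(seg_area.sum())
    frac = total_lad / total_hc_area if total_hc_area > 0 else 0.0
    return LADProfile(segments=df,
                      mean_thickness=float(thickness.mean()),
                      median_thickness=float(np.median(thickness)),
                      peripheral_fraction=float(frac),
                      total_lad_area=total_lad)


def lad_thickness_from_mask(hc_mask: np.ndarray, geom: NucleusGeometry,
                            n_segments: int = 50, band: float | None = None,
                            table: pd.DataFrame | None = None) -> LADProfile:
    """LAD thickness profile of a binarized field.

    Every cell belonging to a LAD-classified component contributes its cell
    area ``h**2`` to the boundary segment nearest to it.
    """
    if table is None:
        table = label_domains(hc_mask, geom, band=band)
    if len(table) == 0:
        return profile_from_assignments(np.empty(0), np.empty(0),
                                        geom.perimeter, n_segments, 0.0)
    labels = table.attrs["labels"]
    lad_ids = table.loc[table["type"] == "LAD", "domain_id"].to_numpy()
    lad_cells = np.isin(labels, lad_ids) & hc_mask
    total_hc = float(table["area_nm2"].sum())
    if not lad_cells.any():
        return profile_from_assignments(np.empty(0), np.empty(0),
                                        geom.perimeter, n_segments, total_hc)
    X, Y = geom.cell_centers()
    pts = np.column_stack([X[lad_cells], Y[lad_cells]])
    s = geom.arc_position(pts)
    areas = np.full(len(pts), geom.h ** 2)
    return profile_from_assignments(s, areas, geom.perimeter, n_segments,
                                    total_hc)


def contact_angle(domain_mask: np.ndarray, geom: NucleusGeometry) -> float:
    """Contact angle (degrees) of a peripheral domain against the lamina.

    The domain is modelled as a circular cap sitting on the locally straight
    envelope: from the contact width ``w`` (arc extent of cells adjacent to
    the boundary) and the cap height ``hh`` (maximum distance-to-boundary),
    the cap circle radius is ``R = w^2/(8 hh) + hh/2`` and
    ``theta = arccos(1 - hh/R)``; a half-disk gives 90 degrees, a thin
    spread lamella a small angle.  Returns NaN for interior domains.
    """
    d = geom.distance[domain_mask]
    if d.size == 0:
        return float("nan")
    if d.min() > 0.025 * geom.R_nuc + geom.h:
        return float("nan")  # not peripheral
    hh = float(d.max()) + 0.5 * geom.h
    X, Y = geom.cell_centers()
    pts = np.column_stack([X[domain_mask], Y[domain_mask]])
    contact = d <= 1.5 * geom.h
    if not contact.any():
        return float("nan")
    s = geom.arc_position(pts[contact])
    per = geom.perimeter
    # circular arc extent, careful with wrap-around
    s_sorted = np.sort(s)
    gaps = np.diff(np.concatenate([s_sorted, [s_sorted[0] + per]]))
    w = per - float(gaps.max()) + geom.h
    if w <= 0 or hh <= 0:
        return float("nan")
    R = w * w / (8.0 * hh) + hh / 2.0
    cos_t = np.clip(1.0 - hh / R, -1.0, 1.0)
    return float(np.degrees(np.arccos(cos_t)))


def size_distributions(tables: dict[str, pd.DataFrame] | dict[str, list],
                       value: str = "R_d_nm",
                       domain_type: str = "interior") -> pd.DataFrame:
    """Summary statistics of domain sizes per condition.

    ``tables`` maps condition name to a DomainTable (or list of them).
    Returns one row per condition: n, mean, median, q25, q75, std, and the
    percent change of the mean relative to the first condition.
    """
    if not tables:
        raise ValueError("no tables given")
    rows = []
    ref_mean = None
    for cond, tab in tables.items():
        if isinstance(tab, (list, tuple)):
            tab = pd.concat(tab, ignore_index=True) if len(tab) else \
                empty_domain_table()
        vals = tab.loc[tab["type"] == domain_type, value].to_numpy(float) \
            if len(tab) else np.empty(0)
        mean = float(vals.mean()) if vals.size else np.nan
        if ref_mean is None:
            ref_mean = mean
        rows.append(dict(
            condition=cond, n=int(vals.size), mean=mean,
            median=float(np.median(vals)) if vals.size else np.nan,
            q25=float(np.percentile(vals, 25)) if vals.size else np.nan,
            q75=float(np.percentile(vals, 75)) if vals.size else np.nan,
            std=float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
            pct_change_mean=(100.0 * (mean - ref_mean) / ref_mean
                             if ref_mean else np.nan),
        ))
    return pd.DataFrame(rows)
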