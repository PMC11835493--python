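"""Plane-projected stretch maps and their summary statistics.

The tracked surface is projected onto its best-fitting plane and the
per-triangle stretch magnitudes and orientations are resampled onto a
regular grid (1 mm default), from which the descriptive statistics of a
stretch study derive: distance profiles along an axis, the spatial stretch
gradient, percentile summaries and axial orientation statistics (circular
statistics on doubled angles, since principal directions are sign-free).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy import ndimage

from .strain import StrainField, TrackedMesh

__all__ = [
    "FittedPlane",
    "GridMap",
    "OrientationStats",
    "ProfileResult",
    "fit_plane",
    "resample_grid",
    "stretch_gradient",
    "axial_stats",
    "profile_along_axis",
    "percentile_summary",
    "weighted_percentile",
]


@dataclass
class FittedPlane:
    """Least-squares plane with an orthonormal in-plane coordinate frame."""

    point: np.ndarray                # (3,) mm
    normal: np.ndarray               # unit vector
    in_plane_axes: np.ndarray        # (2, 3) orthonormal, both _|_ normal

    def to_plane(self, points: np.ndarray) -> np.ndarray:
        """World (N, 3) -> plane coordinates (N, 2), mm."""
        return (np.atleast_2d(points) - self.point) @ self.in_plane_axes.T

    def distance(self, points: np.ndarray) -> np.ndarray:
        return (np.atleast_2d(points) - self.point) @ self.normal


@dataclass
class GridMap:
    """Scalar stretch field and axial orientation field on plane coordinates.

    ``values`` is indexed [row, col]; cell (0, 0) is centred at ``origin``
    in plane coordinates, and masked-off cells (outside the projected
    patch) hold NaN.
    """

    resolution_mm: float
    origin: tuple[float, float]
    values: np.ndarray
    orientations: np.ndarray         # degrees mod 180, NaN where masked
    mask: np.ndarray                 # True = inside patch

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        h, w = self.values.shape
        x = self.origin[0] + np.arange(w) * self.resolution_mm
        y = self.origin[1] + np.arange(h) * self.resolution_mm
        return np.meshgrid(x, y)

    def save(self, path_matrix, path_header) -> None:
        np.savetxt(path_matrix, self.values, fmt="%.6g")
        with open(path_header, "w") as fh:
            yaml.safe_dump({
                "resolution_mm": float(self.resolution_mm),
                "origin": [float(o) for o in self.origin],
                "shape": [int(s) for s in self.values.shape],
            }, fh)


@dataclass
class OrientationStats:
    """Axial orientation summary: mean, SD and normalised histogram."""

    axial_mean_deg: float            # in [0, 180)
    angular_sd_deg: float
    bin_centers_deg: np.ndarray
    histogram: np.ndarray            # relative frequency, sums to 1
    resultant_length: float = 0.0

    def to_frame(self) -> pd.DataFrame:
        """Polar histogram as a table (bin centre deg, relative frequency)."""
        return pd.DataFrame({"bin_center_deg": self.bin_centers_deg,
                             "relative_frequency": self.histogram})


@dataclass
class ProfileResult:
    """Binned means of a grid map projected onto an axis between anchors."""

    anchors: tuple[np.ndarray, np.ndarray]
    bin_centers_cm: np.ndarray
    mean_pct: np.ndarray             # NaN where a bin is empty
    counts: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"distance_cm": self.bin_centers_cm,
                             "mean_stretch_pct": self.mean_pct,
                             "n_cells": self.counts})


def fit_plane(mesh_or_field: TrackedMesh | StrainField,
              which: str = "ref") -> tuple[FittedPlane, float]:
    """Best-fitting plane of the tracked patch and the in-plane strain fraction.

    The plane minimises squared orthogonal distance to the reference
    vertices (principal-axes fit).  The in-plane fraction weights each
    triangle's principal strain direction by |principal strain| x area and
    measures how much of the summed strain lies parallel to the plane:
    fraction = sum_i w_i |P d_i| / sum_i w_i, with P the in-plane projector
    and d_i the unit principal direction.  Exactly planar patches give 1.0.
    """
    if isinstance(mesh_or_field, StrainField):
        fld = mesh_or_field
        mesh = fld.mesh
    else:
        fld, mesh = None, mesh_or_field

    verts = mesh.vertices_ref if which == "ref" else mesh.vertices_def
    centroid = verts.mean(axis=0)
    centred = verts - centroid
    if len(verts) < 3:
        raise ValueError("need at least 3 vertices")
    _, svals, vt = np.linalg.svd(centred, full_matrices=False)
    if svals[1] < 1e-9 * max(svals[0], 1.0):
        raise ValueError("vertices are collinear; plane fit is degenerate")
    plane = FittedPlane(point=centroid, normal=vt[2],
                        in_plane_axes=vt[:2])

    fraction = 1.0
    if fld is not None:
        t = fld.triangles
        ok = t.valid
        areas = mesh.face_areas("ref")[ok]
        emag = np.abs(_principal_strain(t.E[ok]))
        w = emag * areas
        if w.sum() > 0:
            d = t.orientation[ok]
            in_plane = np.linalg.norm(d @ plane.in_plane_axes.T, axis=1)
            fraction = float(np.sum(w * in_plane) / np.sum(w))
    return plane, fraction


def _principal_strain(E: np.ndarray) -> np.ndarray:
    exx, eyy, exy = E[:, 0, 0], E[:, 1, 1], E[:, 0, 1]
    return 0.5 * (exx + eyy) + np.sqrt((0.5 * (exx - eyy)) ** 2 + exy**2)


def resample_grid(fld: StrainField, plane: FittedPlane,
                  resolution_mm: float = 1.0,
                  value: str = "principal_pct",
                  fill_radius_cells: int = 2) -> GridMap:
    """Resample per-triangle stretch onto a regular grid in plane coordinates.

    Each cell takes the area-weighted mean of the triangles whose reference
    centroid projects into it; orientations are averaged axially (vector
    mean of doubled angles).  Interior cells left empty are filled by
    nearest neighbour within ``fill_radius_cells``.
    """
    if resolution_mm <= 0:
        raise ValueError("resolution must be positive")
    t = fld.triangles
    ok = t.valid
    cent = plane.to_plane(fld.mesh.centroids("ref"))[ok]
    vals = getattr(t, value)[ok]
    areas = fld.mesh.face_areas("ref")[ok]
    dirs = t.orientation[ok] @ plane.in_plane_axes.T
    theta = np.arctan2(dirs[:, 1], dirs[:, 0])      # radians, axial

    x0, y0 = cent[:, 0].min(), cent[:, 1].min()
    col = np.floor((cent[:, 0] - x0) / resolution_mm + 0.5).astype(int)
    row = np.floor((cent[:, 1] - y0) / resolution_mm + 0.5).astype(int)
    w, h = col.max() + 1, row.max() + 1

    flat = row * w + col
    wsum = np.bincount(flat, weights=areas, minlength=h * w)
    vsum = np.bincount(flat, weights=areas * vals, minlength=h * w)
    csum = np.bincount(flat, weights=areas * np.cos(2 * theta), minlength=h * w)
    ssum = np.bincount(flat, weights=areas * np.sin(2 * theta), minlength=h * w)

    occupied = (wsum > 0).reshape(h, w)
    with np.errstate(invalid="ignore", divide="ignore"):
        values = (vsum / wsum).reshape(h, w)
        ang = 0.5 * np.arctan2(ssum, csum).reshape(h, w)
    orientations = np.mod(np.degrees(ang), 180.0)
    values[~occupied] = np.nan
    orientations[~occupied] = np.nan

    # fill interior holes by nearest neighbour within the given radius
    if fill_radius_cells > 0 and not occupied.all():
        dist, (ir, ic) = ndimage.distance_transform_edt(
            ~occupied, return_indices=True)
        fill = (~occupied) & (dist <= fill_radius_cells)
        values[fill] = values[ir[fill], ic[fill]]
        orientations[fill] = orientations[ir[fill], ic[fill]]
        mask = occupied | fill
    else:
        mask = occupied

    return GridMap(resolution_mm=resolution_mm,
                   origin=(float(x0), float(y0)),
                   values=values, orientations=orientations, mask=mask)


def stretch_gradient(gmap: GridMap) -> float:
    """Mean magnitude of the spatial stretch gradient, in % per cm.

    Central differences of the gridded stretch field; cells without two
    valid neighbours in either direction are excluded.  Returns NaN when
    fewer than a 2x2 block of cells is unmasked.
    """
    v = np.where(gmap.mask, gmap.values, np.nan)
    if np.sum(gmap.mask) < 4 or min(v.shape) < 2:
        return float("nan")
    gy, gx = np.gradient(v, gmap.resolution_mm)
    mag = np.hypot(gx, gy)
    good = np.isfinite(mag)
    if not good.any():
        return float("nan")
    return float(np.nanmean(mag[good]) * 10.0)       # %/mm -> %/cm


def axial_stats(angles_deg: np.ndarray, weights: np.ndarray | None = None,
                n_bins: int = 36, center: bool = False) -> OrientationStats:
    """Circular statistics for axial (mod-180) orientation data.

    Angles are doubled, the weighted circular mean and the circular
    standard deviation sqrt(-2 ln R) are computed on the doubled scale and
    halved back, so the SD of a tight axial bundle matches its linear SD.
    The histogram covers [-90, 90) around the axial mean when ``center``
    is True, else raw angles mapped to [0, 180).
    """
    a = np.radians(2.0 * np.asarray(angles_deg, dtype=float))
    w = np.ones_like(a) if weights is None else np.asarray(weights, dtype=float)
    if a.size == 0 or w.sum() <= 0:
        raise ValueError("need at least one angle with positive weight")
    C = np.sum(w * np.cos(a)) / w.sum()
    S = np.sum(w * np.sin(a)) / w.sum()
    R = float(np.hypot(C, S))
    mean2 = np.arctan2(S, C)
    axial_mean = np.mod(np.degrees(mean2) / 2.0, 180.0)
    if R < 1e-12:
        sd = np.degrees(np.sqrt(-2.0 * np.log(np.finfo(float).tiny))) / 2.0
    else:
        sd = np.degrees(np.sqrt(-2.0 * np.log(R))) / 2.0

    ang = np.mod(np.asarray(angles_deg, dtype=float), 180.0)
    if center:
        rel = np.mod(ang - axial_mean + 90.0, 180.0) - 90.0
        edges = np.linspace(-90.0, 90.0, n_bins + 1)
        hist, _ = np.histogram(rel, bins=edges, weights=w)
    else:
        edges = np.linspace(0.0, 180.0, n_bins + 1)
        hist, _ = np.histogram(ang, bins=edges, weights=w)
    hist = hist / hist.sum() if hist.sum() > 0 else hist
    centers = 0.5 * (edges[:-1] + edges[1:])
    return OrientationStats(axial_mean_deg=float(axial_mean),
                            angular_sd_deg=float(sd),
                            bin_centers_deg=centers, histogram=hist,
                            resultant_length=R)


def profile_along_axis(gmap: GridMap, anchor_a, anchor_b,
                       bin_cm: float = 1.0) -> ProfileResult:
    """Binned mean stretch along the axis from anchor_a to anchor_b.

    Anchors are plane coordinates in mm; every unmasked cell is projected
    onto the axis and binned by its projected distance from anchor_a.
    Empty bins report NaN means, never zero.
    """
    a = np.asarray(anchor_a, dtype=float)
    b = np.asarray(anchor_b, dtype=float)
    axis = b - a
    norm = np.linalg.norm(axis)
    if norm < 1e-12:
        raise ValueError("anchors must be distinct")
    axis = axis / norm

    xx, yy = gmap.cell_centers()
    ok = gmap.mask & np.isfinite(gmap.values)
    proj_cm = (((xx - a[0]) * axis[0] + (yy - a[1]) * axis[1]) / 10.0)[ok]
    vals = gmap.values[ok]

    lo = np.floor(proj_cm.min() / bin_cm) * bin_cm
    hi = np.ceil(proj_cm.max() / bin_cm) * bin_cm
    edges = np.arange(lo, hi + bin_cm / 2, bin_cm)
    if len(edges) < 2:
        edges = np.array([lo, lo + bin_cm])
    idx = np.clip(np.digitize(proj_cm, edges) - 1, 0, len(edges) - 2)
    counts = np.bincount(idx, minlength=len(edges) - 1)
    sums = np.bincount(idx, weights=vals, minlength=len(edges) - 1)
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return ProfileResult(anchors=(a, b), bin_centers_cm=centers,
                         mean_pct=means, counts=counts)


def weighted_percentile(values: np.ndarray, weights: np.ndarray,
                        q: float) -> float:
    """Area-weighted percentile with linear interpolation between order stats."""
    v = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    order = np.argsort(v)
    v, w = v[order], w[order]
    cw = np.cumsum(w) - 0.5 * w
    cw /= w.sum()
    return float(np.interp(q / 100.0, cw, v))


def percentile_summary(fld: StrainField) -> dict:
    """Area-weighted mean, 5th and 95th percentile of principal stretch,
    plus the mean orthogonal stretch."""
    t = fld.triangles
    ok = t.valid
    if not ok.any():
        raise ValueError("no valid triangles")
    w = fld.mesh.face_areas("ref")[ok]
    p = t.principal_pct[ok]
    return {
        "mean_principal_pct": float(np.average(p, weights=w)),
        "p5_principal_pct": weighted_percentile(p, w, 5.0),
        "p95_principal_pct": weighted_percentile(p, w, 95.0),
        "mean_orthogonal_pct": float(np.average(t.orthogonal_pct[ok], weights=w)),
    }
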