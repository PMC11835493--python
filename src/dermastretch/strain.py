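"""Triangulated surface meshing and per-triangle membrane strain.

Tracked points carry paired 3-D positions in a reference and a deformed
pose.  A Delaunay mesh built on the reference image grid is lifted to 3-D,
and for each triangle the in-plane 2x2 deformation gradient F between the
two poses yields the Green-Lagrange tensor E = (F^T F - I)/2.  Its
principal strains e1 >= e2 are reported as engineering stretches
100 (lambda_i - 1) with lambda_i = sqrt(1 + 2 e_i): the *principal
stretch* along the direction of maximal elongation and the *orthogonal
stretch* (negative = compression) perpendicular to it, together with the
3-D principal direction and the deformed/reference area ratio.

Strain is computed in each triangle's own plane (membrane assumption);
rigid motion of the deformed pose leaves every value unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import trimesh
from scipy.spatial import Delaunay

__all__ = [
    "TrackedMesh",
    "TriangleStrain",
    "StrainField",
    "MeshingError",
    "build_mesh",
    "triangle_strain",
    "strain_field",
]


class MeshingError(ValueError):
    """Tracked points cannot be triangulated (collinear/too few)."""


@dataclass
class TrackedMesh:
    """Triangulated set of points with paired reference/deformed positions."""

    vertices_ref: np.ndarray         # (V, 3) mm
    vertices_def: np.ndarray         # (V, 3) mm, same indexing
    faces: np.ndarray                # (T, 3) vertex index triples
    provenance: np.ndarray | None = None     # per-vertex DIC scores

    def __post_init__(self) -> None:
        self.vertices_ref = np.asarray(self.vertices_ref, dtype=float)
        self.vertices_def = np.asarray(self.vertices_def, dtype=float)
        self.faces = np.asarray(self.faces, dtype=int)
        if self.vertices_ref.shape != self.vertices_def.shape:
            raise ValueError("reference/deformed vertex arrays must match")
        if self.faces.size and self.faces.max() >= len(self.vertices_ref):
            raise ValueError("faces reference missing vertices")

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def face_areas(self, which: str = "ref") -> np.ndarray:
        v = self.vertices_ref if which == "ref" else self.vertices_def
        a = v[self.faces[:, 1]] - v[self.faces[:, 0]]
        b = v[self.faces[:, 2]] - v[self.faces[:, 0]]
        return 0.5 * np.linalg.norm(np.cross(a, b), axis=1)

    def centroids(self, which: str = "ref") -> np.ndarray:
        v = self.vertices_ref if which == "ref" else self.vertices_def
        return v[self.faces].mean(axis=1)

    def export_ply(self, path_ref, path_def) -> None:
        """Reference and deformed positions as two PLY files, shared faces."""
        for path, verts in ((path_ref, self.vertices_ref),
                            (path_def, self.vertices_def)):
            mesh = trimesh.Trimesh(vertices=verts, faces=self.faces,
                                   process=False)
            with open(path, "wb") as fh:
                fh.write(trimesh.exchange.ply.export_ply(mesh, encoding="ascii"))


@dataclass
class TriangleStrain:
    """Per-face strain arrays for a whole mesh (vectorised container)."""

    E: np.ndarray                    # (T, 2, 2) in each triangle's local frame
    principal_pct: np.ndarray        # 100 (lambda1 - 1)
    orthogonal_pct: np.ndarray       # 100 (lambda2 - 1)
    orientation: np.ndarray          # (T, 3) unit vectors, canonical sign
    area_ratio: np.ndarray           # |det F|
    valid: np.ndarray                # degenerate deformed triangles excluded


@dataclass
class StrainField:
    """Strain of every face of a tracked mesh plus summary statistics."""

    mesh: TrackedMesh
    triangles: TriangleStrain
    summary: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        t = self.triangles
        c = self.mesh.centroids("ref")
        return pd.DataFrame({
            "face": np.arange(self.mesh.n_faces),
            "cx": c[:, 0], "cy": c[:, 1], "cz": c[:, 2],
            "Exx": t.E[:, 0, 0], "Eyy": t.E[:, 1, 1], "Exy": t.E[:, 0, 1],
            "principal_pct": t.principal_pct,
            "orthogonal_pct": t.orthogonal_pct,
            "dir_x": t.orientation[:, 0], "dir_y": t.orientation[:, 1],
            "dir_z": t.orientation[:, 2],
            "area_ratio": t.area_ratio,
            "status": np.where(t.valid, "ok", "degenerate"),
        })

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.9g")


def build_mesh(grid_coords: np.ndarray, vertices_ref: np.ndarray,
               vertices_def: np.ndarray,
               provenance: np.ndarray | None = None,
               max_edge_factor: float = 3.0) -> TrackedMesh:
    """Delaunay-triangulate tracked points on their reference image grid.

    ``grid_coords`` are the 2-D reference-image coordinates of the tracked
    points (the DIC grid); triangulation happens there and is lifted to the
    3-D vertex positions.  Sliver/bridging triangles with any edge longer
    than ``max_edge_factor`` x the median edge, and triangles degenerate in
    the reference pose, are removed.
    """
    pts = np.asarray(grid_coords, dtype=float)
    if len(pts) < 3:
        raise MeshingError("need at least 3 tracked points")
    try:
        tri = Delaunay(pts)
    except Exception as exc:             # qhull raises on degenerate input
        raise MeshingError(f"triangulation failed: {exc}") from exc
    if tri.simplices.size == 0:
        raise MeshingError("all tracked points are collinear")
    faces = tri.simplices.copy()

    edges = pts[faces] - pts[np.roll(faces, 1, axis=1)]
    lengths = np.linalg.norm(edges, axis=2)
    median = np.median(lengths)
    keep = (lengths <= max_edge_factor * median).all(axis=1)
    faces = faces[keep]

    mesh = TrackedMesh(vertices_ref=np.asarray(vertices_ref, dtype=float),
                       vertices_def=np.asarray(vertices_def, dtype=float),
                       faces=faces, provenance=provenance)
    areas = mesh.face_areas("ref")
    mesh.faces = mesh.faces[areas > 1e-6]
    if mesh.n_faces == 0:
        raise MeshingError("no non-degenerate triangles")
    return mesh


def _local_frames(v0, v1, v2):
    """Orthonormal in-plane frame (e1 along the first edge) per triangle."""
    a = v1 - v0
    b = v2 - v0
    e1 = a / np.linalg.norm(a, axis=1, keepdims=True)
    n = np.cross(a, b)
    nn = np.linalg.norm(n, axis=1, keepdims=True)
    n = n / np.where(nn > 0, nn, 1.0)
    e2 = np.cross(n, e1)
    return e1, e2, n


def triangle_strain(ref_tri: np.ndarray, def_tri: np.ndarray) -> dict:
    """Strain of a single triangle pair (three 3-D points each).

    Returns a dict with keys ``E`` (2x2), ``principal_pct``,
    ``orthogonal_pct``, ``orientation`` (3-D unit vector in the reference
    surface frame) and ``area_ratio``.
    """
    t = _strain_arrays(np.asarray(ref_tri, dtype=float)[None],
                       np.asarray(def_tri, dtype=float)[None])
    if not t.valid[0]:
        raise ValueError("degenerate triangle")
    return {
        "E": t.E[0],
        "principal_pct": float(t.principal_pct[0]),
        "orthogonal_pct": float(t.orthogonal_pct[0]),
        "orientation": t.orientation[0],
        "area_ratio": float(t.area_ratio[0]),
    }


def _strain_arrays(ref: np.ndarray, dfm: np.ndarray) -> TriangleStrain:
    """Vectorised strain for (T, 3, 3) reference/deformed triangle stacks."""
    r0, r1, r2 = ref[:, 0], ref[:, 1], ref[:, 2]
    d0, d1, d2 = dfm[:, 0], dfm[:, 1], dfm[:, 2]

    e1r, e2r, _ = _local_frames(r0, r1, r2)
    e1d, e2d, _ = _local_frames(d0, d1, d2)

    def plane_coords(p0, pa, pb, e1, e2):
        a = np.stack([np.einsum("ij,ij->i", pa - p0, e1),
                      np.einsum("ij,ij->i", pa - p0, e2)], axis=1)
        b = np.stack([np.einsum("ij,ij->i", pb - p0, e1),
                      np.einsum("ij,ij->i", pb - p0, e2)], axis=1)
        return a, b

    ra, rb = plane_coords(r0, r1, r2, e1r, e2r)
    da, db = plane_coords(d0, d1, d2, e1d, e2d)

    # F maps reference edge vectors to deformed edge vectors:
    # [da db] = F [ra rb]
    Rm = np.stack([ra, rb], axis=2)              # (T, 2, 2), columns = edges
    Dm = np.stack([da, db], axis=2)
    detR = Rm[:, 0, 0] * Rm[:, 1, 1] - Rm[:, 0, 1] * Rm[:, 1, 0]
    detD = Dm[:, 0, 0] * Dm[:, 1, 1] - Dm[:, 0, 1] * Dm[:, 1, 0]
    valid = (np.abs(detR) > 1e-9) & (np.abs(detD) > 1e-12)
    safe_det = np.where(valid, detR, 1.0)
    Rinv = np.empty_like(Rm)
    Rinv[:, 0, 0] = Rm[:, 1, 1] / safe_det
    Rinv[:, 0, 1] = -Rm[:, 0, 1] / safe_det
    Rinv[:, 1, 0] = -Rm[:, 1, 0] / safe_det
    Rinv[:, 1, 1] = Rm[:, 0, 0] / safe_det
    F = Dm @ Rinv

    E = 0.5 * (np.einsum("tki,tkj->tij", F, F) - np.eye(2))
    exx, eyy, exy = E[:, 0, 0], E[:, 1, 1], E[:, 0, 1]
    mean = 0.5 * (exx + eyy)
    rad = np.sqrt((0.5 * (exx - eyy)) ** 2 + exy**2)
    ev1, ev2 = mean + rad, mean - rad
    lam1 = np.sqrt(np.maximum(1.0 + 2.0 * ev1, 0.0))
    lam2 = np.sqrt(np.maximum(1.0 + 2.0 * ev2, 0.0))

    # eigenvector of the larger principal strain, in the local frame
    theta = 0.5 * np.arctan2(2.0 * exy, exx - eyy)
    dir_local = np.stack([np.cos(theta), np.sin(theta)], axis=1)
    orientation = dir_local[:, :1] * e1r + dir_local[:, 1:2] * e2r
    orientation /= np.linalg.norm(orientation, axis=1, keepdims=True)
    # canonical axial sign: first component of largest magnitude positive
    flip = _canonical_sign(orientation)
    orientation *= flip[:, None]

    return TriangleStrain(
        E=E,
        principal_pct=100.0 * (lam1 - 1.0),
        orthogonal_pct=100.0 * (lam2 - 1.0),
        orientation=orientation,
        area_ratio=np.abs(detD / np.where(valid, detR, 1.0)),
        valid=valid,
    )


def _canonical_sign(vecs: np.ndarray, tol: float = 1e-12) -> np.ndarray:
    """+/-1 so the first non-negligible component of each vector is positive."""
    sign = np.ones(len(vecs))
    remaining = np.ones(len(vecs), dtype=bool)
    for k in range(vecs.shape[1]):
        comp = vecs[:, k]
        decide = remaining & (np.abs(comp) > tol)
        sign[decide] = np.sign(comp[decide])
        remaining &= ~decide
    return sign


def analytic_tracked_mesh(model, domain: tuple[float, float, float, float],
                          step_mm: float = 1.0) -> TrackedMesh:
    """Mesh a flat patch and deform its vertices with an analytic model.

    Bypasses imaging and DIC entirely: vertices_ref are the flat material
    grid, vertices_def the model's exact deformed positions.  This is the
    direct route for checking the strain computation against closed-form
    ground truth.
    """
    from .deformation import SurfacePatch

    uv = SurfacePatch(domain).grid(step_mm)
    ref = np.column_stack([uv, np.zeros(len(uv))])
    return build_mesh(uv, ref, model.deform(uv))


def strain_field(mesh: TrackedMesh) -> StrainField:
    """Per-triangle strain for every face plus area-weighted summaries."""
    tris = _strain_arrays(mesh.vertices_ref[mesh.faces],
                          mesh.vertices_def[mesh.faces])
    areas = mesh.face_areas("ref")
    ok = tris.valid
    w = areas[ok]
    p = tris.principal_pct[ok]
    summary = {}
    if ok.any() and w.sum() > 0:
        wn = w / w.sum()
        order = np.argsort(p)
        cdf = np.cumsum(wn[order])
        summary = {
            "n_faces": int(ok.sum()),
            "mean_principal_pct": float(np.sum(wn * p)),
            "mean_orthogonal_pct": float(np.sum(wn * tris.orthogonal_pct[ok])),
            "p5_principal_pct": float(np.interp(0.05, cdf, p[order])),
            "p95_principal_pct": float(np.interp(0.95, cdf, p[order])),
            "mean_area_ratio": float(np.sum(wn * tris.area_ratio[ok])),
        }
    return StrainField(mesh=mesh, triangles=tris, summary=summary)
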