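"""Subset-based digital image correlation (DIC).

Small speckle subsets are matched between two images — either two cameras
viewing the same pose, or the same camera across poses — by maximising the
zero-normalised cross-correlation (ZNCC) over integer displacements, then
refined to subpixel precision by a quadratic fit of the correlation
surface followed by inverse-compositional Gauss-Newton (IC-GN)
registration with a first-order (affine) subset shape function and bicubic
image interpolation.

For large unknown motions (a rotated camera, a 33% stretch) matching is
seeded by a coarse pass on downscaled images whose integer matches are
summarised by a global affine motion model; full-resolution subsets then
search only a small window around their predicted location.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.feature import match_template
from skimage.transform import rescale

__all__ = [
    "SubsetGrid",
    "MatchField",
    "PoseChainResult",
    "MatchingFailure",
    "match_integer",
    "refine_subpixel",
    "match_pair",
    "track_pose_chain",
    "STATUS_MATCHED",
    "STATUS_LOW_SCORE",
    "STATUS_OUT_OF_BOUNDS",
    "STATUS_DIVERGED",
]

STATUS_MATCHED = "matched"
STATUS_LOW_SCORE = "low_score"
STATUS_OUT_OF_BOUNDS = "out_of_bounds"
STATUS_DIVERGED = "diverged"

DEFAULT_SCORE_THRESHOLD = 0.8
_TIE_TOL = 1e-9


class MatchingFailure(RuntimeError):
    """Fewer than half of the grid subsets could be matched reliably."""


@dataclass
class SubsetGrid:
    """Regular grid of subset centres.

    ``centers`` are integer (x, y) pixel coordinates; ``radius`` is the
    subset half-size so each subset spans (2 r + 1)^2 pixels; ``spacing``
    is the grid pitch.  Subsets overlap whenever radius >= spacing, as in
    the full-scale configuration (radius 60 px, spacing 10 px).
    """

    centers: np.ndarray
    radius: int
    spacing: int

    def __post_init__(self) -> None:
        if self.spacing < 1:
            raise ValueError("spacing must be >= 1")
        if self.radius < self.spacing:
            raise ValueError("radius must be >= spacing (subsets must overlap)")
        self.centers = np.atleast_2d(np.asarray(self.centers, dtype=int))

    @classmethod
    def regular(cls, image_shape: tuple[int, int], radius: int, spacing: int,
                margin: int | None = None,
                bbox: tuple[int, int, int, int] | None = None) -> "SubsetGrid":
        """Grid covering an image (or a bbox ``(x0, x1, y0, y1)`` within it)."""
        h, w = image_shape
        m = radius + 2 if margin is None else margin
        x0, x1, y0, y1 = bbox if bbox is not None else (0, w, 0, h)
        xs = np.arange(max(x0, 0) + m, min(x1, w) - m, spacing)
        ys = np.arange(max(y0, 0) + m, min(y1, h) - m, spacing)
        xx, yy = np.meshgrid(xs, ys)
        return cls(np.column_stack([xx.ravel(), yy.ravel()]), radius, spacing)

    def __len__(self) -> int:
        return len(self.centers)


@dataclass
class MatchField:
    """One correspondence per grid centre for a single image pairing."""

    grid: SubsetGrid
    ref_points: np.ndarray           # (N, 2) float
    target_points: np.ndarray        # (N, 2) float, subpixel
    scores: np.ndarray               # ZNCC in [-1, 1]
    status: np.ndarray               # status strings
    pairing: str = ""
    affine: np.ndarray | None = None   # (N, 2, 2) local shape function

    @property
    def matched(self) -> np.ndarray:
        return self.status == STATUS_MATCHED

    @property
    def displacements(self) -> np.ndarray:
        return self.target_points - self.ref_points

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "ref_x": self.ref_points[:, 0], "ref_y": self.ref_points[:, 1],
            "tgt_x": self.target_points[:, 0], "tgt_y": self.target_points[:, 1],
            "score": self.scores, "status": self.status,
            "pairing": self.pairing,
        })

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.6f")


def _zncc_normalise(patch: np.ndarray) -> tuple[np.ndarray, float]:
    mean = patch.mean()
    centred = patch - mean
    norm = float(np.sqrt(np.sum(centred**2)))
    return centred, norm


def _select_peak(corr: np.ndarray, dx_axis: np.ndarray, dy_axis: np.ndarray
                 ) -> tuple[int, int, float]:
    """Argmax with deterministic tie-breaks.

    Among peaks within a small tolerance of the maximum, prefer the
    smallest total displacement magnitude, then lexicographic (dx, dy).
    """
    cmax = np.nanmax(corr)
    iy, ix = np.nonzero(corr >= cmax - _TIE_TOL)
    dx = dx_axis[ix]
    dy = dy_axis[iy]
    order = np.lexsort((dy, dx, np.hypot(dx, dy)))
    k = order[0]
    return int(dx[k]), int(dy[k]), float(corr[iy[k], ix[k]])


def match_integer(ref: np.ndarray, target: np.ndarray, grid: SubsetGrid,
                  search_radius: int,
                  init_offsets: np.ndarray | None = None,
                  epipolar: tuple[np.ndarray, float] | None = None,
                  score_threshold: float = DEFAULT_SCORE_THRESHOLD,
                  pairing: str = "") -> MatchField:
    """Integer-displacement ZNCC matching of every grid subset.

    ``init_offsets`` (N, 2) centres each subset's search window on a
    predicted displacement.  ``epipolar`` = (F, band_px) restricts
    candidate displacements to a band around the epipolar line of the
    subset centre under the fundamental matrix F (pixel coordinates,
    ref -> target).
    """
    ref = np.asarray(ref, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    r, n = grid.radius, len(grid)
    s = int(search_radius)
    offs = (np.zeros((n, 2), dtype=int) if init_offsets is None
            else np.round(np.asarray(init_offsets)).astype(int))

    tgt_pts = np.full((n, 2), np.nan)
    scores = np.zeros(n)
    status = np.full(n, STATUS_OUT_OF_BOUNDS, dtype=object)
    th, tw = target.shape

    for i, (cx, cy) in enumerate(grid.centers):
        if not (r <= cx < ref.shape[1] - r and r <= cy < ref.shape[0] - r):
            continue
        tcx, tcy = cx + offs[i, 0], cy + offs[i, 1]
        # search region, clamped to the target image
        x0 = max(tcx - r - s, 0)
        x1 = min(tcx + r + s + 1, tw)
        y0 = max(tcy - r - s, 0)
        y1 = min(tcy + r + s + 1, th)
        if x1 - x0 < 2 * r + 1 or y1 - y0 < 2 * r + 1:
            continue
        subset = ref[cy - r: cy + r + 1, cx - r: cx + r + 1]
        if subset.std() < 1e-12:
            status[i] = STATUS_LOW_SCORE
            scores[i] = 0.0
            continue
        region = target[y0:y1, x0:x1]
        corr = match_template(region, subset, pad_input=False)
        dx_axis = np.arange(x0 + r, x1 - r) - cx
        dy_axis = np.arange(y0 + r, y1 - r) - cy
        if epipolar is not None:
            F, band = epipolar
            line = F @ np.array([cx, cy, 1.0])
            gx, gy = np.meshgrid(dx_axis + cx, dy_axis + cy)
            dist = np.abs(line[0] * gx + line[1] * gy + line[2]) / np.hypot(
                line[0], line[1])
            corr = np.where(dist <= band, corr, -np.inf)
            if not np.any(np.isfinite(corr)):
                status[i] = STATUS_LOW_SCORE
                continue
        dx, dy, score = _select_peak(corr, dx_axis, dy_axis)
        tgt_pts[i] = (cx + dx, cy + dy)
        scores[i] = score
        status[i] = STATUS_MATCHED if score >= score_threshold else STATUS_LOW_SCORE

    return MatchField(grid=grid, ref_points=grid.centers.astype(float),
                      target_points=tgt_pts, scores=scores,
                      status=status, pairing=pairing)


def _quadratic_peak_offset(c: np.ndarray) -> np.ndarray:
    """Subpixel offset of the extremum of a 3x3 correlation patch."""
    dx = 0.5 * (c[1, 2] - c[1, 0])
    dy = 0.5 * (c[2, 1] - c[0, 1])
    dxx = c[1, 2] - 2.0 * c[1, 1] + c[1, 0]
    dyy = c[2, 1] - 2.0 * c[1, 1] + c[0, 1]
    dxy = 0.25 * (c[2, 2] - c[2, 0] - c[0, 2] + c[0, 0])
    H = np.array([[dxx, dxy], [dxy, dyy]])
    g = np.array([dx, dy])
    det = np.linalg.det(H)
    if abs(det) < 1e-15:
        return np.zeros(2)
    off = -np.linalg.solve(H, g)
    return np.clip(off, -1.0, 1.0)


def _zncc_at(ref_sub_c: np.ndarray, ref_norm: float, target: np.ndarray,
             cx: int, cy: int, r: int) -> float:
    g = target[cy - r: cy + r + 1, cx - r: cx + r + 1]
    gc, gn = _zncc_normalise(g)
    if gn < 1e-12 or ref_norm < 1e-12:
        return 0.0
    return float(np.sum(ref_sub_c * gc) / (ref_norm * gn))


def refine_subpixel(field: MatchField, ref: np.ndarray, target: np.ndarray,
                    mode: str = "icgn", max_iter: int = 50,
                    tol: float = 1e-4,
                    score_threshold: float = DEFAULT_SCORE_THRESHOLD,
                    init_affine: np.ndarray | None = None) -> MatchField:
    """Refine integer matches to subpixel precision.

    ``mode``: 'quadratic' stops after the 3x3 correlation-surface fit;
    'icgn' (default) continues with affine IC-GN.  Convergence is declared
    when the warp-update norm (translation plus gradient terms scaled by
    the subset radius) drops below ``tol`` pixels; non-convergence or a
    singular Hessian marks the point diverged.  ``init_affine`` (a global
    2x2 matrix) seeds the affine part of every subset's shape function,
    which is what lets strongly foreshortened cross-camera pairs converge.
    """
    ref = np.asarray(ref, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    r = field.grid.radius
    n = len(field.grid)
    target_spline = ndimage.spline_filter(target, order=3)
    gy_full, gx_full = np.gradient(ref)

    dyy, dxx = np.mgrid[-r: r + 1, -r: r + 1]
    dxf, dyf = dxx.ravel().astype(float), dyy.ravel().astype(float)

    out_pts = field.target_points.copy()
    out_scores = field.scores.copy()
    out_status = field.status.copy()
    affines = np.tile(np.eye(2), (n, 1, 1))

    th, tw = target.shape
    for i in range(n):
        if field.status[i] != STATUS_MATCHED:
            continue
        cx, cy = field.grid.centers[i]
        txi, tyi = int(round(field.target_points[i, 0])), int(round(field.target_points[i, 1]))

        f = ref[cy - r: cy + r + 1, cx - r: cx + r + 1]
        fc, fn = _zncc_normalise(f)
        if fn < 1e-12:
            out_status[i] = STATUS_LOW_SCORE
            continue

        # stage 1: quadratic fit of the ZNCC surface around the integer peak
        if (r + 1 <= txi < tw - r - 1) and (r + 1 <= tyi < th - r - 1):
            c3 = np.array([[_zncc_at(fc, fn, target, txi + ddx, tyi + ddy, r)
                            for ddx in (-1, 0, 1)] for ddy in (-1, 0, 1)])
            off = _quadratic_peak_offset(c3)
        else:
            off = np.zeros(2)
        u = txi + off[0] - cx
        v = tyi + off[1] - cy

        if mode == "quadratic":
            out_pts[i] = (cx + u, cy + v)
            continue

        # stage 2: inverse-compositional Gauss-Newton, affine shape function
        gx = gx_full[cy - r: cy + r + 1, cx - r: cx + r + 1].ravel()
        gy = gy_full[cy - r: cy + r + 1, cx - r: cx + r + 1].ravel()
        J = np.column_stack([gx, gx * dxf, gx * dyf, gy, gy * dxf, gy * dyf])
        H = J.T @ J
        try:
            Hinv = np.linalg.inv(H)
        except np.linalg.LinAlgError:
            out_status[i] = STATUS_DIVERGED
            continue

        # warp: [x'; y'] = [1+ux, uy; vx, 1+vy] [dx; dy] + [cx+u; cy+v]
        W = np.eye(3)
        if init_affine is not None:
            W[:2, :2] = init_affine
        W[0, 2], W[1, 2] = u, v
        fcv = fc.ravel()
        converged = False
        score = out_scores[i]
        for _ in range(max_iter):
            wx = W[0, 0] * dxf + W[0, 1] * dyf + W[0, 2] + cx
            wy = W[1, 0] * dxf + W[1, 1] * dyf + W[1, 2] + cy
            if (wx.min() < 1 or wy.min() < 1 or wx.max() > tw - 2
                    or wy.max() > th - 2):
                out_status[i] = STATUS_OUT_OF_BOUNDS
                break
            g = map_coords(target_spline, wy, wx)
            gc, gn = _zncc_normalise(g)
            if gn < 1e-12:
                out_status[i] = STATUS_LOW_SCORE
                break
            score = float(np.dot(fcv, gc) / (fn * gn))
            err = fcv - (fn / gn) * gc
            dp = -Hinv @ (J.T @ err)
            dW = np.array([[1.0 + dp[1], dp[2], dp[0]],
                           [dp[4], 1.0 + dp[5], dp[3]],
                           [0.0, 0.0, 1.0]])
            try:
                W = W @ np.linalg.inv(dW)
            except np.linalg.LinAlgError:
                out_status[i] = STATUS_DIVERGED
                break
            upd = np.sqrt(dp[0]**2 + dp[3]**2
                          + (r * dp[1])**2 + (r * dp[2])**2
                          + (r * dp[4])**2 + (r * dp[5])**2)
            if upd < tol:
                converged = True
                break
        else:
            out_status[i] = STATUS_DIVERGED

        if converged:
            out_pts[i] = (cx + W[0, 2], cy + W[1, 2])
            out_scores[i] = score
            affines[i] = W[:2, :2]
            if score < score_threshold:
                out_status[i] = STATUS_LOW_SCORE

    return replace(field, target_points=out_pts, scores=out_scores,
                   status=out_status, affine=affines)


def map_coords(spline: np.ndarray, rows: np.ndarray, cols: np.ndarray
               ) -> np.ndarray:
    return ndimage.map_coordinates(spline, [rows, cols], order=3,
                                   prefilter=False)


def estimate_affine_motion(ref: np.ndarray, target: np.ndarray,
                           scale: float = 0.25, radius: int = 10,
                           spacing: int = 10,
                           search_frac: float = 0.25,
                           score_threshold: float = 0.5) -> np.ndarray:
    """Coarse global affine motion (3x2 matrix A: [x, y, 1] @ A -> target).

    Integer matching on downscaled copies followed by a trimmed least
    squares affine fit; used only to seed full-resolution searches.
    """
    small_ref = rescale(ref, scale, anti_aliasing=True)
    small_tgt = rescale(target, scale, anti_aliasing=True)
    grid = SubsetGrid.regular(small_ref.shape, radius, spacing,
                              margin=radius + 1)
    search = max(int(search_frac * small_ref.shape[1]), 8)
    f = match_integer(small_ref, small_tgt, grid, search,
                      score_threshold=score_threshold)
    ok = f.matched
    if ok.sum() < 6:
        raise MatchingFailure("coarse alignment failed: too few seed matches")
    src = f.ref_points[ok] / scale
    dst = f.target_points[ok] / scale
    X = np.column_stack([src, np.ones(len(src))])
    for _ in range(3):
        A, *_ = np.linalg.lstsq(X, dst, rcond=None)
        resid = np.linalg.norm(X @ A - dst, axis=1)
        keep = resid <= max(3.0 * np.median(resid), 2.0 / scale)
        if keep.all():
            break
        X, dst = X[keep], dst[keep]
    return A


def match_pair(ref: np.ndarray, target: np.ndarray, grid: SubsetGrid,
               fine_search: int = 6, pairing: str = "",
               epipolar: tuple[np.ndarray, float] | None = None,
               score_threshold: float = DEFAULT_SCORE_THRESHOLD,
               integer_score_threshold: float = 0.25,
               coarse_scale: float = 0.25) -> MatchField:
    """Coarse-to-fine matching of one image pair with IC-GN refinement.

    The integer stage accepts weaker peaks (``integer_score_threshold``)
    because unwarped subsets under foreshortening correlate imperfectly;
    the final ``score_threshold`` is enforced on the IC-GN score, whose
    affine part is seeded with the global motion estimate.
    """
    A = estimate_affine_motion(ref, target, scale=coarse_scale)
    pred = np.column_stack([grid.centers, np.ones(len(grid))]) @ A
    init = pred - grid.centers
    f = match_integer(ref, target, grid, fine_search, init_offsets=init,
                      epipolar=epipolar,
                      score_threshold=integer_score_threshold,
                      pairing=pairing)
    return refine_subpixel(f, ref, target, score_threshold=score_threshold,
                           init_affine=A[:2, :2].T)


@dataclass
class PoseChainResult:
    """Pixel tracks of grid points through two cameras and two poses."""

    grid: SubsetGrid
    ok: np.ndarray                   # survivors
    px_ref_a: np.ndarray
    px_ref_b: np.ndarray
    px_def_a: np.ndarray
    px_def_b: np.ndarray
    drop_reason: np.ndarray
    fields: dict = field(default_factory=dict)

    @property
    def n_tracked(self) -> int:
        return int(self.ok.sum())


def track_pose_chain(ref_images: list[np.ndarray],
                     def_images: list[np.ndarray],
                     grid: SubsetGrid,
                     fundamental: np.ndarray | None = None,
                     epipolar_band_px: float = 20.0,
                     fine_search: int = 6,
                     score_threshold: float = DEFAULT_SCORE_THRESHOLD,
                     min_track_fraction: float = 0.5) -> PoseChainResult:
    """Track grid points across cameras (A, B) and poses (ref, deformed).

    Matches A_ref->B_ref (cross-camera), A_ref->A_def (pose), then
    A_def->B_def seeded at the rounded pose-matched positions, with a
    first-order correction through each subset's fitted affine so every
    surviving point has subpixel coordinates in all four images.  Raises
    :class:`MatchingFailure` if fewer than ``min_track_fraction`` of the
    grid survives — the regime where reliable image correlations cannot be
    found.
    """
    ref_a, ref_b = ref_images
    def_a, def_b = def_images
    epi = (fundamental, epipolar_band_px) if fundamental is not None else None

    f_ab = match_pair(ref_a, ref_b, grid, fine_search, pairing="camA-camB@ref",
                      epipolar=epi, score_threshold=score_threshold)
    f_pose = match_pair(ref_a, def_a, grid, fine_search, pairing="camA:ref-def",
                        score_threshold=score_threshold)

    ok01 = f_ab.matched & f_pose.matched
    centers2 = np.round(np.where(ok01[:, None], f_pose.target_points,
                                 grid.centers)).astype(int)
    grid2 = SubsetGrid(centers2, grid.radius, grid.spacing)
    f_def = match_pair(def_a, def_b, grid2, fine_search,
                       pairing="camA-camB@def", epipolar=epi,
                       score_threshold=score_threshold)

    ok = ok01 & f_def.matched
    # carry the exact (subpixel) A_def position through the local affine of
    # the A_def->B_def subset
    delta = f_pose.target_points - centers2
    corr = np.einsum("nij,nj->ni",
                     f_def.affine if f_def.affine is not None
                     else np.tile(np.eye(2), (len(grid), 1, 1)),
                     delta)
    px_def_b = f_def.target_points + corr

    reason = np.full(len(grid), "", dtype=object)
    for name, fld in (("cross_ref", f_ab), ("pose", f_pose), ("cross_def", f_def)):
        bad = fld.status != STATUS_MATCHED
        reason[bad & (reason == "")] = name + ":" + fld.status[bad & (reason == "")]

    frac = ok.mean() if len(ok) else 0.0
    if frac < min_track_fraction:
        raise MatchingFailure(
            f"only {frac:.0%} of grid subsets tracked (need "
            f">= {min_track_fraction:.0%}); reliable image correlations "
            "could not be found")

    return PoseChainResult(
        grid=grid, ok=ok,
        px_ref_a=grid.centers.astype(float),
        px_ref_b=f_ab.target_points,
        px_def_a=f_pose.target_points,
        px_def_b=px_def_b,
        drop_reason=reason,
        fields={"cross_ref": f_ab, "pose": f_pose, "cross_def": f_def},
    )


def fundamental_from_cameras(cam_a, cam_b) -> np.ndarray:
    """Fundamental matrix mapping camera-A pixels to epipolar lines in B."""
    R = cam_b.rotation @ cam_a.rotation.T
    t = cam_b.translation - R @ cam_a.translation
    tx = np.array([[0, -t[2], t[1]], [t[2], 0, -t[0]], [-t[1], t[0], 0]])
    E = tx @ R
    F = np.linalg.inv(cam_b.K).T @ E @ np.linalg.inv(cam_a.K)
    return F / F[2, 2] if abs(F[2, 2]) > 1e-12 else F
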