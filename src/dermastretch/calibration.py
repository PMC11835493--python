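"""Stereo camera calibration from planar checkerboard views.

Implements the standard planar-target workflow: per-view homography
estimation, closed-form intrinsics from the homography constraints
(Zhang's method), per-view extrinsics, then joint nonlinear refinement of
both cameras' intrinsics, the relative pose and all board poses by
minimising reprojection error.  Checkerboard corners can come from images
(synthetic renders are detected with scikit-image) or be supplied directly
as ordered arrays, which is how noise-controlled calibration experiments
are run.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares
from scipy.spatial.transform import Rotation
from scipy.ndimage import gaussian_filter
from skimage.feature import corner_peaks, corner_subpix

from .camera import CameraModel

__all__ = [
    "CheckerboardSpec",
    "CalibrationError",
    "CalibrationResult",
    "board_corners",
    "render_checkerboard",
    "detect_checkerboard",
    "calibrate_stereo",
    "synthetic_stereo_calibration",
]


class CalibrationError(RuntimeError):
    """Calibration could not be completed (too few usable views)."""


@dataclass(frozen=True)
class CheckerboardSpec:
    """Planar target: ``rows`` x ``cols`` *inner* corners, squares in mm."""

    rows: int = 6
    cols: int = 9
    square_mm: float = 10.0


@dataclass
class CalibrationResult:
    """Fitted stereo pair; camera A sits at the origin of the fit frame."""

    camera_pair: tuple[CameraModel, CameraModel]
    reprojection_error: float        # RMS over all corners and both views, px
    n_views: int

    @property
    def baseline_mm(self) -> float:
        a, b = self.camera_pair
        return float(np.linalg.norm(a.center - b.center))


def board_corners(spec: CheckerboardSpec) -> np.ndarray:
    """Inner-corner coordinates (N, 3) in the board frame (z = 0), mm."""
    jj, ii = np.meshgrid(np.arange(spec.cols), np.arange(spec.rows))
    pts = np.column_stack([
        jj.ravel() * spec.square_mm,
        ii.ravel() * spec.square_mm,
        np.zeros(spec.rows * spec.cols),
    ])
    return pts


def render_checkerboard(spec: CheckerboardSpec, camera: CameraModel,
                        board_rotation: np.ndarray, board_translation: np.ndarray,
                        margin_squares: int = 1) -> np.ndarray:
    """Render the board through a pinhole camera with anti-aliased edges.

    The board plane to image map is the homography H = K [r1 r2 t]; pixels
    are inverse-mapped to board coordinates and shaded by the parity of the
    square index, with a ~1 px linear edge ramp.
    """
    R = np.asarray(board_rotation, dtype=float)
    t = np.asarray(board_translation, dtype=float)
    Rc = camera.rotation @ R
    tc = camera.rotation @ t + camera.translation
    H = camera.K @ np.column_stack([Rc[:, 0], Rc[:, 1], tc])
    Hinv = np.linalg.inv(H)

    w, h = camera.image_size
    xx, yy = np.meshgrid(np.arange(w, dtype=float), np.arange(h, dtype=float))
    pts = np.stack([xx, yy, np.ones_like(xx)])
    uvw = np.einsum("ij,jhw->ihw", Hinv, pts)
    u = uvw[0] / uvw[2]
    v = uvw[1] / uvw[2]

    # approximate board-units-per-pixel for anti-aliasing width
    s = spec.square_mm
    # soft square-wave via distance to nearest grid line in square units
    def soft_parity(x):
        cell = np.floor(x / s)
        frac = x / s - cell
        edge = np.minimum(frac, 1.0 - frac)          # distance to edge, cells
        ramp = np.clip(edge * s / _board_px_scale(Hinv, camera) * 2.0, 0.0, 1.0)
        return cell.astype(int), ramp

    cu, ru = soft_parity(u)
    cv, rv = soft_parity(v)
    parity = (cu + cv) % 2
    shade = np.where(parity == 0, 0.1, 0.95)
    # blend across the nearest edge for anti-aliasing
    other = np.where(parity == 0, 0.95, 0.1)
    ramp = np.minimum(ru, rv)
    img = other + (shade - other) * (0.5 + 0.5 * ramp)

    # the window spans whole squares so that the only four-square junctions
    # are the rows x cols inner corners at integer square coordinates
    lo_u, hi_u = -margin_squares * s, (spec.cols - 1 + margin_squares) * s
    lo_v, hi_v = -margin_squares * s, (spec.rows - 1 + margin_squares) * s
    inside = (u >= lo_u) & (u < hi_u) & (v >= lo_v) & (v < hi_v)
    return np.where(inside, img, 0.6)


def _board_px_scale(Hinv: np.ndarray, camera: CameraModel) -> float:
    cx, cy = camera.principal_point
    p = Hinv @ np.array([cx, cy, 1.0])
    p1 = Hinv @ np.array([cx + 1.0, cy, 1.0])
    return float(np.linalg.norm(p1[:2] / p1[2] - p[:2] / p[2])) or 1.0


def detect_checkerboard(image: np.ndarray, spec: CheckerboardSpec
                        ) -> np.ndarray | None:
    """Detect and grid-order the inner corners of a rendered board.

    Returns an (rows*cols, 2) array of (x, y) pixel coordinates in
    row-major board order, or None if detection fails.  Ordering uses the
    four extremal corners to seed a homography from grid indices to the
    image, then snaps every predicted node to its nearest detection.
    """
    n_expected = spec.rows * spec.cols
    # saddle-point response: checkerboard inner corners are strong saddles
    # of the intensity surface (negative Hessian determinant), a criterion
    # that is invariant to in-plane rotation of the board
    img = gaussian_filter(np.asarray(image, dtype=float), 1.5)
    ixx = gaussian_filter(img, 2.0, order=(0, 2))
    iyy = gaussian_filter(img, 2.0, order=(2, 0))
    ixy = gaussian_filter(img, 2.0, order=(1, 1))
    resp = -(ixx * iyy - ixy**2)
    peaks = corner_peaks(resp, min_distance=8, threshold_rel=0.2,
                         num_peaks=n_expected)
    if len(peaks) < n_expected:
        return None
    refined = corner_subpix(image, peaks, window_size=9)
    bad = np.isnan(refined[:, 0])
    refined[bad] = peaks[bad]
    pts = np.column_stack([refined[:, 1], refined[:, 0]])     # (x, y)

    # the four extremal detections traverse the board's corner quad
    # clockwise; which of them is the board's (0, 0) corner is ambiguous,
    # so all four cyclic assignments are tried and the best-snapping one
    # wins (a checkerboard's orientation is only defined modulo 180 deg
    # anyway, which is irrelevant for calibration)
    sums = pts[:, 0] + pts[:, 1]
    diffs = pts[:, 0] - pts[:, 1]
    quad = np.array([pts[np.argmin(sums)], pts[np.argmax(diffs)],
                     pts[np.argmax(sums)], pts[np.argmin(diffs)]])
    grid_ref = np.array([[0, 0], [spec.cols - 1, 0],
                         [spec.cols - 1, spec.rows - 1], [0, spec.rows - 1]],
                        dtype=float)
    jj, ii = np.meshgrid(np.arange(spec.cols), np.arange(spec.rows))
    nodes = np.column_stack([jj.ravel(), ii.ravel()]).astype(float)

    # square centres (board coords) and their colour parity; cell (0, 0) is
    # dark by convention, which disambiguates the 180-degree rotation of
    # the grid whenever rows + cols is odd
    sj, si = np.meshgrid(np.arange(-1, spec.cols), np.arange(-1, spec.rows))
    cells = np.column_stack([sj.ravel() + 0.5, si.ravel() + 0.5])
    parity = ((sj + si) % 2).ravel()

    candidates = []
    for shift in range(4):
        H = _homography_dlt(grid_ref, np.roll(quad, -shift, axis=0))
        pred = _apply_homography(H, nodes)
        tol = 0.4 * _median_spacing(pred, spec)
        ordered = np.empty((n_expected, 2))
        used: set[int] = set()
        cost = 0.0
        for k, p in enumerate(pred):
            d = np.linalg.norm(pts - p, axis=1)
            j = int(np.argmin(d))
            if j in used or d[j] > tol:
                cost = np.inf
                break
            used.add(j)
            ordered[k] = pts[j]
            cost += d[j]
        if not np.isfinite(cost):
            continue
        centres = _apply_homography(H, cells)
        h_img, w_img = image.shape
        inb = ((centres[:, 0] > 1) & (centres[:, 0] < w_img - 2)
               & (centres[:, 1] > 1) & (centres[:, 1] < h_img - 2))
        vals = img[np.round(centres[inb, 1]).astype(int),
                   np.round(centres[inb, 0]).astype(int)]
        polarity = float(np.mean(vals[parity[inb] == 0])
                         - np.mean(vals[parity[inb] == 1]))
        candidates.append((polarity >= 0, cost, ordered))
    if not candidates:
        return None
    # prefer correct colour polarity (dark cell at (0, 0)), then snap cost
    candidates.sort(key=lambda c: (c[0], c[1]))
    return candidates[0][2]


def _median_spacing(pred: np.ndarray, spec: CheckerboardSpec) -> float:
    row = pred[: spec.cols]
    return float(np.median(np.linalg.norm(np.diff(row, axis=0), axis=1)))


def _normalise_points(pts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    c = pts.mean(axis=0)
    s = np.sqrt(2.0) / max(np.mean(np.linalg.norm(pts - c, axis=1)), 1e-12)
    T = np.array([[s, 0, -s * c[0]], [0, s, -s * c[1]], [0, 0, 1.0]])
    return (pts - c) * s, T


def _homography_dlt(src: np.ndarray, dst: np.ndarray) -> np.ndarray:
    """Direct linear transform homography with Hartley normalisation."""
    src_n, Ts = _normalise_points(np.asarray(src, dtype=float))
    dst_n, Td = _normalise_points(np.asarray(dst, dtype=float))
    n = len(src)
    A = np.zeros((2 * n, 9))
    x, y = src_n[:, 0], src_n[:, 1]
    xp, yp = dst_n[:, 0], dst_n[:, 1]
    A[0::2, 0], A[0::2, 1], A[0::2, 2] = -x, -y, -1
    A[0::2, 6], A[0::2, 7], A[0::2, 8] = x * xp, y * xp, xp
    A[1::2, 3], A[1::2, 4], A[1::2, 5] = -x, -y, -1
    A[1::2, 6], A[1::2, 7], A[1::2, 8] = x * yp, y * yp, yp
    _, _, vt = np.linalg.svd(A)
    Hn = vt[-1].reshape(3, 3)
    H = np.linalg.inv(Td) @ Hn @ Ts
    return H / H[2, 2]


def _apply_homography(H: np.ndarray, pts: np.ndarray) -> np.ndarray:
    p = np.column_stack([pts, np.ones(len(pts))]) @ H.T
    return p[:, :2] / p[:, 2:3]


def _intrinsics_from_homographies(Hs: list[np.ndarray]) -> np.ndarray:
    """Zhang's closed-form intrinsics from >= 3 plane homographies."""
    def v(H, i, j):
        return np.array([
            H[0, i] * H[0, j],
            H[0, i] * H[1, j] + H[1, i] * H[0, j],
            H[1, i] * H[1, j],
            H[2, i] * H[0, j] + H[0, i] * H[2, j],
            H[2, i] * H[1, j] + H[1, i] * H[2, j],
            H[2, i] * H[2, j],
        ])

    V = []
    for H in Hs:
        V.append(v(H, 0, 1))
        V.append(v(H, 0, 0) - v(H, 1, 1))
    V = np.asarray(V)
    _, _, vt = np.linalg.svd(V)
    b11, b12, b22, b13, b23, b33 = vt[-1]
    cy = (b12 * b13 - b11 * b23) / (b11 * b22 - b12**2)
    lam = b33 - (b13**2 + cy * (b12 * b13 - b11 * b23)) / b11
    fx = np.sqrt(lam / b11)
    fy = np.sqrt(lam * b11 / (b11 * b22 - b12**2))
    skew = -b12 * fx**2 * fy / lam
    cx = skew * cy / fx - b13 * fx**2 / lam
    return np.array([[fx, skew, cx], [0, fy, cy], [0, 0, 1.0]])


def _extrinsics_from_homography(K: np.ndarray, H: np.ndarray
                                ) -> tuple[np.ndarray, np.ndarray]:
    Kinv = np.linalg.inv(K)
    h1, h2, h3 = H[:, 0], H[:, 1], H[:, 2]
    lam = 1.0 / np.linalg.norm(Kinv @ h1)
    r1 = lam * (Kinv @ h1)
    r2 = lam * (Kinv @ h2)
    t = lam * (Kinv @ h3)
    R = np.column_stack([r1, r2, np.cross(r1, r2)])
    u, _, vt = np.linalg.svd(R)
    R = u @ vt
    if np.linalg.det(R) < 0:
        R = -R
    if t[2] < 0:                       # board must be in front of the camera
        R, t = -R, -t
        R[:, 2] = np.cross(R[:, 0], R[:, 1])
    return R, t


def calibrate_stereo(views, board: CheckerboardSpec,
                     image_size: tuple[int, int] | None = None,
                     from_corners: bool = False) -> CalibrationResult:
    """Calibrate a camera pair from checkerboard views.

    ``views`` is a list of (view_a, view_b) pairs: images when
    ``from_corners`` is False, or pre-ordered corner arrays (N, 2) when
    True.  At least 3 usable views are required; views whose detection
    fails are excluded with a warning.
    """
    obj = board_corners(board)[:, :2]
    corners_a, corners_b = [], []
    for k, (va, vb) in enumerate(views):
        if from_corners:
            ca, cb = np.asarray(va, dtype=float), np.asarray(vb, dtype=float)
        else:
            ca = detect_checkerboard(np.asarray(va, dtype=float), board)
            cb = detect_checkerboard(np.asarray(vb, dtype=float), board)
            if image_size is None:
                image_size = (va.shape[1], va.shape[0])
        if ca is None or cb is None:
            warnings.warn(f"checkerboard detection failed in view {k}; excluded")
            continue
        corners_a.append(ca)
        corners_b.append(cb)
    n_views = len(corners_a)
    if n_views < 3:
        raise CalibrationError(f"only {n_views} usable views; need at least 3")
    if image_size is None:
        raise ValueError("image_size is required when calibrating from corners")

    Ha = [_homography_dlt(obj, c) for c in corners_a]
    Hb = [_homography_dlt(obj, c) for c in corners_b]
    Ka = _intrinsics_from_homographies(Ha)
    Kb = _intrinsics_from_homographies(Hb)

    poses_a = [_extrinsics_from_homography(Ka, H) for H in Ha]
    poses_b = [_extrinsics_from_homography(Kb, H) for H in Hb]
    # relative pose: average over views of pose_b o inverse(pose_a)
    rel_rots = [Rb @ Ra.T for (Ra, _), (Rb, _) in zip(poses_a, poses_b)]
    rel_R = Rotation.from_matrix(rel_rots).mean().as_matrix()
    rel_t = np.mean([tb - (Rb @ Ra.T) @ ta
                     for (Ra, ta), (Rb, tb) in zip(poses_a, poses_b)], axis=0)

    # joint refinement
    def pack():
        p = [Ka[0, 0], Ka[1, 1], Ka[0, 2], Ka[1, 2],
             Kb[0, 0], Kb[1, 1], Kb[0, 2], Kb[1, 2]]
        p += list(Rotation.from_matrix(rel_R).as_rotvec()) + list(rel_t)
        for R, t in poses_a:
            p += list(Rotation.from_matrix(R).as_rotvec()) + list(t)
        return np.array(p)

    objh = np.column_stack([obj, np.zeros(len(obj))])

    def unpack(p):
        ka = p[0:4]
        kb = p[4:8]
        Rr = Rotation.from_rotvec(p[8:11]).as_matrix()
        tr = p[11:14]
        poses = []
        for i in range(n_views):
            q = p[14 + 6 * i: 20 + 6 * i]
            poses.append((Rotation.from_rotvec(q[:3]).as_matrix(), q[3:6]))
        return ka, kb, Rr, tr, poses

    def proj(k, R, t, pts):
        pc = pts @ R.T + t
        uv = pc[:, :2] / pc[:, 2:3]
        return np.column_stack([k[0] * uv[:, 0] + k[2], k[1] * uv[:, 1] + k[3]])

    def residuals(p):
        ka, kb, Rr, tr, poses = unpack(p)
        out = []
        for i, (R, t) in enumerate(poses):
            out.append(proj(ka, R, t, objh) - corners_a[i])
            out.append(proj(kb, Rr @ R, Rr @ t + tr, objh) - corners_b[i])
        return np.concatenate(out).ravel()

    sol = least_squares(residuals, pack(), method="lm", max_nfev=400)
    ka, kb, Rr, tr, _ = unpack(sol.x)
    rms = float(np.sqrt(np.mean(sol.fun**2)))

    cam_a = CameraModel(focal=(ka[0], ka[1]), principal_point=(ka[2], ka[3]),
                        image_size=image_size)
    cam_b = CameraModel(focal=(kb[0], kb[1]), principal_point=(kb[2], kb[3]),
                        image_size=image_size, rotation=Rr, translation=tr)
    return CalibrationResult(camera_pair=(cam_a, cam_b),
                             reprojection_error=rms, n_views=n_views)


def _board_poses(n_views: int, distance_mm: float, rng: np.random.Generator,
                 board: CheckerboardSpec) -> list[tuple[np.ndarray, np.ndarray]]:
    """Varied board placements in front of the rig (world frame)."""
    poses = []
    cx = (board.cols - 1) * board.square_mm / 2.0
    cy = (board.rows - 1) * board.square_mm / 2.0
    # strong tilts and a deep sweep along the optical axis: with a
    # narrow-field rig a planar target constrains focal length (and hence
    # reconstruction scale) only through perspective variation
    for _ in range(n_views):
        tilt = Rotation.from_euler(
            "xyz", rng.uniform([-35, -35, -15], [35, 35, 15]), degrees=True)
        offset = rng.uniform([-8, -6, -80], [8, 6, 80])
        R = tilt.as_matrix()
        # board centre lands near the rig's fixation point
        t = offset - R @ np.array([cx, cy, 0.0])
        poses.append((R, t))
    return poses


def synthetic_stereo_calibration(cam_a: CameraModel, cam_b: CameraModel,
                                 board: CheckerboardSpec | None = None,
                                 n_views: int = 10,
                                 corner_noise_px: float = 0.0,
                                 seed: int = 0,
                                 ) -> tuple[CalibrationResult,
                                            tuple[CameraModel, CameraModel]]:
    """Calibrate a synthetic rig pair from noisy projected board corners.

    Boards are placed at varied poses in front of the true cameras, their
    corners projected exactly and perturbed with isotropic Gaussian noise
    of ``corner_noise_px``; :func:`calibrate_stereo` then fits the pair.
    Returns the raw :class:`CalibrationResult` (camera A at the fit origin)
    and the fitted pair re-expressed in the true world frame by anchoring
    camera A at its true pose — the form needed to triangulate points
    rendered with the true cameras against world-frame ground truth.
    """
    # default board sized to the rig's ~80 x 60 mm field of view
    board = board or CheckerboardSpec(rows=6, cols=9, square_mm=6.0)
    rng = np.random.default_rng(seed)
    obj = board_corners(board)
    views = []
    for R, t in _board_poses(n_views, 300.0, rng, board):
        world = obj @ R.T + t
        pa = cam_a.project(world)
        pb = cam_b.project(world)
        pa = pa + rng.normal(0.0, corner_noise_px, pa.shape)
        pb = pb + rng.normal(0.0, corner_noise_px, pb.shape)
        views.append((pa, pb))
    result = calibrate_stereo(views, board, image_size=cam_a.image_size,
                              from_corners=True)
    fa, fb = result.camera_pair
    # anchor fitted camera A at the true camera-A pose
    world_a = CameraModel(fa.focal, fa.principal_point, fa.image_size,
                          cam_a.rotation, cam_a.translation)
    Rb = fb.rotation @ cam_a.rotation
    tb = fb.rotation @ cam_a.translation + fb.translation
    world_b = CameraModel(fb.focal, fb.principal_point, fb.image_size, Rb, tb)
    return result, (world_a, world_b)
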