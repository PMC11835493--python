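"""Pinhole camera model, multi-camera rig synthesis and stereo triangulation.

Conventions (used everywhere in the package): right-handed coordinates, the
camera looks down its +z axis; pixel (0, 0) is the top-left of the image
and pixel centres sit at integer coordinates.  A world point X maps to
camera coordinates X_c = R X + t and to pixels via the intrinsic matrix
K = [[fx, 0, cx], [0, fy, cy], [0, 0, 1]], optionally after radial
distortion with up to two coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml
from scipy.spatial.transform import Rotation

__all__ = [
    "CameraModel",
    "ProjectionError",
    "look_at",
    "square_rig",
    "triangulate",
    "save_cameras",
    "load_cameras",
]


class ProjectionError(ValueError):
    """A point lies at or behind the camera plane."""


@dataclass
class CameraModel:
    """Calibrated pinhole camera.

    focal, principal_point and image_size are in pixels; translation in mm.
    ``distortion`` holds radial coefficients (k1, k2); empty means none.
    """

    focal: tuple[float, float]
    principal_point: tuple[float, float]
    image_size: tuple[int, int]                 # (width, height)
    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))
    distortion: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)
        if self.focal[0] <= 0 or self.focal[1] <= 0:
            raise ValueError("focal lengths must be positive")
        if not np.allclose(self.rotation @ self.rotation.T, np.eye(3), atol=1e-8):
            raise ValueError("rotation must be orthonormal")
        if np.linalg.det(self.rotation) < 0:
            raise ValueError("rotation must have determinant +1")

    @property
    def K(self) -> np.ndarray:
        fx, fy = self.focal
        cx, cy = self.principal_point
        return np.array([[fx, 0.0, cx], [0.0, fy, cy], [0.0, 0.0, 1.0]])

    @property
    def center(self) -> np.ndarray:
        """Camera centre in world coordinates."""
        return -self.rotation.T @ self.translation

    @property
    def P(self) -> np.ndarray:
        """3x4 projection matrix (undistorted model)."""
        return self.K @ np.column_stack([self.rotation, self.translation])

    def to_camera(self, points: np.ndarray) -> np.ndarray:
        points = np.atleast_2d(np.asarray(points, dtype=float))
        return points @ self.rotation.T + self.translation

    def project(self, points: np.ndarray, strict: bool = True) -> np.ndarray:
        """World points (N, 3) -> pixel coordinates (N, 2)."""
        pc = self.to_camera(points)
        z = pc[:, 2]
        if strict and np.any(z <= 1e-9):
            raise ProjectionError("point at or behind the camera plane")
        with np.errstate(divide="ignore", invalid="ignore"):
            x, y = pc[:, 0] / z, pc[:, 1] / z
        if self.distortion:
            r2 = x * x + y * y
            radial = 1.0
            for i, k in enumerate(self.distortion):
                radial = radial + k * r2 ** (i + 1)
            x, y = x * radial, y * radial
        fx, fy = self.focal
        cx, cy = self.principal_point
        return np.column_stack([fx * x + cx, fy * y + cy])

    def pixel_footprint_mm(self, distance_mm: float) -> float:
        """Size in mm of a central pixel at the given working distance."""
        return distance_mm / float(self.focal[0])

    def with_pose(self, rotation: np.ndarray, translation: np.ndarray) -> "CameraModel":
        return CameraModel(self.focal, self.principal_point, self.image_size,
                           rotation, translation, self.distortion)


def look_at(position: np.ndarray, target: np.ndarray,
            up: np.ndarray = (0.0, -1.0, 0.0), *,
            focal_px: float, image_size: tuple[int, int],
            distortion: tuple[float, ...] = ()) -> CameraModel:
    """Camera at ``position`` with its +z axis through ``target``.

    The default ``up`` makes image rows increase along world -y, matching
    the top-left pixel-origin convention for a patch in the world xy plane.
    """
    position = np.asarray(position, dtype=float)
    z = np.asarray(target, dtype=float) - position
    z = z / np.linalg.norm(z)
    up = np.asarray(up, dtype=float)
    x = np.cross(up, z)
    if np.linalg.norm(x) < 1e-12:
        raise ValueError("up vector is parallel to the viewing direction")
    x = x / np.linalg.norm(x)
    y = np.cross(z, x)
    R = np.stack([x, y, z])            # rows = camera axes in world frame
    t = -R @ position
    w, h = image_size
    return CameraModel(
        focal=(focal_px, focal_px),
        principal_point=((w - 1) / 2.0, (h - 1) / 2.0),
        image_size=(int(w), int(h)),
        rotation=R, translation=t, distortion=distortion,
    )


def square_rig(side_mm: float = 200.0, distance_mm: float = 300.0,
               focal_px: float = 3000.0,
               image_size: tuple[int, int] = (800, 600),
               target: np.ndarray = (0.0, 0.0, 0.0)) -> list[CameraModel]:
    """Four cameras at the corners of a square, all aimed at ``target``.

    Mirrors the study's rig: a rough 20 x 20 cm square of cameras about
    30 cm from the skin patch, each central pixel covering ~0.1 x 0.1 mm
    (focal 3000 px at 300 mm).  The patch lives in the world z = 0 plane;
    cameras sit at z = +distance looking down.
    """
    half = side_mm / 2.0
    target = np.asarray(target, dtype=float)
    corners = [(-half, -half), (half, -half), (-half, half), (half, half)]
    return [
        look_at(target + np.array([dx, dy, distance_mm]), target,
                focal_px=focal_px, image_size=image_size)
        for dx, dy in corners
    ]


def triangulate(pixels_a: np.ndarray, pixels_b: np.ndarray,
                cam_a: CameraModel, cam_b: CameraModel,
                min_ray_angle_deg: float = 0.1,
                ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Linear least-squares (DLT) triangulation of matched pixel pairs.

    Returns ``(points, residuals, degenerate)``: world points (N, 3), the
    mean reprojection distance over the two views in pixels, and a flag for
    pairs whose viewing rays are closer than ``min_ray_angle_deg`` to
    parallel (their solution is unreliable).
    """
    xa = np.atleast_2d(np.asarray(pixels_a, dtype=float))
    xb = np.atleast_2d(np.asarray(pixels_b, dtype=float))
    if xa.shape != xb.shape:
        raise ValueError("pixel arrays must have matching shapes")
    if np.linalg.norm(cam_a.center - cam_b.center) < 1e-9:
        raise ValueError("cameras must have distinct centres")
    Pa, Pb = cam_a.P, cam_b.P

    n = xa.shape[0]
    # stack the four DLT rows per point and solve via SVD, vectorised
    A = np.empty((n, 4, 4))
    A[:, 0] = xa[:, 0, None] * Pa[2] - Pa[0]
    A[:, 1] = xa[:, 1, None] * Pa[2] - Pa[1]
    A[:, 2] = xb[:, 0, None] * Pb[2] - Pb[0]
    A[:, 3] = xb[:, 1, None] * Pb[2] - Pb[1]
    # row normalisation improves conditioning
    A = A / np.linalg.norm(A, axis=2, keepdims=True)
    _, _, vt = np.linalg.svd(A)
    X = vt[:, 3, :]
    points = X[:, :3] / X[:, 3:4]

    ra = points - cam_a.center
    rb = points - cam_b.center
    cosang = np.einsum("ij,ij->i", ra, rb) / (
        np.linalg.norm(ra, axis=1) * np.linalg.norm(rb, axis=1))
    angle = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    degenerate = angle < min_ray_angle_deg

    res_a = np.linalg.norm(cam_a.project(points, strict=False) - xa, axis=1)
    res_b = np.linalg.norm(cam_b.project(points, strict=False) - xb, axis=1)
    residuals = 0.5 * (res_a + res_b)
    return points, residuals, degenerate


def rigid_align(source: np.ndarray, target: np.ndarray
                ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Least-squares rigid registration (Kabsch, no scaling) of point sets.

    Returns ``(aligned, R, t)`` with ``aligned = source @ R.T + t`` closest
    to ``target``.  Used when comparing a reconstruction to ground truth:
    a fitted stereo calibration cannot observe the absolute world pose, so
    only the shape of the reconstruction is meaningful; scale and warp
    errors are *not* removed.
    """
    src = np.asarray(source, dtype=float)
    dst = np.asarray(target, dtype=float)
    cs, cd = src.mean(axis=0), dst.mean(axis=0)
    H = (src - cs).T @ (dst - cd)
    u, _, vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    R = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    t = cd - R @ cs
    return src @ R.T + t, R, t


def _camera_to_dict(cam: CameraModel) -> dict:
    return {
        "focal": [float(f) for f in cam.focal],
        "principal_point": [float(c) for c in cam.principal_point],
        "image_size": [int(s) for s in cam.image_size],
        "rotation_quat_xyzw": [float(q) for q in Rotation.from_matrix(cam.rotation).as_quat()],
        "translation_mm": [float(t) for t in cam.translation],
        "distortion": [float(k) for k in cam.distortion],
    }


def _camera_from_dict(d: dict) -> CameraModel:
    return CameraModel(
        focal=tuple(d["focal"]),
        principal_point=tuple(d["principal_point"]),
        image_size=tuple(d["image_size"]),
        rotation=Rotation.from_quat(d["rotation_quat_xyzw"]).as_matrix(),
        translation=np.asarray(d["translation_mm"], dtype=float),
        distortion=tuple(d.get("distortion", ())),
    )


def save_cameras(path, cameras: list[CameraModel], extra: dict | None = None) -> None:
    doc = {"cameras": [_camera_to_dict(c) for c in cameras]}
    if extra:
        doc.update(extra)
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_cameras(path) -> list[CameraModel]:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return [_camera_from_dict(d) for d in doc["cameras"]]
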