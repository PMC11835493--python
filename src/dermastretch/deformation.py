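"""Analytic surface deformations with closed-form ground-truth strain.

A :class:`DeformationModel` maps flat material coordinates (u, v) in mm to
deformed 3-D positions in mm and exposes the exact membrane strain of that
map, computed from the first fundamental form (metric tensor) of the
deformed surface relative to the flat reference.  These models stand in
for the physical manipulations used to validate the imaging chain: rigid
repositioning, uniform uniaxial stretch, linearly ramped stretch and
out-of-plane bulging/contraction of a skin-like patch.

Stretch is reported as engineering stretch in percent: 100 * (lambda - 1),
with lambda_i = sqrt(1 + 2 e_i) for principal Green-Lagrange strains e_i.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "SurfacePatch",
    "DeformationModel",
    "GroundTruthStrain",
    "identity_model",
    "rigid_motion",
    "uniaxial_stretch",
    "ramp_stretch",
    "bulge",
    "strain_from_jacobian",
]


@dataclass(frozen=True)
class SurfacePatch:
    """Rectangular material domain of a skin-like patch, in mm.

    ``domain`` is (u_min, u_max, v_min, v_max).  The undeformed embedding is
    flat: (u, v) -> (u, v, 0).
    """

    domain: tuple[float, float, float, float]

    @property
    def width(self) -> float:
        return self.domain[1] - self.domain[0]

    @property
    def height(self) -> float:
        return self.domain[3] - self.domain[2]

    @property
    def center(self) -> tuple[float, float]:
        return (0.5 * (self.domain[0] + self.domain[1]),
                0.5 * (self.domain[2] + self.domain[3]))

    def contains(self, uv: np.ndarray) -> np.ndarray:
        uv = np.atleast_2d(uv)
        u0, u1, v0, v1 = self.domain
        return ((uv[:, 0] >= u0) & (uv[:, 0] <= u1)
                & (uv[:, 1] >= v0) & (uv[:, 1] <= v1))

    def grid(self, step_mm: float) -> np.ndarray:
        """Regular (N, 2) sampling of the domain including both edges."""
        u0, u1, v0, v1 = self.domain
        u = np.linspace(u0, u1, max(int(round((u1 - u0) / step_mm)), 1) + 1)
        v = np.linspace(v0, v1, max(int(round((v1 - v0) / step_mm)), 1) + 1)
        uu, vv = np.meshgrid(u, v)
        return np.column_stack([uu.ravel(), vv.ravel()])


@dataclass
class GroundTruthStrain:
    """Exact strain of an analytic deformation at a set of material points."""

    principal_pct: np.ndarray      # 100 * (lambda_1 - 1)
    orthogonal_pct: np.ndarray     # 100 * (lambda_2 - 1)
    orientation_deg: np.ndarray    # principal direction in material plane, axial [0, 180)
    area_ratio: np.ndarray         # lambda_1 * lambda_2


def strain_from_jacobian(J: np.ndarray) -> GroundTruthStrain:
    """Membrane strain from the 3x2 Jacobian of a material->space map.

    The metric of the deformed surface is G = J^T J; relative to the flat
    reference (metric = I) the Green-Lagrange tensor is E = (G - I) / 2.
    """
    J = np.asarray(J, dtype=float)
    G = np.einsum("...ki,...kj->...ij", J, J)
    E = 0.5 * (G - np.eye(2))
    # closed-form symmetric 2x2 eigendecomposition
    exx, eyy, exy = E[..., 0, 0], E[..., 1, 1], E[..., 0, 1]
    mean = 0.5 * (exx + eyy)
    rad = np.sqrt((0.5 * (exx - eyy)) ** 2 + exy**2)
    e1, e2 = mean + rad, mean - rad
    lam1 = np.sqrt(np.maximum(1.0 + 2.0 * e1, 0.0))
    lam2 = np.sqrt(np.maximum(1.0 + 2.0 * e2, 0.0))
    theta = 0.5 * np.degrees(np.arctan2(2.0 * exy, exx - eyy))
    return GroundTruthStrain(
        principal_pct=100.0 * (lam1 - 1.0),
        orthogonal_pct=100.0 * (lam2 - 1.0),
        orientation_deg=np.mod(theta, 180.0),
        area_ratio=lam1 * lam2,
    )


@dataclass
class DeformationModel:
    """Analytic map from material coordinates to deformed 3-D positions.

    ``_map`` and ``_jac`` operate on (N, 2) arrays; an optional rigid motion
    (rotation + translation, applied after the deformation) never changes
    the ground-truth strain.
    """

    name: str
    _map: callable
    _jac: callable
    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def deform(self, uv: np.ndarray) -> np.ndarray:
        uv = np.atleast_2d(np.asarray(uv, dtype=float))
        xyz = self._map(uv)
        return xyz @ self.rotation.T + self.translation

    def jacobian(self, uv: np.ndarray) -> np.ndarray:
        uv = np.atleast_2d(np.asarray(uv, dtype=float))
        return np.einsum("ij,njk->nik", self.rotation, self._jac(uv))

    def ground_truth_strain(self, uv: np.ndarray) -> GroundTruthStrain:
        """Exact strain (rigid part drops out of the metric)."""
        uv = np.atleast_2d(np.asarray(uv, dtype=float))
        return strain_from_jacobian(self._jac(uv))

    def with_rigid(self, rotation: np.ndarray | None = None,
                   translation: np.ndarray | None = None) -> "DeformationModel":
        """Compose with a rigid motion applied after the deformation."""
        R = np.eye(3) if rotation is None else np.asarray(rotation, dtype=float)
        t = np.zeros(3) if translation is None else np.asarray(translation, dtype=float)
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-10) or np.linalg.det(R) < 0:
            raise ValueError("rotation must be a proper orthonormal matrix")
        return DeformationModel(
            name=self.name,
            _map=self._map,
            _jac=self._jac,
            rotation=R @ self.rotation,
            translation=R @ self.translation + t,
        )


def _flat_map(stretch_x):
    def f(uv):
        out = np.zeros((uv.shape[0], 3))
        out[:, 0] = stretch_x(uv[:, 0])
        out[:, 1] = uv[:, 1]
        return out
    return f


def identity_model() -> DeformationModel:
    """The undeformed flat embedding (u, v) -> (u, v, 0)."""
    return uniaxial_stretch(0.0)


def rigid_motion(rotation: np.ndarray | None = None,
                 translation: np.ndarray | None = None) -> DeformationModel:
    """Rigid repositioning of the flat patch; ground-truth stretch is 0%."""
    m = identity_model().with_rigid(rotation, translation)
    m.name = "rigid"
    return m


def uniaxial_stretch(magnitude: float) -> DeformationModel:
    """Uniform uniaxial stretch along u: (u, v) -> ((1+m) u, v, 0).

    Ground truth: principal stretch 100*m %, orthogonal 0%, orientation
    along u (0 deg).  ``magnitude`` must exceed -1.
    """
    if magnitude <= -1.0:
        raise ValueError("stretch magnitude must be > -1")
    m = float(magnitude)

    def jac(uv):
        J = np.zeros((uv.shape[0], 3, 2))
        J[:, 0, 0] = 1.0 + m
        J[:, 1, 1] = 1.0
        return J

    return DeformationModel(
        name=f"uniaxial_{m:g}",
        _map=_flat_map(lambda u: (1.0 + m) * u),
        _jac=jac,
    )


def ramp_stretch(gradient_pct_per_cm: float, start_pct: float = 0.0,
                 domain: tuple[float, float, float, float] | None = None,
                 ) -> DeformationModel:
    """Linearly ramped uniaxial stretch along u.

    Local engineering stretch is s(u) = start + gradient * u (gradient in
    percent per cm, u in mm), so the deformed position integrates to
    x(u) = u (1 + s0) + g u^2 / 2 with s0, g as fractions per mm.  If a
    material ``domain`` is given, the model checks that local stretch stays
    above -100% everywhere on it.
    """
    g = gradient_pct_per_cm / 1000.0   # fraction per mm
    s0 = start_pct / 100.0

    def local(u):
        return s0 + g * u

    if domain is not None:
        u0, u1 = domain[0], domain[1]
        if min(local(u0), local(u1)) <= -1.0:
            raise ValueError(
                "domain too large for gradient: local stretch reaches -100%")

    def mapped(u):
        if np.any(local(u) <= -1.0):
            raise ValueError("local stretch reaches -100% at evaluated points")
        return u * (1.0 + s0) + 0.5 * g * u**2

    def jac(uv):
        J = np.zeros((uv.shape[0], 3, 2))
        J[:, 0, 0] = 1.0 + local(uv[:, 0])
        J[:, 1, 1] = 1.0
        return J

    return DeformationModel(
        name=f"ramp_{gradient_pct_per_cm:g}",
        _map=_flat_map(mapped),
        _jac=jac,
    )


def bulge(amplitude_mm: float, radius_mm: float, sign: int = 1,
          center: tuple[float, float] = (0.0, 0.0),
          inplane_coupling: float = 0.2) -> DeformationModel:
    """Smooth radial out-of-plane bulge (sign=+1) or contraction (sign=-1).

    Inside ``radius_mm`` of ``center`` the patch is displaced out of plane
    by sign * amplitude * b(r), with the C^1 bump b(r) = (1 + cos(pi r/R))/2,
    and dilated in plane by a factor 1 + eta * b(r) with
    eta = sign * inplane_coupling * amplitude / radius.  An outward bulge
    therefore stretches the skin both radially and circumferentially near
    the apex (area ratio > 1, both principal and orthogonal stretch
    positive), while an inward contraction compresses it circumferentially
    (negative orthogonal stretch) -- the cheek puff vs. pout signature.
    """
    if radius_mm <= 0:
        raise ValueError("radius must be > 0")
    a, R = float(amplitude_mm), float(radius_mm)
    s = float(np.sign(sign) if sign != 0 else 1.0)
    eta = s * inplane_coupling * a / R
    cu, cv = center

    def bump(r):
        inside = r < R
        b = np.where(inside, 0.5 * (1.0 + np.cos(np.pi * np.minimum(r, R) / R)), 0.0)
        db = np.where(inside, -0.5 * np.pi / R * np.sin(np.pi * np.minimum(r, R) / R), 0.0)
        return b, db

    def mapping(uv):
        du, dv = uv[:, 0] - cu, uv[:, 1] - cv
        r = np.hypot(du, dv)
        b, _ = bump(r)
        out = np.empty((uv.shape[0], 3))
        out[:, 0] = cu + (1.0 + eta * b) * du
        out[:, 1] = cv + (1.0 + eta * b) * dv
        out[:, 2] = s * a * b
        return out

    def jac(uv):
        du, dv = uv[:, 0] - cu, uv[:, 1] - cv
        r = np.hypot(du, dv)
        b, db = bump(r)
        with np.errstate(invalid="ignore", divide="ignore"):
            ru = np.where(r > 0, du / r, 0.0)
            rv = np.where(r > 0, dv / r, 0.0)
        J = np.empty((uv.shape[0], 3, 2))
        J[:, 0, 0] = (1.0 + eta * b) + eta * db * ru * du
        J[:, 0, 1] = eta * db * rv * du
        J[:, 1, 0] = eta * db * ru * dv
        J[:, 1, 1] = (1.0 + eta * b) + eta * db * rv * dv
        J[:, 2, 0] = s * a * db * ru
        J[:, 2, 1] = s * a * db * rv
        return J

    return DeformationModel(name=f"bulge_{s * a:g}", _map=mapping, _jac=jac)


def rotation_about(axis: str | np.ndarray, degrees: float) -> np.ndarray:
    """Convenience rotation matrix, e.g. ``rotation_about('y', 15)``."""
    if isinstance(axis, str):
        return Rotation.from_euler(axis, degrees, degrees=True).as_matrix()
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    return Rotation.from_rotvec(np.radians(degrees) * axis).as_matrix()
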