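"""Render speckle-textured, analytically deformed surfaces through pinhole
cameras.

The renderer inverse-maps image pixels to material coordinates and samples
the speckle texture with bicubic interpolation — no lighting model, since
the emulated targets are high-contrast ink patterns on matte paper/skin.
The pixel->material map is also exposed directly (:class:`ViewGeometry`),
which is how synthetic experiments obtain exact ground truth for any
tracked image location.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import LinearNDInterpolator
from scipy.ndimage import map_coordinates

from .camera import CameraModel
from .deformation import DeformationModel, SurfacePatch
from .speckle import SpecklePattern

__all__ = ["EmptyViewError", "ViewGeometry", "render_view"]

BACKGROUND = 0.75


class EmptyViewError(RuntimeError):
    """The surface patch projects entirely outside the camera frustum."""


@dataclass
class ViewGeometry:
    """Invertible pixel<->material correspondence for one camera and pose.

    Built by sampling the material domain on a fine grid, deforming,
    projecting, and interpolating material coordinates as a piecewise
    linear function of pixel position (valid for the injective, mildly
    curved surfaces this package simulates).
    """

    camera: CameraModel
    surface: SurfacePatch
    model: DeformationModel
    grid_step_mm: float = 0.5

    def __post_init__(self) -> None:
        uv = self.surface.grid(self.grid_step_mm)
        xyz = self.model.deform(uv)
        px = self.camera.project(xyz)
        w, h = self.camera.image_size
        margin = 2.0
        inside = ((px[:, 0] >= -margin) & (px[:, 0] <= w - 1 + margin)
                  & (px[:, 1] >= -margin) & (px[:, 1] <= h - 1 + margin))
        if not np.any(inside):
            raise EmptyViewError("surface patch projects outside the image")
        self._interp = LinearNDInterpolator(px, uv, fill_value=np.nan)
        self._px_bounds = (px[:, 0].min(), px[:, 0].max(),
                           px[:, 1].min(), px[:, 1].max())

    def material_at(self, pixels: np.ndarray) -> np.ndarray:
        """Pixel coordinates (N, 2) -> material (u, v); NaN outside patch."""
        return self._interp(np.atleast_2d(pixels))

    def project_material(self, uv: np.ndarray) -> np.ndarray:
        return self.camera.project(self.model.deform(uv))


def render_view(surface: SurfacePatch, texture: SpecklePattern,
                model: DeformationModel, camera: CameraModel,
                noise_sd: float = 0.0, seed: int | None = None,
                grid_step_mm: float = 0.5,
                geometry: ViewGeometry | None = None) -> np.ndarray:
    """Render one camera view of the deformed, textured patch.

    Returns a float image in [0, 1] of the camera's size.  Pixels off the
    patch take a uniform background value; optional additive Gaussian
    intensity noise (sd in intensity units) is seeded and clipped to [0, 1].
    """
    geom = geometry or ViewGeometry(camera, surface, model, grid_step_mm)
    w, h = camera.image_size
    x0 = max(int(np.floor(geom._px_bounds[0])) - 1, 0)
    x1 = min(int(np.ceil(geom._px_bounds[1])) + 2, w)
    y0 = max(int(np.floor(geom._px_bounds[2])) - 1, 0)
    y1 = min(int(np.ceil(geom._px_bounds[3])) + 2, h)

    image = np.full((h, w), BACKGROUND, dtype=np.float64)
    xx, yy = np.meshgrid(np.arange(x0, x1, dtype=float),
                         np.arange(y0, y1, dtype=float))
    uv = geom.material_at(np.column_stack([xx.ravel(), yy.ravel()]))
    valid = ~np.isnan(uv[:, 0])
    if np.any(valid):
        row, col = texture.sample_coords(uv[valid, 0], uv[valid, 1])
        samples = map_coordinates(texture.image, [row, col], order=3,
                                  mode="constant", cval=1.0)
        block = np.full(xx.size, BACKGROUND)
        block[valid] = np.clip(samples, 0.0, 1.0)
        image[y0:y1, x0:x1] = block.reshape(xx.shape)

    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        image = np.clip(image + rng.normal(0.0, noise_sd, image.shape), 0.0, 1.0)
    return image
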