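"""Random speckle-pattern synthesis.

Emulates the ink speckle patterns used for optical skin-strain tracking:
dark dots stamped on a light background, characterised by a nominal dot
diameter, a target ink-covered area fraction (dot density) and a per-dot
diameter jitter (dot variation).  Patterns are rendered as physically
scaled grayscale rasters (pixels-per-mm known) so the same texture can be
viewed through any simulated camera.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SpeckleParams",
    "SpecklePattern",
    "UnreachableDensityError",
    "generate_speckle",
    "measure_ink_fraction",
]

# Overlapping-dot coverage saturates at 1 - exp(-lambda) for mean dot
# intensity lambda; we cap lambda at 2.2 (coverage ~0.89), beyond which the
# ink merges into solid regions that defeat patch matching.
_MAX_INTENSITY = 2.2
_INK_THRESHOLD = 0.5


class UnreachableDensityError(ValueError):
    """Requested ink density cannot be reached by overlapping-dot sampling."""


@dataclass(frozen=True)
class SpeckleParams:
    """Parameters of an ink speckle pattern.

    Attributes
    ----------
    dot_diameter : float
        Nominal dot diameter in mm (the stamped patterns use 1.27 mm).
    dot_density : float
        Target ink-covered area fraction in (0, 1); 0.65 in the study.
    dot_variation : float
        Per-dot diameter jitter fraction in [0, 1]: each dot's diameter is
        drawn uniformly from ``dot_diameter * [1 - variation, 1]``.
    canvas_size : tuple[float, float]
        Pattern width x height in mm.
    raster_scale : float
        Rendering resolution in pixels per mm.
    seed : int
        Seed for the dot-placement stream; identical params + seed give a
        bit-identical raster.
    """

    dot_diameter: float = 1.27
    dot_density: float = 0.65
    dot_variation: float = 0.75
    canvas_size: tuple[float, float] = (64.0, 48.0)
    raster_scale: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dot_diameter <= 0:
            raise ValueError("dot_diameter must be > 0")
        if not 0 < self.dot_density < 1:
            raise ValueError("dot_density must lie in (0, 1)")
        if not 0 <= self.dot_variation <= 1:
            raise ValueError("dot_variation must lie in [0, 1]")
        if self.raster_scale <= 0:
            raise ValueError("raster_scale must be > 0")
        if min(self.canvas_size) <= 0:
            raise ValueError("canvas_size must be positive")


@dataclass
class SpecklePattern:
    """A rendered speckle raster with physical scale.

    ``image`` is float grayscale in [0, 1] (1 = paper white, 0 = ink),
    indexed [row, col] = [y, x].  ``origin`` is the material (u, v)
    coordinate, in mm, of the centre of pixel (0, 0).
    """

    image: np.ndarray
    scale: float
    origin: tuple[float, float] = (0.0, 0.0)
    params: SpeckleParams | None = None
    n_dots: int = 0
    ink_fraction: float = field(default=0.0)

    @property
    def size_mm(self) -> tuple[float, float]:
        h, w = self.image.shape
        return (w / self.scale, h / self.scale)

    def sample_coords(self, u: np.ndarray, v: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Material (u, v) mm -> fractional raster (row, col) coordinates."""
        col = (np.asarray(u) - self.origin[0]) * self.scale
        row = (np.asarray(v) - self.origin[1]) * self.scale
        return row, col


def measure_ink_fraction(image: np.ndarray, threshold: float = _INK_THRESHOLD) -> float:
    """Fraction of pixels darker than ``threshold`` (ink-covered)."""
    return float(np.mean(np.asarray(image) < threshold))


def _stamp_dots(image: np.ndarray, xy_px: np.ndarray, radii_px: np.ndarray) -> None:
    """Anti-aliased accumulation of dark circular dots into ``image`` in place.

    Per-pixel ink coverage uses a linear edge ramp one pixel wide around the
    circle boundary; overlapping dots combine by maximum coverage.
    """
    h, w = image.shape
    for (cx, cy), r in zip(xy_px, radii_px):
        x0 = max(int(np.floor(cx - r - 1)), 0)
        x1 = min(int(np.ceil(cx + r + 2)), w)
        y0 = max(int(np.floor(cy - r - 1)), 0)
        y1 = min(int(np.ceil(cy + r + 2)), h)
        if x0 >= x1 or y0 >= y1:
            continue
        yy, xx = np.mgrid[y0:y1, x0:x1]
        dist = np.hypot(xx - cx, yy - cy)
        cov = np.clip(r - dist + 0.5, 0.0, 1.0)
        patch = image[y0:y1, x0:x1]
        np.minimum(patch, 1.0 - cov, out=patch)


def generate_speckle(params: SpeckleParams) -> SpecklePattern:
    """Generate a seeded random speckle pattern.

    Dots are placed by seeded rejection-free sampling (overlap allowed) in
    batches until the measured ink fraction reaches ``dot_density``; the
    realised fraction is measured post hoc on the raster.  Densities at or
    above ~0.9 are unreachable before ink saturation and raise
    :class:`UnreachableDensityError`.
    """
    w_mm, h_mm = params.canvas_size
    scale = params.raster_scale
    w_px, h_px = int(round(w_mm * scale)), int(round(h_mm * scale))
    image = np.ones((h_px, w_px), dtype=np.float64)

    rng = np.random.default_rng(params.seed)
    # E[d^2] for d ~ U[(1-v) D, D] -- the quantity controlling coverage
    v = params.dot_variation
    mean_sq_diam = params.dot_diameter**2 * (1 + (1 - v) + (1 - v) ** 2) / 3.0
    mean_dot_area = np.pi / 4.0 * mean_sq_diam * scale**2
    # expected dot count to first reach the target under Poisson overlap
    lam_target = -np.log1p(-min(params.dot_density, 0.999))
    n_expected = max(int(lam_target * w_px * h_px / mean_dot_area), 1)
    n_cap = max(int(_MAX_INTENSITY * w_px * h_px / mean_dot_area), n_expected + 1)
    batch = max(n_expected // 20, 1)

    n_dots = 0
    frac = 0.0
    while frac < params.dot_density:
        if n_dots >= n_cap:
            raise UnreachableDensityError(
                f"ink fraction saturated at {frac:.3f} after {n_dots} dots; "
                f"requested density {params.dot_density} is unreachable"
            )
        n = min(batch, n_cap - n_dots)
        xy = rng.uniform([0, 0], [w_px, h_px], size=(n, 2))
        diam = params.dot_diameter * rng.uniform(1.0 - params.dot_variation, 1.0, size=n)
        _stamp_dots(image, xy, diam * scale / 2.0)
        n_dots += n
        frac = measure_ink_fraction(image)

    return SpecklePattern(
        image=image, scale=scale, origin=(0.0, 0.0), params=params,
        n_dots=n_dots, ink_fraction=frac,
    )


def single_dot_pattern(params: SpeckleParams) -> SpecklePattern:
    """Degenerate pattern with exactly one centred dot (density -> 0 limit)."""
    w_mm, h_mm = params.canvas_size
    scale = params.raster_scale
    w_px, h_px = int(round(w_mm * scale)), int(round(h_mm * scale))
    image = np.ones((h_px, w_px), dtype=np.float64)
    _stamp_dots(
        image,
        np.array([[w_px / 2.0, h_px / 2.0]]),
        np.array([params.dot_diameter * scale / 2.0]),
    )
    return SpecklePattern(image=image, scale=scale, params=params, n_dots=1,
                          ink_fraction=measure_ink_fraction(image))
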