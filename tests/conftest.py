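"""Shared fixtures: small synthetic scenes sized for fast unit tests.

Full desk-scale accuracy runs live in test_acceptance; everything else
uses a reduced patch (30 x 22 mm, 420 x 320 px images) that exercises the
identical code paths in a few seconds.
"""

from __future__ import annotations

import numpy as np
import pytest

from dermastretch.deformation import SurfacePatch, identity_model
from dermastretch.pipeline import RunConfig, run_pipeline
from dermastretch.render import render_view
from dermastretch.speckle import SpeckleParams, generate_speckle


def small_config(**overrides) -> RunConfig:
    base = dict(patch_mm=(30.0, 22.0), image_size=(420, 320),
                subset_radius=15, subset_spacing=8, fine_search=8, seed=1)
    base.update(overrides)
    return RunConfig(**base)


@pytest.fixture(scope="session")
def small_identity_run():
    return run_pipeline(small_config(preset="identity"))


@pytest.fixture(scope="session")
def small_stretch_run():
    return run_pipeline(small_config(preset="uniaxial_33"))


@pytest.fixture(scope="session")
def speckle_small():
    return generate_speckle(SpeckleParams(canvas_size=(30.0, 24.0), seed=5))


@pytest.fixture(scope="session")
def flat_scene_pair():
    """Two noiseless renders of the same flat patch from one camera."""
    cfg = small_config()
    surf = SurfacePatch((-15, 15, -11, 11))
    tex = generate_speckle(SpeckleParams(canvas_size=(34, 26), seed=2))
    tex.origin = (-17.0, -13.0)
    cam = cfg.cameras()[0]
    img = render_view(surf, tex, identity_model(), cam)
    return img, surf, tex, cam
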