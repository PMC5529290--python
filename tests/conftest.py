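"""Shared fixtures: small rendered scenes reused across the suite.

All test inputs are generated programmatically; the default test frame is
128×128×48 voxels at 0.06/0.06/0.18 μm (same voxel geometry as the full
imaging frame, trimmed laterally so the whole suite stays fast).
"""

from __future__ import annotations

import logging

import numpy as np
import pytest

from ttvsa import (
    CellGeometry,
    PhantomSpec,
    PSFSpec,
    Tubule,
    render_halfspace_calibration,
    render_phantom,
)
from ttvsa.preprocess import normalize_pair
from ttvsa.segmentation import build_masks

logging.disable(logging.INFO)

VOXEL_UM = (0.18, 0.06, 0.06)
SHAPE = (48, 128, 128)
RAW_PSF = PSFSpec(fwhm_x=0.25, fwhm_y=0.25, fwhm_z=0.6, state="raw")


def straight_tubule(diameter_um: float, orient: str = "y", ellipticity: float = 1.0) -> Tubule:
    """A straight tubule well inside the default cell (surface at x = 1.53 μm)."""
    if orient == "y":  # transverse plane (here: the cell's long axis is y... see spec)
        pts = [[4.33, 1.0, 4.53], [4.33, 6.7, 4.53]]
    elif orient == "z":
        pts = [[1.0, 3.84, 4.53], [7.6, 3.84, 4.53]]
    elif orient == "x":
        pts = [[4.33, 3.84, 2.6], [4.33, 3.84, 7.3]]
    else:
        raise ValueError(orient)
    return Tubule(points_um=pts, diameter_um=diameter_um, ellipticity=ellipticity)


def make_scene(tubules, noise: str = "none", seed: int = 0, **cell_kwargs) -> PhantomSpec:
    cell = CellGeometry(axis="x", surface_um=1.53, long_axis="y", **cell_kwargs)
    return PhantomSpec(
        shape=SHAPE, voxel_um=VOXEL_UM, cell=cell, tubules=tubules, noise=noise, seed=seed
    )


@pytest.fixture(scope="session")
def raw_psf() -> PSFSpec:
    return RAW_PSF


@pytest.fixture(scope="session")
def tubule_scene(raw_psf):
    """Rendered D = 0.3 μm tubule scene: (membrane, volume, truth, spec)."""
    spec = make_scene([straight_tubule(0.3)])
    membrane, volume, truth = render_phantom(spec, raw_psf)
    return membrane, volume, truth, spec


@pytest.fixture(scope="session")
def tubule_masks(tubule_scene, raw_psf):
    membrane, volume, _, _ = tubule_scene
    return build_masks(membrane, volume, raw_psf)


@pytest.fixture(scope="session")
def tubule_pair(tubule_scene, tubule_masks, raw_psf):
    membrane, volume, _, _ = tubule_scene
    return normalize_pair(volume, membrane, tubule_masks, raw_psf)


@pytest.fixture(scope="session")
def halfspace(raw_psf):
    """Flat-interface calibration scene: (membrane, volume, masks, pair)."""
    membrane, volume = render_halfspace_calibration(raw_psf)
    masks = build_masks(membrane, volume, raw_psf)
    pair = normalize_pair(volume, membrane, masks, raw_psf)
    return membrane, volume, masks, pair
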