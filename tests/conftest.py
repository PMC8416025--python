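"""Shared fixtures: small synthetic scenes generated once per session."""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from mtquant.simgen import SceneSpec, simulate_scene

# STED-like acquisition defaults used across the suite
STED = dict(
    psf_sigma_lateral=0.03,
    psf_sigma_axial=0.25,
    voxel_size=(0.04, 0.04, 0.15),
    filament_photons=20000.0,
    background_level=10.0,
)

# ExM/FlipExM-like acquisition (isotropic voxels on a 4.15x expanded gel)
FLIPEXM = dict(
    psf_sigma_lateral=0.10,
    psf_sigma_axial=0.30,
    voxel_size=(0.06, 0.06, 0.06),
    expansion_factor=4.15,
    filament_photons=40000.0,
    background_level=5.0,
)


@pytest.fixture(scope="session")
def soma_scene():
    """A calibration-grade soma sheet with bundles and crosstalk."""
    spec = SceneSpec(
        scene_kind="soma_sheet",
        n_microtubules=200,
        sheet_size=25.0,
        bundle_fraction=0.2,
        true_alpha=0.53,
        true_beta=0.45,
        fraction_acetylated=0.5,
        fraction_tyrosinated=0.5,
        fraction_other=0.0,
        noise_model="poisson",
        seed=7,
        **STED,
    )
    return spec, *simulate_scene(spec)


@pytest.fixture(scope="session")
def soma_calibration_result(soma_scene):
    from mtquant.pipeline import soma_calibration

    _, stack, _ = soma_scene
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return soma_calibration(stack)


@pytest.fixture(scope="session")
def flipped_dendrite_scene():
    """30-microtubule flipped dendrite for cross-section counting."""
    spec = SceneSpec(
        scene_kind="dendrite",
        orientation="flipped",
        dendrite_diameter=1.0,
        dendrite_length=4.0,
        n_microtubules=30,
        fraction_acetylated=22 / 30,
        fraction_tyrosinated=7 / 30,
        fraction_other=1 / 30,
        true_alpha=0.45,
        true_beta=0.60,
        radial_bias=0.3,
        noise_model="poisson",
        seed=5,
        **FLIPEXM,
    )
    return spec, *simulate_scene(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def disk_image(n: int = 101, radius: float = 30.0, value: float = 100.0,
               center: tuple[float, float] | None = None) -> np.ndarray:
    cy, cx = center or (n // 2, n // 2)
    ys, xs = np.mgrid[0:n, 0:n]
    return (np.hypot(xs - cx, ys - cy) <= radius).astype(float) * value


def circle_contour(radius: float, center: tuple[float, float],
                   n_pts: int = 64):
    """ClosedContour for an exact circle (bypasses boundary detection)."""
    from mtquant.radial import ClosedContour

    t = np.linspace(0, 2 * np.pi, n_pts, endpoint=False)
    poly = np.column_stack([
        center[0] + radius * np.cos(t),
        center[1] + radius * np.sin(t),
    ])
    return ClosedContour(anchors=poly[:: n_pts // 8], polygon=poly)
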